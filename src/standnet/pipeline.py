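"""End-to-end orchestration: generate -> sqi -> diversity -> network -> linkage.

A single :class:`PipelineConfig` carries all thresholds (defaults equal the
analysis' stated values) and one global seed. Stage seeds derive from the
global seed by fixed offsets (documented on ``stage_seed``) so a stage
re-run in isolation reproduces its in-pipeline output.

Network usage: one co-occurrence network per stand type (pooled bacteria +
fungi) supplies the topology panel, robustness, and Zi-Pi roles; the
keystone set for the linkage stage is the union of keystones over the
three stand networks. Per-sample complexity comes from a pooled all-sample
network so sub-network z-scores are comparable across stands.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from standnet import community, io, linkage, network, soil_quality, synthetic
from standnet.tables import STAND_COLUMN, combine_domains

_STAGE_OFFSETS = {
    "generate": 0,
    "anosim": 11,
    "modularity": 21,
    "robustness": 31,
}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: global seed + a fixed stage offset (kept < 2^31)."""
    return (seed + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds.

    If ``soil_path``/``bacteria_path``/``fungi_path`` are unset, the
    synthetic generator supplies the tables.
    """

    output_dir: str = "results/pipeline"
    seed: int = 0
    soil_path: str | None = None
    bacteria_path: str | None = None
    fungi_path: str | None = None
    # MDS / SQI
    eig_min: float = 1.0
    loading_band: float = 0.10
    corr_cut: float = 0.7
    directions: dict = field(default_factory=dict)
    # network
    min_occurrence_fraction: float = 1.0 / 5.0
    min_mean_relative_abundance: float = 0.0001
    r_threshold: float = 0.7
    edge_alpha: float = 0.05
    use_adjusted_p: bool = True
    attack_strategy: str = "random"
    removal_fraction: float = 0.5
    n_robustness_replicates: int = 100
    # diversity
    n_permutations: int = 999
    diversity_metric: str = "shannon"  # or "chao1"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest of produced artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save(writer, obj, name: str) -> Path:
        path = out / name
        writer(obj, path)
        files.append(path)
        return path

    # ---- stage 1: input tables -------------------------------------------
    design = synthetic.StandDesign(seed=stage_seed(config.seed, "generate"))
    if config.soil_path:
        soil = io.read_soil_table(config.soil_path)
    else:
        soil = synthetic.generate_soil_table(design)
    if config.bacteria_path and config.fungi_path:
        bacteria = io.read_abundance_table(config.bacteria_path)
        fungi = io.read_abundance_table(config.fungi_path)
    else:
        bacteria, fungi = synthetic.generate_abundance_tables(design)
    save(io.write_soil_table, soil, "soil_table.tsv")
    save(io.write_abundance_table, bacteria, "bacteria.tsv")
    save(io.write_abundance_table, fungi, "fungi.tsv")

    # ---- stage 2: soil quality index -------------------------------------
    mds, sqires = soil_quality.sqi_pipeline(
        soil,
        directions=config.directions or None,
        eig_min=config.eig_min,
        loading_band=config.loading_band,
        corr_cut=config.corr_cut,
    )
    sqi_table = sqires.snl.copy()
    sqi_table["SQI"] = sqires.sqi
    sqi_table[STAND_COLUMN] = soil[STAND_COLUMN]
    save(lambda df, p: df.to_csv(p, sep="\t", index_label="sample_id"),
         sqi_table, "sqi_per_sample.tsv")
    stand_sqi = {
        s: sqires.sqi[soil[STAND_COLUMN] == s].to_numpy()
        for s in design.stand_labels
    }
    sqi_anova = community.group_compare(stand_sqi)
    save(io.write_json, {
        "selected": mds.selected,
        "weights": sqires.weights.to_dict(),
        "eigenvalues": mds.eigenvalues,
        "screening_trace": mds.trace,
        "group_stats": sqires.group_stats.to_dict(),
        "anova_f": sqi_anova.f_statistic,
        "anova_p": sqi_anova.p_value,
        "tukey_letters": sqi_anova.letters,
    }, "sqi_report.json")

    # ---- stage 3: diversity ----------------------------------------------
    stands = soil[STAND_COLUMN]
    diversity: dict[str, pd.DataFrame] = {}
    anosim_results = {}
    for table in (bacteria, fungi):
        div = community.alpha_diversity(table)
        diversity[table.domain] = div
        save(lambda df, p: df.to_csv(p, sep="\t", index_label="sample_id"),
             div, f"diversity_{table.domain}.tsv")
        dist = community.bray_curtis_matrix(table.counts)
        ord_res = community.pcoa(dist, n_axes=2)
        save(lambda df, p: df.to_csv(p, sep="\t", index_label="sample_id"),
             ord_res.coordinates, f"pcoa_{table.domain}.tsv")
        an = community.anosim(
            dist,
            stands.loc[dist.index].to_numpy(),
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "anosim"),
        )
        anosim_results[table.domain] = {
            "R": an.r,
            "p": an.p_value,
            "n_permutations": an.n_permutations,
            "percent_explained_axis1": float(ord_res.percent_explained[0]),
            "percent_explained_axis2": float(ord_res.percent_explained[1]),
        }
    save(io.write_json, anosim_results, "anosim.json")

    # ---- stage 4: co-occurrence networks ---------------------------------
    combined = combine_domains(bacteria, fungi)
    filter_policy = network.FilterPolicy(
        min_occurrence_fraction=config.min_occurrence_fraction,
        min_mean_relative_abundance=config.min_mean_relative_abundance,
    )
    edge_policy = network.EdgePolicy(
        r_threshold=config.r_threshold,
        alpha=config.edge_alpha,
        use_adjusted=config.use_adjusted_p,
    )
    topo_panel = {}
    keystone_union: set[str] = set()
    mod_seed = stage_seed(config.seed, "modularity")
    rob_seed = stage_seed(config.seed, "robustness")
    for stand in design.stand_labels:
        sub = combined.subset_samples(stands.index[stands == stand])
        net = network.build_network(sub, filter_policy, edge_policy, stand=stand)
        topo = network.topology(net, seed=mod_seed)
        roles = network.zipi(net.graph, topo.modules)
        keystone_union |= set(roles.index[roles["role"].isin(network.KEYSTONE_ROLES)])
        rob_random = network.robustness(
            net, "random", config.removal_fraction,
            config.n_robustness_replicates, seed=rob_seed, roles=roles,
        )
        rob_hubs = network.robustness(
            net, "hubs", config.removal_fraction,
            config.n_robustness_replicates, seed=rob_seed, roles=roles,
        )
        topo_panel[stand] = {
            **topo.as_dict(),
            "robustness_random_50pct": float(rob_random.mean_remaining[0]),
            "robustness_hubs_50pct": float(rob_hubs.mean_remaining[0]),
            "n_keystones": int(roles["role"].isin(network.KEYSTONE_ROLES).sum()),
        }
        topo_panel[stand].pop("Connected")
        save(io.write_edge_list, net.graph, f"network_{stand}_edges.tsv")
        save(io.write_graphml, net.graph, f"network_{stand}.graphml")
        save(lambda df, p: df.to_csv(p, sep="\t", index_label="node"),
             roles, f"node_roles_{stand}.tsv")
    save(io.write_json, topo_panel, "network_topology.json")

    pooled_net = network.build_network(
        combined, filter_policy, edge_policy, stand="all"
    )
    complexity = network.subnetwork_complexity(pooled_net, combined)
    pooled_roles = pd.DataFrame(
        {"role": ["connector"] * len(keystone_union)},
        index=sorted(keystone_union),
    )
    keystone = network.keystone_abundance(combined, pooled_roles)
    save(lambda s, p: s.to_frame().to_csv(p, sep="\t", index_label="sample_id"),
         complexity, "complexity_per_sample.tsv")
    save(lambda s, p: s.to_frame().to_csv(p, sep="\t", index_label="sample_id"),
         keystone, "keystone_abundance_per_sample.tsv")

    # ---- stage 5: linkage -------------------------------------------------
    metric = config.diversity_metric
    report = linkage.linkage_report(
        sqires.sqi,
        diversity["bacteria"][metric],
        diversity["fungi"][metric],
        complexity,
        keystone,
    )
    save(lambda df, p: df.to_csv(p, sep="\t"), report, "linkage_report.tsv")

    manifest = {
        "seed": config.seed,
        "stage_seeds": {k: stage_seed(config.seed, k) for k in _STAGE_OFFSETS},
        "files": {str(p.relative_to(out)): _checksum(p) for p in files},
        "mds_selected": mds.selected,
        "anosim": anosim_results,
        "sqi_group_means": sqires.group_stats["mean"].to_dict(),
        "linkage": report["r_squared"].to_dict(),
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
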