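"""Stand-wise co-occurrence networks: topology, keystones, robustness.

One pooled bacteria+fungi network per stand type (occurrence > 1/5 of
samples, mean relative abundance > 0.01%, Spearman |r| > 0.7 with BH
q < 0.05). Reports the topology panel per stand, Zi-Pi keystone counts,
and robustness after 50% node removal (random and module-hubs-first), plus
the pooled-network per-sample complexity used by the linkage stage.

Reads results/data/; writes results/network/.
"""

import warnings
from pathlib import Path

import pandas as pd

from standnet import io, network
from standnet.tables import combine_domains

DATA = Path("results/data")
OUT = Path("results/network")
SEED = 1


def main() -> None:
    warnings.filterwarnings("ignore", message="no edges")
    OUT.mkdir(parents=True, exist_ok=True)
    bacteria = io.read_abundance_table(DATA / "bacteria.tsv")
    fungi = io.read_abundance_table(DATA / "fungi.tsv")
    combined = combine_domains(bacteria, fungi)
    stands = combined.metadata["stand"]

    panel = {}
    keystone_union: set[str] = set()
    for stand in ("LF", "MF", "BF"):
        sub = combined.subset_samples(stands.index[stands == stand])
        net = network.build_network(sub, stand=stand)
        topo = network.topology(net, seed=SEED)
        roles = network.zipi(net.graph, topo.modules)
        keystones = roles.index[roles["role"].isin(network.KEYSTONE_ROLES)]
        keystone_union |= set(keystones)
        rob_rand = network.robustness(net, "random", 0.5, 100, seed=SEED, roles=roles)
        rob_hubs = network.robustness(net, "hubs", 0.5, 100, seed=SEED, roles=roles)

        io.write_edge_list(net.graph, OUT / f"edges_{stand}.tsv")
        roles.to_csv(OUT / f"node_roles_{stand}.tsv", sep="\t", index_label="node")
        panel[stand] = {
            **topo.as_dict(),
            "Keystone taxa": len(keystones),
            "Robustness (random, 50%)": round(float(rob_rand.mean_remaining[0]), 3),
            "Robustness (hubs first, 50%)": round(float(rob_hubs.mean_remaining[0]), 3),
        }

    table = pd.DataFrame(panel).round(3)
    table.to_csv(OUT / "topology_by_stand.tsv", sep="\t",
                 index_label="topological_property")
    print("topological characteristics by stand type:")
    print(table.to_string())

    pooled = network.build_network(combined, stand="all")
    complexity = network.subnetwork_complexity(pooled, combined)
    complexity.to_frame().to_csv(
        OUT / "complexity_per_sample.tsv", sep="\t", index_label="sample_id"
    )
    roles_union = pd.DataFrame(
        {"role": ["connector"] * len(keystone_union)}, index=sorted(keystone_union)
    )
    keystone = network.keystone_abundance(combined, roles_union)
    keystone.to_frame().to_csv(
        OUT / "keystone_abundance_per_sample.tsv", sep="\t",
        index_label="sample_id",
    )
    print(f"\npooled network: {pooled.graph.number_of_nodes()} nodes, "
          f"{pooled.graph.number_of_edges()} edges; "
          f"keystone union across stands: {len(keystone_union)} ASVs")
    by_stand = complexity.groupby(stands).mean().round(3)
    print(f"mean per-sample complexity by stand: {by_stand.to_dict()}")


if __name__ == "__main__":
    main()
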