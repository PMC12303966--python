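"""Co-occurrence networks: construction, topology, robustness, keystones.

Networks are built per stand type from the pooled bacterial + fungal ASV
table. ASVs must occur in more than 1/5 of the stand's samples and exceed
0.01% mean relative abundance; edges are Spearman correlations with
|r| > 0.7 whose Benjamini-Hochberg-adjusted p-value is below 0.05.

Downstream analyses:

* a topology panel (nodes, edges, % negative edges, diameter, density,
  average degree, average path length, clustering, modularity) matching the
  standard descriptors for microbial networks;
* per-sample sub-network complexity: the induced subgraph on the ASVs
  present in a sample is summarized by a parameter panel, each parameter
  z-scored across samples, and the z-scores averaged;
* robustness: the proportion of species that retain at least one edge after
  removing a fraction of nodes (at random, or module hubs first);
* Zi-Pi node roles: within-module degree z-score (Zi) and participation
  coefficient (Pi), with module hubs (Zi >= 2.5, Pi < 0.62), connectors
  (Zi < 2.5, Pi >= 0.62) and network hubs (Zi >= 2.5, Pi >= 0.62)
  together forming the keystone set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from standnet.tables import AbundanceTable

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

KEYSTONE_ROLES = ("module hub", "connector", "network hub")


@dataclass(frozen=True)
class FilterPolicy:
    """Prevalence and abundance filters applied before correlation."""

    min_occurrence_fraction: float = 1.0 / 5.0
    min_mean_relative_abundance: float = 0.0001  # 0.01%

    def __post_init__(self) -> None:
        if not 0 < self.min_occurrence_fraction < 1:
            raise ValueError("occurrence fraction must be in (0, 1)")
        if not 0 < self.min_mean_relative_abundance < 1:
            raise ValueError("abundance threshold must be in (0, 1)")


@dataclass(frozen=True)
class EdgePolicy:
    """Edge-calling thresholds for Spearman co-occurrence."""

    r_threshold: float = 0.7
    alpha: float = 0.05
    use_adjusted: bool = True  # BH-adjusted q < alpha; raw p if False

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r threshold must be in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class CooccurrenceNetwork:
    """Undirected signed co-occurrence graph over retained ASVs.

    ``graph`` holds only nodes with at least one edge; ``n_candidates`` is
    the number of ASVs that survived filtering before isolate removal.
    """

    graph: nx.Graph
    stand: str = ""
    n_candidates: int = 0


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    percent_negative_edges: float
    diameter: float
    density: float
    average_degree: float
    average_path_length: float
    average_clustering: float
    modularity: float
    modules: dict = field(default_factory=dict)  # node -> module id
    connected: bool = True

    def as_dict(self) -> dict:
        return {
            "Number of nodes": self.n_nodes,
            "Number of edges": self.n_edges,
            "Negative edges (%)": self.percent_negative_edges,
            "Network diameter": self.diameter,
            "Graph density": self.density,
            "Average degree": self.average_degree,
            "Average path length": self.average_path_length,
            "Average clustering coefficient": self.average_clustering,
            "Modularity": self.modularity,
            "Connected": self.connected,
        }


@dataclass
class RobustnessCurve:
    strategy: str
    fractions: np.ndarray
    mean_remaining: np.ndarray
    sd_remaining: np.ndarray
    n_replicates: int
    seed: int | None


def filter_asvs(table: AbundanceTable, policy: FilterPolicy | None = None) -> AbundanceTable:
    """Keep ASVs above the occurrence and mean-relative-abundance bars.

    Occurrence must strictly exceed ``min_occurrence_fraction`` of samples
    and mean relative abundance must strictly exceed
    ``min_mean_relative_abundance``. Column order is preserved.
    """
    if policy is None:
        policy = FilterPolicy()
    if table.counts.empty:
        raise ValueError("empty abundance table")
    n_samples = len(table.counts)
    occurrence = (table.counts > 0).sum(axis=0)
    mean_rel = table.relative_abundance().mean(axis=0)
    keep = (occurrence > policy.min_occurrence_fraction * n_samples) & (
        mean_rel > policy.min_mean_relative_abundance
    )
    if not keep.any():
        raise ValueError(
            "no ASVs pass the occurrence/abundance filters; relax the policy"
        )
    return table.subset_asvs(table.counts.columns[keep])


def spearman_edges(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlations and two-sided p-values.

    Average ranks on ties; p from the t approximation. Pairs involving a
    constant ASV get NaN and are excluded from edge calling.
    """
    if len(counts) < 4:
        raise ValueError("need at least 4 samples for correlation")
    x = counts.to_numpy(dtype=float)
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant ASVs excluded from edge calling",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on constant columns
        r, p = stats.spearmanr(x)
    if x.shape[1] == 2:  # scipy returns scalars for a single pair
        r = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    else:
        r = np.atleast_2d(r)
        p = np.atleast_2d(p)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(r, np.nan)
    np.fill_diagonal(p, np.nan)
    ids = counts.columns
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    table: AbundanceTable,
    filter_policy: FilterPolicy | None = None,
    edge_policy: EdgePolicy | None = None,
    stand: str = "",
    prefiltered: bool = False,
) -> CooccurrenceNetwork:
    """Filter, correlate, FDR-adjust, and threshold into a network.

    Isolated nodes are dropped from the graph; the pre-drop candidate count
    is recorded on the result. Node attributes: domain inferred from the
    ASV id prefix where possible, taxonomy, mean relative abundance. Edge
    attributes: r, p, q, sign.
    """
    if edge_policy is None:
        edge_policy = EdgePolicy()
    filtered = table if prefiltered else filter_asvs(table, filter_policy)
    r_mat, p_mat = spearman_edges(filtered.counts)
    ids = list(filtered.counts.columns)
    iu, ju = np.triu_indices(len(ids), k=1)
    r_flat = r_mat.to_numpy()[iu, ju]
    p_flat = p_mat.to_numpy()[iu, ju]
    valid = ~np.isnan(p_flat)
    q_flat = np.full_like(p_flat, np.nan)
    if valid.any():
        q_flat[valid] = bh_adjust(p_flat[valid])

    sig = q_flat if edge_policy.use_adjusted else p_flat
    edge_mask = valid & (np.abs(r_flat) > edge_policy.r_threshold) & (
        sig < edge_policy.alpha
    )

    mean_rel = filtered.relative_abundance().mean(axis=0)
    g = nx.Graph()
    for i, j, r, p, q in zip(
        iu[edge_mask], ju[edge_mask], r_flat[edge_mask], p_flat[edge_mask], q_flat[edge_mask]
    ):
        g.add_edge(
            ids[i],
            ids[j],
            r=float(r),
            p=float(p),
            q=float(q),
            sign=1 if r > 0 else -1,
        )
    for node in g.nodes:
        g.nodes[node]["taxonomy"] = str(filtered.taxonomy.get(node, "Unassigned"))
        g.nodes[node]["mean_relative_abundance"] = float(mean_rel[node])
        g.nodes[node]["domain"] = (
            "bacteria" if node.startswith("B") else
            "fungi" if node.startswith("F") else table.domain
        )
    if g.number_of_edges() == 0:
        warnings.warn("no edges pass the thresholds; network is empty", stacklevel=2)
    return CooccurrenceNetwork(graph=g, stand=stand, n_candidates=len(ids))


def detect_modules(graph: nx.Graph, seed: int = 0) -> dict:
    """Louvain community detection with a fixed seed; node -> module id."""
    if graph.number_of_nodes() == 0:
        return {}
    communities = nx.community.louvain_communities(graph, seed=seed, resolution=1.0)
    return {node: m for m, members in enumerate(communities) for node in members}


def topology(net: CooccurrenceNetwork, seed: int = 0) -> TopologySummary:
    """The standard topology panel; path metrics on the largest component."""
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, {}, True)
    negative = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) < 0)
    modules = detect_modules(g, seed=seed)
    partition = {}
    for node, m in modules.items():
        partition.setdefault(m, set()).add(node)
    q = nx.community.modularity(g, partition.values()) if e > 0 else 0.0

    connected = nx.is_connected(g)
    lcc = g if connected else g.subgraph(max(nx.connected_components(g), key=len))
    diameter = nx.diameter(lcc) if lcc.number_of_nodes() > 1 else 0
    apl = (
        nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0
    )
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        percent_negative_edges=100.0 * negative / e if e else 0.0,
        diameter=float(diameter),
        density=nx.density(g),
        average_degree=2.0 * e / n,
        average_path_length=float(apl),
        average_clustering=float(nx.average_clustering(g)),
        modularity=float(q),
        modules=modules,
        connected=connected,
    )


def zipi(graph: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against the mean and SD of
    within-module degrees in its module (SD = 0 gives Zi = 0). Pi is
    1 - sum_m (k_im / k_i)^2 over modules m. Roles partition all nodes by
    the Zi >= 2.5 / Pi >= 0.62 thresholds.
    """
    empty_cols = ["module", "zi", "pi", "role"]
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=empty_cols, index=pd.Index([], name="node"))
    uncovered = [node for node in graph.nodes if node not in modules]
    if uncovered:
        raise ValueError(f"module partition does not cover: {uncovered[:5]}")

    members: dict[int, list] = {}
    for node in graph.nodes:
        members.setdefault(modules[node], []).append(node)

    within = {
        node: sum(1 for nb in graph[node] if modules[nb] == modules[node])
        for node in graph.nodes
    }
    rows = []
    for m, nodes in members.items():
        ks = np.array([within[node] for node in nodes], dtype=float)
        mean, sd = ks.mean(), ks.std()  # population SD, as in the original role metric
        for node in nodes:
            zi = 0.0 if sd == 0 else (within[node] - mean) / sd
            k = graph.degree(node)
            if k == 0:
                pi = 0.0
            else:
                per_module: dict[int, int] = {}
                for nb in graph[node]:
                    per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
                pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
            if zi >= ZI_THRESHOLD and pi >= PI_THRESHOLD:
                role = "network hub"
            elif zi >= ZI_THRESHOLD:
                role = "module hub"
            elif pi >= PI_THRESHOLD:
                role = "connector"
            else:
                role = "peripheral"
            rows.append(
                {"node": node, "module": m, "zi": zi, "pi": pi, "role": role}
            )
    return pd.DataFrame(rows).set_index("node")


def keystone_abundance(table: AbundanceTable, roles: pd.DataFrame) -> pd.Series:
    """Per-sample summed relative abundance of keystone taxa.

    Keystones are module hubs, connectors, and network hubs. Returns zeros
    (with a warning) if the keystone set is empty.
    """
    keystones = roles.index[roles["role"].isin(KEYSTONE_ROLES)]
    keystones = [k for k in keystones if k in table.counts.columns]
    totals = table.counts.sum(axis=1)
    if len(keystones) == 0:
        warnings.warn("empty keystone set; abundances are zero", stacklevel=2)
        return pd.Series(0.0, index=table.counts.index, name="keystone_abundance")
    frac = table.counts[keystones].sum(axis=1) / totals
    frac.name = "keystone_abundance"
    return frac


def _remaining_fraction(graph: nx.Graph, removed: set, n_original: int) -> float:
    """Species remaining = surviving nodes that retain >= 1 edge."""
    kept = [node for node in graph.nodes if node not in removed]
    sub = graph.subgraph(kept)
    with_edges = sum(1 for node in sub.nodes if sub.degree(node) > 0)
    return with_edges / n_original


def robustness(
    net: CooccurrenceNetwork,
    strategy: str = "random",
    removal_fraction: float = 0.5,
    n_replicates: int = 100,
    seed: int | None = None,
    roles: pd.DataFrame | None = None,
) -> RobustnessCurve:
    """Proportion of species remaining after node removal.

    Removes floor(fraction x N) nodes per replicate, either uniformly at
    random or module hubs first (ordered by Zi descending, ties by node id;
    any shortfall filled with random nodes). A species "remains" iff it
    keeps at least one edge; the proportion is relative to the original
    node count.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network needs at least 2 nodes")
    if not 0 < removal_fraction < 1:
        raise ValueError("removal fraction must be in (0, 1)")
    if strategy not in ("random", "hubs"):
        raise ValueError(f"unknown strategy {strategy!r}")

    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)

    hub_order: list = []
    if strategy == "hubs":
        if roles is None:
            modules = detect_modules(g, seed=0 if seed is None else seed)
            roles = zipi(g, modules)
        hubs = roles[roles["role"].isin(("module hub", "network hub"))]
        hub_order = hubs.sort_values(
            ["zi"], ascending=False, kind="stable"
        ).index.tolist()
        hub_order.sort(key=lambda x: (-roles.loc[x, "zi"], str(x)))

    props = np.empty(n_replicates)
    for rep in range(n_replicates):
        if strategy == "random":
            removed = set(rng.choice(nodes, size=n_remove, replace=False))
        else:
            removed = set(hub_order[:n_remove])
            if len(removed) < n_remove:
                pool = [x for x in nodes if x not in removed]
                extra = rng.choice(pool, size=n_remove - len(removed), replace=False)
                removed |= set(extra)
        props[rep] = _remaining_fraction(g, removed, n)
    return RobustnessCurve(
        strategy=strategy,
        fractions=np.array([removal_fraction]),
        mean_remaining=np.array([props.mean()]),
        sd_remaining=np.array([props.std(ddof=0)]),
        n_replicates=n_replicates,
        seed=seed,
    )


def robustness_curve(
    net: CooccurrenceNetwork,
    fractions=np.round(np.arange(0.1, 1.0, 0.1), 2),
    strategy: str = "random",
    n_replicates: int = 50,
    seed: int | None = None,
    roles: pd.DataFrame | None = None,
) -> RobustnessCurve:
    """Robustness over a grid of removal fractions (fraction 0 maps to 1)."""
    means, sds = [], []
    for i, f in enumerate(np.asarray(fractions, dtype=float)):
        if f == 0:
            means.append(1.0 if _has_no_isolates(net.graph) else _remaining_fraction(net.graph, set(), net.graph.number_of_nodes()))
            sds.append(0.0)
            continue
        rc = robustness(
            net,
            strategy=strategy,
            removal_fraction=float(f),
            n_replicates=n_replicates,
            seed=None if seed is None else seed + i,
            roles=roles,
        )
        means.append(float(rc.mean_remaining[0]))
        sds.append(float(rc.sd_remaining[0]))
    return RobustnessCurve(
        strategy=strategy,
        fractions=np.asarray(fractions, dtype=float),
        mean_remaining=np.asarray(means),
        sd_remaining=np.asarray(sds),
        n_replicates=n_replicates,
        seed=seed,
    )


def _has_no_isolates(g: nx.Graph) -> bool:
    return all(d > 0 for _, d in g.degree)


DEFAULT_COMPLEXITY_PANEL = ("average_degree", "density", "average_clustering")


def subnetwork_complexity(
    net: CooccurrenceNetwork,
    table: AbundanceTable,
    panel: tuple[str, ...] = DEFAULT_COMPLEXITY_PANEL,
) -> pd.Series:
    """Per-sample network complexity from induced sub-networks.

    For each sample, the subgraph induced on the network nodes present
    (count > 0) in that sample is summarized by the panel parameters; each
    parameter is z-scored across samples (zero SD gives z = 0) and the
    z-scores averaged. Samples with fewer than 2 present nodes get NaN.
    """
    g = net.graph
    metrics = {
        "average_degree": lambda s: 2.0 * s.number_of_edges() / s.number_of_nodes(),
        "density": nx.density,
        "average_clustering": lambda s: float(nx.average_clustering(s)),
        "n_edges": lambda s: float(s.number_of_edges()),
    }
    unknown = [m for m in panel if m not in metrics]
    if unknown:
        raise ValueError(f"unknown panel metrics: {unknown}")
    rows = {}
    node_set = set(g.nodes)
    for sid, row in table.counts.iterrows():
        present = [a for a in row.index[row > 0] if a in node_set]
        if len(present) < 2:
            rows[sid] = {m: np.nan for m in panel}
            continue
        sub = g.subgraph(present)
        rows[sid] = {m: metrics[m](sub) for m in panel}
    raw = pd.DataFrame.from_dict(rows, orient="index")
    means, sds = raw.mean(), raw.std(ddof=1)
    z = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        if sds[col] == 0 or np.isnan(sds[col]):
            # constant panel parameter: every sample sits at the mean
            z[col] = np.where(raw[col].notna(), 0.0, np.nan)
        else:
            z[col] = (raw[col] - means[col]) / sds[col]
    complexity = z.mean(axis=1)
    complexity.name = "complexity"
    complexity.attrs["panel"] = list(panel)
    return complexity
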