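"""Alpha/beta diversity and group-comparison statistics.

Alpha diversity: Shannon entropy (natural log by default) and the
bias-corrected Chao1 richness estimator. Beta diversity: Bray-Curtis
dissimilarity, principal coordinates analysis (Gower double-centering),
and ANOSIM with a label-permutation p-value. Group comparison: one-way
ANOVA with Tukey HSD and a compact letter display.

ANOSIM and PCoA are implemented here from their rank/eigen definitions so
that tests can cross-check them against independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from standnet.tables import AbundanceTable


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with positive counts.

    Natural log by default; pass ``base`` (e.g. 2) to change it.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton and doubleton counts.

    Bias-corrected form S_obs + F1(F1-1) / (2(F2+1)) by default, which is
    defined even when no doubletons are observed; the classical form
    S_obs + F1^2/(2 F2) is available with ``bias_corrected=False``.
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        raise ValueError("all-zero count vector")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(table: AbundanceTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon for an abundance table."""
    rows = {
        sid: {
            "chao1": chao1(row.to_numpy()),
            "shannon": shannon(row.to_numpy(), base=base),
        }
        for sid, row in table.counts.iterrows()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum min(a,b) / (sum a + sum b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def bray_curtis_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis over samples (rows)."""
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero samples present")
    n = len(x)
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * mins / (totals[i] + totals[i + 1 :])
    d = d + d.T
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates, eigenvalues, percent explained.

    Axes are ordered by decreasing eigenvalue. Negative eigenvalues (the
    input need not be Euclidean-embeddable) are reported but excluded from
    both the coordinates and the percent-explained denominator.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(distances: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering."""
    if isinstance(distances, pd.DataFrame):
        ids = distances.index
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = pd.RangeIndex(len(d))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")

    n = len(d)
    a = -0.5 * d**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-10 * max(abs(eigval[0]), 1.0)
    positive = eigval > tol
    negatives = eigval[eigval < -tol]
    pos_eig = eigval[positive]
    coords = eigvec[:, positive] * np.sqrt(pos_eig)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pos_eig_kept = pos_eig[:n_axes]
    else:
        pos_eig_kept = pos_eig
    percent = 100.0 * pos_eig_kept / pos_eig.sum() if pos_eig.sum() > 0 else pos_eig_kept
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=pos_eig_kept,
        percent_explained=percent,
        negative_eigenvalues=negatives,
    )


@dataclass
class AnosimResult:
    """ANOSIM statistic and permutation p-value."""

    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def _anosim_r(rank_condensed: np.ndarray, groups: np.ndarray) -> float:
    n = len(groups)
    gi, gj = np.triu_indices(n, k=1)
    within = groups[gi] == groups[gj]
    m = n * (n - 1) / 2
    return float(
        (rank_condensed[~within].mean() - rank_condensed[within].mean()) / (m / 2.0)
    )


def anosim(
    distances: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with average ties. The p-value
    is (1 + #{permuted R >= observed}) / (1 + n_permutations) under random
    relabeling of samples.
    """
    if isinstance(distances, pd.DataFrame):
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    if len(groups) != len(d):
        raise ValueError("group labels must match distance matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")

    condensed = squareform(d, checks=False)
    ranks = stats.rankdata(condensed)
    r_obs = _anosim_r(ranks, groups)

    rng = np.random.default_rng(seed)
    exceed = 0
    perm = groups.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _anosim_r(ranks, perm) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return AnosimResult(r=r_obs, p_value=p, n_permutations=n_permutations, seed=seed)


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD multiple comparisons."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # pairwise: group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]  # compact letter display, 'a' = lowest mean


def _compact_letters(groups: list[str], means: dict[str, float], nonsig_pairs: set) -> dict[str, str]:
    """Compact letter display via maximal cliques of the non-significance graph.

    Groups sharing a letter are not significantly different. Letters are
    ordered so 'a' belongs to the clique containing the lowest mean, matching
    the convention of annotating ascending group means.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nonsig_pairs)
    cliques = [set(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: min(means[m] for m in c))
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for grp in clique:
            letters[grp].append(letter)
    return {grp: "".join(sorted(v)) for grp, v in letters.items()}


def group_compare(values: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA + Tukey HSD + compact letter display.

    ``values`` maps group label -> 1-D array of observations.
    """
    groups = list(values)
    arrays = [np.asarray(values[g], dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")

    f_stat, p_val = stats.f_oneway(*arrays)

    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    tukey = tukey.rename(columns={"p-adj": "p_adj"})

    means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
    nonsig = {
        (row["group1"], row["group2"])
        for _, row in tukey.iterrows()
        if not row["reject"]
    }
    letters = _compact_letters(groups, means, nonsig)
    return GroupComparison(
        f_statistic=float(f_stat), p_value=float(p_val), tukey=tukey, letters=letters
    )
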