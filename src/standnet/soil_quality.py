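"""Minimum-data-set selection, nonlinear indicator scoring, and the SQI.

The soil quality index (SQI) pipeline has three steps:

1. **MDS selection.** PCA on the correlation matrix of the standardized
   indicators. Principal components with eigenvalue > 1.0 are retained; on
   each retained PC the candidate indicators are those whose |loading| is
   within the top 10% band of that PC's maximum |loading|; candidates that
   are mutually Pearson-correlated at |r| >= 0.7 are reduced to the
   highest-loading one. The union over PCs is the minimum data set. Each
   selected indicator's weight is its communality over the retained PCs
   (sum of squared loadings, loadings scaled by sqrt(eigenvalue)),
   normalized to sum to one.

2. **Nonlinear scoring.** Each indicator value x is mapped to a score

       SNL = 1 / (1 + (x / x0)^b)

   where x0 is the dataset mean of the indicator and b is -2.5 for
   "more is better" indicators and +2.5 for "less is better" (bulk
   density). SNL(x0) = 0.5 for any b, and SNL(b) + SNL(-b) = 1.

3. **Weighted index.** SQI = sum_i W_i * SNL_i per sample, in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from standnet.tables import SOIL_INDICATORS, STAND_COLUMN

#: Default scoring directions: b = -2.5 means "more is better".
#: Bulk density is the one uncontroversially "less is better" indicator;
#: pH defaults to "more is better" in the mildly acidic range studied and
#: is overridable per analysis.
DEFAULT_DIRECTIONS: dict[str, float] = {
    "SOC": -2.5,
    "TN": -2.5,
    "TP": -2.5,
    "AN": -2.5,
    "AP": -2.5,
    "pH": -2.5,
    "MWHC": -2.5,
    "BD": 2.5,
}


@dataclass(frozen=True)
class ScoringCurve:
    """Sigmoid scoring curve: baseline ``x0`` (dataset mean) and shape ``b``."""

    x0: float
    b: float

    def __post_init__(self) -> None:
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")


@dataclass
class MdsResult:
    """Outcome of minimum-data-set selection."""

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # indicators x retained PCs, sqrt(eig)-scaled
    selected: list[str]
    weights: pd.Series  # over selected indicators, sums to 1
    trace: list[str] = field(default_factory=list)


@dataclass
class SqiResult:
    """Per-sample nonlinear scores and weighted soil quality index."""

    snl: pd.DataFrame  # samples x selected indicators, each in (0, 1)
    sqi: pd.Series  # samples, in [0, 1]
    group_stats: pd.DataFrame  # stand x {mean, sd, n}
    weights: pd.Series


def score_nonlinear(x, curve: ScoringCurve):
    """Evaluate SNL = 1 / (1 + (x/x0)^b) elementwise.

    Monotone increasing in x for b < 0, decreasing for b > 0; bounded in
    (0, 1) for finite positive x. x = 0 with b < 0 returns 0 by continuous
    extension (with a warning); negative x is rejected.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("indicator values must be non-negative")
    if (arr == 0).any():
        if curve.b > 0:
            raise ValueError("x = 0 undefined for a 'less is better' curve (b > 0)")
        warnings.warn("x = 0 scored as 0 by continuous extension", stacklevel=2)
    with np.errstate(divide="ignore"):
        out = 1.0 / (1.0 + (arr / curve.x0) ** curve.b)
    out = np.where(arr == 0, 0.0, out)
    return float(out) if np.isscalar(x) else out


def _pca_correlation(values: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Eigendecomposition of the correlation matrix, PCs sorted by eigenvalue.

    Returns (eigenvalues desc, loadings) with loadings scaled by
    sqrt(eigenvalue) and sign-fixed so each PC's largest-|loading| entry is
    positive.
    """
    corr = np.corrcoef(values.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))
    cols = [f"PC{k + 1}" for k in range(len(eigval))]
    return eigval, pd.DataFrame(loadings, index=values.columns, columns=cols)


def select_mds(
    table: pd.DataFrame,
    indicators: list[str] | None = None,
    eig_min: float = 1.0,
    loading_band: float = 0.10,
    corr_cut: float = 0.7,
) -> MdsResult:
    """Select the minimum data set and per-indicator weights by PCA.

    ``table`` is a soil table (samples x indicators, extra columns such as
    the stand label are ignored). Indicators are standardized internally;
    PCA operates on their correlation matrix, so rescaling any column by a
    positive constant leaves the selection unchanged.
    """
    if indicators is None:
        indicators = [c for c in SOIL_INDICATORS if c in table.columns]
    values = table[indicators].astype(float)
    n, p = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples for PCA")
    if n < p:
        warnings.warn(
            f"fewer samples ({n}) than indicators ({p}); PCA proceeds but "
            "loadings are unstable",
            stacklevel=2,
        )
    if (values.std(ddof=1) == 0).any():
        flat = values.columns[values.std(ddof=1) == 0].tolist()
        raise ValueError(f"zero-variance indicators: {flat}")

    eigval, loadings = _pca_correlation(values)
    retained = [k for k, ev in enumerate(eigval) if ev > eig_min]
    if not retained:
        raise ValueError(
            f"no principal component has eigenvalue > {eig_min}; "
            "lower eig_min to proceed"
        )
    trace = [
        f"retained {len(retained)} PCs with eigenvalue > {eig_min}: "
        + ", ".join(f"PC{k + 1}={eigval[k]:.3f}" for k in retained),
        "varimax rotation not applied",
    ]

    corr = values.corr()
    selected: list[str] = []
    for k in retained:
        pc = loadings.columns[k]
        load = loadings[pc].abs()
        cutoff = (1.0 - loading_band) * load.max()
        candidates = load[load >= cutoff].sort_values(ascending=False).index.tolist()
        trace.append(f"{pc}: candidates {candidates} (|loading| >= {cutoff:.3f})")
        kept: list[str] = []
        for cand in candidates:  # highest |loading| first
            clash = [
                other for other in kept if abs(corr.loc[cand, other]) >= corr_cut
            ]
            if clash:
                trace.append(
                    f"{pc}: dropped {cand} (|r| >= {corr_cut} with {clash[0]})"
                )
            else:
                kept.append(cand)
        for name in kept:
            if name not in selected:
                selected.append(name)

    retained_cols = [loadings.columns[k] for k in retained]
    communality = (loadings[retained_cols] ** 2).sum(axis=1)
    weights = communality.loc[selected]
    weights = weights / weights.sum()
    trace.append(f"MDS = {selected}; weights = {weights.round(4).to_dict()}")
    return MdsResult(
        eigenvalues=eigval,
        loadings=loadings[retained_cols],
        selected=selected,
        weights=weights,
        trace=trace,
    )


def score_table(
    table: pd.DataFrame,
    mds: MdsResult,
    directions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Score each selected indicator with its dataset-mean baseline."""
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    snl = {}
    for ind in mds.selected:
        if ind not in table.columns:
            raise KeyError(f"indicator {ind!r} missing from table")
        if ind not in directions:
            raise KeyError(f"no scoring direction for indicator {ind!r}")
        curve = ScoringCurve(x0=float(table[ind].mean()), b=directions[ind])
        snl[ind] = score_nonlinear(table[ind].to_numpy(), curve)
    return pd.DataFrame(snl, index=table.index)


def compute_sqi(scores: pd.DataFrame, mds: MdsResult) -> SqiResult:
    """Weighted sum of nonlinear scores per sample; group stats if stands known.

    ``scores`` must contain one column per selected indicator; the group
    summary is empty unless the caller attaches a ``stand`` column via
    ``scores.attrs['stand']`` or uses :func:`sqi_pipeline`.
    """
    missing = [ind for ind in mds.selected if ind not in scores.columns]
    if missing:
        raise KeyError(f"scored indicators missing: {missing}")
    if not np.isclose(mds.weights.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    sqi = (scores[mds.selected] * mds.weights).sum(axis=1)
    sqi.name = "SQI"
    stand = scores.attrs.get("stand")
    if stand is not None:
        grp = sqi.groupby(pd.Series(stand, index=sqi.index))
        group_stats = pd.DataFrame(
            {"mean": grp.mean(), "sd": grp.std(ddof=1), "n": grp.size()}
        )
    else:
        group_stats = pd.DataFrame(columns=["mean", "sd", "n"])
    return SqiResult(
        snl=scores[mds.selected],
        sqi=sqi,
        group_stats=group_stats,
        weights=mds.weights,
    )


def sqi_pipeline(
    soil: pd.DataFrame,
    directions: dict[str, float] | None = None,
    eig_min: float = 1.0,
    loading_band: float = 0.10,
    corr_cut: float = 0.7,
) -> tuple[MdsResult, SqiResult]:
    """Full chain: MDS selection -> scoring -> SQI on one soil table."""
    mds = select_mds(
        soil, eig_min=eig_min, loading_band=loading_band, corr_cut=corr_cut
    )
    scores = score_table(soil, mds, directions=directions)
    if STAND_COLUMN in soil.columns:
        scores.attrs["stand"] = soil[STAND_COLUMN]
    return mds, compute_sqi(scores, mds)


def sqi_percent_change(reference: float, other: float) -> float:
    """Percent change of ``other`` relative to ``reference``, to 2 decimals."""
    if reference <= 0:
        raise ValueError("reference SQI must be positive")
    return round(100.0 * (other - reference) / reference, 2)
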