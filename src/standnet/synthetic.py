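"""Synthetic soil-property and ASV abundance tables with known structure.

The generator emulates the sampling design of a three-stand-type forest
study: larch (LF), mixed larch-birch (MF), and birch (BF) stands, seven
plots per stand, two composite soil samples per plot (42 samples total).
Soil indicators are drawn around published per-stand means and standard
deviations; microbial communities follow a log-normal-latent /
multinomial-sampling model with optional stand effects (applied to a
designated responsive ASV subset) and correlated ASV blocks so that
co-occurrence networks built downstream recover modular structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from standnet.tables import SOIL_INDICATORS, STAND_COLUMN, AbundanceTable

# Per-stand (mean, sd) for each indicator: LF, MF, BF.
# SOC/TN/TP/AN in g/kg, AP in mg/kg, pH unitless, MWHC %, BD g/cm3.
TABLE2_SOIL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "SOC": {"LF": (63.19, 12.57), "MF": (121.01, 30.49), "BF": (100.47, 6.71)},
    "TN": {"LF": (3.08, 0.52), "MF": (5.46, 1.21), "BF": (4.55, 0.63)},
    "TP": {"LF": (0.43, 0.21), "MF": (0.97, 0.25), "BF": (0.64, 0.15)},
    "AN": {"LF": (293.16, 49.89), "MF": (549.19, 122.25), "BF": (505.98, 73.18)},
    "AP": {"LF": (8.00, 2.5), "MF": (12.93, 1.8), "BF": (13.39, 1.7)},
    "pH": {"LF": (6.19, 0.25), "MF": (6.06, 0.09), "BF": (6.35, 0.12)},
    "MWHC": {"LF": (37.87, 3.26), "MF": (44.41, 2.36), "BF": (44.12, 4.58)},
    "BD": {"LF": (0.97, 0.09), "MF": (0.84, 0.10), "BF": (0.84, 0.09)},
}

# Published group-mean SQI per stand, used only as a reference point in
# worked examples (the pipeline recomputes SQI from generated data).
REPORTED_SQI = {"LF": 0.35, "MF": 0.54, "BF": 0.52}


@dataclass(frozen=True)
class StandDesign:
    """Sampling design: stands x plots x samples-per-plot."""

    stand_labels: tuple[str, ...] = ("LF", "MF", "BF")
    n_plots_per_stand: int = 7
    n_samples_per_plot: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.stand_labels)) != len(self.stand_labels):
            raise ValueError("stand labels must be unique")
        if self.n_plots_per_stand < 1 or self.n_samples_per_plot < 1:
            raise ValueError("plots and samples per plot must be positive")

    @property
    def n_samples(self) -> int:
        return (
            len(self.stand_labels) * self.n_plots_per_stand * self.n_samples_per_plot
        )

    def sample_frame(self) -> pd.DataFrame:
        """One row per sample: sample_id index, stand and plot columns."""
        rows = []
        for stand in self.stand_labels:
            for plot in range(1, self.n_plots_per_stand + 1):
                for rep in range(1, self.n_samples_per_plot + 1):
                    rows.append(
                        {
                            "sample_id": f"{stand}_p{plot:02d}_s{rep}",
                            STAND_COLUMN: stand,
                            "plot": f"{stand}_p{plot:02d}",
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class SoilGeneratorParams:
    """Per-stand normal parameters for the eight soil indicators.

    ``indicator_params[indicator][stand] = (mean, sd)``. Defaults equal the
    published per-stand means and standard deviations. ``correlation`` adds
    an exchangeable between-indicator correlation through a shared latent
    factor per sample (needed to exercise the MDS correlation screening);
    ``plot_sd_fraction`` adds a plot-level random intercept expressed as a
    fraction of the indicator SD (samples within a plot share it).
    """

    indicator_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in TABLE2_SOIL_PARAMS.items()
        }
    )
    correlation: float = 0.0
    plot_sd_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        if self.plot_sd_fraction < 0:
            raise ValueError("plot_sd_fraction must be >= 0")
        for ind, stands in self.indicator_params.items():
            for stand, (_, sd) in stands.items():
                if sd < 0:
                    raise ValueError(
                        f"negative SD for indicator {ind!r}, stand {stand!r}"
                    )


def generate_soil_table(
    design: StandDesign, params: SoilGeneratorParams | None = None
) -> pd.DataFrame:
    """Draw a soil-property table under the design.

    Each indicator is drawn from a normal with its stand's mean and SD,
    truncated at zero by rejection for all indicators except pH (whose range
    keeps it safely positive anyway). Deterministic given ``design.seed``.
    """
    if params is None:
        params = SoilGeneratorParams()
    frame = design.sample_frame()
    rng = np.random.default_rng(design.seed)
    n = len(frame)
    indicators = list(params.indicator_params)
    for ind in indicators:
        missing = set(design.stand_labels) - set(params.indicator_params[ind])
        if missing:
            raise ValueError(f"no parameters for indicator {ind!r} in stands {missing}")

    rho = params.correlation
    shared = rng.standard_normal(n)  # latent factor inducing exchangeable corr
    plot_codes, plot_idx = np.unique(frame["plot"], return_inverse=True)

    data = {}
    for ind in indicators:
        means = np.array(
            [params.indicator_params[ind][s][0] for s in frame[STAND_COLUMN]]
        )
        sds = np.array(
            [params.indicator_params[ind][s][1] for s in frame[STAND_COLUMN]]
        )
        plot_effect = rng.standard_normal(len(plot_codes))[plot_idx]
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        x = means + sds * (z + params.plot_sd_fraction * plot_effect)
        if ind != "pH":
            # rejection-resample the rare negatives (only TP comes close)
            bad = x <= 0
            guard = 0
            while bad.any():
                x[bad] = means[bad] + sds[bad] * rng.standard_normal(bad.sum())
                bad = x <= 0
                guard += 1
                if guard > 1000:
                    raise RuntimeError(f"cannot draw positive values for {ind!r}")
        data[ind] = x
    out = frame.copy()
    for ind in indicators:
        out[ind] = data[ind]
    return out[[STAND_COLUMN, "plot", *indicators]]


@dataclass(frozen=True)
class DomainParams:
    """Community model parameters for one domain.

    Latent per-sample log-abundance of ASV i:

        l_is = mu_i + sigma * (sqrt(rho_b) f_{block(i),s} + sqrt(1-rho_b) e_is)
               + log(1 + effect) * [i responsive to stand(s)]

    with mu_i ~ N(0, tau^2) giving the rank-abundance spread; counts are
    multinomial at ``depth`` over softmax(l_.s). The first
    ``n_modules * block_size`` ASVs form correlated blocks; a random
    ``responsive_fraction`` of ASVs is split evenly across stands and
    up-shifted in its stand's samples.
    """

    n_asvs: int = 400
    depth: int = 10_000
    tau: float = 1.5
    sigma: float = 1.0
    stand_effect: float = 0.0
    responsive_fraction: float = 0.3
    n_modules: int = 5
    block_size: int = 20
    block_correlation: float = 0.9

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.stand_effect < 0:
            raise ValueError("stand effect must be >= 0")
        if self.n_modules < 1:
            raise ValueError("module count must be >= 1")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block correlation must be in [0, 1)")
        if self.n_modules * self.block_size > self.n_asvs:
            raise ValueError("blocked ASVs exceed n_asvs")


@dataclass(frozen=True)
class CommunityGeneratorParams:
    """Paired domain parameters.

    Defaults encode the study's contrast: fungal communities carry a
    stand-type effect sized so ANOSIM R lands near 0.4, bacterial
    communities carry none (R near 0).
    """

    bacteria: DomainParams = field(default_factory=lambda: DomainParams(n_asvs=400))
    fungi: DomainParams = field(
        default_factory=lambda: DomainParams(n_asvs=200, stand_effect=2.5)
    )


_BACT_PHYLA = [
    "Actinobacteria", "Proteobacteria", "Acidobacteria",
    "Chloroflexi", "Verrucomicrobia", "Gemmatimonadetes",
]
_FUNG_PHYLA = [
    "Basidiomycota", "Ascomycota", "Mortierellomycota", "Mucoromycota",
]


def _taxonomy(rng: np.random.Generator, n: int, domain: str) -> list[str]:
    phyla = _BACT_PHYLA if domain == "bacteria" else _FUNG_PHYLA
    kingdom = "Bacteria" if domain == "bacteria" else "Fungi"
    picks = rng.choice(len(phyla), size=n)
    return [f"k__{kingdom};p__{phyla[i]};g__genus{j:04d}" for j, i in enumerate(picks)]


def _generate_domain(
    design: StandDesign,
    dp: DomainParams,
    domain: str,
    rng: np.random.Generator,
) -> AbundanceTable:
    frame = design.sample_frame()
    n_samples = len(frame)
    n = dp.n_asvs
    prefix = "B" if domain == "bacteria" else "F"
    asv_ids = [f"{prefix}ASV{i:04d}" for i in range(n)]

    if dp.depth < 5 * n:
        warnings.warn(
            f"depth {dp.depth} is small for {n} ASVs; realized richness will "
            "fall short of the requested value",
            stacklevel=2,
        )

    mu = rng.normal(0.0, dp.tau, size=n)
    n_blocked = dp.n_modules * dp.block_size
    block_of = np.full(n, -1)
    block_of[:n_blocked] = np.repeat(np.arange(dp.n_modules), dp.block_size)

    # stand-responsive subset, split evenly across stands
    n_resp = int(round(dp.responsive_fraction * n))
    resp = rng.choice(n, size=n_resp, replace=False)
    stand_of_asv = np.full(n, -1)
    for k in range(len(design.stand_labels)):
        stand_of_asv[resp[k :: len(design.stand_labels)]] = k

    stand_idx = np.array(
        [design.stand_labels.index(s) for s in frame[STAND_COLUMN]]
    )
    rho = dp.block_correlation
    latent = np.empty((n_samples, n))
    factors = rng.standard_normal((n_samples, dp.n_modules))
    noise = rng.standard_normal((n_samples, n))
    for i in range(n):
        b = block_of[i]
        if b >= 0:
            e = np.sqrt(rho) * factors[:, b] + np.sqrt(1 - rho) * noise[:, i]
        else:
            e = noise[:, i]
        latent[:, i] = mu[i] + dp.sigma * e
    if dp.stand_effect > 0:
        shift = np.log1p(dp.stand_effect)
        responsive_mask = stand_of_asv[None, :] == stand_idx[:, None]
        latent = latent + shift * responsive_mask

    logits = latent - latent.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(dp.depth, probs[s]) for s in range(n_samples)]
    )

    table = AbundanceTable(
        counts=pd.DataFrame(counts, index=frame.index, columns=asv_ids),
        taxonomy=pd.Series(_taxonomy(rng, n, domain), index=asv_ids),
        domain=domain,
        metadata=frame[[STAND_COLUMN, "plot"]],
    )
    # planted structure, for block-recovery and effect-recovery tests
    table.metadata.attrs["planted_blocks"] = pd.Series(block_of, index=asv_ids)
    table.metadata.attrs["responsive_stand"] = pd.Series(
        [design.stand_labels[k] if k >= 0 else "" for k in stand_of_asv],
        index=asv_ids,
    )
    return table


def generate_abundance_tables(
    design: StandDesign, params: CommunityGeneratorParams | None = None
) -> tuple[AbundanceTable, AbundanceTable]:
    """Generate paired bacterial and fungal ASV count tables.

    Returns ``(bacteria, fungi)``. Deterministic given ``design.seed``;
    the bacterial table is drawn first from the shared stream.
    """
    if params is None:
        params = CommunityGeneratorParams()
    rng = np.random.default_rng(design.seed + 1)  # distinct from soil stream
    bacteria = _generate_domain(design, params.bacteria, "bacteria", rng)
    fungi = _generate_domain(design, params.fungi, "fungi", rng)
    return bacteria, fungi


def with_stand_effects(
    params: CommunityGeneratorParams,
    bacteria_effect: float | None = None,
    fungi_effect: float | None = None,
) -> CommunityGeneratorParams:
    """Convenience copy-with-new-effect-sizes."""
    bact = params.bacteria
    fung = params.fungi
    if bacteria_effect is not None:
        bact = replace(bact, stand_effect=bacteria_effect)
    if fungi_effect is not None:
        fung = replace(fung, stand_effect=fungi_effect)
    return CommunityGeneratorParams(bacteria=bact, fungi=fung)
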