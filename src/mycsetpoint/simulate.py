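"""Synthetic data with the statistical structure of the study system.

Generates every input the pipeline consumes: per-cell expression
populations built from log-normal setpoint subpopulations with heritable
drift, dose-dependent stimulation with a Stage-I expression ceiling and
Stage-II breakthrough, two-channel nucleus images with optical blur and
Poisson shot noise, globally amplified transcriptomes with fixed-per-cell
ERCC-like spike-ins, and qPCR Cq tables.  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import ImagePair

__all__ = [
    "Subpopulation",
    "StageIConfig",
    "StageIIConfig",
    "PopulationConfig",
    "TruePopulation",
    "ImageLayout",
    "simulate_population",
    "apply_stimulus",
    "render_images",
    "simulate_rnaseq",
    "simulate_qpcr",
    "LOW_DOSE",
    "HIGH_DOSE",
]

# Doses mirror the growth-factor titration: 1 (partial induction, Stage I)
# vs 4 (maximal induction, Stage II breakthrough), in the same arbitrary
# concentration units as K_d / K_II.
LOW_DOSE = 1.0
HIGH_DOSE = 4.0


@dataclass(frozen=True)
class Subpopulation:
    weight: float
    mu_log: float
    sigma_log: float


@dataclass(frozen=True)
class StageIConfig:
    """Bounded induction: x -> x * g(dose), softly clamped below the ceiling."""

    g_max: float = 2.5   # maximal fold induction
    K_d: float = 1.0     # half-saturating dose


@dataclass(frozen=True)
class StageIIConfig:
    """Ceiling breakthrough: probability pi(dose), log-normal boost."""

    pi_max: float = 0.25
    K_II: float = 2.8284271247461903   # 2*sqrt(2): pi(dose=4) = 0.20 at m=4
    hill_m: float = 4.0
    boost_mu_log: float = 1.1
    boost_sigma_log: float = 0.25


@dataclass(frozen=True)
class PopulationConfig:
    """Generative model of a per-cell expression population.

    Defaults describe a two-subpopulation steady state (low/high setpoint,
    delta mu_log = 0.8), moderate intrinsic noise, weak inheritance drift,
    and a ceiling near the 99th percentile of the unstimulated mixture.
    """

    subpopulations: tuple[Subpopulation, ...] = (
        Subpopulation(0.6, 0.8, 0.25),
        Subpopulation(0.4, 1.6, 0.25),
    )
    sigma_intrinsic: float = 0.15   # per-cell log noise around the setpoint
    sigma_inherit: float = 0.05     # setpoint drift per division (log scale)
    divisions: int = 0
    # Squash asymptote of the Stage-I clamp.  Set just below the q=0.99
    # quantile of the default unstimulated mixture (~8.8 AU) so that a
    # ceiling-respecting (Stage I) population stays below the empirical
    # reference ceiling; only Stage-II breakthrough cells exceed it.
    ceiling_AU: float = 8.0
    stageI: StageIConfig = field(default_factory=StageIConfig)
    stageII: StageIIConfig = field(default_factory=StageIIConfig)
    kappa: float = 0.0              # priming exponent: high setpoints break through more
    n_cells: int = 2000
    seed: int = 0

    def __post_init__(self):
        w = sum(s.weight for s in self.subpopulations)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("subpopulation weights must sum to 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.sigma_intrinsic, self.sigma_inherit) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0 <= self.stageII.pi_max <= 1):
            raise ValueError("pi_max must be in [0, 1]")


@dataclass
class TruePopulation:
    """Ground truth per cell: setpoint, observed total, lineage, flags."""

    cells: pd.DataFrame  # columns: setpoint_log, observed, subpopulation, breakthrough
    config: PopulationConfig


def simulate_population(config: PopulationConfig) -> TruePopulation:
    """Draw a population of cells from the setpoint mixture.

    Each cell samples a subpopulation, a heritable setpoint around that
    subpopulation's mean, accumulates Gaussian setpoint drift over
    ``divisions`` divisions (SD scaling with sqrt(divisions)), and is
    observed with log-normal intrinsic noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    weights = np.array([s.weight for s in config.subpopulations])
    sub = rng.choice(len(weights), size=n, p=weights)
    mu = np.array([s.mu_log for s in config.subpopulations])[sub]
    sd = np.array([s.sigma_log for s in config.subpopulations])[sub]
    setpoint = rng.normal(mu, sd)
    if config.divisions > 0 and config.sigma_inherit > 0:
        setpoint = setpoint + rng.normal(
            0, config.sigma_inherit * np.sqrt(config.divisions), size=n
        )
    observed = np.exp(setpoint + rng.normal(0, config.sigma_intrinsic, size=n))
    cells = pd.DataFrame(
        {
            "setpoint_log": setpoint,
            "observed": observed,
            "subpopulation": sub,
            "breakthrough": np.zeros(n, dtype=bool),
        }
    )
    return TruePopulation(cells=cells, config=config)


def _soft_clamp(x: np.ndarray, ceiling: float) -> np.ndarray:
    """Logistic squash above 0.9 * ceiling; identity (and C1) below it."""
    t = 0.9 * ceiling
    span = ceiling - t
    out = x.copy()
    above = x > t
    z = (x[above] - t) / span
    out[above] = t + span * 2.0 * (1.0 / (1.0 + np.exp(-2.0 * z)) - 0.5)
    return out


def apply_stimulus(
    population: TruePopulation, dose: float, seed: int | None = None
) -> TruePopulation:
    """Dose-dependent induction with a Stage-I ceiling and Stage-II breakthrough.

    Stage I multiplies every cell by the saturating gain g(dose) and
    squashes the result below the configured ceiling.  Stage II lets each
    cell break through the ceiling with probability pi(dose), weighted by
    (setpoint / median setpoint)^kappa (priming) and capped at 1;
    breakthrough cells take their unclamped value times a log-normal boost.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    cfg = population.config
    cells = population.cells.copy()
    if dose == 0:
        return TruePopulation(cells=cells, config=cfg)
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    x = cells["observed"].to_numpy()

    g = 1.0 + (cfg.stageI.g_max - 1.0) * dose / (dose + cfg.stageI.K_d)
    raised = x * g
    clamped = _soft_clamp(raised, cfg.ceiling_AU)

    s2 = cfg.stageII
    pi = s2.pi_max * dose**s2.hill_m / (dose**s2.hill_m + s2.K_II**s2.hill_m)
    setpoint = np.exp(cells["setpoint_log"].to_numpy())
    prime = (setpoint / np.median(setpoint)) ** cfg.kappa
    p_break = np.minimum(pi * prime, 1.0)
    breakthrough = rng.random(x.size) < p_break
    boost = np.exp(rng.normal(s2.boost_mu_log, s2.boost_sigma_log, size=x.size))

    out = np.where(breakthrough, raised * boost, clamped)
    cells["observed"] = out
    cells["breakthrough"] = breakthrough
    return TruePopulation(cells=cells, config=cfg)


# ---------------------------------------------------------------------------
# image rendering


@dataclass(frozen=True)
class ImageLayout:
    """Geometry and optics of rendered nucleus images."""

    shape: tuple[int, int] = (512, 512)
    cells_per_image: int = 120
    radius_range: tuple[float, float] = (8.0, 13.0)
    margin: int = 16                 # keep nuclei off the border
    min_separation: float = 4.0      # gap between nucleus edges, px
    # Image counts per AU of expression: puts a typical cell (~5 AU, ~330 px)
    # at ~150 counts/px over the 100-count background (per-pixel SNR ~5),
    # the photon budget of a routine 16-bit fluorescence acquisition.
    gain: float = 10000.0
    dna_intensity: float = 500.0
    background: float = 100.0
    psf_sigma: float = 1.0
    poisson_noise: bool = True
    max_attempts: int = 5000


def render_images(
    population: TruePopulation,
    layout: ImageLayout | None = None,
    seed: int = 0,
) -> tuple[list[ImagePair], pd.DataFrame]:
    """Render the population as two-channel images plus a ground-truth table.

    Nuclei are disks; the signal channel carries total/area intensity per
    pixel so the integrated signal equals gain * observed AU.  Images get
    Gaussian PSF blur and (optionally) Poisson shot noise over a constant
    background.  Ground truth records each cell's placement and its total
    in image units.
    """
    layout = layout or ImageLayout()
    rng = np.random.default_rng(seed)
    obs = population.cells["observed"].to_numpy()
    n = obs.size
    n_images = int(np.ceil(n / layout.cells_per_image))
    h, w = layout.shape

    pairs: list[ImagePair] = []
    truth_rows = []
    yy, xx = np.mgrid[0:h, 0:w]
    idx = 0
    for img_i in range(n_images):
        batch = obs[idx : idx + layout.cells_per_image]
        idx += batch.size
        centers: list[tuple[float, float, float]] = []
        dna = np.zeros((h, w))
        sig = np.zeros((h, w))
        for ci, total_au in enumerate(batch):
            r = rng.uniform(*layout.radius_range)
            placed = False
            for _ in range(layout.max_attempts):
                cy = rng.uniform(layout.margin + r, h - layout.margin - r)
                cx = rng.uniform(layout.margin + r, w - layout.margin - r)
                if all(
                    np.hypot(cy - py, cx - px) > r + pr + layout.min_separation
                    for py, px, pr in centers
                ):
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not place all nuclei: lower cells_per_image or density"
                )
            centers.append((cy, cx, r))
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            area = int(disk.sum())
            total_img = total_au * layout.gain
            dna[disk] += layout.dna_intensity
            sig[disk] += total_img / area
            truth_rows.append(
                {
                    "image_id": f"img_{img_i:03d}",
                    "cell_index": ci,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "radius": r,
                    "area": area,
                    "observed_au": total_au,
                    "total_image_units": total_img,
                }
            )
        if layout.psf_sigma > 0:
            dna = ndi.gaussian_filter(dna, layout.psf_sigma)
            sig = ndi.gaussian_filter(sig, layout.psf_sigma)
        dna = dna + layout.background
        sig = sig + layout.background
        if layout.poisson_noise:
            dna = rng.poisson(dna).astype(float)
            sig = rng.poisson(sig).astype(float)
        else:
            dna = np.round(dna)
            sig = np.round(sig)
        pairs.append(
            ImagePair(
                dna_channel=np.clip(dna, 0, 65535).astype(np.uint16),
                signal_channel=np.clip(sig, 0, 65535).astype(np.uint16),
                image_id=f"img_{img_i:03d}",
            )
        )
    return pairs, pd.DataFrame(truth_rows)


def match_measurements_to_truth(
    measured: pd.DataFrame, truth: pd.DataFrame, max_dist: float = 5.0
) -> pd.DataFrame:
    """Join measured objects to ground-truth cells by nearest centroid."""
    rows = []
    for image_id, mgrp in measured.groupby("image_id"):
        tgrp = truth[truth["image_id"] == image_id]
        tx = tgrp["centroid_x"].to_numpy()
        ty = tgrp["centroid_y"].to_numpy()
        for _, m in mgrp.iterrows():
            d = np.hypot(tx - m["centroid_x"], ty - m["centroid_y"])
            j = int(np.argmin(d))
            if d[j] <= max_dist:
                row = m.to_dict()
                row["true_total"] = tgrp.iloc[j]["total_image_units"]
                row["true_area"] = tgrp.iloc[j]["area"]
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA-seq counts


def simulate_rnaseq(
    n_genes: int = 2000,
    amplification: float = 2.0,
    depth_factors: dict[str, float] | None = None,
    dispersion: float = 0.05,
    spikein_dispersion: float = 0.0,
    n_spikeins: int = 60,
    n_replicates: int = 2,
    mean_log_count: float = 5.0,
    seed: int = 0,
):
    """Counts for a global-amplification experiment with per-cell spike-ins.

    Gene expression means are log-normal; the "high" condition multiplies
    every gene mean by ``amplification`` while spike-in means stay fixed
    per cell across conditions (they were added in proportion to cell
    count).  Gene counts are negative-binomial (gamma-Poisson) at the
    given biological dispersion; spike-ins carry only technical noise
    (``spikein_dispersion``, default 0 = Poisson: they are a pipetted
    reagent, not a biological signal).  Per-sample depth factors scale
    genes and spike-ins alike.
    Returns (counts DataFrame, lengths Series, spike_in Series).
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if n_spikeins < 50:
        raise ValueError("n_spikeins must be >= 50")
    rng = np.random.default_rng(seed)
    samples = [f"low_{i + 1}" for i in range(n_replicates)] + [
        f"high_{i + 1}" for i in range(n_replicates)
    ]
    if depth_factors is None:
        # realistic library-size variation (~15% CV); with exactly equal
        # depths the spike-in correlation rule has no common signal to track
        depth_factors = {s: float(np.exp(rng.normal(0.0, 0.15))) for s in samples}

    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    spike_ids = [f"ERCC-{i:05d}" for i in range(n_spikeins)]
    gene_mu = np.exp(rng.normal(mean_log_count, 1.0, size=n_genes))
    # spike-ins total a few percent of the library (standard ERCC dilution)
    # while the reference candidates still carry hundreds-to-thousands of
    # reads, keeping their technical CV small
    spike_mu = np.exp(rng.normal(mean_log_count + 0.75, 1.0, size=n_spikeins))
    lengths = pd.Series(
        np.concatenate(
            [
                rng.integers(500, 5000, size=n_genes),
                rng.integers(250, 2000, size=n_spikeins),
            ]
        ),
        index=gene_ids + spike_ids,
        name="length",
    )
    spike_flag = pd.Series(
        [False] * n_genes + [True] * n_spikeins, index=lengths.index, name="spike_in"
    )

    def draw(mu_vec, disp):
        if disp <= 0:
            return rng.poisson(mu_vec)
        lam = rng.gamma(1.0 / disp, mu_vec * disp)
        return rng.poisson(lam)

    cols = {}
    for s in samples:
        amp = amplification if s.startswith("high") else 1.0
        d = depth_factors[s]
        cols[s] = np.concatenate(
            [
                draw(gene_mu * amp * d, dispersion),
                draw(spike_mu * d, spikein_dispersion),
            ]
        )
    counts = pd.DataFrame(cols, index=lengths.index)
    return counts, lengths, spike_flag


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_enrichments: dict[str, float],
    input_fraction: float = 0.01,
    cq_noise_sd: float = 0.0,
    base_cq_input: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq pairs whose noiseless percent-input equals the given enrichments.

    ``true_enrichments`` maps target names to percent-of-input values.
    Gaussian cycle noise (SD in cycles) is added independently to ChIP and
    input Cqs.
    """
    if any(v <= 0 for v in true_enrichments.values()):
        raise ValueError("enrichments must be > 0 (percent of input)")
    rng = np.random.default_rng(seed)
    rows = []
    for target, pi in true_enrichments.items():
        cq_input = base_cq_input
        adj = cq_input - np.log2(1.0 / input_fraction)
        cq_chip = adj - np.log2(pi / 100.0)
        rows.append(
            {
                "target": target,
                "cq_chip": cq_chip + rng.normal(0, cq_noise_sd),
                "cq_input": cq_input + rng.normal(0, cq_noise_sd),
                "input_fraction": input_fraction,
            }
        )
    return pd.DataFrame(rows)
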