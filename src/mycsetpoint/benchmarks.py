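"""End-to-end validation scenarios run by the acceptance machinery.

Each function simulates a study condition with the package's own
generators, runs the corresponding analysis, and returns the measured
quantities.  They are consumed by ``tests/test_acceptance.py`` and
``scripts/acceptance.py``; sub-seeds are derived deterministically from
the single seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import distributions as dist
from . import imaging, seqquant, sidd, simulate

_MOD = 2**31 - 1


def _subseeds(seed: int, n: int, tag: int) -> list[int]:
    return [int(s) for s in (seed * 1_000_003 + tag * 10_007 + np.arange(n)) % _MOD]


def sidd_oracle_benchmark(seed: int, n_domains: int = 10, n_bp: int = 16) -> dict:
    """Ensemble profile vs exhaustive 2^N enumeration on random domains.

    Matched state spaces: both enumerate every configuration with at most
    ``max_runs`` runs and no energy cutoff.
    """
    params = sidd.SIDDParams(theta=1e9)
    worst = 0.0
    for s in _subseeds(seed, n_domains, tag=1):
        rng = np.random.default_rng(s)
        seq = "".join(rng.choice(list("ACGT"), n_bp))
        for sigma in (0.0, -0.06, -0.12):
            domain = sidd.make_domain(seq, sigma=sigma, params=params)
            prof = sidd.melt_profile(sidd.enumerate_states(domain, params))
            oracle = sidd.brute_force_profile(domain, params)
            worst = max(worst, float(np.abs(prof.p - oracle.p).max()))
    return {"max_abs_diff": worst, "n": n_domains * 3}


def sidd_monotonicity_benchmark(seed: int) -> dict:
    """Total melting vs stress, and A/T-island localization of the maximum."""
    rng = np.random.default_rng(seed + 17)
    seq60 = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=60))
    sums = []
    for sigma in (0.0, -0.03, -0.06, -0.09):
        d = sidd.make_domain(seq60, sigma=sigma)
        sums.append(float(sidd.melt_profile(sidd.enumerate_states(d)).p.sum()))
    monotone = bool(np.all(np.diff(sums) >= -1e-12))

    island = "G" * 25 + "AT" * 5 + "G" * 25
    d = sidd.make_domain(island, sigma=-0.09)
    p = sidd.melt_profile(sidd.enumerate_states(d)).p
    captured = bool(25 <= int(np.argmax(p)) < 35)
    return {"sum_p": sums, "monotone": monotone, "island_captured": captured}


def mixture_recovery_benchmark(
    seed: int, n_trials: int = 20, n_cells: int = 4000
) -> dict:
    """Two-component setpoint recovery (delta mu_log = 0.8) across seeds."""
    successes = 0
    for s in _subseeds(seed, n_trials, tag=2):
        rng = np.random.default_rng(s)
        v = np.exp(
            np.concatenate(
                [
                    rng.normal(0.8, 0.25, int(0.6 * n_cells)),
                    rng.normal(1.6, 0.25, n_cells - int(0.6 * n_cells)),
                ]
            )
        )
        k, models = dist.select_k(v, k_max=3, n_restarts=8, seed=s)
        if k != 2:
            continue
        m = models[1]
        if abs(m.mu_log[0] - 0.8) <= 0.05 and abs(m.mu_log[1] - 1.6) <= 0.05:
            successes += 1
    return {"n_success": successes, "n_trials": n_trials}


def two_stage_calibration_benchmark(
    seed: int, n_null: int = 500, n_cells: int = 2000
) -> dict:
    """Stage-II false-call rate under the null; injected-breakthrough recovery."""
    false_calls = 0
    for s in _subseeds(seed, n_null, tag=3):
        base = simulate.simulate_population(
            simulate.PopulationConfig(seed=s, n_cells=n_cells)
        )
        treated = simulate.simulate_population(
            simulate.PopulationConfig(seed=s + 1_000_000, n_cells=n_cells)
        )
        rep = dist.two_stage_report(
            base.cells["observed"], treated.cells["observed"], q=0.99
        )
        if rep.stage == "II":
            false_calls += 1

    s0 = _subseeds(seed, 1, tag=4)[0]
    base = simulate.simulate_population(
        simulate.PopulationConfig(seed=s0, n_cells=n_cells)
    )
    high = simulate.apply_stimulus(base, simulate.HIGH_DOSE, seed=s0 + 5)
    rep = dist.two_stage_report(
        base.cells["observed"], high.cells["observed"], q=0.99
    )
    return {
        "false_call_rate": false_calls / n_null,
        "n_null": n_null,
        "recovered_fraction": rep.breakthrough_fraction,
        "injected_fraction": float(high.cells["breakthrough"].mean()),
        "nominal_fraction": 0.20,
        "high_dose_stage": rep.stage,
    }


def spikein_benchmark(seed: int, n_genes: int = 1500) -> dict:
    """Global 2x amplification recovery with spike-in vs total-count scores."""
    counts, lengths, flag = simulate.simulate_rnaseq(
        n_genes=n_genes, amplification=2.0, seed=seed % _MOD
    )
    cm = seqquant.CountMatrix(counts, lengths, flag)
    norm = seqquant.normalize(cm)
    genes = norm.normalized.loc[~flag]
    low = genes[["low_1", "low_2"]].mean(axis=1)
    high = genes[["high_1", "high_2"]].mean(axis=1)
    pos = low > 0
    ratio = float((high[pos] / low[pos]).median())

    cpm = counts.div(counts.sum(axis=0), axis=1).loc[~flag]
    lowc = cpm[["low_1", "low_2"]].mean(axis=1)
    highc = cpm[["high_1", "high_2"]].mean(axis=1)
    ratio_tc = float((highc[lowc > 0] / lowc[lowc > 0]).median())

    # depth-doubling invariance with the reference held fixed
    fpk = norm.fpk
    doubled = counts.copy()
    doubled["low_1"] = doubled["low_1"] * 2
    fpk2 = seqquant.compute_fpk(doubled, lengths)
    col = fpk.div(seqquant.normalization_scores(fpk, norm.reference_ids), axis=1)
    col2 = fpk2.div(seqquant.normalization_scores(fpk2, norm.reference_ids), axis=1)
    depth_change = float(np.abs(col["low_1"] - col2["low_1"]).max())

    return {
        "spikein_median_ratio": ratio,
        "totalcount_median_ratio": ratio_tc,
        "depth_doubling_max_change": depth_change,
        "n_genes": n_genes,
    }


def image_roundtrip_benchmark(seed: int, n_cells: int = 1080) -> dict:
    """Render >= 1000 nuclei, re-measure, compare totals to ground truth."""
    pop = simulate.simulate_population(
        simulate.PopulationConfig(seed=seed % _MOD, n_cells=n_cells)
    )
    pairs, truth = simulate.render_images(pop, seed=(seed + 99) % _MOD)
    cells = pd.concat(
        [imaging.quantify_pair(p) for p in pairs], ignore_index=True
    )
    matched = simulate.match_measurements_to_truth(cells, truth)
    rel = np.abs(matched["total"] - matched["true_total"]) / matched["true_total"]
    return {
        "median_relative_error": float(np.median(rel)),
        "n_cells_rendered": n_cells,
        "n_cells_matched": int(len(matched)),
    }
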