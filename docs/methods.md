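# Methods

`mycsetpoint` implements the quantitative machinery for studying heritable
per-cell expression setpoints of a dosage-sensitive gene (the motivating
system is MYC in primary murine cells): superhelical DNA melting profiles
of the locus, per-cell fluorescence quantification, distribution
statistics for setpoint mixtures and two-stage induction, spike-in
normalized RNA-seq for global transcriptome amplification, and qPCR /
region-density quantification.  A synthetic-data generator reproduces the
statistical structure of each input so every stage is testable without
external downloads.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Superhelical melting (SIDD)

A linear genomic segment of length `N` is treated as a torsionally closed
superhelical domain with linking difference `alpha = sigma * N / h`
(`sigma` = superhelical density, default −0.06; `h` = 10.4 bp/turn).  A
state opens `r` runs of denatured base pairs, `n` bp in total, with free
energy

    G = a·r + Σ_{x open} b(x) + G_res(n)

- `a` (10.84 kcal/mol): nucleation cost per run.
- `b(x)`: per-bp separation energy, copolymeric — `b_AT` = 0.255,
  `b_GC` = 1.301 kcal/mol.  Nearest-neighbor energetics are out of scope.
- `G_res(n) = (K/2)(alpha + n/h)² / (1 + K·n/(4π²C))` with
  `K = K_coeff·R·T/N` (`K_coeff` = 2200, `C` = 2.5 kcal/(mol·rad²·bp),
  `T` = 310 K): the residual supercoiling energy after the analytic
  minimization over the interstrand twist of the open region.  The closed
  form is verified against 1-D numerical minimization over the twist in
  the test suite (agreement to 1e-8).

The ensemble contains every state with at most `max_runs` runs (default 2)
within `theta` (default 12 kcal/mol) of the minimum-energy state; the
per-bp melting probability is the Boltzmann average
`p(x) = Σ_{states opening x} exp(−G/RT) / Z`.  Enumeration is exact within
that state space: window energy sums come from prefix sums, per-length
minima prune dominated `(start, length)` windows, and two-run states are
enumerated as ordered, non-adjacent window pairs under the same bound.  A
configurable state cap (default 2·10⁷) guards against pathological
domains; large ensembles are held as packed start/length arrays, and the
profile is accumulated through a difference array, so multi-million-state
ensembles (a 2-kb domain with a long A/T island admits ~4.7M states at the
defaults) remain tractable.  A brute-force oracle enumerating all 2^N
configurations (N ≤ 22) provides the exactness check.

Peaks are maximal runs of `p(x) ≥ p_threshold` (default 0.5); summits take
the leftmost argmax; distances to an anchor (e.g. a TSS) are signed,
negative upstream.  Energetic constants live in config, not code: the
motivating study prints only the superhelical density and the domain
boundaries, so figure-level reproduction may require matching the original
model's parameter set.  Whether to report `p(x)` or a destabilization free
energy is also open; this package reports `p(x)` and leaves transforms to
plotting.

## Image quantification

Per-cell totals are the product of mean signal intensity and object size
(equivalently the background-corrected integrated intensity).  The
segmentation recipe is this package's own (the original measurements used
closed vendor software): Gaussian smoothing (σ = 2 px; cell mode doubles
it), Otsu threshold, hole filling, minimum-area (50 px) and border
removal, optional distance-transform watershed splitting, and finally a
2-px label expansion.  The expansion exists because a PSF blurs ~4–5% of
an object's flux just outside its DNA-stain-derived mask; measuring on the
expanded mask recovers it (round-trip bias falls from −4.5% to ~0%).  The
background policy subtracts the mode of non-object pixel intensities per
image; `total = mean × area` holds exactly for every row by construction.
Whole-cell ("contour") mode is a stand-in for an undocumented vendor
function and is flagged as such.

## Distribution statistics

All fits operate on natural logs of per-cell totals (the distributions are
log-normal-like) and back-transform to AU for reporting.

- **Mixture decomposition.** k-component Gaussian mixture on logs by EM:
  k-means++ initialization per restart (default 50 restarts; the
  validation scenarios use 8), convergence at log-likelihood gain < 1e-8
  or 500 iterations, best restart by likelihood, components sorted by
  mean.  A variance floor (σ ≥ 1e-3 on logs) prevents collapse.  The EM
  trace is recorded and its monotonicity asserted in tests; the fit is
  cross-checked against scikit-learn's `GaussianMixture` as an independent
  route.  Model order is chosen by BIC.
- **Two-stage statistics.** The expression ceiling is the empirical
  q-quantile (default q = 0.99, linear interpolation) of the unstimulated
  reference — the study defines ceilings graphically, never numerically,
  so a reference quantile is this package's operationalization.  The
  breakthrough fraction is the share of treated cells above it.  The
  stage call in `two_stage_report` uses an exact one-sided conditional
  (Fisher) test of the treated exceedance count against the reference's
  own exceedance.  A plain binomial test against the nominal rate 1−q
  (also reported, and used when only a ceiling value is available) is
  anti-conservative here: the ceiling is estimated, and its sampling noise
  inflates the nominal 1% false-call rate to ~4.5% at n = 2000; the
  conditional test restores calibration (measured ≤ 1% over 500 null
  replicates) at any sample size.
- **Setpoint memory.** Separation `d` between sorted low/high pools is
  the difference of median log-expression standardized by the pooled MAD
  (normal-consistent, root-mean-square of the two pool MADs). Memory is
  declared when `d > 1` at both timepoints and each pool differs from the
  parental distribution (two-sample KS, p < 0.01); persistence is
  d(day 7)/d(day 1).  KS is this package's choice of two-sample test; the
  motivating study plots CDFs without naming one.
- Condition means are compared with Welch's two-sided t-test.

## Spike-in RNA-seq normalization

Counts are length-normalized to FPK (fragments per kilobase; no depth
normalization).  Among spike-ins with positive FPK in every sample, the
top 50 by mean FPK are candidates; the 10 with the highest mean pairwise
Pearson correlation of log2 FPK across samples become the reference
("highly correlated" is operationalized as mean pairwise correlation; ties
break by mean FPK, then ID).  The per-sample normalization score is the
geometric mean of the reference FPKs; normalized FPK = FPK / score.
Because spike-ins are added in proportion to cell count, this preserves
global amplification signals that total-count normalization cancels.  With
few samples the correlation rule is weakly determined — a warning is
emitted below 4 samples.  Differential tables use fold changes on mean
normalized FPK with a 0.5 pseudocount (in the matrix's units), Welch
t-tests on log2 values, and Benjamini–Hochberg adjustment.

ChIP-qPCR enrichment is percent of input,
`PI = 100 · 2^((Cq_input − log2(1/f)) − Cq_chip)` for input fraction `f`;
values above 100% warn as implausible.  Region read densities from
bedGraph tracks are coverage-weighted sums over the region, divided by
region length and library size (×10⁶); fold changes are ratios of
condition means over replicates.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions every validation scenario runs under.

- **Population.** Cells draw a subpopulation (defaults: 60%/40% with
  `mu_log` 0.8/1.6, `sigma_log` 0.25 — two nested setpoint populations
  Δμ = 0.8 apart), a heritable setpoint, Gaussian setpoint drift per
  division (σ = 0.05·√divisions on logs; inheritance fidelity is not
  quantified in the motivating study, so this default is illustrative),
  and log-normal intrinsic noise (σ = 0.15).
- **Stimulation.** Stage I multiplies by the saturating gain
  `g(dose) = 1 + (g_max−1)·dose/(dose+K_d)` (g_max = 2.5, K_d = 1) and
  squashes logistically above 0.9× the ceiling — a soft clamp, because
  measured CDFs converge smoothly to a common upper limit rather than
  truncating.  The ceiling default (8 AU) sits just below the q = 0.99
  quantile of the default unstimulated mixture (~8.8 AU): a
  ceiling-respecting population must stay below the *measured* reference
  ceiling, which pins the squash asymptote to (at most) that quantile.
  Stage II lets cells break through with probability
  `π(dose) = π_max·dose^m/(dose^m + K_II^m)` (π_max = 0.25, K_II = 2√2,
  m = 4, so π = 0.20 at the high dose), optionally weighted by
  (setpoint/median)^κ (priming; κ = 0 by default, κ > 0 reproduces the
  higher re-induction of high-setpoint cells), multiplied by a log-normal
  boost (μ = 1.1, σ = 0.25 on logs) that ignores the clamp.  Low/high
  dose presets (1 and 4, in K_d units) mirror a partial vs maximal
  growth-factor titration: the low dose shifts the CDF under the ceiling,
  the high dose sends ~20% of cells through it.
- **Images.** Nuclei are disks (radius 8–13 px) with per-pixel intensity
  total/area, gain 10⁴ counts/AU over a 100-count background — a typical
  cell then sits ~150 counts/px above background (per-pixel SNR ~5, a
  routine 16-bit acquisition; at much lower gain, shot noise alone
  dominates the round-trip error).  Gaussian PSF (σ = 1 px) and Poisson
  shot noise are applied; ground truth (placement, area, total in image
  units) is emitted alongside.  Not emulated: illumination-field
  inhomogeneity, focus drift, overlapping/touching nuclei, and
  non-circular morphology — so the round-trip error bound demonstrates
  estimator correctness, not performance on difficult real images.
- **RNA-seq.** Gene means are log-normal (mean log count 5.0); the "high"
  condition multiplies every gene mean by the amplification factor
  (default 2.0) while spike-in means stay fixed per cell.  Gene counts
  are gamma-Poisson at dispersion 0.05; spike-ins draw Poisson only —
  they are a pipetted reagent with technical, not biological,
  variability, and that distinction is what makes them usable anchors.
  Spike-ins total ~5% of reads (a standard dilution); per-sample depth
  factors default to ~15% CV log-normal variation, as real libraries are
  never sequenced to identical depth (and exactly equal depths would
  leave the correlation-based reference selection with no common signal
  to track).
- **qPCR.** Cq pairs are constructed by inverting the percent-input
  formula, plus independent Gaussian cycle noise.

All generators are pure functions of (config, seed).

## Validation scenarios and problem sizes

The benchmark suite (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses: 10 random 16-bp domains × 3 superhelical
densities for the exhaustive-oracle check (tolerance 1e-9); a 60-bp domain
for stress monotonicity and a 60-bp A/T-island construct for composition
sensitivity; 20 populations of 4000 cells for mixture recovery (means
within ±0.05, ≥ 18/20); 500 null replicates of 2000+2000 cells for
stage-call calibration (≤ 2% false calls) plus one high-dose scenario
(breakthrough within ±3 points of the injected 20%); 1500-gene/60-spike-in
matrices for amplification recovery (median ratio within [1.9, 2.1],
depth-doubling invariance exact); and 1080 rendered nuclei for the imaging
round trip (median relative error ≤ 5%).  These sizes are the package's
validation design — large enough for the stated tolerances, small enough
to run routinely.

## Known limitations

- The SIDD energetics are a standard parameterization, not fitted to the
  motivating study's figure; only σ and the domain windows are printed
  there.
- Copolymeric melting energies ignore sequence context
  (nearest-neighbor and Z-DNA/cruciform competition are non-goals).
- The two-run ensemble limit (`max_runs` = 2) truncates the state space
  for very long or multi-island domains.
- Mixture identifiability degrades as component separation falls below
  ~1 pooled SD; BIC then prefers fewer components by design.
- The spike-in reference selection degenerates with two samples per
  group; the minimum-sample warning flags this.
- The cell-body segmentation mode is a stand-in; no 3-D stacks, tracking
  or illumination correction.
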