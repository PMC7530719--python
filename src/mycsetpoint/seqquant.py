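"""RNA-seq spike-in normalization, qPCR and region-density quantification.

When a transcription factor acts as a global transcriptome amplifier,
normalizing read counts to total library size erases the signal: every
gene appears unchanged.  ERCC spike-ins added in proportion to cell count
provide an absolute per-cell reference instead.  Counts are first
length-normalized to Fragments Per Kilobase (FPK, no depth normalization),
a per-sample normalization score is derived from the geometric mean of a
stable subset of highly expressed spike-ins, and normalized FPK = FPK /
score preserves global fold changes between conditions.

Also here: ChIP-qPCR percent-of-input and bedGraph region read-density
fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "SpikeInNormalizedMatrix",
    "compute_fpk",
    "select_spikein_reference",
    "normalization_scores",
    "normalize",
    "differential_table",
    "threshold_fc",
    "percent_input",
    "region_fold_change",
    "read_counts_tsv",
    "read_bedgraph",
    "read_bed",
]

MIN_SPIKEINS = 20


@dataclass
class CountMatrix:
    """Transcripts x samples integer counts with lengths and spike-in flags."""

    counts: pd.DataFrame          # index: transcript_id, columns: samples
    lengths: pd.Series            # bp, aligned to counts.index
    spike_in: pd.Series           # bool, aligned to counts.index

    def __post_init__(self):
        self.lengths = self.lengths.reindex(self.counts.index)
        self.spike_in = self.spike_in.reindex(self.counts.index).astype(bool)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be > 0")

    @property
    def n_spikeins(self) -> int:
        return int(self.spike_in.sum())


@dataclass
class SpikeInNormalizedMatrix:
    fpk: pd.DataFrame
    scores: pd.Series              # per-sample normalization score
    normalized: pd.DataFrame       # fpk / score, column-wise
    reference_ids: list[str]       # the chosen spike-in transcripts


def compute_fpk(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments Per Kilobase: count / (length/1000).  No depth scaling."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all transcript lengths must be > 0")
    return counts.div(lengths / 1000.0, axis=0)


def select_spikein_reference(
    spike_fpk: pd.DataFrame, top_n: int = 50, subset: int = 10
) -> list[str]:
    """Pick a stable spike-in reference set.

    From the ``top_n`` spike-ins by mean FPK over all samples (rows with a
    zero in any sample are excluded from candidacy), select the ``subset``
    transcripts whose log2 FPK is most correlated (mean pairwise Pearson)
    with the other candidates.  Ties break by mean FPK, then by ID.
    """
    positive = spike_fpk[(spike_fpk > 0).all(axis=1)]
    n_dropped = spike_fpk.shape[0] - positive.shape[0]
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} spike-ins with zero FPK in some sample")
    if positive.shape[0] < subset:
        raise ValueError(
            f"only {positive.shape[0]} all-positive spike-in candidates; need >= {subset}"
        )
    if spike_fpk.shape[1] < 4:
        warnings.warn(
            "fewer than 4 samples: cross-sample correlation is weakly determined"
        )
    mean_fpk = positive.mean(axis=1)
    top = positive.loc[mean_fpk.sort_values(ascending=False, kind="stable").index[:top_n]]
    logs = np.log2(top)
    corr = np.corrcoef(logs.to_numpy())
    corr = np.nan_to_num(corr, nan=1.0)  # zero-variance rows correlate degenerately
    k = corr.shape[0]
    mean_corr = (corr.sum(axis=1) - 1.0) / max(k - 1, 1)
    rank = pd.DataFrame(
        {
            "mean_corr": mean_corr,
            "mean_fpk": mean_fpk.loc[top.index].to_numpy(),
        },
        index=top.index,
    )
    rank = rank.sort_values(
        by=["mean_corr", "mean_fpk"], ascending=[False, False], kind="stable"
    )
    # final tie-break on ID for fully degenerate blocks
    rank["_id"] = rank.index
    rank = rank.sort_values(
        by=["mean_corr", "mean_fpk", "_id"], ascending=[False, False, True], kind="stable"
    )
    return list(rank.index[:subset])


def normalization_scores(fpk: pd.DataFrame, reference_ids) -> pd.Series:
    """Per-sample score: geometric mean of reference spike-in FPK."""
    ref = fpk.loc[list(reference_ids)]
    zero = ref <= 0
    if zero.any().any():
        t = ref.index[zero.any(axis=1)][0]
        s = ref.columns[zero.any(axis=0)][0]
        raise ValueError(f"reference spike-in {t} has zero FPK in sample {s}")
    return np.exp(np.log(ref).mean(axis=0)).rename("score")


def normalize(
    cm: CountMatrix, top_n: int = 50, subset: int = 10
) -> SpikeInNormalizedMatrix:
    """Full spike-in normalization: FPK -> reference selection -> scores."""
    if cm.n_spikeins < MIN_SPIKEINS:
        raise ValueError(f"need >= {MIN_SPIKEINS} spike-in rows, got {cm.n_spikeins}")
    fpk = compute_fpk(cm.counts, cm.lengths)
    top_n = min(top_n, int((fpk.loc[cm.spike_in] > 0).all(axis=1).sum()))
    ref = select_spikein_reference(fpk.loc[cm.spike_in], top_n=top_n, subset=subset)
    scores = normalization_scores(fpk, ref)
    return SpikeInNormalizedMatrix(
        fpk=fpk, scores=scores, normalized=fpk.div(scores, axis=1), reference_ids=ref
    )


def differential_table(
    normalized: pd.DataFrame,
    groups: dict[str, list[str]],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene fold change and Welch t-test between two sample groups.

    ``groups`` maps two condition names to their sample columns; fold
    change is condition A over condition B on mean normalized FPK with a
    pseudocount; the test is Welch's t on log2(normalized + pseudocount),
    BH-adjusted.  Single-replicate groups get fold changes but missing
    p-values (with a warning).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name_a, cols_a), (name_b, cols_b) = groups.items()
    a = normalized[cols_a]
    b = normalized[cols_b]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    out = pd.DataFrame(
        {
            f"mean_{name_a}": mean_a,
            f"mean_{name_b}": mean_b,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
        }
    )
    if len(cols_a) < 2 or len(cols_b) < 2:
        warnings.warn("single-replicate group: p-values reported as missing")
        out["p_value"] = np.nan
        out["q_value"] = np.nan
        return out
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    t = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    pvals = np.asarray(t.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance genes
    out["p_value"] = pvals
    out["q_value"] = multipletests(pvals, method="fdr_bh")[1]
    return out


def threshold_fc(table: pd.DataFrame, fc_min: float = 5.0) -> list[str]:
    """Genes with fold change >= fc_min (the FC >= 5 selection)."""
    return list(table.index[table["fold_change"] >= fc_min])


def percent_input(cq_chip, cq_input, input_fraction: float = 1.0):
    """ChIP-qPCR enrichment as percent of (dilution-adjusted) input.

    PI = 100 * 2^((cq_input - log2(1/input_fraction)) - cq_chip).
    Values above 100% (ChIP amplifying earlier than total input) are
    physically implausible and trigger a warning.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    cq_chip = np.asarray(cq_chip, dtype=float)
    cq_input = np.asarray(cq_input, dtype=float)
    if not (np.all(np.isfinite(cq_chip)) and np.all(np.isfinite(cq_input))):
        raise ValueError("Cq values must be finite")
    adj = cq_input - np.log2(1.0 / input_fraction)
    pi = 100.0 * 2.0 ** (adj - cq_chip)
    if np.any(pi > 100.0):
        warnings.warn("percent input above 100%: implausible Cq values")
    return pi if pi.ndim else float(pi)


def region_fold_change(
    tracks_a: list[pd.DataFrame],
    tracks_b: list[pd.DataFrame],
    region: tuple[str, int, int],
    library_sizes_a: list[float],
    library_sizes_b: list[float],
) -> dict:
    """Normalized read density ratio over a region between two conditions.

    Each track is a bedGraph DataFrame (chrom, start, end, value).  Density
    per replicate = (coverage-weighted sum over the region) / region length
    / library size * 1e6; the fold change is the ratio of condition means
    (A over B).  A zero denominator yields an infinite fold change with a
    flag.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("region end must exceed start")

    def density(track: pd.DataFrame, libsize: float) -> float:
        t = track[track.iloc[:, 0] == chrom]
        s = t.iloc[:, 1].to_numpy()
        e = t.iloc[:, 2].to_numpy()
        v = t.iloc[:, 3].to_numpy(dtype=float)
        ov = np.minimum(e, end) - np.maximum(s, start)
        ov = np.clip(ov, 0, None)
        total = float((ov * v).sum())
        return total / (end - start) / libsize * 1e6

    dens_a = [density(t, ls) for t, ls in zip(tracks_a, library_sizes_a)]
    dens_b = [density(t, ls) for t, ls in zip(tracks_b, library_sizes_b)]
    mean_a, mean_b = float(np.mean(dens_a)), float(np.mean(dens_b))
    infinite = mean_b == 0
    if infinite:
        warnings.warn("zero denominator density: fold change reported as inf")
    return {
        "densities_a": dens_a,
        "densities_b": dens_b,
        "mean_density_a": mean_a,
        "mean_density_b": mean_b,
        "fold_change": float("inf") if infinite else mean_a / mean_b,
        "infinite": infinite,
    }


# ---------------------------------------------------------------------------
# plain-text format I/O


def read_counts_tsv(path) -> CountMatrix:
    """Counts TSV: transcript_id, length, spike_in, then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    lengths = df.pop("length")
    spike = df.pop("spike_in").astype(bool)
    return CountMatrix(counts=df, lengths=lengths, spike_in=spike)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df
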