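"""Stress-induced duplex destabilization (SIDD) melting profiles.

A linear genomic segment is treated as a torsionally closed superhelical
domain of length ``N`` with linking difference ``alpha = sigma * N / h``.
Each equilibrium state opens ``r`` runs of denatured base pairs (``n`` bp in
total); its free energy is

    G = a*r + sum_{x open} b(x) + G_res(n)

where ``a`` is the run-nucleation cost, ``b(x)`` the per-bp separation
energy (copolymeric: one value for A/T, one for G/C), and ``G_res`` the
residual supercoiling energy after the torsional stress partitions between
interstrand twist of the open region and residual superhelicity:

    G_res(n) = (K/2) * (alpha + n/h)^2 / (1 + K*n / (4*pi^2*C)),
    K = K_coeff * R * T / N.

This closed form is the analytic minimum over the interstrand twist ``tau``
of ``(C/2)*n*tau^2 + (K/2)*(alpha + n/h - n*tau/(2*pi))^2``.

The Boltzmann-weighted ensemble of low-energy states (all states within
``theta`` kcal/mol of the minimum, with at most ``max_runs`` runs) yields a
per-base-pair transition probability profile p(x): the equilibrium
probability that base pair x is melted.  Destabilized sites (e.g. the FUSE
element upstream of *Myc*) appear as peaks in p(x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SIDDParams",
    "SuperhelicalDomain",
    "MeltState",
    "StateEnsemble",
    "TransitionProbabilityProfile",
    "MeltPeak",
    "InvalidAlphabetError",
    "EnsembleTooLargeError",
    "make_domain",
    "state_energy",
    "residual_energy",
    "enumerate_states",
    "melt_profile",
    "brute_force_profile",
    "find_melt_peaks",
]

_TWO_PI_SQ_4 = 4.0 * math.pi**2


class InvalidAlphabetError(ValueError):
    """Sequence contains a character outside A/C/G/T."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid base {char!r} at index {position}: sequence must be A/C/G/T only"
        )


class EnsembleTooLargeError(RuntimeError):
    """Admitted state count exceeds the configured cap.

    Raise theta pruning (smaller ``theta``), reduce ``max_runs``, shorten the
    domain, or raise ``max_states`` explicitly.
    """


@dataclass(frozen=True)
class SIDDParams:
    """Energetic constants of the superhelical melting model.

    Defaults follow the standard SIDD parameterization for physiological
    conditions; all are configurable.  Units: kcal/mol unless noted.
    """

    a: float = 10.84            # run nucleation free energy
    b_AT: float = 0.255         # per-bp separation energy, A/T
    b_GC: float = 1.301         # per-bp separation energy, G/C
    C: float = 2.5              # torsional stiffness of melted DNA, kcal/(mol rad^2 bp)
    K_coeff: float = 2200.0     # supercoiling stiffness numerator; K = K_coeff*R*T/N
    h: float = 10.4             # helical repeat, bp/turn
    T: float = 310.0            # temperature, K
    R: float = 1.987e-3         # gas constant, kcal/(mol K)
    sigma: float = -0.06        # superhelical density
    theta: float = 12.0         # ensemble energy cutoff above the minimum
    max_runs: int = 2           # maximum denatured runs per state

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not (0 < self.b_AT < self.b_GC):
            raise ValueError("require 0 < b_AT < b_GC")
        if self.C <= 0 or self.K_coeff <= 0 or self.h <= 0 or self.T <= 0:
            raise ValueError("C, K_coeff, h, T must be > 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")

    @property
    def RT(self) -> float:
        return self.R * self.T

    def K(self, N: int) -> float:
        """Quadratic supercoiling stiffness for a domain of N bp."""
        return self.K_coeff * self.R * self.T / N


@dataclass(frozen=True)
class SuperhelicalDomain:
    """A sequence under superhelical stress."""

    sequence: str
    sigma: float
    origin: int = 0            # genomic coordinate of the first base (0-based)
    anchor: int | None = None  # e.g. TSS position, for distance reporting
    h: float = 10.4

    @property
    def N(self) -> int:
        return len(self.sequence)

    @property
    def alpha(self) -> float:
        """Linking difference in turns: sigma * N / h."""
        return self.sigma * self.N / self.h


@dataclass(frozen=True)
class MeltState:
    """One melted configuration: disjoint, non-adjacent open runs."""

    runs: tuple[tuple[int, int], ...]  # (start, length), 0-based half-open
    G: float

    @property
    def n(self) -> int:
        return sum(l for _, l in self.runs)

    @property
    def r(self) -> int:
        return len(self.runs)


@dataclass
class StateEnsemble:
    """Low-energy state ensemble in compact array form.

    ``starts``/``lengths`` are (M, max_runs) int arrays padded with -1; the
    helical state is the all-(-1) row.  ``states`` materializes the list of
    :class:`MeltState` objects on demand (fine for test-scale domains; large
    ensembles are consumed directly from the arrays by
    :func:`melt_profile`).
    """

    domain: SuperhelicalDomain
    params: SIDDParams
    starts: np.ndarray
    lengths: np.ndarray
    G: np.ndarray
    Z: float
    G_min: float

    def __len__(self) -> int:
        return self.G.size

    @property
    def states(self) -> list[MeltState]:
        out = []
        for i in range(self.G.size):
            runs = tuple(
                (int(s), int(l))
                for s, l in zip(self.starts[i], self.lengths[i])
                if s >= 0
            )
            out.append(MeltState(runs=runs, G=float(self.G[i])))
        return out


@dataclass
class TransitionProbabilityProfile:
    """Per-base-pair equilibrium melting probability."""

    p: np.ndarray
    origin: int = 0
    anchor: int | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class MeltPeak:
    start: int      # genomic
    end: int        # genomic, half-open
    summit: int     # genomic
    max_p: float
    distance_to_anchor: int | None


def make_domain(
    fasta_record,
    sigma: float,
    params: SIDDParams | None = None,
    anchor: int | None = None,
    origin: int = 0,
) -> SuperhelicalDomain:
    """Build a superhelical domain from a sequence or Bio.SeqRecord.

    Raises :class:`InvalidAlphabetError` on the first non-ACGT character
    (after uppercasing; N and IUPAC ambiguity codes are rejected).
    """
    params = params or SIDDParams()
    seq = str(getattr(fasta_record, "seq", fasta_record)).upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    for i, c in enumerate(seq):
        if c not in "ACGT":
            raise InvalidAlphabetError(c, i)
    return SuperhelicalDomain(sequence=seq, sigma=sigma, origin=origin, anchor=anchor, h=params.h)


def _b_array(domain: SuperhelicalDomain, params: SIDDParams) -> np.ndarray:
    arr = np.frombuffer(domain.sequence.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    return np.where(is_at, params.b_AT, params.b_GC)


def residual_energy(n, alpha: float, K: float, h: float, C: float):
    """Residual supercoiling free energy after opening n bp (closed form)."""
    n = np.asarray(n, dtype=float)
    return 0.5 * K * (alpha + n / h) ** 2 / (1.0 + K * n / (_TWO_PI_SQ_4 * C))


def state_energy(domain: SuperhelicalDomain, state: MeltState, params: SIDDParams) -> float:
    """Free energy of one melted state, kcal/mol."""
    b = _b_array(domain, params)
    sum_b = 0.0
    for s, l in state.runs:
        sum_b += float(b[s : s + l].sum())
    K = params.K(domain.N)
    g_res = float(residual_energy(state.n, domain.alpha, K, params.h, params.C))
    return params.a * state.r + sum_b + g_res


def enumerate_states(
    domain: SuperhelicalDomain,
    params: SIDDParams | None = None,
    max_states: int = 20_000_000,
) -> StateEnsemble:
    """Enumerate all melted states within ``theta`` of the energy minimum.

    The helical state is always included.  States are returned in a
    deterministic order (energy, then leftmost run start, then length).
    Raises :class:`EnsembleTooLargeError` if the admitted count would
    exceed ``max_states``.
    """
    params = params or SIDDParams()
    N = domain.N
    b = _b_array(domain, params)
    P = np.concatenate(([0.0], np.cumsum(b)))  # prefix sums
    K = params.K(domain.N)
    alpha = domain.alpha
    g_res = residual_energy(np.arange(N + 1), alpha, K, params.h, params.C)

    if params.max_runs <= 2:
        starts, lengths, G = _enumerate_fast(N, P, g_res, params, max_states)
    else:
        starts, lengths, G = _enumerate_dfs(N, P, g_res, params, max_states)

    g_min = float(G.min())
    keep = G <= g_min + params.theta + 1e-12
    starts, lengths, G = starts[keep], lengths[keep], G[keep]
    # canonical order: energy, then leftmost run start, then lengths
    order = np.lexsort(
        tuple(lengths[:, j] for j in range(lengths.shape[1] - 1, -1, -1))
        + tuple(starts[:, j] for j in range(starts.shape[1] - 1, -1, -1))
        + (G,)
    )
    starts, lengths, G = starts[order], lengths[order], G[order]
    Z_shifted = float(np.exp(-(G - g_min) / params.RT).sum())
    raw = g_min / params.RT
    Z = Z_shifted * math.exp(-raw) if abs(raw) < 600 else Z_shifted
    return StateEnsemble(
        domain=domain, params=params, starts=starts, lengths=lengths,
        G=G, Z=Z, G_min=g_min,
    )


def _too_large(max_states):
    return EnsembleTooLargeError(
        f"more than {max_states} states admitted; reduce theta, "
        f"max_runs, or domain length, or raise max_states"
    )


def _enumerate_fast(N, P, g_res, params: SIDDParams, max_states):
    """Vectorized enumeration for max_runs <= 2."""
    a, theta = params.a, params.theta
    # Window b-sums per length; exact per-length minima for pruning.
    W = [None] + [P[l:] - P[:-l] for l in range(1, N + 1)]
    minW = np.array([0.0] + [float(w.min()) for w in W[1:]])

    g_helical = float(g_res[0])
    r1_bound = a + minW[1:] + g_res[1 : N + 1]
    # T0 >= G_min + theta is guaranteed because G_min <= min(helical, best r=1).
    T0 = min(g_helical, float(r1_bound.min())) + theta + 1e-12

    R = max(params.max_runs, 1)
    s_chunks = [np.full((1, R), -1, dtype=np.int32)]
    l_chunks = [np.full((1, R), -1, dtype=np.int32)]
    g_chunks = [np.array([g_helical])]
    count = 1

    # r = 1
    for l in range(1, N + 1):
        budget = T0 - a - g_res[l]
        if minW[l] > budget:
            continue
        s1 = np.nonzero(W[l] <= budget)[0].astype(np.int32)
        if s1.size == 0:
            continue
        count += s1.size
        if count > max_states:
            raise _too_large(max_states)
        sc = np.full((s1.size, R), -1, dtype=np.int32)
        lc = np.full((s1.size, R), -1, dtype=np.int32)
        sc[:, 0] = s1
        lc[:, 0] = l
        s_chunks.append(sc)
        l_chunks.append(lc)
        g_chunks.append(a + W[l][s1] + g_res[l])

    # r = 2: ordered run pairs separated by >= 1 closed bp
    if params.max_runs >= 2:
        for l1 in range(1, N - 1):
            for l2 in range(1, N - l1):
                n = l1 + l2
                budget = T0 - 2 * a - g_res[n]
                if minW[l1] + minW[l2] > budget:
                    continue
                i1 = np.nonzero(W[l1] <= budget - minW[l2])[0]
                i2 = np.nonzero(W[l2] <= budget - minW[l1])[0]
                if i1.size == 0 or i2.size == 0:
                    continue
                w1 = W[l1][i1]
                w2 = W[l2][i2]
                ok = (w1[:, None] + w2[None, :] <= budget) & (
                    i2[None, :] >= i1[:, None] + l1 + 1
                )
                ii, jj = np.nonzero(ok)
                if ii.size == 0:
                    continue
                count += ii.size
                if count > max_states:
                    raise _too_large(max_states)
                sc = np.empty((ii.size, R), dtype=np.int32)
                lc = np.empty((ii.size, R), dtype=np.int32)
                sc[:, 0] = i1[ii]
                lc[:, 0] = l1
                sc[:, 1] = i2[jj]
                lc[:, 1] = l2
                s_chunks.append(sc)
                l_chunks.append(lc)
                g_chunks.append(2 * a + w1[ii] + w2[jj] + g_res[n])

    return (
        np.concatenate(s_chunks),
        np.concatenate(l_chunks),
        np.concatenate(g_chunks),
    )


def _enumerate_dfs(N, P, g_res, params: SIDDParams, max_states):
    """Generic recursive enumeration for arbitrary max_runs (small domains)."""
    a = params.a
    runs_list: list[tuple[tuple[int, int], ...]] = []
    energies: list[float] = []

    def emit(runs, sum_b):
        n = sum(l for _, l in runs)
        g = a * len(runs) + sum_b + float(g_res[n])
        runs_list.append(tuple(runs))
        energies.append(g)
        if len(runs_list) > max_states:
            raise _too_large(max_states)

    def rec(pos, runs, sum_b):
        emit(runs, sum_b)
        if len(runs) >= params.max_runs:
            return
        for s in range(pos, N):
            for l in range(1, N - s + 1):
                w = float(P[s + l] - P[s])
                runs.append((s, l))
                rec(s + l + 1, runs, sum_b + w)
                runs.pop()

    rec(0, [], 0.0)
    R = max(params.max_runs, 1)
    starts = np.full((len(runs_list), R), -1, dtype=np.int32)
    lengths = np.full((len(runs_list), R), -1, dtype=np.int32)
    for i, runs in enumerate(runs_list):
        for j, (s, l) in enumerate(runs):
            starts[i, j] = s
            lengths[i, j] = l
    return starts, lengths, np.array(energies)


def melt_profile(ensemble: StateEnsemble) -> TransitionProbabilityProfile:
    """Boltzmann-average the ensemble into per-bp melting probabilities.

    Accumulation is O(states) via a difference array over run intervals.
    """
    N = ensemble.domain.N
    RT = ensemble.params.RT
    w = np.exp(-(ensemble.G - ensemble.G_min) / RT)
    Z = w.sum()
    diff = np.zeros(N + 1)
    for j in range(ensemble.starts.shape[1]):
        s = ensemble.starts[:, j]
        l = ensemble.lengths[:, j]
        valid = s >= 0
        if not valid.any():
            continue
        np.add.at(diff, s[valid], w[valid])
        np.subtract.at(diff, s[valid] + l[valid], w[valid])
    p = np.cumsum(diff[:N]) / Z
    p = np.clip(p, 0.0, 1.0)  # guard float round-off at the bounds
    return TransitionProbabilityProfile(
        p=p, origin=ensemble.domain.origin, anchor=ensemble.domain.anchor
    )


def brute_force_profile(
    domain: SuperhelicalDomain, params: SIDDParams | None = None
) -> TransitionProbabilityProfile:
    """Exact profile by enumerating all 2^N open/closed configurations.

    Configurations with more than ``params.max_runs`` runs are excluded so
    the state space matches :func:`enumerate_states`; no theta cutoff is
    applied.  Test oracle only: refuses N > 22.
    """
    params = params or SIDDParams()
    N = domain.N
    if N > 22:
        raise ValueError("brute_force_profile is a combinatorial oracle; N must be <= 22")
    b = _b_array(domain, params)
    K = params.K(N)
    masks = np.arange(1 << N, dtype=np.uint32)
    n = np.bitwise_count(masks).astype(np.int64)
    run_starts = masks & ~(masks << np.uint32(1))
    r = np.bitwise_count(run_starts).astype(np.int64)
    keep = r <= params.max_runs
    masks, n, r = masks[keep], n[keep], r[keep]
    sum_b = np.zeros(masks.size)
    for i in range(N):
        sum_b += ((masks >> np.uint32(i)) & np.uint32(1)) * b[i]
    g_res = residual_energy(n, domain.alpha, K, params.h, params.C)
    G = params.a * r + sum_b + g_res
    w = np.exp(-(G - G.min()) / params.RT)
    Z = w.sum()
    p = np.empty(N)
    for i in range(N):
        open_i = ((masks >> np.uint32(i)) & np.uint32(1)).astype(bool)
        p[i] = w[open_i].sum() / Z
    return TransitionProbabilityProfile(p=p, origin=domain.origin, anchor=domain.anchor)


def find_melt_peaks(
    profile: TransitionProbabilityProfile,
    p_threshold: float = 0.5,
    anchor: int | None = None,
) -> list[MeltPeak]:
    """Call maximal contiguous runs of p(x) >= threshold as melt peaks.

    Summit is the leftmost argmax within the run; distances to the anchor
    (e.g. a TSS) are signed, negative = upstream.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    anchor = anchor if anchor is not None else profile.anchor
    p = profile.p
    above = p >= p_threshold
    peaks: list[MeltPeak] = []
    i = 0
    N = p.size
    while i < N:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < N and above[j]:
            j += 1
        summit_local = i + int(np.argmax(p[i:j]))
        summit = profile.origin + summit_local
        peaks.append(
            MeltPeak(
                start=profile.origin + i,
                end=profile.origin + j,
                summit=summit,
                max_p=float(p[summit_local]),
                distance_to_anchor=(summit - anchor) if anchor is not None else None,
            )
        )
        i = j
    return peaks


def strongest_peak(peaks: Sequence[MeltPeak]) -> MeltPeak | None:
    """Peak with maximal max_p; ties broken by leftmost summit."""
    if not peaks:
        return None
    return min(peaks, key=lambda pk: (-pk.max_p, pk.summit))


def profile_to_bedgraph(profile: TransitionProbabilityProfile, chrom: str, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(profile.p):
            s = profile.origin + i
            fh.write(f"{chrom}\t{s}\t{s + 1}\t{v:.6g}\n")


def peaks_to_bed(peaks: Iterable[MeltPeak], chrom: str, path) -> None:
    with open(path, "w") as fh:
        for k, pk in enumerate(peaks):
            score = int(round(1000 * pk.max_p))
            fh.write(f"{chrom}\t{pk.start}\t{pk.end}\tpeak_{k + 1}\t{score}\t.\n")
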