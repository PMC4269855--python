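"""Penalized Gaussian segmentation of per-chromosome genomic signals.

Two exact routes are provided, both minimizing the within-segment sum of
squared errors (the Gaussian maximum-likelihood contrast under a
homoscedastic model):

* a fixed-K dynamic program over K = 1..Kmax segments, with the number of
  segments chosen by the penalty C*K*(2.5 + log(P/K)) whose constant C is
  calibrated by the slope heuristic (default route, "cghseg");
* PELT (Pruned Exact Linear Time) with a per-segment penalty rho*log(P),
  whose constant rho is calibrated per chromosome by a stability-plateau
  rule ("pelt" route).

Both dynamic programs are exact; PELT's pruning never changes the optimum
for this additive cost.  Tie-breaks prefer the earliest breakpoint, so all
results are deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SEGMENT_COLUMNS, SignalMatrix, split_by_chromosome

__all__ = [
    "Segmentation",
    "PenaltySpec",
    "segment_cost",
    "segment_fixed_k",
    "lavielle_penalty",
    "select_k_slope_heuristic",
    "pelt",
    "calibrate_rho",
    "segment_profile",
    "smooth_by_segmentation",
    "SegmentationModel",
    "SegmentationResults",
]

_DEFAULT_KMAX = 30


@dataclass(frozen=True)
class Segmentation:
    """Piecewise-constant fit of one series.

    ``ends`` holds the 1-based last index of each segment (so the final
    entry equals the series length P); ``means`` the per-segment averages;
    ``sse`` the total within-segment sum of squared errors.
    """

    P: int
    ends: np.ndarray
    means: np.ndarray
    sse: float

    def __post_init__(self):
        ends = np.asarray(self.ends, dtype=np.int64)
        means = np.asarray(self.means, dtype=np.float64)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "means", means)
        if len(ends) != len(means):
            raise ValueError("one mean per segment required")
        if len(ends) == 0 or ends[-1] != self.P:
            raise ValueError("last segment must end at P")
        if (np.diff(ends) <= 0).any() or ends[0] <= 0:
            raise ValueError("segment ends must be strictly increasing and positive")
        if self.sse < -1e-9:
            raise ValueError("sse must be nonnegative")

    @property
    def K(self) -> int:
        return len(self.ends)

    @property
    def starts(self) -> np.ndarray:
        """1-based first index of each segment."""
        return np.concatenate(([1], self.ends[:-1] + 1))

    def fitted(self) -> np.ndarray:
        """Expand the piecewise-constant fit to a length-P series."""
        lengths = np.diff(np.concatenate(([0], self.ends)))
        return np.repeat(self.means, lengths)


@dataclass(frozen=True)
class PenaltySpec:
    """Choice of segmentation route and its penalty constants.

    method: 'lavielle_slope_heuristic' (fixed-K DP + slope heuristic; the
    constant C is calibrated from data unless given) or 'pelt_log' (PELT
    with per-segment penalty rho*log(P); rho calibrated per chromosome
    unless given).  Kmax caps the fixed-K dynamic program.
    """

    method: str = "lavielle_slope_heuristic"
    C: Optional[float] = None
    rho: Optional[float] = None
    Kmax: int = _DEFAULT_KMAX

    def __post_init__(self):
        if self.method not in ("lavielle_slope_heuristic", "pelt_log"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.C is not None and self.C <= 0:
            raise ValueError("C must be positive")
        if self.rho is not None and self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.Kmax < 1:
            raise ValueError("Kmax must be >= 1")


class _PrefixCost:
    """O(1) within-segment SSE queries via prefix sums of y and y^2."""

    __slots__ = ("s1", "s2", "n")

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=np.float64)
        self.n = len(y)
        self.s1 = np.concatenate(([0.0], np.cumsum(y)))
        self.s2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(self, i: int, j: int) -> float:
        """SSE of segment covering 1-based positions i..j inclusive."""
        n = j - i + 1
        s = self.s1[j] - self.s1[i - 1]
        q = self.s2[j] - self.s2[i - 1]
        return max(q - s * s / n, 0.0)

    def cost_matrix(self) -> np.ndarray:
        """Full (P, P) matrix C[a, b] = SSE of 0-based inclusive span a..b.

        Invalid entries (a > b) are +inf.  Memory is O(P^2): only used for
        series short enough for the fixed-K DP anyway.
        """
        P = self.n
        a = np.arange(P)
        s = self.s1[1:][None, :] - self.s1[:-1][:, None]   # sum over a..b
        q = self.s2[1:][None, :] - self.s2[:-1][:, None]
        n = a[None, :] - a[:, None] + 1
        with np.errstate(divide="ignore", invalid="ignore"):
            cost = q - s * s / n
        cost[n <= 0] = np.inf
        return np.maximum(cost, 0.0, out=cost)


def segment_cost(y, i: int, j: int) -> float:
    """Gaussian ML cost (SSE around the segment mean) of y_i..y_j.

    Indices are 1-based inclusive, matching the statistical convention for
    a segment spanning observations i..j.
    """
    y = np.asarray(y, dtype=np.float64)
    if not (1 <= i <= j <= len(y)):
        raise ValueError(f"invalid segment bounds ({i}, {j}) for series of length {len(y)}")
    return _PrefixCost(y).sse(i, j)


def segment_fixed_k(y, Kmax: int) -> list:
    """Exact best segmentations into K = 1..Kmax segments.

    Classical O(Kmax * P^2) dynamic program on the SSE cost; each returned
    Segmentation is the global optimum for its K, so sse is non-increasing
    in K.  Ties prefer the earliest breakpoint.
    """
    y = np.asarray(y, dtype=np.float64)
    P = len(y)
    if P == 0:
        raise ValueError("empty series")
    if not (1 <= Kmax <= P):
        raise ValueError(f"Kmax must be in 1..P={P}, got {Kmax}")

    pc = _PrefixCost(y)
    cost = pc.cost_matrix()  # cost[a, b], 0-based inclusive

    # F[k][b] = optimal cost of splitting y[0..b] into k+1 segments
    F = np.empty((Kmax, P))
    back = np.zeros((Kmax, P), dtype=np.int64)  # start index of last segment
    F[0] = cost[0]
    for k in range(1, Kmax):
        # candidate start a of the last segment: total = F[k-1][a-1] + cost[a, b]
        M = F[k - 1][: P - 1, None] + cost[1:, :]  # rows a-1 = 0..P-2
        # argmin over rows; first occurrence = smallest a = earliest breakpoint
        amin = np.nanargmin(M, axis=0)
        F[k] = M[amin, np.arange(P)]
        back[k] = amin + 1
        F[k][:k] = np.inf  # cannot split fewer points than segments

    out = []
    for k in range(Kmax):
        ends = np.empty(k + 1, dtype=np.int64)
        b = P - 1
        for kk in range(k, -1, -1):
            ends[kk] = b + 1  # 1-based end
            a = back[kk][b] if kk > 0 else 0
            b = a - 1
        starts = np.concatenate(([0], ends[:-1]))
        # slice means rather than prefix differences: exact for constant data
        means = np.array([float(np.mean(y[s:e])) for s, e in zip(starts, ends)])
        sse = float(sum(pc.sse(s + 1, e) for s, e in zip(starts, ends)))
        out.append(Segmentation(P=P, ends=ends, means=means, sse=sse))
    return out


def lavielle_penalty(K: int, P, C: float) -> float:
    """Model-selection penalty C * K * (2.5 + log(P / K)), natural log."""
    if C <= 0:
        raise ValueError("C must be positive")
    if not (1 <= K <= P):
        raise ValueError(f"K must be in 1..P, got K={K}, P={P}")
    return C * K * (2.5 + math.log(P / K))


def penalty_shape(K, P) -> np.ndarray:
    """The K-dependent factor K * (2.5 + log(P/K)) of the penalty."""
    K = np.asarray(K, dtype=np.float64)
    return K * (2.5 + np.log(P / K))


def select_k_slope_heuristic(sse_by_k, P: int, *, fit_fraction: float = 0.5):
    """Choose the number of segments by the slope heuristic.

    The empirical contrast sse(K) behaves, for K beyond the true number of
    segments, like an affine function of the penalty shape
    K*(2.5+log(P/K)) with negative slope -s.  A robust (Theil-Sen) line fit
    over the largest-K half of the range estimates s; the calibrated
    constant is C = 2*s (the factor-2 rule), and
    K* = argmin_K sse(K) + C*K*(2.5+log(P/K)).

    Returns (K*, C_hat).
    """
    sse_by_k = np.asarray(sse_by_k, dtype=np.float64)
    Kmax = len(sse_by_k)
    if Kmax < 2:
        raise ValueError("slope heuristic needs sse for at least K=1, 2")
    if np.any(np.diff(sse_by_k) > 1e-8 * max(sse_by_k[0], 1.0)):
        raise ValueError("sse_by_k must be non-increasing in K")

    Ks = np.arange(1, Kmax + 1)
    shape = penalty_shape(Ks, P)
    lo = max(int(math.ceil(Kmax * (1.0 - fit_fraction))) - 1, 0)
    if Kmax - lo < 2:
        lo = Kmax - 2
    xs, ys = shape[lo:], sse_by_k[lo:]
    if len(xs) == 2:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    else:
        slope = stats.theilslopes(ys, xs).slope
    s_hat = max(-slope, 0.0)
    if s_hat <= 0.0:
        # flat contrast: any positive C selects K=1; use a scale-aware floor
        s_hat = max(sse_by_k[0] / max(P, 1), np.finfo(float).tiny)
    C_hat = 2.0 * s_hat
    crit = sse_by_k + C_hat * shape
    K_star = int(np.argmin(crit)) + 1
    return K_star, float(C_hat)


def _optimal_partition(y: np.ndarray, beta: float, prune: bool = True) -> Segmentation:
    """Penalized optimal partitioning, optionally with PELT pruning.

    Minimizes sum of segment SSEs + (number of segments) * beta.  With
    ``prune`` the candidate set is reduced by the PELT condition, which is
    valid (K=0) for the concentrated Gaussian cost; the solution is
    identical either way.
    """
    y = np.asarray(y, dtype=np.float64)
    P = len(y)
    if P == 0:
        raise ValueError("empty series")
    pc = _PrefixCost(y)
    s1, s2 = pc.s1, pc.s2

    F = np.empty(P + 1)
    F[0] = -beta
    last = np.zeros(P + 1, dtype=np.int64)
    cands = [0]
    for t in range(1, P + 1):
        tau = np.array(cands)
        n = t - tau
        seg_sum = s1[t] - s1[tau]
        seg_cost = (s2[t] - s2[tau]) - seg_sum * seg_sum / n
        total = F[tau] + seg_cost + beta
        j = int(np.argmin(total))  # first occurrence -> earliest changepoint
        F[t] = total[j]
        last[t] = tau[j]
        if prune:
            keep = total - beta <= F[t] + 1e-12
            cands = [c for c, k in zip(cands, keep) if k]
        cands.append(t)

    ends = []
    t = P
    while t > 0:
        ends.append(t)
        t = last[t]
    ends = np.array(ends[::-1], dtype=np.int64)
    starts = np.concatenate(([0], ends[:-1]))
    means = np.array([float(np.mean(y[s:e])) for s, e in zip(starts, ends)])
    sse = float(sum(pc.sse(s + 1, e) for s, e in zip(starts, ends)))
    return Segmentation(P=P, ends=ends, means=means, sse=sse)


def pelt(y, rho: float) -> Segmentation:
    """Exact minimizer of total SSE + K * rho * log(P) via PELT.

    The per-segment additive penalty is beta = rho*log(P).  Pruning keeps
    the computation near-linear in P without changing the optimum.
    """
    y = np.asarray(y, dtype=np.float64)
    if rho <= 0:
        raise ValueError("rho must be positive")
    P = len(y)
    if P == 0:
        raise ValueError("empty series")
    beta = rho * math.log(P) if P > 1 else rho
    return _optimal_partition(y, beta, prune=True)


def _mad_variance(y: np.ndarray) -> float:
    """Robust noise-variance estimate from first differences.

    sigma^2 = (MAD(diff(y)) / Phi^-1(3/4))^2 / 2; robust to the sparse
    level shifts a piecewise-constant signal contributes to diff(y).
    """
    d = np.diff(np.asarray(y, dtype=np.float64))
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    sigma2 = (mad / 0.6744897501960817) ** 2 / 2.0
    if sigma2 <= 0.0:
        sigma2 = float(np.var(d)) / 2.0
    return sigma2


def calibrate_rho(y, *, n_grid: int = 40, span=(0.05, 50.0)) -> float:
    """Sample-specific PELT penalty constant by a stability-plateau rule.

    pelt is run over a logarithmic grid of rho spanning
    [span[0], span[1]] * sigma^2 (sigma^2 the robust first-difference
    variance estimate); the returned rho is the geometric midpoint of the
    widest log-rho interval on which the segment count K(rho) is constant.
    The rule rewards segmentations that persist over a broad penalty range
    and is deterministic for fixed input.  This calibration is this
    package's own construction.

    Series shorter than 20 points fall back to rho = sigma^2 with a
    warning.  Ties between equally wide plateaus prefer the smaller K,
    then the larger rho.
    """
    y = np.asarray(y, dtype=np.float64)
    sigma2 = _mad_variance(y)
    if sigma2 <= 0.0:
        sigma2 = max(float(np.var(y)) * 1e-6, np.finfo(float).tiny * 1e6)
    if len(y) < 20:
        warnings.warn("series shorter than 20 points: falling back to rho = sigma^2")
        return float(sigma2)

    rhos = np.geomspace(span[0] * sigma2, span[1] * sigma2, n_grid)
    ks = np.array([pelt(y, r).K for r in rhos])

    # runs of constant K; width measured in grid steps (uniform in log-rho)
    best = None  # (length, -K(desc via smaller K), rho_mid) with custom compare
    i = 0
    while i < len(ks):
        j = i
        while j + 1 < len(ks) and ks[j + 1] == ks[i]:
            j += 1
        length = j - i + 1
        mid = math.sqrt(rhos[i] * rhos[j])
        key = (length, -ks[i], mid)
        if best is None or key > best:
            best = key
        i = j + 1
    return float(best[2])


def _segments_to_rows(seg: Segmentation, positions: np.ndarray, chrom: str,
                      sample: str) -> list:
    rows = []
    starts = seg.starts
    for s, e, m in zip(starts, seg.ends, seg.means):
        rows.append(
            {
                "chromosome": chrom,
                "start": int(positions[s - 1]) - 1,  # BED: 0-based half-open
                "end": int(positions[e - 1]),
                "sample": sample,
                "mean": float(m),
                "n_probes": int(e - s + 1),
            }
        )
    return rows


def _segment_series(y: np.ndarray, spec: PenaltySpec) -> Segmentation:
    P = len(y)
    if P < 2:
        warnings.warn("chromosome with fewer than 2 markers: single trivial segment")
        return Segmentation(P=P, ends=np.array([P]), means=np.array([float(np.mean(y))]),
                            sse=0.0)
    if spec.method == "pelt_log":
        rho = spec.rho if spec.rho is not None else calibrate_rho(y)
        return pelt(y, rho)
    kmax = max(min(P // 2, spec.Kmax), 1)
    segs = segment_fixed_k(y, kmax)
    if kmax == 1:
        return segs[0]
    sse_by_k = np.minimum.accumulate([s.sse for s in segs])
    if spec.C is not None:
        crit = [s.sse + lavielle_penalty(s.K, P, spec.C) for s in segs]
        k_star = int(np.argmin(crit)) + 1
    else:
        k_star, _ = select_k_slope_heuristic(sse_by_k, P)
    return segs[k_star - 1]


def segment_profile(signal: SignalMatrix, sample: str,
                    method: PenaltySpec | str = "lavielle_slope_heuristic",
                    ) -> pd.DataFrame:
    """Segment one sample's profile chromosome by chromosome.

    Returns a BED-like segment table (chromosome, start, end, sample, mean,
    n_probes).  The penalty constant (C for the fixed-K route, rho for
    PELT) is calibrated independently on each chromosome unless fixed in
    the PenaltySpec.
    """
    if isinstance(method, str):
        method = PenaltySpec(method=method)
    col = signal.column(sample)  # KeyError for unknown sample
    rows = []
    for part in split_by_chromosome(signal):
        chrom = part.markers.chromosome[0]
        sl_values = part.values[:, signal.sample_index(sample)]
        seg = _segment_series(sl_values, method)
        rows.extend(_segments_to_rows(seg, part.markers.position, chrom, str(sample)))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def smooth_by_segmentation(signal: SignalMatrix, segments: pd.DataFrame) -> SignalMatrix:
    """Replace each marker value by its segment mean for its sample.

    Shape is preserved; dimensionality reduction happens downstream when
    identical columns collapse.  Every marker of every signal sample must
    be covered by exactly the segments of that sample.
    """
    out = signal.values.copy()
    pos = signal.markers.position
    chroms = signal.markers.chromosome
    for j, sample in enumerate(signal.samples):
        sub = segments[segments["sample"] == sample]
        if sub.empty:
            raise ValueError(f"no segments for sample {sample!r}")
        covered = np.zeros(len(pos), dtype=bool)
        for _, row in sub.iterrows():
            mask = (
                (chroms == row["chromosome"])
                & (pos > row["start"])
                & (pos <= row["end"])
            )
            out[mask, j] = row["mean"]
            covered |= mask
        if not covered.all():
            p = int(np.flatnonzero(~covered)[0])
            raise ValueError(
                f"marker {signal.markers.marker_id[p]!r} not covered by any "
                f"segment of sample {sample!r}"
            )
    return SignalMatrix(signal.markers, signal.samples, out, signal.signal_kind,
                        validate=False)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class SegmentationModel:
    """Penalized segmentation of a multi-sample signal matrix.

    Parameters
    ----------
    signal : SignalMatrix
        Copy-number, log2-ratio or mirrored-BAF signal.
    method : {'cghseg', 'pelt'} or PenaltySpec
        'cghseg' = fixed-K dynamic program + slope-heuristic penalty
        (default, faster); 'pelt' = PELT with calibrated rho*log(P).
    kmax, C, rho : optional overrides of the PenaltySpec fields.
    """

    _ALIASES = {"cghseg": "lavielle_slope_heuristic", "pelt": "pelt_log"}

    def __init__(self, signal: SignalMatrix, method="cghseg", *,
                 kmax: int = _DEFAULT_KMAX, C: Optional[float] = None,
                 rho: Optional[float] = None):
        self.signal = signal
        if isinstance(method, PenaltySpec):
            self.penalty = method
        else:
            method = self._ALIASES.get(method, method)
            self.penalty = PenaltySpec(method=method, C=C, rho=rho, Kmax=kmax)

    def fit(self, samples: Optional[Sequence[str]] = None) -> "SegmentationResults":
        samples = list(self.signal.samples) if samples is None else list(samples)
        tables = [segment_profile(self.signal, s, self.penalty) for s in samples]
        segments = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
            columns=SEGMENT_COLUMNS
        )
        return SegmentationResults(self, segments, samples)


class SegmentationResults:
    """Fitted segmentation: one piecewise-constant profile per sample."""

    def __init__(self, model: SegmentationModel, segments: pd.DataFrame, samples):
        self.model = model
        self.segments = segments
        self.samples = list(samples)

    def smooth(self) -> SignalMatrix:
        """Signal with every marker replaced by its segment mean."""
        sub = self.model.signal
        if set(self.samples) != set(sub.samples):
            keep = [sub.sample_index(s) for s in self.samples]
            sub = SignalMatrix(sub.markers, self.samples, sub.values[:, keep],
                               sub.signal_kind, validate=False)
        return smooth_by_segmentation(sub, self.segments)

    def sse(self, sample: str) -> float:
        """Residual SSE of one sample's piecewise-constant fit."""
        raw = self.model.signal.column(sample)
        smoothed = self.smooth().column(sample)
        return float(np.sum((raw - smoothed) ** 2))

    def summary(self) -> str:
        lines = [
            "Segmentation results",
            f"  method: {self.model.penalty.method}",
            f"  samples: {len(self.samples)}   markers: {self.model.signal.n_markers}",
            "",
            f"  {'sample':<16}{'segments':>9}{'breakpoints':>13}",
        ]
        for s in self.samples:
            sub = self.segments[self.segments["sample"] == s]
            lines.append(f"  {s:<16}{len(sub):>9}{max(len(sub) - sub['chromosome'].nunique(), 0):>13}")
        return "\n".join(lines)

    def plot(self, sample: str, path=None):
        from .plot import plot_profile

        return plot_profile(self.model.signal, self.segments, sample, path)
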