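"""Binned Hi-C contact matrices and the three contact-map statistics.

* separation scores S and R at a candidate junction — S is the between-class
  variance (Otsu-style) between the near-diagonal region on each side of the
  junction ("inner") and the cross-junction band ("outer"), accumulated over
  diagonal distances k = 1..k_max; R is the fraction of outer pixels falling
  below the inner mean, guarding against sparse maps;
* the erroneous-edge test: an edge is flagged when
  S_upper/S_upper,0 + S_lower/S_lower,0 >= s  and  R_upper + R_lower >= r,
  where S_side,0 is S with all outer pixel values zeroed;
* the misassembly score: for each bin b, a triangular motif along the
  diagonal compares the local per-distance band means mu_target,k(b) against
  the genome-wide means mu_all,k via a chi-square-like sum
  Score(b) = sum_k (mu_all,k - mu_target,k)^2 / mu_target,k,
  with peak detection and an automatic threshold P chosen to maximise the
  mean separation score over the implied cut set.

Junction geometry (junction between bins b-1 and b): at each diagonal
distance k, the outer pixels are the distance-k band crossing the junction,
{(i,j): i < b <= j, j-i = k}; the inner pixels of the upper side are the
distance-k band immediately before the junction, {(i,j): j-i = k, b-k <= j
< b}, and the lower side is its mirror image {(i,j): j-i = k, b <= i < b+k}.
Matching the distance on both sides keeps the two pixel classes comparable
under the strong distance decay of Hi-C contact counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assembly_model import AssemblyError

__all__ = [
    "HiCMatrix",
    "SeparationScores",
    "MisassemblyProfile",
    "build_matrix",
    "separation_scores",
    "is_erroneous_edge_hic",
    "global_distance_profile",
    "misassembly_score_profile",
    "detect_peaks",
    "select_threshold_P",
]


@dataclass
class HiCMatrix:
    scaffold_ids: tuple[str, ...]
    bin_size: int
    M: np.ndarray  # symmetric, counts
    junction_bin: int | None = None

    @property
    def n_bins(self) -> int:
        return self.M.shape[0]


@dataclass
class SeparationScores:
    S_upper: float
    S_lower: float
    R_upper: float
    R_lower: float
    S_upper_0: float
    S_lower_0: float

    @property
    def s_ratio_sum(self) -> float:
        up = self.S_upper / self.S_upper_0 if self.S_upper_0 > 0 else 0.0
        lo = self.S_lower / self.S_lower_0 if self.S_lower_0 > 0 else 0.0
        return up + lo

    @property
    def r_sum(self) -> float:
        return self.R_upper + self.R_lower


@dataclass
class MisassemblyProfile:
    scores: np.ndarray
    mu_all: np.ndarray  # index 1..k_max used; [0] unused
    peaks: list[int] = field(default_factory=list)
    P: float = math.inf


def build_matrix(
    lengths: list[tuple[str, int]],
    contacts,
    bin_size: int,
    junction_bin: int | None = None,
) -> HiCMatrix:
    """Bin contacts over one or more concatenated sequences.

    ``contacts`` is an iterable of (seq_a, pos_a, seq_b, pos_b) or a tuple of
    four numpy arrays. Trailing partial bins are dropped; contacts falling in
    a dropped bin are ignored. Positions at or beyond a sequence length raise.
    """
    if bin_size <= 0 or not lengths:
        raise AssemblyError("bin_size must be positive and sequences nonempty")
    offsets = {}
    lens = {}
    total_bins = 0
    for sid, ln in lengths:
        offsets[sid] = total_bins
        lens[sid] = ln
        total_bins += ln // bin_size
    M = np.zeros((total_bins, total_bins), dtype=np.float64)
    if isinstance(contacts, tuple) and len(contacts) == 4:
        sa, pa, sb, pb = contacts
        bi = np.empty(len(pa), dtype=np.int64)
        bj = np.empty(len(pb), dtype=np.int64)
        ok = np.ones(len(pa), dtype=bool)
        for sid in offsets:
            for arr_s, arr_p, out in ((sa, pa, bi), (sb, pb, bj)):
                m = arr_s == sid
                if not np.any(m):
                    continue
                if np.any(arr_p[m] >= lens[sid]):
                    raise AssemblyError(f"contact position beyond sequence {sid!r}")
                b = arr_p[m] // bin_size
                valid = b < lens[sid] // bin_size
                out[m] = offsets[sid] + np.minimum(b, max(0, lens[sid] // bin_size - 1))
                ok[m] &= valid
        known = np.isin(sa, list(offsets)) & np.isin(sb, list(offsets))
        ok &= known
        bi, bj = bi[ok], bj[ok]
        np.add.at(M, (bi, bj), 1.0)
        np.add.at(M, (bj, bi), 1.0)
        np.fill_diagonal(M, np.diagonal(M) / 2)  # self-bin contacts counted once
    else:
        for sa_, pa_, sb_, pb_ in contacts:
            for s, p in ((sa_, pa_), (sb_, pb_)):
                if s not in offsets:
                    raise AssemblyError(f"contact references unknown sequence {s!r}")
                if p >= lens[s]:
                    raise AssemblyError(f"contact position {p} beyond sequence {s!r}")
            ba = pa_ // bin_size
            bb = pb_ // bin_size
            if ba >= lens[sa_] // bin_size or bb >= lens[sb_] // bin_size:
                continue
            i, j = offsets[sa_] + ba, offsets[sb_] + bb
            M[i, j] += 1
            if i != j:
                M[j, i] += 1
    return HiCMatrix(tuple(sid for sid, _ in lengths), bin_size, M, junction_bin)


def _diag(M: np.ndarray, k: int) -> np.ndarray:
    return np.diagonal(M, offset=k)


def separation_scores(matrix: HiCMatrix, k_max: int = 10) -> SeparationScores:
    """Separation scores S and R (and the zeroed-outer normalisers) at the
    junction between bins b-1 and b."""
    if k_max < 1:
        raise AssemblyError("k_max must be >= 1")
    b = matrix.junction_bin
    if b is None or b < 1 or b > matrix.n_bins - 1:
        raise AssemblyError("junction_bin must leave at least one bin on each side")
    M = matrix.M
    n = matrix.n_bins

    S = {"upper": 0.0, "lower": 0.0}
    S0 = {"upper": 0.0, "lower": 0.0}
    Lsum = {"upper": 0.0, "lower": 0.0}
    Nout_sum = 0.0
    for k in range(1, k_max + 1):
        dk = _diag(M, k)  # dk[i] = M[i, i+k]
        # outer: i < b <= i+k  ->  i in [b-k, b-1], bounded to the matrix
        lo, hi = max(0, b - k), min(b, n - k)
        outer = dk[lo:hi]
        n_out = outer.size
        mu_out = outer.mean() if n_out else 0.0
        for side in ("upper", "lower"):
            if side == "upper":
                # j = i+k in [b-k, b-1]  ->  i in [b-2k, b-k-1]
                s, e = max(0, b - 2 * k), max(0, b - k)
            else:
                # i in [b, b+k-1], j = i+k <= n-1
                s, e = b, min(n - k, b + k)
            inner = dk[s:e]
            n_in = inner.size
            mu_in = inner.mean() if n_in else 0.0
            denom = (n_in + n_out) ** 2
            if denom > 0:
                S[side] += n_in * n_out * (mu_in - mu_out) ** 2 / denom
                S0[side] += n_in * n_out * (mu_in - 0.0) ** 2 / denom
            if n_out:
                Lsum[side] += float(np.count_nonzero(outer < mu_in))
        Nout_sum += n_out
    R_up = Lsum["upper"] / Nout_sum if Nout_sum > 0 else 0.0
    R_lo = Lsum["lower"] / Nout_sum if Nout_sum > 0 else 0.0
    return SeparationScores(S["upper"], S["lower"], R_up, R_lo, S0["upper"], S0["lower"])


def is_erroneous_edge_hic(
    scores: SeparationScores,
    s_threshold: float = 1.0,
    r_threshold: float = 1.6,
) -> bool:
    """True iff both the normalised-S and the R criteria hold.

    A zero normaliser (degenerate sparse map) contributes a ratio of 0.
    """
    return scores.s_ratio_sum >= s_threshold and scores.r_sum >= r_threshold


def global_distance_profile(matrices: list[HiCMatrix], k_max: int = 10) -> np.ndarray:
    """Pooled per-distance mean contact count mu_all,k over all supplied
    matrices (pooled pixels, not mean of means). Index 0 is unused."""
    if not matrices:
        raise AssemblyError("no matrices for the global distance profile")
    mu = np.zeros(k_max + 1)
    for k in range(1, k_max + 1):
        tot, cnt = 0.0, 0
        for m in matrices:
            if m.n_bins > k:
                d = _diag(m.M, k)
                tot += d.sum()
                cnt += d.size
        mu[k] = tot / cnt if cnt else 0.0
    return mu


def misassembly_score_profile(
    matrix: HiCMatrix,
    mu_all: np.ndarray,
    k_max: int = 10,
    motif_halfwidth: int = 10,
    zero_mean_floor: float = 0.5,
) -> MisassemblyProfile:
    """Per-bin misassembly score from a triangular motif along the diagonal.

    mu_target,k(b) is the mean over pixels (i, i+k) with both indices within
    ``motif_halfwidth`` bins of b; zero means are replaced by
    ``zero_mean_floor`` before dividing.
    """
    n = matrix.n_bins
    if n < k_max + 1:
        raise AssemblyError("matrix too small for the misassembly score")
    M = matrix.M
    scores = np.zeros(n)
    # per-k prefix sums over the diagonal for O(1) windowed means
    csums = {}
    for k in range(1, k_max + 1):
        d = _diag(M, k)
        csums[k] = np.concatenate(([0.0], np.cumsum(d)))
    for b in range(n):
        total = 0.0
        for k in range(1, k_max + 1):
            lo = max(0, b - motif_halfwidth)
            hi = min(n - k, b + motif_halfwidth - k + 1)
            if hi <= lo:
                continue
            c = csums[k]
            mu_t = (c[hi] - c[lo]) / (hi - lo)
            if mu_t <= 0:
                mu_t = zero_mean_floor
            total += (mu_all[k] - mu_t) ** 2 / mu_t
        scores[b] = total
    return MisassemblyProfile(scores, np.asarray(mu_all, dtype=float))


def detect_peaks(scores: np.ndarray, window: int = 2) -> list[int]:
    """Local maxima of the score profile.

    A bin is a peak iff its score is positive, strictly greater than every
    score in the ``window`` bins to its left, and at least as large as every
    score in the ``window`` bins to its right (plateaus keep their leftmost
    bin). Bins whose window extends past the profile are excluded.
    """
    n = len(scores)
    peaks = []
    for b in range(window, n - window):
        v = scores[b]
        if v <= 0:
            continue
        if all(v > scores[b - d] for d in range(1, window + 1)) and all(
            v >= scores[b + d] for d in range(1, window + 1)
        ):
            peaks.append(b)
    return peaks


def select_threshold_P(
    profile: MisassemblyProfile,
    matrix: HiCMatrix,
    k_max: int = 10,
    s_threshold: float = 1.0,
    r_threshold: float = 1.6,
    peak_window: int = 2,
) -> tuple[float, list[int]]:
    """Automatic peak threshold P and the flagged misassembly-candidate bins.

    P is swept over {0} union {peak heights}; for each trial value the
    scaffold is notionally split at every peak above it and the mean
    separation score S (both sides summed) over the cuts is computed; the P
    maximising that mean wins, ties resolved toward larger P (fewer splits).
    Peaks above P* are flagged only if they also pass the erroneous-edge
    test at their boundary.
    """
    peaks = detect_peaks(profile.scores, peak_window)
    profile.peaks = peaks
    usable = [b for b in peaks if 1 <= b <= matrix.n_bins - 1]
    if not usable:
        profile.P = math.inf
        return math.inf, []
    cut_scores = {}
    for b in usable:
        sc = separation_scores(
            HiCMatrix(matrix.scaffold_ids, matrix.bin_size, matrix.M, junction_bin=b), k_max
        )
        cut_scores[b] = sc
    heights = sorted({0.0} | {float(profile.scores[b]) for b in usable})
    best_P, best_mean = math.inf, -math.inf
    for P in heights:
        cuts = [b for b in usable if profile.scores[b] > P]
        if not cuts:
            continue
        mean_s = float(np.mean([cut_scores[b].S_upper + cut_scores[b].S_lower for b in cuts]))
        if mean_s > best_mean or (mean_s == best_mean and P > best_P):
            best_mean, best_P = mean_s, P
    if not math.isfinite(best_P) and best_mean == -math.inf:
        profile.P = math.inf
        return math.inf, []
    candidates = [
        b
        for b in usable
        if profile.scores[b] > best_P
        and is_erroneous_edge_hic(cut_scores[b], s_threshold, r_threshold)
    ]
    profile.P = best_P
    return best_P, candidates
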