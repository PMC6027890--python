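"""k-mer spectrum genome profiling.

Canonical k-mer counting of short reads, the depth histogram, detection of
the error / haploid / diploid peak structure, spectrum-based genome-size
estimation, and heterozygosity ranking.

The depth spectrum of a heterozygous diploid sequenced at coverage c per
haplotype is bimodal above the error noise: k-mers private to one
haplotype (spanning a heterozygous site) pile up at depth ~c (the
"haploid" peak) while k-mers shared by both haplotypes pile up at ~2c
(the "diploid" peak). The haploid-peak area fraction is a monotone proxy
for per-base heterozygosity, and total filtered k-mer volume divided by
the homozygous depth gives the haploid genome size.

Counting is canonical: each window is identified with the lexicographic
minimum of itself and its reverse complement, encoded in 2 bits/base
(k <= 31 fits an int64). The inner rolling-code loop is numba-compiled;
counts come from one ``np.unique`` over the window codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .synthetic import ReadSet, encode


class SpectrumError(ValueError):
    """Raised when a histogram lacks the peak structure an operation needs."""


# ---------------------------------------------------------------------------
# Canonical window codes
# ---------------------------------------------------------------------------

@njit(cache=True)
def _canonical_codes(codes, k):  # pragma: no cover - compiled
    n = codes.shape[0]
    m_max = n - k + 1 if n >= k else 0
    out = np.empty(max(m_max, 0), dtype=np.int64)
    mask = (np.int64(1) << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = np.int64(0)
    rev = np.int64(0)
    valid = 0
    m = 0
    for i in range(n):
        b = codes[i]
        if b > 3:
            valid = 0
            fwd = 0
            rev = 0
            continue
        fwd = ((fwd << 2) | np.int64(b)) & mask
        rev = (rev >> 2) | (np.int64(3 - b) << shift)
        valid += 1
        if valid >= k:
            out[m] = fwd if fwd <= rev else rev
            m += 1
    return out[:m]


def canonical_codes(seq, k: int) -> np.ndarray:
    """Canonical 2-bit window codes for a sequence (str or uint8 codes).

    Windows containing a non-ACGT base are skipped. Palindromic k-mers
    cannot occur for odd k, so canonicalization is unambiguous.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (even k has no unique canonical form)")
    if not 3 <= k <= 31:
        raise ValueError("k must be odd and in [3, 31] (2-bit int64 encoding)")
    arr = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    if arr.size < k:
        raise ValueError("sequence shorter than k")
    return _canonical_codes(arr, k)


def kmer_set(seq, k: int = 31) -> set[int]:
    """Distinct canonical k-mer codes of a sequence."""
    return set(np.unique(canonical_codes(seq, k)).tolist())


# ---------------------------------------------------------------------------
# Histogram and depth index
# ---------------------------------------------------------------------------

@dataclass
class KmerHistogram:
    """Depth spectrum: distinct canonical k-mers per depth.

    ``total_kmers`` is the number of k-mer instances counted,
    i.e. sum(depth * count) over the histogram.
    """

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        return int(sum(d * c for d, c in self.counts.items()))

    @property
    def distinct_kmers(self) -> int:
        return int(sum(self.counts.values()))

    def dense(self, max_depth: int | None = None) -> np.ndarray:
        """Counts as a dense array indexed by depth (index 0 unused)."""
        top = max(self.counts) if self.counts else 0
        if max_depth is not None:
            top = min(top, max_depth)
        arr = np.zeros(top + 1, dtype=np.float64)
        for d, c in self.counts.items():
            if d <= top:
                arr[d] = c
        return arr

    def filtered_total(self, cutoff: int) -> int:
        """k-mer instances at depths strictly above the error cutoff."""
        return int(sum(d * c for d, c in self.counts.items() if d > cutoff))


@dataclass
class KmerDepthIndex:
    """Sorted canonical-code -> depth index supporting vectorized lookup."""

    k: int
    codes: np.ndarray  # sorted int64
    depths: np.ndarray  # int64, parallel to codes

    def query(self, query_codes: np.ndarray) -> np.ndarray:
        """Depth of each query code; absent k-mers report 0."""
        idx = np.searchsorted(self.codes, query_codes)
        idx = np.clip(idx, 0, self.codes.size - 1)
        hit = self.codes.size > 0
        out = np.zeros(query_codes.size, dtype=np.int64)
        if hit:
            found = self.codes[idx] == query_codes
            out[found] = self.depths[idx[found]]
        return out


def count_kmers(reads, k: int = 31) -> tuple[KmerHistogram, KmerDepthIndex]:
    """Count canonical k-mers in a read set.

    ``reads`` may be a :class:`ReadSet` (fast path over its code matrix) or
    any iterable of sequence strings. Returns the depth histogram and a
    queryable depth index; the two are consistent by construction.
    """
    if isinstance(reads, ReadSet):
        if len(reads) == 0:
            raise ValueError("empty read set")
        mat = reads.codes
        sep = np.full((mat.shape[0], 1), 4, dtype=np.uint8)
        flat = np.concatenate([mat, sep], axis=1).ravel()
    else:
        seqs = list(reads)
        if not seqs:
            raise ValueError("empty read set")
        flat = np.concatenate([np.append(encode(s), np.uint8(4)) for s in seqs])
    codes = canonical_codes(flat, k)
    if codes.size == 0:
        raise ValueError("no valid k-mer windows in input")
    uniq, depth = np.unique(codes, return_counts=True)
    dvals, dcounts = np.unique(depth, return_counts=True)
    hist = KmerHistogram(k, {int(d): int(c) for d, c in zip(dvals, dcounts)})
    return hist, KmerDepthIndex(k, uniq, depth.astype(np.int64))


def sequence_kmer_depths(seq: str, index: KmerDepthIndex) -> np.ndarray:
    """Read-set depth of every k-mer window of ``seq`` (0 where absent)."""
    return index.query(canonical_codes(seq, index.k))


# ---------------------------------------------------------------------------
# Peak structure
# ---------------------------------------------------------------------------

def _smooth(arr: np.ndarray, window: int = 3) -> np.ndarray:
    if arr.size < window:
        return arr.astype(np.float64)
    kern = np.ones(window) / window
    return np.convolve(arr, kern, mode="same")


def find_error_cutoff(hist: KmerHistogram, window: int = 3) -> int:
    """Depth of the first local minimum after the sequencing-error peak.

    The error k-mers form an extreme peak at the origin of the depth axis;
    the cutoff is the depth at which the smoothed spectrum first starts
    rising again. Depths <= cutoff are treated as error k-mers. A spectrum
    that only decreases (no real-coverage peak) raises :class:`SpectrumError`
    rather than guessing.
    """
    dense = _smooth(hist.dense(), window)
    if dense.size < 4:
        raise SpectrumError("histogram too short to locate an error cutoff")
    # apex of the error peak: first local maximum of the smoothed spectrum
    # (smoothing can shift the apex off depth 1, so scan rather than assume)
    apex = None
    for i in range(1, dense.size - 1):
        if dense[i] >= dense[i - 1] and dense[i] > dense[i + 1]:
            apex = i
            break
    if apex is None:
        raise SpectrumError("monotone spectrum: no separable error peak")
    for i in range(apex + 1, dense.size - 1):
        if dense[i + 1] > dense[i]:
            return i
    raise SpectrumError("monotone decreasing spectrum: no separable error peak")


def _local_maxima(s: np.ndarray, lo: int) -> list[int]:
    out = []
    for i in range(max(lo, 1), s.size - 1):
        if s[i] > 0 and s[i] >= s[i - 1] and s[i] > s[i + 1]:
            out.append(i)
    return out


@dataclass
class GenomeProfile:
    """Peak structure of a k-mer spectrum and the statistics derived from it.

    ``het_fraction`` = A_h / (A_h + A_d), the haploid-peak share of the
    two-peak area: the quantity the heterozygosity ranking sorts on.
    """

    error_cutoff: int
    haploid_peak: tuple[int, float]  # (depth, area in distinct k-mers); (0, 0) if absent
    diploid_peak: tuple[int, float]
    genome_size_estimate: float
    het_fraction: float
    filtered_total: int

    @property
    def haploid_depth(self) -> int:
        return self.haploid_peak[0]

    @property
    def diploid_depth(self) -> int:
        return self.diploid_peak[0]


def detect_peaks(
    hist: KmerHistogram,
    cutoff: int,
    ratio_range: tuple[float, float] = (1.6, 2.4),
    min_peak_frac: float = 0.05,
    window: int = 3,
) -> tuple[tuple[int, float], tuple[int, float]]:
    """Locate the haploid and diploid peaks above the error cutoff.

    Returns ((haploid_depth, haploid_area), (diploid_depth, diploid_area)).
    A fully homozygous genome shows a single peak: it is reported as the
    diploid peak with haploid area 0. Two clear peaks whose depth ratio
    falls outside ``ratio_range`` raise :class:`SpectrumError` with
    diagnostics. Areas integrate raw distinct-k-mer counts between the
    flanking local minima; the valley bin between the peaks is assigned to
    the nearer peak (tie -> haploid).
    """
    raw = hist.dense()
    s = _smooth(raw, window)
    cands = _local_maxima(s, cutoff + 1)
    cands = [i for i in cands if s[i] >= min_peak_frac * max(s[j] for j in cands)] if cands else []
    if not cands:
        raise SpectrumError("no peaks above the error cutoff")
    # merge noise maxima riding on one peak: keep only the tallest candidate
    # within a 1.4x depth window
    merged: list[int] = []
    for i in sorted(cands, key=lambda i: -s[i]):
        if all(not (1 / 1.4 <= i / j <= 1.4) for j in merged):
            merged.append(i)
    cands = sorted(merged)
    main = max(cands, key=lambda i: s[i])
    lo_r, hi_r = ratio_range
    partners = [
        i
        for i in cands
        if i != main
        and (lo_r <= main / i <= hi_r or lo_r <= i / main <= hi_r)
    ]
    others = [i for i in cands if i != main]
    if not partners:
        if others and max(s[i] for i in others) >= 0.2 * s[main]:
            best = max(others, key=lambda i: s[i])
            raise SpectrumError(
                f"two peaks at depths {min(main, best)} and {max(main, best)} have ratio "
                f"{max(main, best) / min(main, best):.2f} outside {ratio_range}"
            )
        # homozygous genome: single (diploid) peak
        d_area = float(raw[cutoff + 1 :].sum())
        return (0, 0.0), (main, d_area)
    partner = max(partners, key=lambda i: s[i])
    h, d = (main, partner) if main < partner else (partner, main)
    # valley between the peaks; boundary bin goes to the nearer peak (tie -> haploid)
    valley = h + int(np.argmin(s[h : d + 1]))
    h_hi = valley if (valley - h) <= (d - valley) else valley - 1
    a_h = float(raw[cutoff + 1 : h_hi + 1].sum())
    a_d = float(raw[h_hi + 1 :].sum())
    return (h, a_h), (d, a_d)


def spectrum_genome_size(
    filtered_total: float, diploid_depth: float, strand_collapsed: bool = True
) -> float:
    """Haploid genome size from filtered k-mer volume and the diploid peak.

    With canonical (strand-collapsed) counting the homozygous peak sits at
    the full k-mer coverage 2c and G = filtered_total / diploid_depth.
    Histograms produced by strand-specific counters report peak depths
    halved (a locus's occurrences split between a k-mer and its reverse
    complement), in which case the same estimate reads
    G = filtered_total / (2 * diploid_depth); pass
    ``strand_collapsed=False`` for such depths.
    """
    if diploid_depth <= 0:
        raise ValueError("diploid depth must be positive")
    denom = diploid_depth if strand_collapsed else 2.0 * diploid_depth
    return float(filtered_total) / denom


def profile_histogram(hist: KmerHistogram, window: int = 3) -> GenomeProfile:
    """Full spectrum profile: cutoff, peaks, genome size, het fraction."""
    cutoff = find_error_cutoff(hist, window)
    hap, dip = detect_peaks(hist, cutoff, window=window)
    ft = hist.filtered_total(cutoff)
    g = spectrum_genome_size(ft, dip[0], strand_collapsed=True)
    a_h, a_d = hap[1], dip[1]
    het = a_h / (a_h + a_d) if (a_h + a_d) > 0 else 0.0
    return GenomeProfile(cutoff, hap, dip, g, het, ft)


def profile_reads(reads, k: int = 31) -> tuple[GenomeProfile, KmerHistogram, KmerDepthIndex]:
    """Count k-mers in a read set and profile the resulting spectrum."""
    hist, index = count_kmers(reads, k)
    return profile_histogram(hist), hist, index


def heterozygosity_rank(
    profiles: list[GenomeProfile], labels: list[str] | None = None
) -> list[tuple[int, str, float, bool]]:
    """Rank genome profiles by het fraction, 1 = most heterozygous.

    Returns (rank, label, het_fraction, tied) tuples in rank order. Ties
    keep input order and share the smaller rank, flagged ``tied=True``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to rank")
    labels = labels or [f"genome{i}" for i in range(len(profiles))]
    order = sorted(range(len(profiles)), key=lambda i: (-profiles[i].het_fraction, i))
    hets = [profiles[i].het_fraction for i in order]
    out = []
    rank = 0
    for j, i in enumerate(order):
        if j == 0 or hets[j] != hets[j - 1]:
            rank = j + 1
        tied = hets.count(hets[j]) > 1
        out.append((rank, labels[i], hets[j], tied))
    return out
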