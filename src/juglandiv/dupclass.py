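"""Allele-vs-duplicate classification of extra assembled gene copies.

Heterozygous diploid assemblies often report a gene twice when the two
haplotype versions of one locus were too diverged to collapse. Such an
"extra copy" is an assembly artifact (an uncollapsed allele), not a true
duplication. The two cases separate cleanly in read space: k-mers
specific to an allelic copy exist on only one haplotype and occur at
haploid read depth, while k-mers specific to a genuine (e.g. tandem)
duplicate exist on both haplotypes and occur at diploid depth.

The classifier takes the two copy sequences, intersects their canonical
k-mer sets, queries the read-depth of the copy-specific k-mers against a
:class:`~juglandiv.kmer.KmerDepthIndex`, and compares the median specific
depth to the haploid and diploid peaks of the genome's
:class:`~juglandiv.kmer.GenomeProfile` with a log-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer import GenomeProfile, KmerDepthIndex, canonical_codes

ALLELIC = "allelic"
DUPLICATED = "duplicated"
AMBIGUOUS = "ambiguous"


@dataclass
class CopyKmerReport:
    """Set sizes, depth medians, and verdicts for a pair of gene copies."""

    copy_a: str
    copy_b: str
    specific_a: int
    specific_b: int
    shared: int
    median_depth_specific_a: float
    median_depth_specific_b: float
    median_depth_shared: float
    verdict_a: str
    verdict_b: str


def copy_kmer_sets(seq_a: str, seq_b: str, k: int = 31) -> tuple[set, set, set]:
    """Exact canonical k-mer set difference/intersection of two copies."""
    a = set(np.unique(canonical_codes(seq_a, k)).tolist())
    b = set(np.unique(canonical_codes(seq_b, k)).tolist())
    return a - b, b - a, a & b


def classify_copy(
    median_specific_depth: float,
    profile: GenomeProfile,
    n_specific: int,
    min_specific: int = 20,
    margin: float = 0.2,
) -> str:
    """Verdict for one copy from the median depth of its specific k-mers.

    ``allelic`` when the median m is closer to the haploid peak h than to
    the diploid peak d on a log scale (|log m/h| < |log m/d|) and below the
    midpoint (h+d)/2; ``duplicated`` when closer to d and above the
    midpoint. With fewer than ``min_specific`` specific k-mers (the median
    of a handful is noise), or when the two log-distances differ by less
    than ``log(1 + margin)``, the verdict is ``ambiguous``.
    """
    if profile.haploid_depth <= 0 or profile.diploid_depth <= 0:
        raise ValueError("profile lacks haploid/diploid peaks")
    if n_specific < min_specific or median_specific_depth <= 0:
        return AMBIGUOUS
    h, d = profile.haploid_depth, profile.diploid_depth
    m = median_specific_depth
    dist_h = abs(np.log(m / h))
    dist_d = abs(np.log(m / d))
    if abs(dist_h - dist_d) < np.log1p(margin):
        return AMBIGUOUS
    if dist_h < dist_d and m < (h + d) / 2.0:
        return ALLELIC
    if dist_d < dist_h and m > (h + d) / 2.0:
        return DUPLICATED
    return AMBIGUOUS


def report(
    seq_a: str,
    seq_b: str,
    index: KmerDepthIndex,
    profile: GenomeProfile,
    min_specific: int = 20,
    margin: float = 0.2,
) -> CopyKmerReport:
    """Full classification report for a pair of assembled gene copies.

    Builds the copy-specific and shared k-mer sets, queries their read
    depths from the index, and classifies each copy. The pipeline is
    symmetric: swapping the copies swaps the report's sides.
    """
    if index.codes.size == 0:
        raise ValueError("empty read k-mer index")
    only_a, only_b, shared = copy_kmer_sets(seq_a, seq_b, index.k)

    def _median(codes: set) -> float:
        if not codes:
            return 0.0
        depths = index.query(np.fromiter(codes, dtype=np.int64))
        return float(np.median(depths))

    med_a = _median(only_a)
    med_b = _median(only_b)
    med_sh = _median(shared)
    v_a = classify_copy(med_a, profile, len(only_a), min_specific, margin)
    v_b = classify_copy(med_b, profile, len(only_b), min_specific, margin)
    return CopyKmerReport(
        "copy_a", "copy_b", len(only_a), len(only_b), len(shared),
        med_a, med_b, med_sh, v_a, v_b,
    )
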