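"""Whole-genome pairwise alignment statistics.

Parses MUMmer ``show-coords -T -l`` segment tables, applies the
minimum-reference-sequence-length filter, and computes per-ordered-pair
coverage and divergence:

* coverage = aligned query bases / total bases of reference sequences
  longer than ``min_ref_len`` (strictly greater than),
* divergence = mismatches / aligned query bases, with per-segment
  mismatches recovered from the printed percent identity as
  round(aligned_query_len * (1 - pct_identity/100)).

The symmetric distance of a genome pair pools mismatches and aligned
bases over the forward and reciprocal alignments (concatenation
semantics). A micro-synteny check decides whether two reference gene
intervals are covered co-linearly, in one orientation, by a single query
scaffold.

Coordinates are 1-based inclusive in the files (MUMmer convention) and
0-based half-open internally. Running the aligner itself is out of scope:
segment tables are inputs, fabricated directly from known haplotype
alignments in the synthetic tests.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class AlignmentSegment:
    """One aligned block between a reference and a query sequence.

    Internal coordinates are 0-based half-open; ``strand`` is '-' when the
    query coordinates in the source file ran backwards.
    """

    ref_id: str
    ref_start: int
    ref_end: int
    query_id: str
    query_start: int
    query_end: int
    strand: str
    aligned_len_ref: int
    aligned_len_query: int
    pct_identity: float

    def __post_init__(self):
        if self.ref_start > self.ref_end or self.query_start > self.query_end:
            raise ValueError("segment coordinates not normalized")
        if not 0.0 < self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in (0, 100]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def mismatches(self) -> int:
        """Mismatch count recovered from percent identity (nearest integer)."""
        return int(round(self.aligned_len_query * (1.0 - self.pct_identity / 100.0)))


@dataclass
class PairStats:
    """Coverage/divergence statistics for one ordered genome pair."""

    ref_genome: str
    query_genome: str
    coverage: float
    divergence: float | None  # None when no aligned bases
    aligned_query_bases: int
    ref_total_bases: int
    mismatches: int


@dataclass
class SyntenyVerdict:
    """Micro-synteny verdict for two reference gene intervals."""

    same_scaffold: bool
    colinear: bool
    same_orientation: bool
    gap_between: int

    @property
    def syntenic(self) -> bool:
        return self.same_scaffold and self.colinear and self.same_orientation


# ---------------------------------------------------------------------------
# show-coords I/O
# ---------------------------------------------------------------------------

_NCOLS = 11  # S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ refID qryID


def parse_coords(path) -> list[AlignmentSegment]:
    """Parse a ``show-coords -T -l`` table into alignment segments.

    Header/banner lines are tolerated (any line whose first field is not an
    integer). Rows with reversed query coordinates are normalized and
    flagged strand '-'. A malformed data row raises with its line number.
    """
    segments: list[AlignmentSegment] = []
    close = False
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path)
        close = True
    try:
        for lineno, line in enumerate(handle, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if not fields or not fields[0]:
                continue
            try:
                int(fields[0])
            except ValueError:
                continue  # banner or column header
            if len(fields) < _NCOLS:
                raise ValueError(
                    f"line {lineno}: expected {_NCOLS} columns, got {len(fields)}"
                )
            try:
                s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
                len1, len2 = int(fields[4]), int(fields[5])
                pid = float(fields[6])
                ref_id, qry_id = fields[9], fields[10]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"line {lineno}: malformed row: {exc}") from exc
            strand = "+"
            if s2 > e2:
                s2, e2 = e2, s2
                strand = "-"
            if s1 > e1:
                s1, e1 = e1, s1
            segments.append(
                AlignmentSegment(
                    ref_id, s1 - 1, e1, qry_id, s2 - 1, e2, strand, len1, len2, pid
                )
            )
    finally:
        if close:
            handle.close()
    return segments


def write_coords(path, segments: list[AlignmentSegment], ref_lengths=None, query_lengths=None) -> None:
    """Write segments in show-coords -T -l layout (1-based inclusive)."""
    ref_lengths = ref_lengths or {}
    query_lengths = query_lengths or {}
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w")
        close = True
    try:
        handle.write("[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[LEN R]\t[LEN Q]\t[TAGS]\n")
        for seg in segments:
            s2, e2 = seg.query_start + 1, seg.query_end
            if seg.strand == "-":
                s2, e2 = e2, s2
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        seg.ref_start + 1,
                        seg.ref_end,
                        s2,
                        e2,
                        seg.aligned_len_ref,
                        seg.aligned_len_query,
                        f"{seg.pct_identity:.6f}",
                        ref_lengths.get(seg.ref_id, 0),
                        query_lengths.get(seg.query_id, 0),
                        seg.ref_id,
                        seg.query_id,
                    )
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Filtering and pair statistics
# ---------------------------------------------------------------------------

def filter_segments(
    segments: list[AlignmentSegment],
    ref_lengths: dict[str, int],
    min_ref_len: int = 1000,
) -> tuple[list[AlignmentSegment], int]:
    """Drop segments whose reference SEQUENCE is <= min_ref_len bp.

    The threshold applies to the length of the reference scaffold, not the
    segment. Returns (kept segments, number dropped).
    """
    kept = []
    dropped = 0
    for seg in segments:
        if seg.ref_id not in ref_lengths:
            raise KeyError(f"unknown reference sequence {seg.ref_id!r}")
        if ref_lengths[seg.ref_id] > min_ref_len:
            kept.append(seg)
        else:
            dropped += 1
    return kept, dropped


def overlap_diagnostic(segments: list[AlignmentSegment]) -> int:
    """Total reference bp covered more than once (segments are not merged)."""
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        by_ref.setdefault(seg.ref_id, []).append((seg.ref_start, seg.ref_end))
    overlap = 0
    for ivs in by_ref.values():
        ivs.sort()
        hi = -1
        for s, e in ivs:
            if s < hi:
                overlap += min(e, hi) - s
            hi = max(hi, e)
    return overlap


def pair_stats(
    segments: list[AlignmentSegment],
    ref_lengths: dict[str, int],
    ref_genome: str = "ref",
    query_genome: str = "query",
    min_ref_len: int = 1000,
) -> PairStats:
    """Coverage and divergence for one ordered genome pair.

    ``segments`` should already be filtered to reference sequences longer
    than ``min_ref_len`` (the denominator uses the same threshold).
    Divergence is None (not 0) when no bases aligned.
    """
    ref_total = sum(v for v in ref_lengths.values() if v > min_ref_len)
    aligned = sum(s.aligned_len_query for s in segments)
    mism = sum(s.mismatches for s in segments)
    coverage = aligned / ref_total if ref_total > 0 else 0.0
    divergence = mism / aligned if aligned > 0 else None
    return PairStats(ref_genome, query_genome, coverage, divergence, aligned, ref_total, mism)


def symmetric_distance(stats_fwd: PairStats, stats_rev: PairStats) -> float:
    """Pooled mismatch fraction over the forward and reciprocal alignments.

    Equivalent to concatenating the two segment lists before dividing:
    an aligned-base-weighted average of the two directional divergences.
    """
    pair_f = {stats_fwd.ref_genome, stats_fwd.query_genome}
    pair_r = {stats_rev.ref_genome, stats_rev.query_genome}
    if pair_f != pair_r:
        raise ValueError("forward and reverse statistics are for different genome pairs")
    aligned = stats_fwd.aligned_query_bases + stats_rev.aligned_query_bases
    if aligned == 0:
        raise ValueError("no aligned bases in either orientation")
    return (stats_fwd.mismatches + stats_rev.mismatches) / aligned


# ---------------------------------------------------------------------------
# Micro-synteny
# ---------------------------------------------------------------------------

def _interval_coverage(segs: list[AlignmentSegment], start: int, end: int) -> float:
    """Fraction of [start, end) covered by the segments' reference spans."""
    ivs = sorted(
        (max(s.ref_start, start), min(s.ref_end, end))
        for s in segs
        if s.ref_end > start and s.ref_start < end
    )
    covered = 0
    hi = start
    for s, e in ivs:
        s = max(s, hi)
        if e > s:
            covered += e - s
            hi = e
    return covered / (end - start) if end > start else 0.0


def synteny_check(
    segments: list[AlignmentSegment],
    gene_a: tuple[str, int, int],
    gene_b: tuple[str, int, int],
    min_cov: float = 0.8,
) -> SyntenyVerdict:
    """Decide whether two reference gene intervals are micro-syntenic.

    Gene intervals are (ref_id, start, end), 0-based half-open, and must lie
    on the same reference scaffold. The verdict is positive when one query
    scaffold covers >= ``min_cov`` of both intervals with segments that are
    consistently ordered in reference and query and share one orientation.
    """
    ref_id_a, a_start, a_end = gene_a
    ref_id_b, b_start, b_end = gene_b
    known = {s.ref_id for s in segments}
    if ref_id_a not in known or ref_id_b not in known:
        raise KeyError("gene interval on a scaffold absent from the segment table")
    if ref_id_a != ref_id_b:
        return SyntenyVerdict(False, False, False, 0)
    gap = max(0, max(a_start, b_start) - min(a_end, b_end))
    best = SyntenyVerdict(False, False, False, gap)
    by_query: dict[str, list[AlignmentSegment]] = {}
    for s in segments:
        if s.ref_id == ref_id_a:
            by_query.setdefault(s.query_id, []).append(s)
    for segs in by_query.values():
        cov_a = _interval_coverage(segs, a_start, a_end)
        cov_b = _interval_coverage(segs, b_start, b_end)
        if cov_a < min_cov or cov_b < min_cov:
            continue
        rel = sorted(
            (s for s in segs if s.ref_end > min(a_start, b_start) and s.ref_start < max(a_end, b_end)),
            key=lambda s: s.ref_start,
        )
        strands = {s.strand for s in rel}
        same_orient = len(strands) == 1
        qstarts = [s.query_start for s in rel]
        if len(qstarts) < 2:
            colinear = True
        elif strands == {"+"}:
            colinear = all(x <= y for x, y in zip(qstarts, qstarts[1:]))
        elif strands == {"-"}:
            colinear = all(x >= y for x, y in zip(qstarts, qstarts[1:]))
        else:
            colinear = False
        verdict = SyntenyVerdict(True, colinear, same_orient, gap)
        if verdict.syntenic:
            return verdict
        best = verdict
    return best


def segments_from_haplotypes(
    ref_seq: str,
    query_seq: str,
    ref_id: str = "ref1",
    query_id: str = "qry1",
) -> AlignmentSegment:
    """Fabricate the single full-length segment of two pre-aligned sequences.

    Used by synthetic tests in place of running an aligner: the sequences
    share a coordinate system (substitution-only simulation), so the exact
    percent identity is known.
    """
    if len(ref_seq) != len(query_seq):
        raise ValueError("sequences must be pre-aligned (equal length)")
    n = len(ref_seq)
    mism = sum(1 for x, y in zip(ref_seq, query_seq) if x != y)
    pid = 100.0 * (1.0 - mism / n)
    return AlignmentSegment(ref_id, 0, n, query_id, 0, n, "+", n, n, pid)
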