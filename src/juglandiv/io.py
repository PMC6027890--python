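"""Shared readers/writers, run configuration, and browser-track export.

Conventions: internal coordinates are 0-based half-open everywhere;
VCF/GFF3/coords files are 1-based inclusive and BED is 0-based half-open,
with conversion only at these I/O boundaries. FASTA/FASTQ go through
Biopython; the VCF dialect is minimal v4.2 (CHROM POS ID REF ALT QUAL
FILTER INFO FORMAT with GT and DP per sample).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence dict."""
    with _open(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    with _open(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fastq(path):
    """Read FASTQ (plain or gzip) into a :class:`~juglandiv.synthetic.ReadSet`.

    Reads must share one length (the simulator's convention); qualities are
    discarded, since nothing downstream consumes them.
    """
    from .synthetic import ReadSet, encode

    seqs = []
    with _open(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            seqs.append(str(rec.seq))
    if not seqs:
        raise ValueError(f"no reads in {path}")
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("reads have mixed lengths; expected a fixed read length")
    mat = np.stack([encode(s) for s in seqs])
    return ReadSet(mat, lens.pop())


# ---------------------------------------------------------------------------
# Minimal VCF v4.2
# ---------------------------------------------------------------------------

def write_vcf(path, sample, chrom: str = "locus1", ref: str = "A", alt: str = "T") -> None:
    """Write a :class:`~juglandiv.synthetic.PolymorphismSample` as minimal VCF.

    Haploid columns are paired into diploid samples (n must be even);
    genotypes are unphased GT with a per-sample DP equal to the site's
    simulated depth. Positions convert to 1-based.
    """
    if sample.n % 2:
        raise ValueError("need an even haploid sample size to write diploid VCF")
    n_ind = sample.n // 2
    names = "\t".join(f"ind{i}" for i in range(n_ind))
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={sample.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for s in range(sample.S):
            gts = sample.genotypes[s]
            dp = int(sample.depths[s])
            cols = "\t".join(
                f"{gts[2 * i]}/{gts[2 * i + 1]}:{dp}" for i in range(n_ind)
            )
            fh.write(
                f"{chrom}\t{int(sample.positions[s]) + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t{cols}\n"
            )


def read_vcf_sites(path):
    """Read biallelic SNP sites of a VCF: (positions, alt counts, called n, depths).

    Thin wrapper over the cyvcf2 reader used by the diversity estimator;
    positions convert to 0-based.
    """
    from cyvcf2 import VCF

    pos, alts, called, depths = [], [], [], []
    for v in VCF(str(path)):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        a = c = 0
        for g in v.genotypes:
            for allele in g[:-1]:
                if allele >= 0:
                    c += 1
                    a += allele == 1
        dp = v.format("DP")
        depth = float(np.mean(dp[dp >= 0])) if dp is not None and np.any(dp >= 0) else float("nan")
        pos.append(v.POS - 1)
        alts.append(a)
        called.append(c)
        depths.append(depth)
    return (
        np.array(pos, dtype=np.int64),
        np.array(alts, dtype=np.int64),
        np.array(called, dtype=np.int64),
        np.array(depths),
    )


# ---------------------------------------------------------------------------
# Histogram TSV (depth <tab> distinct k-mers, counter-tool histo layout)
# ---------------------------------------------------------------------------

def write_histogram(path, hist) -> None:
    with _open(path, "wt") as fh:
        for depth in sorted(hist.counts):
            fh.write(f"{depth}\t{hist.counts[depth]}\n")


def read_histogram(path, k: int = 31):
    from .kmer import KmerHistogram

    counts = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 'depth count'")
            counts[int(parts[0])] = int(parts[1])
    return KmerHistogram(k, counts)


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def write_bed(path, intervals) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED (0-based half-open)."""
    with _open(path, "wt") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with _open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return out


def write_gff3(path, features) -> None:
    """Write (chrom, source, type, start0, end0, strand, name) features as GFF3.

    Internal 0-based half-open intervals convert to GFF3 1-based inclusive.
    """
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for chrom, source, ftype, start, end, strand, name in features:
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\tID={name}\n"
            )


def read_gene_intervals(path) -> list[tuple[str, int, int, str]]:
    """Read gene intervals from BED or GFF3 into 0-based half-open tuples."""
    path = str(path)
    out = []
    if path.endswith((".gff", ".gff3")):
        with _open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[8].split("ID=")[-1].split(";")[0] if len(f) > 8 else f[2]
                out.append((f[0], int(f[3]) - 1, int(f[4]), name))
    else:
        for iv in read_bed(path):
            out.append((iv[0], iv[1], iv[2], iv[3] if len(iv) > 3 else "gene"))
    return out


# ---------------------------------------------------------------------------
# Browser tracks
# ---------------------------------------------------------------------------

def export_tracks(
    snp_positions,
    genes,
    alignments,
    scaffold: str,
    scaffold_len: int,
    bin_size: int = 1000,
    bed_path=None,
    gff_path=None,
):
    """Bin SNPs into a density BED track and emit genes/alignments as GFF3.

    ``snp_positions`` are 0-based positions on ``scaffold``; ``genes`` are
    (start, end, name) and ``alignments`` (start, end, query_id, strand)
    intervals on the same scaffold. Returns (density bins, gff features);
    writes files when paths are given. The density bin score of an interval
    equals the number of SNPs it contains.
    """
    pos = np.asarray(snp_positions, dtype=np.int64)
    if np.any((pos < 0) | (pos >= scaffold_len)):
        raise ValueError(f"SNP position outside scaffold {scaffold!r}")
    n_bins = max(1, int(np.ceil(scaffold_len / bin_size)))
    counts = np.bincount(pos // bin_size, minlength=n_bins)
    bins = [
        (scaffold, int(b * bin_size), int(min((b + 1) * bin_size, scaffold_len)),
         f"snps_{b}", int(counts[b]))
        for b in range(n_bins)
    ]
    features = [
        (scaffold, "juglandiv", "gene", int(s), int(e), "+", name)
        for s, e, name in genes
    ] + [
        (scaffold, "juglandiv", "match", int(s), int(e), strand, qid)
        for s, e, qid, strand in alignments
    ]
    if bed_path is not None:
        write_bed(bed_path, bins)
    if gff_path is not None:
        write_gff3(gff_path, features)
    return bins, features


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fixed pipeline constants, validated on construction.

    Defaults mirror the study conditions: 31-mers, a 1000 bp minimum
    reference sequence length for alignment statistics, 100 bootstrap
    replicates, a 45 Mya crown-group calibration, quantile depth cutoffs
    (2.5% / 99%), and a 20% ambiguity margin for the copy classifier.
    """

    k: int = 31
    min_ref_len: int = 1000
    bootstrap_replicates: int = 100
    calibration_age_mya: float = 45.0
    depth_lower_q: float = 0.025
    depth_upper_q: float = 0.99
    ambiguity_margin: float = 0.2
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k % 2 == 0 or not 15 <= self.k <= 31:
            raise ValueError("k must be odd and in [15, 31]")
        if self.min_ref_len < 0:
            raise ValueError("min_ref_len must be >= 0")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.calibration_age_mya <= 0:
            raise ValueError("calibration age must be positive")
        if not 0 <= self.depth_lower_q < self.depth_upper_q <= 1:
            raise ValueError("depth quantiles must satisfy 0 <= lower < upper <= 1")
        if self.ambiguity_margin < 0:
            raise ValueError("ambiguity margin must be >= 0")

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "min_ref_len": self.min_ref_len,
            "bootstrap_replicates": self.bootstrap_replicates,
            "calibration_age_mya": self.calibration_age_mya,
            "depth_lower_q": self.depth_lower_q,
            "depth_upper_q": self.depth_upper_q,
            "ambiguity_margin": self.ambiguity_margin,
            "seed": self.seed,
            "paths": dict(self.paths),
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat key = value file (comments with #)."""
        kwargs = {}
        with _open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in ("k", "min_ref_len", "bootstrap_replicates", "seed"):
                    kwargs[key] = int(val)
                elif key in (
                    "calibration_age_mya", "depth_lower_q", "depth_upper_q", "ambiguity_margin"
                ):
                    kwargs[key] = float(val)
                else:
                    kwargs.setdefault("paths", {})[key] = val
        return cls(**kwargs)
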