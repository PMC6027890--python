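"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (k-mer profiling, alignment
divergence, phylogeny, diversity, Ka/Ks, duplicate classification) is
exercised against data produced here, so each generator records the truth
it planted: heterozygous sites, tree path distances, per-branch
substitution counts, the scaled mutation rate theta, and the mode of a
planted gene copy.

Sequences are handled internally as uint8 code arrays (A=0, C=1, G=2,
T=3, N=4) and decoded to strings at the API boundary. All generators are
pure functions of their arguments including the seed; each call owns one
``numpy.random.Generator`` and no global state is touched.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import msprime
import numpy as np
from skbio import TreeNode

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGTN string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    codes = encode(seq)[::-1]
    out = np.where(codes < 4, 3 - codes, codes).astype(np.uint8)
    return decode(out)


# ---------------------------------------------------------------------------
# Diploid genomes
# ---------------------------------------------------------------------------

@dataclass
class DiploidGenome:
    """Two aligned haplotypes of equal length.

    ``het_sites`` lists (position, allele_a, allele_b) for every site where
    the haplotypes differ; ``target_het`` is the per-base heterozygosity the
    generator aimed for (expected fraction of differing sites).
    """

    haplotype_a: str
    haplotype_b: str
    het_sites: list[tuple[int, str, str]]
    target_het: float

    def __post_init__(self):
        if len(self.haplotype_a) != len(self.haplotype_b):
            raise ValueError("haplotypes must have equal length")

    @property
    def length(self) -> int:
        return len(self.haplotype_a)


def _het_sites_from_codes(a: np.ndarray, b: np.ndarray) -> list[tuple[int, str, str]]:
    pos = np.nonzero(a != b)[0]
    return [(int(p), decode(a[p : p + 1]), decode(b[p : p + 1])) for p in pos]


def simulate_diploid_genome(
    length: int, het: float, gc: float = 0.37, seed: int = 0
) -> DiploidGenome:
    """Draw a random diploid genome with Bernoulli(het) heterozygous sites.

    Substitutions only: both haplotypes have the same length and coordinate
    system. ``gc`` sets the stationary G+C fraction of haplotype A; the
    alternate allele at a het site is uniform over the three other bases.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0.0 <= het <= 0.05:
        raise ValueError("het must be in [0, 0.05]")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    a = rng.choice(4, size=length, p=p).astype(np.uint8)
    b = a.copy()
    mask = rng.random(length) < het
    n_het = int(mask.sum())
    if n_het:
        offs = rng.integers(1, 4, size=n_het).astype(np.uint8)
        b[mask] = (b[mask] + offs) % 4
    return DiploidGenome(decode(a), decode(b), _het_sites_from_codes(a, b), het)


# ---------------------------------------------------------------------------
# Shotgun reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated single-end reads stored as a (n_reads, read_len) code matrix."""

    codes: np.ndarray
    read_len: int

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def total_bases(self) -> int:
        return int(self.codes.size)

    def sequences(self):
        for i in range(self.codes.shape[0]):
            yield decode(self.codes[i])

    def to_fastq(self, path) -> None:
        qual = "I" * self.read_len
        handle = open(path, "w") if not hasattr(path, "write") else path
        try:
            for i, seq in enumerate(self.sequences()):
                handle.write(f"@read{i}\n{seq}\n+\n{qual}\n")
        finally:
            if handle is not path:
                handle.close()

    def to_fastq_string(self) -> str:
        buf = _io.StringIO()
        self.to_fastq(buf)
        return buf.getvalue()


def simulate_reads(
    genome: DiploidGenome,
    depth: float,
    read_len: int = 150,
    err: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniform shotgun reads from both haplotypes and both strands.

    ``depth`` is fold coverage of the haplotype pair relative to the
    haploid length: total bases ~= depth * genome.length, so each haplotype
    is covered ~depth/2 times. Base errors are i.i.d. substitutions at rate
    ``err``; qualities (written by :meth:`ReadSet.to_fastq`) are constant.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= err <= 0.05:
        raise ValueError("err must be in [0, 0.05]")
    L = genome.length
    if read_len > L:
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * L / read_len))
    haps = np.stack([encode(genome.haplotype_a), encode(genome.haplotype_b)])
    which = rng.integers(0, 2, size=n_reads)
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strand = rng.integers(0, 2, size=n_reads)
    mat = haps[which[:, None], starts[:, None] + np.arange(read_len)]
    if err > 0:
        emask = rng.random(mat.shape) < err
        n_err = int(emask.sum())
        if n_err:
            offs = rng.integers(1, 4, size=n_err).astype(np.uint8)
            mat[emask] = (mat[emask] + offs) % 4
    rev = strand == 1
    mat[rev] = (3 - mat[rev, ::-1]) % 4
    return ReadSet(mat.astype(np.uint8), read_len)


# ---------------------------------------------------------------------------
# Species sets under Jukes-Cantor evolution
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSpeciesSet:
    """Leaf genomes evolved along a known tree, plus the true path distances."""

    tree: TreeNode
    sequences: dict[str, str]
    true_pairwise_d: "object"  # skbio DistanceMatrix


def _as_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    try:
        return TreeNode.read(_io.StringIO(str(tree)))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed Newick tree: {exc}") from exc


def jc_evolve(codes: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a code array for branch length d (substitutions/site) under JC69.

    Each site changes with probability (3/4)(1 - exp(-4d/3)); a changed site
    takes one of the three other bases uniformly. Composition over successive
    branches is exact because JC transition matrices commute.
    """
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    out = codes.copy()
    mask = rng.random(codes.shape[0]) < p_change
    n = int(mask.sum())
    if n:
        offs = rng.integers(1, 4, size=n).astype(np.uint8)
        out[mask] = (out[mask] + offs) % 4
    return out


def simulate_species_set(tree, length: int, seed: int = 0) -> SimulatedSpeciesSet:
    """Simulate one genome per leaf under Jukes-Cantor along a known tree.

    Branch lengths are substitutions/site and must each be < 0.75. The
    returned distance matrix holds the additive tree path lengths (the
    ground truth that alignment-divergence estimates should converge to
    after JC correction).
    """
    from skbio import DistanceMatrix

    t = _as_tree(tree)
    rng = np.random.default_rng(seed)
    for node in t.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if not 0.0 <= node.length < 0.75:
            raise ValueError("branch lengths must be in [0, 0.75)")
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)
    seqs_by_node = {id(t): root_seq}
    for node in t.preorder(include_self=False):
        seqs_by_node[id(node)] = jc_evolve(seqs_by_node[id(node.parent)], node.length, rng)
    leaves = {leaf.name: decode(seqs_by_node[id(leaf)]) for leaf in t.tips()}
    dm = t.tip_tip_distances()
    return SimulatedSpeciesSet(t, leaves, DistanceMatrix(dm.data, list(dm.ids)))


# ---------------------------------------------------------------------------
# Codon evolution with per-branch omega
# ---------------------------------------------------------------------------

_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def _codon_table() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


_AA = _codon_table()
_SENSE_CODONS = sorted(c for c, a in _AA.items() if a != "*")


@dataclass
class SimulatedCodonSet:
    """Codon alignment evolved on a tree with known per-branch Ka/Ks targets.

    ``alignment`` holds leaf sequences; ``internal`` the recorded ancestral
    sequences; ``true_branch_changes`` maps each non-root node name to the
    (nonsynonymous, synonymous) substitution counts actually applied on the
    branch above it.
    """

    tree: TreeNode
    alignment: dict[str, str]
    internal: dict[str, str]
    branch_omega: dict[str, float]
    true_branch_changes: dict[str, tuple[int, int]]


def name_internal_nodes(tree: TreeNode, prefix: str = "n") -> TreeNode:
    """Assign deterministic names (n1, n2, ... in postorder) to unnamed nodes."""
    i = 0
    for node in tree.postorder():
        if not node.is_tip() and not node.name:
            i += 1
            node.name = f"{prefix}{i}"
    return tree


def simulate_codon_set(
    tree,
    branch_omega: dict[str, float],
    codons: int,
    kappa: float = 2.0,
    seed: int = 0,
) -> SimulatedCodonSet:
    """Evolve codon sequences with branch-specific Ka/Ks acceptance ratios.

    Point mutations are proposed along each branch at a Poisson rate of
    (branch length) expected proposals per nucleotide site, with a ts/tv
    bias ``kappa``. Proposals creating a stop codon are rejected outright.
    Synonymous proposals are accepted with probability min(1, 1/omega) and
    nonsynonymous ones with probability min(1, omega), so the realized
    nonsynonymous:synonymous acceptance odds equal omega on every branch.
    The mutations actually applied are counted per branch as ground truth.
    """
    if codons < 100:
        raise ValueError("codons must be >= 100")
    t = name_internal_nodes(_as_tree(tree))
    for node in t.traverse(include_self=False):
        if node.name not in branch_omega:
            raise ValueError(f"no omega given for branch above node {node.name!r}")
        if branch_omega[node.name] < 0:
            raise ValueError("omega must be >= 0")
    rng = np.random.default_rng(seed)
    nsites = 3 * codons
    root = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=codons)
    )
    seqs: dict[str, np.ndarray] = {t.name: encode(root)}
    changes: dict[str, tuple[int, int]] = {}
    for node in t.preorder(include_self=False):
        seq = seqs[node.parent.name].copy()
        omega = branch_omega[node.name]
        p_nonsyn = min(1.0, omega)
        p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
        n_prop = rng.poisson((node.length or 0.0) * nsites)
        n_non = n_syn = 0
        for _ in range(n_prop):
            site = int(rng.integers(0, nsites))
            old = int(seq[site])
            ts = _TRANSITION[old]
            alts = [b for b in range(4) if b != old]
            w = np.array([kappa if b == ts else 1.0 for b in alts])
            new = alts[int(rng.choice(3, p=w / w.sum()))]
            c0 = 3 * (site // 3)
            codon = seq[c0 : c0 + 3].copy()
            codon[site % 3] = new
            new_codon = decode(codon)
            if new_codon in _STOP_CODONS:
                continue
            old_codon = decode(seq[c0 : c0 + 3])
            if _AA[new_codon] == _AA[old_codon]:
                if rng.random() < p_syn:
                    seq[site] = new
                    n_syn += 1
            else:
                if rng.random() < p_nonsyn:
                    seq[site] = new
                    n_non += 1
        seqs[node.name] = seq
        changes[node.name] = (n_non, n_syn)
    leaves = {n.name for n in t.tips()}
    aln = {name: decode(s) for name, s in seqs.items() if name in leaves}
    internal = {name: decode(s) for name, s in seqs.items() if name not in leaves}
    return SimulatedCodonSet(t, aln, internal, dict(branch_omega), changes)


# ---------------------------------------------------------------------------
# Population polymorphism (per-block coalescent)
# ---------------------------------------------------------------------------

@dataclass
class PolymorphismSample:
    """Haploid polymorphism sample from a per-block coalescent.

    ``genotypes`` is an (S, n) 0/1 matrix over segregating sites at 0-based
    ``positions``; ``depths`` are simulated per-site read depths at those
    sites. With the scaling used here the expected per-site pairwise
    diversity equals ``theta``.
    """

    n: int
    length: int
    theta: float
    positions: np.ndarray
    genotypes: np.ndarray
    depths: np.ndarray

    @property
    def S(self) -> int:
        return int(self.positions.size)

    def pairwise_pi(self) -> float:
        """Mean pairwise difference per site (the quantity E[.] = theta)."""
        if self.S == 0:
            return 0.0
        k = self.genotypes.sum(axis=1)
        n = self.n
        return float(np.sum(2.0 * k * (n - k) / (n * (n - 1))) / self.length)

    def to_vcf(self, path, chrom: str = "locus1", ref: str = "A", alt: str = "T") -> None:
        """Write a minimal VCF v4.2 pairing haploid columns into diploid samples."""
        from .io import write_vcf

        write_vcf(path, self, chrom=chrom, ref=ref, alt=alt)


def simulate_polymorphism(
    n: int,
    length: int,
    theta: float,
    seed: int = 0,
    block_len: int = 10_000,
    mean_depth: float = 30.0,
) -> PolymorphismSample:
    """Sample n haploid sequences under the neutral coalescent, block by block.

    Each non-recombining block of ``block_len`` bp gets an independent
    coalescent genealogy (msprime, ploidy 1, population size 1) with binary
    mutations at rate theta/2 per site per generation, so E[pi] = theta per
    site. Sites driven monomorphic by back mutation are dropped.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= theta <= 0.05:
        raise ValueError("theta must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    n_blocks = max(1, int(np.ceil(length / block_len)))
    seeds = rng.integers(1, 2**31 - 1, size=(n_blocks, 2))
    pos_parts, gt_parts = [], []
    for b in range(n_blocks):
        blen = min(block_len, length - b * block_len)
        if blen <= 0:
            break
        ts = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1.0,
            sequence_length=blen,
            random_seed=int(seeds[b, 0]),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=theta / 2.0,
            model=msprime.BinaryMutationModel(),
            random_seed=int(seeds[b, 1]),
        )
        if mts.num_sites == 0:
            continue
        gt = mts.genotype_matrix()
        pos = np.array([s.position for s in mts.sites()], dtype=np.int64) + b * block_len
        counts = gt.sum(axis=1)
        keep = (counts >= 1) & (counts <= n - 1)
        pos_parts.append(pos[keep])
        gt_parts.append(gt[keep])
    if pos_parts:
        positions = np.concatenate(pos_parts)
        genotypes = np.concatenate(gt_parts).astype(np.uint8)
    else:
        positions = np.empty(0, dtype=np.int64)
        genotypes = np.empty((0, n), dtype=np.uint8)
    depths = rng.poisson(mean_depth, size=positions.size).astype(np.int64)
    return PolymorphismSample(n, length, theta, positions, genotypes, depths)


# ---------------------------------------------------------------------------
# Planted gene copies (allele vs tandem duplicate)
# ---------------------------------------------------------------------------

@dataclass
class PlantedCopy:
    """Ground truth for a planted gene copy scenario."""

    mode: str  # "allelic" or "tandem_duplicate"
    gene_interval: tuple[int, int]  # 0-based half-open, original copy
    copy_interval: tuple[int, int] | None  # tandem copy interval (both haps)
    copy_a: str  # original gene sequence
    copy_b: str  # diverged copy sequence


def _diverge(codes: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.shape[0]) < frac
    k = int(mask.sum())
    if k:
        offs = rng.integers(1, 4, size=k).astype(np.uint8)
        out[mask] = (out[mask] + offs) % 4
    return out


def plant_gene_copy(
    genome: DiploidGenome,
    gene: str,
    mode: str,
    copy_divergence: float = 0.02,
    seed: int = 0,
    position: int | None = None,
) -> tuple[DiploidGenome, PlantedCopy]:
    """Plant a gene plus a diverged second copy that is either allelic or tandem.

    The gene is first inserted identically into both haplotypes at
    ``position`` (default: one third of the way in). In ``allelic`` mode the
    copy on haplotype B is then replaced by a version diverged by
    ``copy_divergence`` (an uncollapsed-allele scenario: copy-specific
    k-mers sit on one haplotype and appear at haploid read depth). In
    ``tandem_duplicate`` mode the diverged copy is inserted directly
    downstream of the gene on BOTH haplotypes in the same orientation, so
    its specific k-mers appear at diploid depth.
    """
    if mode not in ("allelic", "tandem_duplicate"):
        raise ValueError("mode must be 'allelic' or 'tandem_duplicate'")
    if len(gene) > genome.length:
        raise ValueError("gene longer than genome")
    rng = np.random.default_rng(seed)
    g = encode(gene)
    diverged = _diverge(g, copy_divergence, rng)
    a = encode(genome.haplotype_a)
    b = encode(genome.haplotype_b)
    pos = genome.length // 3 if position is None else position
    glen = len(gene)
    if mode == "allelic":
        a = np.concatenate([a[:pos], g, a[pos:]])
        b = np.concatenate([b[:pos], diverged, b[pos:]])
        truth = PlantedCopy(mode, (pos, pos + glen), None, gene, decode(diverged))
    else:
        ins = np.concatenate([g, diverged])
        a = np.concatenate([a[:pos], ins, a[pos:]])
        b = np.concatenate([b[:pos], ins, b[pos:]])
        truth = PlantedCopy(
            mode, (pos, pos + glen), (pos + glen, pos + 2 * glen), gene, decode(diverged)
        )
    new = DiploidGenome(decode(a), decode(b), _het_sites_from_codes(a, b), genome.target_het)
    return new, truth
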