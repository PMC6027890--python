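"""Population-genetic and molecular-evolution statistics.

Four related analyses used to read selection off polymorphism and
divergence data:

* coverage-class-weighted nucleotide diversity pi (Nei-Li pairwise
  heterozygosity, unbiased per-site estimator 2 p(1-p) n/(n-1), averaged
  over depth-defined coverage classes with callable-site weights),
* Tajima's relative rate test (chi^2 = (m1-m2)^2/(m1+m2), 1 df) on counts
  of changes unique to each of two ingroup lineages given an outgroup,
* an HKA-like 2x2 chi-square contrasting polymorphism and divergence at
  two loci (no continuity correction; a polymorphism deficit at one locus
  relative to its divergence signals hitchhiking),
* lineage-specific Ka/Ks on a gene tree: Fitch parsimony ancestral
  sequences followed by Nei-Gojobori (1986) pathway counting per branch
  with Jukes-Cantor multiple-hit correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skbio import TreeNode

from .synthetic import _AA, _STOP_CODONS, name_internal_nodes


# ---------------------------------------------------------------------------
# Depth cutoffs and coverage classes
# ---------------------------------------------------------------------------

@dataclass
class DepthCutoffs:
    """Inclusive [min_depth, max_depth] callable-depth window."""

    min_depth: float
    max_depth: float

    def __post_init__(self):
        if not self.min_depth < self.max_depth:
            raise ValueError("min_depth must be < max_depth")

    def __contains__(self, depth) -> bool:
        return self.min_depth <= depth <= self.max_depth


def depth_cutoffs(
    depth_histogram: dict[int, int], lower_q: float = 0.025, upper_q: float = 0.99
) -> DepthCutoffs:
    """Quantile-based min/max depth cutoffs from an aligned-depth histogram.

    Sites outside the window are non-callable; the upper quantile trims the
    high-depth shoulder produced by collapsed repeats.
    """
    if not depth_histogram or sum(depth_histogram.values()) == 0:
        raise ValueError("empty depth histogram")
    depths = np.array(sorted(depth_histogram))
    weights = np.array([depth_histogram[d] for d in depths], dtype=np.float64)
    cum = np.cumsum(weights) / weights.sum()
    lo = float(depths[np.searchsorted(cum, lower_q, side="left")]) if lower_q > 0 else float(depths[0])
    hi = float(depths[np.searchsorted(cum, upper_q, side="left")]) if upper_q < 1 else float(depths[-1])
    if lo >= hi:
        lo, hi = lo - 0.5, hi + 0.5  # degenerate (single-depth) histogram: bracket it
    return DepthCutoffs(lo, hi)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class PolymorphismSummary:
    """Segregating sites, callable sites per coverage class, and pi."""

    locus: str
    n: int
    S: int
    callable_by_class: dict[str, int]
    pi: float
    allele_counts: list[int] = field(default_factory=list)
    pi_by_class: dict[str, float] = field(default_factory=dict)


def _pi_site(minor: int, n_called: int) -> float:
    if n_called < 2:
        raise ValueError("need at least 2 called alleles at a site")
    p = minor / n_called
    return 2.0 * p * (1.0 - p) * n_called / (n_called - 1)


def _iter_vcf_sites(vcf_path):
    """Yield (alt_count, n_called, mean_depth) for biallelic SNPs of a VCF."""
    from cyvcf2 import VCF

    for v in VCF(str(vcf_path)):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # not a biallelic SNP
        alt = 0
        called = 0
        for g in v.genotypes:
            for allele in g[:-1]:
                if allele >= 0:
                    called += 1
                    alt += allele == 1
        dp = v.format("DP")
        depth = float(np.mean(dp[dp >= 0])) if dp is not None and np.any(dp >= 0) else np.nan
        yield alt, called, depth


def nucleotide_diversity(
    variants,
    callable_by_class: dict[str, int],
    classes: dict[str, DepthCutoffs] | None = None,
    locus: str = "locus",
) -> PolymorphismSummary:
    """Coverage-class-weighted nucleotide diversity.

    ``variants`` is a VCF path (read with cyvcf2; biallelic SNPs only) or a
    :class:`juglandiv.synthetic.PolymorphismSample`. ``callable_by_class``
    gives the number of callable sites per class label; with ``classes``
    omitted a single class "all" is assumed. Per class c,
    pi_c = sum over segregating sites in c of 2 p(1-p) n/(n-1), divided by
    callable_c (monomorphic callable sites contribute 0 to the numerator
    and 1 to the denominator); the overall pi is the callable-site-weighted
    average of the pi_c. Sites whose depth matches no class raise.
    """
    from .synthetic import PolymorphismSample

    single = classes is None
    if single:
        classes = {label: DepthCutoffs(-np.inf, np.inf) for label in callable_by_class}
        if len(classes) != 1:
            raise ValueError("without explicit classes, callable_by_class must have one entry")
    if set(classes) != set(callable_by_class):
        raise ValueError("classes and callable_by_class must share labels")

    if isinstance(variants, PolymorphismSample):
        counts = variants.genotypes.sum(axis=1).astype(int)
        sites = [
            (int(c), variants.n, float(d))
            for c, d in zip(counts, variants.depths)
        ]
        n_max = variants.n
    else:
        sites = list(_iter_vcf_sites(variants))
        n_max = max((s[1] for s in sites), default=0)

    num = {label: 0.0 for label in classes}
    S = 0
    allele_counts = []
    for alt, called, depth in sites:
        if called < 2 or alt == 0 or alt == called:
            continue
        if single:
            label = next(iter(classes))
        else:
            label = next((lb for lb, cc in classes.items() if depth in cc), None)
            if label is None:
                raise ValueError(f"site depth {depth} matches no coverage class")
        num[label] += _pi_site(alt, called)
        S += 1
        allele_counts.append(min(alt, called - alt))
    pi_by_class = {
        lb: (num[lb] / callable_by_class[lb] if callable_by_class[lb] > 0 else 0.0)
        for lb in classes
    }
    total_callable = sum(callable_by_class.values())
    if total_callable <= 0:
        raise ValueError("no callable sites")
    pi = sum(pi_by_class[lb] * callable_by_class[lb] for lb in classes) / total_callable
    return PolymorphismSummary(locus, n_max, S, dict(callable_by_class), pi, allele_counts, pi_by_class)


# ---------------------------------------------------------------------------
# Relative rate and HKA-like tests
# ---------------------------------------------------------------------------

@dataclass
class RelativeRateResult:
    m1: int
    m2: int
    chi2: float
    p: float


def count_lineage_changes(a: str, b: str, outgroup: str) -> tuple[int, int]:
    """Changes unique to each ingroup lineage, polarized by the outgroup.

    m1 counts sites where ``a`` differs while ``b`` equals the outgroup;
    m2 the converse. Sites with three distinct states are uninformative and
    ignored, as are sites where the two ingroup sequences agree.
    """
    if not (len(a) == len(b) == len(outgroup)):
        raise ValueError("sequences must have equal length")
    A = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    B = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    O = np.frombuffer(outgroup.upper().encode(), dtype=np.uint8)
    m1 = int(np.sum((B == O) & (A != B)))
    m2 = int(np.sum((A == O) & (B != A)))
    return m1, m2


def tajima_relative_rate(m1: int, m2: int) -> RelativeRateResult:
    """Tajima's relative rate test: chi^2 = (m1-m2)^2/(m1+m2), 1 df."""
    if m1 < 0 or m2 < 0:
        raise ValueError("counts must be non-negative")
    if m1 + m2 == 0:
        raise ValueError("m1 + m2 = 0: test undefined")
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    return RelativeRateResult(m1, m2, float(chi2), float(stats.chi2.sf(chi2, 1)))


@dataclass
class HKAResult:
    S1: int
    S2: int
    D1: int
    D2: int
    chi2: float
    p: float
    expected: np.ndarray


def hka_test(S1: int, S2: int, D1: int, D2: int) -> HKAResult:
    """HKA-like 2x2 chi-square of {polymorphism, divergence} x {locus1, locus2}.

    Expected counts come from the row/column margins; no continuity
    correction is applied (the full multilocus HKA variance model is out of
    scope). Expected cells below 1 raise; below 5 warn.
    """
    obs = np.array([[S1, S2], [D1, D2]], dtype=np.float64)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("all-zero table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin: test undefined")
    exp = row @ col / obs.sum()
    if np.any(exp < 1):
        raise ValueError("expected cell count below 1: chi-square approximation invalid")
    if np.any(exp < 5):
        warnings.warn("expected cell count below 5: chi-square approximation is rough")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return HKAResult(S1, S2, D1, D2, chi2, float(stats.chi2.sf(chi2, 1)), exp)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) codon counting
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Per position, the synonymous fraction is the share of the three
    alternative bases preserving the amino acid; mutations to stop codons
    count as nonsynonymous, so the two counts always sum to 3.
    """
    codon = codon.upper()
    if codon in _STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = _AA[codon]
    syn = 0.0
    for pos in range(3):
        same = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _AA[alt] == aa:
                same += 1
        syn += same / 3.0
    return 3.0 - syn, syn


_SITE_COUNTS = {c: ng86_site_counts(c) for c in _AA if c not in _STOP_CODONS}


def ng86_pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons.

    Counts are averaged over all minimal mutational pathways between the
    codons, excluding pathways passing through a stop codon (unless every
    pathway does, in which case all are used). Single-difference codon
    pairs reduce to the one path.
    """
    a, b = codon_a.upper(), codon_b.upper()
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOP_CODONS and nxt != b:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked] or [s for _, s in paths]
    nd = sd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
    return nd / len(usable), sd / len(usable)


@dataclass
class BranchRates:
    """Per-branch substitution counts and corrected rates.

    Na/Ns are nonsynonymous/synonymous difference counts, A/Sy the
    corresponding site counts (A + Sy = 3 x codons); Ka and Ks carry the
    Jukes-Cantor multiple-hit correction of Na/A and Ns/Sy.
    """

    branch: str
    Na: float
    Ns: float
    A: float
    Sy: float
    Ka: float
    Ks: float

    @property
    def omega(self) -> float:
        """Ka/Ks; inf when Ks == 0 and Ka > 0, nan when both are 0."""
        if self.Ks > 0:
            return self.Ka / self.Ks
        return float("inf") if self.Ka > 0 else float("nan")


def _jc_rate(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p:.3f} >= 3/4: JC correction saturates")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def branch_ka_ks(
    parent_seq: str,
    child_seq: str,
    branch: str = "branch",
    skip_stop_codons: bool = False,
) -> BranchRates:
    """Nei-Gojobori Ka and Ks between an ancestral and a descendant sequence.

    Site counts are averaged over the two sequences; differences use
    minimal-pathway averaging; pa and ps get the Jukes-Cantor correction.
    ``skip_stop_codons`` drops codons that contain a stop in either
    sequence instead of raising (useful downstream of parsimony
    reconstruction, which can occasionally assemble a stop at an internal
    node).
    """
    p, c = parent_seq.upper(), child_seq.upper()
    if len(p) != len(c):
        raise ValueError("sequences must have equal length")
    if len(p) % 3:
        raise ValueError("sequence length must be divisible by 3")
    A = Sy = Nd = Sd = 0.0
    for i in range(0, len(p), 3):
        cp, cc = p[i : i + 3], c[i : i + 3]
        if cp in _STOP_CODONS or cc in _STOP_CODONS:
            if skip_stop_codons:
                continue
            raise ValueError(f"internal stop codon at codon {i // 3}")
        np_, sp_ = _SITE_COUNTS[cp]
        nc_, sc_ = _SITE_COUNTS[cc]
        A += (np_ + nc_) / 2.0
        Sy += (sp_ + sc_) / 2.0
        nd, sd = ng86_pathway_counts(cp, cc)
        Nd += nd
        Sd += sd
    ka = _jc_rate(Nd / A) if A > 0 else 0.0
    ks = _jc_rate(Sd / Sy) if Sy > 0 else 0.0
    return BranchRates(branch, Nd, Sd, A, Sy, ka, ks)


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction
# ---------------------------------------------------------------------------

_NT_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_BIT_NT = {1: "A", 2: "C", 4: "G", 8: "T"}


@dataclass
class AncestralReconstruction:
    """One most-parsimonious nucleotide reconstruction of the internal nodes.

    ``score`` is the Fitch parsimony change count of the alignment;
    ``ambiguous_nodes`` counts (site, node) pairs where more than one state
    was most parsimonious and the deterministic rule (parent state if
    available, else first in A<C<G<T order) chose one.
    """

    sequences: dict[str, str]
    score: int
    ambiguous_nodes: int


def ancestral_parsimony(aln: dict[str, str], tree: TreeNode) -> AncestralReconstruction:
    """Fitch parsimony (up-pass + down-pass) per nucleotide position.

    Leaves must match the tree's tips exactly. The down-pass resolves each
    internal node to its parent's state when that state is in the node's
    up-pass set, otherwise to the first set state in A<C<G<T order, which
    yields one canonical most-parsimonious reconstruction.
    """
    t = name_internal_nodes(tree.copy())
    tips = {n.name for n in t.tips()}
    if tips != set(aln):
        raise ValueError("alignment names do not match tree tips")
    L = len(next(iter(aln.values())))
    if any(len(s) != L for s in aln.values()):
        raise ValueError("ragged alignment")
    bit = np.zeros(256, dtype=np.uint8)
    for nt, b in _NT_BIT.items():
        bit[ord(nt)] = b
        bit[ord(nt.lower())] = b
    sets: dict[str, np.ndarray] = {}
    score = 0
    for node in t.postorder():
        if node.is_tip():
            arr = bit[np.frombuffer(aln[node.name].upper().encode(), dtype=np.uint8)]
            if np.any(arr == 0):
                raise ValueError(f"non-ACGT character in sequence {node.name!r}")
            sets[node.name] = arr
        else:
            acc = sets[node.children[0].name]
            for ch in node.children[1:]:
                inter = acc & sets[ch.name]
                union = acc | sets[ch.name]
                empty = inter == 0
                score += int(empty.sum())
                acc = np.where(empty, union, inter)
            sets[node.name] = acc
    lowest = np.zeros(16, dtype=np.uint8)
    nbits = np.zeros(16, dtype=np.uint8)
    for v in range(1, 16):
        lowest[v] = v & -v
        nbits[v] = bin(v).count("1")
    states: dict[str, np.ndarray] = {}
    ambiguous = 0
    for node in t.preorder():
        s = sets[node.name]
        if node.parent is None:
            chosen = lowest[s]
            ambiguous += int(np.sum(nbits[s] > 1))
        else:
            pstate = states[node.parent.name]
            has_parent = (s & pstate) != 0
            chosen = np.where(has_parent, pstate, lowest[s])
            ambiguous += int(np.sum((~has_parent) & (nbits[s] > 1)))
        states[node.name] = chosen.astype(np.uint8)
    decode_map = np.zeros(16, dtype=np.uint8)
    for b, nt in _BIT_NT.items():
        decode_map[b] = ord(nt)
    internal = {
        node.name: decode_map[states[node.name]].tobytes().decode()
        for node in t.non_tips(include_self=True)
    }
    return AncestralReconstruction(internal, score, ambiguous)


def lineage_ka_ks(
    codon_aln: dict[str, str], tree: TreeNode, skip_stop_codons: bool = True
) -> list[BranchRates]:
    """Per-branch Ka/Ks from parsimony ancestors on a rooted gene tree.

    Each non-root node's branch is scored with :func:`branch_ka_ks` against
    its reconstructed parent sequence. Codons where the reconstruction
    produced an internal stop are skipped by default.
    """
    t = name_internal_nodes(tree.copy())
    rec = ancestral_parsimony(codon_aln, t)
    seqs = dict(codon_aln)
    seqs.update(rec.sequences)
    out = []
    for node in t.preorder(include_self=False):
        out.append(
            branch_ka_ks(
                seqs[node.parent.name],
                seqs[node.name],
                branch=node.name,
                skip_stop_codons=skip_stop_codons,
            )
        )
    return out
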