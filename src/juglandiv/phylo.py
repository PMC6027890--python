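"""Distance correction, neighbor joining, bootstrap, and chronogram.

The distance track of the pipeline: observed genome-alignment mismatch
fractions are corrected to substitutions/site with the Jukes-Cantor
formula d = -(3/4) ln(1 - 4p/3); an unrooted tree is built with classical
neighbor joining (Saitou-Nei Q criterion); supports come from a
nonparametric bootstrap over alignment columns; and a rooted tree is
converted to an ultrametric chronogram by least-squares clock smoothing
(mean root-path projection per node) anchored at a single calibration
node (45 Mya for the walnut crown group in the study this reproduces).

Trees are scikit-bio ``TreeNode`` objects throughout; distance matrices
are scikit-bio ``DistanceMatrix``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode


# ---------------------------------------------------------------------------
# Jukes-Cantor correction
# ---------------------------------------------------------------------------

def jukes_cantor(p):
    """JC69 corrected distance d = -(3/4) ln(1 - 4p/3) for mismatch fraction p.

    Accepts scalars or arrays; p must satisfy 0 <= p < 0.75 (the correction
    diverges at the saturation point 3/4).
    """
    arr = np.asarray(p, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr >= 0.75):
        raise ValueError("mismatch fraction must be in [0, 0.75)")
    d = -0.75 * np.log1p(-4.0 * arr / 3.0)
    return float(d) if np.isscalar(p) else d


def jc_mismatch_fraction(d):
    """Inverse of :func:`jukes_cantor`: expected mismatch fraction at distance d."""
    arr = np.asarray(d, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("distance must be non-negative")
    p = 0.75 * (1.0 - np.exp(-4.0 * arr / 3.0))
    return float(p) if np.isscalar(d) else p


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Classical neighbor joining on a distance matrix.

    Exact (topology and branch lengths) on additive matrices. Ties in the
    Q criterion break on the lexicographically first index pair, so the
    result is deterministic. Negative branch lengths are clamped to zero
    when ``clamp_negative`` (the total clamped deficit is stored on the
    returned tree as ``tree.clamped_deficit``). The final three lineages
    join at an unresolved (trifurcating) node, the standard unrooted form.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=np.float64)
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    nodes = [TreeNode(name=i) for i in ids]
    deficit = 0.0

    def _clamp(x: float) -> float:
        nonlocal deficit
        if clamp_negative and x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        # Q[i, j] = (n - 2) D[i, j] - r_i - r_j
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # argmin is first minimum: lexicographic tie-break
        i, j = (best[0], best[1]) if best[0] < best[1] else (best[1], best[0])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = _clamp(li)
        nodes[j].length = _clamp(lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
    # join the last three at a trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    root = TreeNode(children=nodes)
    for node, ln in zip(root.children, (l0, l1, l2)):
        node.length = _clamp(ln)
    root.clamped_deficit = deficit
    return root


# ---------------------------------------------------------------------------
# Alignment filtering and bootstrap
# ---------------------------------------------------------------------------

class AlignmentRejected(ValueError):
    """Raised when an alignment is >= 50% gap columns and is dropped whole."""


def filter_alignment(aln: dict[str, str], max_gap_col_frac: float = 0.5) -> dict[str, str]:
    """Remove every column containing a gap; reject gap-saturated alignments.

    If the fraction of gap-containing columns is >= ``max_gap_col_frac``
    (default: half), the whole alignment is rejected with
    :class:`AlignmentRejected` rather than silently reduced to scraps.
    """
    seqs = list(aln.values())
    if not seqs:
        raise ValueError("empty alignment")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment")
    mat = np.array([list(s) for s in seqs])
    gap_col = np.any((mat == "-") | (mat == "."), axis=0)
    if L > 0 and gap_col.sum() / L >= max_gap_col_frac:
        raise AlignmentRejected(
            f"{gap_col.sum()}/{L} columns contain gaps (>= {max_gap_col_frac:.0%})"
        )
    keep = ~gap_col
    return {name: "".join(mat[i, keep]) for i, name in enumerate(aln)}


def p_distance_matrix(aln: dict[str, str]) -> DistanceMatrix:
    """Pairwise mismatch fractions of an ungapped alignment."""
    names = list(aln)
    mat = np.array([np.frombuffer(aln[n].encode(), dtype=np.uint8) for n in names])
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = np.mean(mat[i] != mat[j])
    return DistanceMatrix(D, names)


def bipartitions(tree: TreeNode, min_branch_length: float = 1e-12) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree as min-side tip-name sets.

    Internal branches of (near-)zero length do not define a real split and
    are skipped, so a star-like tree contributes no bipartitions.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        if (node.length or 0.0) < min_branch_length:
            continue
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_nj(
    aln: dict[str, str], replicates: int = 100, seed: int = 0
) -> tuple[TreeNode, dict[frozenset, int]]:
    """NJ tree with bootstrap supports over resampled alignment columns.

    The full-data tree is built from JC-corrected p-distances; each
    replicate resamples columns with replacement and the support of each
    internal bipartition of the full tree is the number of replicates whose
    tree contains it. Supports are attached to the corresponding internal
    nodes as ``node.support`` and returned keyed by bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(aln)
    L = len(next(iter(aln.values())))
    full = neighbor_joining(DistanceMatrix(jukes_cantor(p_distance_matrix(aln).data), names))
    target = bipartitions(full)
    supports = {b: 0 for b in target}
    mat = np.array([np.frombuffer(aln[n].encode(), dtype=np.uint8) for n in names])
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        sub = mat[:, cols]
        n = len(names)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = np.mean(sub[i] != sub[j])
        if np.any(D >= 0.75):
            continue
        rep = neighbor_joining(DistanceMatrix(jukes_cantor(D), names))
        for b in bipartitions(rep) & target:
            supports[b] += 1
    all_tips = frozenset(names)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        if key in supports:
            node.support = supports[key]
    return full, supports


# ---------------------------------------------------------------------------
# Rooting and chronogram
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root an unrooted NJ tree on the branch leading to the outgroup tip."""
    t = tree.copy()
    og = t.find(outgroup)
    try:
        return t.root_at(og, above=True, reset=True)
    except TypeError:  # older scikit-bio without edge rooting
        return t.root_at(og.parent, reset=True)


@dataclass
class Chronogram:
    """Rooted ultrametric tree with absolute node ages.

    ``tree`` carries branch lengths in time units (Mya); ``ages`` maps node
    name to age, leaves at 0; ``calibration`` records the anchor.
    """

    tree: TreeNode
    ages: dict[str, float]
    calibration: tuple[str, float]

    def age(self, name: str) -> float:
        return self.ages[name]


def calibrate_chronogram(tree: TreeNode, node, age_mya: float = 45.0) -> Chronogram:
    """Clock-smooth a rooted tree and anchor one internal node's age.

    ``node`` is the calibration node's name, or a collection of tip names
    whose last common ancestor is calibrated. Each node's relative height
    is the mean of its path lengths to the leaves below it (a
    least-squares clock projection); heights are forced monotone up the
    tree, then every height is scaled so the calibration node sits at
    ``age_mya``. Branch lengths of the returned tree are age differences,
    so it is ultrametric by construction.
    """
    t = tree.copy()
    from .synthetic import name_internal_nodes

    name_internal_nodes(t, prefix="cn")
    cal = t.lca(list(node)) if isinstance(node, (list, tuple, set, frozenset)) else t.find(node)
    if cal.is_tip():
        raise ValueError("calibration node must be internal")
    heights: dict[int, float] = {}
    ntips: dict[int, int] = {}
    for node in t.postorder():
        if node.is_tip():
            heights[id(node)] = 0.0
            ntips[id(node)] = 1
        else:
            tot, cnt = 0.0, 0
            for ch in node.children:
                w = ntips[id(ch)]
                tot += w * (heights[id(ch)] + (ch.length or 0.0))
                cnt += w
            ntips[id(node)] = cnt
            h = tot / cnt
            h_min = max(heights[id(ch)] for ch in node.children)
            heights[id(node)] = max(h, h_min + 1e-12)
    h_cal = heights[id(cal)]
    if h_cal <= 0:
        raise ValueError("calibration node has zero height")
    scale = age_mya / h_cal
    ages = {}
    for node in t.postorder():
        a = heights[id(node)] * scale
        ages[node.name] = a
        for ch in node.children:
            ch.length = a - heights[id(ch)] * scale
    return Chronogram(t, ages, (cal.name, age_mya))


# ---------------------------------------------------------------------------
# Newick / matrix I/O helpers
# ---------------------------------------------------------------------------

def read_newick(source) -> TreeNode:
    if hasattr(source, "read"):
        return TreeNode.read(source)
    text = str(source)
    if text.strip().startswith("(") or text.strip().endswith(";"):
        return TreeNode.read(_io.StringIO(text))
    return TreeNode.read(text)


def write_newick(tree: TreeNode, path=None) -> str | None:
    if path is None:
        buf = _io.StringIO()
        tree.write(buf)
        return buf.getvalue().strip()
    tree.write(path)
    return None
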