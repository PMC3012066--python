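"""Distance phylogenetics for KIR domain analysis.

Implements the classic distance pipeline used for domain-by-domain KIR
trees: Tamura-Nei (TN93) distances with pairwise or complete deletion,
neighbor-joining with the Studier-Keppler Q criterion, nonparametric
bootstrap of alignment columns with bipartition support, midpoint rooting,
annotation-driven domain partitioning, clade membership checks, and a
chi-square informative-site scan that localises recombination breakpoints
between two candidate groupings and assesses them by permutation.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports are
stored on internal nodes both as ``node.support`` (float, percent) and as
the node label for Newick output.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import dendropy
import numpy as np

from .diversity import Alignment

__all__ = [
    "DistanceMatrix",
    "DomainPartition",
    "BreakpointResult",
    "tn93_distance",
    "nj_tree",
    "bootstrap_support",
    "midpoint_root",
    "partition_by_domains",
    "clade_by_label_check",
    "breakpoint_scan",
    "tree_bipartitions",
    "leaf_path_lengths",
]

#: Distance assigned to pairs too diverged for the TN93 correction.
SATURATION_CEILING = 5.0


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero-diagonal, substitutions/site

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if (v < 0).any():
            raise ValueError("negative distances")

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class DomainPartition:
    """Named, non-overlapping column intervals (0-based half-open)."""

    intervals: tuple[tuple[str, int, int], ...]

    def validate(self, length: int) -> None:
        occupied: list[tuple[int, int]] = []
        for name, start, end in self.intervals:
            if not (0 <= start < end <= length):
                raise ValueError(f"domain {name}: [{start}, {end}) outside alignment")
            for a, b in occupied:
                if start < b and a < end:
                    raise ValueError(f"domain {name} overlaps another interval")
            occupied.append((start, end))


# ---------------------------------------------------------------------------
# TN93 distances
# ---------------------------------------------------------------------------

_BASES = (b"A", b"C", b"G", b"T")


def _tn93_pair(x: np.ndarray, y: np.ndarray, ceiling: float) -> float:
    ok = np.isin(x, _BASES) & np.isin(y, _BASES)
    L = int(ok.sum())
    if L == 0:
        raise ValueError("sequence pair shares no comparable sites")
    x, y = x[ok], y[ok]
    both = np.concatenate([x, y])
    freqs = {b: float((both == b).sum()) / (2 * L) for b in _BASES}
    pA, pC, pG, pT = (freqs[b] for b in _BASES)
    pR, pY = pA + pG, pC + pT

    diff = x != y
    purine = np.isin(x, (b"A", b"G")) & np.isin(y, (b"A", b"G"))
    pyrimidine = np.isin(x, (b"C", b"T")) & np.isin(y, (b"C", b"T"))
    P1 = float((diff & purine).sum()) / L
    P2 = float((diff & pyrimidine).sum()) / L
    Q = float((diff & ~purine & ~pyrimidine).sum()) / L
    if P1 == P2 == Q == 0.0:
        return 0.0

    k1 = 2 * pA * pG / pR if pR > 0 else 0.0
    k2 = 2 * pT * pC / pY if pY > 0 else 0.0
    k3 = 2 * (pR * pY - (pA * pG * pY / pR if pR > 0 else 0.0) - (pT * pC * pR / pY if pY > 0 else 0.0))

    terms = []
    for k, w_arg in (
        (k1, 1.0 - (P1 / k1 if k1 > 0 else 0.0) - (Q / (2 * pR) if pR > 0 else 0.0)),
        (k2, 1.0 - (P2 / k2 if k2 > 0 else 0.0) - (Q / (2 * pY) if pY > 0 else 0.0)),
        (k3, 1.0 - (Q / (2 * pR * pY) if pR * pY > 0 else 0.0)),
    ):
        if k <= 0:
            continue
        if w_arg <= 0:
            warnings.warn("saturated sequence pair; TN93 distance set to ceiling")
            return ceiling
        terms.append(-k * np.log(w_arg))
    return float(sum(terms))


def tn93_distance(
    aln: Alignment,
    deletion: Literal["pairwise", "complete"] = "pairwise",
    ceiling: float = SATURATION_CEILING,
) -> DistanceMatrix:
    """Pairwise Tamura-Nei (1993) distances from observed base frequencies.

    The closed form corrects separately for the two transition classes
    (purine A<->G and pyrimidine C<->T) and for transversions, using base
    frequencies observed in each compared pair.  Pairs whose divergence
    exceeds the domain of the logarithms are reported at ``ceiling`` with a
    warning.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = aln.matrix()
    if deletion == "complete":
        keep = np.isin(mat, _BASES).all(axis=0)
        mat = mat[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion rule {deletion!r}")
    n = aln.n
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = _tn93_pair(mat[i], mat[j], ceiling)
    return DistanceMatrix(tuple(aln.ids), d)


def p_distance(aln: Alignment, deletion: Literal["pairwise", "complete"] = "pairwise") -> DistanceMatrix:
    """Uncorrected proportion-of-differences distance (companion to TN93)."""
    mat = aln.matrix()
    ok = np.isin(mat, _BASES)
    if deletion == "complete":
        keep = ok.all(axis=0)
        mat, ok = mat[:, keep], ok[:, keep]
    n = aln.n
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ok[i] & ok[j]
        L = int(both.sum())
        if L == 0:
            raise ValueError("sequence pair shares no comparable sites")
        d[i, j] = d[j, i] = float(((mat[i] != mat[j]) & both).sum()) / L
    return DistanceMatrix(tuple(aln.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Ties in Q are broken by the lexicographically lowest pair of cluster
    representative labels (the smallest leaf label in each cluster).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  With three or more leaves the result is unrooted
    (trifurcating seed node).
    """
    n0 = len(D.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(list(D.labels))
    tree = dendropy.Tree(taxon_namespace=ns)

    nodes = []
    for label in D.labels:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)
    reps = list(D.labels)
    d = D.values.astype(float).copy()
    active = list(range(n0))

    def clamp(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a, b in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[a, b] - r[a] - r[b]
            ia, ib = active[a], active[b]
            key = tuple(sorted((reps[ia], reps[ib])))
            if best is None or (q, key) < (best[0], best[1]):
                best = (q, key, a, b)
        _, _, a, b = best
        ia, ib = active[a], active[b]
        via = sub[a, b] / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        vib = sub[a, b] - via
        via, vib = clamp(via, vib)

        parent = dendropy.Node()
        parent.add_child(nodes[ia])
        nodes[ia].edge.length = via
        parent.add_child(nodes[ib])
        nodes[ib].edge.length = vib

        new = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[ia], reps[ib]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (ia, ib):
                continue
            d[new, c] = d[c, new] = (d[ia, c] + d[ib, c] - d[ia, ib]) / 2.0
        active = [c for c in active if c not in (ia, ib)] + [new]

    # Join the final three clusters at an unrooted (trifurcating) seed node.
    ia, ib, ic = sorted(active, key=lambda k: reps[k])
    va = (d[ia, ib] + d[ia, ic] - d[ib, ic]) / 2.0
    vb = (d[ia, ib] + d[ib, ic] - d[ia, ic]) / 2.0
    vc = (d[ia, ic] + d[ib, ic] - d[ia, ib]) / 2.0
    root = dendropy.Node()
    for k, v in ((ia, va), (ib, vb), (ic, vc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(v, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, rooting
# ---------------------------------------------------------------------------


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def tree_bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions as canonical label sets, mapped to nodes.

    Each internal edge splits the leaves in two; the canonical
    representative is the side that excludes the alphabetically smallest
    leaf label, making the encoding independent of rooting.
    """
    all_labels = _leaf_labels(tree)
    anchor = min(all_labels)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        canonical = all_labels - side if anchor in side else side
        if 0 < len(canonical) < len(all_labels) - 1:
            out[canonical] = node
    return out


def bootstrap_support(
    aln: Alignment,
    builder: Callable[[Alignment], dendropy.Tree] | None = None,
    B: int = 500,
    seed: int | None = None,
) -> dendropy.Tree:
    """Point-estimate tree with column-bootstrap bipartition support.

    Columns are resampled with replacement ``B`` times; each internal node
    of the point tree gets ``support`` = percentage of replicate trees
    containing its bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if builder is None:
        builder = lambda a: nj_tree(tn93_distance(a, deletion="pairwise"))
    rng = np.random.default_rng(seed)
    point = builder(aln)
    target = tree_bipartitions(point)
    counts = {bip: 0 for bip in target}
    base = aln.matrix()
    for _ in range(B):
        resampled = rng.integers(0, aln.length, size=aln.length)
        rows = tuple(r.tobytes().decode() for r in base[:, resampled])
        rep = builder(Alignment(aln.ids, rows))
        rep_bips = tree_bipartitions(rep)
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in target.items():
        support = 100.0 * counts[bip] / B
        node.support = support
        node.label = f"{support:.0f}"
    return point


def leaf_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Patristic distances between all leaf pairs, keyed by sorted label pair."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((t for t in tree.taxon_namespace), key=lambda t: t.label)
    out = {}
    for t1, t2 in itertools.combinations(taxa, 2):
        out[(t1.label, t2.label)] = float(pdm.patristic_distance(t1, t2))
    return out


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest (label, label) pair.  Path lengths are preserved.
    """
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    dists = leaf_path_lengths(tree)
    (la, lb), dmax = min(dists.items(), key=lambda kv: (-kv[1], kv[0]))
    leaf_by_label = {leaf.taxon.label: leaf for leaf in leaves}
    a, b = leaf_by_label[la], leaf_by_label[lb]

    # Node path a -> seed -> b, then trim to a -> mrca -> b.
    up_a = [a]
    while up_a[-1].parent_node is not None:
        up_a.append(up_a[-1].parent_node)
    up_b = [b]
    while up_b[-1].parent_node is not None:
        up_b.append(up_b[-1].parent_node)
    in_a = {id(x) for x in up_a}
    mrca = next(x for x in up_b if id(x) in in_a)
    path = up_a[: [id(x) for x in up_a].index(id(mrca)) + 1]
    down_b = up_b[: [id(x) for x in up_b].index(id(mrca))]
    # edges walked child-side first from a up to mrca, then parent-side down to b
    edges = [(node, "up") for node in path[:-1]] + [(node, "down") for node in reversed(down_b)]

    half = dmax / 2.0
    walked = 0.0
    for node, direction in edges:
        length = node.edge.length or 0.0
        if walked + length >= half - 1e-12:
            offset = half - walked  # distance from the end nearer `a`
            child = node  # edge runs child -> parent
            parent = child.parent_node
            if direction == "up":
                from_child = offset
            else:
                from_child = length - offset
            if from_child <= 1e-12:
                new_root = child
            elif length - from_child <= 1e-12:
                new_root = parent
            else:
                parent.remove_child(child)
                mid = parent.new_child(edge_length=length - from_child)
                mid.add_child(child)
                child.edge.length = from_child
                new_root = mid
            tree.reroot_at_node(
                new_root, suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=False
            )
            tree.is_rooted = True
            return tree
        walked += length
    raise AssertionError("midpoint not located on path")  # pragma: no cover


def partition_by_domains(
    aln: Alignment, part: DomainPartition
) -> list[tuple[str, Alignment]]:
    """Column-slice the alignment into named domains for per-domain trees."""
    part.validate(aln.length)
    return [(name, aln.slice(start, end)) for name, start, end in part.intervals]


def clade_by_label_check(
    tree: dendropy.Tree, labels: set[str]
) -> tuple[bool, float | None]:
    """Whether ``labels`` form a clade of the rooted tree, with its support.

    Returns ``(True, support)`` when some node's leaf set equals ``labels``
    (support is that node's bootstrap value, or None if absent), else
    ``(False, None)``.
    """
    all_labels = _leaf_labels(tree)
    unknown = set(labels) - all_labels
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    target = frozenset(labels)
    complement = all_labels - target
    found = False
    support = None
    for node in tree.preorder_node_iter():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if side == target:
            found = True
        # the unrooted bipartition {target | complement} carries the support,
        # which after rerooting may sit on the complement-side node
        if side in (target, complement) and getattr(node, "support", None) is not None:
            support = node.support
    return (True, support) if found else (False, None)


# ---------------------------------------------------------------------------
# Recombination breakpoint scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakpointResult:
    breakpoint: int | None  # column index; None when no signal
    score: float  # max 2x2 chi-square
    p_value: float
    informative_columns: tuple[int, ...]
    categories: tuple[int, ...]  # 1 or 2, parallel to informative_columns


def _column_support(col: np.ndarray, g_mask: np.ndarray) -> bool:
    """True when the column cleanly separates the masked group from the rest."""
    g, rest = col[g_mask], col[~g_mask]
    if np.isin(g, _BASES).all() and np.isin(rest, _BASES).all():
        return len(set(g.tolist())) == 1 and len(set(rest.tolist())) == 1 and g[0] != rest[0]
    return False


def _max_chi2(cats: np.ndarray) -> tuple[int, float]:
    """Best split position (index into cats, split before it) and chi-square.

    For a 2x2 table with fixed margins the chi-square statistic reduces to
    N (ad - bc)^2 / (r1 r2 c1 c2); all split positions are evaluated at once.
    """
    m = len(cats)
    if m < 2:
        return 0, 0.0
    n1 = float((cats == 1).sum())
    n2 = float((cats == 2).sum())
    if n1 == 0 or n2 == 0:
        return 0, 0.0
    left1 = np.cumsum(cats == 1)[:-1].astype(float)  # counts left of split pos=1..m-1
    left2 = np.cumsum(cats == 2)[:-1].astype(float)
    right1, right2 = n1 - left1, n2 - left2
    r1, r2 = left1 + left2, right1 + right2
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = m * (left1 * right2 - left2 * right1) ** 2 / (r1 * r2 * n1 * n2)
    scores = np.nan_to_num(scores, nan=0.0, posinf=0.0)
    best = int(np.argmax(scores))
    return best + 1, float(scores[best])


def breakpoint_scan(
    aln: Alignment,
    grouping1: set[str],
    grouping2: set[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> BreakpointResult:
    """Locate the column where phylogenetic support switches between groupings.

    Each polymorphic column is scored as supporting ``grouping1`` (all its
    members share a base that differs from the base shared by everyone
    else), supporting ``grouping2``, or neither.  The breakpoint is placed
    between the informative sites maximising the 2x2 chi-square of
    (supports-1, supports-2) counts left versus right; significance comes
    from permuting the order of the informative-site categories.
    """
    ids = list(aln.ids)
    for g in (grouping1, grouping2):
        unknown = set(g) - set(ids)
        if unknown:
            raise ValueError(f"unknown sequence ids in grouping: {sorted(unknown)}")
    mat = aln.matrix()
    m1 = np.array([sid in grouping1 for sid in ids])
    m2 = np.array([sid in grouping2 for sid in ids])

    columns, cats = [], []
    for c in range(aln.length):
        col = mat[:, c]
        s1 = _column_support(col, m1)
        s2 = _column_support(col, m2)
        if s1 == s2:
            continue  # neither, or uninformative about the contrast
        columns.append(c)
        cats.append(1 if s1 else 2)
    if not columns:
        raise ValueError("no informative columns for either grouping")
    cats_arr = np.array(cats)
    pos, score = _max_chi2(cats_arr)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        _, perm_score = _max_chi2(rng.permutation(cats_arr))
        if perm_score >= score:
            exceed += 1
    p_value = (1 + exceed) / (n_permutations + 1)

    if score == 0.0 or pos == 0:
        breakpoint = None
    else:
        # midpoint between the flanking informative sites
        breakpoint = int(round((columns[pos - 1] + columns[pos]) / 2.0)) + 1
    return BreakpointResult(
        breakpoint=breakpoint,
        score=score,
        p_value=p_value,
        informative_columns=tuple(columns),
        categories=tuple(cats),
    )
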