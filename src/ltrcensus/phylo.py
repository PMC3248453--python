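"""Concatenated-domain phylogeny of most-successful elements, plus the
threshold similarity graph used to contrast superfamilies.

The chain mirrors the classical pol-domain workflow: align each protein
domain across elements (progressive alignment: k-mer guide tree, then
profile-profile Needleman-Wunsch/Gotoh with BLOSUM62 and affine gaps), keep
columns below a gap-fraction ceiling, concatenate the per-domain blocks,
compute Poisson-corrected protein distances, build a neighbor-joining tree
and root it on an outgroup. Distance/NJ inference is the deliberate,
deterministic stand-in for maximum-likelihood inference; it is validated by
the classical guarantee that NJ recovers any additive distance matrix
exactly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

__all__ = [
    "MSA",
    "DistanceMatrix",
    "Node",
    "Tree",
    "progressive_align",
    "pairwise_score",
    "trim_columns",
    "concatenate",
    "distance_matrix",
    "nj_tree",
    "root_with_outgroup",
    "similarity_components",
    "mantel_r",
]

_BLOSUM = substitution_matrices.load("BLOSUM62")
_B62_AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = np.array([[float(_BLOSUM[a][b]) for b in _B62_AA] for a in _B62_AA])
_B62_INDEX = {aa: i for i, aa in enumerate(_B62_AA)}

GAP_OPEN = -11.0  # cost of the first residue of a gap run
GAP_EXTEND = -1.0
_NEG = -1e30


@dataclass
class MSA:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


# ---------------------------------------------------------------------------
# progressive alignment


def _profile_counts(rows: list[str]) -> np.ndarray:
    out = np.zeros((len(rows[0]), 20))
    for r in rows:
        for j, aa in enumerate(r):
            k = _B62_INDEX.get(aa)
            if k is not None:
                out[j, k] += 1
    return out


def _gotoh_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str], float]:
    """Profile-profile global alignment (affine gaps); returns gapped rows
    of each profile plus the alignment score."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    S = (ca @ _B62 @ cb.T) / (na * nb)
    m, n = S.shape

    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # gap in B (A column vs '-')
    Iy = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, n + 1):
        Iy[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX[2:, 0] = 1  # boundary gap runs chain within their own state
    ptrY[0, 2:] = 2
    for i in range(1, m + 1):
        Mi1, Ii1, Yi1 = M[i - 1], Ix[i - 1], Iy[i - 1]
        for j in range(1, n + 1):
            best = max(Mi1[j - 1], Ii1[j - 1], Yi1[j - 1])
            M[i, j] = best + S[i - 1, j - 1]
            ptrM[i, j] = (0 if best == Mi1[j - 1]
                          else 1 if best == Ii1[j - 1] else 2)
            xo, xe, xy = Mi1[j] + GAP_OPEN, Ii1[j] + GAP_EXTEND, Yi1[j] + GAP_OPEN
            Ix[i, j] = max(xo, xe, xy)
            ptrX[i, j] = 0 if Ix[i, j] == xo else (1 if Ix[i, j] == xe else 2)
            yo, ye, yx = M[i, j - 1] + GAP_OPEN, Iy[i, j - 1] + GAP_EXTEND, Ix[i, j - 1] + GAP_OPEN
            Iy[i, j] = max(yo, ye, yx)
            ptrY[i, j] = 0 if Iy[i, j] == yo else (2 if Iy[i, j] == ye else 1)

    # pointer values are previous-state ids: 0 = M, 1 = Ix, 2 = Iy
    finals = [M[m, n], Ix[m, n], Iy[m, n]]
    state = int(np.argmax(finals))
    score = float(finals[state])
    i, j = m, n
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            nxt = ptrM[i, j]
            ops.append("M")
            i, j = i - 1, j - 1
        elif state == 1:
            nxt = ptrX[i, j]
            ops.append("X")
            i -= 1
        else:
            nxt = ptrY[i, j]
            ops.append("Y")
            j -= 1
        state = int(nxt)
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
        if op in ("M", "Y"):
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += "-"
    return out_a, out_b, score


def pairwise_score(a: str, b: str) -> float:
    """Optimal global alignment score of two proteins under the package's
    scheme (BLOSUM62, gap open -11, extend -1)."""
    _, _, score = _gotoh_profiles([a], [b])
    return score


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(max(0, len(a) - k + 1))}
    kb = {b[i:i + k] for i in range(max(0, len(b) - k + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_align(seqs: dict[str, str] | list[tuple[str, str]]) -> MSA:
    """Progressive multiple alignment: average-linkage guide tree on k-mer
    distances, then profile-profile Gotoh merges."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences")
    if len(items) == 1:
        return MSA([items[0][0]], [items[0][1]])
    names = [n for n, _ in items]
    raw = [s for _, s in items]

    if len(items) == 2:
        merged = _gotoh_profiles([raw[0]], [raw[1]])
        rows = [merged[0][0], merged[1][0]]
        return MSA(names, rows)

    cond = [
        _kmer_distance(raw[i], raw[j])
        for i in range(len(raw)) for j in range(i + 1, len(raw))
    ]
    Z = linkage(np.array(cond), method="average")
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [raw[i]]) for i in range(len(raw))
    }
    for step, (a, b, _dist, _cnt) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = profiles.pop(ia)
        idx_b, rows_b = profiles.pop(ib)
        ga, gb, _score = _gotoh_profiles(rows_a, rows_b)
        profiles[len(raw) + step] = (idx_a + idx_b, ga + gb)
    (_, (order, rows)), = profiles.items()
    aligned = [None] * len(raw)
    for pos, original in enumerate(order):
        aligned[original] = rows[pos]
    return MSA(names, aligned)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# trimming / concatenation


def trim_columns(msa: MSA, max_gap_fraction: float) -> MSA:
    """Keep exactly the columns whose gap fraction <= ``max_gap_fraction``."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0,1]")
    n = len(msa.rows)
    keep = [j for j in range(msa.n_columns)
            if sum(r[j] == "-" for r in msa.rows) / n <= max_gap_fraction]
    if not keep:
        warnings.warn("all alignment columns removed by trimming")
        return MSA(msa.taxa, ["" for _ in msa.rows])
    return MSA(msa.taxa, ["".join(r[j] for j in keep) for r in msa.rows])


def concatenate(msas: list[MSA]) -> MSA:
    """Concatenate per-domain blocks over a shared taxon set; a taxon missing
    from one block gets an all-gap filler for that block."""
    if not msas:
        raise ValueError("no alignments")
    # blocks must overlap in taxa (directly or transitively)
    g = nx.Graph()
    g.add_nodes_from(range(len(msas)))
    for i, j in itertools.combinations(range(len(msas)), 2):
        if set(msas[i].taxa) & set(msas[j].taxa):
            g.add_edge(i, j)
    if len(msas) > 1 and not nx.is_connected(g):
        raise ValueError("alignments have disjoint taxa sets")

    taxa: list[str] = []
    for msa in msas:
        for t in msa.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = []
    for t in taxa:
        parts = []
        for msa in msas:
            if t in msa.taxa:
                parts.append(msa.row(t))
            else:
                parts.append("-" * msa.n_columns)
        rows.append("".join(parts))
    return MSA(taxa, rows)


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("distances must be finite and nonnegative")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def distance_matrix(msa: MSA, model: str = "poisson",
                    max_distance: float = 3.0) -> DistanceMatrix:
    """Pairwise protein distances with pairwise deletion of gaps.

    ``p`` is the mismatch fraction over comparable columns (both residues
    canonical amino acids); ``poisson`` applies -ln(1-p), capped at
    ``max_distance`` for p >= 0.95.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    enc = []
    for r in msa.rows:
        enc.append(np.array([_B62_INDEX.get(aa, -1) for aa in r]))
    n = len(enc)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (enc[i] >= 0) & (enc[j] >= 0)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {msa.taxa[i]!r} and {msa.taxa[j]!r}")
            p = float(((enc[i] != enc[j]) & ok).sum() / total)
            if model == "p":
                d = p
            elif p >= 0.95:
                d = max_distance
            else:
                d = min(-math.log(1.0 - p), max_distance)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(list(msa.taxa), m)


# ---------------------------------------------------------------------------
# trees


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"


@dataclass
class Tree:
    root: Node
    rooted: bool = False

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def newick(self) -> str:
        if self.root.is_leaf:
            return f"{self.root.name};"
        inner = ",".join(c._newick() for c in self.root.children)
        return f"({inner});"

    def _graph(self) -> nx.Graph:
        g = nx.Graph()
        counter = itertools.count()

        def walk(node: Node) -> int:
            nid = next(counter)
            g.add_node(nid, name=node.name, leaf=node.is_leaf)
            for c in node.children:
                cid = walk(c)
                g.add_edge(nid, cid, length=c.length, child=cid)
            return nid

        walk(self.root)
        return g

    def leaf_distances(self) -> DistanceMatrix:
        g = self._graph()
        leaf_ids = [n for n, d in g.nodes(data=True) if d["leaf"]]
        names = [g.nodes[n]["name"] for n in leaf_ids]
        n = len(leaf_ids)
        m = np.zeros((n, n))
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = lengths[leaf_ids[i]][leaf_ids[j]]
        return DistanceMatrix(names, m)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken deterministically by the lowest (i, j) index pair.
    Negative branch-length estimates are clamped to zero. The result is the
    conventional unrooted tree, represented with a trifurcating root.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.copy()
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(k):
            for bi in range(ai + 1, k):
                i, j = active[ai], active[bi]
                q = (k - 2) * D[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = D[i, j] - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent = Node(children=[nodes[i], nodes[j]])
        new_idx = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for m_ in active:
            if m_ in (i, j):
                continue
            d = 0.5 * (D[i, m_] + D[j, m_] - D[i, j])
            D[new_idx, m_] = D[m_, new_idx] = d
        active = [a for a in active if a not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(0.0, ln)
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root, rooted=False)


def root_with_outgroup(tree: Tree, outgroup: list[str] | set[str]) -> Tree:
    """Root on the branch separating the outgroup from the ingroup, at that
    branch's midpoint. A non-monophyletic outgroup triggers a warning and
    rooting on the branch that best separates outgroup from ingroup."""
    outgroup = set(outgroup)
    all_leaves = set(tree.leaf_names())
    if not outgroup <= all_leaves:
        raise ValueError("outgroup labels missing from the tree")
    if outgroup == all_leaves:
        raise ValueError("outgroup cannot contain every taxon")
    if not outgroup:
        raise ValueError("empty outgroup")

    parent: dict[int, int | None] = {}
    nodes: dict[int, Node] = {}
    counter = itertools.count()

    def index(node: Node, par: int | None) -> int:
        nid = next(counter)
        nodes[nid] = node
        parent[nid] = par
        for c in node.children:
            index(c, nid)
        return nid

    root_id = index(tree.root, None)
    children = {nid: [c for c in parent if parent[c] == nid] for nid in nodes}

    def side_leaves(nid: int) -> set[str]:
        node = nodes[nid]
        return {lf.name for lf in node.leaves()}

    # candidate edges: (parent, child) pairs; the child-side leafset defines
    # the bipartition induced by removing that edge
    best_edge = None
    best_score = None
    exact_edge = None
    for cid, pid in parent.items():
        if pid is None:
            continue
        side = side_leaves(cid)
        other = all_leaves - side
        if side == outgroup or other == outgroup:
            exact_edge = cid
            break
        score = max(
            len(side & outgroup) - len(side - outgroup),
            len(other & outgroup) - len(other - outgroup),
        )
        key = (score, -cid)
        if best_score is None or key > best_score:
            best_score = key
            best_edge = cid
    if exact_edge is None:
        warnings.warn("outgroup is not monophyletic on the unrooted tree; "
                      "rooting on the branch maximizing outgroup separation")
        edge_child = best_edge
    else:
        edge_child = exact_edge

    def rebuild(nid: int, exclude: int | None) -> Node:
        """Copy of node ``nid`` with edges oriented away from the new root."""
        node = nodes[nid]
        kids = []
        for c in children[nid]:
            if c == exclude:
                continue
            sub = rebuild(c, nid)
            sub.length = nodes[c].length
            kids.append(sub)
        pid = parent[nid]
        if pid is not None and pid != exclude:
            up = rebuild(pid, nid)
            up.length = nodes[nid].length  # edge (pid, nid) reused upward
            kids.append(up)
        return Node(name=node.name, children=kids)

    half = nodes[edge_child].length / 2.0
    below = rebuild(edge_child, parent[edge_child])
    below.length = half
    above = rebuild(parent[edge_child], edge_child)
    above.length = half
    new_root = Node(children=[below, above])
    # orient outgroup side first for readability
    if not ({lf.name for lf in below.leaves()} <= outgroup):
        new_root.children.reverse()
    return Tree(new_root, rooted=True)


# ---------------------------------------------------------------------------
# similarity graph & matrix correlation


def similarity_components(seqs: dict[str, str],
                          score_threshold: float) -> list[list[str]]:
    """Connected components of the pairwise-alignment-score graph, largest
    first (ties by smallest member label)."""
    if not seqs:
        raise ValueError("no sequences")
    names = sorted(seqs)
    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        if pairwise_score(seqs[a], seqs[b]) >= score_threshold:
            g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def mantel_r(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Mantel correlation (Pearson r over the off-diagonal entries) between
    two distance matrices on the same taxa."""
    if a.taxa != b.taxa:
        order = [a.taxa.index(t) for t in b.taxa]
        if sorted(a.taxa) != sorted(b.taxa):
            raise ValueError("distance matrices are over different taxa")
        bm = b.matrix
        perm = [b.taxa.index(t) for t in a.taxa]
        bm = bm[np.ix_(perm, perm)]
        b = DistanceMatrix(list(a.taxa), bm)
    return float(pearsonr(a.condensed(), b.condensed())[0])
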