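"""BLOSUM62 distances, neighbor-joining trees, and cleavage-motif scanning.

The score-to-distance transform is ``d_ij = 1 - 2 S_ij / (S_ii + S_jj)``
clamped below at zero, where S is the summed BLOSUM62 similarity over the
columns in which both sequences carry a residue (gap-containing columns are
ignored; self-scores use the same joint columns so identical sequences are
at distance exactly 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

GAP_CHARS = frozenset("-.")

_BLOSUM62 = None


def blosum62_matrix() -> dict:
    """The standard BLOSUM62 substitution table as a (res, res) -> int dict."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        text = (
            resources.files("seedcontrast.data")
            .joinpath("blosum62.tsv")
            .read_text()
        )
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        header = lines[0].split("\t")[1:]
        table = {}
        for ln in lines[1:]:
            parts = ln.split("\t")
            a = parts[0]
            for b, score in zip(header, parts[1:]):
                table[(a, b)] = int(score)
        _BLOSUM62 = table
    return _BLOSUM62


# ---------------------------------------------------------------------------
# alignments and distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedProteinSet:
    ids: tuple
    seqs: tuple  # gapped amino-acid strings, all equal length

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(self.seqs) < 2:
            raise ValueError("an alignment needs >= 2 sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    def __len__(self):
        return len(self.seqs)


def read_fasta_alignment(path) -> AlignedProteinSet:
    """Read a gapped FASTA alignment into an AlignedProteinSet."""
    ids, seqs, cur = [], [], []
    with open(path) as fh:
        name = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs.append("".join(cur))
                name = line[1:].split()[0]
                ids.append(name)
                cur = []
            else:
                cur.append(line.upper())
        if name is not None:
            seqs.append("".join(cur))
    return AlignedProteinSet(ids=tuple(ids), seqs=tuple(seqs))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    matrix: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])


def blosum62_distance(aln: AlignedProteinSet) -> DistanceMatrix:
    """Pairwise BLOSUM62-based distances over jointly ungapped columns."""
    table = blosum62_matrix()
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = aln.seqs[i], aln.seqs[j]
            s_ij = s_ii = s_jj = 0
            joint = 0
            for a, b in zip(si, sj):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                joint += 1
                s_ij += table[(a, b)]
                s_ii += table[(a, a)]
                s_jj += table[(b, b)]
            if joint == 0:
                raise ValueError(
                    f"no jointly ungapped columns between {aln.ids[i]!r} "
                    f"and {aln.ids[j]!r}: distance undefined"
                )
            dist = 1.0 - 2.0 * s_ij / (s_ii + s_jj)
            d[i, j] = d[j, i] = max(0.0, dist)
    return DistanceMatrix(ids=tuple(aln.ids), matrix=d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree as an edge list with branch lengths."""

    edges: list = field(default_factory=list)  # (node_a, node_b, length)
    leaves: list = field(default_factory=list)

    def adjacency(self) -> dict:
        adj = {}
        for a, b, ln in self.edges:
            adj.setdefault(a, []).append((b, ln))
            adj.setdefault(b, []).append((a, ln))
        return adj

    @property
    def nodes(self) -> list:
        seen = []
        for a, b, _ in self.edges:
            for x in (a, b):
                if x not in seen:
                    seen.append(x)
        return seen

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        adj = self.adjacency()
        ids = tuple(sorted(self.leaves))
        n = len(ids)
        d = np.zeros((n, n))
        for i, src in enumerate(ids):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, ln in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + ln
                        stack.append(v)
            for j, dst in enumerate(ids):
                d[i, j] = dist[dst]
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2  # exact symmetry despite float accumulation order
        return DistanceMatrix(ids=ids, matrix=d)

    def bipartitions(self) -> set:
        """Leaf bipartitions induced by internal edges (topology signature)."""
        adj = self.adjacency()
        all_leaves = frozenset(self.leaves)
        splits = set()
        for a, b, _ in self.edges:
            # leaves on the 'a' side when edge (a,b) is cut
            side = set()
            stack = [a]
            seen = {a, b}
            while stack:
                u = stack.pop()
                if u in all_leaves:
                    side.add(u)
                for v, _ln in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            side = frozenset(side)
            other = all_leaves - side
            if len(side) > 1 and len(other) > 1:
                splits.add(frozenset((side, other)))
        return splits


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classical neighbor-joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing
    ``Q_ij = (r - 2) d_ij - R_i - R_j`` (R = row sums, r = active taxa),
    with the standard branch-length and distance-reduction formulas.
    Negative branch lengths are clamped to zero with the deficit reported
    through a warning.  Ties break on the lowest index pair so the result is
    deterministic.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    ids = list(D.ids)
    d = {
        (ids[i], ids[j]): float(D.matrix[i, j])
        for i in range(n)
        for j in range(n)
    }
    active = list(ids)
    edges = []
    clamp_deficit = 0.0
    next_internal = 0

    def dist(a, b):
        return 0.0 if a == b else d[(a, b)]

    def clamp(x):
        nonlocal clamp_deficit
        if x < 0:
            clamp_deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(dist(a, b) for b in active) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * dist(a, b) - rowsum[a] - rowsum[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        a, b = active[i], active[j]
        u = f"_nj{next_internal}"
        next_internal += 1
        la = 0.5 * dist(a, b) + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        lb = dist(a, b) - la
        edges.append((a, u, clamp(la)))
        edges.append((b, u, clamp(lb)))
        for k in active:
            if k in (a, b):
                continue
            duk = 0.5 * (dist(a, k) + dist(b, k) - dist(a, b))
            d[(u, k)] = d[(k, u)] = duk
        active = [x for x in active if x not in (a, b)]
        active.append(u)

    a, b, c = active
    u = f"_nj{next_internal}"
    edges.append((a, u, clamp(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)))))
    edges.append((b, u, clamp(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)))))
    edges.append((c, u, clamp(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)))))

    if clamp_deficit > 0:
        warnings.warn(
            f"clamped negative NJ branch lengths (total deficit "
            f"{clamp_deficit:.6g})",
            stacklevel=2,
        )
    return PhyloTree(edges=edges, leaves=list(ids))


def write_newick(tree: PhyloTree) -> str:
    """Serialize an unrooted tree as Newick, rooted at an internal node."""
    adj = tree.adjacency()
    leaves = set(tree.leaves)
    internal = [x for x in tree.nodes if x not in leaves]
    root = internal[0] if internal else tree.nodes[0]

    def render(node, parent):
        children = [(v, ln) for v, ln in adj[node] if v != parent]
        if not children:
            return node
        inner = ",".join(
            f"{render(v, node)}:{ln:.10g}" for v, ln in children
        )
        label = node if node in leaves else ""
        return f"({inner}){label}"

    return render(root, None) + ";"


def find_ng_cleavage(sequence: str, context: int = 5) -> list:
    """1-based positions of N immediately followed by G, with context windows.

    Overlapping occurrences are all reported.  Returns a list of
    ``(position, window)`` tuples where position indexes the N residue.
    """
    seq = str(sequence).upper()
    if any(c in GAP_CHARS for c in seq):
        raise ValueError("motif scanning expects an ungapped sequence")
    hits = []
    for i in range(len(seq) - 1):
        if seq[i] == "N" and seq[i + 1] == "G":
            lo = max(0, i - context)
            hi = min(len(seq), i + 2 + context)
            hits.append((i + 1, seq[lo:hi]))
    return hits
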