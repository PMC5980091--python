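"""Pairwise/progressive alignment, distances, UPGMA trees and indel analysis.

The aligner is a Gotoh affine-gap Needleman–Wunsch with a fixed, documented
tie-break (prefer diagonal, then up, then left) so that alignments — and
everything downstream of them — are bit-reproducible.  A gap of length L
costs ``gap_open + (L-1) * gap_extend``.

UPGMA is implemented directly (size-weighted average linkage, node height at
half the merge distance) with a lexicographic tie-break on the smallest leaf
label of each cluster, yielding deterministic ultrametric trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core_io import GliaError, NucleotideSeq, ProteinSeq, translate


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


DEFAULT_NT_PARAMS = AlignParams()


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


_M, _X, _Y = 0, 1, 2  # states: diagonal, gap-in-b (up), gap-in-a (left)


@njit(cache=False)
def _affine_nw_moves(C, gap_open, gap_ext):  # pragma: no cover - numba kernel
    """Fill + traceback; returns (score, moves) with moves in 0=diag,1=up,2=left."""
    n, m = C.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_ext
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            b = M[i - 1, j - 1]
            if X[i - 1, j - 1] > b:
                b = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > b:
                b = Y[i - 1, j - 1]
            M[i, j] = b + C[i - 1, j - 1]
            x = M[i - 1, j] + gap_open
            if X[i - 1, j] + gap_ext > x:
                x = X[i - 1, j] + gap_ext
            if Y[i - 1, j] + gap_open > x:
                x = Y[i - 1, j] + gap_open
            X[i, j] = x
            y = M[i, j - 1] + gap_open
            if X[i, j - 1] + gap_open > y:
                y = X[i, j - 1] + gap_open
            if Y[i, j - 1] + gap_ext > y:
                y = Y[i, j - 1] + gap_ext
            Y[i, j] = y
    # final state: prefer M, then X, then Y on ties
    state = _M
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = _X
    if Y[n, m] > score:
        score = Y[n, m]
        state = _Y
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if state == _M:
            moves[k] = 0
            k += 1
            target = M[i, j] - C[i - 1, j - 1]
            if abs(M[i - 1, j - 1] - target) < eps:
                state = _M
            elif abs(X[i - 1, j - 1] - target) < eps:
                state = _X
            else:
                state = _Y
            i -= 1
            j -= 1
        elif state == _X:
            moves[k] = 1
            k += 1
            if i == 1 and j == 0:
                state = _M  # boundary column origin
            else:
                v = X[i, j]
                if abs(M[i - 1, j] + gap_open - v) < eps:
                    state = _M
                elif abs(X[i - 1, j] + gap_ext - v) < eps:
                    state = _X
                else:
                    state = _Y
            i -= 1
        else:
            moves[k] = 2
            k += 1
            if j == 1 and i == 0:
                state = _M
            else:
                v = Y[i, j]
                if abs(M[i, j - 1] + gap_open - v) < eps:
                    state = _M
                elif abs(Y[i, j - 1] + gap_ext - v) < eps:
                    state = _Y
                else:
                    state = _X
            j -= 1
    return score, moves[:k][::-1].copy()


def _score_matrix(a: str, b: str, params: AlignParams) -> np.ndarray:
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    eq = aa[:, None] == bb[None, :]
    # 'N' (and 'X' for proteins) never count as a match
    amb = (aa[:, None] == ord("N")) | (bb[None, :] == ord("N"))
    eq = eq & ~amb
    return np.where(eq, params.match, params.mismatch).astype(np.float64)


def global_align(
    a: NucleotideSeq | ProteinSeq,
    b: NucleotideSeq | ProteinSeq,
    params: AlignParams = DEFAULT_NT_PARAMS,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences (affine gaps, deterministic)."""
    if not a.seq or not b.seq:
        raise GliaError("cannot align empty sequences")
    C = _score_matrix(a.seq, b.seq, params)
    score, moves = _affine_nw_moves(C, params.gap_open, params.gap_extend)
    ra, rb = [], []
    i = j = 0
    for mv in moves:
        if mv == 0:
            ra.append(a.seq[i])
            rb.append(b.seq[j])
            i += 1
            j += 1
        elif mv == 1:
            ra.append(a.seq[i])
            rb.append("-")
            i += 1
        else:
            ra.append("-")
            rb.append(b.seq[j])
            j += 1
    sa, sb = "".join(ra), "".join(rb)
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return PairwiseAlignment(sa, sb, float(score), matches / len(sa))


# ---------------------------------------------------------------------------
# Distances


def p_distance(alignment: PairwiseAlignment) -> float:
    """Mismatch proportion over columns without gaps (pairwise deletion)."""
    compared = mismatches = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise GliaError("no comparable (gap-free) columns in alignment")
    return mismatches / compared


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor corrected distance; diverges as p -> 3/4."""
    if p >= 0.75:
        raise GliaError(f"p-distance {p} out of Jukes-Cantor domain")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.any(np.isnan(self.d)) or np.any(self.d < 0):
            raise GliaError("distance matrix contains NaN or negative entries")
        if not np.allclose(self.d, self.d.T):
            raise GliaError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise GliaError("distance matrix diagonal is not zero")


def distance_matrix(
    seqs: list[NucleotideSeq],
    params: AlignParams = DEFAULT_NT_PARAMS,
    correction: str = "p",
) -> DistanceMatrix:
    """All-pairs distances (substitutions/site) from pairwise global alignments."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(global_align(seqs[i], seqs[j], params))
            d[i, j] = d[j, i] = jukes_cantor(p) if correction == "jc" else p
    return DistanceMatrix([s.id for s in seqs], d)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    name: str | None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _min_leaf(self) -> str:
        return min(l.name for l in self.leaves())

    def newick(self, parent_height: float | None = None) -> str:
        if self.is_leaf:
            core = self.name
        else:
            kids = sorted(self.children, key=lambda c: c._min_leaf())
            core = "(" + ",".join(c.newick(self.height) for c in kids) + ")"
        if parent_height is None:
            return core
        return f"{core}:{parent_height - self.height:g}"


@dataclass
class PhyloTree:
    """Rooted ultrametric tree with heights in substitutions/site."""

    root: TreeNode

    def newick(self) -> str:
        return self.root.newick() + ";"

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                depths.append(depth)
            for c in node.children:
                walk(c, depth + node.height - c.height)

        walk(self.root, 0.0)
        return max(depths) - min(depths) <= tol


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration; ties broken by the lexicographically
    smallest (min-leaf-label) pair, producing a deterministic tree."""
    if len(dm.labels) < 2:
        raise GliaError("UPGMA requires at least two taxa")
    nodes = [TreeNode(name=l, height=0.0) for l in dm.labels]
    sizes = [1] * len(nodes)
    keys = [n.name for n in nodes]
    d = dm.d.astype(float).copy()
    active = list(range(len(nodes)))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (d[i, j], pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, _, i, j = best
        parent = TreeNode(name=None, height=dij / 2.0, children=[nodes[i], nodes[j]])
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
        nodes[i] = parent
        sizes[i] = ni + nj
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    return PhyloTree(root=nodes[active[0]])


def extract_clades(tree: PhyloTree, genome_labels: dict[str, str]) -> dict:
    """Maximal single-genome (pure) clades plus the mixed junction clades.

    ``genome_labels`` maps leaf label -> genome tag; every leaf must be
    labeled.  A pure clade is a maximal node whose leaves all share one
    genome; mixed clades are the minimal nodes joining more than one genome.
    """
    for name in tree.leaf_names():
        if name not in genome_labels:
            raise GliaError(f"unlabeled leaf: {name}")
    pure: list[dict] = []
    mixed: list[dict] = []

    def genomes_of(node: TreeNode) -> set[str]:
        return {genome_labels[l.name] for l in node.leaves()}

    def walk(node: TreeNode) -> None:
        gs = genomes_of(node)
        if len(gs) == 1:
            pure.append(
                {"genome": next(iter(gs)), "leaves": sorted(l.name for l in node.leaves())}
            )
            return
        if all(len(genomes_of(c)) == 1 for c in node.children):
            mixed.append(
                {"genomes": sorted(gs), "leaves": sorted(l.name for l in node.leaves())}
            )
        for c in node.children:
            walk(c)

    walk(tree.root)
    return {"pure": pure, "mixed": mixed}


# ---------------------------------------------------------------------------
# Progressive MSA (guide tree from p-distances, profile-profile NW merges)

_GAP = "-"


def _profile_freqs(rows: list[str], alphabet: str) -> np.ndarray:
    idx = {c: k for k, c in enumerate(alphabet)}
    F = np.zeros((len(rows[0]), len(alphabet)))
    for row in rows:
        for pos, ch in enumerate(row):
            F[pos, idx.get(ch, idx[_GAP])] += 1
    return F / len(rows)


def _merge_profiles(
    rows_a: dict[str, str], rows_b: dict[str, str], alphabet: str, params: AlignParams
) -> dict[str, str]:
    S = len(alphabet)
    smat = np.full((S, S), params.mismatch)
    np.fill_diagonal(smat, params.match)
    gap_i = alphabet.index(_GAP)
    smat[gap_i, :] = params.mismatch
    smat[:, gap_i] = params.mismatch
    smat[gap_i, gap_i] = 0.0
    Fa = _profile_freqs(list(rows_a.values()), alphabet)
    Fb = _profile_freqs(list(rows_b.values()), alphabet)
    C = Fa @ smat @ Fb.T
    _, moves = _affine_nw_moves(C, params.gap_open, params.gap_extend)
    out: dict[str, str] = {}
    for src, consume in ((rows_a, {0, 1}), (rows_b, {0, 2})):
        take = 1 if src is rows_a else 2
        for rid, row in src.items():
            pieces = []
            p = 0
            for mv in moves:
                if mv == 0 or mv == take:
                    pieces.append(row[p])
                    p += 1
                else:
                    pieces.append(_GAP)
            out[rid] = "".join(pieces)
    return out


def progressive_msa(
    seqs: list[NucleotideSeq | ProteinSeq],
    params: AlignParams = DEFAULT_NT_PARAMS,
) -> dict[str, str]:
    """Multiple alignment: UPGMA guide tree over pairwise p-distances, then
    profile–profile merges in guide-tree order.  Returns id -> gapped row."""
    if len(seqs) < 2:
        raise GliaError("MSA requires at least two sequences")
    if len(seqs) == 2:
        aln = global_align(seqs[0], seqs[1], params)
        return {seqs[0].id: aln.aligned_a, seqs[1].id: aln.aligned_b}
    letters = sorted(set("".join(s.seq for s in seqs)))
    alphabet = "".join(letters) + _GAP
    dm = distance_matrix(seqs, params)
    guide = upgma(dm)
    by_id = {s.id: s for s in seqs}

    def build(node: TreeNode) -> dict[str, str]:
        if node.is_leaf:
            return {node.name: by_id[node.name].seq}
        kids = sorted(node.children, key=lambda c: c._min_leaf())
        acc = build(kids[0])
        for c in kids[1:]:
            acc = _merge_profiles(acc, build(c), alphabet, params)
        return acc

    msa = build(guide.root)
    return {s.id: msa[s.id] for s in seqs}


# ---------------------------------------------------------------------------
# Indels and the 33-mer origin analysis


@dataclass
class IndelEvent:
    position: int  # alignment column of the first gap in the run
    length: int
    in_frame: bool
    inserted_in: str  # which sequence carries the extra residues: 'a' or 'b'

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.in_frame != (self.length % 3 == 0):
            raise ValueError("in_frame inconsistent with length")


def indel_report(alignment: PairwiseAlignment, frame_offset: int = 0) -> list[IndelEvent]:
    """Maximal gap runs of a pairwise alignment as polarity-tagged events."""
    events: list[IndelEvent] = []
    col = 0
    n = len(alignment.aligned_a)
    while col < n:
        xa, xb = alignment.aligned_a[col], alignment.aligned_b[col]
        if xa == "-" or xb == "-":
            which = "b" if xa == "-" else "a"
            gapped = alignment.aligned_a if xa == "-" else alignment.aligned_b
            start = col
            while col < n and gapped[col] == "-":
                col += 1
            length = col - start
            events.append(
                IndelEvent(
                    position=start - frame_offset,
                    length=length,
                    in_frame=(length % 3 == 0),
                    inserted_in=which,
                )
            )
        else:
            col += 1
    return events


def epitope_gain_loss(cds_a: NucleotideSeq, cds_b: NucleotideSeq, catalog=None) -> dict:
    """Align two homologous CDSs, translate, and attribute epitope-content
    changes to the overlapping indel events (the 33-mer-origin analysis)."""
    from .epitopes import DEFAULT_CATALOG, scan_epitopes

    catalog = catalog or DEFAULT_CATALOG
    aln = global_align(cds_a, cds_b)
    indels = indel_report(aln)
    try:
        prot_a = translate(cds_a, truncate_at_stop=True)
        prot_b = translate(cds_b, truncate_at_stop=True)
    except GliaError as exc:
        raise GliaError(f"untranslatable CDS in epitope_gain_loss: {exc}") from exc
    prof_a = scan_epitopes(prot_a, catalog)
    prof_b = scan_epitopes(prot_b, catalog)
    diff = {
        name: prof_b.counts[name] - prof_a.counts[name]
        for name in catalog.entries
        if prof_b.counts[name] != prof_a.counts[name]
    }
    changes = {
        "epitope_diff": diff,
        "gained_33mer": prof_b.has_33mer and not prof_a.has_33mer,
        "lost_33mer": prof_a.has_33mer and not prof_b.has_33mer,
        "indels": indels,
        "associated_indels": [],
    }
    if diff or changes["gained_33mer"] or changes["lost_33mer"]:
        # an epitope change is associated with an indel when the indel falls
        # inside the translated span of the sequence that gained material
        for ev in indels:
            carrier_len = len(cds_b) if ev.inserted_in == "b" else len(cds_a)
            if ev.position < carrier_len:
                changes["associated_indels"].append(ev)
    return changes
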