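"""Distance phylogenetics for DQB locus assignment.

DQB primers are not fully locus-specific, so the locus of origin of an
amplified allele is not always known.  Alleles of the three DQB loci
(DQB1, DQB2, DQB2-like) form three distinct sequence clusters, and an
unplaced allele is assigned to the locus whose reference clade contains it
on a bootstrap-replicated neighbour-joining tree of K80 (Kimura
two-parameter) distances.

K80 distinguishes transition and transversion rates; for transition and
transversion proportions P and Q over pairwise-complete sites,

    d = 1/2 ln(1 / (1 - 2P - Q)) + 1/4 ln(1 / (1 - 2Q)).

Gap and N positions are excluded pairwise (pairwise deletion), so
exon-2-only fragments remain comparable with full-length alleles; such
queries lack the 3' UTR where the locus signal is strongest and are
flagged low-confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

_DNA = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distances undefined: substitution proportions exceed the K80 domain."""


# base coding chosen so that purines (A, G) share the high bit with each
# other and pyrimidines (C, T) likewise: a transition preserves code >> 1
_CHARMAP = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CHARMAP[ord(_b)] = _i
    _CHARMAP[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CHARMAP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    diff = valid & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def k80_distance(seq1: str, seq2: str) -> tuple[float, float, float]:
    """K80 distance and the (P, Q) transition/transversion proportions.

    Positions where either sequence has a gap, N or other non-ACGT symbol
    are excluded pairwise.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    n, ts, tv = _pair_counts(_encode(seq1), _encode(seq2))
    if n == 0:
        raise ValueError("no pairwise-complete sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair (P={P:.3f}, Q={Q:.3f}): K80 distance undefined"
        )
    d = 0.5 * math.log(1.0 / w1) + 0.25 * math.log(1.0 / w2)
    return d, P, Q


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.abs(np.diag(m)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        if (m < -1e-12).any() or not np.isfinite(m).all():
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    @classmethod
    def from_alignment(cls, alignment: Mapping[str, str]) -> "DistanceMatrix":
        labels = sorted(alignment)
        n = len(labels)
        enc = [_encode(alignment[lab]) for lab in labels]
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                cnt, ts, tv = _pair_counts(enc[i], enc[j])
                if cnt == 0:
                    raise ValueError(
                        f"{labels[i]} vs {labels[j]}: no pairwise-complete sites"
                    )
                P, Q = ts / cnt, tv / cnt
                w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if w1 <= 0 or w2 <= 0:
                    raise SaturationError(
                        f"{labels[i]} vs {labels[j]}: saturated pair "
                        f"(P={P:.3f}, Q={Q:.3f})"
                    )
                m[i, j] = m[j, i] = (
                    0.5 * math.log(1.0 / w1) + 0.25 * math.log(1.0 / w2)
                )
        return cls(labels, m)

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.matrix[i])
            lines.append(f"{lab}  {row}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Neighbour joining (Saitou-Nei Q-criterion agglomeration)
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbour joining.

    Negative intermediate branch lengths are clamped to zero with the
    deficit moved to the sister edge, preserving the path length between
    the joined pair.  Ties in the Q criterion resolve to the
    lexicographically first index pair, so the result is deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 labels")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    d = dm.matrix.copy()
    active = list(range(n))

    def clamp(v1: float, v2: float) -> tuple[float, float]:
        if v1 < 0:
            v2 += v1
            v1 = 0.0
        if v2 < 0:
            v1 += v2
            v2 = 0.0
        return max(v1, 0.0), max(v2, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = clamp(vi, vj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        # new distances to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = dendropy.Node()
    for idx, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Edge]:
    """Non-trivial bipartitions as frozensets of leaf labels (one side).

    Each split is normalised to the side *not* containing the
    alphabetically first taxon, so splits compare across trees.
    """
    labels = sorted(t.label for t in tree.taxon_namespace)
    anchor = labels[0]
    all_labels = frozenset(labels)
    splits: dict[frozenset[str], dendropy.Edge] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            splits[side] = node.edge
    return splits


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _resample_columns(
    alignment: Mapping[str, str], rng: np.random.Generator
) -> dict[str, str]:
    labels = sorted(alignment)
    ncol = len(alignment[labels[0]])
    idx = rng.integers(ncol, size=ncol)
    return {lab: "".join(alignment[lab][i] for i in idx) for lab in labels}


def bootstrap_support(
    alignment: Mapping[str, str], B: int, seed: int
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree from the full alignment with bootstrap split supports.

    Column-resampled replicates are rebuilt by NJ and their bipartitions
    counted; support fractions are mapped onto the full-data tree (internal
    node labels carry the support).  Replicates whose distance matrix
    saturates are skipped and still count in the denominator.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ncols = len(next(iter(alignment.values())))
    if ncols < 2:
        raise ValueError("alignment must have at least 2 columns")
    full = nj_tree(DistanceMatrix.from_alignment(alignment))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        rep = _resample_columns(alignment, rng)
        try:
            tree = nj_tree(DistanceMatrix.from_alignment(rep))
        except SaturationError:
            continue
        for split in tree_splits(tree):
            counts[split] = counts.get(split, 0) + 1
    supports = {s: c / B for s, c in counts.items()}
    for split, edge in tree_splits(full).items():
        edge.head_node.label = f"{supports.get(split, 0.0):.3f}"
    return full, supports


# ---------------------------------------------------------------------------
# Locus assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterAssignment:
    query: str
    locus: str  # target locus or "unassigned"
    support: float
    low_confidence: bool = False
    method: str = "bootstrap_clade"  # or "nearest_distance"
    notes: str = ""


def _minimal_containing_side(
    splits: Sequence[frozenset[str]],
    all_labels: frozenset[str],
    members: frozenset[str],
) -> frozenset[str]:
    """Smallest split side (either orientation) containing all members."""
    best = all_labels
    for side in splits:
        for s in (side, all_labels - side):
            if members <= s and len(s) < len(best):
                best = s
    return best


def _vote(
    tree: dendropy.Tree,
    query: str,
    references: Mapping[str, Sequence[str]],
) -> Optional[str]:
    """One replicate's vote: the locus whose references the query clusters with.

    The smallest clade containing the query together with all of a locus's
    references must contain no other locus's references (a query branching
    immediately outside a two-member reference cherry still clusters with
    it); among admissible loci the tightest such clade wins.
    """
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    splits = list(tree_splits(tree))
    candidates = []
    for locus, refs in references.items():
        side = _minimal_containing_side(
            splits, all_labels, frozenset(refs) | {query}
        )
        others = {
            r for loc, rr in references.items() if loc != locus for r in rr
        }
        if not side & others:
            candidates.append((len(side), locus))
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][1]


def reference_clusters_monophyletic(
    tree: dendropy.Tree, references: Mapping[str, Sequence[str]], query: str
) -> bool:
    """Each locus's minimal clade (query aside) excludes other loci's refs."""
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    splits = list(tree_splits(tree))
    for locus, refs in references.items():
        side = _minimal_containing_side(splits, all_labels, frozenset(refs))
        others = {
            r for loc, rr in references.items() if loc != locus for r in rr
        }
        if (side - {query}) & others:
            return False
    return True


def assign_locus(
    query: str,
    references: Mapping[str, Sequence[str]],
    alignment: Mapping[str, str],
    B: int = 200,
    seed: int = 0,
) -> ClusterAssignment:
    """Assign a query allele to the locus whose reference clade contains it.

    Majority vote across ``B`` bootstrap replicates; support below 0.5
    leaves the query unassigned.  Queries with substantial missing data
    (exon-2-only fragments lacking the 3' UTR) are flagged low-confidence.
    If the reference clusters are not monophyletic on the full-data tree,
    assignment falls back to nearest mean K80 distance, flagged.
    """
    for locus, refs in references.items():
        if len(refs) < 2:
            raise ValueError(f"locus {locus!r} needs >= 2 reference alleles")
    qseq = alignment[query]
    gap_frac = sum(c not in _DNA for c in qseq.upper()) / len(qseq)
    low_confidence = gap_frac > 0.05

    full = nj_tree(DistanceMatrix.from_alignment(alignment))
    if not reference_clusters_monophyletic(full, references, query):
        means = {}
        for locus, refs in references.items():
            ds = [k80_distance(qseq, alignment[r])[0] for r in refs]
            means[locus] = float(np.mean(ds))
        locus = min(sorted(means), key=means.get)
        return ClusterAssignment(
            query, locus, support=0.0, low_confidence=True,
            method="nearest_distance",
            notes="reference clusters not monophyletic on full-data tree",
        )

    rng = np.random.default_rng(seed)
    votes: dict[str, int] = {}
    for _ in range(B):
        rep = _resample_columns(alignment, rng)
        try:
            tree = nj_tree(DistanceMatrix.from_alignment(rep))
        except SaturationError:
            continue
        v = _vote(tree, query, references)
        if v is not None:
            votes[v] = votes.get(v, 0) + 1
    if not votes:
        return ClusterAssignment(query, "unassigned", 0.0, low_confidence)
    locus = max(sorted(votes), key=votes.get)
    support = votes[locus] / B
    if support < 0.5:
        return ClusterAssignment(query, "unassigned", support, low_confidence)
    return ClusterAssignment(query, locus, support, low_confidence)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
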