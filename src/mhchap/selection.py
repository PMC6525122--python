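"""Positive-selection analysis on codon alignments.

Selection acting over the evolutionary history of MHC alleles is detected
from the ratio omega = dN/dS of nonsynonymous to synonymous substitution
rates.  Two routes are provided:

* **Counting** (Nei-Gojobori 1986): per-codon synonymous/nonsynonymous
  site and difference counts with Jukes-Cantor correction, for pairwise
  dN/dS.
* **Likelihood** (GY94-style codon model): site-class mixture models
  M1a (nearly neutral: omega0 < 1, omega1 = 1), M2a (adds a positive
  class omega2 > 1), M7 (beta-distributed omega on (0,1)) and M8 (beta
  plus a positive class), compared by likelihood-ratio tests with 2
  degrees of freedom, with F3x4 codon frequencies throughout.  Per-site
  classification uses naive empirical Bayes (NEB) posteriors under M2a,
  and a FEL-style fixed-effects scan fits per-site synonymous (alpha) and
  nonsynonymous (beta) rates with a one-sided df=1 LRT of beta = alpha.

The rate matrix is GY94: single-nucleotide codon changes only, with
rate(i -> j) proportional to pi_j, times kappa for transitions and omega
for nonsynonymous changes, scaled so the class-weighted expected number of
substitutions per codon per unit branch length is one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import optimize, special, stats

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO = {c: _TABLE.forward_table[c] for c in CODONS}

_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


# single-nucleotide-step structure of the codon graph
_N = len(CODONS)
_ONESTEP = np.zeros((_N, _N), dtype=bool)
_TS = np.zeros((_N, _N), dtype=bool)
_SYN = np.zeros((_N, _N), dtype=bool)
for _i, _ci in enumerate(CODONS):
    for _j, _cj in enumerate(CODONS):
        diffs = [k for k in range(3) if _ci[k] != _cj[k]]
        if len(diffs) != 1:
            continue
        _ONESTEP[_i, _j] = True
        k = diffs[0]
        _TS[_i, _j] = _is_transition(_ci[k], _cj[k])
        _SYN[_i, _j] = AMINO[_ci] == AMINO[_cj]


class SaturationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences.

    Codons containing a gap or ambiguity are treated as missing data
    (excluded pairwise in counting methods; partial likelihood one in the
    pruning algorithm).  Internal stop codons are rejected.
    """

    names: list[str]
    sequences: dict[str, str]
    codes: np.ndarray = field(repr=False, default=None)  # (N, L), -1 = missing

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned to equal length")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")
        L = length // 3
        codes = np.full((len(self.names), L), -1, dtype=int)
        for r, name in enumerate(self.names):
            seq = self.sequences[name].upper()
            for s in range(L):
                codon = seq[3 * s : 3 * s + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"internal stop codon {codon} in {name!r} at codon {s + 1}"
                    )
                codes[r, s] = CODON_INDEX.get(codon, -1)
        self.codes = codes

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "CodonAlignment":
        return cls(names=sorted(sequences), sequences=dict(sequences))

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1]


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies over the 61 sense codons.

    Position-specific nucleotide frequencies (codon positions 1-3) are
    multiplied per codon, stop codons zeroed and the vector renormalised.
    """
    counts = np.zeros((3, 4))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for seq in aln.sequences.values():
        s = seq.upper()
        for pos, base in enumerate(s):
            if base in base_index:
                counts[pos % 3, base_index[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("empty alignment: no bases at some codon position")
    freqs = counts / totals
    pi = np.array(
        [
            freqs[0, base_index[c[0]]]
            * freqs[1, base_index[c[1]]]
            * freqs[2, base_index[c[2]]]
            for c in CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("all F3x4 codon frequencies are zero")
    return pi / total


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Potential synonymous / nonsynonymous sites of one codon.

    Substitutions creating stop codons count as nonsynonymous.
    """
    syn = 0.0
    for k in range(3):
        for b in "ACGT":
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1 :]
            if alt not in STOP_CODONS and AMINO[alt] == AMINO[codon]:
                syn += 1.0
    return syn / 3.0, 3.0 - syn / 3.0


def _path_differences(c1: str, c2: str) -> Optional[tuple[float, float]]:
    """Mean (synonymous, nonsynonymous) differences over minimal paths.

    All orderings of the differing positions are averaged with equal
    weight; paths passing through a stop codon are excluded.  Returns
    ``None`` if every path is blocked.
    """
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diffs):
        cur = c1
        syn = non = 0
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AMINO[cur] == AMINO[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            totals.append((syn, non))
    if not totals:
        return None
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n


def _jc_correct(p: float) -> float:
    if p == 0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(
            f"proportion {p:.4f} beyond the Jukes-Cantor domain (4p/3 >= 1)"
        )
    return -0.75 * math.log(arg)


@dataclass(frozen=True)
class DnDsResult:
    dN: float
    dS: float
    ratio: Optional[float]  # None when dS == 0 (undefined)
    n_codons_used: int


def ng86_dnds(seq1: str, seq2: str) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

    Codons with gaps or ambiguity in either sequence are excluded
    pairwise.  The ratio is reported as undefined (``None``) when dS = 0.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be of equal length")
    if len(seq1) % 3:
        raise ValueError("sequences must be in frame (length divisible by 3)")
    S = N = Sd = Nd = 0.0
    used = 0
    for s in range(len(seq1) // 3):
        c1 = seq1[3 * s : 3 * s + 3].upper()
        c2 = seq2[3 * s : 3 * s + 3].upper()
        if c1 not in CODON_INDEX or c2 not in CODON_INDEX:
            continue
        path = _path_differences(c1, c2)
        if path is None:
            continue
        used += 1
        s1s, s1n = _codon_site_counts(c1)
        s2s, s2n = _codon_site_counts(c2)
        S += (s1s + s2s) / 2.0
        N += (s1n + s2n) / 2.0
        Sd += path[0]
        Nd += path[1]
    if used == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    return DnDsResult(dN=dN, dS=dS, ratio=(dN / dS if dS > 0 else None),
                      n_codons_used=used)


# ---------------------------------------------------------------------------
# GY94 machinery
# ---------------------------------------------------------------------------

def _unscaled_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    Q = np.zeros((_N, _N))
    factor = np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    Q[_ONESTEP] = (factor * pi[np.newaxis, :])[_ONESTEP]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class _ClassMatrices:
    """Per-class transition-probability calculators for a site mixture.

    The common scale makes the class-weighted expected substitution rate
    one per codon per unit branch length.  Reversibility of GY94 permits a
    symmetric eigendecomposition (restricted to the support of pi).
    """

    def __init__(self, kappa: float, classes: Sequence[tuple[float, float]],
                 pi: np.ndarray) -> None:
        self.classes = list(classes)
        self.pi = pi
        support = pi > 0
        self.support = support
        qs = [_unscaled_rate_matrix(kappa, w, pi) for _, w in classes]
        rates = [-(pi * np.diag(q)).sum() for q in qs]
        scale = sum(w * r for (w, _), r in zip(classes, rates))
        if scale <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        self._eigs = []
        sq = np.sqrt(pi[support])
        for q in qs:
            qs_sub = q[np.ix_(support, support)] / scale
            sym = sq[:, None] * qs_sub / sq[None, :]
            lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
            self._eigs.append((lam, u, sq))

    def transition(self, class_idx: int, t: float) -> np.ndarray:
        """P(t) on the full 61-state space (zero rows/cols off support)."""
        lam, u, sq = self._eigs[class_idx]
        inner = (u * np.exp(lam * t)) @ u.T
        p_sub = (inner / sq[:, None]) * sq[None, :]
        np.clip(p_sub, 0.0, None, out=p_sub)
        p_sub /= p_sub.sum(axis=1, keepdims=True)
        P = np.zeros((_N, _N))
        P[np.ix_(self.support, self.support)] = p_sub
        return P


@dataclass
class TreeIndex:
    """Array-form rooted traversal of a (possibly unrooted) tree."""

    n_nodes: int
    postorder: list[int]                 # internal node visit order
    children: dict[int, list[tuple[int, float]]]
    leaf_of: dict[int, str]              # node id -> taxon label

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeIndex":
        ids: dict[int, int] = {}
        children: dict[int, list[tuple[int, float]]] = {}
        leaf_of: dict[int, str] = {}
        order: list[int] = []
        for node in tree.postorder_node_iter():
            nid = ids.setdefault(id(node), len(ids))
            if node.is_leaf():
                leaf_of[nid] = node.taxon.label
            else:
                kids = []
                for child in node.child_nodes():
                    length = child.edge.length
                    kids.append((ids[id(child)], float(length or 0.0)))
                children[nid] = kids
                order.append(nid)
        return cls(n_nodes=len(ids), postorder=order, children=children,
                   leaf_of=leaf_of)

    @classmethod
    def from_newick(cls, newick: str) -> "TreeIndex":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def scaled(self, factor: float) -> "TreeIndex":
        children = {
            nid: [(c, t * factor) for c, t in kids]
            for nid, kids in self.children.items()
        }
        return TreeIndex(self.n_nodes, list(self.postorder), children,
                         dict(self.leaf_of))

    @property
    def labels(self) -> list[str]:
        return sorted(self.leaf_of.values())

    @property
    def total_length(self) -> float:
        return sum(t for kids in self.children.values() for _, t in kids)


def _as_tree_index(tree: Union[TreeIndex, dendropy.Tree, str]) -> TreeIndex:
    if isinstance(tree, TreeIndex):
        return tree
    if isinstance(tree, dendropy.Tree):
        return TreeIndex.from_dendropy(tree)
    return TreeIndex.from_newick(tree)


def _leaf_partials(aln: CodonAlignment) -> dict[str, np.ndarray]:
    partials = {}
    for r, name in enumerate(aln.names):
        part = np.zeros((aln.n_codons, _N))
        codes = aln.codes[r]
        missing = codes < 0
        part[np.arange(aln.n_codons)[~missing], codes[~missing]] = 1.0
        part[missing, :] = 1.0
        partials[name] = part
    return partials


def _class_site_likelihoods(
    aln: CodonAlignment,
    tree: TreeIndex,
    kappa: float,
    classes: Sequence[tuple[float, float]],
    pi: np.ndarray,
) -> np.ndarray:
    """Per-class, per-site likelihoods (C, L) by Felsenstein pruning."""
    leaf_parts = _leaf_partials(aln)
    if not tree.postorder:  # single-leaf tree
        (label,) = tree.leaf_of.values()
        site = leaf_parts[label] @ pi
        return np.tile(site, (len(classes), 1))
    mats = _ClassMatrices(kappa, classes, pi)
    out = np.zeros((len(classes), aln.n_codons))
    for c in range(len(classes)):
        node_part: dict[int, np.ndarray] = {}
        for nid, label in tree.leaf_of.items():
            node_part[nid] = leaf_parts[label]
        for nid in tree.postorder:
            part = None
            for child, t in tree.children[nid]:
                contrib = node_part[child] @ mats.transition(c, t).T
                part = contrib if part is None else part * contrib
                node_part.pop(child, None)
            node_part[nid] = part
        root = tree.postorder[-1]
        out[c] = node_part[root] @ pi
    return out


def codon_loglik(
    aln: CodonAlignment,
    tree: Union[TreeIndex, dendropy.Tree, str],
    kappa: float,
    classes: Sequence[tuple[float, float]],
    pi: np.ndarray,
) -> float:
    """Log-likelihood of the site-class mixture codon model.

    ``classes`` is a sequence of (weight, omega) pairs; weights must be
    non-negative and sum to one.
    """
    weights = np.array([w for w, _ in classes])
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("class weights must be non-negative and sum to 1")
    tree = _as_tree_index(tree)
    site_class = _class_site_likelihoods(aln, tree, kappa, classes, pi)
    site = weights @ site_class
    if (site <= 0).any():
        bad = int(np.argmin(site)) + 1
        raise ValueError(f"non-finite site likelihood at codon {bad}")
    return float(np.log(site).sum())


# ---------------------------------------------------------------------------
# Site models
# ---------------------------------------------------------------------------

N_BETA_CATEGORIES = 10


def beta_categories(p: float, q: float,
                    k: int = N_BETA_CATEGORIES) -> list[tuple[float, float]]:
    """Equal-probability discretisation of Beta(p, q) by category means."""
    edges = special.betaincinv(p, q, np.linspace(0.0, 1.0, k + 1))
    cum = special.betainc(p + 1.0, q, edges)
    mean = p / (p + q)
    means = (cum[1:] - cum[:-1]) * mean * k
    means = np.clip(means, 1e-8, 1.0 - 1e-8)
    return [(1.0 / k, float(m)) for m in means]


_BOUNDS = {
    "prop": (1e-6, 1.0 - 1e-6),
    "w0": (1e-4, 0.999),
    "w_pos": (1.000001, 50.0),
    "kappa": (0.1, 20.0),
    "beta_shape": (0.05, 99.0),
    "scale": (1e-3, 100.0),
}

_MODEL_SPECS = {
    # param names (excluding kappa/scale) and fixed multistart points
    "M0": {
        "params": [("omega", (1e-4, 50.0))],
        "starts": [[0.4, 2.0], [0.1, 1.0], [1.5, 4.0]],
    },
    "M1a": {
        "params": [("p0", _BOUNDS["prop"]), ("omega0", _BOUNDS["w0"])],
        "starts": [[0.7, 0.3, 2.0], [0.5, 0.1, 1.0], [0.9, 0.5, 4.0]],
    },
    "M2a": {
        "params": [("q0", _BOUNDS["prop"]), ("q1", _BOUNDS["prop"]),
                   ("omega0", _BOUNDS["w0"]), ("omega2", _BOUNDS["w_pos"])],
        "starts": [[0.6, 0.8, 0.3, 2.5, 2.0], [0.4, 0.5, 0.1, 1.5, 1.0],
                   [0.8, 0.9, 0.5, 5.0, 4.0]],
    },
    "M7": {
        "params": [("p", _BOUNDS["beta_shape"]), ("q", _BOUNDS["beta_shape"])],
        "starts": [[0.5, 1.5, 2.0], [1.0, 1.0, 1.0], [0.2, 2.0, 4.0]],
    },
    "M8": {
        "params": [("p", _BOUNDS["beta_shape"]), ("q", _BOUNDS["beta_shape"]),
                   ("p0", _BOUNDS["prop"]), ("omega_s", _BOUNDS["w_pos"])],
        "starts": [[0.5, 1.5, 0.9, 2.5, 2.0], [1.0, 1.0, 0.7, 1.5, 1.0],
                   [0.2, 2.0, 0.95, 5.0, 4.0]],
    },
}


def model_classes(model: str, params: Mapping[str, float]) -> list[tuple[float, float]]:
    """(weight, omega) site classes of a named model at given parameters."""
    if model == "M0":
        return [(1.0, params["omega"])]
    if model == "M1a":
        p0 = params["p0"]
        return [(p0, params["omega0"]), (1.0 - p0, 1.0)]
    if model == "M2a":
        p0 = params["q0"]
        p1 = (1.0 - p0) * params["q1"]
        p2 = 1.0 - p0 - p1
        return [(p0, params["omega0"]), (p1, 1.0), (p2, params["omega2"])]
    if model == "M7":
        return beta_categories(params["p"], params["q"])
    if model == "M8":
        p0 = params["p0"]
        cats = beta_categories(params["p"], params["q"])
        return [(p0 * w, m) for w, m in cats] + [(1.0 - p0, params["omega_s"])]
    raise ValueError(f"unknown model {model!r}")


@dataclass
class SiteModelFit:
    model: str
    params: dict[str, float]
    kappa: float
    scale: float
    log_likelihood: float
    pi: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    n_starts: int = 3

    @property
    def classes(self) -> list[tuple[float, float]]:
        return model_classes(self.model, self.params)


class NonConvergenceError(RuntimeError):
    def __init__(self, message: str, best: Optional[SiteModelFit]) -> None:
        super().__init__(message)
        self.best = best


def fit_site_model(
    aln: CodonAlignment,
    tree: Union[TreeIndex, dendropy.Tree, str],
    model: str,
    pi: Optional[np.ndarray] = None,
    optimize_scale: bool = False,
    n_starts: int = 3,
    extra_starts: Sequence[Sequence[float]] = (),
    tol: float = 1e-8,
) -> SiteModelFit:
    """Maximum-likelihood fit of a site-class model.

    Bounded quasi-Newton (L-BFGS-B) maximisation over the model's omega
    parameters, class weights and kappa, from ``n_starts`` fixed starting
    points (multistart mitigates local optima).  Branch lengths are taken
    from the tree as given; ``optimize_scale`` adds a global branch-length
    multiplier (used by the M0 pre-fit that calibrates a nucleotide-units
    guide tree into expected substitutions per codon).
    """
    if model not in _MODEL_SPECS:
        raise ValueError(f"unknown model {model!r}")
    tree = _as_tree_index(tree)
    if pi is None:
        pi = f3x4_frequencies(aln)
    spec = _MODEL_SPECS[model]
    names = [n for n, _ in spec["params"]] + ["kappa"]
    bounds = [b for _, b in spec["params"]] + [_BOUNDS["kappa"]]
    if optimize_scale:
        names.append("scale")
        bounds.append(_BOUNDS["scale"])

    def objective(x: np.ndarray) -> float:
        values = dict(zip(names, x))
        scale = values.pop("scale", 1.0)
        kappa = values.pop("kappa")
        classes = model_classes(model, values)
        try:
            ll = codon_loglik(aln, tree.scaled(scale), kappa, classes, pi)
        except (ValueError, FloatingPointError):
            return 1e10
        return -ll

    starts = [list(s) for s in spec["starts"][:n_starts]]
    if optimize_scale:
        starts = [s + [1.0] for s in starts]
    starts += [list(s) for s in extra_starts]

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective, np.asarray(x0, dtype=float), method="L-BFGS-B",
            bounds=bounds, options={"ftol": tol, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    values = dict(zip(names, best.x))
    fit = SiteModelFit(
        model=model,
        params={k: float(v) for k, v in values.items()
                if k not in ("kappa", "scale")},
        kappa=float(values["kappa"]),
        scale=float(values.get("scale", 1.0)),
        log_likelihood=-float(best.fun),
        pi=pi,
        converged=any_converged,
        n_starts=len(starts),
    )
    if not any_converged:
        raise NonConvergenceError(
            f"{model} fit failed to converge from {len(starts)} starts", fit
        )
    return fit


def m0_prefit(
    aln: CodonAlignment,
    tree: Union[TreeIndex, dendropy.Tree, str],
    pi: Optional[np.ndarray] = None,
    n_starts: int = 3,
) -> tuple[SiteModelFit, TreeIndex]:
    """Calibrate guide-tree branch lengths into substitutions/codon.

    Fits the single-omega M0 model with a free global branch-length
    multiplier and returns the fit plus the rescaled tree, on which the
    site models are subsequently fitted with branch lengths fixed.
    """
    tree = _as_tree_index(tree)
    fit = fit_site_model(aln, tree, "M0", pi=pi, optimize_scale=True,
                         n_starts=n_starts)
    return fit, tree.scaled(fit.scale)


def fit_model_pair(
    aln: CodonAlignment,
    tree: Union[TreeIndex, dendropy.Tree, str],
    pair: tuple[str, str] = ("M1a", "M2a"),
    pi: Optional[np.ndarray] = None,
    n_starts: int = 3,
) -> tuple[SiteModelFit, SiteModelFit]:
    """Fit a nested null/alternative pair, seeding the alternative from the
    null's optimum so the nesting inequality holds numerically."""
    null_name, alt_name = pair
    null = fit_site_model(aln, tree, null_name, pi=pi, n_starts=n_starts)
    if pair == ("M1a", "M2a"):
        seed = [null.params["p0"], 1.0 - 1e-6, null.params["omega0"],
                1.000001, null.kappa]
    elif pair == ("M7", "M8"):
        seed = [null.params["p"], null.params["q"], 1.0 - 1e-6, 1.000001,
                null.kappa]
    else:
        raise ValueError(f"unsupported nested pair {pair}")
    alt = fit_site_model(aln, tree, alt_name, pi=pi, n_starts=n_starts,
                         extra_starts=[seed])
    return null, alt


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

_NESTED_PAIRS = {("M1a", "M2a"), ("M7", "M8"), ("M0", "M2a")}


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    null_model: str
    alt_model: str


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit, df: int = 2) -> LRTResult:
    """Likelihood-ratio test of nested site models (chi-squared, df=2).

    The statistic 2(l_alt - l_null) is clamped at zero (boundary cases can
    make the difference marginally negative at optimizer tolerance).
    """
    if (null_fit.model, alt_fit.model) not in _NESTED_PAIRS:
        raise ValueError(
            f"{null_fit.model} is not nested in {alt_fit.model}"
        )
    statistic = max(0.0, 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic=statistic, df=df, p_value=p,
                     null_model=null_fit.model, alt_model=alt_fit.model)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Per-site scans
# ---------------------------------------------------------------------------

@dataclass
class SiteScanResult:
    method: str
    posteriors: Optional[np.ndarray] = None      # (L, C) NEB class posteriors
    positive_posterior: Optional[np.ndarray] = None  # (L,)
    p_values: Optional[np.ndarray] = None        # (L,) FEL
    alpha: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    flags: np.ndarray = None                     # (L,) bool
    excluded_sites: tuple[int, ...] = ()         # 1-based codon numbers


def neb_sites(
    fit: SiteModelFit,
    aln: CodonAlignment,
    tree: Union[TreeIndex, dendropy.Tree, str],
) -> SiteScanResult:
    """Naive empirical Bayes site classification under a fitted M2a.

    Posterior of class c at a site is proportional to the class weight
    times the site likelihood under omega_c.  Sites with posterior > 0.95
    in a positive-selection class (omega > 1) are flagged.  NEB plugs in
    the MLEs without integrating parameter uncertainty and can be
    anti-conservative when estimates are poor.
    """
    tree = _as_tree_index(tree).scaled(fit.scale)
    classes = fit.classes
    site_class = _class_site_likelihoods(aln, tree, fit.kappa, classes, fit.pi)
    weights = np.array([w for w, _ in classes])
    joint = weights[:, None] * site_class
    total = joint.sum(axis=0)
    posteriors = (joint / total).T  # (L, C)
    positive = np.array([w_omega > 1.0 for _, w_omega in classes])
    positive_post = posteriors[:, positive].sum(axis=1)
    return SiteScanResult(
        method="NEB",
        posteriors=posteriors,
        positive_posterior=positive_post,
        flags=positive_post > 0.95,
    )


def fel_scan(
    aln: CodonAlignment,
    tree: Union[TreeIndex, dendropy.Tree, str],
    m0: Optional[SiteModelFit] = None,
    alpha_level: float = 0.05,
) -> SiteScanResult:
    """Fixed-effects likelihood scan for per-site positive selection.

    Requires a global kappa and codon-unit branch lengths, obtained from
    an M0 pre-fit (run internally when not supplied).  Per site the
    likelihood is maximised over a synonymous rate alpha and a
    nonsynonymous rate beta (rate matrix alpha*R_syn + beta*R_nonsyn,
    normalised so alpha = beta = 1 recovers one expected substitution per
    codon); the null constrains beta = alpha (df=1).  The positive flag is
    one-sided: p below the level *and* beta-hat > alpha-hat.
    """
    tree = _as_tree_index(tree)
    if m0 is None:
        m0, tree = m0_prefit(aln, tree)
    else:
        tree = tree.scaled(m0.scale)
    pi = m0.pi
    kappa = m0.kappa
    leaf_parts = _leaf_partials(aln)
    support = pi > 0
    sq = np.sqrt(pi[support])

    factor_ts = np.where(_TS, kappa, 1.0)
    r_syn = np.where(_SYN & _ONESTEP, factor_ts * pi[None, :], 0.0)
    r_non = np.where(~_SYN & _ONESTEP, factor_ts * pi[None, :], 0.0)
    base = r_syn + r_non
    norm = (pi * base.sum(axis=1)).sum()  # rate at alpha = beta = 1

    def site_loglik(site: int, alpha: float, beta: float) -> float:
        q = (alpha * r_syn + beta * r_non) / norm
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        q_sub = q[np.ix_(support, support)]
        sym = sq[:, None] * q_sub / sq[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)

        def ptrans(t: float) -> np.ndarray:
            inner = (u * np.exp(lam * t)) @ u.T
            p_sub = (inner / sq[:, None]) * sq[None, :]
            np.clip(p_sub, 0.0, None, out=p_sub)
            P = np.zeros((_N, _N))
            P[np.ix_(support, support)] = p_sub
            return P

        node_part: dict[int, np.ndarray] = {
            nid: leaf_parts[label][site] for nid, label in tree.leaf_of.items()
        }
        for nid in tree.postorder:
            part = None
            for child, t in tree.children[nid]:
                contrib = ptrans(t) @ node_part[child]
                part = contrib if part is None else part * contrib
            node_part[nid] = part
        val = float(node_part[tree.postorder[-1]] @ pi)
        return math.log(val) if val > 0 else -1e10

    L = aln.n_codons
    p_values = np.ones(L)
    alphas = np.zeros(L)
    betas = np.zeros(L)
    flags = np.zeros(L, dtype=bool)
    excluded = []
    lo, hi = 1e-4, 50.0
    for s in range(L):
        if (aln.codes[:, s] < 0).all():
            excluded.append(s + 1)
            continue
        null = optimize.minimize_scalar(
            lambda a: -site_loglik(s, a, a), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5},
        )
        best = None
        for x0 in ([0.5, 0.5], [0.2, 2.0]):
            res = optimize.minimize(
                lambda x: -site_loglik(s, x[0], x[1]), x0, method="L-BFGS-B",
                bounds=[(lo, hi), (lo, hi)], options={"ftol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        stat = max(0.0, 2.0 * (null.fun - best.fun))
        if stat <= 1e-4:  # below optimizer resolution: identical fits
            stat = 0.0
        p = float(stats.chi2.sf(stat, 1))
        alphas[s], betas[s] = best.x
        p_values[s] = p
        flags[s] = (p < alpha_level) and (betas[s] > alphas[s])
    return SiteScanResult(
        method="FEL",
        p_values=p_values,
        alpha=alphas,
        beta=betas,
        flags=flags,
        excluded_sites=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Simulation under site models (for calibration and power studies)
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: Union[TreeIndex, dendropy.Tree, str],
    kappa: float,
    classes: Sequence[tuple[float, float]],
    pi: np.ndarray,
    n_codons: int,
    seed: int,
) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate codon sequences site-by-site under a class mixture.

    Each site draws a class with the class weights, a root codon from pi,
    and evolves along the tree with the class's transition matrices.
    Returns the alignment and the true class index per site.
    """
    tree = _as_tree_index(tree)
    rng = np.random.default_rng(seed)
    weights = np.array([w for w, _ in classes])
    site_class = rng.choice(len(classes), size=n_codons, p=weights / weights.sum())
    mats = _ClassMatrices(kappa, classes, pi)
    # edge list in preorder (parents before children)
    root = tree.postorder[-1] if tree.postorder else None
    states = np.zeros((tree.n_nodes, n_codons), dtype=int)
    support_idx = np.flatnonzero(pi > 0)
    pi_support = pi[support_idx] / pi[support_idx].sum()
    if root is None:
        (nid,) = tree.leaf_of
        states[nid] = support_idx[rng.choice(len(support_idx), size=n_codons,
                                             p=pi_support)]
    else:
        states[root] = support_idx[rng.choice(len(support_idx), size=n_codons,
                                              p=pi_support)]
        trans_cache: dict[tuple[int, float], np.ndarray] = {}
        stack = [root]
        order = []
        while stack:
            nid = stack.pop()
            order.append(nid)
            for child, _ in tree.children.get(nid, ()):
                stack.append(child)
        for nid in order:
            for child, t in tree.children.get(nid, ()):
                for c in set(site_class):
                    key = (c, t)
                    if key not in trans_cache:
                        trans_cache[key] = mats.transition(c, t)
                for s in range(n_codons):
                    P = trans_cache[(site_class[s], t)]
                    row = P[states[nid, s]]
                    states[child, s] = rng.choice(_N, p=row / row.sum())
    seqs = {
        label: "".join(CODONS[states[nid, s]] for s in range(n_codons))
        for nid, label in tree.leaf_of.items()
    }
    return CodonAlignment.from_sequences(seqs), site_class


def balanced_tree(n_leaves: int, branch_length: float) -> TreeIndex:
    """A balanced binary tree in newick form (simulation scaffolding)."""
    labels = [f"t{i + 1}" for i in range(n_leaves)]

    def build(items: list[str]) -> str:
        if len(items) == 1:
            return f"{items[0]}:{branch_length}"
        mid = len(items) // 2
        return (f"({build(items[:mid])},{build(items[mid:])})"
                f":{branch_length}")

    newick = f"({build(labels[: n_leaves // 2])},{build(labels[n_leaves // 2:])});"
    return TreeIndex.from_newick(newick)
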