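"""Codon-model selection analysis: MG94 likelihoods, branch and
branch-site tests, NG86 counting, and the selection-classification
decision tree.

Model family
------------
The substitution process is an MG94-style codon model: codons differing
at more than one nucleotide exchange at rate 0; single-nucleotide
changes i->j have rate

    q_ij = r(a,b) * pi_j * (omega if nonsynonymous else 1)

with r(a,b) the nucleotide exchangeability (HKY kappa or GTR), pi the
F3x4 codon frequencies, and omega = dN/dS.  Every rate matrix is
normalized to one expected substitution per codon per unit branch
length, so branch lengths are expected substitutions per codon under
that branch's own omega.

Branch models: M0 (one omega tree-wide), b_neut (foreground omega fixed
at 1, background free), b_free (foreground and background omegas free).
Branch-site models: bsA1 (null) vs bsA (foreground omega2 >= 1 free),
four site classes with shared proportions; positively selected sites
are identified by empirical Bayes at the MLEs (NEB) with posterior
>= 0.95.  All LRTs use 2*(l1 - l0) against chi-square with df equal to
the difference in free parameters.

Classification: a gene with a significant b_free vs M0 LRT (p < 0.05)
is "Relaxed" when the foreground omega exceeds the background omega and
"Strengthened" when it is lower; it is additionally under relaxed
selection when the foreground omega does not deviate significantly
from neutrality (b_free vs b_neut p >= 0.05).  Genes with extreme
omega estimates (>= 10 or <= 0.001 in any model) are excluded.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy import optimize, stats

from .codon import (
    AA_OF,
    CODONS,
    CODON_INDEX,
    N_CODONS,
    NEIGHBOR_FROM,
    NEIGHBOR_I,
    NEIGHBOR_J,
    NEIGHBOR_SYN,
    NEIGHBOR_TO,
    NEIGHBOR_TRANSITION,
    NUC_INDEX,
    STOP_CODONS,
    encode_codons,
    f3x4_frequencies,
)

OMEGA_BOUNDS = (1e-4, 20.0)
MULTISTART_OMEGAS = (0.1, 0.3, 0.5, 1.0, 2.0)


# ----------------------------------------------------------------------
# Trees


@dataclass
class TreeModel:
    """Phylogeny flattened for pruning: postorder arrays + branch labels.

    ``fg[v]`` marks the branch above node v as foreground.  Foreground
    is declared either with the ``#1`` suffix convention in the newick
    (leaf or internal labels) or with ``foreground_taxa``.
    """

    taxa: List[str]
    parent: np.ndarray  # parent index per node; -1 for root
    lengths: np.ndarray  # branch length above each node
    fg: np.ndarray  # bool per node
    postorder: List[int]  # children before parents; root last
    children: List[List[int]]
    leaf_index: Dict[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @classmethod
    def from_newick(
        cls, newick: str, foreground_taxa: Sequence[str] = ()
    ) -> "TreeModel":
        text = newick
        if "(" not in text:  # looks like a path
            with open(text) as fh:
                text = fh.read()
        # accept the tag before or after the branch length (t8#1:0.3 / t8:0.3#1)
        text = re.sub(r"(:[0-9.eE+\-]+)\s*#\s*1", r"__FG__\1", text)
        text = re.sub(r"\s*#\s*1", "__FG__", text)
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
        nodes = list(tree.postorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        fg = np.zeros(n, dtype=bool)
        children: List[List[int]] = [[] for _ in range(n)]
        taxa: List[str] = []
        leaf_index: Dict[str, int] = {}
        fset = set(foreground_taxa)
        for i, nd in enumerate(nodes):
            label = None
            if nd.taxon is not None:
                label = nd.taxon.label
            elif nd.label:
                label = nd.label
            is_fg = False
            if label and label.endswith("__FG__"):
                label = label[: -len("__FG__")].rstrip("_ ")
                is_fg = True
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                children[parent[i]].append(i)
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
                if lengths[i] < 0:
                    raise ValueError("negative branch length in tree")
            if nd.is_leaf():
                if label is None:
                    raise ValueError("unlabeled leaf in tree")
                taxa.append(label)
                leaf_index[label] = i
                if label in fset:
                    is_fg = True
            fg[i] = is_fg and nd.parent_node is not None
        tm = cls(taxa, parent, lengths, fg, list(range(n)), children, leaf_index)
        missing = fset - set(taxa)
        if missing:
            raise ValueError(f"foreground taxa not in tree: {sorted(missing)}")
        return tm

    def with_lengths(self, lengths: np.ndarray) -> "TreeModel":
        tm = TreeModel(
            self.taxa, self.parent, np.asarray(lengths, dtype=float), self.fg,
            self.postorder, self.children, self.leaf_index,
        )
        return tm

    def require_foreground(self):
        if not self.fg.any():
            raise ValueError("no foreground branch set on the tree")


# ----------------------------------------------------------------------
# Alignments


@dataclass
class CodonAlignment:
    """Gap-free codon alignment over the 61 sense codons."""

    taxa: List[str]
    codons: np.ndarray  # (ntaxa, ncodons) codon indices

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa")

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "CodonAlignment":
        taxa = list(seqs)
        arrays = [encode_codons(seqs[t]) for t in taxa]
        lens = {len(a) for a in arrays}
        if len(lens) != 1:
            raise ValueError(f"taxa differ in codon length: {sorted(lens)}")
        return cls(taxa, np.stack(arrays))

    @classmethod
    def from_fasta(cls, path: str) -> "CodonAlignment":
        from Bio import SeqIO

        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}
        if not seqs:
            raise ValueError(f"{path}: no sequences")
        return cls.from_sequences(seqs)

    def f3x4(self) -> np.ndarray:
        counts = np.zeros((3, 4))
        for row in self.codons:
            for ci in row:
                for p, ch in enumerate(CODONS[ci]):
                    counts[p, NUC_INDEX[ch]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                freqs[0, NUC_INDEX[c[0]]] * freqs[1, NUC_INDEX[c[1]]] * freqs[2, NUC_INDEX[c[2]]]
                for c in CODONS
            ]
        )
        return pi / pi.sum()


# ----------------------------------------------------------------------
# Rate matrices and transition probabilities


def codon_rate_matrix(
    pi: np.ndarray, omega: float, kappa: float = 2.0, gtr: Optional[np.ndarray] = None,
    normalize: bool = True,
) -> np.ndarray:
    """Normalized MG94 rate matrix for one omega class.

    ``gtr`` is an optional symmetric 4x4 exchangeability matrix (TCAG
    order); when absent HKY with transition/transversion ratio
    ``kappa`` is used.
    """
    pi = np.asarray(pi, dtype=float)
    Q = np.zeros((N_CODONS, N_CODONS))
    if gtr is not None:
        exch = np.asarray(gtr, dtype=float)[NEIGHBOR_FROM, NEIGHBOR_TO]
    else:
        exch = np.where(NEIGHBOR_TRANSITION, kappa, 1.0)
    rates = exch * pi[NEIGHBOR_J]
    rates = np.where(NEIGHBOR_SYN, rates, omega * rates)
    Q[NEIGHBOR_I, NEIGHBOR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        scale = -(pi * np.diag(Q)).sum()
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        Q = Q / scale
    return Q


class SpectralQ:
    """Eigendecomposition of a reversible Q for fast P(t) = exp(Qt).

    Uses the pi-symmetrized form D^1/2 Q D^-1/2 so that a symmetric
    eigensolver applies; detailed balance of MG94 guarantees symmetry.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(np.maximum(pi, 1e-300))
        S = (Q * d[:, None]) / d[None, :]
        S = (S + S.T) / 2.0
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.A = U / d[:, None]
        self.B = U.T * d[None, :]

    def P(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.lam * t)) @ self.B
        return np.maximum(P, 0.0)


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray) -> np.ndarray:
    return SpectralQ(Q, pi).P(t)


# ----------------------------------------------------------------------
# Pruning likelihood


def _patterns(aln: CodonAlignment, tree: TreeModel) -> Tuple[np.ndarray, np.ndarray]:
    order = []
    for t in tree.taxa:
        if t not in aln.taxa:
            raise ValueError(f"taxon {t!r} in tree but not in alignment")
        order.append(aln.taxa.index(t))
    mat = aln.codons[order]
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _site_loglik(
    tree: TreeModel,
    patterns: np.ndarray,
    P_per_node: Dict[int, np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """Per-pattern log-likelihood by Felsenstein pruning with scaling."""
    npat = patterns.shape[1]
    logscale = np.zeros(npat)
    messages: Dict[int, np.ndarray] = {}
    # pattern rows follow tree.taxa order
    taxon_row = {tree.leaf_index[t]: r for r, t in enumerate(tree.taxa)}
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:  # leaf
            s = patterns[taxon_row[v]]
            messages[v] = P_per_node[v][:, s].T
            continue
        L = messages[tree.children[v][0]].copy()
        for c in kids[1:]:
            L *= messages[c]
        m = L.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        L /= m[:, None]
        logscale += np.log(m)
        if tree.parent[v] >= 0:
            messages[v] = L @ P_per_node[v].T
        else:
            return np.log(np.maximum(L @ pi, 1e-300)) + logscale
    raise AssertionError("tree has no root")


def mg94_loglik(
    aln: CodonAlignment,
    tree: TreeModel,
    pi: np.ndarray,
    omega_fg: float,
    omega_bg: float,
    kappa: float = 2.0,
    gtr: Optional[np.ndarray] = None,
    method: str = "expm",
) -> float:
    """Log-likelihood of the alignment under a two-class branch MG94 model.

    Transition matrices come from scipy's Pade expm by default (full
    double precision); ``method="spectral"`` uses the eigendecomposition
    fast path employed inside the optimizers, which agrees to ~1e-6 on
    the log-likelihood.
    """
    from scipy.linalg import expm as _expm

    patterns, counts = _patterns(aln, tree)
    Q_bg = codon_rate_matrix(pi, omega_bg, kappa, gtr)
    Q_fg = Q_bg if omega_fg == omega_bg else codon_rate_matrix(pi, omega_fg, kappa, gtr)
    if method == "spectral":
        s_bg = SpectralQ(Q_bg, pi)
        s_fg = s_bg if Q_fg is Q_bg else SpectralQ(Q_fg, pi)
        make_P = lambda fg, t: (s_fg if fg else s_bg).P(t)
    else:
        cache: Dict[Tuple[bool, float], np.ndarray] = {}

        def make_P(fg, t):
            key = (fg and Q_fg is not Q_bg, t)
            if key not in cache:
                cache[key] = _expm((Q_fg if key[0] else Q_bg) * t)
            return cache[key]

    P = {}
    for v in tree.postorder:
        if tree.parent[v] >= 0:
            P[v] = make_P(bool(tree.fg[v]), float(tree.lengths[v]))
    site_ll = _site_loglik(tree, patterns, P, pi)
    return float((counts * site_ll).sum())


# ----------------------------------------------------------------------
# Model fitting


@dataclass
class ModelFit:
    model_id: str
    lnl: float
    params: Dict[str, float]
    converged: bool
    n_free_params: int


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def lrt(alt: ModelFit, null: ModelFit) -> LRTResult:
    stat = 2.0 * (alt.lnl - null.lnl)
    if stat < -1e-6:
        raise ValueError(
            f"alternative {alt.model_id} has lower likelihood than null {null.model_id}"
        )
    stat = max(stat, 0.0)
    df = alt.n_free_params - null.n_free_params
    if df <= 0:
        raise ValueError("alternative must have more free parameters than null")
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


def _maximize(fun, x0_list, bounds, n_local: int = 2) -> Tuple[np.ndarray, float, bool]:
    """Box-constrained maximization with multi-start.

    All start points are evaluated; a local L-BFGS-B search is launched
    from the ``n_local`` most promising, and the best point seen
    (including raw starts) is returned.
    """
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]
    scored = []
    for x0 in x0_list:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        scored.append((fun(x0), x0))
    scored.sort(key=lambda t: -t[0])
    best_f, best_x = scored[0]
    ok = False
    for f0, x0 in scored[: max(1, n_local)]:
        res = optimize.minimize(
            lambda x: -fun(x), x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if -res.fun > best_f:
            best_x, best_f = res.x, -res.fun
        ok = ok or res.success
    return best_x, best_f, ok


def fit_model(
    aln: CodonAlignment,
    tree: TreeModel,
    model_id: str,
    pi: Optional[np.ndarray] = None,
    kappa: Optional[float] = None,
    gtr: Optional[np.ndarray] = None,
    n_starts: int = 5,
) -> ModelFit:
    """Fit one of M0 / b_neut / b_free / bsA1 / bsA by constrained ML.

    F3x4 frequencies are taken from the alignment (never optimized);
    branch lengths come from the tree.  With ``kappa=None`` the HKY
    kappa is estimated jointly for M0 and must be supplied (typically
    from the M0 fit) for the other models.
    """
    if model_id in ("bsA", "bsA1"):
        return _fit_branch_site(aln, tree, model_id, pi=pi, kappa=kappa, gtr=gtr)
    if pi is None:
        pi = aln.f3x4()
    patterns, counts = _patterns(aln, tree)
    lo, hi = np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1])
    starts = list(MULTISTART_OMEGAS[: max(1, n_starts)])

    def lnl_two_class(w_fg, w_bg, kap):
        Qbg = SpectralQ(codon_rate_matrix(pi, w_bg, kap, gtr), pi)
        Qfg = Qbg if w_fg == w_bg else SpectralQ(codon_rate_matrix(pi, w_fg, kap, gtr), pi)
        P = {
            v: (Qfg if tree.fg[v] else Qbg).P(tree.lengths[v])
            for v in tree.postorder
            if tree.parent[v] >= 0
        }
        return float((counts * _site_loglik(tree, patterns, P, pi)).sum())

    # n_free_params counts omega parameters only: kappa is estimated a
    # single time under M0 and held fixed across the nested models, so
    # it cancels from every LRT (df = difference in omega parameters).
    if model_id == "M0":
        if kappa is None:
            fun = lambda x: lnl_two_class(math.exp(x[0]), math.exp(x[0]), math.exp(x[1]))
            x, f, ok = _maximize(
                fun, [[math.log(w), math.log(2.0)] for w in starts],
                [(lo, hi), (math.log(0.2), math.log(20.0))],
            )
            params = {"omega": math.exp(x[0]), "kappa": math.exp(x[1])}
        else:
            fun = lambda x: lnl_two_class(math.exp(x[0]), math.exp(x[0]), kappa)
            x, f, ok = _maximize(fun, [[math.log(w)] for w in starts], [(lo, hi)])
            params = {"omega": math.exp(x[0]), "kappa": kappa}
        return ModelFit("M0", f, params, ok, 1)

    tree.require_foreground()
    if kappa is None:
        raise ValueError(f"{model_id}: pass kappa (typically the M0 estimate)")

    if model_id == "b_neut":
        fun = lambda x: lnl_two_class(1.0, math.exp(x[0]), kappa)
        x, f, ok = _maximize(fun, [[math.log(w)] for w in starts], [(lo, hi)])
        return ModelFit(
            "b_neut", f, {"omega_fg": 1.0, "omega_bg": math.exp(x[0]), "kappa": kappa}, ok, 1
        )
    if model_id == "b_free":
        fun = lambda x: lnl_two_class(math.exp(x[0]), math.exp(x[1]), kappa)
        b_starts = [[math.log(w), math.log(w)] for w in starts]
        b_starts += [[0.0, math.log(w)] for w in (0.2, 0.5)]  # fg at neutrality
        x, f, ok = _maximize(fun, b_starts, [(lo, hi), (lo, hi)])
        return ModelFit(
            "b_free",
            f,
            {"omega_fg": math.exp(x[0]), "omega_bg": math.exp(x[1]), "kappa": kappa},
            ok,
            2,
        )
    raise ValueError(f"unknown model {model_id!r}")


def fit_branch_models(
    aln: CodonAlignment, tree: TreeModel, pi: Optional[np.ndarray] = None,
    kappa: Optional[float] = None, n_starts: int = 5,
) -> Dict[str, ModelFit]:
    """M0, b_neut and b_free on one gene; kappa estimated under M0 and reused."""
    if pi is None:
        pi = aln.f3x4()
    m0 = fit_model(aln, tree, "M0", pi=pi, kappa=kappa, n_starts=n_starts)
    kap = m0.params["kappa"]
    out = {"M0": m0}
    out["b_neut"] = fit_model(aln, tree, "b_neut", pi=pi, kappa=kap, n_starts=n_starts)
    out["b_free"] = fit_model(aln, tree, "b_free", pi=pi, kappa=kap, n_starts=n_starts)
    # nesting guards: both null optima are points of the b_free space,
    # so the b_free likelihood may never fall below either null's
    bf = out["b_free"]
    if bf.lnl < out["b_neut"].lnl:
        out["b_free"] = ModelFit(
            "b_free", out["b_neut"].lnl,
            {"omega_fg": 1.0, "omega_bg": out["b_neut"].params["omega_bg"], "kappa": kap},
            bf.converged, 2,
        )
    if out["b_free"].lnl < m0.lnl:
        out["b_free"] = ModelFit(
            "b_free", m0.lnl,
            {"omega_fg": m0.params["omega"], "omega_bg": m0.params["omega"], "kappa": kap},
            bf.converged, 2,
        )
    return out


# ----------------------------------------------------------------------
# Branch-site models


def _branch_site_lnl(
    tree: TreeModel,
    patterns: np.ndarray,
    counts: np.ndarray,
    pi: np.ndarray,
    kappa: float,
    gtr: Optional[np.ndarray],
    p0: float,
    p1: float,
    w0: float,
    w2: float,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Mixture log-likelihood of bsA/bsA1; returns (lnl, class site logliks, props)."""
    p2 = max(1.0 - p0 - p1, 0.0)
    denom = max(p0 + p1, 1e-12)
    props = np.array([p0, p1, p2 * p0 / denom, p2 * p1 / denom])
    # (fg omega, bg omega) per class
    class_omegas = [(w0, w0), (1.0, 1.0), (w2, w0), (w2, 1.0)]
    specs: Dict[float, SpectralQ] = {}
    for w in {w0, 1.0, w2}:
        specs[w] = SpectralQ(codon_rate_matrix(pi, w, kappa, gtr), pi)
    site_ll = np.empty((4, patterns.shape[1]))
    for c, (wf, wb) in enumerate(class_omegas):
        P = {
            v: specs[wf if tree.fg[v] else wb].P(tree.lengths[v])
            for v in tree.postorder
            if tree.parent[v] >= 0
        }
        site_ll[c] = _site_loglik(tree, patterns, P, pi)
    m = site_ll.max(axis=0)
    mix = np.log((props[:, None] * np.exp(site_ll - m)).sum(axis=0)) + m
    return float((counts * mix).sum()), site_ll, props


def _fit_branch_site(
    aln: CodonAlignment,
    tree: TreeModel,
    model_id: str,
    pi: Optional[np.ndarray] = None,
    kappa: Optional[float] = None,
    gtr: Optional[np.ndarray] = None,
) -> ModelFit:
    tree.require_foreground()
    if pi is None:
        pi = aln.f3x4()
    if kappa is None:
        kappa = fit_model(aln, tree, "M0", pi=pi).params["kappa"]
    patterns, counts = _patterns(aln, tree)
    free_w2 = model_id == "bsA"

    def unpack(x):
        ea, eb = math.exp(x[0]), math.exp(x[1])
        z = 1.0 + ea + eb
        p0, p1 = ea / z, eb / z
        w0 = 1.0 / (1.0 + math.exp(-x[2]))  # in (0, 1)
        w0 = min(max(w0, 1e-4), 1.0 - 1e-6)
        w2 = math.exp(x[3]) if free_w2 else 1.0
        return p0, p1, w0, w2

    def fun(x):
        p0, p1, w0, w2 = unpack(x)
        lnl, _, _ = _branch_site_lnl(
            tree, patterns, counts, pi, kappa, gtr, p0, p1, w0, w2
        )
        return lnl

    bounds = [(-6, 6), (-6, 6), (-9, 9)]
    starts = [[1.0, 0.0, 0.0], [0.5, 0.5, -1.5], [2.0, -1.0, 1.0]]
    if free_w2:
        bounds.append((0.0, math.log(OMEGA_BOUNDS[1])))
        starts = [s + [math.log(w2)] for s in starts for w2 in (1.5, 4.0)]
    x, f, ok = _maximize(fun, starts, bounds)
    p0, p1, w0, w2 = unpack(x)
    params = {"p0": p0, "p1": p1, "omega0": w0, "omega2": w2, "kappa": kappa}
    return ModelFit(model_id, f, params, ok, 4 if free_w2 else 3)


@dataclass
class BranchSiteResult:
    lrt: LRTResult
    fits: Dict[str, ModelFit]
    site_posteriors: np.ndarray  # per alignment column, P(class 2a or 2b)
    selected_sites: List[int]  # 0-based codon columns with posterior >= threshold
    beb_ratio: float
    beb_bin: str


def beb_bin_of(ratio: float) -> str:
    """Bin a selected-site ratio for summary reporting."""
    if ratio <= 0:
        return "none"
    if ratio < 0.0025:
        return "<0.25%"
    if ratio <= 0.005:
        return "0.25-0.50%"
    return ">0.50%"


def branch_site_test(
    aln: CodonAlignment,
    tree: TreeModel,
    pi: Optional[np.ndarray] = None,
    kappa: Optional[float] = None,
    posterior_threshold: float = 0.95,
) -> BranchSiteResult:
    """bsA vs bsA1 LRT (df = 1) with NEB site posteriors at the bsA MLEs."""
    tree.require_foreground()
    if pi is None:
        pi = aln.f3x4()
    null = _fit_branch_site(aln, tree, "bsA1", pi=pi, kappa=kappa)
    alt = _fit_branch_site(aln, tree, "bsA", pi=pi, kappa=kappa)
    if alt.lnl < null.lnl - 1e-6:
        # w2=1 reduces bsA to bsA1: re-anchor at the null optimum
        alt = ModelFit("bsA", null.lnl, dict(null.params, omega2=1.0), alt.converged, 4)
    test = lrt(alt, null)
    patterns, counts = _patterns(aln, tree)
    _, site_ll, props = _branch_site_lnl(
        tree, patterns, counts, pi, alt.params["kappa"], None,
        alt.params["p0"], alt.params["p1"], alt.params["omega0"], alt.params["omega2"],
    )
    m = site_ll.max(axis=0)
    w = props[:, None] * np.exp(site_ll - m)
    post_sel_pat = w[2:].sum(axis=0) / w.sum(axis=0)
    # map patterns back to columns
    order = [aln.taxa.index(t) for t in tree.taxa]
    mat = aln.codons[order]
    _, inverse = np.unique(mat, axis=1, return_inverse=True)
    post = post_sel_pat[np.ravel(inverse)]
    selected = [i for i, p in enumerate(post) if p >= posterior_threshold]
    ratio = len(selected) / aln.n_codons
    return BranchSiteResult(test, {"bsA1": null, "bsA": alt}, post, selected, ratio, beb_bin_of(ratio))


# ----------------------------------------------------------------------
# Selection classification


@dataclass
class SelectionCall:
    gene: str
    constraint_status: str  # Relaxed | Strengthened | NS
    relaxed_selection: bool
    delta_omega: Optional[float]
    p_bfree_vs_m0: Optional[float]
    p_bfree_vs_bneut: Optional[float]
    beb_ratio: Optional[float] = None
    beb_bin: str = "none"
    excluded: bool = False
    omega_fg: Optional[float] = None
    omega_bg: Optional[float] = None


def classify_selection(
    fits: Mapping[str, ModelFit],
    gene: str = "",
    branch_site: Optional[BranchSiteResult] = None,
    alpha: float = 0.05,
    omega_exclude: Tuple[float, float] = (0.001, 10.0),
) -> SelectionCall:
    """Apply the selection decision tree to fitted branch models.

    Requires M0, b_neut and b_free fits on the same gene and tree.
    """
    for mid in ("M0", "b_neut", "b_free"):
        if mid not in fits:
            raise ValueError(f"missing fit for model {mid}")
    lo, hi = omega_exclude
    omegas = [
        v
        for f in fits.values()
        for k, v in f.params.items()
        if k.startswith("omega") and isinstance(v, float)
    ]
    excluded = any(w >= hi or w <= lo for w in omegas) or not all(
        f.converged for f in fits.values()
    )
    w_fg = fits["b_free"].params["omega_fg"]
    w_bg = fits["b_free"].params["omega_bg"]
    p_fm = lrt(fits["b_free"], fits["M0"]).pvalue
    p_fn = lrt(fits["b_free"], fits["b_neut"]).pvalue
    if excluded:
        return SelectionCall(gene, "NS", False, None, p_fm, p_fn, excluded=True)
    delta = (w_fg - w_bg) / w_bg
    if p_fm < alpha:
        if w_fg > w_bg:
            constraint = "Relaxed"
        elif w_fg < w_bg:
            constraint = "Strengthened"
        else:
            constraint = "NS"
    else:
        constraint = "NS"
    relaxed = p_fm < alpha and p_fn >= alpha
    call = SelectionCall(
        gene, constraint, relaxed, delta, p_fm, p_fn,
        omega_fg=w_fg, omega_bg=w_bg,
    )
    if branch_site is not None:
        call.beb_ratio = branch_site.beb_ratio
        call.beb_bin = branch_site.beb_bin
    return call


# ----------------------------------------------------------------------
# NG86 pairwise rates


@dataclass
class PairwiseRates:
    dN: float
    dS: float
    omega: Optional[float]
    pN: float = math.nan
    pS: float = math.nan
    S_sites: float = math.nan
    N_sites: float = math.nan
    method: str = "NG86"
    saturated: bool = False


def _codon_site_counts(ci: int) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position distributes weight 1/3 per alternative nucleotide;
    changes creating stop codons are discarded from both tallies.
    """
    codon = CODONS[ci]
    s = n = 0.0
    for p in range(3):
        for b in "TCAG":
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1 :]
            if alt in STOP_CODONS:
                continue
            if AA_OF[ci] == AA_OF[CODON_INDEX[alt]]:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


_SITE_COUNTS = [_codon_site_counts(i) for i in range(N_CODONS)]
_PATH_CACHE: Dict[Tuple[int, int], Tuple[float, float]] = {}


def _pair_differences(ci: int, cj: int) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways.

    Pathways through stop codons are excluded; if every ordering hits a
    stop, all orderings are averaged instead.
    """
    key = (ci, cj)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    a, b = CODONS[ci], CODONS[cj]
    diffs = [p for p in range(3) if a[p] != b[p]]
    paths = []
    for order in itertools.permutations(diffs):
        cur = a
        sd = nd = 0.0
        valid = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if GENETIC_AA(cur) == GENETIC_AA(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((valid, sd, nd))
    valid_paths = [(s, n) for v, s, n in paths if v]
    if not valid_paths:
        valid_paths = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid_paths) / len(valid_paths)
    nd = sum(n for _, n in valid_paths) / len(valid_paths)
    _PATH_CACHE[key] = (sd, nd)
    return sd, nd


def GENETIC_AA(codon: str) -> str:
    return AA_OF[CODON_INDEX[codon]] if codon in CODON_INDEX else "*"


def _jc_correct(p: float) -> Tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    if p <= 0:
        return 0.0, False
    return -0.75 * math.log(1 - 4 * p / 3), False


def ng86_rates(seq1: str, seq2: str) -> PairwiseRates:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction."""
    c1, c2 = encode_codons(seq1), encode_codons(seq2)
    if len(c1) != len(c2):
        raise ValueError("sequences differ in codon length")
    S = N = 0.0
    Sd = Nd = 0.0
    for i, j in zip(c1, c2):
        s1, n1 = _SITE_COUNTS[i]
        s2, n2 = _SITE_COUNTS[j]
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        if i != j:
            sd, nd = _pair_differences(int(i), int(j))
            Sd += sd
            Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, sat_s = _jc_correct(pS)
    dN, sat_n = _jc_correct(pN)
    omega = None
    if dS > 0 and math.isfinite(dS) and math.isfinite(dN):
        omega = dN / dS
    return PairwiseRates(dN, dS, omega, pN, pS, S, N, "NG86", sat_s or sat_n)


# ----------------------------------------------------------------------
# 2-taxon ML pairwise rates under MG94


def _syn_flow_fractions(pi: np.ndarray, omega: float, kappa: float) -> Tuple[float, float]:
    """(syn flow fraction at omega, syn flow fraction at omega=1) of the MG94 chain."""

    def frac(w):
        Q = codon_rate_matrix(pi, w, kappa, normalize=False)
        flow = pi[NEIGHBOR_I] * Q[NEIGHBOR_I, NEIGHBOR_J]
        syn = flow[NEIGHBOR_SYN].sum()
        return syn / flow.sum()

    return frac(omega), frac(1.0)


def pairwise_rates_ml(
    seq1: str, seq2: str, kappa: Optional[float] = None
) -> PairwiseRates:
    """ML pairwise dN/dS: 2-taxon MG94 fit of (t, omega) with F3x4 frequencies.

    dS and dN partition the ML branch length t by synonymous /
    nonsynonymous flow, normalized by the mutational-opportunity site
    fractions (evaluated at omega = 1), so omega = dN/dS exactly.
    """
    aln = CodonAlignment.from_sequences({"a": seq1, "b": seq2})
    pi = aln.f3x4()
    tree = TreeModel.from_newick("(a:0.5,b:0.5);")
    patterns, counts = _patterns(aln, tree)
    lo, hi = np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1])

    fit_kappa = kappa is None

    def fun(x):
        t, w = math.exp(x[0]), math.exp(x[1])
        kap = math.exp(x[2]) if fit_kappa else kappa
        spec = SpectralQ(codon_rate_matrix(pi, w, kap), pi)
        P = {
            v: spec.P(t * tree.lengths[v] * 2)
            for v in tree.postorder
            if tree.parent[v] >= 0
        }
        return float((counts * _site_loglik(tree, patterns, P, pi)).sum())

    bounds = [(math.log(1e-6), math.log(20.0)), (lo, hi)]
    starts = [[math.log(0.2), math.log(w)] for w in (0.1, 0.5, 1.0)]
    if fit_kappa:
        bounds.append((math.log(0.2), math.log(20.0)))
        starts = [s + [math.log(2.0)] for s in starts]
    x, f, ok = _maximize(fun, starts, bounds)
    t, w = math.exp(x[0]), math.exp(x[1])
    kap = math.exp(x[2]) if fit_kappa else kappa
    fS, fS1 = _syn_flow_fractions(pi, w, kap)
    dS = t * fS / (3 * fS1)
    dN = t * (1 - fS) / (3 * (1 - fS1))
    saturated = t >= 19.0
    return PairwiseRates(
        dN, dS, (dN / dS if dS > 0 else None), method="ML", saturated=saturated,
        S_sites=math.nan, N_sites=math.nan,
    )


# ----------------------------------------------------------------------
# HKY85 nucleotide distance (non-CDS regions)


def hky85_distance(seq1: str, seq2: str) -> Tuple[float, float]:
    """ML pairwise distance (substitutions/site) and kappa under HKY85.

    Saturation is flagged by returning inf.  Sites with non-ACGT bases
    in either sequence are ignored.
    """
    s1 = seq1.upper()
    s2 = seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned (equal length)")
    pairs = [(a, b) for a, b in zip(s1, s2) if a in "TCAG" and b in "TCAG"]
    if not pairs:
        raise ValueError("no comparable sites")
    counts = np.zeros((4, 4))
    base_counts = np.zeros(4)
    for a, b in pairs:
        counts[NUC_INDEX[a], NUC_INDEX[b]] += 1
        base_counts[NUC_INDEX[a]] += 1
        base_counts[NUC_INDEX[b]] += 1
    pi = base_counts / base_counts.sum()

    transition_pairs = {(NUC_INDEX["A"], NUC_INDEX["G"]), (NUC_INDEX["G"], NUC_INDEX["A"]),
                        (NUC_INDEX["C"], NUC_INDEX["T"]), (NUC_INDEX["T"], NUC_INDEX["C"])}

    def hky_Q(kap):
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = (kap if (i, j) in transition_pairs else 1.0) * pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def fun(x):
        t, kap = math.exp(x[0]), math.exp(x[1])
        P = transition_matrix(hky_Q(kap), t, pi)
        ll = 0.0
        for i in range(4):
            for j in range(4):
                if counts[i, j]:
                    ll += counts[i, j] * math.log(max(pi[i] * P[i, j], 1e-300))
        return ll

    if all(a == b for a, b in pairs):
        return 0.0, 2.0
    x, f, _ = _maximize(
        fun,
        [[math.log(0.1), math.log(2.0)], [math.log(1.0), math.log(2.0)]],
        [(math.log(1e-8), math.log(20.0)), (math.log(0.05), math.log(100.0))],
    )
    t, kap = math.exp(x[0]), math.exp(x[1])
    if t >= 19.0:
        return math.inf, kap
    return t, kap


# ----------------------------------------------------------------------
# Branch-level dN-dS regression


@dataclass
class BranchRateRegression:
    slope_ds_on_dn: float
    slope_dn_on_ds: float
    r2: float
    pvalue: float
    n_branches: int
    excluded_ratios: Dict[str, float]  # label -> dS/dN of excluded branches


def branch_rate_regression(
    dn: Mapping[str, float],
    ds: Mapping[str, float],
    exclude_labels: Sequence[str] = (),
) -> BranchRateRegression:
    """OLS relation between per-branch dN and dS across the tree.

    Both regression directions are reported; excluded branches are
    summarized by their own dS/dN ratio rather than entering the fit.
    """
    exclude = set(exclude_labels)
    labels = [k for k in dn if k in ds and k not in exclude]
    if len(labels) < 3:
        raise ValueError("need at least 3 branches after exclusion")
    x = np.array([dn[k] for k in labels], dtype=float)
    y = np.array([ds[k] for k in labels], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate variance in branch rates")
    r1 = stats.linregress(x, y)
    r2 = stats.linregress(y, x)
    ratios = {
        k: (ds[k] / dn[k] if dn.get(k) else math.nan) for k in exclude if k in dn
    }
    return BranchRateRegression(
        slope_ds_on_dn=float(r1.slope),
        slope_dn_on_ds=float(r2.slope),
        r2=float(r1.rvalue**2),
        pvalue=float(r1.pvalue),
        n_branches=len(labels),
        excluded_ratios=ratios,
    )
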