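"""Phylogenetic trees, nucleotide substitution models and pruning likelihoods.

This module is the numerical core of the package: rooted trees with
branch lengths in expected substitutions per site, time-reversible
nucleotide models (JC69, HKY85, general REV) normalized to one expected
substitution per unit branch length, column log-likelihoods by
Felsenstein pruning with gaps/N treated as missing data, and bounded
maximum-likelihood fitting of rate-scale parameters (an element-wide
scale ``s`` and an optional per-branch multiplier ``lambda``).

Branches are addressed by the name of their child node, so named
internal nodes (e.g. the ancestor of a bat clade) are first-class test
targets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = 4  # gap, N, or any ambiguity code

# leaf partial-likelihood rows: one-hot for A,C,G,T; all-ones for missing
_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones(4)])


def encode_base(ch: str) -> int:
    """Map a character to 0..3 (ACGT) or 4 (missing: gap, N, anything else)."""
    return BASE_INDEX.get(ch.upper(), MISSING)


class NewickError(ValueError):
    """Malformed newick input."""


@dataclass
class PhyloTree:
    """Rooted tree stored as parallel arrays indexed by node id.

    ``parent[i]`` is -1 for the root; ``lengths[i]`` is the length of the
    branch above node ``i`` (0 for the root); ``names[i]`` is the leaf or
    internal node label (None for unnamed internal nodes).
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list
    root: int

    children: list = field(init=False, repr=False)
    postorder: np.ndarray = field(init=False, repr=False)
    label_to_node: dict = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.parent)
        if np.any(self.lengths < 0):
            bad = int(np.argmin(self.lengths))
            raise ValueError(
                f"negative branch length {self.lengths[bad]} above node "
                f"{self.names[bad] or bad}"
            )
        self.children = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if i != self.root:
                self.children[p].append(i)
        # iterative postorder (children before parents)
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        self.postorder = np.array(order[::-1], dtype=np.intp)
        self.label_to_node = {}
        for i, nm in enumerate(self.names):
            if nm is None:
                continue
            if nm in self.label_to_node:
                raise ValueError(f"duplicate node name {nm!r}")
            self.label_to_node[nm] = i

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaves(self) -> list:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_names(self) -> list:
        return [self.names[i] for i in self.leaves]

    def branch_node(self, label: str) -> int:
        """Node id of the branch addressed by its child-node name."""
        try:
            return self.label_to_node[label]
        except KeyError:
            raise KeyError(f"no branch labelled {label!r} in tree") from None

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    # -- serialization ---------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node):
            label = self.names[node] or ""
            if self.is_leaf(node):
                inner = label
            else:
                inner = "(" + ",".join(fmt(c) for c in self.children[node]) + ")" + label
            if node == self.root:
                return inner
            return f"{inner}:{self.lengths[node]:.10g}"

        return fmt(self.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a single rooted newick string into a :class:`PhyloTree`.

    Internal node labels are preserved; a missing branch length is an
    error except on the root.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer errors
        raise NewickError(f"malformed newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise NewickError("newick tree has no branching structure")

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.intp)
    lengths = np.zeros(len(nodes))
    names: list = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickError(f"branch without length at node index {i}")
            lengths[i] = nd.edge.length
        if nd.taxon is not None:
            names[i] = nd.taxon.label
        elif nd.label:
            names[i] = nd.label
    return PhyloTree(parent=parent, lengths=lengths, names=names, root=0)


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------


@dataclass
class SubstModel:
    """Time-reversible nucleotide model with Q normalized to rate 1.

    ``pi`` is the equilibrium distribution over A,C,G,T. The rate matrix
    satisfies stationarity (pi Q = 0), detailed balance, zero row sums,
    and -sum_i pi_i Q_ii = 1 so branch lengths read as expected
    substitutions per site.
    """

    family: str
    pi: np.ndarray
    Q: np.ndarray

    # eigendecomposition of the pi^{1/2}-symmetrized Q, for fast expm
    _w: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.pi.shape != (4,) or not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must be a 4-vector summing to 1")
        if np.any(self.pi <= 0):
            raise ValueError("pi entries must be positive")
        if not np.allclose(self.Q.sum(axis=1), 0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to 0")
        if not np.allclose(self.pi @ self.Q, 0, atol=1e-8):
            raise ValueError("pi is not stationary for Q")
        sq = np.sqrt(self.pi)
        sym = (self.Q * sq[:, None]) / sq[None, :]
        if not np.allclose(sym, sym.T, atol=1e-8):
            raise ValueError("Q is not reversible with respect to pi")
        w, v = np.linalg.eigh((sym + sym.T) / 2)
        self._w = w
        self._left = v / sq[:, None]
        self._right = v.T * sq[None, :]

    # -- constructors ----------------------------------------------------
    @classmethod
    def jc69(cls) -> "SubstModel":
        Q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(Q, -1.0)
        return cls("JC69", np.full(4, 0.25), Q)

    @classmethod
    def hky85(cls, kappa: float, pi=None) -> "SubstModel":
        pi = np.full(4, 0.25) if pi is None else np.asarray(pi, float)
        Q = np.tile(pi, (4, 1)).astype(float)
        # transitions: A<->G (0,2), C<->T (1,3)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            Q[i, j] *= kappa
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls("HKY85", pi, _normalize(Q, pi))

    @classmethod
    def rev(cls, exchangeabilities: np.ndarray, pi) -> "SubstModel":
        """General reversible model from a symmetric exchangeability matrix."""
        S = np.asarray(exchangeabilities, float)
        pi = np.asarray(pi, float)
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("exchangeability matrix must be symmetric")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls("REV", pi, _normalize(Q, pi))

    @classmethod
    def from_rate_matrix(cls, Q: np.ndarray, pi) -> "SubstModel":
        """Reversible model from an explicit rate matrix (renormalized).

        The off-diagonals are symmetrized through the exchangeability
        parameterization, which absorbs the rounding that printed model
        files carry.
        """
        Q = np.array(Q, float)
        pi = np.asarray(pi, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            S = Q / pi[None, :]
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        return cls.rev(S, pi)

    # -- transition probabilities ---------------------------------------
    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for a branch of length ``t`` >= 0."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        P = (self._left * np.exp(self._w * t)) @ self._right
        return np.clip(P, 0.0, 1.0)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths (n, 4, 4)."""
        ts = np.asarray(ts, float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be >= 0")
        ew = np.exp(np.outer(ts, self._w))
        P = np.einsum("ij,nj,jk->nik", self._left, ew, self._right)
        return np.clip(P, 0.0, 1.0)


def _normalize(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / rate


@dataclass
class PhyloModel:
    """A tree plus a substitution model: the neutral model of the pipeline."""

    tree: PhyloTree
    model: SubstModel

    def require_species(self, species) -> np.ndarray:
        """Node ids for the given leaf names; error on unknown species."""
        idx = []
        for sp in species:
            node = self.tree.label_to_node.get(sp)
            if node is None or not self.tree.is_leaf(node):
                raise KeyError(f"species {sp!r} is not a leaf of the tree")
            idx.append(node)
        return np.asarray(idx, dtype=np.intp)


@dataclass
class BranchScaling:
    """Rate scaling: global scale ``s`` plus per-branch multipliers."""

    s: float = 1.0
    branch_scales: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("global scale s must be > 0")
        if any(v < 0 for v in self.branch_scales.values()):
            raise ValueError("branch multipliers must be >= 0")


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def effective_lengths(pm: PhyloModel, scaling: BranchScaling | None) -> np.ndarray:
    """Per-node branch length after applying s and any branch multipliers."""
    t = pm.tree.lengths.copy()
    if scaling is None:
        return t
    t *= scaling.s
    for label, lam in scaling.branch_scales.items():
        t[pm.tree.branch_node(label)] *= lam
    return t


def alignment_log_likelihoods(
    pm: PhyloModel,
    species: list,
    columns: np.ndarray,
    scaling: BranchScaling | None = None,
) -> np.ndarray:
    """Per-column log-likelihoods by Felsenstein pruning.

    ``columns`` is an integer array (n_species, n_cols) with 0..3 = ACGT
    and 4 = missing. Missing leaves contribute an all-ones partial vector.
    Columns are assumed independent; sum the result for a region.
    """
    columns = np.atleast_2d(np.asarray(columns))
    leaf_nodes = pm.require_species(species)
    tree = pm.tree
    n_cols = columns.shape[1]

    t_eff = effective_lengths(pm, scaling)
    P = pm.model.transition_matrices(t_eff)

    partials = [None] * tree.n_nodes
    row_of = {int(node): r for r, node in enumerate(leaf_nodes)}
    logscale = np.zeros(n_cols)
    for node in tree.postorder:
        node = int(node)
        if tree.is_leaf(node):
            if node not in row_of:
                # leaf absent from the column set: missing data
                partials[node] = np.ones((n_cols, 4))
            else:
                partials[node] = _LEAF_PARTIALS[columns[row_of[node]]]
        else:
            prod = None
            for c in tree.children[node]:
                term = partials[c] @ P[c].T
                partials[c] = None
                prod = term if prod is None else prod * term
            m = prod.max(axis=1)
            nz = m > 0
            with np.errstate(divide="ignore"):
                logscale += np.where(nz, np.log(np.where(nz, m, 1.0)), -np.inf)
            prod = np.where(nz[:, None], prod / np.where(nz, m, 1.0)[:, None], 0.0)
            partials[node] = prod
    root_like = partials[tree.root] @ pm.model.pi
    with np.errstate(divide="ignore"):
        return np.log(root_like) + logscale


def column_log_likelihood(
    pm: PhyloModel, column: dict, scaling: BranchScaling | None = None
) -> float:
    """Log-likelihood of a single column given as {leaf name: base char}."""
    if not column:
        raise ValueError("empty column")
    species = sorted(column)
    col = np.array([[encode_base(column[sp])] for sp in species], dtype=np.int8)
    if np.all(col == MISSING):
        raise ValueError("column has no non-missing base")
    return float(alignment_log_likelihoods(pm, species, col, scaling)[0])


# ---------------------------------------------------------------------------
# scale fitting
# ---------------------------------------------------------------------------

S_BOUNDS = (1e-4, 20.0)
LAMBDA_BOUNDS = (1.0, 50.0)


@dataclass
class ScaleFit:
    scaling: BranchScaling
    log_likelihood: float
    converged: bool
    n_evaluations: int


def fit_scales(
    pm: PhyloModel,
    species: list,
    columns: np.ndarray,
    branch: str | None = None,
    s_bounds: tuple = S_BOUNDS,
    lambda_bounds: tuple = LAMBDA_BOUNDS,
    rtol: float = 1e-6,
    max_cycles: int = 12,
) -> ScaleFit:
    """Maximize the column-set log-likelihood over s (and lambda on one branch).

    The null parameterization (``branch=None``) frees only the global
    scale s; with ``branch`` set, s and the branch multiplier lambda are
    maximized by cyclic bounded Brent searches on a log scale. The fit is
    deterministic and the returned log-likelihood never falls below the
    value at the starting point (s=1, lambda at its lower bound).
    """
    columns = np.atleast_2d(np.asarray(columns))
    if columns.size == 0:
        raise ValueError("no columns to fit")
    if np.all(columns == MISSING):
        raise ValueError("all columns are entirely missing")
    if branch is not None:
        pm.tree.branch_node(branch)  # raises on unknown label

    n_evals = 0

    def loglik(s, lam):
        nonlocal n_evals
        n_evals += 1
        scaling = BranchScaling(s=s, branch_scales={} if branch is None else {branch: lam})
        return float(alignment_log_likelihoods(pm, species, columns, scaling).sum())

    def maximize_1d(f, bounds):
        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        res = minimize_scalar(
            lambda x: -f(np.exp(x)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        return float(np.exp(res.x)), float(-res.fun)

    s, lam = 1.0, lambda_bounds[0]
    best = loglik(s, lam)
    converged = True
    if branch is None:
        s_new, ll = maximize_1d(lambda v: loglik(v, lam), s_bounds)
        if ll > best:
            s, best = s_new, ll
    else:
        converged = False
        for _ in range(max_cycles):
            s_prev, lam_prev = s, lam
            s_new, ll = maximize_1d(lambda v: loglik(v, lam), s_bounds)
            if ll > best:
                s, best = s_new, ll
            lam_new, ll = maximize_1d(lambda v: loglik(s, v), lambda_bounds)
            if ll > best:
                lam, best = lam_new, ll
            if abs(s - s_prev) <= rtol * max(1.0, abs(s)) and abs(
                lam - lam_prev
            ) <= rtol * max(1.0, abs(lam)):
                converged = True
                break
    scaling = BranchScaling(s=s, branch_scales={} if branch is None else {branch: lam})
    return ScaleFit(scaling, best, converged, n_evals)
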