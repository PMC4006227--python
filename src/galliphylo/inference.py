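"""Desk-scale gene-tree estimation.

This module provides the native inference stack used throughout the package:

* corrected pairwise distances (p, Jukes–Cantor, Kimura 2-parameter);
* neighbor joining with the classic Q criterion and a deterministic
  lexicographic tie rule;
* Felsenstein pruning log-likelihood under JC/K80/HKY/GTR, optionally with
  discrete-gamma rate variation (4 categories, mean-of-quantile-slice rates);
* AIC model choice over a reduced candidate set;
* nearest-neighbor-interchange (NNI) hill climbing with per-edge Brent
  branch-length optimization;
* the nonparametric (site-resampling) bootstrap.

Heavy ML tree searches of the kind production phylogenetics programs run are
deliberately out of scope: the experiments here compare trees, and NJ + NNI
provides a deterministic, testable engine at desk scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .alignment import IUPAC_STATES, MultiLocusAlignment
from .trees import Node, Tree, TreeSample

logger = logging.getLogger(__name__)

_BASES = "ACGT"

# ---------------------------------------------------------------------------
# Substitution models


def _gamma_category_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rate of each of ``ncat`` equal-probability slices of a
    Gamma(alpha, 1/alpha) distribution (mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    cuts = stats.gamma.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # E[X; X <= c] for Gamma(a, s) equals a*s*F(c; a+1, s)
    mass = stats.gamma.cdf(cuts, a=alpha + 1, scale=1.0 / alpha)
    rates = ncat * np.diff(mass)
    return rates / rates.mean() * 1.0  # guard tiny numerical drift


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide model with optional discrete-gamma rates.

    ``exchangeabilities`` are the six symmetric terms in the fixed order
    AC, AG, AT, CG, CT, GT; the rate matrix is scaled to one expected
    substitution per unit branch length at stationarity.
    """

    name: str
    pi: tuple = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    alpha: float | None = None
    ncat: int = 4

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be a positive 4-vector summing to 1")
        ex = np.asarray(self.exchangeabilities, dtype=float)
        if ex.shape != (6,) or (ex <= 0).any():
            raise ValueError("exchangeabilities must be six positive reals")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")

    # -- constructors -------------------------------------------------------

    @classmethod
    def jc(cls, alpha: float | None = None) -> "SubstitutionModel":
        return cls("JC", alpha=alpha)

    @classmethod
    def k80(cls, kappa: float = 2.0, alpha: float | None = None) -> "SubstitutionModel":
        ex = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        return cls("K80", exchangeabilities=ex, alpha=alpha)

    @classmethod
    def hky(cls, kappa: float, pi, alpha: float | None = None) -> "SubstitutionModel":
        ex = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        return cls("HKY", pi=tuple(pi), exchangeabilities=ex, alpha=alpha)

    @classmethod
    def gtr(cls, exchangeabilities, pi, alpha: float | None = None) -> "SubstitutionModel":
        return cls(
            "GTR", pi=tuple(pi), exchangeabilities=tuple(exchangeabilities), alpha=alpha
        )

    # -- derived quantities --------------------------------------------------

    @property
    def n_free_params(self) -> int:
        base = {"JC": 0, "K80": 1, "HKY": 4, "GTR": 8}[self.name]
        return base + (1 if self.alpha is not None else 0)

    @property
    def display_name(self) -> str:
        return self.name + ("+G" if self.alpha is not None else "")

    def rate_matrix(self) -> np.ndarray:
        """Scaled GTR rate matrix Q with stationary mean rate 1."""
        pi = np.asarray(self.pi)
        ex = self.exchangeabilities
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        q = np.zeros((4, 4))
        for s, (i, j) in zip(ex, pairs):
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def _spectral(self):
        """Eigen-decomposition of Q via the symmetrized form (reversibility)."""
        pi = np.asarray(self.pi)
        sq = np.sqrt(pi)
        q = self.rate_matrix()
        sym = (q * sq[:, None]) / sq[None, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2.0)
        left = u.T * sq[None, :]  # rows of U^T D^{1/2}
        right = (u.T / sq[None, :]).T  # D^{-1/2} U
        return w, right, left

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return _gamma_category_rates(self.alpha, self.ncat)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q t rate), computed spectrally (fast for 4x4)."""
        if t < 0:
            raise ValueError("negative branch length")
        w, right, left = self._cached_spectral()
        p = (right * np.exp(w * t * rate)) @ left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def _cached_spectral(self):
        cached = getattr(self, "_spec", None)
        if cached is None:
            cached = self._spectral()
            object.__setattr__(self, "_spec", cached)
        return cached


# ---------------------------------------------------------------------------
# Distances


class SaturationError(ValueError):
    """Raised when a corrected distance is undefined (saturated divergence)."""


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over an ordered taxon list."""

    taxa: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains NaN")
        if (np.diag(self.values) != 0).any():
            raise ValueError("diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    def __getitem__(self, pair) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


_PLAIN_MASK = np.zeros(256, dtype=bool)
_PURINE_MASK = np.zeros(256, dtype=bool)
for _b in "ACGT":
    _PLAIN_MASK[ord(_b)] = True
for _b in "AG":
    _PURINE_MASK[ord(_b)] = True


def _comparable(seq_i: str, seq_j: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.frombuffer(seq_i.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_j.upper().encode(), dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    ok = _PLAIN_MASK[a] & _PLAIN_MASK[b]
    return a[ok], b[ok]


def pairwise_distance(seq_i: str, seq_j: str, model: str = "JC") -> float:
    """Pairwise distance between two IUPAC sequences.

    Sites where either symbol is ambiguous or a gap are skipped.  ``model``
    is ``'p'`` (raw mismatch fraction), ``'JC'`` or ``'K80'``.  Saturated
    pairs (log arguments <= 0) raise :class:`SaturationError`; callers
    building matrices apply the saturation policy.
    """
    a, b = _comparable(seq_i, seq_j)
    n = a.size
    if n == 0:
        raise ValueError("no comparable sites")
    if model == "p":
        return float((a != b).mean())
    if model == "JC":
        p = (a != b).mean()
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise SaturationError(f"JC distance undefined at p={p:.4f}")
        return float(-0.75 * math.log(arg))
    if model == "K80":
        is_pur_a = _PURINE_MASK[a]
        is_pur_b = _PURINE_MASK[b]
        diff = a != b
        transitions = diff & (is_pur_a == is_pur_b)
        p_ts = transitions.mean()
        p_tv = (diff & ~transitions).mean()
        arg1 = 1.0 - 2.0 * p_ts - p_tv
        arg2 = 1.0 - 2.0 * p_tv
        if arg1 <= 0 or arg2 <= 0:
            raise SaturationError("K80 distance undefined (saturated)")
        return float(-0.5 * math.log(arg1) - 0.25 * math.log(arg2))
    raise ValueError("model must be 'p', 'JC' or 'K80'")


def distance_matrix(
    aln: MultiLocusAlignment, model: str = "JC"
) -> DistanceMatrix:
    """All pairwise distances with the saturation policy applied.

    Undefined corrected distances are replaced by twice the largest finite
    distance in the matrix (with a warning) so NJ can proceed.
    """
    taxa = list(aln.taxa)
    seqs = [aln.sequence(t) for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j], model)
            except SaturationError:
                saturated.append((i, j))
                d[i, j] = d[j, i] = np.nan
    if saturated:
        finite_max = np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0
        for i, j in saturated:
            d[i, j] = d[j, i] = 2.0 * finite_max
        logger.warning(
            "%d saturated pairs set to 2 x max finite distance (%.4f)",
            len(saturated),
            2.0 * finite_max,
        )
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Classic Q-criterion neighbor joining.

    Deterministic: among equal Q values the pair whose (sorted) representative
    taxon labels are lexicographically smallest is joined.  Negative branch
    lengths are clamped to zero with the deficit moved to the sister edge.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [Node(label=t) for t in dm.taxa]
    reps = [t for t in dm.taxa]  # smallest taxon label in each cluster
    active = list(range(n))

    def join_pair(i, j, li, lj):
        vi, vj = max(li, 0.0), max(lj, 0.0)
        # move any clamped deficit to the sister edge
        vj = max(vj + min(li, 0.0), 0.0)
        vi = max(vi + min(lj, 0.0), 0.0)
        parent = Node()
        a, b = nodes[i], nodes[j]
        a.length, b.length = vi, vj
        parent.add(a)
        parent.add(b)
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=1e-12, atol=1e-12))
        best = min(
            (tuple(sorted((reps[active[a]], reps[active[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = join_pair(i, j, li, lj)
        # distances from the new cluster
        dnew = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            dnew[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        d[i, :] = dnew
        d[:, i] = dnew
        d[i, i] = 0.0
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final trivalent node
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node()
    for idx, l in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(l, 0.0)
        root.add(nodes[idx])
    return Tree(root, rooted=False)


# ---------------------------------------------------------------------------
# Likelihood


_LEAF_PARTIALS = {}
for _sym, _states in IUPAC_STATES.items():
    v = np.zeros(4)
    if _states:
        for s in _states:
            v[_BASES.index(s)] = 1.0
    else:
        v[:] = 1.0  # gap / missing: compatible with every state
    _LEAF_PARTIALS[_sym.encode()] = v


@dataclass
class SitePatterns:
    """Compressed alignment: unique columns with multiplicities."""

    taxa: list
    partials: dict  # taxon -> (n_patterns, 4) leaf partial matrix
    weights: np.ndarray

    @classmethod
    def from_alignment(cls, aln) -> "SitePatterns":
        if isinstance(aln, MultiLocusAlignment):
            taxa, data = list(aln.taxa), aln.data
        else:  # mapping taxon -> sequence
            taxa = list(aln.keys())
            data = np.array(
                [np.frombuffer(s.upper().encode(), dtype="S1") for s in aln.values()]
            )
        if data.shape[1] == 0:
            raise ValueError("zero-length alignment")
        patterns, weights = np.unique(data, axis=1, return_counts=True)
        partials = {
            t: np.array([_LEAF_PARTIALS[b] for b in patterns[i]])
            for i, t in enumerate(taxa)
        }
        return cls(taxa=taxa, partials=partials, weights=weights.astype(float))

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())


def _ensure_patterns(aln) -> SitePatterns:
    return aln if isinstance(aln, SitePatterns) else SitePatterns.from_alignment(aln)


def log_likelihood(tree: Tree, aln, model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood of an alignment on a tree.

    Works on the tree's current (rooted or unrooted) representation — by
    reversibility the likelihood is identical for any rooting.  Ambiguity
    codes contribute partial likelihoods over their compatible states; site
    patterns are compressed before the recursion.
    """
    pats = _ensure_patterns(aln)
    if set(t for t in tree.taxa) != set(pats.taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    rates = model.category_rates()
    ncat = len(rates)
    npat = len(pats.weights)
    site_lik = np.zeros(npat)
    pi = np.asarray(model.pi)

    for rate in rates:
        partial_cache: dict[int, np.ndarray] = {}
        for nd in tree.root.postorder():
            if nd.is_leaf():
                part = pats.partials[nd.label]
            else:
                part = np.ones((npat, 4))
                for c in nd.children:
                    if c.length is None:
                        raise ValueError("branch length missing")
                    p = model.transition_matrix(c.length, rate)
                    part = part * (partial_cache.pop(id(c)) @ p.T)
            partial_cache[id(nd)] = part
        root_part = partial_cache[id(tree.root)]
        site_lik += (root_part @ pi) / ncat
    if (site_lik <= 0).any():
        return -np.inf
    return float(np.log(site_lik) @ pats.weights)


# ---------------------------------------------------------------------------
# Branch-length optimization


_MAX_BRANCH = 10.0


def optimize_edge_length(tree: Tree, node: Node, pats: SitePatterns, model) -> float:
    """Brent-optimize one edge length in place; returns the new lnL."""

    def neg(x):
        node.length = float(x)
        return -log_likelihood(tree, pats, model)

    res = optimize.minimize_scalar(
        neg, bounds=(1e-9, _MAX_BRANCH), method="bounded",
        options={"xatol": 1e-6},
    )
    node.length = float(res.x)
    return -float(res.fun)


def optimize_branch_lengths(
    tree: Tree, aln, model: SubstitutionModel, rounds: int = 2
) -> float:
    """Cycle Brent optimization over every edge; returns the final lnL."""
    pats = _ensure_patterns(aln)
    lnl = log_likelihood(tree, pats, model)
    for _ in range(rounds):
        for nd in list(tree.root.postorder()):
            if nd.parent is None:
                continue
            lnl = optimize_edge_length(tree, nd, pats, model)
    return lnl


# ---------------------------------------------------------------------------
# Model selection


def empirical_frequencies(aln) -> np.ndarray:
    pats = _ensure_patterns(aln)
    counts = np.zeros(4)
    for t in pats.taxa:
        part = pats.partials[t]
        plain = part.sum(axis=1) == 1
        counts += (part[plain] * pats.weights[plain, None]).sum(axis=0)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    freqs = counts / total
    return (freqs + 1e-6) / (freqs + 1e-6).sum()


def default_candidates(aln, gamma: bool = True) -> list:
    """The reduced candidate set: {JC, K80, HKY, GTR} x {none, +G}."""
    pi = tuple(empirical_frequencies(aln))
    base = [
        SubstitutionModel.jc(),
        SubstitutionModel.k80(),
        SubstitutionModel.hky(2.0, pi),
        SubstitutionModel.gtr((1.0, 2.0, 1.0, 1.0, 2.0, 1.0), pi),
    ]
    out = list(base)
    if gamma:
        out += [replace(mdl, alpha=0.5) for mdl in base]
    return out


def _fit_model(tree: Tree, pats: SitePatterns, model: SubstitutionModel):
    """Maximize lnL over the model's free parameters (branch lengths fixed)."""
    free_exchange = {"K80": 1, "HKY": 1, "GTR": 5}.get(model.name, 0)
    fit_alpha = model.alpha is not None
    ndim = free_exchange + (1 if fit_alpha else 0)
    if ndim == 0:
        return model, log_likelihood(tree, pats, model)

    def build(x) -> SubstitutionModel:
        vals = np.exp(x)
        i = 0
        ex = list(model.exchangeabilities)
        if model.name in ("K80", "HKY"):
            kappa = vals[0]
            ex = [1.0, kappa, 1.0, 1.0, kappa, 1.0]
            i = 1
        elif model.name == "GTR":
            ex = list(vals[:5]) + [1.0]
            i = 5
        alpha = float(vals[i]) if fit_alpha else None
        return replace(model, exchangeabilities=tuple(ex), alpha=alpha)

    def neg(x):
        try:
            return -log_likelihood(tree, pats, build(x))
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = []
    if model.name in ("K80", "HKY"):
        x0.append(math.log(model.exchangeabilities[1]))
    elif model.name == "GTR":
        x0.extend(math.log(e) for e in model.exchangeabilities[:5])
    if fit_alpha:
        x0.append(math.log(model.alpha))
    res = optimize.minimize(
        neg, np.array(x0), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400 * max(ndim, 1)},
    )
    fitted = build(res.x)
    return fitted, -float(res.fun)


def aic_select(aln, topology: Tree, candidates=None):
    """AIC model choice on a fixed topology with fixed branch lengths.

    AIC = 2k - 2 lnL with k the number of free model parameters (branch
    lengths are shared by all candidates and excluded).  Ties go to the model
    with fewer parameters.  Returns (best fitted model, report DataFrame).
    """
    pats = _ensure_patterns(aln)
    if candidates is None:
        candidates = default_candidates(pats)
    if not candidates:
        raise ValueError("no candidate models")
    rows = []
    fitted_models = []
    for cand in candidates:
        try:
            fitted, lnl = _fit_model(topology, pats, cand)
        except Exception as exc:  # noqa: BLE001 - candidate dropped, not fatal
            logger.warning("candidate %s dropped: %s", cand.display_name, exc)
            continue
        k = cand.n_free_params
        rows.append(
            {"model": cand.display_name, "lnL": lnl, "k": k, "AIC": 2 * k - 2 * lnl}
        )
        fitted_models.append(fitted)
    if not rows:
        raise ValueError("every candidate failed to optimize")
    table = pd.DataFrame(rows)
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    order = sorted(range(len(rows)), key=lambda i: (rows[i]["AIC"], rows[i]["k"]))
    best = fitted_models[order[0]]
    return best, table


# ---------------------------------------------------------------------------
# NNI search


def _internal_edges(tree: Tree) -> list:
    return [
        nd
        for nd in tree.root.postorder()
        if nd.children and nd.parent is not None
    ]


def _nni_swaps(tree: Tree, v: Node):
    """The two NNI rearrangements around the internal edge above ``v``.

    Yields (subtree_below, subtree_on_parent_side) pairs to exchange.
    """
    u = v.parent
    sibling = next(c for c in u.children if c is not v)
    for child in v.children[:2]:
        yield child, sibling


def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def nni_hill_climb(
    start: Tree, aln, model: SubstitutionModel, max_rounds: int = 20
) -> Tree:
    """Steepest-ascent NNI search from a binary starting tree.

    Each round evaluates both rearrangements of every internal edge,
    re-optimizing only that edge's length (Brent), and applies the best
    improving move; stops at a local optimum or after ``max_rounds``.  The
    returned tree's lnL is never below the start tree's.
    """
    pats = _ensure_patterns(aln)
    tree = start.copy()
    for nd in tree.root.postorder():
        if nd.parent is not None and nd.length is None:
            nd.length = 0.01
    current = optimize_branch_lengths(tree, pats, model, rounds=1)
    for _ in range(max_rounds):
        best_gain = 0.0
        best_move = None
        for v in _internal_edges(tree):
            saved_len = v.length
            for a, b in _nni_swaps(tree, v):
                _swap_subtrees(a, b)
                lnl = optimize_edge_length(tree, v, pats, model)
                _swap_subtrees(a, b)
                v.length = saved_len
                if lnl - current > best_gain + 1e-9:
                    best_gain = lnl - current
                    best_move = (v, a, b)
        if best_move is None:
            break
        v, a, b = best_move
        _swap_subtrees(a, b)
        optimize_edge_length(tree, v, pats, model)
        current = optimize_branch_lengths(tree, pats, model, rounds=1)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def _resample_columns(aln: MultiLocusAlignment, rng) -> MultiLocusAlignment:
    cols = rng.integers(0, aln.length, size=aln.length)
    scheme = aln.scheme  # identity of resampled columns is not partition-true
    from .alignment import PartitionEntry, PartitionScheme

    flat = PartitionScheme(
        [PartitionEntry("bootstrap", aln.scheme.entries[0].locus_class, 0, aln.length)]
    )
    return MultiLocusAlignment(
        aln.taxa, aln.data[:, cols], flat, aln.source_columns[cols]
    )


def bootstrap_trees(
    aln: MultiLocusAlignment,
    B: int,
    method: str = "nj",
    seed: int = 0,
    model: SubstitutionModel | None = None,
    distance: str = "JC",
    locus: str | None = None,
) -> TreeSample:
    """Nonparametric bootstrap: resample columns, re-infer, collect trees.

    ``method='nj'`` infers each replicate by NJ on corrected distances;
    ``'nj+nni'`` follows with NNI hill climbing under ``model`` (GTR+G by
    default).  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if method not in ("nj", "nj+nni"):
        raise ValueError("method must be 'nj' or 'nj+nni'")
    rng = np.random.default_rng(seed)
    out = []
    for b in range(B):
        rep = _resample_columns(aln, rng)
        t = neighbor_joining(distance_matrix(rep, distance))
        if method == "nj+nni":
            mdl = model
            if mdl is None:
                mdl = SubstitutionModel.gtr(
                    (1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
                    tuple(empirical_frequencies(rep)),
                    alpha=0.5,
                )
            t = nni_hill_climb(t, rep, mdl)
        out.append(t)
    return TreeSample(out, locus=locus, seed=seed, replicate_ids=list(range(B)))
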