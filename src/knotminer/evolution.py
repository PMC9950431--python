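"""Distance phylogeny, bootstrap supports and site-specific rates.

The tree stage is distance-based: Kimura-corrected protein p-distances,
Saitou–Nei neighbour-joining with deterministic tie-breaking, and a
nonparametric column-resampling bootstrap with branches under a support
threshold collapsed into multifurcations.  Per-column relative
substitution rates come from Felsenstein-pruning likelihoods under a
Poisson amino-acid model (uniform exchangeabilities and frequencies)
across discrete-gamma rate categories; the reported column rate is the
posterior-mean category rate, normalised to mean 1 over scored columns.

The Poisson model has closed-form transition probabilities,
``P(same) = (1 + 19 e^{-20/19 rt})/20``, which makes every likelihood
unit-testable against direct enumeration.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from skbio import TreeNode

from .regional_msa import GAP, RegionalAlignment

#: saturation cap: p with 1 - p - 0.2 p^2 <= 0.01 maps to this distance
MAX_DISTANCE = -np.log(0.01)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(_AA)}
N_STATES = 20


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric, zero diag")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and nonnegative")


@dataclass
class PhyloTree:
    """A (possibly multifurcating) unrooted tree with bootstrap supports."""

    root: TreeNode

    @property
    def newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def __str__(self) -> str:
        return self.newick


@dataclass(frozen=True)
class SiteRateProfile:
    rates: np.ndarray          # NaN where unscored
    scored: np.ndarray         # bool mask
    alpha: float
    log_likelihood: float

    def __post_init__(self) -> None:
        sc = self.rates[self.scored]
        if sc.size and abs(float(np.mean(sc)) - 1.0) > 1e-9:
            raise ValueError("scored rates must be mean-normalised to 1")


def kimura_distance(p: float) -> float:
    """Kimura's protein distance correction d = -ln(1 - p - 0.2 p^2)."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.01:
        return MAX_DISTANCE
    return -np.log(arg)


def protein_distance(aln: RegionalAlignment) -> DistanceMatrix:
    """Kimura-corrected pairwise p-distances over mutually ungapped columns."""
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    rows = aln.rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            shared = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
            if not shared:
                raise ValueError(
                    f"no mutually ungapped columns between {aln.ids[i]} "
                    f"and {aln.ids[j]}")
            p = sum(1 for x, y in shared if x != y) / len(shared)
            d[i, j] = d[j, i] = kimura_distance(p)
    return DistanceMatrix(ids=aln.ids, d=d)


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour-joining with deterministic id tie-breaking.

    Negative branch lengths are clamped to zero.  Ties in the Q matrix
    are broken by the lexicographically smallest leaf name under each
    candidate node, so the result is independent of input order.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in D.ids]
    keys: list[str] = list(D.ids)  # min leaf name under each active node
    d = D.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        u.extend([ci, cj])
        # distances to the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[-1, k] = d[k, -1] = max(
                0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
        nodes.append(u)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    root = TreeNode()
    ci, cj = nodes[i], nodes[j]
    half = max(d[i, j], 0.0) / 2.0
    ci.length = cj.length = float(half)
    root.extend([ci, cj])
    return PhyloTree(root=root)


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (for additivity checks and reporting)."""
    tips = sorted(tree.root.tips(), key=lambda t: t.name)
    ids = tuple(t.name for t in tips)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tips[i].distance(tips[j])
    return DistanceMatrix(ids=ids, d=d)


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: PhyloTree) -> dict[int, frozenset[str]]:
    """Canonical leaf-set per internal edge (keyed by node id).

    Each internal edge splits the leaves in two; the returned set is the
    side NOT containing the alphabetically first leaf, so the key is
    invariant to rooting.
    """
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    out: dict[int, frozenset[str]] = {}
    for node in tree.root.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = below if ref not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[id(node)] = side
    return out


def _resample_columns(aln: RegionalAlignment,
                      rng: np.random.Generator) -> RegionalAlignment:
    cols = rng.integers(0, aln.width, size=aln.width)
    rows = tuple("".join(r[c] for c in cols) for r in aln.rows)
    return RegionalAlignment(ids=aln.ids, rows=rows,
                             anchor_columns=(), region_blocks=((0, aln.width),))


def bootstrap_support(aln: RegionalAlignment, n_reps: int = 1000,
                      seed: int = 0, collapse_below: float = 50.0,
                      ) -> PhyloTree:
    """NJ tree with nonparametric bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times
    (one generator stream per replicate index); support for each
    internal edge of the point-estimate tree is the percentage of
    replicate trees containing the same bipartition.  Edges below
    ``collapse_below`` are collapsed into multifurcations.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = nj_tree(protein_distance(aln))
    point_bip = _bipartitions(point)
    counts = {k: 0 for k in point_bip}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        try:
            rep_tree = nj_tree(protein_distance(_resample_columns(aln, rng)))
        except ValueError:
            continue  # a pair lost all shared columns in this replicate
        rep_sets = set(_bipartitions(rep_tree).values())
        for k, s in point_bip.items():
            if s in rep_sets:
                counts[k] += 1
    # annotate supports and collapse weak edges
    to_collapse = []
    for node in list(point.root.non_tips(include_self=False)):
        support = 100.0 * counts.get(id(node), 0) / n_reps
        node.support = support  # skbio writes this as the edge label
        if support < collapse_below:
            to_collapse.append(node)
    for node in to_collapse:
        parent = node.parent
        length = node.length or 0.0
        for child in list(node.children):
            node.remove(child)
            if child.length is not None:
                child.length += length
            parent.append(child)
        parent.remove(node)
    return point


# ---------------------------------------------------------------------------
# site-specific rates under the Poisson model


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rate of each equal-probability bin of Gamma(alpha, 1/alpha)."""
    k = n_categories
    edges = np.array(
        [0.0] + [_gamma_ppf(alpha, q) for q in np.arange(1, k) / k]
        + [np.inf])
    # E[X; a<X<b] for Gamma(shape a, scale 1/a): P(a+1, alpha*b)-P(a+1, alpha*a)
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    return k * (upper - lower)


def _gamma_ppf(alpha: float, q: float) -> float:
    from scipy.stats import gamma as gamma_dist
    return float(gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha))


def _column_codes(aln: RegionalAlignment) -> np.ndarray:
    """(n_seq, width) integer residue codes; -1 for gaps/unknowns."""
    n, w = len(aln), aln.width
    codes = np.full((n, w), -1, dtype=int)
    for i, row in enumerate(aln.rows):
        for j, c in enumerate(row):
            codes[i, j] = _AA_INDEX.get(c, -1)
    return codes


def _column_likelihoods(codes: np.ndarray, tree: PhyloTree,
                        rates: np.ndarray,
                        leaf_index: dict[str, int]) -> np.ndarray:
    """(width, n_categories) likelihood of every column at every rate.

    Felsenstein pruning; the Poisson model lets the per-branch transform
    be written as ``e^{-lam} L(x) + (1 - e^{-lam}) mean(L)`` with
    ``lam = (20/19) * rate * t``.
    """
    width = codes.shape[1]
    n_cat = rates.size
    # partials: node -> array (width, n_cat, 20)
    partials: dict[int, np.ndarray] = {}
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            arr = np.ones((width, n_cat, N_STATES))
            row = codes[leaf_index[node.name]]
            obs = row >= 0
            arr[obs] = 0.0
            arr[np.arange(width)[obs], :, row[obs]] = 1.0
            partials[id(node)] = arr
        else:
            arr = np.ones((width, n_cat, N_STATES))
            for child in node.children:
                t = child.length or 0.0
                lam = (N_STATES / (N_STATES - 1.0)) * rates * t  # (n_cat,)
                decay = np.exp(-lam)[None, :, None]
                cl = partials.pop(id(child))
                mean = cl.mean(axis=2, keepdims=True)
                arr *= decay * cl + (1.0 - decay) * mean
            partials[id(node)] = arr
    root_partial = partials[id(tree.root)]
    return root_partial.mean(axis=2)  # uniform root frequencies 1/20


def site_rates(aln: RegionalAlignment, tree: PhyloTree,
               n_categories: int = 4, alpha: float | None = None,
               ) -> SiteRateProfile:
    """Posterior-mean per-column substitution rates, mean-normalised to 1.

    ``alpha`` (the gamma shape) is optimised by bounded 1-D maximisation
    of the total log-likelihood when not supplied.  All-gap columns are
    flagged unscored and excluded from the normalisation.
    """
    if tree.leaf_names != set(aln.ids):
        raise ValueError("tree leaves must match alignment ids")
    codes = _column_codes(aln)
    leaf_index = {sid: i for i, sid in enumerate(aln.ids)}
    scored = np.array([np.any(codes[:, j] >= 0) for j in range(aln.width)])

    def loglik(a: float) -> float:
        cat_rates = discrete_gamma_rates(a, n_categories)
        lk = _column_likelihoods(codes, tree, cat_rates, leaf_index)
        col_lk = lk.mean(axis=1)  # uniform category prior
        return float(np.sum(np.log(np.maximum(col_lk[scored], 1e-300))))

    if alpha is None:
        res = minimize_scalar(lambda a: -loglik(a), bounds=(0.05, 50.0),
                              method="bounded",
                              options={"xatol": 1e-3})
        alpha = float(res.x)
    cat_rates = discrete_gamma_rates(alpha, n_categories)
    lk = _column_likelihoods(codes, tree, cat_rates, leaf_index)
    total_ll = float(np.sum(np.log(np.maximum(lk.mean(axis=1)[scored],
                                              1e-300))))
    post = lk / np.maximum(lk.sum(axis=1, keepdims=True), 1e-300)
    rates = post @ cat_rates
    rates = np.where(scored, rates, np.nan)
    mean_rate = float(np.nanmean(rates[scored])) if scored.any() else 1.0
    if mean_rate > 0:
        rates = np.where(scored, rates / mean_rate, np.nan)
    return SiteRateProfile(rates=rates, scored=scored, alpha=alpha,
                           log_likelihood=total_ll)
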