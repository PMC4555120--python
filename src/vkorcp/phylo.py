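"""Likelihood machinery and tree estimation.

The engine is Felsenstein pruning under an empirical amino-acid model with
optional invariant-sites and discrete-gamma rate heterogeneity.  Topologies
come from neighbor joining on pairwise maximum-likelihood distances; branch
lengths are then re-optimized coordinate-wise on the full alignment.
Bootstrap supports resample alignment columns and rebuild the tree per
replicate.  Gaps and 'X' are treated as missing data (partial-likelihood
vector of ones).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .io_formats import Alignment, SequenceRecord
from .substitution import (
    AA_INDEX,
    N_STATES,
    SubstitutionModel,
    discretize_gamma,
    get_model,
)

__all__ = [
    "discretize_gamma",
    "site_log_likelihoods",
    "total_log_likelihood",
    "ml_distance",
    "ml_distance_matrix",
    "nj_tree",
    "optimize_branch_lengths",
    "estimate_rate_params",
    "select_model",
    "ModelFit",
    "bootstrap_supports",
    "distance_nj_builder",
    "root_with_outgroup",
    "prune_to_taxa",
    "tree_splits",
    "robinson_foulds",
]

_MAX_BRANCH = 10.0
_MIN_BRANCH = 1e-9


def encode_sequence(residues: str) -> np.ndarray:
    """Residues to state indices; gaps and 'X' become -1 (missing)."""
    return np.array([AA_INDEX.get(ch, -1) for ch in residues], dtype=np.int64)


# ---------------------------------------------------------------------------
# Pruning engine


class _TreeData:
    """Indexed postorder view of a tree bound to an alignment."""

    def __init__(self, tree: dendropy.Tree, alignment: Alignment):
        self.nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children: list[list[int]] = []
        self.lengths = np.zeros(len(self.nodes))
        self.leaf_state: list[np.ndarray | None] = []
        ids = set(alignment.ids)
        for i, node in enumerate(self.nodes):
            self.children.append([index[id(c)] for c in node.child_nodes()])
            if node.edge.length is not None:
                if node.edge.length < 0:
                    raise ValueError(f"negative branch length {node.edge.length}")
                self.lengths[i] = node.edge.length
            if node.is_leaf():
                label = node.taxon.label if node.taxon else None
                if label not in ids:
                    raise KeyError(f"tree leaf {label!r} has no sequence")
                self.leaf_state.append(encode_sequence(alignment[label].residues))
            else:
                self.leaf_state.append(None)
        self.root = len(self.nodes) - 1
        self.n_sites = alignment.n_columns

    def leaf_partial(self, i: int) -> np.ndarray:
        """(n_sites, 20) one-hot partial; rows of ones for missing states."""
        states = self.leaf_state[i]
        part = np.zeros((self.n_sites, N_STATES))
        obs = states >= 0
        part[obs, states[obs]] = 1.0
        part[~obs, :] = 1.0
        return part


def _category_partials(
    td: _TreeData, model: SubstitutionModel, rate: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Scaled down-pass partials for one rate category.

    Returns per-node (n_sites, 20) partials and (n_sites,) log scale factors.
    """
    pmats = model.transition_matrices(np.maximum(td.lengths * rate, 0.0))
    partials: list[np.ndarray | None] = [None] * len(td.nodes)
    scales: list[np.ndarray | None] = [None] * len(td.nodes)
    for i, kids in enumerate(td.children):
        if not kids:
            partials[i] = td.leaf_partial(i)
            scales[i] = np.zeros(td.n_sites)
            continue
        part = np.ones((td.n_sites, N_STATES))
        scale = np.zeros(td.n_sites)
        for c in kids:
            part *= partials[c] @ pmats[c].T
            scale += scales[c]
        m = part.max(axis=1)
        pos = m > 0
        part[pos] /= m[pos, None]
        with np.errstate(divide="ignore"):
            scale += np.where(pos, np.log(np.where(pos, m, 1.0)), -np.inf)
        partials[i] = part
        scales[i] = scale
    return partials, scales


def _category_site_loglik(
    td: _TreeData, model: SubstitutionModel, rates: np.ndarray
) -> np.ndarray:
    """(n_categories, n_sites) log-likelihood of each column per category."""
    out = np.empty((len(rates), td.n_sites))
    pi = model.frequencies
    for k, rate in enumerate(rates):
        partials, scales = _category_partials(td, model, rate)
        lik = partials[td.root] @ pi
        with np.errstate(divide="ignore"):
            out[k] = np.log(lik) + scales[td.root]
    return out


def _invariant_site_loglik(td: _TreeData, model: SubstitutionModel) -> np.ndarray:
    """Per-column log-probability of the column under a zero-rate site.

    A column contributes pi_s when every non-missing observation equals s,
    the sum of such pi_s when several states remain possible (all-missing
    column), and probability 0 otherwise.
    """
    possible = np.ones((td.n_sites, N_STATES), dtype=bool)
    for i, kids in enumerate(td.children):
        if kids:
            continue
        states = td.leaf_state[i]
        obs = states >= 0
        row = np.zeros((td.n_sites, N_STATES), dtype=bool)
        row[obs, states[obs]] = True
        row[~obs, :] = True
        possible &= row
    lik = possible @ model.frequencies
    with np.errstate(divide="ignore"):
        return np.log(lik)


def _mix_site_loglik(
    cat_logs: np.ndarray, inv_logs: np.ndarray, p_inv: float
) -> np.ndarray:
    """Combine per-category and invariant log-likelihoods into the mixture."""
    n_cat = cat_logs.shape[0]
    gamma_logs = logsumexp(cat_logs, axis=0) - math.log(n_cat)
    if p_inv <= 0:
        return gamma_logs
    with np.errstate(divide="ignore"):
        return np.logaddexp(
            math.log(p_inv) + inv_logs, math.log1p(-p_inv) + gamma_logs
        )


def site_log_likelihoods(
    alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel
) -> np.ndarray:
    """Per-column log-likelihood under the model's +I/+Gamma mixture.

    Returns finite values, or -inf for zero-probability configurations
    (e.g. a non-constant column on a zero-length tree).
    """
    td = _TreeData(tree, alignment)
    cat_logs = _category_site_loglik(td, model, model.category_rates)
    inv_logs = _invariant_site_loglik(td, model)
    return _mix_site_loglik(cat_logs, inv_logs, model.proportion_invariant)


def total_log_likelihood(
    alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel
) -> float:
    return float(site_log_likelihoods(alignment, tree, model).sum())


# ---------------------------------------------------------------------------
# Pairwise ML distances


def _pair_counts(si: np.ndarray, sj: np.ndarray) -> np.ndarray:
    """20x20 counts over columns where both sequences are non-missing."""
    both = (si >= 0) & (sj >= 0)
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (si[both], sj[both]), 1.0)
    return counts


def ml_distance(
    seq_i: SequenceRecord | str,
    seq_j: SequenceRecord | str,
    model: SubstitutionModel,
    t_max: float = _MAX_BRANCH,
) -> float:
    """Maximum-likelihood distance (substitutions/site) between two rows."""
    ri = seq_i.residues if isinstance(seq_i, SequenceRecord) else seq_i
    rj = seq_j.residues if isinstance(seq_j, SequenceRecord) else seq_j
    if len(ri) != len(rj):
        raise ValueError("sequences must have equal (aligned) lengths")
    si, sj = encode_sequence(ri), encode_sequence(rj)
    both = (si >= 0) & (sj >= 0)
    if not both.any():
        raise ValueError("no shared non-missing columns: distance undefined")
    if np.array_equal(si[both], sj[both]):
        return 0.0
    counts = _pair_counts(si, sj)
    pi = model.frequencies
    rates = model.category_rates
    weights = model.category_weights
    p_inv = model.proportion_invariant
    inv = np.diag(pi) * p_inv

    def neg_loglik(t: float) -> float:
        pmats = model.transition_matrices(rates * t)
        mix = np.einsum("k,kij->ij", weights, pmats)
        joint = inv + (1.0 - p_inv) * pi[:, None] * mix
        with np.errstate(divide="ignore"):
            return -float((counts * np.log(joint)).sum())

    res = minimize_scalar(
        neg_loglik, bounds=(_MIN_BRANCH, t_max), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def ml_distance_matrix(
    alignment: Alignment, model: SubstitutionModel
) -> pd.DataFrame:
    """Symmetric matrix of pairwise ML distances, labelled by sequence id."""
    ids = alignment.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_distance(
                alignment.records[i], alignment.records[j], model
            )
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Neighbor joining


def _as_matrix(distance_matrix) -> tuple[list[str], np.ndarray]:
    if isinstance(distance_matrix, pd.DataFrame):
        labels = [str(x) for x in distance_matrix.index]
        mat = distance_matrix.to_numpy(dtype=float)
    else:
        labels, mat = distance_matrix
        labels = [str(x) for x in labels]
        mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    return labels, mat


def nj_tree(distance_matrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic with lexicographic
    tie-breaking and negative branch-length estimates clamped to zero.

    Accepts a labelled pandas DataFrame or a ``(labels, matrix)`` pair;
    returns an unrooted dendropy tree (trifurcation at the seed node).
    """
    labels, mat = _as_matrix(distance_matrix)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    # sort key of a cluster: lexicographically smallest leaf label within it
    keys = list(labels)
    active = list(range(n))
    dist = {(i, j): mat[i, j] for i in range(n) for j in range(n) if i < j}

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for a_idx, i in enumerate(active):
            for j in active[a_idx + 1 :]:
                q = (m - 2) * d(i, j) - r[i] - r[j]
                ki, kj = sorted((keys[i], keys[j]))
                cand = (q, ki, kj)
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        vi = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        vj = d(i, j) - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = max(
                0.5 * (d(i, k) + d(j, k) - d(i, j)), 0.0
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    root = dendropy.Node()
    nodes[i].edge.length = max(0.5 * (d(i, j) + d(i, k) - d(j, k)), 0.0)
    nodes[j].edge.length = max(0.5 * (d(i, j) + d(j, k) - d(i, k)), 0.0)
    nodes[k].edge.length = max(0.5 * (d(i, k) + d(j, k) - d(i, j)), 0.0)
    for idx in (i, j, k):
        root.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Branch-length optimization


def _edge_objective_arrays(
    td: _TreeData,
    model: SubstitutionModel,
    rates: np.ndarray,
    edge_node: int,
):
    """Inside (below) and outside (above) arrays for one edge per category.

    For edge e = (parent, v) the site likelihood in category k is
    ``sum_xy A_k[s, x] P_k(t)[x, y] B_k[s, y]`` where B is the below-partial
    of v and A the outside partial at the parent (equilibrium frequencies
    absorbed at the root).  Returned with accumulated log scale factors.
    """
    parent_of = np.full(len(td.nodes), -1, dtype=int)
    for i, kids in enumerate(td.children):
        for c in kids:
            parent_of[c] = i
    path = []
    node = parent_of[edge_node]
    while node != -1:
        path.append(node)
        node = parent_of[node]
    path.reverse()  # root ... parent(edge_node)

    a_list, b_list, scale_list = [], [], []
    pi = model.frequencies
    for rate in rates:
        pmats = model.transition_matrices(np.maximum(td.lengths * rate, 0.0))
        partials, scales = _category_partials(td, model, rate)
        outside = np.tile(pi, (td.n_sites, 1))
        oscale = np.zeros(td.n_sites)
        for step, node in enumerate(path):
            target = path[step + 1] if step + 1 < len(path) else edge_node
            for c in td.children[node]:
                if c == target:
                    continue
                outside = outside * (partials[c] @ pmats[c].T)
                oscale = oscale + scales[c]
            if target != edge_node:
                outside = outside @ pmats[target]
            m = outside.max(axis=1)
            pos = m > 0
            outside[pos] /= m[pos, None]
            with np.errstate(divide="ignore"):
                oscale += np.where(pos, np.log(np.where(pos, m, 1.0)), -np.inf)
        a_list.append(outside)
        b_list.append(partials[edge_node])
        scale_list.append(oscale + scales[edge_node])
    return a_list, b_list, scale_list


def _edge_loglik(model, rates, a_list, b_list, scale_list, inv_logs, t):
    p_inv = model.proportion_invariant
    cat_logs = np.empty((len(rates), a_list[0].shape[0]))
    for k, rate in enumerate(rates):
        p = model.transition_matrices([t * rate])[0]
        lik = np.einsum("si,ij,sj->s", a_list[k], p, b_list[k])
        with np.errstate(divide="ignore"):
            cat_logs[k] = np.log(lik) + scale_list[k]
    return float(_mix_site_loglik(cat_logs, inv_logs, p_inv).sum())


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_passes: int = 20,
) -> dendropy.Tree:
    """Coordinate-wise ML branch-length optimization on a fixed topology.

    Each branch is optimized by bounded scalar search on [0, 10] with the
    rest of the tree held fixed; passes repeat until the total
    log-likelihood improves by less than ``tol`` or ``max_passes`` is
    reached.  The log-likelihood never decreases across passes.
    """
    tree = tree.clone(depth=1)
    nodes = list(tree.postorder_node_iter())
    td = _TreeData(tree, alignment)
    rates = model.category_rates
    inv_logs = _invariant_site_loglik(td, model)
    p_inv = model.proportion_invariant

    def total() -> float:
        cat_logs = _category_site_loglik(td, model, rates)
        return float(_mix_site_loglik(cat_logs, inv_logs, p_inv).sum())

    prev = total()
    for _ in range(max_passes):
        for idx in range(len(nodes) - 1):  # exclude the seed node's edge
            a, b, s = _edge_objective_arrays(td, model, rates, idx)

            def neg(t: float) -> float:
                return -_edge_loglik(model, rates, a, b, s, inv_logs, t)

            t0 = td.lengths[idx]
            res = minimize_scalar(
                neg, bounds=(0.0, _MAX_BRANCH), method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun > -neg(t0):
                td.lengths[idx] = float(res.x)
                nodes[idx].edge.length = float(res.x)
        cur = total()
        if cur - prev < tol:
            break
        prev = cur
    return tree


# ---------------------------------------------------------------------------
# Rate-parameter estimation and model selection


def estimate_rate_params(
    alignment: Alignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    alpha_bounds: tuple[float, float] = (0.05, 20.0),
    p_inv_bounds: tuple[float, float] = (0.0, 0.95),
) -> tuple[float | None, float | None]:
    """Jointly estimate the gamma shape and invariant proportion by nested
    bounded scalar optimization on a fixed tree.

    Components absent from the model (``alpha``/``p_inv`` set to None) are
    not estimated and returned as None.  An alignment without variable
    columns triggers a warning and a boundary estimate.
    """
    td = _TreeData(tree, alignment)
    inv_logs = _invariant_site_loglik(td, model)
    est_alpha = model.alpha is not None
    est_pinv = model.p_inv is not None
    if np.all(np.isfinite(inv_logs)):
        warnings.warn(
            "alignment has no variable columns; rate estimates lie on the "
            "search boundary",
            stacklevel=2,
        )

    def best_pinv(cat_logs: np.ndarray) -> tuple[float, float]:
        """(p_inv, total log-likelihood) maximizing the mixture."""
        if not est_pinv:
            return 0.0, float(_mix_site_loglik(cat_logs, inv_logs, 0.0).sum())
        res = minimize_scalar(
            lambda p: -float(_mix_site_loglik(cat_logs, inv_logs, p).sum()),
            bounds=p_inv_bounds,
            method="bounded",
            options={"xatol": 1e-6},
        )
        return float(res.x), -float(res.fun)

    if not est_alpha:
        cat_logs = _category_site_loglik(td, model, np.ones(1))
        p, _ = best_pinv(cat_logs)
        return None, (p if est_pinv else None)

    def neg(alpha: float) -> float:
        rates = discretize_gamma(alpha, model.n_cat)
        cat_logs = _category_site_loglik(td, model, rates)
        return -best_pinv(cat_logs)[1]

    res = minimize_scalar(
        neg, bounds=alpha_bounds, method="bounded", options={"xatol": 1e-3}
    )
    alpha = float(res.x)
    cat_logs = _category_site_loglik(td, model, discretize_gamma(alpha, model.n_cat))
    p, _ = best_pinv(cat_logs)
    return alpha, (p if est_pinv else None)


@dataclass(frozen=True)
class ModelFit:
    """One fitted candidate with its information-criterion scores."""

    model: SubstitutionModel
    log_likelihood: float
    k: int
    n: int

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k

    @property
    def aicc(self) -> float:
        if self.n - self.k - 1 <= 0:
            return math.nan
        return self.aic + 2.0 * self.k * (self.k + 1) / (self.n - self.k - 1)

    @property
    def aicc_defined(self) -> bool:
        return self.n - self.k - 1 > 0

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.k * math.log(self.n)

    @property
    def name(self) -> str:
        suffix = ""
        if self.model.p_inv is not None:
            suffix += "+I"
        if self.model.alpha is not None:
            suffix += "+G"
        return self.model.name + suffix


def select_model(
    alignment: Alignment,
    tree: dendropy.Tree,
    candidates,
    criterion: str = "bic",
    opt_passes: int = 3,
) -> list[ModelFit]:
    """Fit each candidate model on the fixed topology and rank by criterion.

    Candidates are names like ``"WAG"``, ``"WAG+G"``, ``"WAG+I+G"`` or
    ready-made :class:`SubstitutionModel` instances.  Fitting alternates
    branch-length optimization and rate-parameter estimation.  ``k`` counts
    the rate-heterogeneity parameters only (branch lengths are shared by
    all candidates on the fixed topology).
    """
    fits: list[ModelFit] = []
    for cand in candidates:
        model = get_model(cand) if isinstance(cand, str) else cand
        fitted = optimize_branch_lengths(
            tree, alignment, model, max_passes=opt_passes
        )
        if model.alpha is not None or model.p_inv is not None:
            alpha, p_inv = estimate_rate_params(alignment, fitted, model)
            model = model.with_rates(alpha=alpha, p_inv=p_inv)
            fitted = optimize_branch_lengths(
                fitted, alignment, model, max_passes=opt_passes
            )
            alpha, p_inv = estimate_rate_params(alignment, fitted, model)
            model = model.with_rates(alpha=alpha, p_inv=p_inv)
        lnl = total_log_likelihood(alignment, fitted, model)
        k = int(model.alpha is not None) + int(model.p_inv is not None)
        fits.append(ModelFit(model, lnl, k, alignment.n_columns))
    key = {"aic": lambda f: f.aic, "aicc": lambda f: f.aicc, "bic": lambda f: f.bic}[
        criterion
    ]
    fits.sort(key=key)
    return fits


def model_fit_table(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "lnL": [f.log_likelihood for f in fits],
            "k": [f.k for f in fits],
            "AIC": [f.aic for f in fits],
            "AICc": [f.aicc for f in fits],
            "BIC": [f.bic for f in fits],
        }
    )


# ---------------------------------------------------------------------------
# Bootstrap, rooting, pruning


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets, normalized to the side
    not containing the lexicographically smallest taxon."""
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = labels[0]
    all_set = frozenset(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted RF distance (symmetric difference of bipartition sets)."""
    return len(tree_splits(t1) ^ tree_splits(t2))


def distance_nj_builder(model: SubstitutionModel):
    """Tree-builder callable: pairwise ML distances followed by NJ."""

    def build(alignment: Alignment) -> dendropy.Tree:
        return nj_tree(ml_distance_matrix(alignment, model))

    return build


def _resample_columns(alignment: Alignment, idx: np.ndarray) -> Alignment:
    arr = np.array([list(r.residues) for r in alignment.records])
    res = arr[:, idx]
    return Alignment(
        [
            SequenceRecord(r.id, "".join(row), r.description)
            for r, row in zip(alignment.records, res)
        ]
    )


def bootstrap_supports(
    alignment: Alignment,
    n_reps: int,
    seed: int,
    tree_builder,
) -> dendropy.Tree:
    """Nonparametric bootstrap supports on the point-estimate tree.

    Columns are resampled with replacement per replicate; the support of
    each internal bipartition of the point tree is the percentage of
    replicate trees containing it, stored as the internal node label (and a
    ``support`` attribute).  Reproducible given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = tree_builder(alignment)
    labels = sorted(l.taxon.label for l in point.leaf_node_iter())
    ref = labels[0]
    all_set = frozenset(labels)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, alignment.n_columns, alignment.n_columns)
        rep_tree = tree_builder(_resample_columns(alignment, idx))
        for split in tree_splits(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    for node in point.postorder_node_iter():
        if node.is_leaf() or node is point.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if not (2 <= len(side) <= len(labels) - 2):
            continue
        support = 100.0 * counts.get(side, 0) / n_reps
        node.label = f"{support:g}"
        node.support = support
    return point


def root_with_outgroup(tree: dendropy.Tree, outgroup_taxon: str) -> dendropy.Tree:
    """Root on the outgroup's pendant branch, splitting it in half."""
    tree = tree.clone(depth=1)
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon and node.taxon.label == outgroup_taxon:
            leaf = node
            break
    if leaf is None:
        raise KeyError(f"outgroup taxon {outgroup_taxon!r} not in tree")
    t = leaf.edge.length if leaf.edge.length is not None else 0.0
    tree.reroot_at_edge(leaf.edge, length1=t / 2.0, length2=t / 2.0)
    tree.is_rooted = True
    return tree


def prune_to_taxa(tree: dendropy.Tree, keep_set) -> dendropy.Tree:
    """Restrict the tree to ``keep_set`` leaves, suppressing degree-2 nodes
    (their branch lengths are summed)."""
    keep = set(keep_set)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    extra = keep - leaves
    if extra:
        raise KeyError(f"taxa not in tree: {sorted(extra)}")
    if len(keep) < 2:
        raise ValueError("keep_set must contain at least 2 taxa")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned
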