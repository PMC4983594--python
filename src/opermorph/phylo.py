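"""Phylogenetic comparative analysis of species-mean shapes.

Species means are matched to the tips of a time-calibrated tree; ancestral
shapes are reconstructed by branch-length-weighted squared-change parsimony
(the maximum-likelihood estimate under Brownian motion), phylogenetic
signal is tested by permuting tip values and comparing minimized tree
lengths, and Pagel's lambda is fitted per ordination axis by maximum
likelihood under a multivariate-normal Brownian model.

Newick parsing is delegated to dendropy; the tree is then flattened to
parent/child index arrays so the comparative statistics operate on plain
arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "PhyloTree",
    "PhyloSignalResult",
    "LambdaFit",
    "read_newick",
    "match_species",
    "ancestral_states",
    "tree_length",
    "phylo_signal_permutation",
    "pagels_lambda",
    "phylomorphospace",
]

_MIN_BRANCH = 1e-8


@dataclass
class PhyloTree:
    """A rooted tree flattened to arrays.

    Nodes 0..n_tips-1 are tips (in ``tip_names`` order); the remaining
    nodes are internal. ``edges`` is an (n_edges, 2) array of
    (parent, child) node indices with ``edge_lengths`` aligned to it.
    Polytomies are allowed; branch lengths are non-negative (zero lengths
    are nudged to a small positive value where division is needed).
    """

    tip_names: list
    edges: np.ndarray
    edge_lengths: np.ndarray
    root: int
    n_nodes: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        tip_names = [t.taxon.label if t.taxon else "" for t in tips]
        if len(set(tip_names)) != len(tip_names):
            raise ValueError("tip names must be unique")
        index = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        next_idx = len(tips)
        for nd in nodes:
            if not nd.is_leaf():
                index[id(nd)] = next_idx
                next_idx += 1
        edges = []
        lengths = []
        for nd in nodes:
            if nd.parent_node is not None:
                length = nd.edge.length if nd.edge.length is not None else 0.0
                if length < 0:
                    raise ValueError("negative branch length")
                edges.append((index[id(nd.parent_node)], index[id(nd)]))
                lengths.append(float(length))
        return cls(
            tip_names=tip_names,
            edges=np.asarray(edges, dtype=int),
            edge_lengths=np.asarray(lengths, dtype=float),
            root=index[id(tree.seed_node)],
            n_nodes=next_idx,
        )

    def prune_to(self, keep_names) -> "PhyloTree":
        """Return a copy pruned to the given tip names (order preserved)."""
        keep = set(keep_names)
        dtree = self.to_dendropy()
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        return PhyloTree.from_dendropy(dtree)

    def to_dendropy(self) -> dendropy.Tree:
        taxon_ns = dendropy.TaxonNamespace(self.tip_names)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, name in enumerate(self.tip_names):
            nodes[i].taxon = taxon_ns.get_taxon(name)
        for (p, c), length in zip(self.edges, self.edge_lengths):
            nodes[p].add_child(nodes[c])
            nodes[c].edge.length = float(length)
        tree = dendropy.Tree(taxon_namespace=taxon_ns)
        tree.seed_node = nodes[self.root]
        return tree

    def tip_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        # edges are in preorder: parent depth known before child
        for (p, c), length in zip(self.edges, self.edge_lengths):
            depth[c] = depth[p] + length
        return depth[: self.n_tips]

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path lengths."""
        n = self.n_tips
        # node -> set of descendant tips, accumulated over edges in reverse
        desc = [set() for _ in range(self.n_nodes)]
        for i in range(n):
            desc[i].add(i)
        for (p, c) in self.edges[::-1]:
            desc[p] |= desc[c]
        C = np.zeros((n, n))
        for (p, c), length in zip(self.edges, self.edge_lengths):
            tips = sorted(desc[c])
            idx = np.asarray(tips, dtype=int)
            C[np.ix_(idx, idx)] += length
        return C


def read_newick(path_or_string) -> PhyloTree:
    """Read a rooted tree with branch lengths from Newick text or a file."""
    text = str(path_or_string)
    if "(" in text and ";" in text:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    else:
        dtree = dendropy.Tree.get(path=text, schema="newick")
    return PhyloTree.from_dendropy(dtree)


def match_species(tree: PhyloTree, species, values, merge_map=None):
    """Match species rows to tree tips, merging and pruning as needed.

    ``merge_map`` maps species names to tip names (many-to-one allowed);
    species mapping to the same tip have their rows averaged. Tips absent
    from the data are pruned (and reported); species without a tip raise.
    Returns ``(pruned_tree, tip_values, report)`` with ``tip_values`` in
    the pruned tree's tip order.
    """
    merge_map = merge_map or {}
    values = np.asarray(values, float)
    species = list(species)
    rows_by_tip: dict[str, list[int]] = {}
    for i, sp in enumerate(species):
        tip = merge_map.get(sp, sp)
        rows_by_tip.setdefault(tip, []).append(i)

    tips = set(tree.tip_names)
    unmatched = sorted(t for t in rows_by_tip if t not in tips)
    if unmatched:
        raise ValueError(f"species without a tree tip (after merge): {unmatched}")
    dropped = sorted(t for t in tips if t not in rows_by_tip)
    pruned = tree.prune_to(rows_by_tip.keys()) if dropped else tree
    tip_values = np.stack(
        [values[rows_by_tip[name]].mean(axis=0) for name in pruned.tip_names]
    )
    merged = {t: [species[i] for i in rows] for t, rows in rows_by_tip.items() if len(rows) > 1}
    report = {"dropped_tips": dropped, "merged": merged}
    return pruned, tip_values, report


# ---------------------------------------------------------------------------
# Ancestral states and tree length (weighted squared-change parsimony)
# ---------------------------------------------------------------------------

def _laplacian_blocks(tree: PhyloTree):
    """Weighted graph Laplacian split into tip/internal blocks.

    Edge weight = 1/branch_length (zero lengths nudged, with warning).
    Returns (L_II, L_IT, L_TT, internal_index) where internal nodes are
    numbered n_tips..n_nodes-1.
    """
    lengths = tree.edge_lengths.copy()
    if np.any(lengths <= 0):
        warnings.warn("zero-length branch treated as 1e-8", stacklevel=3)
        lengths = np.maximum(lengths, _MIN_BRANCH)
    w = 1.0 / lengths
    n = tree.n_nodes
    L = np.zeros((n, n))
    for (p, c), wt in zip(tree.edges, w):
        L[p, p] += wt
        L[c, c] += wt
        L[p, c] -= wt
        L[c, p] -= wt
    t = tree.n_tips
    return L[t:, t:], L[t:, :t], L[:t, :t]


def ancestral_states(tree: PhyloTree, tip_values) -> np.ndarray:
    """Internal-node values minimizing sum ||z_p - z_c||^2 / branch_length.

    The branch-length-weighted squared-change parsimony solution, which is
    also the ML reconstruction under Brownian motion. Returns an
    (n_internal, d) array, rows in internal-node index order
    (node n_tips + i).
    """
    Z = np.atleast_2d(np.asarray(tip_values, float))
    if Z.shape[0] != tree.n_tips:
        Z = Z.T
    if Z.shape[0] != tree.n_tips:
        raise ValueError("tip_values must have one row per tip")
    L_II, L_IT, _ = _laplacian_blocks(tree)
    return np.linalg.solve(L_II, -L_IT @ Z)


def tree_length(tree: PhyloTree, tip_values, node_values) -> float:
    """Sum of squared changes over branches, weighted by 1/branch_length."""
    Z = np.atleast_2d(np.asarray(tip_values, float))
    if Z.shape[0] != tree.n_tips:
        Z = Z.T
    node_values = np.atleast_2d(np.asarray(node_values, float))
    n_internal = tree.n_nodes - tree.n_tips
    if node_values.shape[0] != n_internal:
        raise ValueError("node_values must have one row per internal node")
    all_vals = np.vstack([Z, node_values])
    lengths = np.maximum(tree.edge_lengths, _MIN_BRANCH)
    total = 0.0
    for (p, c), length in zip(tree.edges, lengths):
        diff = all_vals[p] - all_vals[c]
        total += float(diff @ diff) / length
    return total


def min_tree_length_form(tree: PhyloTree) -> np.ndarray:
    """Quadratic form S with min-over-ancestors tree length = tr(Z' S Z).

    The Schur complement of the Laplacian's internal block: evaluating
    ``sum(Z * (S @ Z))`` gives the minimized weighted squared-change tree
    length directly, which makes permutation tests cheap.
    """
    L_II, L_IT, L_TT = _laplacian_blocks(tree)
    S = L_TT - L_IT.T @ np.linalg.solve(L_II, L_IT)
    return 0.5 * (S + S.T)


@dataclass
class PhyloSignalResult:
    """Permutation test of phylogenetic signal via minimized tree length."""

    observed_tree_length: float
    permuted_lengths: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None


def phylo_signal_permutation(
    tree: PhyloTree,
    tip_values,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Test phylogenetic signal by permuting tip values across tips.

    The statistic is the minimized branch-length-weighted squared-change
    tree length; each round permutes the rows of ``tip_values`` uniformly
    at random and re-minimizes. P = (#{permuted <= observed} + 1)/n_perm,
    clamped to 1 — the proportion of permutations giving an equal or
    shorter tree length, with the observed arrangement counted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    Z = np.atleast_2d(np.asarray(tip_values, float))
    if Z.shape[0] != tree.n_tips:
        Z = Z.T
    S = min_tree_length_form(tree)
    observed = float(np.sum(Z * (S @ Z)))
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm - 1)
    for r in range(n_perm - 1):
        Zp = Z[rng.permutation(tree.n_tips)]
        permuted[r] = float(np.sum(Zp * (S @ Zp)))
    count = int(np.sum(permuted <= observed + 1e-12 * max(1.0, observed)))
    p = min(1.0, (count + 1) / n_perm)
    return PhyloSignalResult(
        observed_tree_length=observed,
        permuted_lengths=permuted,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass
class LambdaFit:
    """ML fit of Pagel's lambda for one univariate trait on a tree.

    lambda scales the off-diagonal (shared-history) entries of the
    Brownian covariance: 1 recovers Brownian motion, 0 phylogenetic
    independence. Likelihood-ratio P values against both boundaries are
    reported (chi-square with 1 df; conservative at the boundary).
    """

    lambda_hat: float
    sigma2_hat: float
    mu_hat: float
    loglik_at: dict = field(default_factory=dict)
    p_vs_zero: float = float("nan")
    p_vs_one: float = float("nan")


def _lambda_loglik(lam: float, C: np.ndarray, x: np.ndarray):
    """Profile log-likelihood of N(mu 1, sigma^2 C(lambda)) at lambda."""
    s = x.size
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    try:
        cho = np.linalg.cholesky(Cl)
    except np.linalg.LinAlgError:
        Cl = Cl + np.eye(s) * 1e-10
        warnings.warn("covariance jittered for positive definiteness", stacklevel=3)
        cho = np.linalg.cholesky(Cl)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho))))
    ones = np.ones(s)
    Ci_x = np.linalg.solve(Cl, x)
    Ci_1 = np.linalg.solve(Cl, ones)
    mu = float(ones @ Ci_x) / float(ones @ Ci_1)
    r = x - mu
    sigma2 = float(r @ np.linalg.solve(Cl, r)) / s
    if sigma2 <= 0:
        return -np.inf, mu, 0.0
    ll = -0.5 * (s * np.log(2.0 * np.pi * sigma2) + logdet + s)
    return ll, mu, sigma2


def pagels_lambda(tree: PhyloTree, trait, *, tol: float = 1e-6) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda on [0, 1] for one trait.

    The Brownian covariance C holds shared root-to-MRCA path lengths;
    C(lambda) multiplies off-diagonals by lambda. mu and sigma^2 have
    closed forms given lambda; lambda is found by bounded scalar search.
    """
    x = np.asarray(trait, float).ravel()
    if x.size != tree.n_tips:
        raise ValueError("trait length must equal number of tips")
    if x.size < 4:
        raise ValueError("need at least 4 tips")
    if np.allclose(x, x[0]):
        raise ValueError("constant trait: lambda undefined")
    C = tree.vcv()
    if np.any(np.diag(C) <= 0):
        raise ValueError("tree must have positive root-to-tip depths")

    def neg_ll(lam):
        return -_lambda_loglik(lam, C, x)[0]

    res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    lam_hat = float(res.x)
    # snap to boundary when the optimum is flat against it
    for boundary in (0.0, 1.0):
        if abs(lam_hat - boundary) < 10 * tol and neg_ll(boundary) <= res.fun + 1e-10:
            lam_hat = boundary
    ll_hat, mu_hat, sigma2_hat = _lambda_loglik(lam_hat, C, x)
    ll_0 = _lambda_loglik(0.0, C, x)[0]
    ll_1 = _lambda_loglik(1.0, C, x)[0]
    lr0 = max(0.0, 2.0 * (ll_hat - ll_0))
    lr1 = max(0.0, 2.0 * (ll_hat - ll_1))
    return LambdaFit(
        lambda_hat=lam_hat,
        sigma2_hat=sigma2_hat,
        mu_hat=mu_hat,
        loglik_at={lam_hat: ll_hat, 0.0: ll_0, 1.0: ll_1},
        p_vs_zero=float(stats.chi2.sf(lr0, 1)) if lr0 > 0 else 1.0,
        p_vs_one=float(stats.chi2.sf(lr1, 1)) if lr1 > 0 else 1.0,
    )


# ---------------------------------------------------------------------------
# Phylomorphospace
# ---------------------------------------------------------------------------

def phylomorphospace(tree: PhyloTree, species_scores, ancestral=None):
    """Node coordinates plus branch segments for a phylomorphospace plot.

    Tips take their score coordinates; internal nodes take the supplied
    (or freshly reconstructed) ancestral states. Purely a data product:
    returns ``(nodes, segments)`` where ``nodes`` is a list of
    (node_id, is_tip, coordinates) and ``segments`` a list of
    (parent_id, child_id) pairs, one per branch.
    """
    Z = np.atleast_2d(np.asarray(species_scores, float))
    if Z.shape[0] != tree.n_tips:
        Z = Z.T
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 score dimensions")
    if ancestral is None:
        ancestral = ancestral_states(tree, Z)
    ancestral = np.atleast_2d(np.asarray(ancestral, float))
    coords = np.vstack([Z, ancestral])
    nodes = [
        (i, i < tree.n_tips, coords[i]) for i in range(tree.n_nodes)
    ]
    segments = [(int(p), int(c)) for p, c in tree.edges]
    return nodes, segments
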