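"""Fixed-topology likelihood engine for alignments under empirical models.

The model family is the classic workhorse of phylogenomics: a reversible
continuous-time Markov chain built from an empirical exchangeability matrix
(LG, WAG, MtZoa, or Poisson/equal-rates), equilibrium frequencies either
from the matrix or estimated from the data ("+F"), and discrete-gamma
among-site rate heterogeneity ("+G", category means, equal weights).

Per-site log-likelihoods come from Felsenstein pruning with per-node
scaling, so deep trees and small likelihoods do not underflow.  Branch
lengths on a fixed topology are optimized by coordinate ascent with a
bounded scalar search per branch; the topology itself is never searched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from . import _aa_data
from .alphabets import AMINO_ACID, Alphabet
from .errors import OptimizationError
from .seqio import Alignment, PartitionMap, PhyloTree, SiteLnLMatrix, TreeNode

BRANCH_LENGTH_BOUNDS = (1e-8, 20.0)

_AA_PRESETS = {
    "LG": (_aa_data.LG_EXCH_LOWER, _aa_data.LG_FREQS),
    "WAG": (_aa_data.WAG_EXCH_LOWER, _aa_data.WAG_FREQS),
    "MTZOA": (_aa_data.MTZOA_EXCH_LOWER, _aa_data.MTZOA_FREQS),
}


def _lower_triangle_to_symmetric(values, k: int) -> np.ndarray:
    """Column-wise lower-triangle exchangeabilities -> full symmetric matrix."""
    mat = np.zeros((k, k))
    it = iter(values)
    for j in range(k - 1):
        for i in range(j + 1, k):
            mat[i, j] = mat[j, i] = next(it)
    return mat


def discrete_gamma_rates(alpha: float, n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight discrete-gamma category rates (category means).

    The Gamma(alpha, alpha) density (mean 1) is cut at its n-quantiles and
    each category rate is the conditional mean within its bin, so the
    weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if n_categories < 1:
        raise ValueError(f"need at least one rate category, got {n_categories}")
    n = n_categories
    if n == 1:
        return np.array([1.0]), np.array([1.0])
    cuts = gamma_dist.ppf(np.arange(1, n) / n, a=alpha, scale=1.0 / alpha)
    # E[X; X<=t] for Gamma(a, rate a) equals the CDF of Gamma(a+1, rate a)
    upper_mass = gamma_dist.cdf(cuts, a=alpha + 1, scale=1.0 / alpha)
    upper_mass = np.concatenate([[0.0], upper_mass, [1.0]])
    rates = (upper_mass[1:] - upper_mass[:-1]) * n
    weights = np.full(n, 1.0 / n)
    return rates, weights


def empirical_frequencies(alignment: Alignment, pseudo: float | None = None) -> np.ndarray:
    """Observed residue frequencies ("+F"), with zero counts replaced by a
    pseudo-frequency (default 1/(2 * total residues)) and renormalized."""
    idx = alignment.state_indices()
    observed = idx[idx >= 0]
    if observed.size == 0:
        raise ValueError("alignment has no unambiguous residues")
    counts = np.bincount(observed, minlength=alignment.alphabet.k).astype(float)
    total = counts.sum()
    freqs = counts / total
    if pseudo is None:
        pseudo = 1.0 / (2.0 * total)
    freqs[freqs == 0.0] = pseudo
    return freqs / freqs.sum()


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible CTMC: exchangeabilities x frequencies, +G rate mixture.

    The rate matrix is normalized to one expected substitution per unit
    branch length at the stationary distribution.
    """

    exchangeabilities: np.ndarray  # (k, k) symmetric, zero diagonal
    frequencies: np.ndarray  # simplex of length k
    alphabet: Alphabet
    gamma_shape: float | None = None  # None = rate homogeneity
    n_rate_categories: int = 4
    name: str = "custom"
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        exch = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        k = self.alphabet.k
        if exch.shape != (k, k):
            raise ValueError(f"exchangeability matrix must be {k}x{k}")
        if not np.allclose(exch, exch.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(exch < 0) or np.any(np.diag(exch) != 0):
            raise ValueError("exchangeabilities must be non-negative with zero diagonal")
        if pi.shape != (k,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be a strictly positive simplex")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        object.__setattr__(self, "exchangeabilities", exch)
        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "_eig", self._decompose())

    def _decompose(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pi = self.frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()  # expected substitutions per unit time
        q = q / mu
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        eigvals, eigvecs = np.linalg.eigh((sym + sym.T) / 2.0)
        left = eigvecs.T * sqrt_pi[None, :]
        right = eigvecs / sqrt_pi[:, None]
        return eigvals, right, left

    @property
    def k(self) -> int:
        return self.alphabet.k

    def rate_matrix(self) -> np.ndarray:
        eigvals, right, left = self._eig
        return (right * eigvals[None, :]) @ left

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        if self.gamma_shape is None:
            return np.array([1.0]), np.array([1.0])
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    def with_frequencies(self, freqs: np.ndarray) -> "SubstitutionModel":
        return replace(self, frequencies=np.asarray(freqs, float), _eig=None)

    def with_gamma_shape(self, alpha: float) -> "SubstitutionModel":
        return replace(self, gamma_shape=alpha, _eig=None)

    @classmethod
    def named(
        cls,
        name: str,
        gamma_shape: float | None = None,
        n_rate_categories: int = 4,
        frequencies: np.ndarray | None = None,
    ) -> "SubstitutionModel":
        """Named empirical amino-acid presets: LG, WAG, MtZoa, Poisson.

        ``frequencies`` overrides the matrix's own frequencies (the "+F"
        option when passed :func:`empirical_frequencies` output).
        """
        key = name.upper().replace("-", "")
        if key in _AA_PRESETS:
            lower, freqs = _AA_PRESETS[key]
            exch = _lower_triangle_to_symmetric(lower, 20)
            pi = np.asarray(freqs, float)
            pi = pi / pi.sum()
            alphabet = AMINO_ACID
        elif key == "POISSON":
            alphabet = AMINO_ACID
            exch = np.ones((20, 20)) - np.eye(20)
            pi = np.full(20, 1 / 20)
        else:
            raise ValueError(f"unknown model preset {name!r}")
        if frequencies is not None:
            pi = np.asarray(frequencies, float)
        return cls(exch, pi, alphabet, gamma_shape, n_rate_categories, name=name)

    @classmethod
    def poisson(cls, alphabet: Alphabet, gamma_shape: float | None = None,
                n_rate_categories: int = 4) -> "SubstitutionModel":
        """Equal-rates equal-frequency model on any alphabet (tests, toys)."""
        k = alphabet.k
        return cls(
            np.ones((k, k)) - np.eye(k),
            np.full(k, 1.0 / k),
            alphabet,
            gamma_shape,
            n_rate_categories,
            name=f"Poisson-{k}",
        )


def transition_probabilities(
    model: SubstitutionModel, branch_length: float, rate: float = 1.0
) -> np.ndarray:
    """P(t) = exp(Q * t * rate) via the cached symmetric eigendecomposition."""
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    eigvals, right, left = model._eig
    p = (right * np.exp(eigvals * branch_length * rate)[None, :]) @ left
    np.clip(p, 0.0, None, out=p)
    return p


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _leaf_index_matrix(alignment: Alignment, leaves: list[str]) -> np.ndarray:
    taxa_index = {t: i for i, t in enumerate(alignment.taxa)}
    missing = [lf for lf in leaves if lf not in taxa_index]
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {missing}")
    idx = alignment.state_indices()
    return idx[[taxa_index[lf] for lf in leaves], :]


def _pattern_site_lnl(
    patterns: np.ndarray, tree: PhyloTree, model: SubstitutionModel
) -> np.ndarray:
    """Log-likelihood of each site pattern (columns of ``patterns``, ordered
    as the tree's postorder leaves)."""
    k = model.k
    n_pat = patterns.shape[1]
    pi = model.frequencies
    rates, weights = model.category_rates()
    leaves = [n for n in tree.root.postorder() if n.is_leaf]
    leaf_pos = {id(n): i for i, n in enumerate(leaves)}

    # Leaf conditionals are rate-independent: unit vector, or ones if ambiguous.
    leaf_partials: dict[int, np.ndarray] = {}
    for node in leaves:
        states = patterns[leaf_pos[id(node)]]
        part = np.zeros((k, n_pat))
        amb = states < 0
        part[:, amb] = 1.0
        obs = ~amb
        part[states[obs], np.nonzero(obs)[0]] = 1.0
        leaf_partials[id(node)] = part

    per_cat = np.empty((len(rates), n_pat))
    for ci, rate in enumerate(rates):
        log_scale = np.zeros(n_pat)
        partials: dict[int, np.ndarray] = {}
        for node in tree.root.postorder():
            if node.is_leaf:
                partials[id(node)] = leaf_partials[id(node)]
                continue
            part = np.ones((k, n_pat))
            for child in node.children:
                p = transition_probabilities(model, child.length, rate)
                part *= p @ partials.pop(id(child))
            scale = part.max(axis=0)
            nonzero = scale > 0
            part[:, nonzero] /= scale[nonzero]
            with np.errstate(divide="ignore"):
                log_scale += np.where(nonzero, np.log(scale, where=nonzero,
                                                      out=np.zeros_like(scale)),
                                      -np.inf)
            partials[id(node)] = part
        root_part = partials[id(tree.root)]
        site_lik = pi @ root_part
        with np.errstate(divide="ignore"):
            per_cat[ci] = np.log(site_lik) + log_scale
    return logsumexp(per_cat, axis=0, b=weights[:, None])


def site_log_likelihoods(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> np.ndarray:
    """Per-site natural-log likelihoods by pruning, mixture-averaged over
    gamma categories; identical site patterns are computed once."""
    leaves = [n.label for n in tree.root.postorder() if n.is_leaf]
    idx = _leaf_index_matrix(alignment, leaves)
    patterns, inverse = np.unique(idx, axis=1, return_inverse=True)
    lnl_pat = _pattern_site_lnl(patterns, tree, model)
    return lnl_pat[inverse]


def tree_log_likelihood(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> float:
    """Total lnL = sum of per-site lnLs (0.0 for a zero-column alignment)."""
    if alignment.n_sites == 0:
        return 0.0
    return float(site_log_likelihoods(alignment, tree, model).sum())


def _compressed_total_lnl(patterns, counts, tree, model) -> float:
    return float(np.dot(_pattern_site_lnl(patterns, tree, model), counts))


def optimize_branch_lengths(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> tuple[PhyloTree, float]:
    """Maximize lnL over branch lengths on the fixed topology.

    Coordinate ascent: each branch in turn is optimized by a bounded Brent
    search on [1e-8, 20] while the others are held fixed; rounds repeat
    until the total lnL improves by less than ``tol``.  Returns the
    optimized tree (a copy) and its total lnL, which is never below the
    input tree's.
    """
    tree = tree.copy()
    leaves = [n.label for n in tree.root.postorder() if n.is_leaf]
    idx = _leaf_index_matrix(alignment, leaves)
    patterns, _, counts = np.unique(idx, axis=1, return_inverse=True, return_counts=True)

    current = _compressed_total_lnl(patterns, counts, tree, model)
    if not np.isfinite(current):
        raise OptimizationError(
            f"starting lnL is {current}; check branch lengths and data "
            "(zero-length branches with conflicting states give -inf)"
        )
    branches = [n for n in tree.root.postorder() if n.parent is not None]
    lo, hi = BRANCH_LENGTH_BOUNDS
    for _ in range(max_rounds):
        round_start = current
        for node in branches:
            original = node.length

            def neg_lnl(t: float) -> float:
                node.length = t
                return -_compressed_total_lnl(patterns, counts, tree, model)

            res = minimize_scalar(neg_lnl, bounds=(lo, hi), method="bounded",
                                  options={"xatol": max(tol, 1e-8)})
            if -res.fun > current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = original
        if current - round_start < tol:
            break
    return tree, current


def optimize_gamma_shape(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.02, 100.0),
) -> tuple[SubstitutionModel, float]:
    """Maximize lnL over the gamma shape with the tree held fixed."""
    leaves = [n.label for n in tree.root.postorder() if n.is_leaf]
    idx = _leaf_index_matrix(alignment, leaves)
    patterns, _, counts = np.unique(idx, axis=1, return_inverse=True, return_counts=True)

    def neg_lnl(alpha: float) -> float:
        return -_compressed_total_lnl(patterns, counts, tree,
                                      model.with_gamma_shape(alpha))

    res = minimize_scalar(neg_lnl, bounds=bounds, method="bounded")
    return model.with_gamma_shape(float(res.x)), -float(res.fun)


# ---------------------------------------------------------------------------
# Multi-tree / partitioned evaluation
# ---------------------------------------------------------------------------

def site_lnl_matrix(
    alignment: Alignment,
    trees: dict[str, PhyloTree],
    model: SubstitutionModel,
    optimize: bool = True,
    tol: float = 1e-4,
) -> SiteLnLMatrix:
    """Evaluate every candidate tree against the alignment.

    With ``optimize=True`` each tree's branch lengths are first fitted by
    :func:`optimize_branch_lengths` (the topology stays fixed), mirroring
    constrained ML evaluation; per-site lnLs of the fitted trees form the
    returned matrix.
    """
    ids = list(trees)
    rows = []
    for tree_id in ids:
        tree = trees[tree_id]
        if optimize:
            tree, _ = optimize_branch_lengths(alignment, tree, model, tol=tol)
        rows.append(site_log_likelihoods(alignment, tree, model))
    return SiteLnLMatrix(ids, np.vstack(rows))


def partitioned_site_log_likelihoods(
    alignment: Alignment,
    tree: PhyloTree,
    models: dict[str, SubstitutionModel],
    partition_map: PartitionMap,
) -> np.ndarray:
    """Per-site lnL with a per-locus model, branch lengths linked across
    partitions; sites keep alignment order."""
    out = np.empty(alignment.n_sites)
    for name, sl in partition_map.slices():
        if name not in models:
            raise ValueError(f"no model for partition {name!r}")
        sub = alignment.subset_columns(sl.start, sl.stop)
        out[sl] = site_log_likelihoods(sub, tree, models[name])
    return out


__all__ = [
    "SubstitutionModel",
    "discrete_gamma_rates",
    "empirical_frequencies",
    "transition_probabilities",
    "site_log_likelihoods",
    "tree_log_likelihood",
    "optimize_branch_lengths",
    "optimize_gamma_shape",
    "site_lnl_matrix",
    "partitioned_site_log_likelihoods",
    "BRANCH_LENGTH_BOUNDS",
]
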