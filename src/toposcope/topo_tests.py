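"""Likelihood-based tree-topology hypothesis tests.

Given per-site log-likelihoods of a candidate tree set, this module
provides the classic discrimination toolkit:

* the likelihood-ratio statistic comparing each alternative against a
  designated null tree (two sign/scale conventions, see
  :func:`delta_lnl`);
* the RELL bootstrap (resampling estimated log-likelihoods: sites are
  resampled, trees are never re-optimized);
* the approximately unbiased (AU) test via the multiscale bootstrap,
  fitting a signed distance and boundary curvature to normal-quantile
  transformed bootstrap proportions across resample sizes;
* posterior probabilities over the candidate set from the BIC
  approximation (a penalized log-likelihood softmax).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .phylo_likelihood import SubstitutionModel, site_lnl_matrix
from .seqio import Alignment, PhyloTree, SiteLnLMatrix

DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


def delta_lnl(lnl_null: float, lnl_alt: float, convention: str = "table") -> float:
    """Likelihood-ratio statistic of an alternative tree against the null.

    Two conventions are in circulation and they disagree in both sign and
    scale; both are offered rather than silently picking one:

    * ``"equation"``: 2 * (lnL_alt - lnL_null) — the textbook likelihood
      ratio on the deviance scale (negative when the null fits better).
    * ``"table"``: lnL_null - lnL_alt — the raw log-likelihood difference
      with a positive value meaning the null fits better, the convention
      that matches published comparison tables built this way.
    """
    if not (math.isfinite(lnl_null) and math.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    if convention == "equation":
        return 2.0 * (lnl_alt - lnl_null)
    if convention == "table":
        return lnl_null - lnl_alt
    raise ValueError(f"unknown convention {convention!r}")


def rell_bootstrap(
    site_lnl: SiteLnLMatrix,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """RELL bootstrap replicate totals, shape (n_trees, n_boot).

    Each replicate draws ``n_sites`` site indices with replacement and the
    same indices are applied to every tree (paired resampling — the
    variance of interest is of between-tree differences).
    """
    if site_lnl.n_sites == 0:
        raise ValueError("empty site-lnL matrix")
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = site_lnl.n_sites
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)  # (B, n)
    return site_lnl.values @ counts.T.astype(np.float64)  # (trees, B)


def _argmax_with_random_ties(totals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Column-wise argmax of (trees, B), ties broken uniformly at random."""
    is_max = totals == totals.max(axis=0, keepdims=True)
    noise = rng.random(totals.shape)
    return np.argmax(np.where(is_max, noise, -1.0), axis=0)


def au_test(
    site_lnl: SiteLnLMatrix,
    scales: tuple[float, ...] = DEFAULT_AU_SCALES,
    n_boot_per_scale: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Approximately unbiased test p-value per candidate tree.

    For each scale r, ceil(r * n_sites) sites are resampled per replicate
    and each tree's bootstrap proportion (BP) of having the maximum total
    is recorded.  BPs are mapped through the inverse standard normal and
    the model  z(r) = d*sqrt(r) + c/sqrt(r)  is fitted by weighted least
    squares (binomial variance weights); p_AU = 1 - Phi(d - c).

    Degenerate cases: a tree winning (losing) every replicate at every
    scale has no curvature information and its p is reported saturated at
    1 - 1/(2B) (respectively 1/(2B)); with a single scale the naive
    bootstrap proportion itself is returned.
    """
    if site_lnl.n_trees < 2:
        raise ValueError("AU test needs at least two candidate trees")
    scales = tuple(float(r) for r in scales)
    if any(r <= 0 for r in scales):
        raise ValueError("scales must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = site_lnl.n_sites
    n_trees = site_lnl.n_trees
    B = n_boot_per_scale

    bp = np.empty((n_trees, len(scales)))
    for si, r in enumerate(scales):
        m = max(1, math.ceil(r * n))
        counts = rng.multinomial(m, np.full(n, 1.0 / n), size=B)
        totals = site_lnl.values @ counts.T.astype(np.float64)
        winners = _argmax_with_random_ties(totals, rng)
        bp[:, si] = np.bincount(winners, minlength=n_trees) / B

    eps = 1.0 / (2.0 * B)
    sqrt_r = np.sqrt(np.asarray(scales))
    design = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    p_values: dict[str, float] = {}
    for ti, tree_id in enumerate(site_lnl.tree_ids):
        raw = bp[ti]
        if np.all(raw >= 1.0 - eps):
            p_values[tree_id] = 1.0 - eps
            continue
        if np.all(raw <= eps):
            p_values[tree_id] = eps
            continue
        bp_t = np.clip(raw, eps, 1.0 - eps)
        if len(scales) == 1:
            p_values[tree_id] = float(bp_t[0])
            continue
        z = norm.ppf(1.0 - bp_t)
        weights = B * norm.pdf(z) ** 2 / (bp_t * (1.0 - bp_t))
        w_sqrt = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(design * w_sqrt[:, None], z * w_sqrt, rcond=None)
        d, c = coef
        p_values[tree_id] = float(np.clip(1.0 - norm.cdf(d - c), 0.0, 1.0))
    return p_values


def bic_posteriors(
    tree_lnls: np.ndarray | list[float],
    penalty_terms: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Posterior probabilities over candidate trees via the BIC approximation.

    posterior_i proportional to exp(lnL_i - penalty_i / 2), computed with a
    max shift (log-sum-exp) so widely separated lnLs stay finite.  Equal
    penalties — same parameter dimension, same model across trees — cancel
    and the result is a pure log-likelihood softmax.
    """
    lnls = np.asarray(tree_lnls, dtype=float)
    if lnls.size < 1:
        raise ValueError("need at least one tree")
    if not np.all(np.isfinite(lnls)):
        raise ValueError("log-likelihoods must be finite")
    if penalty_terms is None:
        penalties = np.zeros_like(lnls)
    else:
        penalties = np.asarray(penalty_terms, dtype=float)
        if penalties.shape != lnls.shape:
            raise ValueError("penalties must match the number of trees")
    scores = lnls - penalties / 2.0
    scores = scores - scores.max()  # max shift keeps precision at huge |lnL|
    return np.exp(scores - logsumexp(scores))


@dataclass(frozen=True)
class TopologyTestResult:
    """Per-tree outcome of the full topology-testing stage."""

    tree_ids: tuple[str, ...]
    total_lnl: dict[str, float]
    delta_lnl_table: dict[str, float]  # lnL(null) - lnL(alt)
    delta_lnl_equation: dict[str, float]  # 2 * (lnL(alt) - lnL(null))
    au_p: dict[str, float]
    bic_posterior: dict[str, float]
    null_id: str
    n_boot: int
    scales: tuple[float, ...]
    seed: int | None

    def __post_init__(self) -> None:
        if abs(sum(self.bic_posterior.values()) - 1.0) > 1e-10:
            raise ValueError("BIC posteriors must sum to 1")
        if any(not 0.0 <= p <= 1.0 for p in self.au_p.values()):
            raise ValueError("AU p-values must lie in [0, 1]")
        if abs(self.delta_lnl_table[self.null_id]) > 1e-9:
            raise ValueError("the null tree's delta lnL against itself must be 0")


def topology_tests_from_matrix(
    site_lnl: SiteLnLMatrix,
    null_id: str,
    n_boot: int = 10_000,
    scales: tuple[float, ...] = DEFAULT_AU_SCALES,
    seed: int | None = None,
) -> TopologyTestResult:
    """Run delta-lnL (both conventions), AU, and BIC on a site-lnL matrix."""
    if null_id not in site_lnl.tree_ids:
        raise ValueError(f"null tree {null_id!r} not in candidate set")
    totals = site_lnl.totals()
    lnl = dict(zip(site_lnl.tree_ids, map(float, totals)))
    au = au_test(site_lnl, scales=scales, n_boot_per_scale=n_boot, seed=seed)
    bic = bic_posteriors(totals)
    return TopologyTestResult(
        tree_ids=tuple(site_lnl.tree_ids),
        total_lnl=lnl,
        delta_lnl_table={
            t: delta_lnl(lnl[null_id], lnl[t], "table") for t in site_lnl.tree_ids
        },
        delta_lnl_equation={
            t: delta_lnl(lnl[null_id], lnl[t], "equation") for t in site_lnl.tree_ids
        },
        au_p=au,
        bic_posterior=dict(zip(site_lnl.tree_ids, map(float, bic))),
        null_id=null_id,
        n_boot=n_boot,
        scales=tuple(scales),
        seed=seed if isinstance(seed, int) else None,
    )


def run_topology_tests(
    alignment: Alignment,
    trees: dict[str, PhyloTree],
    model: SubstitutionModel,
    null_id: str,
    n_boot: int = 10_000,
    scales: tuple[float, ...] = DEFAULT_AU_SCALES,
    seed: int | None = None,
    optimize: bool = True,
    brlen_tol: float = 1e-4,
) -> tuple[TopologyTestResult, SiteLnLMatrix]:
    """Full pipeline: fit branch lengths per candidate topology, compute
    per-site lnLs, then run every test against the designated null."""
    matrix = site_lnl_matrix(alignment, trees, model, optimize=optimize, tol=brlen_tol)
    result = topology_tests_from_matrix(
        matrix, null_id, n_boot=n_boot, scales=scales, seed=seed
    )
    return result, matrix


__all__ = [
    "DEFAULT_AU_SCALES",
    "TopologyTestResult",
    "delta_lnl",
    "rell_bootstrap",
    "au_test",
    "bic_posteriors",
    "topology_tests_from_matrix",
    "run_topology_tests",
]
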