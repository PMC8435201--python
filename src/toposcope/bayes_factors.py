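"""Marginal likelihoods from MCMC traces and Bayes-factor tree comparison.

The marginal likelihood of a fixed-topology Bayesian analysis is estimated
by the harmonic mean of the sampled posterior likelihoods — computed
entirely in log space — and, for stability diagnostics, by a moving
version over a sliding window whose size grows with the chain (window =
ceil(fraction * current cycle), step 1).  The harmonic-mean estimator is
known to be upwardly biased and high-variance; the moving series makes its
(in)stability visible.

Bayes factors comparing tree T1 against null T0 are computed from the two
estimated log marginals.  The default transformation is

    BF10 = 2 * ln(|lnm1 - lnm0|) * sign(lnm1 - lnm0),

i.e. the log is taken of the *difference of log marginals* with the sign
carried separately.  This is not the textbook 2 * (lnm1 - lnm0); both are
available (``formula="log-of-difference"`` vs ``formula="standard"``) and
an explicit direction label is always attached, because the two scales are
easy to confuse in the literature this module is designed to interoperate
with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .errors import FormatError

PathLike = Union[str, Path]


@dataclass(frozen=True)
class MCMCTrace:
    """Post-burn-in, thinned log-likelihood samples of one MCMC chain."""

    chain_id: str
    cycles: np.ndarray  # original cycle indices of the retained samples
    lnl: np.ndarray
    burn_in: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=np.int64)
        lnl = np.asarray(self.lnl, dtype=np.float64)
        if cycles.shape != lnl.shape or lnl.ndim != 1:
            raise ValueError("cycles and lnl must be matching 1-D arrays")
        if lnl.size < 1:
            raise ValueError("trace must retain at least one post-burn-in sample")
        if np.any(np.diff(cycles) <= 0):
            raise ValueError("cycle indices must be strictly increasing")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "lnl", lnl)

    @property
    def n_samples(self) -> int:
        return self.lnl.size


def read_trace(
    path: PathLike,
    lnl_column: str | int = "lnL",
    burn_in: int = 0,
    thin: int = 1,
    chain_id: str | None = None,
) -> MCMCTrace:
    """Read one chain from a tab-separated trace file with a header row
    (the tabular dialect of common Bayesian phylogenetics programs).

    ``lnl_column`` may be a header name or a 0-based column index;
    ``burn_in`` rows are dropped from the front, then every ``thin``-th
    remaining row is kept.
    """
    if thin < 1:
        raise ValueError("thin must be >= 1")
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"trace file {path} has no sample rows")
    header = lines[0].split("\t")
    if isinstance(lnl_column, int):
        col = lnl_column
        if not 0 <= col < len(header):
            raise FormatError(f"column index {col} outside header of width {len(header)}")
    else:
        try:
            col = header.index(lnl_column)
        except ValueError as exc:
            raise FormatError(
                f"no column {lnl_column!r} in trace header {header}"
            ) from exc
    rows = lines[1:]
    if burn_in >= len(rows):
        raise ValueError(f"burn-in {burn_in} >= {len(rows)} sample rows")
    kept = rows[burn_in:][::thin]
    cycles = np.arange(burn_in, len(rows))[::thin]
    try:
        lnl = np.array([float(r.split("\t")[col]) for r in kept])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"non-numeric or missing value in column {col}") from exc
    return MCMCTrace(
        chain_id=chain_id or Path(path).stem,
        cycles=cycles,
        lnl=lnl,
        burn_in=burn_in,
        thin=thin,
    )


def pool_chains(traces: Sequence[MCMCTrace]) -> np.ndarray:
    """Concatenate post-burn-in samples of several chains, in chain order."""
    if not traces:
        raise ValueError("need at least one trace")
    return np.concatenate([t.lnl for t in traces])


def log_harmonic_mean(lnl_samples: np.ndarray | Sequence[float]) -> float:
    """Log of the harmonic mean of likelihoods, from log-likelihood samples.

    Computed as -(logsumexp(-lnL) - ln n): no likelihood is ever
    exponentiated on the natural scale, so traces spanning thousands of
    log units are handled without overflow.
    """
    x = np.asarray(lnl_samples, dtype=np.float64)
    if x.size < 1:
        raise ValueError("need at least one sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("all lnL samples must be finite")
    return float(-(logsumexp(-x) - math.log(x.size)))


@dataclass(frozen=True)
class MarginalLikelihoodEstimate:
    """Point and moving-window harmonic-mean log marginal likelihood."""

    point: float
    series: np.ndarray  # moving estimates, one per emitted cycle
    series_cycles: np.ndarray  # 1-based cycle index of each emitted estimate
    window_sizes: np.ndarray
    n_samples: int
    window_fraction: float

    def __post_init__(self) -> None:
        if self.series.size and self.series_cycles[-1] == self.n_samples:
            assert self.point == self.series[-1]


def moving_harmonic_mean(
    trace: MCMCTrace | np.ndarray | Sequence[float],
    window_fraction: float = 0.33,
    step: int = 1,
) -> MarginalLikelihoodEstimate:
    """Moving harmonic-mean marginal-likelihood series over a growing window.

    At (1-based) cycle i of the post-burn-in sample sequence the estimate
    is the log harmonic mean of the most recent ceil(window_fraction * i)
    samples (minimum 1); estimates are emitted every ``step`` cycles, and
    the final cycle's value is the reported point estimate.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must be in (0, 1]")
    if step < 1:
        raise ValueError("step must be >= 1")
    x = trace.lnl if isinstance(trace, MCMCTrace) else np.asarray(trace, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one sample")
    n = x.size
    cycles = list(range(1, n + 1, step))
    if cycles[-1] != n:
        cycles.append(n)  # the point estimate always uses the full chain length
    windows = np.array([max(1, math.ceil(window_fraction * i)) for i in cycles])
    series = np.array(
        [log_harmonic_mean(x[i - w:i]) for i, w in zip(cycles, windows)]
    )
    return MarginalLikelihoodEstimate(
        point=float(series[-1]),
        series=series,
        series_cycles=np.asarray(cycles),
        window_sizes=windows,
        n_samples=n,
        window_fraction=window_fraction,
    )


EVIDENCE_BANDS = (
    (2.0, "none"),
    (6.0, "some"),
    (10.0, "strong"),
    (math.inf, "very strong"),
)


def classify_evidence(bf: float) -> str:
    """Evidence category from |BF|: <2 none, 2-6 some, 6-10 strong, >=10
    very strong (the modified Jeffreys bands; sign is direction only)."""
    if not math.isfinite(bf):
        raise ValueError("Bayes factor must be finite")
    magnitude = abs(bf)
    for upper, label in EVIDENCE_BANDS:
        if magnitude < upper:
            return label
    return "very strong"


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    marginal_t1: float
    marginal_t0: float
    formula: str
    direction: str  # "favors T1" / "favors T0" / "equal"
    category: str

    def __post_init__(self) -> None:
        if self.category != classify_evidence(self.bf10):
            raise ValueError("evidence category inconsistent with BF value")


def bayes_factor(
    marginal_t1: float,
    marginal_t0: float,
    formula: str = "log-of-difference",
    model_label: str | None = None,
) -> BayesFactorResult:
    """Bayes factor BF10 from two estimated log marginal likelihoods.

    ``formula="log-of-difference"`` (default): with d = lnm1 - lnm0,
    BF10 = 2*ln(d) for d > 0 and -2*ln(-d) for d < 0; d = 0 is reported as
    BF 0 / category "none" with a warning rather than an exception.
    ``formula="standard"``: BF10 = 2 * d, the conventional scale.

    Because the sign conventions attached to these numbers are
    inconsistent in practice, an explicit ``direction`` label derived from
    the marginals themselves is always included.
    """
    if not (math.isfinite(marginal_t1) and math.isfinite(marginal_t0)):
        raise ValueError("marginal log-likelihoods must be finite")
    d = marginal_t1 - marginal_t0
    if formula == "log-of-difference":
        if d == 0.0:
            warnings.warn(
                "equal marginal likelihoods: log-of-difference BF undefined, "
                "reporting 0",
                stacklevel=2,
            )
            bf = 0.0
        else:
            bf = math.copysign(2.0 * math.log(abs(d)), d)
    elif formula == "standard":
        bf = 2.0 * d
    else:
        raise ValueError(f"unknown formula {formula!r}")
    direction = "equal" if d == 0 else ("favors T1" if d > 0 else "favors T0")
    return BayesFactorResult(
        bf10=bf,
        marginal_t1=marginal_t1,
        marginal_t0=marginal_t0,
        formula=formula,
        direction=direction,
        category=classify_evidence(bf),
    )


def compare_tree_models(
    traces_t1: Sequence[MCMCTrace],
    traces_t0: Sequence[MCMCTrace],
    window_fraction: float = 0.33,
    formula: str = "log-of-difference",
) -> tuple[BayesFactorResult, MarginalLikelihoodEstimate, MarginalLikelihoodEstimate]:
    """Pool each hypothesis's chains, estimate both marginals by the moving
    harmonic mean, and return the Bayes factor with both estimates."""
    est_t1 = moving_harmonic_mean(pool_chains(traces_t1), window_fraction)
    est_t0 = moving_harmonic_mean(pool_chains(traces_t0), window_fraction)
    return bayes_factor(est_t1.point, est_t0.point, formula), est_t1, est_t0


__all__ = [
    "MCMCTrace",
    "MarginalLikelihoodEstimate",
    "BayesFactorResult",
    "read_trace",
    "pool_chains",
    "log_harmonic_mean",
    "moving_harmonic_mean",
    "bayes_factor",
    "classify_evidence",
    "compare_tree_models",
    "EVIDENCE_BANDS",
]
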