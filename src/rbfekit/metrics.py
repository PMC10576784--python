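"""Error and rank metrics for relative binding free energies.

Pairwise errors compare predicted and experimental ddGs over all
N(N-1)/2 ligand pairs, computed from per-ligand dGs and therefore
independent of graph topology and of any additive offset between the two
dG sets.  Edgewise errors restrict the comparison to the edges a campaign
actually simulated.  Collections of comparisons are aggregated with
compound- (or edge-) count weights,

    RMSE = sqrt( sum_i w_i RMSE_i^2 / sum_i w_i ),

with linear weighted means for MUE, R^2 and Kendall's tau, and percentile
bootstrap confidence intervals obtained by resampling whole comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    RbfeError,
    UndefinedCorrelationError,
)
from .graph import PerturbationGraph


@dataclass
class ComparisonMetrics:
    """Metrics of one assay-vs-assay or prediction-vs-experiment comparison."""

    label: str
    n_compounds: int
    pairwise_rmse: float
    pairwise_mue: float
    r_squared: Optional[float] = None
    kendall_tau: Optional[float] = None
    n_edges: Optional[int] = None
    edgewise_rmse: Optional[float] = None
    edgewise_mue: Optional[float] = None

    def to_dict(self) -> Dict[str, object]:
        return {k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class AggregateResult:
    """A weighted point estimate with a 95% percentile-bootstrap interval."""

    point: float
    ci_low: float
    ci_high: float
    weights_used: str
    m: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise RbfeError("bootstrap interval has ci_low > ci_high")

    def to_dict(self) -> Dict[str, object]:
        return {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "weights_used": self.weights_used,
            "m": self.m,
        }


def pairwise_error_set(
    pred_dg: Sequence[float], exp_dg: Sequence[float]
) -> np.ndarray:
    """Signed errors (pred_i - pred_j) - (exp_i - exp_j) over all i < j.

    Invariant to additive offsets on either dG list; N compounds give
    N(N-1)/2 errors.
    """
    pred = np.asarray(pred_dg, dtype=float)
    exp = np.asarray(exp_dg, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise RbfeError(f"paired 1-D dG lists required, got {pred.shape}, {exp.shape}")
    n = pred.size
    if n < 2:
        raise InsufficientDataError("pairwise errors need at least 2 compounds")
    delta = (pred[:, None] - pred[None, :]) - (exp[:, None] - exp[None, :])
    iu = np.triu_indices(n, k=1)
    return delta[iu]


def edgewise_error_set(
    g: PerturbationGraph, exp_dg: Optional[Dict[str, float]] = None
) -> np.ndarray:
    """Signed per-edge errors ddg_pred - (exp dG_a - exp dG_b)."""
    exp = g.exp_dg if exp_dg is None else exp_dg
    missing = sorted(n for n in g.nodes if n not in exp)
    if missing:
        raise RbfeError(f"experimental dG missing for compounds: {missing}")
    return np.asarray([e.ddg - (exp[e.a] - exp[e.b]) for e in g.edges])


def rmse(errors: Sequence[float]) -> float:
    """Root-mean-square of a set of signed errors."""
    e = np.asarray(errors, dtype=float)
    if e.size < 1:
        raise InsufficientDataError("rmse of an empty error set")
    return float(np.sqrt(np.mean(e**2)))


def mue(errors: Sequence[float]) -> float:
    """Mean unsigned (absolute) error."""
    e = np.asarray(errors, dtype=float)
    if e.size < 1:
        raise InsufficientDataError("mue of an empty error set")
    return float(np.mean(np.abs(e)))


def _check_weights(values: np.ndarray, weights: np.ndarray) -> None:
    if values.shape[-1] != weights.shape[-1] or values.shape[-1] < 1:
        raise RbfeError("values and weights must be equal-length and nonempty")
    if np.any(weights <= 0):
        raise RbfeError("weights must be strictly positive")


def weighted_rmse(rmse_list: Sequence[float], weight_list: Sequence[float]):
    """Weighted quadratic mean of per-comparison RMSEs.

    Accepts stacked 2-D inputs (replicates in rows) and reduces along the
    last axis, so it can score bootstrap resamples in one call.
    """
    v = np.asarray(rmse_list, dtype=float)
    w = np.asarray(weight_list, dtype=float)
    _check_weights(v, w)
    out = np.sqrt(np.sum(w * v**2, axis=-1) / np.sum(w, axis=-1))
    return float(out) if np.ndim(out) == 0 else out


def weighted_mean(values: Sequence[float], weights: Sequence[float]):
    """Weighted arithmetic mean; used for MUE, R^2 and Kendall's tau.

    NaN entries (comparisons where a correlation is undefined) are excluded
    together with their weights.  Reduces along the last axis like
    :func:`weighted_rmse`.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    _check_weights(v, w)
    ok = ~np.isnan(v)
    num = np.sum(np.where(ok, w * v, 0.0), axis=-1)
    den = np.sum(np.where(ok, w, 0.0), axis=-1)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if np.ndim(out) == 0 else out


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation (offset- and scale-invariant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("r_squared needs >= 2 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall rank correlation, tau-b variant (tie-corrected)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("kendall_tau needs >= 2 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def bootstrap_ci(
    values: Sequence[float],
    weights: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], np.ndarray],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    weights_used: str = "compounds",
) -> AggregateResult:
    """Percentile-bootstrap 95% CI of a weighted aggregate statistic.

    The M comparisons are resampled with replacement as whole units, each
    carrying its weight; ``statistic(values, weights)`` must reduce along
    the last axis (as :func:`weighted_rmse` and :func:`weighted_mean` do)
    so all replicates are evaluated vectorized.  Deterministic for a fixed
    ``seed``.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size < 1:
        raise InsufficientDataError("bootstrap over an empty comparison list")
    _check_weights(v, w)
    if n_boot < 1:
        raise RbfeError("n_boot must be >= 1")
    point = float(statistic(v, w))
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    reps = np.asarray(statistic(v[idx], w[idx]), dtype=float)
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return AggregateResult(point, float(lo), float(hi), weights_used, int(v.size))
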