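"""Symmetrized pairwise-error samples and heavy-tailed error models.

Pairwise ddG errors have an arbitrary sign per unordered ligand pair, so the
error sample is symmetrized by concatenating it with its negation — using
all N(N-1) ordered pairs — which forces an exactly zero mean.  The sample is
then summarized by (i) the fraction of errors within/beyond fixed kcal/mol
thresholds, (ii) a zero-mean Gaussian whose sd is the sample RMS, and
(iii) a zero-location Student-t fitted by maximum likelihood with free
degrees of freedom nu and scale.  Smaller nu means fatter tails; survey
error distributions typically need nu well below the effectively-Gaussian
regime, i.e. large errors occur more often than a Gaussian with the same
RMSE predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import FitFailureError, InsufficientDataError, RbfeError

#: Degrees of freedom above which the fitted t is reported "effectively Gaussian".
EFFECTIVELY_GAUSSIAN_DF = 100.0

#: Hard cap on the fitted degrees of freedom.
DF_CAP = 1000.0


class TFit(NamedTuple):
    df: float
    scale: float
    effectively_gaussian: bool


@dataclass(frozen=True)
class ErrorDistributionFit:
    """Summary of a symmetrized pairwise error sample."""

    n_pairs: int  # symmetrized count, N(N-1) summed over series
    gaussian_sd: float
    t_df: float
    t_scale: float
    frac_within_1: float
    frac_beyond_2: float

    def to_dict(self):
        return dict(self.__dict__)


def symmetrize(signed_pair_errors: Sequence[float]) -> np.ndarray:
    """Concatenate the unordered-pair error set with its negation."""
    e = np.asarray(signed_pair_errors, dtype=float)
    if e.size < 1:
        raise InsufficientDataError("cannot symmetrize an empty error set")
    return np.concatenate([e, -e])


def fraction_within(sym_errors: Sequence[float], threshold: float) -> float:
    """Fraction of errors with |e| <= threshold (kcal/mol)."""
    if not threshold > 0:
        raise RbfeError(f"threshold must be > 0, got {threshold}")
    e = np.asarray(sym_errors, dtype=float)
    if e.size < 1:
        raise InsufficientDataError("empty error set")
    return float(np.mean(np.abs(e) <= threshold))


def fraction_beyond(sym_errors: Sequence[float], threshold: float) -> float:
    """Fraction of errors with |e| > threshold (kcal/mol)."""
    return 1.0 - fraction_within(sym_errors, threshold)


def gaussian_expected_within(sd: float, threshold: float) -> float:
    """P(|E| <= threshold) for E ~ N(0, sd^2): 2*Phi(threshold/sd) - 1."""
    if not (sd > 0 and threshold > 0):
        raise RbfeError("sd and threshold must be > 0")
    return float(2.0 * stats.norm.cdf(threshold / sd) - 1.0)


def t_expected_within(df: float, scale: float, threshold: float) -> float:
    """P(|E| <= threshold) for a zero-location Student-t(df, scale)."""
    if not (df > 0 and scale > 0 and threshold > 0):
        raise RbfeError("df, scale and threshold must be > 0")
    return float(2.0 * stats.t.cdf(threshold / scale, df) - 1.0)


def t_negative_log_likelihood(
    sym_errors: np.ndarray, df: float, scale: float
) -> float:
    """Negative log-likelihood of a zero-location Student-t."""
    return float(-np.sum(stats.t.logpdf(sym_errors, df, loc=0.0, scale=scale)))


def fit_t_df(sym_errors: Sequence[float]) -> TFit:
    """Maximum-likelihood Student-t fit with location fixed at 0.

    Symmetrization makes a free location redundant, so only the degrees of
    freedom nu and the scale are optimized (Nelder-Mead on log-parameters).
    nu is capped at 1000 and flagged effectively Gaussian above 100.
    """
    e = np.asarray(sym_errors, dtype=float)
    if e.size < 10:
        raise InsufficientDataError("t fit needs at least 10 samples")
    sd = float(np.std(e))
    if sd == 0:
        raise FitFailureError("zero-variance sample")

    log_df_hi = math.log(10 * DF_CAP)

    def nll(params: np.ndarray) -> float:
        # clamp instead of walling off: the likelihood is flat in df beyond
        # the Gaussian limit, so the simplex collapses there cleanly
        log_df = min(params[0], log_df_hi)
        log_scale = float(np.clip(params[1], math.log(sd) - 10, math.log(sd) + 10))
        return t_negative_log_likelihood(e, math.exp(log_df), math.exp(log_scale))

    res = optimize.minimize(
        nll,
        x0=np.array([math.log(10.0), math.log(sd)]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 5000},
    )
    if not res.success:
        raise FitFailureError(f"t MLE did not converge: {res.message}")
    df = min(math.exp(min(res.x[0], log_df_hi)), DF_CAP)
    scale = math.exp(res.x[1])
    return TFit(df, scale, df > EFFECTIVELY_GAUSSIAN_DF)


def fit_error_distribution(signed_pair_errors: Sequence[float]) -> ErrorDistributionFit:
    """Symmetrize a pooled unordered-pair error set and fit both models.

    ``gaussian_sd`` is the sample RMS (the zero-mean Gaussian MLE);
    thresholds 1 and 2 kcal/mol follow the conventional accuracy bands.
    """
    sym = symmetrize(signed_pair_errors)
    tfit = fit_t_df(sym)
    return ErrorDistributionFit(
        n_pairs=int(sym.size),
        gaussian_sd=float(np.sqrt(np.mean(sym**2))),
        t_df=tfit.df,
        t_scale=tfit.scale,
        frac_within_1=fraction_within(sym, 1.0),
        frac_beyond_2=fraction_beyond(sym, 2.0),
    )
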