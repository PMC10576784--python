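"""The experimental-reproducibility survey pipeline.

Two assays that measured the same congeneric series are compared by (i)
matching compounds by id, (ii) removing detection-limit-censored values,
(iii) converting each assay's affinities to absolute dGs, and (iv) scoring
the two dG sets with offset-invariant pairwise error metrics and rank
statistics.  Many such assay comparisons are then aggregated with
compound-count weights and bootstrap confidence intervals, overall and
split by assay category (binding vs functional), and complemented by the
RMS of reported repeat-measurement standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .affinity import (
    DEFAULT_THERMO,
    AffinityMeasurement,
    Qualifier,
    ThermoConstants,
    abs_dg,
)
from .exceptions import (
    InsufficientDataError,
    InsufficientOverlapError,
    RbfeError,
    UndefinedCorrelationError,
)
from .metrics import (
    AggregateResult,
    ComparisonMetrics,
    bootstrap_ci,
    kendall_tau,
    mue,
    pairwise_error_set,
    r_squared,
    rmse,
    weighted_mean,
    weighted_rmse,
)

CATEGORIES = ("binding", "functional")
CENSOR_POLICIES = ("qualifier_only", "qualifier_plus_plateau")


@dataclass
class AssaySeries:
    """One assay's measurements over a congeneric series."""

    assay_id: str
    category: str
    measurements: List[AffinityMeasurement]
    source_tag: str = "public"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RbfeError(
                f"assay {self.assay_id}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )
        ids = [m.compound_id for m in self.measurements]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise RbfeError(f"assay {self.assay_id}: duplicate compound ids {dupes}")

    def by_id(self) -> Dict[str, AffinityMeasurement]:
        return {m.compound_id: m for m in self.measurements}


@dataclass
class AssayComparison:
    """The result of comparing two assay series on their shared compounds."""

    series_a: AssaySeries
    series_b: AssaySeries
    shared_compounds: List[str]
    comparison_category: str
    metrics: ComparisonMetrics
    removal_log: List[Dict[str, str]] = field(default_factory=list)


MeasurementPair = Tuple[AffinityMeasurement, AffinityMeasurement]


def comparison_category(cat_a: str, cat_b: str) -> str:
    """Order-independent category label, e.g. 'binding_vs_functional'."""
    for c in (cat_a, cat_b):
        if c not in CATEGORIES:
            raise RbfeError(f"unknown assay category {c!r}")
    lo, hi = sorted((cat_a, cat_b))
    return f"{lo}_vs_{hi}"


def match_compounds(a: AssaySeries, b: AssaySeries) -> List[MeasurementPair]:
    """Inner-join the two series on compound id, sorted by id."""
    ma, mb = a.by_id(), b.by_id()
    shared = sorted(ma.keys() & mb.keys())
    if len(shared) < 2:
        raise InsufficientOverlapError(
            f"assays {a.assay_id} and {b.assay_id} share only "
            f"{len(shared)} compounds; need >= 2"
        )
    return [(ma[c], mb[c]) for c in shared]


def censor_filter(
    pairs: Sequence[MeasurementPair],
    policy: str = "qualifier_only",
    plateau_k: int = 3,
) -> Tuple[List[MeasurementPair], List[Dict[str, str]]]:
    """Drop detection-limit-censored pairs; log every removal with a reason.

    ``qualifier_only`` drops a pair when either measurement carries a
    lt/gt qualifier.  ``qualifier_plus_plateau`` additionally drops pairs
    sitting at one assay's extreme value when at least ``plateau_k``
    compounds share that exact extreme — the horizontal/vertical lines a
    detection limit produces in a scatter plot even when qualifiers were
    not reported.
    """
    if policy not in CENSOR_POLICIES:
        raise RbfeError(f"censoring policy must be one of {CENSOR_POLICIES}")
    kept: List[MeasurementPair] = []
    log: List[Dict[str, str]] = []

    plateau_values: List[set] = [set(), set()]
    if policy == "qualifier_plus_plateau" and pairs:
        for side in (0, 1):
            vals = [p[side].value for p in pairs]
            for extreme in (min(vals), max(vals)):
                if vals.count(extreme) >= plateau_k:
                    plateau_values[side].add(extreme)

    for pair in pairs:
        reason = None
        for side, m in enumerate(pair):
            if m.qualifier is not Qualifier.EQ:
                reason = f"qualifier_{m.qualifier.value}_side_{'ab'[side]}"
                break
            if m.value in plateau_values[side]:
                reason = f"plateau_side_{'ab'[side]}"
                break
        if reason is None:
            kept.append(pair)
        else:
            log.append({"compound_id": pair[0].compound_id, "reason": reason})
    return kept, log


def compare_assays(
    a: AssaySeries,
    b: AssaySeries,
    policy: str = "qualifier_only",
    plateau_k: int = 3,
    thermo: ThermoConstants = DEFAULT_THERMO,
) -> AssayComparison:
    """Full comparison: match, censor, convert to dGs, score.

    Pairwise RMSE/MUE need >= 2 shared compounds after censoring; R^2 and
    Kendall's tau need >= 3 and are left unset below that (or when an
    assay's values are all identical).  Mixed measure types across the two
    assays are allowed: all metrics are offset-invariant, so the unknown
    additive constant of IC50-derived dGs drops out.
    """
    pairs = match_compounds(a, b)
    pairs, removal_log = censor_filter(pairs, policy=policy, plateau_k=plateau_k)
    if len(pairs) < 2:
        raise InsufficientOverlapError(
            f"assays {a.assay_id} and {b.assay_id}: only {len(pairs)} usable "
            "pairs remain after censoring; need >= 2"
        )
    shared = [p[0].compound_id for p in pairs]
    dg_a = [abs_dg(p[0], thermo) for p in pairs]
    dg_b = [abs_dg(p[1], thermo) for p in pairs]

    errors = pairwise_error_set(dg_a, dg_b)
    r2 = tau = None
    if len(pairs) >= 3:
        try:
            r2 = r_squared(dg_a, dg_b)
            tau = kendall_tau(dg_a, dg_b)
        except UndefinedCorrelationError:
            pass
    m = ComparisonMetrics(
        label=f"{a.assay_id}_vs_{b.assay_id}",
        n_compounds=len(pairs),
        pairwise_rmse=rmse(errors),
        pairwise_mue=mue(errors),
        r_squared=r2,
        kendall_tau=tau,
    )
    return AssayComparison(
        series_a=a,
        series_b=b,
        shared_compounds=shared,
        comparison_category=comparison_category(a.category, b.category),
        metrics=m,
        removal_log=removal_log,
    )


def _aggregate_block(
    comparisons: Sequence[AssayComparison],
    n_boot: int,
    rng: np.random.Generator,
) -> Dict[str, AggregateResult]:
    w = [c.metrics.n_compounds for c in comparisons]
    rmses = [c.metrics.pairwise_rmse for c in comparisons]
    mues = [c.metrics.pairwise_mue for c in comparisons]
    r2s = [np.nan if c.metrics.r_squared is None else c.metrics.r_squared
           for c in comparisons]
    taus = [np.nan if c.metrics.kendall_tau is None else c.metrics.kendall_tau
            for c in comparisons]
    out = {
        "pairwise_rmse": bootstrap_ci(rmses, w, weighted_rmse, n_boot, rng=rng),
        "pairwise_mue": bootstrap_ci(mues, w, weighted_mean, n_boot, rng=rng),
    }
    if not all(np.isnan(r2s)):
        out["r_squared"] = bootstrap_ci(r2s, w, weighted_mean, n_boot, rng=rng)
        out["kendall_tau"] = bootstrap_ci(taus, w, weighted_mean, n_boot, rng=rng)
    return out


def survey_aggregate(
    comparisons: Sequence[AssayComparison],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> Dict[str, object]:
    """Weighted aggregates with bootstrap CIs, overall and per category.

    Weights are shared-compound counts; RMSE aggregates quadratically, the
    other metrics linearly.  The bootstrap resamples whole assay
    comparisons so that no single large comparison dominates the interval.
    """
    if len(comparisons) < 1:
        raise InsufficientDataError("survey_aggregate needs >= 1 comparison")
    rng = np.random.default_rng(seed)
    result: Dict[str, object] = {
        "n_comparisons": len(comparisons),
        "overall": _aggregate_block(comparisons, n_boot, rng),
        "by_category": {},
    }
    for cat in sorted({c.comparison_category for c in comparisons}):
        members = [c for c in comparisons if c.comparison_category == cat]
        result["by_category"][cat] = {
            "n_comparisons": len(members),
            **_aggregate_block(members, n_boot, rng),
        }
    return result


def repeatability_rms(
    per_assay_sds: Mapping[str, Sequence[float]],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> AggregateResult:
    """RMS of reported repeat-measurement SDs, bootstrapped over assays.

    Pools every reported per-compound standard deviation (kcal/mol) and
    takes the root-mean-square; the CI resamples whole assay groups with
    replacement, matching how heterogeneous assay panels are summarized.
    """
    groups = [np.asarray(v, dtype=float) for v in per_assay_sds.values() if len(v)]
    if not groups:
        raise InsufficientDataError("repeatability_rms needs >= 1 assay group")
    if any(np.any(g < 0) for g in groups):
        raise RbfeError("reported standard deviations must be >= 0")
    pooled = np.concatenate(groups)
    point = float(np.sqrt(np.mean(pooled**2)))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        take = rng.integers(0, len(groups), size=len(groups))
        sample = np.concatenate([groups[j] for j in take])
        reps[i] = np.sqrt(np.mean(sample**2))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return AggregateResult(point, float(lo), float(hi), "assays", len(groups))


def pooled_pairwise_errors(
    comparisons: Sequence[AssayComparison],
    thermo: ThermoConstants = DEFAULT_THERMO,
) -> np.ndarray:
    """Concatenate every comparison's unordered-pair error set (unweighted).

    Each usable ligand pair counts once; the pooled sample feeds the
    error-distribution fit.
    """
    if not comparisons:
        raise InsufficientDataError("no comparisons to pool")
    chunks = []
    for c in comparisons:
        ma, mb = c.series_a.by_id(), c.series_b.by_id()
        dg_a = [abs_dg(ma[i], thermo) for i in c.shared_compounds]
        dg_b = [abs_dg(mb[i], thermo) for i in c.shared_compounds]
        chunks.append(pairwise_error_set(dg_a, dg_b))
    return np.concatenate(chunks)
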