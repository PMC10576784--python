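# Methods

This note documents the models, conventions, default conditions and
numerical choices behind `rbfekit`, and what the synthetic-data tests do and
do not demonstrate about real assay data.

## Free-energy conversions and sign conventions

A measured affinity X (a Kd, Ki or IC50 in molar units) maps to an absolute
binding free energy `ΔG = kT ln X` with `k = 1.9872e-3 kcal/mol/K` and
`T = 300 K` by default.  Both constants are configurable, but the familiar
scalar conversions (1 pKi unit ↔ 1.37 kcal/mol; 0.3 pKi ↔ 0.41 kcal/mol)
hold only at 300 K, so that is the fixed default.  The relative free energy
between ligands a and b is defined as

    ΔΔG_ab = −kT ln(X_b / X_a) = ΔG_a − ΔG_b .

This is the reverse of the also-common `ΔG_b − ΔG_a` convention; the
definition is applied consistently everywhere (perturbation-graph edges
(a, b) predict `ΔG_a − ΔG_b`), and every reported metric is built from
pairwise *differences* or symmetrized samples, so no result depends on the
choice.

IC50-derived ΔGs carry an unknown assay-specific additive constant (the
ratio of two IC50s, not the IC50 itself, is assumed equal to the Ki ratio;
no Cheng–Prusoff correction is attempted because substrate/enzyme
concentrations are out of scope).  `MeasureType.absolute_scale_known` flags
this; all shipped metrics are offset-invariant, so mixed Kd/Ki/IC50
comparisons are allowed at the series level while single-measurement
cross-type ratios require an explicit opt-in (`allow_mixed_types`).

## Graph-consistent node ΔGs

Raw edge predictions violate cycle closure.  A consistent set of per-ligand
ΔGs is the minimizer of

    Σ_e w_e (dg_a − dg_b − ddg_e)² ,

solved through the pseudo-inverse of the weighted normal matrix `AᵀWA`
built on the edge–node incidence matrix A.  Choices:

- **Gauge.** The pseudo-inverse solution is orthogonal to the constant null
  vector of a connected graph, i.e. mean-centered; this keeps the output
  symmetric under node relabeling (pinning one node would not).
- **Weights.** `w_e = 1/se_e²` when *every* edge reports a positive standard
  error; any gap falls back to unit weights with a warning, rather than
  silently mixing weighted and unweighted scales.
- **Duplicate edges** are independent observations (their information adds);
  they are not pre-averaged.
- **Node standard errors** come from the diagonal of the pseudo-inverse —
  directly in the weighted case, scaled by the residual variance with
  `E − (N − 1)` degrees of freedom in the unit-weight case (a cycle-free
  unweighted graph therefore reports zero SEs: it has no redundancy to
  estimate noise from).
- Disconnected graphs are rejected with the component list; within a
  connected graph the normal matrix has rank N−1 and the solve cannot be
  singular.

Pairwise errors are always computed from these inferred node ΔGs; edgewise
errors always use the raw edge predictions, so the two metrics answer
different questions (global ranking quality vs accuracy on the similar-pair
transformations actually simulated).

## Metrics and aggregation

- **Pairwise error set**: `(pred_i − pred_j) − (exp_i − exp_j)` over all
  i < j; invariant to additive offsets on either side.
- **R²** is the squared Pearson correlation, *not* 1 − SS_res/SS_tot about
  the identity line, because inter-assay ΔG offsets are real and irrelevant
  to ranking; reports label it "R² (squared Pearson)".
- **Kendall τ** is the tie-corrected τ-b: affinities rounded to assay
  precision produce ties and τ-b handles them without an arbitrary
  tie-breaking rule.
- **Aggregation** over M comparisons/graphs uses weights equal to the
  number of compounds (pairwise metrics, R², τ) or edges (edgewise
  metrics): quadratic for RMSE (`sqrt(Σ wᵢ RMSEᵢ²/Σ wᵢ)`), linear for MUE,
  R², τ.  The quadratic form makes category-level aggregates recompose
  exactly into the overall aggregate when paired with their summed weights.
- **Bootstrap**: percentile method, 2.5/97.5 percentiles, default
  n_boot = 10,000, mandatory seed in the CLI.  The resampling unit is the
  whole comparison or graph — never individual compounds — with its weight
  traveling along, so one large comparison can dominate the point estimate
  but not the interval.  Statistics passed to `bootstrap_ci` must reduce
  along the last axis, which lets all replicates be evaluated in one
  vectorized call.  At M ≈ 20 the percentile method is known to slightly
  undercover (realized coverage ≈ 93–94% for nominal 95%); this is an
  accepted property of the method, not corrected by BCa or studentization.

## Censoring

Detection limits appear in data either as explicit `<`/`>` qualifiers or as
many compounds stacked at one assay's extreme value (the vertical/horizontal
lines visible in scatter plots).  `censor_filter` formalizes both:
`qualifier_only` drops pairs where either side is qualified, and
`qualifier_plus_plateau` additionally drops pairs sitting at an assay's
minimum or maximum when at least `plateau_k = 3` compounds share that exact
extreme.  The plateau threshold is heuristic and config-exposed; every drop
is logged with compound id and reason so the reduction in pair count is
auditable.

## Error-distribution modeling

Unordered-pair errors have arbitrary sign, so the sample is symmetrized
(concatenated with its negation, all N(N−1) ordered pairs), which forces an
exactly zero mean and makes a location parameter meaningless.  Two models
are fitted to the symmetrized sample:

- a zero-mean Gaussian whose sd is the sample RMS (its MLE), and
- a zero-location Student-t with free degrees of freedom ν and scale,
  fitted by maximum likelihood.

The t MLE runs Nelder–Mead on (log ν, log scale) — log-parameterization
keeps both positive without constraints — with ν clamped (not walled off
with infinities, which would stall the simplex) so that Gaussian-like
samples converge on the flat upper plateau of the likelihood.  ν̂ is capped
at 1000 and flagged "effectively Gaussian" above 100, where the t is
numerically indistinguishable from a Gaussian.  Recovery accuracy is ~±10%
on ν for 50,000-sample draws at ν ∈ [4, 10].  Threshold fractions (within
1, beyond 2 kcal/mol) are reported empirically and as model expectations
(`2Φ(t/σ) − 1` and the t analogue); histogram exports use fixed
0.25 kcal/mol bins centered on zero.

## Synthetic-data generator: what it emulates

`simulate_assay_pair` draws one set of true ΔGs per series (default:
uniform over a 5 kcal/mol dynamic range centered at −10 kcal/mol, i.e.
tens of nanomolar — a typical congeneric series; the range matters because
narrow series depress correlation statistics) and gives each assay a
measured `ΔG = true + offset + noise`.  Noise is applied on the ΔG
(log-concentration) scale, consistent with how affinity errors are
multiplicative in concentration; it is Gaussian (default sd
0.45 kcal/mol per assay, so two independent assays disagree by
2 × 0.45 = 0.9 kcal/mol pairwise RMSE — the regime observed between real
assays) or Student-t for heavy-tail studies.  Concentrations are
back-computed as `X = exp(ΔG/kT)`; values beyond a configured detection
limit are clamped to the limit and flagged `lt`/`gt` (not dropped), so the
censoring filter has realistic work to do.  `simulate_graph` builds a
random spanning tree (guaranteed connected) plus cycle-closing chords and
perturbs each true edge ΔΔG with Gaussian noise.

All randomness flows from a single `numpy` Generator seeded by the config;
identical configs give bit-identical outputs, which the end-to-end
determinism test (simulate → survey → fit-errors, twice, byte-compared)
relies on.

What passing these tests shows: the estimators recover the parameters of
the generating model (√2 error propagation, cycle-averaged variance
reduction, ν recovery, nominal-ish bootstrap coverage) at realistic sample
sizes.  What they do not show: real assays violate the model in known ways —
inter-assay errors correlate across compounds within a chemical subseries,
noise is heteroscedastic near detection limits, offsets can drift within a
series, and reported values are rounded to assay precision.  Conclusions
about real data should lean on the offset-invariant and rank-based metrics,
which are least sensitive to these violations.

## The √2 propagation law, stated carefully

If each of two assays adds independent noise of sd s per measurement, the
per-compound *absolute* ΔG difference between them has sd `√2·s`, and the
pairwise ΔΔG error between them has sd `2s = √2 · (√2·s)`.  The factor of
√2 therefore converts an absolute-difference RMSE into a pairwise RMSE —
`abs_rmse_to_pairwise_rmse(0.95) = 1.34` — and *not* a per-assay noise sd
into a pairwise RMSE.  The acceptance property is exercised accordingly:
per-assay noise `0.6/√2` gives an inter-assay absolute difference sd of 0.6
and a predicted pairwise RMSE of `√2 × 0.6 ≈ 0.85`.

## Problem sizes and reproducibility

Statistical checks use the smallest sizes at which the tested law is
sharply distinguishable from its alternatives: N = 2000 compounds for the
√2 law (sampling error ≈ 2%), 50,000 symmetrized draws for ν recovery,
500 replications × M = 20 comparisons × 5000 bootstrap resamples for
coverage, and 50 seeds for the cycle-averaging comparison.
`scripts/acceptance.py --seed S --out results.json` re-derives every
reported quantity from scratch with all randomness keyed to S; the analytic
conversions are seed-independent by construction.

## Known limitations

- The weighted-least-squares construction is one of several ways to produce
  cycle-consistent ΔGs; alternatives (e.g. Bayesian or hysteresis-weighted
  schemes) would differ on noisy graphs, though all agree on trees and on
  noiseless data.
- The plateau censoring heuristic can both miss soft detection limits and
  false-positive on genuinely discrete assay readouts.
- Bootstrap intervals are percentile-method and mildly anti-conservative at
  small M (see above).
- The t fit fixes location at 0; on non-symmetrized (absolute-error) data a
  free location would be required.
- No multiple-assay (>2) joint model: compounds measured by three assays
  enter as all three pairwise comparisons, which double-counts shared noise
  across those comparisons; aggregation treats comparisons as exchangeable
  units.
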