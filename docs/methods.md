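# Methods

`quinpk` implements three linked analyses around chloroquine (CQ) and
hydroxychloroquine (HCQ) dosing for COVID-19-era treatment and
prophylaxis: regimen construction in base-equivalent doses, virtual-
population whole-blood pharmacokinetic (PK) simulation, and a pooled
self-poisoning concentration–mortality analysis. This note records the
models, the defaults and why, the numerical choices, and the limits of
what the synthetic data can show.

## Dose arithmetic and regimens

Doses are tracked as free base. A salt mass converts to base as
`m_base = m_salt · MW_base / MW_salt`; the two marketed tablets
(CQ diphosphate 250 mg salt, MW 515.86/319.87; HCQ sulphate 200 mg
salt, MW 433.95/335.87) both round to 155 mg base, and the package uses
the rounded 155 mg as tablet base mass because regimens are stated in
155-mg units.

Treatment schedules give a loading dose at 0 and 6 h and maintenance
doses every 12 h starting at 12 h. The last maintenance dose falls
strictly before `days × 24 h`, giving 13 maintenance doses over 7 days
and 19 over 10 days; the source regimens state only the total duration,
so this convention is the package's choice (it is the one that makes
"two tablets twice daily for 7 days" come out to whole days of
dosing). Weight-based variants quantise `10 mg base/kg` loading within
3–5 tablets and `5 mg base/kg` 12-hourly maintenance within 1–3
tablets, minimising the absolute mg error; ties break toward fewer
tablets (safety-conservative; the quantisation target leaves this
open). Prophylaxis uses the same loading rule followed by one tablet
daily (2.5 mg base/kg per day at the 62-kg reference weight). The
supported weight range is 40–90 kg; out-of-range weights warn rather
than fail.

The renal "half maintenance" alternative halves maintenance tablet
counts for treatment (2 → 1 tablet, 12-hourly). For prophylaxis, where
the full maintenance dose is already a single tablet, the halved rate
is delivered as one whole tablet every 48 h rather than half-tablets,
keeping every dose a whole-tablet multiple; over a month the delivered
dose matches half-rate dosing to within one tablet.

## PK model

Disposition is a linear mammillary model: first-order absorption from a
depot with rate `ka` and lag `tlag` into a central compartment
(`Vc/F`), elimination `CL/F` from central, and one (default) or two
peripheral compartments (`Q/F`, `Vp/F`). All parameters are apparent
oral quantities referenced to whole blood, the preferred matrix for
these intensely cell-bound drugs. One peripheral compartment is the
default because a single intercompartmental clearance is parameterised;
the model structure is recorded in run metadata and a second peripheral
compartment is available.

Because the system is linear and time-invariant, a multi-dose profile
is the superposition of shifted single-dose responses. The single-dose
response is computed in closed form by eigendecomposition of the full
(absorption + disposition) rate matrix — concentrations are exact on
any grid, with no ODE-solver error. If `ka` collides with a
disposition eigenvalue the matrix is defective; `ka` is then nudged by
one part in 1e9, which changes concentrations by far less than any
reported precision. The test suite checks this closed form against an
independent stiff ODE integration (LSODA, rtol 1e-10) to a relative
error below 1e-6, and checks mass balance of the oracle itself to
1e-8.

The terminal half-life is `ln 2` over the slowest disposition exponent
whose residue in the central compartment is non-negligible (amplitudes
below 1e-9 of the largest are ignored, so the one-compartment limit
`Q → 0` correctly returns `ln 2 · Vc/CL` rather than the vanishing
peripheral washout mode).

### Virtual populations

Between-patient variability is exponential: each clearance, volume and
`ka` is multiplied by `exp(η)`, `η ~ N(0, ω²)` independently per
parameter, with `ω = 0.30`. The stated "30%" variability is
interpreted as the log-scale standard deviation (geometric CV
`sqrt(exp(0.09) − 1) ≈ 30.7%`); the difference from an exact 30% CV is
below every tolerance used. Allometric scaling uses the standard
pharmacometric exponents, 0.75 on clearances and 1.0 on volumes,
around a 62-kg reference adult — 62 kg because the regimen identities
(4 × 155 mg = 10 mg/kg) are exact there. Renal impairment multiplies
`CL/F` by `1 − renal_fraction × impairment`; the worst-case scenario
(renal fraction 0.5, 90% impairment) reduces total clearance by 45%.

### Illustrative parameter values

The typical parameter values behind the published simulations are not
redistributable, so `make_fixture_pk_set` ships constructed,
clearly-flagged ILLUSTRATIVE sets. They were chosen (before any test
outcome was inspected) to satisfy the qualitative constraints of
4-aminoquinoline disposition: terminal half-life beyond 28 days (the
fixtures give ≈ 39 days for both drugs), total apparent volume above
100 L/kg (≈ 650 and ≈ 500 L/kg), peak whole-blood concentrations of a
few µM under the standard treatment regimen, and absorption reaching
peak within hours. Absolute concentrations from these fixtures are
demonstrations of the machinery, not predictions; all quantitative
acceptance checks are properties (linearity, oracle agreement,
coverage, sampling-law recovery) or closed-form arithmetic that do not
depend on the fixture values.

## Exposure metrics

`Cmax` is the grid maximum (first attaining time reported). AUC is the
trapezoidal integral from zero to the last dose plus 720 h ("one
month" is fixed at exactly 720 h). The 95% prediction band is the
pointwise empirical 2.5th–97.5th percentile across simulated subjects,
with numpy's linear interpolation between order statistics — at
n = 1,000 the difference between percentile definitions is below all
tolerances used. The threshold report is the fraction of subjects
whose Cmax strictly exceeds 10 µM whole blood (= 3.2 µg/mL for CQ),
the upper safety bound implied by the poisoning data after metabolite
correction. In vitro EC50s (1.13 µM CQ, 0.72 µM HCQ, taken as
plasma-equivalent) are scaled to whole blood by the blood:plasma
ratios 3 and 4, giving 3.39 and 2.88 µM; these are overlays only — no
effect model is fitted.

## Poisoning analysis

Cohort tables (`study_id, conc_um, died`) are strictly validated:
concentrations must be positive numbers, outcomes coded 0/1, failures
reported with row index. Binned mortality uses half-open
`[lower, upper)` bins; default edges 0, 5, 10, 15, 20, 25, 30, 40, 55,
85 µM, aligned with the 15/20/25 µM thresholds discussed for the
pooled data (the published figure does not state its edges, so these
are configurable). Confidence intervals are percentile bootstrap,
resampling patients with replacement within each bin, B = 2,000 by
default, seeded; the point estimate is seed-free. A bin of all
survivors yields the degenerate CI [0, 0] — correct for the percentile
method, though it understates uncertainty when n is small. Empty bins
report NaN rather than erroring. The two-group contingency summary
reports mortality percentages (integer precision, one decimal for
nonzero values below 1%), risk ratio, and odds ratio with a
Haldane–Anscombe (+0.5) variant when a cell is zero. The metabolite
correction multiplies a combined CQ + desethyl-CQ measurement by
`1 − 0.30` to approximate the parent-drug concentration.

## Synthetic data

The patient-level pooled cohort is not redistributable, so the
generator emulates its reported structure rather than fitting it:
n = 258; concentrations lognormal with log-median `ln 10` and log-sd
0.8, truncated to the reported 1.1–81 µM range (sampled as a truncated
normal on the log scale); death Bernoulli with probability
`logistic((c − c50)/s)`, `c50 = 38 µM`, `s = 2.5 µM`. The mortality
law was calibrated by simulation, before freezing the test
expectations, to reproduce the qualitative published pattern: across
200 seeded replicates the no-death threshold on a 5-µM grid is ≥ 15 µM
in ≥ 95% of cohorts (observed: 100%), mortality above 20 µM exceeds 5%
essentially always (mean ≈ 25%), and a cohort carries ≈ 12 deaths
(the real pooled cohort has 14). The steeper-than-clinical logistic is
deliberate: a shallower law would scatter occasional deaths below
15 µM, contradicting the pattern the analysis is designed to detect.

What passing tests on synthetic data do show: the pipeline recovers a
generating concentration–mortality law (binned estimates within 3
binomial SDs at n = 50,000), conserves counts, and reproduces the
reported qualitative thresholds. What they do not show: anything about
the true clinical concentration–mortality relationship, inter-study
heterogeneity, assay error, or censoring — none of which the generator
models.

## Problem sizes and numerical choices

Default simulations use 1,000 subjects (the published figure size);
property tests use up to 10,000 subjects and 50,000–100,000 parameter
draws, chosen so Monte-Carlo error sits well below the asserted
tolerances while the whole suite runs in seconds. The default output
grid is 1-h steps over dosing then 24-h steps to 720 h past the last
dose. AUC convergence was checked by grid refinement (< 0.5% change for
a 10× finer grid). All randomness flows through
`numpy.random.default_rng` seeded per run; population simulation,
bootstrap and generators are bit-reproducible given a seed.

## Known limitations

- No parameter estimation: the package simulates from given parameter
  sets; it cannot fit concentration data.
- No PK/PD linking, QT modelling, or metabolite kinetics; the EC50
  lines and the 10 µM bound are static overlays.
- Whole-blood referencing is assumed for the PK parameters; the
  blood:plasma ratio is used only to scale EC50s.
- The prophylaxis half-maintenance alternative is implemented as
  alternate-day dosing (see above), which matches the average rate but
  not an exact half-tablet-daily profile shape.
- The synthetic cohort is a stand-in: conclusions about the real
  pooled data require the original patient-level table.
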