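# Methods

## Scope and data model

The package analyses milk-clotting enzyme (MCE) measurements from a
producing microorganism in two physical forms — free cells and cells
entrapped in calcium-alginate beads — and quantifies what immobilization
buys: operational reuse, leakage containment, and thermal robustness.
Inputs are long-format CSV tables (one measurement per row); results are
tidy tables and JSON report bundles. Nothing here models the clotting
reaction itself (casein micelle kinetics); the assay statistic and the
downstream kinetics are the subject.

## The Soxhlet-unit statistic

One Soxhlet unit (SU) clots 1 ml of standard reconstituted skim milk with
CaCl₂ in 40 min at 35 °C. With clotting time T (s), dilution D, milk
volume 5 ml and enzyme volume 0.5 ml, activity is

SU/ml = (2400 × 5 × D) / (T × 0.5) = 24000·D/T.

The one-line form of this formula that circulates in the assay literature,
"2400 × 5 × D/T × 0.5", is ambiguous: read left to right it gives
6000·D/T, which contradicts the unit's own definition (an undiluted sample
whose 0.5 ml holds 5 SU clots 5 ml of milk in exactly 2400 s and must
score 10 SU/ml). We therefore group it as (2400 × 5 × D)/(T × 0.5);
the definitional case is asserted in the tests. Volumes and the reference
time are fields of the assay record and can be overridden; the invariant
SU·T/D = 24000 holds at the defaults.

## Profile normalization and the optimum

A condition profile (activity across temperature, pH, medium composition,
…) is normalized by its maximum: normalized_i = 100·(a_i / max a). The
division happens before the scaling by 100 so the optimum is exactly
100.0 in floating point. Ties are broken by first occurrence, so a
plateau (e.g. equal activity at 35 and 40 °C) reports the lower
temperature as the optimum; this matches the convention of quoting the
mildest condition that achieves the maximum. All-zero profiles are
refused as degenerate. Printed "±" dispersions are stored but never
propagated; the package does no error propagation on assay tables.

Leakage of cells from beads is scored from culture-filtrate optical
density as 100 − 100·OD_immobilized/OD_free. Noise can push this negative
(immobilized filtrate denser than free); such values are returned as-is
with an `out_of_range` flag rather than clamped or refused, so the caller
sees the measurement problem. Reuse retention is each cycle's production
as a percent of cycle 1 and is invariant to rescaling the series.

## First-order inactivation fitting

Residual activity (percent of unheated control) at a fixed temperature is
modelled as A(t) = A₀·e^(−kd·t). The fit is unweighted ordinary least
squares of ln(A/100) on time in minutes; kd = −slope. Choices:

* **Natural log.** A base-10 regression would estimate kd/ln10 and need a
  conversion before t½ = ln2/kd; both give identical half-lives, so the
  natural log is used throughout.
* **The 0-min point is a data point.** Activities are converted to
  fractions of the control, and a 100 % point at t = 0 enters the
  regression like any other; the intercept is estimated, not forced to 0.
* **Non-positive activities** cannot be logged; they are excluded with a
  logged warning, not an error. Fewer than 2 usable points is an error;
  fewer than `min_points` (default 3) warns that the fit has no
  redundancy.
* **A non-negative slope** is reported as `decaying=False` with NaN
  half-life and D-value; callers must not read a rate out of it.
* r² is the sole fit diagnostic, matching how such fits are reported in
  the application literature; no weighting, no confidence intervals.

Derived times: t½ = ln2/kd and D = ln10/kd, so D/t½ = log₂10 ≈ 3.32193 for
every fit regardless of the data. This constant makes reported (t½, D)
pairs checkable: `check_half_life_d_value` computes the D implied by a
half-life and flags deviations beyond a tolerance (default 2 min, the
worst case explainable by rounding both numbers to whole minutes). In the
packaged reference summary, the free-form 50 °C pair (238, 793 min)
deviates by 2.38 min and the immobilized 60 °C pair (164, 547 min) by
2.20 min — both flagged as rounding artifacts of an unprinted kd; the
package does not attempt to back out the unrounded rate.

Temperatures convert to Kelvin as K = °C + 273.15; time is fixed to
minutes and kd to min⁻¹.

## Arrhenius energies

OLS of ln(response) on 1/T (K⁻¹) gives slope −E/R; the energy is reported
as E = −slope·R/1000 kJ/mol in **both** modes. The two printed sign
conventions in the field ("slope = −Ea/R" for activation, "slope = Ed/R"
for deactivation) cannot both yield positive energies from the same
negatively-sloped plot, so one convention is used and a negative energy is
flagged (`well_posed=False`) instead of silently returned. 1/T in K⁻¹ is
the internal axis; the conventional 1000/T axis is exposed as a pure
rescale of the slope (`slope_per_1000K`) and leaves the energy unchanged.

For activation energies from an activity–temperature profile, the points
entering the fit are not standardized in the literature. The default here
is the **ascending limb**: temperatures up to and including the optimum
(first maximum), where activity is rate-limited and Arrhenius-like; above
the optimum denaturation dominates and the law no longer applies. An
explicit temperature range can override the default. The published
activation energies for this system (54.96/35.99 and 64.20/38.75 kJ/mol)
cannot be reproduced from the printed activity tables under any contiguous
temperature subset — the underlying relative-activity series for those
fits was not printed — so E_a values are validated by parameter recovery
on synthetic data, not against those numbers.

Similarly, the published E_d values (25.62 free → 55.19 immobilized
kJ/mol) are inconsistent with the published half-lives: the kd implied by
the free t½ triple (238/182/133 min at 50/55/60 °C) regresses to
E_d = 52.06 kJ/mol and the immobilized triple (216/192/164 min) to
24.63 kJ/mol — the free/immobilized assignment appears swapped in the
source. The package computes and reports the regression from the
half-life inputs; the discrepancy is documented here and is not silently
reconciled.

## Synthetic data and what it does (not) show

The generator produces exactly the model the estimators assume:

* **Thermal series** — residual(t) = 100·e^(−kd·t) with kd either given
  per temperature or derived from an Arrhenius law kd(T) = A·e^(−E/RT).
  The default design mirrors a typical stability experiment: 25–60 °C in
  5 °C steps, times {0, 15, 30, 45, 60} min.
* **Reuse series** — constant production through a plateau of p cycles,
  then geometric decline (1 − d) per cycle. The defaults (plateau 5,
  decline 0.077, 10 cycles) reproduce the reference behaviour of full
  production for five cycles and 67 % at cycle ten.
* **Clotting times** — T = 24000·D/SU inverted from a true activity.

Noise is multiplicative lognormal by default (activity measurements are
positive and their dispersions scale with the mean); additive Gaussian is
available for robustness testing, with values floored at a tiny positive
epsilon and flagged when noise drives them non-positive. Every generator
takes an explicit seed and uses its own `numpy.random.Generator`; no
global state, and identical (config, seed) is bit-identical.

Because the generator implements the assumed model, passing recovery
tests show the estimators are correct and well-conditioned — they do not
show that real inactivation is first order, that real noise is lognormal,
or that biphasic/Weibull decays would be detected. The non-decaying flag
and r² are the only guards against model misfit.

**Recovery study design.** Noise recovery uses kd = 0.005 min⁻¹ with six
timepoints spanning 0–300 min (≈ two half-lives) and σ = 0.05 lognormal
noise over 200 replicates; the median relative kd error is ≈ 2–3 %.
The window length matters: sampling only 0–60 min at this kd leaves 74 %
of the activity in place and the slope ill-conditioned relative to the
noise, which is itself a useful design lesson for real experiments.
Noiseless recovery is exact to numerical precision (≤ 1e−10 relative on
kd, ≤ 1e−6 kJ/mol on the energy) and the fits agree with a direct
normal-equations oracle to 1e−10.

## Reference tables

Small published-style summary tables (isolate screening, production
parameters, pH stability, the thermodynamic summary) are packaged as
in-memory DataFrames, transcribed exactly and guarded by frozen SHA-256
checksums. The printed "±" dispersions are kept as literal digit strings
(`spread_printed`) because their notation is ambiguous; they never enter a
computation. The reuse table is *synthetic in shape*: only the cycle-5
(100 %) and cycle-10 (67 %) anchors are published, and the intermediate
cycles are interpolated geometrically. One source table lists the same
nitrogen-source label twice; the duplicate is kept with a `_2` suffix
rather than guessed away. Fixture ids are content-based because the
source's own table numbering is internally inconsistent.

## Numerical and interface choices

* CSV dialect: comma-separated UTF-8, header row required, dot decimals.
  Readers validate cell-by-cell and report every offending row at once.
* JSON reports serialize with sorted keys and no timestamp (unless
  pinned), so identical runs are byte-identical; NaN serializes as null.
* Replicate aggregation reports mean ± SE (sample SD/√n); n = 1 gives
  SE = 0 with a `single_replicate` flag.
* Defaults — R = 8.314 J K⁻¹ mol⁻¹, Kelvin offset 273.15, assay volumes
  5/0.5 ml, reference time 2400 s — are overridable per call/flag.
* The CLI (`thermoclot su|profile|decay|arrhenius|simulate|report`) is a
  thin layer over the library; every computation is importable.

## Known limitations

* Single-exponential decay only: no z-value, Weibull or biphasic models.
* pH stability is reported as raw retained percentages; no pH-decay
  constants are fitted.
* No transition-state thermodynamics (ΔH‡, ΔG‡, ΔS‡) beyond E_a/E_d.
* No error propagation of reported dispersions; no confidence intervals
  on fitted parameters.
* No mechanistic simulation of cell growth, bead mass transfer or leakage
  dynamics; the generators are phenomenological.
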