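# Methods

## The survival model

`umasurv` implements a two-parameter unified multi-activation (UMA)
model of clonogenic cell survival after an acute radiation dose
*D* (Gy):

    S(D) = n / (exp(D/D0) + n − 1)

* **D0** (Gy, > 0) — the dose slope of the straight high-dose portion
  of the curve: one extra D0 of dose reduces survival e-fold once the
  exponential term dominates.
* **n** (dimensionless, > 0) — the activation (extrapolation) number:
  the back-extrapolated zero-dose intercept of the straight portion,
  interpretable as the number of cell-death pathways that must be
  activated.  `n > 1` gives the familiar shoulder, `n = 1` collapses
  the model to the pure exponential `exp(−D/D0)`, and `0 < n < 1`
  produces an inverted (negatively curved) shoulder, observed for some
  metastatic endometrial and tongue-base carcinoma lines.

The form satisfies S(0) = 1 exactly, is strictly decreasing and
bounded in (0, 1], and is asymptotically linear in log-survival,
`ln S → ln n − D/D0`.  The exact deviation from that asymptote is
`log1p((n−1)e^{−D/D0})`; it falls below 1e−4 for every n ≤ 100 once
D/D0 ≥ 14 (at D/D0 = 12 it can still be ~6e−4 for n = 100).  Unlike
piecewise constructions that switch between a linear-quadratic (LQ)
low-dose regime and a multitarget (MT) high-dose regime, a single
mechanism covers the entire dose range.

A tumour with distinguishable sub-populations (e.g. a hypoxic
compartment, or the irregular-shouldered NHIK 3025 cervical line) is
modelled as a weighted mixture: survival is the weighted sum of
component survivals, with weights on the simplex.

### Derived radiosensitivity quantities

Writing the LQ model as `ln S = −αD − βD²`, the UMA curve implies
dose-*dependent* coefficients:

    β(D) = (n−1) e^{D/D0} / (2 D0² (e^{D/D0}+n−1)²)
    α(D) = e^{D/D0} / (D0 (e^{D/D0}+n−1)) + 2 β(D) D
    α/β  = 2 D0 (e^{D/D0}+n−1)/(n−1) + 2D

β is zero at n = 1 (α = 1/D0, ratio undefined — returned as NaN) and
negative for n < 1, giving negative α/β ratios.  The published closed
form for α/β carries a `−2D` final term; the quotient of the α and β
expressions, and every tabulated ratio we reproduce, require `+2D`, so
the ratio is implemented strictly as `α/β` (the sign in the printed
standalone formula appears to be a typographical slip).  Derivative
quantities are exposed for single populations only; a mixture has no
single (α, β) pair.

The mean inactivation dose, MID = ∫₀^∞ S dD = `n ln(n) D0/(n−1)`
(continuous limit D0 at n = 1), is provided as a one-number
radiosensitivity summary; it is checked against adaptive quadrature of
S to 1e−6 relative over D0 ∈ [0.5, 7] Gy, n ∈ [0.2, 60].

### Numerical policy

All evaluations route through the stabilised logarithm
`ln(e^x + n − 1) = x + log1p((n−1)e^{−x})`, exact for every n > 0 and
x ≥ 0 and overflow-free to x ≈ 700; α/β ratios of order 1e10 occur in
the packaged table at 20-Gy fractions and are computed without loss.
`exp(ln S)` is clipped at 1.0, since for n < 1 at tiny doses rounding
can land infinitesimally above unity.  MID uses `log1p(n−1)`, keeping
the n → 1 limit continuous to ~1e−12.

## Equivalent dose (EQD2 / EQDx)

Because log-survival per fraction is additive, a course of N fractions
of D Gy is iso-effective with N₂ fractions of 2 Gy where

    N₂ = N · [ln n − ln(e^{D/D0}+n−1)] / [ln n − ln(e^{2/D0}+n−1)]

and EQD2 = 2·N₂.  Multi-session schemes sum per-session EQD2 exactly
(session additivity is exact in floating point).  For n = 1 the
quotient collapses and EQD2 equals the physical dose for every scheme
— a pure exponential response cannot distinguish fractionation
schedules.  The reference fraction size is configurable (EQDx); only
x = 2 values are compared against published tables.

Mixed radiation qualities (the α-particle breast-cancer course) use
the treatment-radiation parameters in the numerator and the same
line's reference-radiation (γ-ray) parameters in the denominator.
For mixed cell populations the governing EQD2 is the **minimum** over
components: the compartment that is hardest to trade up to 2-Gy
fractions dominates regrowth at the end of treatment.

Under this model the biologically effective dose is the physical dose
itself; the classical LQ BED `N·D·(1+D/(α/β))` and LQ EQD2
`N·D·(1+D/(α/β))/(1+2/(α/β))` are provided only as comparators.
Negative α/β ratios are accepted there with a warning (they arise as
analogues of inverted shoulders); α/β = −2 Gy is the formula's only
pole and raises.  Equivalent fraction numbers are kept real-valued;
rounding up to deliverable fractions is a CLI flag, never implicit.

## Curve fitting

Input curves hold replicate survival fractions per dose point; the
zero-dose point is the normalisation anchor (mean exactly 1, no error
bar).  Goodness is measured on the linear survival scale:
R² = 1 − RSS/SSS, the mean relative residual
r = (1/I)·Σ|S(D_i)−S_i|/S_i over all I points, and the mean relative
experimental error e = (1/I′)·Σ ΔS_i/S_i over the I′ points carrying a
replicate SD (sample SD, ddof = 1).  A fit is "good" when R² ∈ [0.9, 1]
and r < e; r is the operative index because R² is insensitive to
misfit at high doses where survival is tiny.

**UMA fit.**  The model linearises: `y = ln(n/S + 1 − n) = D/D0`.  For
a candidate n, D0 is the reciprocal slope of the through-origin
least-squares regression of y on D (unweighted; the zero-dose anchor
contributes the exact point y = 0).  n itself is initialised from the
two highest-dose points (D0⁰ from their log-slope,
n⁰ = S_{I−1}·e^{D_{I−1}/D0⁰}) and then searched deterministically: a
241-point log-spaced grid over n ∈ [0.05, 200] (always including n⁰
and 1), followed by golden-section refinement of the best candidate's
bracket.  The returned n minimises r subject to R² ≥ 0.9 whenever any
candidate attains that; otherwise the constraint is dropped with a
warning.  Ties within 1e−10 in r break towards higher R², then
smaller n.  With survival clipped to (0, 1] the linearisation argument
`n/S + 1 − n ≥ 1` is always positive, so candidate infeasibility can
only arise for malformed inputs, which are skipped.

**Two-population fit.**  The mixture objective (the same r) is
minimised by Nelder–Mead in log-parameter space from a fixed-seed set
of 12 starting points (one derived from the single-population fit);
weights default to fixed equal halves, optionally free on the simplex.
Components are reported sorted by descending D0, most radioresistant
first.  The fit is reproducible; non-convergence raises an error
carrying the best single-population result.

**LQ and MT comparators.**  The LQ fit is a zero-intercept least
squares of ln S on (D, D²), optionally restricted to a dose range —
the fitted α/β is strongly range-sensitive on curved data, which is
the point of exposing the option.  The MT fit regresses ln S on D over
points above 3 Gy (configurable), giving D0 = −1/slope,
n = e^intercept.  Both report goodness over *all* points so that
out-of-range misfit (LQ bending away at high dose, MT overestimating
the shoulder) stays visible.

An exact equivalence used in testing: the LQ formalism reproduces the
UMA EQD2 precisely when α and β are chosen so the LQ log-survival
matches the UMA curve at both the fractional dose and 2 Gy — i.e. only
when both coefficients are allowed to vary with D.  Fixed clinical
ratios cannot achieve this, which is the source of the EQD2
discrepancies the comparison tables show.

## Fractionation surfaces

`scheme_survival_ratio` compares two schemes of equal physical dose by
S(Da)^Na / S(Db)^Nb with real-valued exponents (the twice-daily 1.2-Gy
comparison uses 2/1.2 fractions per 2-Gy day); values below 1 favour
scheme A.  Two canonical surfaces over the (D0, n) plane are built in:
one 10-Gy fraction vs five 2-Gy fractions (hypofractionation), and BID
1.2-Gy vs one 2-Gy fraction (hyperfractionation).  Both are exactly 1
along n = 1.  The hypofractionation ratio increases monotonically with
D0 for n > 1 and has an interior minimum across n for D0 ≳ 2 Gy (the
stationary point where the large fraction gains the most control);
the hyperfractionation ratio rises steeply with n through the n ≤ 1
regime — the inverted-shoulder lines benefit most — and relaxes back
towards 1 above it.  Grid axes are geometric, default
D0 ∈ [0.5, 7] Gy and n ∈ [0.2, 20], chosen to cover the packaged
cell-line table; contour plotting is an optional thin layer, the
tested artifact is the grid of values.

## Synthetic data and the packaged table

The generator emulates a multi-replicate clonogenic assay: replicate
survivals are the model mean times `exp(ε)`, ε ~ N(0, σ²) —
multiplicative lognormal noise, because count-derived survival
fractions are positive with roughly dose-proportional scatter.  The
default σ = 0.1 with 3 replicates matches careful triplicate assays.
Replicates are clipped into (0, 1]; the zero-dose point is emitted
noise-free.  What the generator does **not** emulate: Poisson colony
statistics and plating-efficiency estimation, dose-rate and repair
kinetics, repopulation, and inter-experiment batch effects — so
passing recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to every feature of real assays.

The packaged table (`table1_parameters.csv`, 31 rows) carries the
published (D0, n) per cell line with its fractionation scheme, the
published dose-dependent α and α/β, the UMA EQD2 and the LQ EQD2 under
the clinical ratios (3 Gy prostate, 8 Gy lung and colorectal, 10 Gy
otherwise).  Re-deriving α, α/β (two-significant-figure, half-ulp
tolerance) and EQD2 (±0.1 Gy) from each row's (D0, n, D, N) reproduces
30 of 31 rows; the single outlier ("Bell,MelH", recomputed EQD2 42.3
vs tabulated 41.9) is consistent with the tabulated D0/n themselves
being rounded to three significant figures, and is reported by the
self-test rather than absorbed.  Four tabulated LQ-EQD2 entries (DaFu,
SKX, UM-EC-2, UT-EC-2) are not reproducible from the stated clinical
ratios (algebraically they correspond to α/β = −10 Gy, an apparent
sign slip); the table stores them verbatim and the batch command
recomputes LQ EQD2 from the stated ratios.

The 7 Gy × 5 cervical/endometrial cohort aggregate (45.5 Gy, range
35–52.6) is reconstructed from eight rows: the NHIK 3025 mixture
collapsed to its governing component via the minimum rule, the other
five 7 Gy × 5 lines, and the two metastatic-EC hyperfractionated
lines; this reconstruction is documented here because the cohort
membership is not otherwise explicit.

### Parameter-recovery study

The end-to-end check generates 200 curves with D0 ~ U(0.8, 6.5) Gy,
n log-uniform on [0.5, 20], σ = 0.1, 3 replicates, and 8 dose points
over 0–20 Gy, then refits each with the UMA procedure.  The dose grid
spans to 20 Gy so that the straight portion is reached even for the
most resistant simulated lines (D0 = 6.5 Gy ⇒ D_max ≈ 3·D0); assays
of such lines are published over comparably wide ranges for the same
reason.  On a 0–12 Gy grid the activation number of high-D0 curves is
under-determined — a brute-force scan of the same objective shows its
median error floor there is ~11% — so grid width is a property of
study design, not of the estimator.  Observed medians: ~1.4% relative
error in D0 and ~7% in n (fixed seed 20210216).

## Problem sizes and determinism

All published-value reproductions are closed-form evaluations and run
in milliseconds.  The recovery study (200 fits) and the mixture fits
(12 Nelder–Mead starts) are the only heavier components, each tens of
seconds at most.  Every stochastic component is seeded: the generator
per `GeneratorConfig.seed`, the mixture fit's starting points by a
fixed documented seed, the recovery study by one session seed.  Fits
are deterministic functions of the curve and configuration.

## Known limitations

* Parameters are treated as dose-rate-independent; split-dose repair,
  repopulation and cell-cycle redistribution are outside the model.
* No confidence intervals on (D0, n) — the published tables report
  none, and the linearised search does not propagate replicate error.
* The activation number of very shouldered, high-D0 curves is weakly
  identified unless the assay reaches well into the straight portion;
  fits from narrow dose ranges should be treated with caution (the
  same caveat the LQ range-sensitivity comparison quantifies).
* Mixture fits beyond two components are supported mechanically but
  rarely identifiable from a single curve.
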