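# Methods

This note records the modelling and numerical choices behind `apsens`:
what is simulated, how the statistics are computed, what the synthetic
surfaces do and do not stand in for, and where the design was genuinely
open.

## The cell model

`apsens.shannon` hand-codes the Shannon et al. (2004) rabbit ventricular
myocyte model from its published formulation / CellML encoding: membrane
potential, Luo–Rudy-lineage INa/IK1 gating, rapid and slow delayed
rectifiers (IKs with calcium-dependent conductance), fast and slow
transient outward currents, GHK-form L-type calcium current with
calcium-dependent inactivation in junctional and sub-sarcolemmal
compartments, Na/Ca exchange, Na/K and sarcolemmal Ca pumps, background
Na/Ca/Cl/K currents, RyR release with SR-load-dependent gating, SERCA
uptake, SR leak, and the full complement of cytosolic/membrane/SR calcium
buffers — 40 state variables in mV, ms, mM and A/F. The constant table
`apsens.shannon.CONSTANTS` is the single source of truth and can be
dumped as JSON for audit.

Choices fixed here:

* **Scaling factors.** Each of the fifteen currents is multiplied by a
  dimensionless factor `p_i` *everywhere* it appears, including the
  concentration balance equations (so e.g. scaling INaCa scales both its
  membrane-potential contribution and its Ca/Na fluxes). Baseline is all
  ones.
* **Constant intracellular Cl⁻ and K⁺**, exactly as in the model
  formulation. We verified empirically that evolving Ki instead
  (dKi/dt = −IK,tot·Cm/(Vmyo·F)) changes the paced steady state by under
  0.5 mM and the excitation threshold by < 0.01 A/F, so the constant-K⁺
  encoding is not a behavioural simplification at 2 Hz pacing.
* **Stimulus.** Rectangular, depolarizing, 5 ms by default (the CellML
  protocol convention; the pulse duration is exposed in configuration
  because the threshold in A/F trades off directly against it). The
  stimulus enters the voltage equation only.
* **Initial state.** The published initial values; steady state is
  reached by pre-pacing (1000 beats at paper scale; pacing-convergence
  diagnostics show biomarker drift < 2% after ~1000 beats), never by a
  saved-state file.
* **Solver.** LSODA (stiff-capable, adaptive) through `scipy`, with
  rtol 1e-6 and per-variable atol (1e-8 for concentrations and buffer
  occupancies, 1e-6 for voltage and gates); each beat is integrated in
  two segments (stimulus on / off) so the discontinuity never crosses a
  solver step; recorded beats get dense output at 0.1 ms. Two runs with
  identical inputs are bitwise identical. Solver failures raise with the
  offending sample attached — the sensitivity layer decides policy.

### Fidelity of the reconstruction

No reference execution of the original encoding is bundled, so the
implementation is validated by internal consistency (quiescent steady
state stable over ≥ 10 s; exact per-current scaling linearity;
conservation of the RyR state simplex) and by physiological behaviour
(rest ≈ −85.8 mV, peak ≈ +43 mV, A90 ≈ 196 ms at BCL 500 ms, calcium
transient 114 → 480 nM, IKr-block AP prolongation). One quantitative
caveat is documented rather than hidden: the baseline excitation
threshold computes to ≈ 9.0–9.1 A/F here, a few percent below the
reference value of ≈ 9.4 A/F for this model and protocol, and the
one-at-a-time normal-response boundaries are correspondingly slightly
wider. The threshold is dominated by IK1 (we measure ∂threshold/∂pK1 ≈
+2.5 A/F per unit), so a small systematic difference in effective
inward-rectifier strength between encodings is the likely cause; no
identifiable equation error remained after line-by-line review, and no
constant was tuned to move the number.

## Biomarkers

Per analysed beat window `[t0, t0+bcl]` (t0 = stimulus onset): `Vmax` is
the window maximum; `Vrest = V(t0+bcl)`; `A90`/`A30` are the times from
stimulus to the level `Vmax − q·|Vmax − Vrest|` (q = 0.9/0.3), taking the
*first crossing after the peak* (guards against early-repolarization
notches) by linear interpolation; `Vplt = V(t0 + A90/2)` interpolated;
`B = ∫|V − Vrest| dt` by trapezoid. Calcium: `ED = Cai(t0)`,
`PSV = max Cai`, `Tpeak = argmax − t0`, `D50` = total time above the
midpoint between `PSV` and the end-of-beat value, with interpolated
crossings. The end-of-beat (not pre-beat) diastolic value defines the
50%-recovery level; that choice is recorded here because either reading
is defensible.

A beat "elicits an AP" when its peak exceeds 0 mV **and** the
peak-to-takeoff amplitude exceeds 30 mV; no published criterion exists,
so both levels are package constants. Regime classification works from
per-beat detection flags and per-beat A90: all-detected with stable A90 →
`normal_1_1`; consistent beat-to-beat A90 alternation beyond 5% relative
→ `alternans_2_2`; strict detected/undetected alternation → `block_2_1`;
runs of ≥ 3 APs alternating with runs of ≥ 3 failures → `intermittent`
(Q = mean run length); nothing detected → `non_excitable`; anything else
→ `other`. The 5% alternans tolerance and run-length 3 are configuration
constants, not measurements.

## Sensitivity estimation

Sampling is quasi-random: a scrambled Sobol' sequence of dimension 2N
supplies the base matrices A and B (M a power of two, for the balance
property), mapped affinely onto the parameter box; cross matrices AB_i
(and BA_i when second-order indices are requested) follow the Saltelli
column-swap scheme, for M(N+2) or M(2N+2) evaluations. The distribution
over each range is independent uniform — the natural reading when only a
box is specified.

Outputs are z-scored before estimation (mean 0, SD 1, location/scale
computed once on the full evaluation set and reused inside bootstrap
replicates). This is mathematically a no-op for variance ratios — an
affine-invariance property the tests assert — but keeps intermediate
numerics comparable across biomarkers. Estimators: Jansen for S_i and
S_Ti, the Saltelli cross-block estimator for S_ij; total variance is
taken over the pooled A and B evaluations. Estimates are reported
**unclipped**: sampling noise may push them slightly below 0 or above 1,
and clipping would hide exactly the information the bootstrap quantifies.

Bootstrap: base-point indices are resampled with replacement jointly
across all blocks, 1000 replicates by default; we report the replicate SD
and the 2-SD half-width (the empirical 68–95–99.7 reading of a 95%
interval). On the analytic test functions the bootstrap distributions are
unimodal and close to normal at large M.

Failed evaluations: strict mode (default) raises with the sample
serialized; tolerant mode drops the *entire base point* across all blocks
and records the count, because partial blocks would silently bias the
difference estimators. The normal-response box is designed to make
failures rare in the first place.

The grand-total index `S_Gi = Σ_k w_k S_Ti^k` (weights default to 1 —
all biomarkers of equal interest) ranks parameters across biomarkers;
ties break alphabetically, making the ordering total and deterministic.
Conditional-expectation curves use equal-width bins on the
`(p−pmin)/(pmax−pmin)` scaled axis; empty bins are reported as gaps,
never interpolated.

## Normal-response region scan

One factor at a time, 25 log-spaced grid points over [1e-4, 10] plus the
anchor, classification at each point, then bisection refinement of the
first transition on either side of the anchor to 0.01 absolute — the
two-decimal precision at which such ranges are conventionally reported.
Scan trains default to 200 pre-pacing beats with a 60-beat classification
window (the pacing-convergence diagnostic justifies the shortened
pre-pacing to within ~2%); reported boundaries can be confirmed at full
length. The detected interval is the maximal contiguous normal run
containing the anchor; the scan refuses to run if the anchor itself is
not 1:1.

## Model reduction

The level-M reduced model keeps the M top-ranked factors free and fixes
the rest to 1 — parameter-fixing only, no re-fitting. Both reduced and
full outputs flow through the *same* evaluator, so level N is the
identity bitwise and `E⟨N⟩ = 0`, `R² = 1` holds exactly, not to
tolerance. Global discrepancy uses L quasi-random points (L = 2000 at
paper scale, configurable down; full-model evaluations are computed once
and shared across levels). `E⟨M⟩` is the mean over points and biomarkers
of `|Δy/y|`; biomarkers with an exactly-zero full-model value are
excluded with a warning count. R² is computed per biomarker (full model
as reference, reduced as prediction); the headline aggregate is the mean
of per-biomarker R² — the pooled R² over z-scored stacked columns is
always reported alongside, since no single aggregation is canonical.
Minimal per-biomarker sets grow the prefix of that biomarker's own
total-order ranking until R² ≥ 0.9 (threshold configurable); evaluations
are memoized by free-parameter set because prefixes recur across
biomarkers.

## Synthetic validation surfaces

Two kinds of stand-ins make every stage testable without long ODE runs:

* **Analytic test functions** (linear additive, Ishigami with a = 7,
  b = 0.1, Sobol' g-function) with closed-form variance decompositions
  evaluated inside the package; the estimator suite asserts recovery
  within 3 bootstrap SDs, strict coefficient orderings, affine
  invariance, and `S_Ti ≥ S_i`. A brute-force quadrature oracle for the
  Ishigami pair interaction provides a second, estimator-independent
  route to S₁₃.
* **A parametric AP-waveform surrogate**: a 1 ms linear upstroke to
  `Vr + A`, a quartic-exponential repolarization
  `V = Vr + A·exp(−((t−1)/τ)⁴)`, and a biexponential calcium transient.
  Six pseudo-parameters on [0.5, 2]: q1 scales A, q2 scales τ and (in
  step) the calcium decay constant, q3 shifts Vr, q4 scales the calcium
  amplitude and diastolic level, q5/q6 are exactly inert. All ten
  biomarkers have closed forms (D50's crossing is root-bracketed on the
  exact waveform), so extraction, GSA, ranking, reduction and minimal
  sets can be verified end to end — including the sharp prediction that
  inert parameters get zero indices and never enter a minimal set.

The surrogate is not a physiological model: it has no regimes other than
1:1, no restitution, no interactions between pseudo-parameters (its
second-order indices are exactly zero), and its biomarker map is mostly
additive. Tests passing on it therefore demonstrate the *pipeline
machinery* — not Shannon-model index values, which require the ODE
campaigns in `scripts/reproduce_campaign.py`.

## Problem sizes

Paper-scale defaults (M = 8192 with second-order blocks, 1000-beat
trains, 1000 bootstrap replicates, L = 2000) are preserved in
`RunConfig`; the test suite and examples run the same code at desk scale
(M ≤ 4096 for analytic functions and the surrogate; 3–200-beat trains
for ODE spot checks; the excitation threshold uses 200 pre-pacing beats,
after which it changes by < 0.05 A/F). The evaluation cache doubles as a
checkpoint so long Shannon campaigns are resumable and shardable.

## Known limitations

* The excitation-threshold / stability-margin offset described above:
  absolute regime boundaries carry a few-percent uncertainty relative to
  the original encoding, while within-package comparisons (rankings,
  reductions) are unaffected.
* One pacing rate (BCL 500 ms) anchors all defaults; restitution support
  exists but no rate-dependent sensitivity analysis is wired in.
* No Mahajan-model implementation, no tissue-level simulation, and no
  alternative GSA backends (FAST, PRCC) — variance-based Sobol analysis
  is the single method on purpose.
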