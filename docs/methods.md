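# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.  It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and units

Three table families are read and written as UTF-8 CSV (`nmrbind.tables`):

| family     | layout | quantities | units |
|------------|--------|-----------|-------|
| dilution   | wide: `conc` + one column per proton | Δδ vs. total concentration | mM, Hz |
| diffusion  | long: `species, conc, D, sigma` | diffusion coefficients | mM, 10⁻¹⁰ m² s⁻¹ |
| shift      | long: `unit, class, free, complex` | chemical shifts | ppm |

Units are fixed per dialect; there is no autodetection, because the one
realistic failure mode of this analysis is silently mixing the Hz scale of
dilution tables with the ppm scale of shift tables.  Δδ is always
`reference − observed` (dilution: most dilute sample as reference; CSP:
free species as reference), so a positive value is a low-frequency
(upfield) shift — the ring-current signature of aromatic stacking.
Proton and unit labels are exact, case-sensitive strings.  Unicode minus
signs (U+2212 and en/em dashes) are accepted in numeric cells.

## Isodesmic self-association

Model: indefinite stacking with a single step constant `K_a`; under fast
exchange every proton's shift change obeys

    Δδ_obs(c) = Δδ_max · x(c),
    x(c) = (2C + 1 − √(4C + 1)) / (2C),  C = K_a·c,

where `x = K_a·[monomer]` rises from 0 to 1.  The implementation uses the
algebraically equivalent form `2C / (2C + 1 + √(4C + 1))`, which avoids
cancellation as `C → 0`; tests verify agreement with a bisection solve of
the mass balance `c = m/(1 − K_a·m)²` to 1e-8 relative over
`K_a ∈ [0.1, 100] mM⁻¹`, `c ∈ [1e-3, 10] mM`.

**Reference handling.**  Dilution tables record Δδ relative to the most
dilute sample, not the true infinite-dilution monomer.  The default fit
adopts the monomer-at-lowest-concentration convention and fits the table
values directly, *excluding the lowest-concentration point* — that point
is the reference, identically zero by construction, and carries no
information.  This convention was frozen after verifying that it
reproduces the published per-proton constants of the packaged study to
their printed precision (all 24 (K_a, Δδ_max) pairs; the physically
re-referenced model and a free-offset fit give markedly different
constants and were rejected as readings of the published protocol).  An
`offset_free=True` variant adds a fitted offset δ₀ and uses all points;
it is the exact inverse of the synthetic generator (below) and the right
choice for recovery studies.

**Optimizer.**  `scipy.optimize.least_squares` (Levenberg–Marquardt,
`xtol = ftol = 1e-14`) on θ = (log K_a, Δδ_max[, δ₀]); the log keeps
K_a positive.  Multistart over K_a⁰ ∈ {0.5, 2, 8} mM⁻¹ with
Δδ_max⁰ = 2 × the most extreme observed Δδ; the lowest-RSS solution wins.
The (K_a, Δδ_max) pair is correlated along a flat valley, and the
multistart removes the resulting initialization sensitivity (a
brute-force grid-search oracle over K_a ∈ (0.01, 50] × Δδ_max ∈ [−1000,
1000], refined to 3 significant digits, agrees with the optimizer in the
tests).  Non-convergence from every start returns a fit flagged
`converged=False`, never a silent drop.

**Averaging.**  The compound-level constant is the unweighted arithmetic
mean of the included per-proton constants with the sample (n−1) standard
deviation.  Exclusions are explicit analyst input — the deviant protons in
the packaged study are reported as unexplained, and inventing an automatic
outlier rule would put a criterion into the analysis that the data do not
define.  (On the packaged values the printed ±SDs are matched by the
sample SD for two of the four summaries and by the population SD for one;
the sample convention is kept throughout.)

## DOSY binding chain

Model: 1:1 complexation `DNA + L ⇌ DNA·L` in fast exchange, so observed
diffusion coefficients are population averages.  The chain is closed-form:

1. `MF_L = (D_obs − D_complex)/(D_L − D_complex)` — free-ligand mole
   fraction;
2. `[DNA·L] = (1 − MF_L)·C_L`;
3. `K_a = [DNA·L]/((C_DNA − [DNA·L])(C_L − [DNA·L]))`.

Hard assumptions, echoed in every report: 1:1 stoichiometry; fast
exchange; ligand self-association neglected in the binding equilibrium
(defensible here because the stacking constants are ~20× smaller than the
binding constants); and `D_complex ≈ D_obs(duplex in the mixture)` — the
complex diffuses like the duplex, which is ~15× heavier than the ligand.
An independently measured complex coefficient can be supplied to replace
the approximation, and the synthetic generator can set
`d_complex < d_free_dna` to quantify its bias.

The free-ligand coefficient must come from the most dilute available
measurement (`select_free_ligand_record` enforces this): self-association
depresses the apparent coefficient at working concentrations, which is
also the qualitative signature `check_concentration_trend` verifies.

Mole fractions outside [0, 1] by more than the stated measurement noise
abort the analysis rather than clip silently — such values mean the
two-state fast-exchange model is wrong for the inputs, not merely noisy.
Within-noise excursions clip with a warning.

**Uncertainty.**  First-order (delta-method) propagation of the stated
coefficient sigmas through the chain, with central-difference
sensitivities.  Near saturation the K_a distribution is strongly
heavy-tailed (samples where the bound fraction nears 1 push K_a toward
infinity), so the Monte-Carlo cross-check in the tests measures spread as
half the central 68.3% interval of 10⁴ samples; on the packaged study
inputs it brackets the delta-method sigma within a factor of 2 (ratios
≈ 1.4 and 1.6).  The raw MC standard deviation is meaningless there and is
not used.  The packaged study's own printed "± 0.3 mM⁻¹" on constants of
76 and 150 mM⁻¹ cannot be derived from its stated ±0.05 coefficient
errors; the delta-method sigma (±58 and ±135 mM⁻¹) is reported instead
and the printed figure is not targeted.

**Equilibrium solver.**  The inverse problem (complex concentration from a
known K_a) is the physical root of `K_a x² − (K_a(C_DNA + C_L) + 1)x +
K_a·C_DNA·C_L = 0`, computed in the citardauq form
`x = 2·K_a·C_DNA·C_L / (b + √(b² − 4·K_a²·C_DNA·C_L))` to avoid
cancellation at small K_a; `K_a = 0 → 0`.  Tests check it against a
bisection oracle and through exact generate→invert round trips.

## Chemical-shift perturbation

`Δδ = δ_free − δ_complex` per proton, raw values retained, reported to
3 decimals with decimal half-up rounding (banker's rounding on binary
floats would send a tabulated 0.0195 to 0.019).  Significance threshold
0.02 ppm on the rounded magnitude — the conventional level for these
systems.  A rounding-slack option (default on) admits values within
0.001 ppm below the threshold, because published highlight rules are
typically applied to rounded values and treat 0.019/0.020 as borderline;
both semantics are tested, and neither is asserted to be the only correct
reading.

Localization counts flagged DNA protons inside the nick-adjacent set —
the two base pairs flanking each face of the strand break, {T4, T5, G6,
T7} / {A14, C15, A16, A17} for the packaged decamer, configurable via the
nick-map JSON.  On the packaged tables, every strictly flagged proton of
compound 1 is nick-adjacent; compound 2 additionally flags G3 H1′
(0.022 ppm), two steps from the nick, so its summary reports predominance
rather than exclusivity.  One transcription quirk is documented rather
than reconciled: the G6 H1′ perturbation of compound 2 is printed as
0.095 ppm in the source tabulation while its printed shifts differ by
0.094; the package always reports the raw difference.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` and are
bit-reproducible for a fixed seed and spec.  Noise is additive
homoscedastic Gaussian on each observable (Hz / coefficient units / ppm)
— the study-style symmetric single uncertainties give no basis for
anything richer.  Defaults put the generators at the study's own scale:
the eight-point 0.013–0.789 mM dilution grid, the 13-proton limiting-shift
map of the packaged compound (|Δδ_max| from 27 to 746 Hz), ligand/duplex
coefficients ≈ 2.1/0.75 × 10⁻¹⁰ m² s⁻¹.

* Dilution tables are re-referenced after noise so the most dilute point
  is exactly 0, matching the measured-table convention; the exact inverse
  is therefore the offset-free fit.
* DOSY experiments average the true species coefficients with the
  equilibrium mole fractions; with `d_complex = d_free_dna` and zero noise
  the analysis chain recovers the true K_a to 1e-6 relative.
* CSP tables subtract injected perturbations from a per-unit baseline and
  add noise to the complexed column only.

What they do **not** emulate: correlated noise across protons (one
spectrometer run perturbs all shifts together), exchange broadening,
baseline/referencing drift, heteroscedasticity, and any spin physics.
Passing recovery tests therefore demonstrate estimator correctness under
the stated noise model, not robustness to real-spectrum artifacts.

**Recovery study** (tests and acceptance): 200 replicate dilution
experiments, true K_a drawn uniformly in [2, 10] mM⁻¹ (fixed seed), 3 Hz
noise, offset-free per-proton fits; the median relative K_a error must be
below 25%.  The median computed in the suite is ≈ 0.23.  The upper tail is
dominated by weakly responding protons (|Δδ_max| ≲ 90 Hz), and at the soft
end (fixed K_a = 2 mM⁻¹) the per-proton median alone rises to ≈ 0.30 —
quantitative support for averaging per-proton constants with explicit
exclusions rather than trusting any single proton.

## Problem sizes

Everything runs at desk scale: per-proton fits are 2–3-parameter
least squares on 7–8 points (multistart ×3); the recovery study is
200 × 13 fits (~20 s); Monte-Carlo checks use 10⁴ samples; the CSP
false-flag study uses 500 seeded tables.  The full pipeline on the
packaged tables completes in a few seconds.

## Limitations

* The isodesmic model assumes one stacking constant for all steps;
  dimerization-dominated or cooperative (nucleation–elongation)
  aggregation is out of scope, as is fitting diffusion data to an
  association model.
* The binding chain is strictly 1:1 and diffusion-based; K_a from
  chemical-shift titrations, Stejskal–Tanner fitting of raw gradient
  decays, and multi-site models are out of scope.
* CSP flagging is a threshold rule on magnitudes; it does not model
  exchange broadening, and the 0.02 ppm level is a convention, not an
  error analysis.
* The DNA-side mole-fraction relation is provided only as a consistency
  check (`mf_dna_consistency`): under the complex-diffuses-like-the-duplex
  approximation its contrast is near zero and the estimate is
  uninformatively noisy.
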