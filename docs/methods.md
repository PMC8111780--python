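# Methods

This note records the models implemented in shiftprobe, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## CSP titration analysis

**Metric.** The weighted shift change of an amide resonance is
CSP = sqrt(ΔδH² + (α ΔδN)²) ppm with α = 0.2 for glycine and 0.14 for all
other residues, applied according to the residue's own code. The metric is
sign-symmetric, non-negative, and reduces to |ΔδH| when ΔδN = 0.

**Concentration bookkeeping.** A titration is specified as ligand:protein
molar ratios. By default ligand totals are `ratio × P0` at constant protein
(no-dilution bookkeeping, appropriate when the stock is concentrated — a
0.5 M stock reaching 13.5 mM ligand adds under 3% volume). A stock-aware
mode applies conservation of moles: the cumulative added stock volume
dilutes both species while preserving the molar ratio exactly. A titration
is rejected as infeasible when the stock concentration does not exceed the
largest nominal ligand concentration.

**Peak tracking.** Later titration steps are matched to the reference by
nearest neighbour in the weighted shift space. A residue is flagged
`untracked` when its step displacement exceeds `max_jump` or when the
nearest peak carries a different residue label (the signature of
mis-tracking onto a neighbour, e.g. two peaks exchanging positions);
conflicting claims on one peak flag all claimants `overlapped`. Flagged
residues are excluded from profiles and fits, never zero-filled. The
`max_jump` default is 0.05 ppm per step for finely spaced titrations; the
pipeline default is 0.2 ppm because a geometric ratio ladder (2, 5, 10, 25,
50, 100) moves strongly perturbed fast-exchange peaks up to ~0.1 ppm in its
late steps.

**Classification.** "Significantly perturbed" is defined as
CSP > trimmed_mean + k·trimmed_SD, where the trim iteratively removes values
more than 3 SD above the mean until stable. The default k = 2 is standard
CSP practice; k = 3 is useful when only unambiguous binding-site residues
should enter the global fit. With per-dimension noise σ the endpoint CSPs of
unperturbed residues are folded-normal distributed, so a k = 2 threshold
admits a few percent of false positives by construction — the classifier
reports the threshold used so this is auditable.

## Global Kd fit

**Model.** One shared Kd and one non-negative amplitude per residue under
the total-concentration (ligand-depletion) isotherm; the quadratic form is
kept rather than the free-ligand approximation because protein (0.135 mM)
is not negligible relative to the smallest ligand totals. The free-ligand
limit CSPmax·L/(L+Kd) is recovered as P → 0 and is exercised in tests.

**Per-step CSP estimates for fitting.** Fitting uses the projection of each
step's 2-D displacement onto the residue's endpoint-trajectory direction
(fast-exchange peaks move on a straight line between free and bound
positions). The projection carries additive, sign-preserving noise; the
per-step CSP *magnitude* is biased upward when the true displacement is
comparable to the shift noise (magnitude of a noisy vector), which
systematically steepens the early part of a weak-binding curve and biases
Kd low by ~10% under the study conditions. Endpoint CSP profiles and
classification still use the magnitude, which is the quantity of record.

**Optimization.** The model is linear in the amplitudes given Kd, so the
solver profiles them out (variable projection) and searches log10 Kd alone:
multistart from 8 log-spaced points over [0.01, 1000] mM (bounds 1e-4 to
1e5 mM, amplitudes capped at 10 ppm), L-BFGS-B refinement, then a joint
`least_squares` polish at the optimum whose Jacobian provides
covariance-based standard errors (Kd SE transformed from the log scale).
Weights are relative and normalized to mean 1; the default is uniform
(matching an unweighted global fit), inverse-variance optional. A fit is
refused as underdetermined with fewer than (number of parameters + 1)
points or fewer than 3 distinct ligand concentrations.

**Uncertainty.** Two estimators are provided and labelled: the Jacobian
covariance SE, and a residual-resampling bootstrap. Bootstrap residuals are
pooled across residues and steps, centred, and inflated by sqrt(n/(n−p))
to undo least-squares variance shrinkage before resampling — without the
inflation, 95% intervals cover the truth in only ~85% of synthetic
replicates; with it, coverage is 90–93% across seed batches (the residual
few percent is the usual percentile-bootstrap small-sample effect at 36
points and 7 parameters). Bootstrap refits reuse the profiled solver with a
golden-section search bracketing the original optimum, which keeps 200
replicates under 0.2 s. Per-residue stratified resampling was evaluated and
rejected: with only 6 residuals per residue it underestimates
within-residue variance and lowers coverage.

## PRE topology

Intensity ratios I/Iref are computed per residue; exclusions are
`unassigned` (missing in the probe spectrum), `overlap` (an input
annotation — overlap cannot be inferred from centroid lists), and
`intensity_increase` (ratio above 1 + tol, default tol 0.2, the signature of
exchange-dynamics changes rather than proximity). Uncertainties use a flat
per-peak error of 5% of the mean reference intensity with first-order
propagation: σ_ratio = ratio·sqrt((σ/I)² + (σ/Iref)²), accurate to ~1%
against Monte Carlo at the intensity levels of interest. Smoothing is a
moving average with weights w_ij = exp(−d²/2σ_g²)/σ_j² over unexcluded
residues; "three-residue halfwidth" is read as half-width at half-maximum
(σ_g = 3/sqrt(2 ln 2) ≈ 2.548 residues; σ_g = 3 available), the window is
truncated at |d| > 4σ_g where weights fall below ~1e-4, and excluded
residues receive a smoothed value from neighbours without contributing.

## Secondary shifts and helix segmentation

ΔδCα = observed − random coil, using a bundled table of published
random-coil Cα values (id `wishart1995-ca`, recorded in every output); no
sequence-neighbour or temperature corrections are applied. Helices are
maximal runs of ≥ 4 consecutive residues with ΔδCα above 0.7 ppm, bridging
at most one interior residue that stays positive but dips below threshold;
missing residues break runs. The 0.7 ppm / 4-residue defaults are
conventional Cα helix criteria and are configurable; under the generator's
conditions (2.5 ppm offset, 0.2 ppm noise — offset-to-noise ratio typical
of a well-resolved helical membrane protein) boundary recovery within ±1
residue exceeds 95% of seeds because a boundary error requires a >3.5σ
noise excursion.

## CD preprocessing

MRE = θ_mdeg / (10·c·l·(n−1)) with c the molar concentration, l the path
length in cm and n−1 the peptide-bond count (the standard mean-residue
convention). Processing order: subtract the matched ligand-in-buffer
background, multiply by the dilution factor, normalize, then smooth with a
centred three-point window whose endpoints shrink to the available two
points. Wavelength grids must match exactly; no interpolation is performed.

## Oxidase kinetics

Turnover = 4·(slope_bg − slope_meas)/[E] in e⁻/s, with slopes from least
squares on [O₂] vs time inside user-specified windows (no automatic window
detection; windows must contain ≥ 3 samples). The 4 e⁻/O₂ stoichiometry is
oxidase chemistry and is a constant, not an option. Rate curves are fitted
as sums of hyperbolae with amplitudes profiled out by non-negative least
squares given the Km's; the Km multistart grid is screened by profiled SSR
and only the best starts are polished, which keeps a two-site fit ~10 ms.
Two-site results are ordered Km1 ≤ Km2 and flagged degenerate when the two
Km's coincide within 1% or one amplitude vanishes (only V1+V2 is then
identifiable). Model comparison reports the extra-sum-of-squares F-test
(α = 0.05, the deciding criterion) and AICc. With multiplicative noise the
F-test should be run on relative-error-weighted fits (weights 1/v²);
unweighted fits inflate the false-two-site rate from ~5% to ~10% because
the homoscedasticity assumption fails.

## Synthetic-data generator

The generator's defaults are the study conditions: 129-residue protein,
titration at P = 0.135 mM over ratios 2–100 with shared Kd 15 mM and
maximal CSPs of 0.55/0.29/0.18/0.29 ppm on four reporter residues
(0.01 ppm per-dimension shift noise per step); four helices at 29–39,
48–79, 93–106, 112–123 with 2.5 ppm Cα offset and 0.2 ppm noise; a
phenomenological exposure→attenuation curve r = r_min + (1−r_min)·x^γ
(γ = 2, r_min = 0.2, x = 1−exposure for a water-soluble probe, x = exposure
for a detergent probe) with 5% log-normal noise; and two-component turnover
kinetics (V 40/70%, Km 1.3/20 µM, 3% multiplicative noise, triplicates) with
a one-component condition (V 208%, Km 8.6 µM) for the ligand-saturated
regime. Peak positions are uniform over the amide window (7.0–9.5 /
105–130 ppm); CSP displacement directions are random but fixed per residue,
since the analysis uses magnitudes and projections but tracking needs 2-D
trajectories. All randomness flows from one spec seed through a named
stream per block.

What the generator does **not** emulate: peak overlap beyond random
near-coincidence, exchange broadening and intensity loss during titration,
slow/intermediate exchange, scalar/residual couplings, baseline and phase
artifacts, temperature drift, or any real micelle geometry (the PRE depth
curve is phenomenological). Passing closure tests therefore demonstrates
correctness of the estimators under their stated noise models, not
robustness to every pathology of real spectra — the exclusion flags and
robust classification are the mechanisms intended to absorb those in
practice.

## Validation studies and problem sizes

The studies in `shiftprobe.studies` (run by both `tests/test_acceptance.py`
and `scripts/acceptance.py`) use: 1000 random cases for CSP arithmetic;
100 seeds × 200 bootstrap replicates for the global-Kd closure (the six
reporter residues; the two loop residues without a printed amplitude use a
mid-range 0.25 ppm); 10 instances against a 400×400 grid oracle; 20 Monte
Carlo cases of 1e5 draws; 100 seeds for helix recovery; and 200 replicates
per generating model for selection rates. These sizes put the binomial
error of each estimated rate at 2–3 percentage points while keeping the
full suite around a minute on one core.

## Known limitations

- Peak tracking relies on residue labels carried by the peak lists for its
  mis-tracking check; fully unlabeled later steps degrade to
  distance-only tracking.
- The global fit assumes a single binding event shared by all fitted
  residues; residues dominated by indirect conformational effects with a
  different apparent affinity will inflate the SSR rather than be detected.
- Bootstrap coverage is calibrated for the additive-noise regime the
  projection estimator produces; magnitude-based curves from very noisy,
  weakly shifted residues would re-introduce bias.
- No exchange-regime modelling: intermediate-exchange broadening or slow
  exchange invalidates the CSP-proportional-to-bound-fraction assumption.
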