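# Methods

## Compartment model and assumptions

Tissue kinetics are described by an irreversible two-tissue compartment
model: delivery `K1` (mL/min/cm³) from arterial plasma into a free
exchangeable pool, efflux `k2` (min⁻¹) back to blood, and irreversible
transfer `k3` (min⁻¹) into a contained pool with no return (`k4 = 0`).
¹⁸F-fluciclovine is transported but not metabolized intracellularly, so
accumulation in the contained compartment is modelled as trapping over the
25-minute acquisition. The PET-measurable signal is
`C_T = v_b·C_b + (1 − v_b)·(C_f + C_c)` with `v_b` the fractional blood
volume. The macro-parameter `Ki = K1·k3/(k2 + k3)` is the net plasma-to-
tissue clearance and is always derived from the fitted micro-parameters.

Assumptions worth making explicit:

- **Input function.** The model is driven by an arterial (aorta-like)
  curve fed directly as the plasma input; by default whole blood and
  plasma are identified (`C_b ≡ C_p`), with an optional constant
  plasma-to-blood ratio. No dispersion or delay correction is applied;
  delay fitting is not implemented.
- **Decay correction.** All concentrations are assumed decay-corrected to
  injection time, as reconstructed PET data are; the model carries no
  physical-decay term.
- **Units.** Time is minutes internally (frame schedules are stored in
  seconds and converted on use); concentration is kBq/mL; `K1` is
  mL/min/cm³ with tissue density taken as 1 g/cm³ wherever mass units
  would be needed.

## Numerical scheme

The two-state system is lower-triangular and linear, so the forward model
uses an exact exponential update on a uniform fine grid (default step
0.5 s, one tenth of the shortest frame), with the input treated as
piecewise linear within steps. For that input class the update is exact up
to roundoff and unconditionally stable; coefficients switch to Taylor
series when `(k2+k3)·Δt < 10⁻⁴` to avoid cancellation. The recursion is
evaluated as a first-order recursive filter (`scipy.signal.lfilter`), so a
full forward evaluation is O(n) in compiled code (~0.5 ms per curve).
Against a generic stiff integrator (LSODA at rtol 10⁻¹⁰) driven by the
same piecewise-linear input, the solution agrees to ~10⁻⁹ relative.

Frame averaging integrates `C_T` over each frame by trapezoidal quadrature
on the fine grid and divides by frame duration; mid-frame timestamps are
`(start+end)/2` in minutes. The canonical schedule constructor produces
the 32-frame protocol (12×5 s, 3×10 s, 3×30 s, 6×60 s, 8×120 s).

## Fitting

`fit_tac` minimizes the weighted residual sum of squares between the
frame-averaged model and the measured TAC with bounded least squares
(trust-region reflective, relative tolerances 10⁻⁸). Bounds are a
generous physiologic envelope for adipose tissue and muscle:
`K1 ∈ [0, 2]` mL/min/cm³, `k2 ∈ [10⁻⁶, 5]` min⁻¹, `k3 ∈ [0, 2]` min⁻¹,
`v_b ∈ [0, 0.3]`. Because the 4-parameter surface can carry local minima,
10 Latin-hypercube starting points (fixed seed, hence bit-reproducible
results) are run and the lowest-WRSS solution kept, ties broken by the
lexicographically smallest `(K1, k2, k3, v_b)`. Default weighting is
uniform; `duration_over_value` (weight ∝ Δt/value, a count-statistics
variance proxy) is available. Standard errors come from the Gauss-Newton
covariance at the optimum; AIC is `n·ln(WRSS/n) + 2p` with `p = 4`.

Identifiability: on noiseless canonical-schedule data the fit recovers
`K1`, `k2+k3` and `Ki` to ~10⁻¹² %; under the default noise model the
Monte-Carlo coefficient of variation of `Ki` (~6 %) is several-fold
smaller than that of `k3` (~25 %) — the macro-parameter is the robust
quantity, as expected for an irreversible model.

## Patlak graphical analysis

`patlak_estimate` regresses `C_T(t)/C_p(t)` on `∫₀ᵗC_p ds / C_p(t)` over
frames with mid-time ≥ `t_star` (default 10 min, well past the bolus
peak). For irreversible tracers the asymptotic slope is `(1 − v_b)·Ki`.
The identity `C_T = Ki·∫C_p + (k2/(k2+k3))·C_f` (for `v_b = 0`) makes the
finite-time error explicit: the lag term `∝ C_f/C_p` keeps drifting as
long as the input's intermediate decay component persists, so with the
default bolus input the 10–25 min slope sits 1–2.4 % below `Ki` depending
on the parameter set (slower `k2+k3` → larger bias). Patlak is therefore
used as an independent cross-check of the compartment fit (agreement
within 5 % on noiseless data), not as the primary estimator.

## VOI quantification

VOIs are refined in two sequential steps on grid-aligned volumes (voxel-
index space; registration is out of scope): a CT window keeps adipose
densities −190…−30 HU (closed interval), then voxels above the 97.5th
percentile of in-VOI PET values are removed to suppress spill-over from
adjacent muscle. The percentile uses linear interpolation between closest
ranks; only strictly-above voxels are dropped, so at most 2.5 % of the VOI
(plus threshold ties, which are kept) can be excluded. The percentile
value is a package default recorded in output metadata — the imaging
protocol this mirrors applies an exclusion without publishing its
threshold. VOIs below 5.0 mL raise an error unless explicitly allowed.

`SUV_mean` (g/mL) is the in-mask mean concentration (kBq/mL) divided by
injected dose per body weight (kBq/g = MBq/kg numerically); the static SUV
frame designation (minutes 4–14, 10 min) is stamped into the result
metadata. The canonical phantom spacing is 2.344 mm isotropic.

## Synthetic data

The generators define the study conditions; all are deterministic per seed
and retain their ground truth.

- **Input:** Feng tri-exponential bolus
  `C_p(t) = (A1·t − A2 − A3)e^{λ1 t} + A2 e^{λ2 t} + A3 e^{λ3 t}` with the
  classic coefficients (A1 = 851.1 kBq/mL/min, A2 = 21.9, A3 = 20.8
  kBq/mL; λ = −4.13, −0.12, −0.01 min⁻¹), giving an arterial peak inside
  the first minute, consistent with the 12×5 s early frames.
- **TAC noise:** zero-mean Gaussian with SD
  `noise_level·sqrt(value/Δt_min)` and clipping at zero — a count-
  statistics proxy in which long frames are less noisy. Default
  `noise_level = 0.2` puts ~5 % noise on late 2-min frames of a
  supraclavicular-like curve, a moderate clinical regime.
- **Depot priors:** log-normal per parameter with medians chosen so median
  `Ki` is 0.012 (supraclavicular), 0.008 (upper chest), 0.005 (abdominal)
  and 0.036 (muscle, ≈3× supraclavicular) mL/min/cm³; log-SD 0.25 (0.2
  for `v_b`) makes neighbouring depots overlap. Only the two anchor values
  (supraclavicular 0.012 and the ~3× muscle ratio) are externally
  motivated; the rest is synthetic calibration.
- **Cohort:** BMI uniform on 20–38 (normal through obese); supraclavicular
  `K1` — and hence `Ki`, proportionally — scaled by
  `exp(bmi_effect·(BMI − 29))` with default slope −0.04 per BMI unit, and
  by `t2d_effect = 0.6` for the T2D-flagged fraction (default 5/36).
  These defaults produce a Spearman(BMI, fitted SCV Ki) around −0.4 to
  −0.6 at n = 50.
- **Phantom:** rectangular blocks (three adipose depots with Gaussian HU
  jitter inside the adipose window, a muscle block at +45 HU, a hot blood
  pool) on a 40³ grid at 2.344 mm; the supraclavicular block is 500 voxels
  ≈ 6.44 mL, above the 5.0 mL VOI floor.
- **qPCR:** reference Ct ~ N(18, 0.5); target Ct = 18 + 5 −
  log₂(fold-change)·[group] + N(0, 0.8), so ΔCt drops by exactly 2 per
  4-fold change in the noiseless limit. Default design: 7 vs 16 subjects
  (low vs high BAT volume), five-gene panel vs RPLP0.

What the generators do **not** emulate: scanner physics (scatter, randoms,
partial volume, PSF), anatomy and registration error, input-function
measurement noise, inter-frame motion, or biological covariance between
depots within a subject (depot parameters are drawn independently).
Passing tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to those real-data effects.

## Statistics

Paired depot comparisons route by Shapiro-Wilk normality at α = 0.05 per
depot: repeated-measures ANOVA with Tukey correction (studentized range on
the subject×depot error term) when all depots are normal, otherwise the
Friedman test with Dunn's mean-rank z-tests and Bonferroni family
correction. Independent comparisons: Mann-Whitney U for two groups (exact
for combined n ≤ 20 without ties, tie-corrected normal approximation
otherwise), one-way ANOVA + Tukey for ≥3 normal groups, Kruskal-Wallis +
Dunn as the ≥3-group rank fallback. Correlations use Spearman's rho with
midranks. All tests are two-sided at α = 0.05. Relative gene expression is
`2^(−ΔCt)` against the housekeeping reference (no calibrator sample). BMI
categories use the WHO cutoffs 25/30; the high/low BAT-volume split is at
20 mL. Whole-tissue clearance is the product volume × Ki (e.g. 100 cm³ ×
0.012 mL/min/cm³ = 1.2 mL/min).

Rank tests are validated against brute-force oracles (exact enumeration of
Mann-Whitney rank assignments, the Friedman and Spearman rank formulas)
for small n.

## Problem sizes and reproducibility

The shipped analysis uses a 50-subject cohort (4 depots each, 200 fits),
200 Monte-Carlo replicates for the recovery study, and a 4×4×4 grid of
noiseless truths — sizes at which every summary statistic is stable across
seeds while a full run stays in the minutes range on one CPU. All
randomness flows from explicit integer seeds; repeated runs are
bit-identical. `scripts/acceptance.py --seed N --out f.json` recomputes
every headline number from scratch.

## Known limitations

- Patlak's finite-time bias (above) means the graphical slope is a
  cross-check, not a reference value, at this acquisition length.
- `k2` and `k3` are individually poorly identified at realistic noise;
  only `K1`, `k2+k3` and `Ki` should be interpreted.
- The VOI spill-over threshold is a stand-in convention; results over
  phantoms are exact by construction but the percentile value itself is
  not externally validated.
- No voxel-wise (parametric-image) fitting, no reversible (`k4 > 0`)
  variants, no registration or anatomical VOI placement.
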