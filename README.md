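# bcaapet

Kinetic analysis of dynamic PET with an ¹⁸F-labelled branched-chain
amino-acid tracer (¹⁸F-fluciclovine, a synthetic L-leucine analog) in
adipose tissue depots and skeletal muscle. The package is written for
imaging scientists who want to quantify BCAA uptake by human brown adipose
tissue (BAT): it provides the forward compartment model, the TAC fitting
machinery, CT/PET volume-of-interest quantification, synthetic data
generators with known ground truth, and the cohort-level statistics used to
compare depots — everything needed to run the analysis end to end without
access to clinical images.

## Model

Tissue kinetics follow an irreversible two-tissue compartment model. Tracer
moves from arterial plasma `Cp(t)` into a free tissue compartment `C_f`
with delivery rate `K1` (mL/min/cm³) and efflux rate constant `k2`
(min⁻¹), and is transferred irreversibly (`k4 = 0`) into a contained
compartment `C_c` with rate constant `k3` (min⁻¹):

    dC_f/dt = K1·Cp(t) − (k2 + k3)·C_f(t)
    dC_c/dt = k3·C_f(t)

The measurable PET concentration mixes tissue and blood signal through the
fractional blood volume `v_b` (mL/mL):

    C_T(t) = v_b·C_b(t) + (1 − v_b)·(C_f(t) + C_c(t))

The macro-parameter of interest is the net uptake rate

    Ki = K1·k3 / (k2 + k3)   [mL/min per cm³ tissue],

the steady-state clearance of tracer from blood into tissue. Dynamic data
use the canonical 32-frame schedule (12×5 s, 3×10 s, 3×30 s, 6×60 s,
8×120 s; 25 min), static SUV uses the 4–14 min frame, and adipose VOIs are
restricted to −190…−30 HU with a PET percentile cut against muscle
spill-over. Details, defaults and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import bcaapet as bp

schedule = bp.FrameSchedule.canonical()
input_fn = bp.default_input_function()          # Feng bolus, peak < 1 min

truth = bp.KineticParameters(K1=0.05, k2=0.40, k3=0.12632, vb=0.03)
print(f"true Ki = {bp.macro_ki(truth):.5f}")    # 0.01200 mL/min/cm^3

tac = bp.simulate_tac(truth, input_fn, schedule, noise_level=0.2, seed=1)
fit = bp.fit_tac(tac, input_fn)
print(f"fitted Ki = {fit.ki:.5f}, K1 = {fit.params.K1:.4f}")
slope, _ = bp.patlak_estimate(tac, input_fn, t_star=10.0)
print(f"Patlak slope = {slope:.5f}")
print(f"100 cm^3 depot clears {bp.clearance_estimate(100, fit.ki):.2f} mL/min")
```

prints

```
true Ki = 0.01200
fitted Ki = 0.01228, K1 = 0.0503
Patlak slope = 0.01338
100 cm^3 depot clears 1.23 mL/min
```

i.e. the nonlinear fit recovers the net uptake rate of a noisy
supraclavicular-like curve to about 2 % on this single noise realization
(the Monte-Carlo median error is under 1 %), the graphical Patlak slope
sits near `(1 − v_b)·Ki` within its noise and finite-time bias, and a
nominal 100 cm³ BAT depot at this uptake rate clears about 1.2 mL of
plasma per minute.

The full analysis chain lives under `analysis/` as numbered drivers:

1. `01_simulate_cohort.py` — 50-subject cohort (BMI, T2D, depot TACs)
2. `02_fit_kinetics.py` — fits all 200 depot TACs, tabulates Ki
3. `03_depot_statistics.py` — paired depot tests, BMI/T2D contrasts,
   clearance estimates
4. `04_phantom_voi.py` — HU masking, spill-over exclusion and SUV on a
   constructed phantom
5. `05_qpcr_expression.py` — relative gene expression (2^(−ΔCt) vs RPLP0)
   between high/low BAT-volume groups

Each writes its tables under `results/`.

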