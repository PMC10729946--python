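# Methods

## Scope and model

`optospiral` simulates optogenetic termination of reentrant arrhythmia in a
two-dimensional sheet of light-sensitized mouse ventricular tissue and
provides the measurement pipeline used to quantify it.  The electrical
substrate is the monodomain equation

    ∂V/∂t = ∇·(D ∇V) − (I_ion + I_ChR2)/C_m

solved on a 100 × 100 lattice with 0.25 mm node spacing (25 mm × 25 mm),
C_m = 1.0 µF/cm², D = 0.00014 cm²/ms and no-flux boundaries.  The
illumination is global and uniform, characterized by its irradiance LI
(µW/mm²) and pulse length PL (ms).

### Membrane model

I_ion is a reduced four-variable formulation written in physical voltage
units (V in mV, gates v, w in [0, 1]) rather than a biophysically detailed
Markov-chain reconstruction.  Its currents are:

- **fast inward** J_fi = −(v/τ_d)·(1−u)·(u−u_thr), active above an
  availability-dependent threshold u_thr = u_c + q_vc·(1−v), where
  u = (V−V_rest)/V_amp.  The coupling q_vc captures the rise of the
  effective excitation threshold when fast channels are partially
  inactivated — the ingredient that makes sustained sub-threshold
  depolarization reduce rather than enhance excitability.
- **outward repolarizing** J_so = u/τ_r above threshold (conductance-like:
  weak at the front foot, fast at the plateau, giving the triangular murine
  action potential), and below threshold an inward-rectifier-like diastolic
  leak (u/τ_0)·exp(−u/u_k)·[(1−a) + a·(1−w)].  The exponential knee at u_k
  makes the resting membrane stiff while letting the leak fade above
  ≈ −75 mV, so a sustained inward photocurrent produces only a bounded
  diastolic elevation until it exceeds the knee current and fires the cell;
  the activity weighting (a = 0.7 on the slow gate w) makes recently active
  tissue leak harder than long-quiescent tissue such as the spiral core.
- **fast-gate kinetics**: inactivation with τ_v⁺ above threshold; recovery
  below threshold toward a voltage-dependent steady state
  v∞(u) = 1/(1+exp((u−u_h)/k_h)) with time constants τ_v1⁻/τ_v2⁻ (split at
  u_v).  v∞ encodes steady-state inactivation: full availability at rest,
  strong inactivation at depolarized diastolic potentials.
- a **slow inward (dome) current** J_si is part of the formulation but its
  activation midpoint is placed outside the physical voltage range in the
  murine calibration (mouse ventricular APs have no dome).

Gates are advanced by Rush–Larsen exponential updates, the voltage and the
photocycle by forward Euler, in a single unsplit explicit step at
dt = 0.01 ms (the solver refuses dt above min(dx²/4D, 0.2 ms)).  The scheme
is fully deterministic; identical configurations give bitwise identical
recordings.

### ChR2 photocurrent

Light sensitivity is a four-state channelrhodopsin-2 photocycle
(C1 → O1 ↔ O2 → C2 → C1) with activation rates linear in irradiance, and
the empirical inward rectification

    I_ChR2 = g_ChR2 (O1 + γ O2) [10.6408 − 14.6408 exp(−V/42.7671)],

the bracket being the analytic product G(V)(V − E_ChR2) with E_ChR2 = 0 mV
(finite at V = 0; sign reversal at +13.65 mV).  Under constant light the
open fraction shows the characteristic early peak followed by a lower
plateau.  Photocycle rates are of the standard literature magnitude
(closing 0.10/0.05 per ms, dark recovery 3.3·10⁻⁴ per ms, interstate
conversion 0.053/0.023 per ms, activation 0.8/0.2 per ms per mW/mm²);
γ = 0.1.

### Calibration

The free parameters of the reduced membrane model were fixed once against
the tissue-level observables that define the study conditions:

| observable | target | achieved |
|---|---|---|
| plane-wave CV at the standard D | 43.9 cm/s | 43.9 |
| resting potential | ≈ −80 mV | −80 |
| AP peak / APD50 / APD90 | mouse-like | +31 mV / 9.5 ms / 15 ms |
| stable single spiral | rigid rotation | 34.7 Hz, stationary core |
| 500-ms single-cell optical threshold | 20–25 µW/mm² | 23.7 |

g_ChR2 is calibrated by bisection so the single-cell threshold falls in the
upper part of the prescribed 20–25 µW/mm² band, which places the
tissue-level sub-/supra-threshold boundary at 25 µW/mm² on the standard
5-µW/mm² grid.  The calibrated set ships as the frozen default
configuration (`optospiral/data/default_config.yaml`); all parameters are
overridable through the YAML config.

### Spiral initiation

Cross-field initiation is implemented as a broken plane wave: an S1 pulse
profile computed on a 1D cable is transplanted into the lower half-plane of
the sheet (equivalent to the S2 half-field stimulus timed into the S1
repolarization tail), and the free wave end curls into a single spiral.
The state is settled for ≥ 500 ms and verified to carry exactly one phase
singularity.  Initial-condition ensembles are snapshots at n equally spaced
phases of one rotation.

## Measurement pipeline

- **Tip tracking**: intersection of the V = −50 mV isoline with its own
  dV/dt = 0 line, solved exactly per lattice plaquette from the bilinear
  interpolants; duplicate detections within 0.5 mm are merged.  On rigid
  rotors the planted-truth error is below one node.
- **Core measurement**: binarize at −50 mV (light morphological cleanup),
  Canny edges (σ = 1 node, hysteresis 0.1/0.3), circular Hough transform
  over 3–45 node radii.  When tracking a dissolving core, candidates are
  selected by centre consensus across frames and the radius-vs-time line is
  fitted by ordinary least squares with residual trimming.
- **Termination**: an episode counts as terminated when, after light-off
  plus a 100-ms relaxation, the whole domain stays below −70 mV for 100 ms.
  The termination time is the interval from light onset to the last
  arrhythmia peak of the probe trace; counted peaks need ≥ 20 mV prominence,
  ≥ 10 ms separation and a genuine downstroke (below −40 mV within 60 ms),
  which excludes the sustained light-driven elevated phase.
- **Dominant frequency**: periodogram peak above a 2-Hz DC-exclusion floor,
  reported with its spectral resolution.
- **Excitation threshold**: lowest grid irradiance whose pulse drives the
  spatial minimum of V above −55 mV (midway between rest and the
  light-driven plateau), i.e. the whole domain is simultaneously
  depolarized beyond the bounded sub-threshold elevation.

## Synthetic optical mapping

The generator emulates the murine panoramic-imaging geometry (64 × 64 px,
133 µm/px, 1 kHz): an Archimedean-spiral phase map through a stylized
upstroke/exponential-repolarization waveform, an unexcited core disk whose
radius follows a configurable trajectory behind a refractory annulus, plus
additive Gaussian noise, linear baseline drift and a uniform blue-light
crosstalk step that is removed by division with the recorded light signal.
It plants rotation frequency, core-radius trajectory and last-peak time, so
the whole analysis chain is validated closed-loop (frequency to spectral
resolution, growth slopes within 5%, last-peak times within one frame).
It does not model dye spectra, photon transport, motion artifacts or 3D
depth averaging, so passing these tests validates the measurement
operators, not the optics of real recordings.

## Problem sizes

Shipped campaign defaults are desk-scale: the dose–response grid is
3 LI × 3 PL × 5 ensemble members (the full published-scale campaign with
25 initial conditions per point is cluster-scale and sits behind
`--full-grid`), the critical-pulse-length search uses bisection at 2-ms
resolution from a single canonical initial state, and acceptance
measurements use a 600-ms settled spiral with 150-ms analysis recordings.

## Known limitations

The reduced membrane model reproduces the calibration targets and the
qualitative régime structure (bounded reversible sub-threshold response at
low irradiance, a sharp excitation boundary at 25 µW/mm², monotone
dose–response, short termination transients at high irradiance), but not
every published-scale observable:

- The rotor's tip-trajectory enclosing circle measures 0.37 mm over the
  first rotation after settling but wobbles between 0.37 and 0.53 mm on
  later rotations (roughly one to two lattice nodes); the sub-threshold
  voltage trough spans one node (0.25 mm).
- The rotor rotates at ≈ 35 Hz with a wavelength of ≈ 5 mm, i.e. the spiral
  is tightly wound (several turns fit in the sheet).  Supra-threshold light
  therefore excites the abundant excitable gap everywhere at once, and
  termination is abrupt (within one rotation) at every irradiance above the
  boundary.  The slow core-dissolution mode — a depolarized core growing
  over hundreds of milliseconds, with measurable radius-growth slopes and
  critical pulse lengths of 80–500 ms — requires a domain-scale wavelength
  (one turn per sheet) together with a sub-millimetre core, a combination
  this reduced formulation does not reach: in its parameter space, tiny
  cores demand short wavelengths for rotor stability.  Consequently
  critical pulse lengths are much shorter than published (a few ms at
  50 µW/mm²) and no growing-core track can be extracted from the solver's
  own terminations (the synthetic generator covers that pipeline instead).
- Nominally sub-threshold irradiances of 15–20 µW/mm² already disrupt the
  rotor in some phases (the wavelength grows transiently and the wave
  collides with its refractory tail), so fully reversible behaviour holds
  only up to ≈ 10 µW/mm².
- No fibre anisotropy, tissue heterogeneity, 3D scroll dynamics, bidomain
  effects, temperature dependence or ChR2 variants.
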