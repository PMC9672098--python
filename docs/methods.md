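# Methods

This note documents the models, estimators and numerical choices behind
`mechanofeedback`, and what the synthetic-data tests do and do not establish
about real imaging data.

## The single-junction model

A cell–cell junction is modeled as an overdamped active elastic element.
Four state variables evolve: edge length `L` (µm), rest length `L0r` (µm),
myosin line density `m` (a.u./µm) and the turnover target density `m0t`
(a.u./µm):

```
gamma dL/dt   = T(t) - k L0r ln(L/L0r) - beta m^2/(m_sat^2 + m^2)
dm/dt         = -(m - m0t)/tau - (m/L) dL/dt + sigma xi(t)
dL0r/dt       = (L - L0r)/tau_r                  (viscoelastic remodeling)
dm0t/dt       = c m0t (1/L) dL/dt                (mechanical feedback)
```

The length equation balances external tension against elasticity and
actomyosin contractility under friction `gamma`.  The density equation
contains the three ingredients of a concentration oscillator: turnover
toward `m0t` with time `tau`, advection/dilution by length change (an exact
conservation law: with turnover, feedback and noise off, `m*L` is constant),
and white density noise.  Rest-length remodeling gives slow plastic
deformation.  The feedback law recruits myosin at a rate proportional to the
strain rate; it integrates exactly to the power law

```
m0t(t) = m0t(0) * (L(t)/L(0))^c  =  m0t(0) * Lambda^c ,
```

so the feedback coefficient `c` is also the exponent relating steady myosin
levels to total strain `Lambda` — the form used for embryo-scale prediction.

Two nonlinearities are deliberate design choices.  The elastic tension is
logarithmic in `L/L0r` (large-deformation elasticity; linear for small
strain, divergent under compression) and the active tension is a Hill-2
sigmoid in `m` (cooperative myosin assembly, saturating at `beta`).  With
purely linear elasticity `k (L - L0r)` and contractility `beta m`, the
dilution nonlinearity `m ~ 1/L` makes the contracted branch of the
oscillation run away and the edge collapses to zero length — no bounded
oscillation exists at any distance from the instability we probed.  The two
sigmoidal/log forms linearize to the same fast subsystem at the fixed point
(all stability formulas below use local slopes) and saturate the Hopf
instability into a stable limit cycle, as required for sustained oscillation.

### Linear stability and oracles

For fixed `L0r` and `m0t`, the fast `(L, m)` subsystem has the fixed point
`m* = m0t`, `L* = L0r exp((T - Ta(m*)) / (k L0r))` and Jacobian

```
[ -k_el/gamma              -s_a/gamma            ]
[  k_el m*/(gamma L*)      -1/tau + s_a m*/(gamma L*) ]
```

with `k_el = k L0r / L*` and `s_a = dTa/dm` at `m*`.  Oscillation sets in
when the trace crosses zero; the determinant `k_el/(gamma tau)` stays
positive, so the bifurcation is a Hopf with angular frequency
`~ sqrt(k_el/(gamma tau))` at threshold.  `linear_stability` returns the
eigenvalues and the linear period `2*pi/|Im lambda|`; `hopf_contractility`
the threshold `beta`.  Simulated noise-free periods agree with the linear
prediction to well under 10% near the threshold (this is a tested oracle).

### Default parameters

All model units are conventions (tension in arbitrary units, density in
units of its baseline):

| parameter | default | rationale |
|---|---|---|
| `elastic_k` | 1.5 a.u./µm | with `gamma`, `tau` below sets the linear period to ~73 s, the observed timescale of junctional oscillations |
| `friction_gamma` | 10 a.u.·s/µm | length relaxation time `gamma/k ≈ 7 s`, fast vs. turnover |
| `contractility_beta` | 41 a.u. | 2.5% past the Hopf threshold (40): stable limit cycle |
| `contractile_saturation` | 1.0 a.u./µm | half-saturation at the baseline density |
| `turnover_tau` | 20 s | junctional myosin turnover, tens of seconds |
| `rest_remodel_tau` | 300 s | plastic remodeling much slower than the oscillation |
| `baseline_density` | 1.0 | density unit |
| `feedback_c` | 1.0 | order-one coefficient, within the estimated ventral–dorsal range |
| `noise_sigma` | 0.05 a.u./µm/√s | stationary density fluctuations ~16% of baseline |
| `dt` | 0.05 s | ≪ all timescales; conservation is exact by construction (below) |

### Discretization

The step is an explicit split scheme at fixed `dt`: Euler for the length,
turnover and remodeling updates and Euler–Maruyama for the noise, but the
advection and feedback sub-steps are applied as exact log-increments
(`m <- m L_old/L_new`, `m0t <- m0t (L_new/L_old)^c`).  This makes the two
structural identities of the model — mass conservation under pure advection
and the `Lambda^c` feedback integral — hold to machine precision at any
`dt`, so they serve as sharp regression tests rather than
discretization-limited ones.  Density is clipped at zero after the noise
increment.  A step that would drive `L <= 0` raises with advice to reduce
`dt`; simulated trajectories in the default regime are bounded (checked
across seeds and noise levels).

## Rate estimation

Strain and myosin rates are incremental relative rates with the current
frame as reference, reported per minute, Gaussian-smoothed (default
`sigma = 10 s`, kernel truncated at `4 sigma` and renormalized at the
boundaries).  The default estimator is the log-increment
`ln(x_{i+1}/x_i)/dt`.  Two properties motivate this choice over the plain
forward difference `(x_{i+1}-x_i)/(x_i dt)` (still available as
`method="forward"`): its cumulative sum telescopes exactly to the log
fold-change (the definition of total strain), and it is unbiased under
multiplicative fluctuations.  The forward difference carries a positive
convexity bias `~(1-rho) CV^2` per frame; at 30-s sampling with ~16% myosin
fluctuations this adds ~0.04/min of spurious apparent recruitment to every
edge, which overwhelms the weak dorsal signal and inflates dorsal feedback
coefficients several-fold.

Correlation functions are per-lag Pearson coefficients over the overlapping
segments (means and variances recomputed per lag).  In
`cross_correlation(x, y, ...)` a peak at positive lag means `y` is delayed
relative to `x`.  The dominant period is the first local maximum of the
autocorrelation at positive lag exceeding a white-noise significance floor,
Bonferroni-corrected for the number of lags examined (so pure noise is
declared aperiodic in ~95% of realizations), with parabolic sub-sample
refinement.  Strain-rate peaks are local maxima with prominence ≥ 1 SD and
separation ≥ 30 s.

The peak-aligned average collects complete windows around strain-rate peaks
across all tracks and averages strain rate, myosin rate and the central-
difference myosin acceleration.  The timing-asymmetry statistic is the time
from the peak to the first post-peak myosin-rate minimum minus the time from
the last pre-peak minimum to the peak.  A limitation worth stating: for any
oscillation whose myosin-rate trough phase-locks a few seconds ahead of the
strain-rate peak — which dilution alone produces, with or without feedback —
this statistic is positive with magnitude close to the oscillation period
minus twice the trough offset.  It therefore separates phase-locked
dynamics from phase-free ones (its value on phase-randomized alignments is
near zero, with a wide null band set by the smoothing correlation length),
but its magnitude should not be read as a direct measure of feedback
strength; in the simulated ensembles the feedback ablation mainly shifts the
oscillation period (feedback raises the oscillation frequency), not the
symmetry of the aligned curve.

## Feedback-coefficient estimation

Edges are classified by orientation (within 30° of the AP axis /
within 30° of the DV axis / unclassified), binned into equal-width DV bins
(default 10 over the trunk half-circumference), and each edge contributes
its time-mean strain and myosin rate over a stated developmental window
(default minutes 10–20, the plateau of the furrow pull).  The feedback
coefficient of a bin is the least-squares slope through the origin,
`c = sum(xy)/sum(x^2)`, with a t-based 95% CI from the residual variance
(coverage verified by simulation).  Through-origin fitting encodes the
model's structural zero: no strain rate, no feedback-driven recruitment.
Bins with fewer than 30 edges are excluded.  Cross-bin and cross-orientation
comparisons use a Welch unequal-variance t-test on the slope estimates with
Welch–Satterthwaite degrees of freedom.  The DV profile is summarized by the
per-bin coefficients plus a linear fit of coefficient against bin center;
profile endpoints are read off the fitted line, which pools information
across bins and is robust to the weak identifiability of the dorsal-most bin
(where per-edge strain signal drops below the fluctuation floor).

## Synthetic embryos

The generator emulates the germband during ventral-furrow formation in a
flat (AP, DV) chart.  Each edge receives a DV position (uniform on the
half-circumference), an orientation drawn from two 10°-wide cones around the
AP and DV axes, and an imposed strain rate

```
eps_dot(edge, t) = peak * max(0, 1 - g * dv) * |sin(theta)|^2 * ramp(t) * mutant_scale
```

with `peak = 0.12/min`, gradient `g = 0.0027/µm` (a linear decay to ~25% of
the ventral value at the dorsal end), quadratic orientation weighting, and a
trapezoidal time ramp (window minutes 2–22, 3-minute rise/fall) over a
25-minute recording sampled every 30 s.  Lengths integrate this field
exactly; myosin comes from the junction model driven kinematically along the
imposed length history (turnover, dilution, noise, and feedback with an
edge-specific coefficient interpolated linearly from 1.0 ventrally to 0.5
dorsally).  Each edge's noise stream derives from its own spawned child
seed.  The mutant condition attenuates the strain field uniformly
(`mutant_scale = 0.4`, chosen so wild-type/mutant rates differ by the 2.5×
factor characteristic of furrow-defective mutants) with geometry and noise
paired to the wild type, isolating the effect of the attenuation.

What the generator does **not** emulate: cell-resolved vertex geometry and
T1 topology, segmentation/tracking errors, spatially correlated mechanics
between neighboring edges, curvature/metric distortions of the embryo
surface, and any genetically patterned myosin input other than the feedback-
coefficient gradient.  Passing recovery tests therefore demonstrate that the
estimators are consistent and unbiased under the model's own assumptions —
not that those assumptions hold in real embryos.

## Embryo-scale prediction

Per edge, total strain `Lambda(t)` is the exponentiated cumulative sum of
the raw interval log-strains (exactly `L(t)/L(0)`).  Predicted myosin is
`A * Lambda(t)^{c(dv)}` with `c(dv)` either the fitted profile or an imposed
one, and `A` a single global constant fitted by least squares over a stated
window; when scoring self-consistency the constant is fitted after the
strain episode completes, where the quasi-steady law applies (during the
ramp, measured myosin lags its target by the turnover factor
`1/(1 + tau * eps_dot)`, a ≤3% transient).  Predictions are compared on
bin-averaged DV profiles.  The default accuracy is the normalized-L1 score
`max(0, 1 - sum|pred - meas| / sum(meas))`, interpretable as the fraction of
the measured profile accounted for; a Pearson variant mapped to [0, 1]
scores pattern fidelity irrespective of scale (flat profiles score a neutral
0.5).  The L1 score is the headline number; the Pearson variant is the
appropriate reading for "accuracy rises as the pattern emerges", since the
L1 score is trivially high while both profiles are still flat.

## JMA metric

Junctional myosin accumulation is junctional intensity normalized to the
cytoplasmic pool, both background-subtracted.  The default junctional
estimator integrates the excess over the cytoplasmic level across the edge
mask dilated by 2 px (capturing PSF-spread signal) and normalizes per
original edge pixel; it is exact on unblurred renders for any dilation and
recovers imposed junction:cytoplasm ratios within ~1% under a 1-px PSF at
SNR 10.  The plain dilated-band mean is available (`method="band_mean"`) but
compresses ratios toward 1 under blur, since the band averages junctional
excess over cytoplasm-dominated pixels.  The synthetic renderer excludes a
3-PSF-wide guard zone next to the dark frame from the cytoplasm mask so
border bleed does not depress the reference level.  Background defaults to
the modal intensity of a stated dark region.  All processing is 2-D.

## Reproducibility

One master seed drives everything; child seeds are spawned with
`numpy.random.SeedSequence` in documented order (pipeline: 0 = wild type,
mutant paired to 0).  Tables are tab-separated text with `# key=value`
headers and 17-significant-digit floats; write→read round trips are exact,
and rerunning any pipeline with the same configuration reproduces outputs
byte for byte.

## Problem sizes

The shipped analyses use 500-run × 600-s ensembles for fluctuation
statistics, 4000-edge embryos (~400 edges per DV bin, the regime where the
per-bin fits are well-conditioned), 20 seeds for the detection-power check,
and 100 seeded renders for the JMA round trip.  These sizes give Monte-Carlo
errors comfortably below the tolerances asserted in the test suite.
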