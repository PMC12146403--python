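# Methods

This note records the model, the numerical choices, and the deliberate
simplifications behind `neckdec`. Units: angles are degrees at file/CLI
boundaries and radians internally; all other quantities are SI.

## 1. Model

### 1.1 Head dynamics

The head is a single inverted pendulum rotating about the neck joint in the
sagittal plane, riding on prescribed leg and trunk kinematics. With
`α_HS` the head-in-space angle, `α_TS` trunk-in-space, `α_LS` leg-in-space and
`α_HT = α_HS − α_TS` the head-to-trunk angle, the small-angle equation of
motion is

```
J_H α̈_HS = τ_act + τ_pass + m_H g h_H α_HS + T_acc
T_acc     = m_H h_H (α̈_LS l_L + α̈_TS l_T)
```

`T_acc` is the torque induced by the linear acceleration of the neck joint as
the body segments below rotate. Anthropometric defaults
(`j_h = 0.4797 kg m²`, `m_h = 4.5 kg`, `h_h = 0.2053 m`, `l_l = 0.8543 m`,
`l_t = 0.5011 m`) are a standard adult set used unchanged for every simulated
subject; `m_H g h_H ≈ 9.063 N m/rad` is the destabilising gravity stiffness.

### 1.2 DEC controller

Seven parameters (`ControllerParams`):

| parameter | meaning | units |
|---|---|---|
| `k_p`, `k_d` | active PD gains on the sensed controlled variable | N m/rad, N m s/rad |
| `k_pp`, `k_pd` | passive neck stiffness and damping on `α_HT` (undelayed) | N m/rad, N m s/rad |
| `k_g` | gravity compensation gain, in [0, 2] | – |
| `theta_fs` | dead-band threshold on foot-space (platform) tilt velocity | rad/s |
| `delta_t` | lumped delay on the active sensory path | s |

Active torque (restoring sign convention):
`τ_act = −(k_p + k_d d/dt) [ (1 + k_g) α̂_HS ](t − Δt)` for head-in-space
control, with `α̂_HS` the internal head-in-space estimate; passive torque
`τ_pass = −(k_pp + k_pd d/dt) α_HT` acts without delay.

### 1.3 Tilt estimator and the single nonlinearity

The platform tilt velocity passes through an odd dead-band with threshold
`theta_fs` and is re-integrated, giving the internal tilt estimate `α̂_FS`.
The head-in-space estimate is fused as

```
α̂_HS = α_HS − (α_FS − α̂_FS)
```

i.e. the *unregistered* part of the platform tilt shifts the controller's
reference so the head partially follows the platform. This is the only
nonlinearity in the loop and produces the amplitude dependence of the FRF
gains: a fixed threshold removes a larger fraction of a smaller stimulus, so
gains are larger at smaller stimulus amplitudes (verified by the
amplitude-nonlinearity test). Note the sign: writing the fusion with the
opposite sign (`+ (α_FS − α̂_FS)`) produces the *inverse* amplitude trend and
is rejected; see the design-decision record.

### 1.4 Playback kinematics (synthetic cohorts)

Leg and trunk sway are not predicted — they are inputs. The synthetic cohort
generator emulates what motion capture would record: a second-order
critically damped low-pass (corner 0.5 Hz) of the platform tilt scaled by
gains 0.8 (leg) and 0.6 (trunk), plus band-limited Gaussian noise. For
whole-period traces the filter is applied exactly in the frequency domain
(transient-free for the periodic stimulus). This playback convention is a
modelling choice, adequate for self-consistency experiments; it is *not* a
claim about real whole-body sway.

## 2. Stimulus (PRTS)

A 5-stage maximal-length shift register over GF(3) (taps `(2,0,0,0,1)`,
recurrence `a[t+5] = 2 a[t] + a[t+4] mod 3`) yields 242 states of 0.25 s,
period `T = 60.5 s`. Symbols map to velocities `{0, +s, −s}`; the symbol
counts (80, 81, 81) make the velocity exactly zero-mean, so the tilt position
is periodic. Velocity power sits on the odd harmonics of `1/T` with exact
nulls on the even harmonics. The integrated position is linear in `s`, so
the speed level for a requested peak-to-peak amplitude is obtained by direct
scaling (no search); 1° pp gives `s ≈ 0.2105 deg/s`. The seed selects the
initial register state, i.e. a cyclic rotation — spectra are rotation
invariant.

## 3. Numerics

- **Integrator.** Fixed-step classical RK4 at the 100 Hz sample rate
  (optional sub-stepping), compiled with numba (pure-Python fallback if numba
  is missing). The delayed head state is read from the integrator's own fine
  history by linear interpolation; for look-backs shorter than the available
  history mid-step, a first-order extrapolation `a(t−Δ) ≈ a(t) − Δ ȧ(t)` is
  used. Feedback therefore never requires numerical differentiation of the
  head trace.
- **Derivative inputs.** Playback traces are optionally smoothed by a
  zero-phase second-order Butterworth low-pass (default 5 Hz) before central
  differencing for `α̇_TS` and the accelerations in `T_acc`. With noise-free
  playback the smoothing can be disabled, which is how the oracle comparisons
  are run.
- **Oracle.** With `theta_fs = 0` the loop is linear and the head-in-space
  transfer has the closed form

  ```
  H(ω) = [ (k_pp + k_pd iω) P_T + m_H h_H (iω)² (l_L P_L + l_T P_T) ]
         / [ J_H (iω)² − m_H g h_H + (k_pp + k_pd iω)
             + (1 + k_g)(k_p + k_d iω) e^(−iωΔt) ]
  ```

  with `P_L, P_T` the playback transfers. The simulation matches this within
  1% at all 11 bands (acceptance criterion), including at `Δt = 0.11315 s`.
- **Divergence.** Runs whose head angle exceeds a configurable limit raise
  `SimulationDivergenceError` with the failure time.

## 4. FRF estimation

`H(f) = S_sr(f) / S_ss(f)` at the excited harmonics (bins `f·T` of the
per-period FFT), averaging complete periods coherently. The first period of a
multi-period trace is discarded as a startup transient. **Per-period mean
removal, not linear detrending**, is applied before the FFT: a least-squares
line fitted to one period of a periodic signal generically has nonzero slope,
and removing it breaks periodicity, leaking a 1/f sawtooth spectrum into
every harmonic bin (measured: up to 5× relative error at the 2.2 Hz band on a
noise-free playback transfer). Mean removal preserves periodicity exactly.

The raw values are averaged in the complex domain over 11 bands with centres
`0.05, 0.15, 0.3, 0.4, 0.55, 0.7, 0.9, 1.1, 1.35, 1.75, 2.2 Hz`; band
membership is nearest-centre on a log-frequency axis, with a `ln(1.05)` tie
zone in which a harmonic joins both neighbouring bands.

## 5. Bootstrap band test

An FRF vector is rendered as a pseudo-impulsive response (PIR)
`p(t) = Σ_k Re[H_k] cos(2πf_k t) − Im[H_k] sin(2πf_k t)` on a 60.5 s window
at 10 Hz (605 points). The two-group statistic is the pointwise difference of
group-mean PIRs normalised by the pooled standard deviation (ddof 1). Each
group is resampled with replacement at its original size, `n_boot` times.
Default bands are **simultaneous**: observed curve ± the `level` quantile of
the maximum absolute replicate deviation, making a single excursion of the
zero line a familywise-valid rejection. A pointwise variant with a minimum
exceedance fraction is available. Bootstrap index streams are tied to a
canonical ordering of the groups (content digest), so swapping the arguments
exactly mirrors the result. Measured type-I rate at the 95% level: ≈ 0.03
over 200 null replicates (nominal 0.05; check bound 0.085 including binomial
sampling margin) — the simultaneous band is conservative, as expected.

## 6. Parameter identification

The objective is the mean over the two stimulus amplitudes of the mean over
the 11 bands of `|H_sim − H_target|`; one candidate parameter set must
reproduce both amplitude conditions simultaneously, which is what constrains
`theta_fs`. Minimisation is Nelder-Mead (adaptive) in a transformed space:
`log10` for the four gains, logit maps onto `[0, 2]` (`k_g`), `[0, 0.5] rad/s`
(`theta_fs`) and `[0, 0.3] s` (`delta_t`). Seeded multiplicative restarts
(`U[0.5, 2]` around the initial point) guard against local minima. Recovery
experiments (truth → simulate → refit from perturbed starts) recover `k_pp`
and `k_p` within a few percent and the delay well within 20 ms for
parameter rows whose delay is large enough to be identifiable; rows with
near-zero delay are under-constrained (small delays trade off against `k_d`),
so only the fit score is asserted for them.

## 7. Design decisions

- **Mean removal instead of linear detrend per period** — see §4.
- **Restoring sign convention with positive printed gains**; the tilt fusion
  sign is chosen so smaller stimuli give larger gains (§1.3).
- **Exact ternary velocity feeds the tilt estimator** (the stimulus waveform
  is known exactly); recorded-data paths rebuild it by differentiating and
  snapping to the ternary levels.
- **`theta_fs` is interpreted in rad/s** consistently with the internal unit
  system. Several tabulated thresholds exceed the 1° stimulus' velocity
  level (≈ 0.0037 rad/s), saturating the dead-band for that condition; this
  is unit-consistent and does not affect recovery experiments, which compare
  like with like.
- **Trial records hold one 60.5 s period** (one full sequence period at
  100 Hz) preceded by one unrecorded warm-up period, so recorded epochs are
  transient-free and text-sized.
- **Plain CSV + JSON sidecars** for all artifacts; every output directory
  gets a manifest with the seed and a config hash.

## 8. Limitations

- Single sagittal degree of freedom; no multi-segment interaction torques
  beyond the prescribed `T_acc` coupling.
- Small-angle linearisation of gravity; valid for the sub-degree to
  few-degree sway regime simulated here.
- The playback model is a convention (§1.4), not a fitted body-sway model.
- Near-zero delays and thresholds are weakly identifiable from band-averaged
  FRFs; the fit reports them but recovery tolerances are only asserted where
  the information exists.
- The synthetic FRF population used for statistical calibration
  (`sample_frf_group`) adds independent complex Gaussian noise per band — a
  compact stand-in, not a generative model of inter-subject variability.
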