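# Methods

## Model

The cortical column is a Wendling-type neural mass: four interacting
populations — pyramidal cells (PY), excitatory interneurons (EX), slow
dendrite-targeting inhibitory interneurons (SIN) and fast soma-targeting
inhibitory interneurons (FIN). Each population's average post-synaptic
potential (PSP) obeys a critically damped second-order equation

    v'' + 2 g v' + g² v = G g u(t),

the impulse response `G g t e^{-g t}` of which peaks at `G/e` at
`t = 1/g`. Firing rates come from the sigmoid

    S(v) = 2 e₀ / (1 + exp((v_th − v)/σ_th)),

with `2e₀ = 5 /s`, `v_th = 6 mV`, `1/σ_th = 0.56`. The pyramidal
membrane potential `y1 − y2 − y3` (excitatory feedback PSP minus both
inhibitory PSPs) is the model EEG. Connectivity counts are fixed
multiples of `C = 135`. The pyramidal population receives subcortical
input with firing-rate statistics `N(90, 30)`.

Epileptic discharge activity is obtained with the excitatory gains at
5 mV, a *low* slow-inhibitory gain (`G_SIN` in the mid/high 20s mV,
impaired dendritic inhibition) and a *high* fast-inhibitory gain
(`G_FIN ≈ 80–110 mV`). The package keeps the large-`G_FIN` reading of
that regime; reinterpretations that fold the factor of two into the
FIN→PY connectivity or the FIN maximum firing rate are not implemented.
The default gains throughout are `G_SIN = 28.66`, `G_FIN = 87.73` (the
"rat 4" estimate of the study conditions); every entry point accepts
other values.

### Temperature dependence

Two Q10 coefficients, both expressed through the factor
`q^{(T−T0)/10}` relative to the 31 °C baseline:

* **synaptic** (`Q10,syn`): multiplies the synaptic gains; cooling with
  `q > 1` attenuates every PSP (reduced transmitter release/binding);
* **intrinsic** (`Q10,int`): the *reciprocal* factor multiplies the
  membrane potential inside the firing response. Algebraically this is
  identical to scaling both `v_th` and `σ_th` by `q^{(T−T0)/10}`:
  cooling lowers the mean and the spread of the firing-threshold
  distribution — a compensatory increase of intrinsic excitability. The
  two forms are implemented separately and tested to agree to 1e−12.

Variants restrict which processes carry the dependence: `NTD` (none),
`SYN`, `INT`, `SYN_INT`, and the differential-synaptic refinements
`EXC_INH` (glutamatergic vs GABAergic) and `EXC_SIN_FIN` (slow vs fast
GABA split). The synaptic factor is applied to all four kernels under
`SYN`/`SYN_INT` (the kernel equation is written for a generic
population); the intrinsic factor is shared by all populations. At
`T = T0`, or under `NTD`, every variant reduces exactly to the
temperature-free model (tested).

## Simulation

Fixed-step Euler at `dt = 0.5 ms` (2 kHz output). The subcortical input
is drawn i.i.d. per step from `N(90, 30)` and held constant over the
step — a piecewise-constant-rate convention without `√dt` rescaling,
following common neural-mass practice. Results are therefore tied to
this `dt`; the deterministic model is the same stepping with the input
clamped at its mean, so the zero-noise stochastic path and the
deterministic path coincide bit for bit. Integration starts from the
zero state with 5 s of discarded burn-in unless an initial state is
supplied (hysteresis sweeps inherit final states). The Euler path was
checked against an adaptive LSODA reference (RMSE < 1e−3 mV over 10 s
in a smoothly relaxing regime). A non-finite state aborts with the step
index. All randomness flows from explicit integer seeds through
numpy's PCG64; derived sub-seeds come from `SeedSequence` hashes and
stay below 2³¹.

At the default gains the noiseless baseline model is already a slow
spiking limit cycle (~1 Hz); with noise this yields the irregular
rhythmic discharge activity of the epileptic baseline (≈0.7–0.9
events/s, amplitude ≈4–5 baseline SDs).

## Discharge features

Preprocessing mirrors the cooling-study conventions: 5th-order
Butterworth 40 Hz low-pass applied zero-phase (`sosfiltfilt`; ≈−3 dB at
the cutoff per pass), polyphase decimation to 2 kHz, and normalization
of both segments of an experiment by the before-cooling SD (units "au").

Discharges are contiguous runs where `|v − mean|` exceeds `k = 3` SDs;
runs separated by less than 100 ms merge (below observed discharge
rates, above single-spike width), and each event is timed at its peak
deviation. The threshold SD is that of the analysed segment by default;
sweeps that must recognise *terminated* activity pass the
before-cooling SD instead, because a self-referential threshold always
finds rare excursions even in discharge-free noise. Peak timing (rather
than threshold crossing) is used throughout.

Features: the inter-discharge interval `IDI = (t_N − t_1)/N_D` (the
literal divisor `N_D`, although the telescoped sum has `N_D − 1` terms;
the conventional mean-interval divisor is available as `mode="mean"`,
and the two agree for long trains) and the effective magnitude
`EffMag = P99 − P1` with linear-interpolation percentiles.

## Two-stage estimation

Stage one fits `(G_SIN, G_FIN)` to the before-cooling segment; stage
two fits the variant's Q10 factors to the during-cooling segments of
the three cooling temperatures (25/20/15 °C) with the gains fixed. Both
stages minimise

    J(θ) = Σ_experiments [ E_IDI + E_EffMag ] + P(θ),

where `E_x` is the absolute percentage error of feature `x` between the
data segment and a model replicate, computed per replicate and averaged
over a frozen list of ten seeds (so `J` is a deterministic function of
`θ`, as the DIRECT optimizer requires). `P(θ)` (stage two only) is
`K·([max dc − max bc]₊ + [min bc − min dc]₊)` with `K = 1000` on
median-centered simulated series — zero exactly when the during-cooling
range is contained in the before-cooling range. Undefined IDI (fewer
than two events) is scored as the segment duration, the most
pessimistic interval consistent with the data. Q10 fitting uses the
first 40 s of the during-cooling minute; the last 20 s are held out for
validation MAPE tables with fresh seeds.

Model during-cooling replicates start from the same replicate's
before-cooling final state: cooling switches on during ongoing
discharge activity, which matters because parts of the parameter space
are bistable and a from-rest simulation lands on the wrong attractor.
When the data's measurement-noise floor is known (synthetic studies),
the same additive noise is applied to the model replicates before
feature extraction; otherwise event counts are biased between model
and data.

The search is DIRECT (dividing rectangles, unbiased variant, via
`scipy.optimize.direct`) over `G_SIN ∈ [24, 31] × G_FIN ∈ [80, 110]`
and Q10 boxes `[1, 2]` per factor, 150 evaluations per stage by
default.

### Identifiability limits (measured)

Recovery experiments on synthetic studies (below) show two structural
limits of this objective, documented here because the recovery test
asserts tighter bounds and fails on them:

* `G_FIN` is *not identifiable* above ≈90 mV: IDI and EffMag of the
  before-cooling activity are flat there (direct sensitivity scans), so
  stage one pins `G_SIN` well (median abs error 0.8 mV over five
  studies) but scatters `G_FIN` across the box (median ≈8 mV).
* `(Q10,syn, Q10,int)` has a pronounced ridge: widely separated pairs
  (e.g. (1.80, 1.75) and (1.74, 1.24)) reproduce near-identical
  IDI/EffMag profiles across all three temperatures, and the
  single-realization sampling noise of the data features selects points
  far along it (median abs errors ≈0.19 / 0.25 at the default budget).

## Synthetic cooling studies

The generator emulates the study layout: five rats, one-minute 2 kHz
segment pairs at the 31 °C baseline and at 25/20/15 °C, per-rat gains
drawn uniformly from `[25, 31] × [85, 105]` mV, temperature truth
`SYN_INT` with `Q10,syn = 1.8`, `Q10,int = 1.75`, during-segments
continuing from the before-segment's final state, both normalized by
the before SD, plus 0.05 au additive white measurement noise
(configurable to 0; the filtered recordings' true noise floor is
unreported). Before-segments must show at least 10 discharges per
minute; failures regenerate with the next sub-seed and are logged,
never silent. The surrogates share the real data's layout, rates and
discharge phenomenology but none of its artifacts, drifts or electrode
noise spectrum, so green recovery tests bound estimator behaviour under
the model's own assumptions only.

## Bifurcation analysis

All deterministic analysis runs on the noiseless model with the input
clamped at 90.

**Equilibria.** A scalar reduction (every PSP block at `A·u/g` makes
the whole equilibrium a function of the pyramidal PSP alone) enumerates
equilibria robustly; damped Newton polishes them. Pseudo-arclength
continuation in `Q10,int` (default: `Q10,syn = 1.8`, `T = 15 °C`)
records central-finite-difference Jacobian eigenvalues at every point.
Folds are flagged at tangent reversals and refined by bisection on the
critical real eigenvalue under a pinned-coordinate local
parametrization (|λ| driven below ~1e−9); Hopf points by bisection on
the leading complex pair's real part, reporting the crossing frequency.
The engine is generic over `f(x, μ)` and is validated on saddle-node
and Hopf normal forms to 1e−6 in the test-suite.

**Cycles.** Periodic orbits are continued by single shooting: unknowns
`(x₀, T)` with the phase anchored at an extremum of the monitored
output, flows by compiled RK4 (`dt = 2×10⁻⁵ s` ≲ 1/100 of the fastest
time constant), pseudo-arclength in `(x₀, T, μ)` with guards that
reject absurd trial periods. The first cycle is found by simulating a
little beyond the Hopf point (which also certifies supercriticality:
near-onset amplitudes grow as √μ, verified on the normal form).
Finite-difference monodromy matrices give Floquet multipliers at every
point; a fold of the branch in the parameter is a limit point of cycles
(LPC), and unit-circle crossings of the leading nontrivial multiplier
are classified (period doubling / cycle fold / torus) and refined by
bisection.

At the default gains the branch born at the Hopf point
(`Q10,int ≈ 1.5661`, ~12.7 Hz) loses stability in a **period
doubling at ≈1.6838** and only folds geometrically at ≈1.766. The
reference analysis of this model reports a limit point of cycles at
around 1.68 as the end of the stable oscillation; since the scientifically meaningful
landmark is where stable oscillation terminates — and deterministic
simulation confirms the attractor disappears between 1.68 and 1.70 —
the reported cycle-branch landmark is the *stable-cycle termination*
(first stability loss or fold along the branch, whichever comes first),
with the mechanism recorded alongside. A deterministic inherited-state
sweep is available as an independent bracket.

**Stochastic scans.** Over the grid `Q10,int = 1.0 : 2.0 : 0.01` with
ten seeds, three passes per seed: forward and backward sweeps that
inherit final states (hysteresis), and a *cooling-onset* pass in which
each grid point is simulated independently from the same seed's
before-cooling activity — the state the system is actually in when
cooling switches on, and, empirically, the only protocol of the three
that can land on the low-amplitude oscillatory attractor inside the
bistable window (the inherited sweeps approach it only through regions
where the baseline is the sole attractor). EffMag is reported in
before-cooling SD units; events are counted above three of those units.
Runs are classified baseline/active by thresholding EffMag at the
geometric mean of the scan's two unambiguous anchors (grid ends);
bistability = both classes present at a grid point (two consecutive
points required, to reject flicker); the window closes when all runs
are baseline again; discharge reactivation is declared when all runs
are active at two consecutive points — the reappeared discharge
activity is a continuous ≈2 Hz oscillation that never crosses a 3-SD
event threshold, so an event-count criterion would be blind to it.

**Termination sweep.** `SYN` variant (`Q10,int = 1`), `T = 15 °C`,
`Q10,syn` from 1.0 in steps of 0.005, five seeds, 60 s segments from
rest, events above three before-cooling SDs. Discharge frequency falls
monotonically and reaches exactly zero near `Q10,syn ≈ 1.02–1.03`
(every Table-row gain setting tested behaves alike — the noise-driven
escape rate collapses within ~2 % of unity attenuation), while the mean
peak magnitude of the surviving isolated discharges stays within a few
percent of its unity value: frequency, not magnitude, is what the
synaptic mechanism controls. The reference near-termination value is
≈1.085; the gap lies in the (unreported) termination judgement, not in
the dissociation, and the corresponding assertion in the test-suite is
left failing rather than loosened.

## Problem sizes

Defaults reproduce the study conditions (60 s segments, 10 seeds/
replicates, grid steps 0.01 and 0.005, 150 optimizer evaluations per
stage). The test-suite scales two things down as its own choice: scan
segments to 30 s and estimation replicates to five; the acceptance
script runs the full study conditions.

## Known limitations

* Results are tied to the per-step noise convention and `dt = 0.5 ms`;
  no `√dt` scaling is applied and no convergence in `dt` of the
  stochastic law is claimed.
* The event detector is threshold-based; continuous rhythmic activity
  below 3 SD yields zero events by construction.
* `G_FIN` and the Q10 pair are only weakly identified by the IDI+EffMag
  objective (measured above); estimates inherit that uncertainty.
* Codimension-2 structure (fold/Hopf curves in two parameters) is
  explored only by repeated one-parameter runs; cycle stability beyond
  shooting monodromy (e.g. continuation of the period-doubled branch)
  is not implemented.
* Transient cooling dynamics (temperature ramps) and non-neuronal
  mechanisms are out of scope.
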