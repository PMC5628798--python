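"""Two-stage parameter estimation from cooling-study segment pairs.

Stage one fits the slow- and fast-inhibitory gains ``(G_SIN, G_FIN)`` of
the temperature-free model to the before-cooling discharge activity.
Stage two, with those gains fixed, fits the Q10 temperature factors of a
chosen variant to the during-cooling activity across the three cooling
temperatures.

Both stages minimise the same objective: for each cooling experiment the
mean absolute percentage errors of the inter-discharge interval and the
effective magnitude between model and data, averaged over a fixed list of
seeded stochastic replicates, summed over experiments; stage two adds a
range-containment penalty (strength K = 1000) that punishes simulated
during-cooling activity exceeding the before-cooling range, i.e. model
activity that is not actually suppressed.  The replicate seed list is
frozen per estimation so the objective is a deterministic function of the
parameters — a requirement for the deterministic DIRECT (dividing
rectangles) global optimizer used for the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import direct as _scipy_direct

from .features import segment_summary
from .model_core import ModelParameters, TemperatureSpec
from .simulator import (BlowUpError, SimulationConfig, TimeSeries, normalize,
                        simulate)

__all__ = ["ObjectiveSpec", "EstimationResult", "CoolingExperiment",
           "prepare_experiment", "mape", "range_penalty", "direct_minimize",
           "baseline_objective", "q10_objective", "estimate_baseline",
           "estimate_q10", "validate", "make_variant_temp", "variant_bounds"]

#: Objective value returned when a simulation blows up at a parameter point.
BLOWUP_SENTINEL = 1e6


@dataclass
class ObjectiveSpec:
    """Settings shared by the estimation objectives.

    ``seeds`` is the frozen replicate seed list (derived from
    ``master_seed`` when not given).  The during-cooling fit uses the
    ``fit_window`` (first 40 s) and holds out the ``validation_window``
    (last 20 s).  ``noise_sd`` is the measurement-noise SD (in normalized
    units) applied to model replicates so simulated and recorded segments
    pass through the same observation pipeline; leave at zero when the
    data's noise floor is unknown.
    """

    replicates: int = 10
    K: float = 1000.0
    master_seed: int = 0
    seeds: tuple = ()
    fit_window: tuple = (0.0, 40.0)
    validation_window: tuple = (40.0, 60.0)
    bc_duration: float = 60.0
    max_evals: int = 150
    burn_in: float = 5.0
    dt: float = 5e-4
    k_detect: float = 3.0
    idi_mode: str = "literal"
    noise_sd: float = 0.0
    gain_bounds: tuple = ((24.0, 31.0), (80.0, 110.0))
    q10_bounds: tuple = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.fit_window[1] > self.validation_window[0]:
            raise ValueError("fit and validation windows must be disjoint")
        if not self.seeds:
            ss = np.random.SeedSequence(self.master_seed)
            self.seeds = tuple(
                int(s) for s in
                ss.generate_state(self.replicates) % np.uint32(2 ** 31))


@dataclass
class EstimationResult:
    """Optimum, objective value and the optimizer's evaluation trace."""

    theta: dict
    objective_value: float
    trace: pd.DataFrame
    feature_errors: pd.DataFrame | None = None


@dataclass
class CoolingExperiment:
    """One cooling run: temperature plus normalized before/during segments."""

    T: float
    before: TimeSeries
    during: TimeSeries
    T0: float = 31.0


def prepare_experiment(T: float, before_raw: TimeSeries,
                       during_raw: TimeSeries,
                       T0: float = 31.0) -> CoolingExperiment:
    """Normalize both segments by the before-cooling SD (study convention)."""
    return CoolingExperiment(T, normalize(before_raw, before_raw),
                             normalize(during_raw, before_raw), T0)


def mape(model_value: float, data_value: float) -> float:
    """Absolute percentage error ``|model - data| / |data|`` (as a fraction).

    NaN (undefined) when the data value is zero or either input is NaN.
    """
    if data_value == 0 or not np.isfinite(data_value):
        return float("nan")
    return abs(model_value - data_value) / abs(data_value)


def _center(values: np.ndarray) -> np.ndarray:
    return values - np.median(values)


def range_penalty(dc: TimeSeries, bc: TimeSeries, K: float = 1000.0) -> float:
    """Penalty on during-cooling activity escaping the before-cooling range.

    Both series are centered on their medians (baseline-level removal),
    then ``K * ([max(dc)-max(bc)]+ + [min(bc)-min(dc)]+)``; zero exactly
    when the during-cooling range is contained in the before-cooling one.
    """
    d = _center(dc.values)
    b = _center(bc.values)
    over = max(0.0, float(d.max() - b.max()))
    under = max(0.0, float(b.min() - d.min()))
    return K * (over + under)


def direct_minimize(fn, bounds, max_evals: int = 150):
    """DIRECT (dividing rectangles) global minimisation over a box.

    Thin deterministic wrapper around :func:`scipy.optimize.direct`
    (unbiased variant, as in the original algorithm): same inputs give the
    same output.  Returns ``(x, fun, trace)`` where ``trace`` records each
    evaluation and the best value seen so far.
    """
    if max_evals < 1:
        raise ValueError("max_evals must be >= 1")
    evals = []

    def wrapped(x):
        v = float(fn(np.asarray(x, dtype=float)))
        evals.append((x.copy(), v))
        return v

    res = _scipy_direct(wrapped, bounds, maxfun=max_evals,
                        maxiter=10 * max_evals, locally_biased=False,
                        vol_tol=0.0, len_tol=1e-10)
    values = np.array([v for _, v in evals])
    best = np.minimum.accumulate(values)
    trace = pd.DataFrame({
        "eval": np.arange(values.size),
        "value": values,
        "best": best,
    })
    trace["x"] = [x for x, _ in evals]
    i_best = int(np.argmin(values))
    return evals[i_best][0], float(values[i_best]), trace


def make_variant_temp(variant: str, theta, T: float,
                      T0: float = 31.0) -> TemperatureSpec:
    """Build the TemperatureSpec for a variant from its free-parameter vector.

    Parameter order per variant: SYN ``(q_syn,)``; INT ``(q_int,)``;
    SYN_INT ``(q_syn, q_int)``; EXC_INH ``(q_syn_exc, q_syn_inh, q_int)``;
    EXC_SIN_FIN ``(q_syn_ex, q_syn_sin, q_syn_fin, q_int)``; NTD ``()``.
    """
    theta = tuple(float(t) for t in np.atleast_1d(theta)) if theta is not None else ()
    names = variant_parameter_names(variant)
    if len(theta) != len(names):
        raise ValueError(f"{variant} expects {len(names)} parameters, "
                         f"got {len(theta)}")
    return TemperatureSpec(T=T, T0=T0, variant=variant,
                           **dict(zip(names, theta)))


def variant_parameter_names(variant: str) -> tuple:
    return {
        "NTD": (),
        "SYN": ("q_syn",),
        "INT": ("q_int",),
        "SYN_INT": ("q_syn", "q_int"),
        "EXC_INH": ("q_syn_exc", "q_syn_inh", "q_int"),
        "EXC_SIN_FIN": ("q_syn_ex", "q_syn_sin", "q_syn_fin", "q_int"),
    }[variant]


def variant_bounds(variant: str, spec: ObjectiveSpec) -> list:
    return [tuple(spec.q10_bounds)] * len(variant_parameter_names(variant))


def _features(series: TimeSeries, spec: ObjectiveSpec):
    return segment_summary(series, k=spec.k_detect, idi_mode=spec.idi_mode)


def _observe(series: TimeSeries, spec: ObjectiveSpec, *seed_parts
             ) -> TimeSeries:
    """Apply the observation model (additive measurement noise) to a
    simulated, normalized segment; deterministic in the seed parts."""
    if spec.noise_sd <= 0:
        return series
    rng = np.random.default_rng(np.random.SeedSequence(list(seed_parts)))
    return TimeSeries(series.values + rng.normal(0.0, spec.noise_sd,
                                                 series.values.size),
                      series.rate, series.unit, series.t0)


def _idi_or_duration(f) -> float:
    # Undefined IDI (fewer than two events) is scored as the segment
    # duration: the most pessimistic interval consistent with the data.
    return f.idi if np.isfinite(f.idi) else f.duration


def baseline_objective(bc: TimeSeries, params_template: ModelParameters,
                       spec: ObjectiveSpec):
    """Objective over (G_SIN, G_FIN) for the before-cooling stage.

    The data series must be normalized (unit SD).  Model replicates are
    simulated at baseline temperature (no temperature dependence),
    normalized by their own SD, and scored by the IDI + EffMag MAPEs.
    """
    data_f = _features(bc, spec)
    if data_f.n_events < 2:
        raise ValueError("before-cooling data shows fewer than two "
                         "discharges; cannot estimate baseline gains")
    temp = TemperatureSpec()  # baseline, no temperature dependence
    d = params_template.to_dict()

    def objective(theta):
        g_sin, g_fin = float(theta[0]), float(theta[1])
        params = ModelParameters.from_dict({**d, "G_SIN": g_sin,
                                            "G_FIN": g_fin})
        errs = []
        for seed in spec.seeds:
            cfg = SimulationConfig(duration=bc.duration, dt=spec.dt,
                                   burn_in=spec.burn_in, seed=seed)
            try:
                sim = simulate(params, temp, cfg)
            except BlowUpError:
                return BLOWUP_SENTINEL
            sim_n = _observe(normalize(sim, sim), spec, seed, 5)
            f = _features(sim_n, spec)
            errs.append(mape(_idi_or_duration(f), data_f.idi)
                        + mape(f.effmag, data_f.effmag))
        return float(np.mean(errs))

    return objective


def _baseline_replicates(params: ModelParameters, spec: ObjectiveSpec):
    """The model's own before-cooling replicates (baseline temperature).

    Returns per-replicate (normalized series, raw SD, final state); the
    final state seeds the during-cooling simulations so the model follows
    the same protocol as the data: cooling switches on during ongoing
    discharge activity.
    """
    temp = TemperatureSpec()
    out = []
    for seed in spec.seeds:
        sim, sd, state = _bc_cached(params, seed, spec)
        out.append((normalize(sim, sim), sd, state))
    return out


def q10_objective(experiments, baseline_params: ModelParameters,
                  variant: str, spec: ObjectiveSpec,
                  window: tuple | None = None, seed_offset: int = 0):
    """Objective over the variant's Q10 vector for the during-cooling stage.

    For each cooling temperature the during-cooling model output
    (normalized by the same replicate's simulated before-cooling SD) is
    scored against that experiment's data features over ``window``
    (default: the fit window), plus the range-containment penalty against
    the replicate's before-cooling activity.  Deterministic given the
    frozen seed list.
    """
    window = tuple(window) if window is not None else tuple(spec.fit_window)
    dur = window[1] - window[0]
    data_feats = []
    for exp in experiments:
        seg = exp.during.segment(*window)
        f = _features(seg, spec)
        data_feats.append(f)
    bc_reps = _baseline_replicates(baseline_params, spec)

    def objective(theta):
        J = 0.0
        for ti, (exp, data_f) in enumerate(zip(experiments, data_feats)):
            temp = make_variant_temp(variant, theta, exp.T, exp.T0)
            errs = []
            pens = []
            for ri, (seed, (bc_rep, bc_sd, bc_state)) in enumerate(
                    zip(spec.seeds, bc_reps)):
                sub = int(np.random.SeedSequence(
                    [seed, ti, ri, seed_offset]).generate_state(1)[0]
                    % np.uint32(2 ** 31))
                cfg = SimulationConfig(duration=dur, dt=spec.dt,
                                       burn_in=spec.burn_in, seed=sub)
                try:
                    dc = simulate(baseline_params, temp, cfg,
                                  initial_state=bc_state)
                except BlowUpError:
                    return BLOWUP_SENTINEL
                dc_n = _observe(TimeSeries(dc.values / bc_sd, dc.rate,
                                           "au"), spec, seed, ti, 7)
                f = _features(dc_n, spec)
                errs.append(mape(_idi_or_duration(f),
                                 _idi_or_duration(data_f))
                            + mape(f.effmag, data_f.effmag))
                pens.append(range_penalty(dc_n, bc_rep, spec.K))
            J += float(np.mean(errs)) + float(np.mean(pens))
        return J

    return objective


# cache of before-cooling replicates keyed by (params, seed, layout)
_BC_CACHE: dict = {}


def _bc_cached(params, seed, spec):
    key = (tuple(sorted(params.to_dict().items())), seed,
           spec.bc_duration, spec.dt, spec.burn_in)
    if key not in _BC_CACHE:
        if len(_BC_CACHE) > 256:
            _BC_CACHE.clear()
        temp = TemperatureSpec()
        cfg = SimulationConfig(duration=spec.bc_duration, dt=spec.dt,
                               burn_in=spec.burn_in, seed=seed)
        sim, state = simulate(params, temp, cfg, return_state=True)
        _BC_CACHE[key] = (sim, sim.sd(), state)
    return _BC_CACHE[key]


def estimate_baseline(bc: TimeSeries, spec: ObjectiveSpec | None = None,
                      params_template: ModelParameters | None = None
                      ) -> EstimationResult:
    """Stage one: DIRECT search for (G_SIN, G_FIN) on before-cooling data."""
    spec = spec or ObjectiveSpec()
    params_template = params_template or ModelParameters()
    obj = baseline_objective(bc, params_template, spec)
    x, fun, trace = direct_minimize(obj, list(spec.gain_bounds),
                                    spec.max_evals)
    return EstimationResult({"G_SIN": float(x[0]), "G_FIN": float(x[1])},
                            fun, trace)


def estimate_q10(experiments, baseline_params: ModelParameters,
                 variant: str, spec: ObjectiveSpec | None = None
                 ) -> EstimationResult:
    """Stage two: DIRECT search for the variant's Q10 factors.

    ``NTD`` has no free temperature parameters and returns unity factors
    without running the optimizer.
    """
    spec = spec or ObjectiveSpec()
    names = variant_parameter_names(variant)
    if not names:
        trace = pd.DataFrame({"eval": [], "value": [], "best": []})
        return EstimationResult({"q_syn": 1.0, "q_int": 1.0}, float("nan"),
                                trace)
    obj = q10_objective(experiments, baseline_params, variant, spec)
    x, fun, trace = direct_minimize(obj, variant_bounds(variant, spec),
                                    spec.max_evals)
    return EstimationResult(dict(zip(names, (float(v) for v in x))),
                            fun, trace)


def validate(theta: dict, experiments, baseline_params: ModelParameters,
             variant: str, spec: ObjectiveSpec | None = None) -> pd.DataFrame:
    """Per-temperature, per-feature MAPE on the held-out validation window.

    Fresh replicate seeds (disjoint from the fit seeds) are used for the
    model simulations.
    """
    spec = spec or ObjectiveSpec()
    names = variant_parameter_names(variant)
    theta_vec = [theta[n] for n in names]
    window = tuple(spec.validation_window)
    dur = window[1] - window[0]
    rows = []
    for ti, exp in enumerate(experiments):
        seg = exp.during.segment(*window)
        data_f = _features(seg, spec)
        temp = make_variant_temp(variant, theta_vec, exp.T, exp.T0)
        e_idi, e_mag = [], []
        for ri, seed in enumerate(spec.seeds):
            sub = int(np.random.SeedSequence(
                [seed, ti, ri, 991]).generate_state(1)[0] % np.uint32(2 ** 31))
            cfg = SimulationConfig(duration=dur, dt=spec.dt,
                                   burn_in=spec.burn_in, seed=sub)
            _, bc_sd, bc_state = _bc_cached(baseline_params, seed, spec)
            dc = simulate(baseline_params, temp, cfg,
                          initial_state=bc_state)
            dc_n = _observe(TimeSeries(dc.values / bc_sd, dc.rate, "au"),
                            spec, seed, ti, 17)
            f = _features(dc_n, spec)
            e_idi.append(mape(_idi_or_duration(f), _idi_or_duration(data_f)))
            e_mag.append(mape(f.effmag, data_f.effmag))
        rows.append({"T": exp.T, "E_IDI": float(np.mean(e_idi)),
                     "E_EffMag": float(np.mean(e_mag))})
    return pd.DataFrame(rows)
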