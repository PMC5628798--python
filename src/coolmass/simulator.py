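"""Stochastic and deterministic integration of the cortical-column model.

The stochastic model is integrated with a fixed-step Euler scheme at
``dt = 0.5 ms`` (2 kHz output): at every step the subcortical input firing
rate is drawn i.i.d. from ``N(input_mean, input_sd)`` and held constant
over the step (a piecewise-constant rate without ``sqrt(dt)`` rescaling,
the usual neural-mass convention; results therefore refer to this fixed
``dt``).  Setting the noise to zero or using
:func:`simulate_deterministic` gives the noiseless model on the identical
stepping, so the zero-noise stochastic path and the deterministic path
coincide bit for bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .model_core import ModelParameters, TemperatureSpec

__all__ = ["SimulationConfig", "TimeSeries", "BlowUpError",
           "simulate", "simulate_deterministic", "normalize",
           "write_timeseries", "read_timeseries"]


class BlowUpError(RuntimeError):
    """Integration produced a non-finite state."""

    def __init__(self, step: int):
        super().__init__(f"state became non-finite at step {step}")
        self.step = step


@dataclass
class SimulationConfig:
    """Integration settings.

    ``dt`` defaults to 0.5 ms (2 kHz); ``burn_in`` seconds are integrated
    and discarded before output so the transient from the (zero) initial
    state never appears in the recorded segment.
    """

    duration: float = 60.0
    dt: float = 5e-4
    burn_in: float = 5.0
    seed: int = 0
    stochastic: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.burn_in < 0 or self.duration <= 0:
            raise ValueError("need duration > 0 and burn_in >= 0")

    @property
    def rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class TimeSeries:
    """Uniformly sampled scalar signal."""

    values: np.ndarray
    rate: float
    unit: str = "mV"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    def sd(self) -> float:
        return float(np.std(self.values))

    def segment(self, start: float, end: float) -> "TimeSeries":
        """Slice by time (seconds relative to t0)."""
        i0 = int(round(start * self.rate))
        i1 = int(round(end * self.rate))
        return TimeSeries(self.values[i0:i1], self.rate, self.unit,
                          self.t0 + i0 / self.rate)


def _run(params: ModelParameters, temp: TemperatureSpec,
         config: SimulationConfig, initial_state, p_arr) -> tuple:
    coeffs = _kernels.pack_coeffs(params, temp)
    x0 = (np.zeros(10) if initial_state is None
          else np.asarray(initial_state, dtype=float).copy())
    if x0.shape != (10,):
        raise ValueError("initial_state must have dimension 10")
    eeg, x_final, bad = _kernels.euler_path(x0, config.dt, p_arr.size,
                                            p_arr, *coeffs)
    if bad >= 0:
        raise BlowUpError(bad)
    return eeg, x_final


def simulate(params: ModelParameters, temp: TemperatureSpec,
             config: SimulationConfig, initial_state=None,
             return_state: bool = False):
    """Integrate the model and return the EEG output after burn-in.

    Stochastic mode draws the subcortical input per step from
    ``N(input_mean, input_sd)`` using ``numpy`` PCG64 seeded with
    ``config.seed``; identical configuration gives identical output bit
    for bit.  ``return_state=True`` additionally returns the final state
    (used by hysteresis sweeps that inherit initial conditions).
    """
    n_total = int(round((config.duration + config.burn_in) / config.dt))
    n_burn = int(round(config.burn_in / config.dt))
    if config.stochastic and params.input_sd > 0:
        rng = np.random.default_rng(config.seed)
        p_arr = rng.normal(params.input_mean, params.input_sd, size=n_total)
    else:
        p_arr = np.full(n_total, params.input_mean)
    eeg, x_final = _run(params, temp, config, initial_state, p_arr)
    ts = TimeSeries(eeg[n_burn:], config.rate, "mV", t0=0.0)
    return (ts, x_final) if return_state else ts


def simulate_deterministic(params: ModelParameters, temp: TemperatureSpec,
                           config: SimulationConfig, initial_state=None,
                           return_state: bool = False):
    """Noiseless model: fixed-step integration with ``p = input_mean``."""
    n_total = int(round((config.duration + config.burn_in) / config.dt))
    n_burn = int(round(config.burn_in / config.dt))
    p_arr = np.full(n_total, params.input_mean)
    eeg, x_final = _run(params, temp, config, initial_state, p_arr)
    ts = TimeSeries(eeg[n_burn:], config.rate, "mV", t0=0.0)
    return (ts, x_final) if return_state else ts


def normalize(series: TimeSeries, reference: TimeSeries) -> TimeSeries:
    """Divide by the standard deviation of ``reference`` (units become au).

    The study convention: both the before-cooling and the during-cooling
    segment are divided by the before-cooling standard deviation.
    """
    sd = reference.sd()
    if sd == 0:
        raise ValueError("reference series has zero variance")
    return TimeSeries(series.values / sd, series.rate, "au", series.t0)


def write_timeseries(series: TimeSeries, path) -> None:
    """Two-column text format ``time_s value`` with a metadata header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={series.rate:.10g} unit={series.unit}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.6f} {v:.9g}\n")


def read_timeseries(path) -> TimeSeries:
    """Read the two-column text format; tolerates extra comment lines."""
    rate = None
    unit = "au"
    times = []
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("rate_hz="):
                        rate = float(tok.split("=", 1)[1])
                    elif tok.startswith("unit="):
                        unit = tok.split("=", 1)[1]
                continue
            t, v = line.split()
            times.append(float(t))
            values.append(float(v))
    if not values:
        raise ValueError(f"no samples in {path}")
    if rate is None:
        if len(times) < 2:
            raise ValueError("cannot infer sampling rate")
        rate = 1.0 / (times[1] - times[0])
    return TimeSeries(np.array(values), rate, unit, t0=times[0])
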