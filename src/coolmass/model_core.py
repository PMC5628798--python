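"""Four-population neural mass model with Q10 temperature dependence.

The model is the Wendling-type cortical column: a pyramidal-cell population
(PY) interacting with excitatory interneurons (EX), slow dendrite-targeting
inhibitory interneurons (SIN) and fast soma-targeting inhibitory
interneurons (FIN).  Each population converts its average presynaptic
firing rate into an average post-synaptic potential (PSP) through a
second-order linear kernel ``G*g*t*exp(-g*t)`` and converts its average
membrane potential into a firing rate through a sigmoid firing-response
function.  The pyramidal membrane potential is the model EEG.

Focal cooling enters through two Q10 temperature coefficients:

* ``Q10,syn`` attenuates the synaptic gains ``G_X`` by
  ``Q10^((T - T0)/10)`` (cooling, ``T < T0``, gives a factor below one),
  modelling reduced neurotransmitter release and binding;
* ``Q10,int`` multiplies the membrane potential inside the firing response
  by the reciprocal factor ``Q10^(-(T - T0)/10)``, modelling a compensatory
  increase of intrinsic excitability (equivalently a lowered mean and
  spread of the firing-threshold distribution, see
  :func:`firing_response_equivalent`).

Several variants restrict or refine which processes carry temperature
dependence (``NTD``, ``SYN``, ``INT``, ``SYN_INT``, ``EXC_INH``,
``EXC_SIN_FIN``); see :class:`TemperatureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

__all__ = [
    "POPULATIONS",
    "VARIANTS",
    "ModelParameters",
    "TemperatureSpec",
    "temperature_factor",
    "firing_response",
    "firing_response_equivalent",
    "effective_gain",
    "psp_kernel",
    "drift",
    "eeg_output",
]

POPULATIONS = ("PY", "EX", "SIN", "FIN")

#: Temperature-dependence variants: which processes carry a Q10 factor.
VARIANTS = ("NTD", "SYN", "INT", "SYN_INT", "EXC_INH", "EXC_SIN_FIN")

# Exponent clamp for the sigmoid: exp() saturates instead of overflowing.
_EXP_CLIP = 700.0


@dataclass
class ModelParameters:
    """Population gains, rate constants, connectivity and input statistics.

    Defaults are the values adopted for the epileptic cortical column:
    excitatory gains 5 mV, slow/fast inhibitory gains in the discharge
    regime, sigmoid with half-max rate ``e0 = 2.5`` /s at threshold 6 mV
    and steepness ``1/sigma_th = 0.56``, and subcortical input firing rate
    ``N(90, 30)``.

    Connectivity counts are all fixed multiples of ``C_PY_EX`` (135),
    exposed as derived properties.
    """

    G_PY: float = 5.0
    G_EX: float = 5.0
    G_SIN: float = 28.66
    G_FIN: float = 87.73
    g_PY: float = 100.0
    g_EX: float = 100.0
    g_SIN: float = 50.0
    g_FIN: float = 500.0
    C_PY_EX: float = 135.0
    v_th: float = 6.0
    e0: float = 2.5
    sigma_th: float = 1.0 / 0.56
    input_mean: float = 90.0
    input_sd: float = 30.0

    def __post_init__(self) -> None:
        for name in ("G_PY", "G_EX", "G_SIN", "G_FIN", "g_PY", "g_EX",
                     "g_SIN", "g_FIN", "C_PY_EX", "e0", "sigma_th"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.input_sd < 0:
            raise ValueError("input_sd must be non-negative")

    # Derived synaptic connection counts (fixed ratios of C_PY_EX).
    @property
    def C_EX_PY(self) -> float:
        return 0.8 * self.C_PY_EX

    @property
    def C_PY_SIN(self) -> float:
        return 0.25 * self.C_PY_EX

    @property
    def C_PY_FIN(self) -> float:
        return 0.3 * self.C_PY_EX

    @property
    def C_SIN_PY(self) -> float:
        return 0.25 * self.C_PY_EX

    @property
    def C_FIN_PY(self) -> float:
        return 0.8 * self.C_PY_EX

    @property
    def C_SIN_FIN(self) -> float:
        return 0.1 * self.C_PY_EX

    def gain(self, population: str) -> float:
        try:
            return getattr(self, f"G_{population}")
        except AttributeError:
            raise KeyError(f"unknown population {population!r}") from None

    def rate_constant(self, population: str) -> float:
        try:
            return getattr(self, f"g_{population}")
        except AttributeError:
            raise KeyError(f"unknown population {population!r}") from None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        known = {k: float(v) for k, v in d.items()
                 if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class TemperatureSpec:
    """Cooling temperature, baseline and the active Q10 factors.

    ``variant`` selects which Q10 fields are read; unread fields are
    ignored (they default to 1).  ``NTD`` ignores every factor, ``SYN``
    reads only ``q_syn``, ``INT`` only ``q_int``, ``SYN_INT`` both.
    ``EXC_INH`` splits the synaptic factor into glutamatergic
    (``q_syn_exc``: PY and EX) and GABAergic (``q_syn_inh``: SIN and FIN)
    parts; ``EXC_SIN_FIN`` further splits GABA into slow (``q_syn_sin``)
    and fast (``q_syn_fin``).  The intrinsic factor ``q_int`` is shared by
    all populations whenever the variant reads it.
    """

    T: float = 31.0
    T0: float = 31.0
    variant: str = "NTD"
    q_syn: float = 1.0
    q_int: float = 1.0
    q_syn_exc: float = 1.0
    q_syn_inh: float = 1.0
    q_syn_ex: float = 1.0
    q_syn_sin: float = 1.0
    q_syn_fin: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name in ("q_syn", "q_int", "q_syn_exc", "q_syn_inh",
                     "q_syn_ex", "q_syn_sin", "q_syn_fin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def synaptic_q10(self, population: str) -> float:
        """Q10 applied to population ``X``'s synaptic gain under this variant."""
        if population not in POPULATIONS:
            raise KeyError(f"unknown population {population!r}")
        v = self.variant
        if v in ("NTD", "INT"):
            return 1.0
        if v in ("SYN", "SYN_INT"):
            return self.q_syn
        if v == "EXC_INH":
            return self.q_syn_exc if population in ("PY", "EX") else self.q_syn_inh
        # EXC_SIN_FIN
        if population in ("PY", "EX"):
            return self.q_syn_ex
        return self.q_syn_sin if population == "SIN" else self.q_syn_fin

    def intrinsic_q10(self) -> float:
        """Q10 of the intrinsic-excitability mechanism under this variant."""
        if self.variant in ("NTD", "SYN"):
            return 1.0
        return self.q_int

    def gain_factor(self, population: str) -> float:
        """Multiplicative temperature factor on ``G_X`` at temperature ``T``."""
        return temperature_factor(self.synaptic_q10(population), self.T, self.T0)

    def intrinsic_factor(self) -> float:
        """Reciprocal factor ``q_int^(-(T-T0)/10)`` applied to the membrane
        potential inside the firing response (> 1 under cooling)."""
        return temperature_factor(self.intrinsic_q10(), self.T, self.T0) ** -1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TemperatureSpec":
        known = {}
        for k, v in d.items():
            if k not in cls.__dataclass_fields__:
                raise KeyError(f"unknown temperature key: {k}")
            known[k] = v if k == "variant" else float(v)
        return cls(**known)

    def replace(self, **kw) -> "TemperatureSpec":
        d = self.to_dict()
        d.update(kw)
        return TemperatureSpec.from_dict(d)


def temperature_factor(q10: float, T: float, T0: float) -> float:
    """Rate factor ``q10**((T - T0)/10)`` relative to baseline ``T0``.

    A Q10 coefficient is the factor by which a process rate changes per
    10 degC rise; cooling below ``T0`` with ``q10 > 1`` gives a factor
    below one.
    """
    if q10 <= 0:
        raise ValueError("q10 must be strictly positive")
    return float(q10) ** ((T - T0) / 10.0)


def _sigmoid(x, e0: float):
    """``2*e0 / (1 + exp(x))`` with overflow-safe saturation."""
    x = np.clip(x, -_EXP_CLIP, _EXP_CLIP)
    return 2.0 * e0 / (1.0 + np.exp(x))


def firing_response(v, params: ModelParameters, temp: TemperatureSpec | None = None):
    """Average firing rate (1/s) for average membrane potential ``v`` (mV).

    The sigmoid ``2*e0 / (1 + exp((v_th - f*v)/sigma_th))`` where
    ``f = q_int^(-(T-T0)/10)`` amplifies the membrane potential under
    cooling (compensatory intrinsic mechanism).  With ``q_int = 1`` or
    ``T = T0`` this is the plain temperature-free firing response.
    Output lies strictly in ``(0, 2*e0)``; overflow saturates.
    """
    f = 1.0 if temp is None else temp.intrinsic_factor()
    v = np.asarray(v, dtype=float)
    out = _sigmoid((params.v_th - f * v) / params.sigma_th, params.e0)
    return float(out) if out.ndim == 0 else out


def firing_response_equivalent(v, params: ModelParameters,
                               temp: TemperatureSpec | None = None):
    """Algebraically equivalent firing response with the Q10 factor moved
    onto the threshold parameters.

    ``2*e0 / (1 + exp((g*v_th - v)/(g*sigma_th)))`` with
    ``g = q_int^((T-T0)/10)``: cooling lowers both the mean and the spread
    of the firing-threshold distribution.  Must agree with
    :func:`firing_response` to floating precision for all inputs.
    """
    g = 1.0 if temp is None else temperature_factor(temp.intrinsic_q10(),
                                                    temp.T, temp.T0)
    v = np.asarray(v, dtype=float)
    out = _sigmoid((g * params.v_th - v) / (g * params.sigma_th), params.e0)
    return float(out) if out.ndim == 0 else out


def effective_gain(population: str, params: ModelParameters,
                   temp: TemperatureSpec) -> float:
    """Temperature-attenuated synaptic gain ``G_X * Q10_X^((T-T0)/10)`` (mV)."""
    return params.gain(population) * temp.gain_factor(population)


def psp_kernel(t, G: float, g: float, temp_factor: float = 1.0):
    """Post-synaptic impulse response ``factor*G*g*t*exp(-g*t)`` for t >= 0.

    Zero at ``t = 0``; peaks at ``t = 1/g`` with value ``factor*G/e``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("psp_kernel requires t >= 0")
    out = temp_factor * G * g * t * np.exp(-g * t)
    return float(out) if out.ndim == 0 else out


def drift(state, p: float, params: ModelParameters,
          temp: TemperatureSpec) -> np.ndarray:
    """Deterministic right-hand side of the 10-dimensional model.

    ``state`` is ``(y0..y4, z0..z4)``: five PSP states and their time
    derivatives.  ``p`` is the subcortical input firing rate entering the
    excitatory-feedback population.  Each PSP block obeys
    ``y'' = A*g*u - 2*g*y' - g^2*y`` with ``A`` the effective
    (temperature-attenuated) gain and ``u`` the presynaptic drive:

    * y0: pyramidal output PSP, driven by ``S(y1 - y2 - y3)``
    * y1: excitatory feedback PSP, driven by ``p + C_EX_PY*S(C_PY_EX*y0)``
    * y2: slow inhibition onto pyramidal cells, ``C_SIN_PY*S(C_PY_SIN*y0)``
    * y3: fast inhibition onto pyramidal cells,
      ``C_FIN_PY*S(C_PY_FIN*y0 - C_SIN_FIN*y4)``
    * y4: slow inhibition onto fast interneurons, ``S(C_PY_SIN*y0)``
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (10,):
        raise ValueError("state must have dimension 10")
    y = state[:5]
    z = state[5:]
    f = temp.intrinsic_factor()

    def S(v):
        return _sigmoid((params.v_th - f * v) / params.sigma_th, params.e0)

    A_PY = effective_gain("PY", params, temp)
    A_EX = effective_gain("EX", params, temp)
    A_SIN = effective_gain("SIN", params, temp)
    A_FIN = effective_gain("FIN", params, temp)
    a, b = params.g_PY, params.g_EX
    c, d = params.g_SIN, params.g_FIN

    u = np.empty(5)
    u[0] = A_PY * a * S(y[1] - y[2] - y[3])
    u[1] = A_EX * b * (p + params.C_EX_PY * S(params.C_PY_EX * y[0]))
    u[2] = A_SIN * c * params.C_SIN_PY * S(params.C_PY_SIN * y[0])
    u[3] = A_FIN * d * params.C_FIN_PY * S(
        params.C_PY_FIN * y[0] - params.C_SIN_FIN * y[4])
    u[4] = A_SIN * c * S(params.C_PY_SIN * y[0])

    # per-block rate constants: y0,y1 -> 100; y2,y4 -> 50; y3 -> 500
    g_vec = np.array([a, b, c, d, c])

    out = np.empty(10)
    out[:5] = z
    out[5:] = u - 2.0 * g_vec * z - g_vec ** 2 * y
    return out


def eeg_output(state) -> float:
    """Pyramidal membrane potential ``y1 - y2 - y3`` (the model EEG, mV)."""
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != 10:
        raise ValueError("state must have dimension 10")
    return state[..., 1] - state[..., 2] - state[..., 3]
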