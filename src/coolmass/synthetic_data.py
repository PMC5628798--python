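"""Surrogate cooling-study datasets with known ground truth.

The animal recordings behind the cooling study are not public, so every
pipeline stage is exercised on synthetic studies instead: per rat, a pair
of one-minute 2 kHz segments (before cooling at the 31 degC baseline,
during cooling at each of 25/20/15 degC) generated by the model itself
under a known variant and known Q10 factors, normalized by the
before-cooling standard deviation, with optional additive white
measurement noise.  The manifest records all ground truth so estimation
results can be scored.

These surrogates share the real data's sampling rate, segment layout,
amplitude convention and discharge phenomenology, but not its artifacts,
non-stationarities or electrode noise spectrum — recovery results bound
estimator behaviour under the model's own assumptions only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .estimation import CoolingExperiment, make_variant_temp, \
    variant_parameter_names
from .features import detect_discharges
from .model_core import ModelParameters, TemperatureSpec
from .simulator import (BlowUpError, SimulationConfig, TimeSeries, normalize,
                        read_timeseries, simulate, write_timeseries)

__all__ = ["SyntheticStudySpec", "RatRecord", "generate_recording",
           "generate_rat", "generate_study", "write_study", "load_study"]

log = logging.getLogger(__name__)


@dataclass
class SyntheticStudySpec:
    """Study layout and ground-truth distribution.

    Defaults mirror the cooling experiments: five rats, cooling
    temperatures 25/20/15 degC from a 31 degC baseline, one-minute
    segments at 2 kHz.  Ground-truth inhibitory gains are sampled
    uniformly over the adopted ranges (G_SIN in [25, 31] mV, G_FIN in
    [85, 105] mV); the temperature truth defaults to the combined
    synaptic-plus-intrinsic variant with Q10,syn = 1.8 and
    Q10,int = 1.75.  ``noise_sd`` is additive white measurement noise in
    units of the before-cooling SD.
    """

    n_rats: int = 5
    temperatures: tuple = (25.0, 20.0, 15.0)
    T0: float = 31.0
    segment: float = 60.0
    dt: float = 5e-4
    burn_in: float = 5.0
    variant: str = "SYN_INT"
    q10_truth: dict = field(default_factory=lambda: {"q_syn": 1.8,
                                                     "q_int": 1.75})
    gain_ranges: tuple = ((25.0, 31.0), (85.0, 105.0))
    noise_sd: float = 0.05
    master_seed: int = 0
    min_events_per_min: float = 10.0
    max_retries: int = 5

    def __post_init__(self) -> None:
        if any(t >= self.T0 for t in self.temperatures):
            raise ValueError("cooling temperatures must lie below T0")
        if self.segment <= 0 or self.n_rats < 1:
            raise ValueError("invalid study layout")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperatures"] = list(self.temperatures)
        d["gain_ranges"] = [list(r) for r in self.gain_ranges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticStudySpec":
        d = dict(d)
        d["temperatures"] = tuple(d["temperatures"])
        d["gain_ranges"] = tuple(tuple(r) for r in d["gain_ranges"])
        return cls(**d)


@dataclass
class RatRecord:
    """One synthetic rat: its ground truth and its cooling experiments."""

    rat_id: int
    params: ModelParameters
    q10_truth: dict
    variant: str
    experiments: list            # list[CoolingExperiment]
    seeds: dict


def _truth_temp(spec: SyntheticStudySpec, temperature: float
                ) -> TemperatureSpec:
    names = variant_parameter_names(spec.variant)
    theta = [spec.q10_truth[n] for n in names]
    return make_variant_temp(spec.variant, theta, temperature, spec.T0)


def generate_recording(params: ModelParameters, temperature: float,
                       spec: SyntheticStudySpec, seed: int
                       ) -> tuple[TimeSeries, TimeSeries]:
    """One (before, during) segment pair, normalized by the before SD.

    The during-cooling simulation continues from the final state of the
    before-cooling simulation — the state the preparation is in when
    cooling switches on.  If the before segment fails to show discharge
    activity (or the integration blows up), the next sub-seed is tried
    and the event is logged; silent failure is never allowed.
    """
    base = TemperatureSpec(T=spec.T0, T0=spec.T0)
    truth = _truth_temp(spec, temperature)
    for attempt in range(spec.max_retries):
        sub = int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0]
                  % np.uint32(2 ** 31))
        cfg_bc = SimulationConfig(duration=spec.segment, dt=spec.dt,
                                  burn_in=spec.burn_in, seed=sub)
        cfg_dc = SimulationConfig(duration=spec.segment, dt=spec.dt,
                                  burn_in=spec.burn_in,
                                  seed=int(np.random.SeedSequence(
                                      [seed, attempt, 1]).generate_state(1)[0]
                                      % np.uint32(2 ** 31)))
        try:
            before, state = simulate(params, base, cfg_bc, return_state=True)
            during = simulate(params, truth, cfg_dc, initial_state=state)
        except BlowUpError as exc:
            log.warning("simulation blow-up (seed %d, attempt %d): %s",
                        seed, attempt, exc)
            continue
        ev = detect_discharges(before)
        if ev.n_events / before.duration * 60.0 < spec.min_events_per_min:
            log.warning("before-cooling segment shows too few discharges "
                        "(%d in %.0f s; seed %d attempt %d); regenerating",
                        ev.n_events, before.duration, seed, attempt)
            continue
        before_n = normalize(before, before)
        during_n = normalize(during, before)
        if spec.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, attempt, 2]))
            before_n.values = before_n.values + rng.normal(
                0.0, spec.noise_sd, before_n.values.size)
            during_n.values = during_n.values + rng.normal(
                0.0, spec.noise_sd, during_n.values.size)
        return before_n, during_n
    raise RuntimeError(f"could not generate a valid recording for seed "
                       f"{seed} after {spec.max_retries} attempts")


def generate_rat(spec: SyntheticStudySpec, rat_id: int) -> RatRecord:
    """Sample one rat's ground-truth gains and generate its experiments."""
    ss = np.random.SeedSequence([spec.master_seed, rat_id])
    rng = np.random.default_rng(ss)
    (gs_lo, gs_hi), (gf_lo, gf_hi) = spec.gain_ranges
    params = ModelParameters(G_SIN=float(rng.uniform(gs_lo, gs_hi)),
                             G_FIN=float(rng.uniform(gf_lo, gf_hi)))
    experiments = []
    seeds = {}
    for ti, T in enumerate(spec.temperatures):
        seed = int(ss.generate_state(10)[3 + ti] % np.uint32(2 ** 31))
        seeds[str(T)] = seed
        before, during = generate_recording(params, T, spec, seed)
        experiments.append(CoolingExperiment(T, before, during, spec.T0))
    return RatRecord(rat_id, params, dict(spec.q10_truth), spec.variant,
                     experiments, seeds)


def generate_study(spec: SyntheticStudySpec | None = None) -> list:
    """All rats of a study, in memory."""
    spec = spec or SyntheticStudySpec()
    return [generate_rat(spec, i) for i in range(spec.n_rats)]


def write_study(spec: SyntheticStudySpec, out_dir) -> Path:
    """Generate a study and write it as text files plus a JSON manifest.

    Layout: ``rat<k>_T<temp>_{before,during}.txt`` pairs and
    ``manifest.json`` holding the spec, per-rat ground truth and seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"spec": spec.to_dict(), "rats": []}
    for rat in generate_study(spec):
        entry = {"rat_id": rat.rat_id,
                 "G_SIN": rat.params.G_SIN, "G_FIN": rat.params.G_FIN,
                 "variant": rat.variant, "q10_truth": rat.q10_truth,
                 "seeds": rat.seeds, "files": {}}
        for exp in rat.experiments:
            stem = f"rat{rat.rat_id}_T{exp.T:g}"
            write_timeseries(exp.before, out / f"{stem}_before.txt")
            write_timeseries(exp.during, out / f"{stem}_during.txt")
            entry["files"][f"{exp.T:g}"] = [f"{stem}_before.txt",
                                            f"{stem}_during.txt"]
        manifest["rats"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def load_study(study_dir) -> tuple[SyntheticStudySpec, list]:
    """Read a written study back into memory via its manifest."""
    study_dir = Path(study_dir)
    manifest = json.loads((study_dir / "manifest.json").read_text())
    spec = SyntheticStudySpec.from_dict(manifest["spec"])
    rats = []
    for entry in manifest["rats"]:
        params = ModelParameters(G_SIN=entry["G_SIN"], G_FIN=entry["G_FIN"])
        experiments = []
        for T_key, (f_bc, f_dc) in entry["files"].items():
            experiments.append(CoolingExperiment(
                float(T_key), read_timeseries(study_dir / f_bc),
                read_timeseries(study_dir / f_dc), spec.T0))
        experiments.sort(key=lambda e: -e.T)
        rats.append(RatRecord(entry["rat_id"], params, entry["q10_truth"],
                              entry["variant"], experiments, entry["seeds"]))
    return spec, rats
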