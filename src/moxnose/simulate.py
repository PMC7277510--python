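"""Synthetic MOX sensor-response generator.

Real acquisitions expose the sensor array to a sample's headspace for one
minute between two clean-air phases; an n-type chemiresistor's resistance
falls exponentially toward a gas-dependent plateau during exposure and
relaxes back toward the baseline afterwards (the single p-type channel
mirrors this upward).  The generator reproduces that shape with a first-order
adsorption/desorption model:

    baseline:  R(t) = R0
    exposure:  R(t) = R0 * (1 -/+ A * (1 - exp(-(t - t_on)/tau_resp)))
    recovery:  exponential return toward R0 with time constant tau_rec

with a multiplicative lognormal between-replica factor on the amplitude A and
additive relative Gaussian measurement noise on R.  Class effects (seasoning,
working process, rind class) act multiplicatively on A and tau_resp; the
shipped defaults reproduce the qualitative class orderings reported for the
real instrument (deeper/faster responses for 24-month cheese, amplitude
scaling with rind fraction, a channel-pattern difference between the two rind
working processes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import (
    DesignManifest,
    Process,
    RindClass,
    SampleLabel,
    Seasoning,
    SensorSpec,
    default_sensor_array,
)

__all__ = [
    "AcquisitionProtocol",
    "SensorKinetics",
    "ClassEffects",
    "GeneratorParams",
    "ResponseCurve",
    "SensorDataset",
    "simulate_curve",
    "simulate_dataset",
]

# n-type amplitudes are capped below 1 so resistance stays positive
_MAX_N_AMPLITUDE = 0.95


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of one acquisition: clean-air baseline, headspace exposure
    (the one-minute analysis time), clean-air recovery."""

    baseline_s: float = 30.0
    exposure_s: float = 60.0
    recovery_s: float = 210.0
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "exposure_s", "recovery_s", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def duration_s(self) -> float:
        return self.baseline_s + self.exposure_s + self.recovery_s

    @property
    def exposure_onset_s(self) -> float:
        return self.baseline_s

    @property
    def exposure_end_s(self) -> float:
        return self.baseline_s + self.exposure_s

    def time_grid(self) -> np.ndarray:
        dt = 1.0 / self.sample_rate_hz
        n = int(round(self.duration_s / dt))
        return np.arange(n + 1) * dt


@dataclass(frozen=True)
class SensorKinetics:
    """Per-channel base response parameters."""

    amplitude: float  # fraction of baseline (depth for n-type, height for p)
    tau_resp_s: float
    tau_rec_s: float
    baseline_ohm: float
    # per-process amplitude re-weighting of this channel
    process_amp: Mapping[str, float] = field(
        default_factory=lambda: {"WR": 1.0, "SR": 1.0, "NONE": 1.0}
    )

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.tau_resp_s <= 0 or self.tau_rec_s <= 0:
            raise ValueError("time constants must be positive")
        if self.baseline_ohm <= 0:
            raise ValueError("baseline_ohm must be positive")


@dataclass(frozen=True)
class ClassEffects:
    """Multiplicative label effects on amplitude and response time constant."""

    seasoning_amp: Mapping[str, float]
    seasoning_tau: Mapping[str, float]
    rind_amp: Mapping[str, float]

    @classmethod
    def null(cls) -> "ClassEffects":
        return cls(
            seasoning_amp={s.value: 1.0 for s in Seasoning},
            seasoning_tau={s.value: 1.0 for s in Seasoning},
            rind_amp={c.value: 1.0 for c in RindClass},
        )


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of the synthetic generator."""

    sensors: Mapping[str, SensorKinetics]
    effects: ClassEffects
    noise_sd: float = 0.005
    replica_cv: float = 0.08

    @classmethod
    def default(cls) -> "GeneratorParams":
        text = resources.files("moxnose.data").joinpath("default_generator.yaml").read_text()
        return cls.from_yaml_text(text)

    @classmethod
    def null_effects(cls) -> "GeneratorParams":
        """Default kinetics with every class effect set to 1 (and the
        per-channel process re-weighting flattened): no label signal at all."""
        base = cls.default()
        flat = {
            sid: SensorKinetics(
                amplitude=k.amplitude,
                tau_resp_s=k.tau_resp_s,
                tau_rec_s=k.tau_rec_s,
                baseline_ohm=k.baseline_ohm,
                process_amp={"WR": 1.0, "SR": 1.0, "NONE": 1.0},
            )
            for sid, k in base.sensors.items()
        }
        return cls(
            sensors=flat,
            effects=ClassEffects.null(),
            noise_sd=base.noise_sd,
            replica_cv=base.replica_cv,
        )

    @classmethod
    def from_yaml_text(cls, text: str) -> "GeneratorParams":
        raw = yaml.safe_load(text)
        sensors = {
            sid: SensorKinetics(
                amplitude=float(s["amplitude"]),
                tau_resp_s=float(s["tau_resp_s"]),
                tau_rec_s=float(s["tau_rec_s"]),
                baseline_ohm=float(s["baseline_ohm"]),
                process_amp={k: float(v) for k, v in s.get("process_amp", {}).items()}
                or {"WR": 1.0, "SR": 1.0, "NONE": 1.0},
            )
            for sid, s in raw["sensors"].items()
        }
        eff = raw["effects"]
        effects = ClassEffects(
            seasoning_amp={k: float(v) for k, v in eff["seasoning_amp"].items()},
            seasoning_tau={k: float(v) for k, v in eff["seasoning_tau"].items()},
            rind_amp={k: float(v) for k, v in eff["rind_amp"].items()},
        )
        return cls(
            sensors=sensors,
            effects=effects,
            noise_sd=float(raw.get("noise_sd", 0.005)),
            replica_cv=float(raw.get("replica_cv", 0.08)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorParams":
        return cls.from_yaml_text(Path(path).read_text())

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "noise_sd": self.noise_sd,
            "replica_cv": self.replica_cv,
            "effects": {
                "seasoning_amp": dict(self.effects.seasoning_amp),
                "seasoning_tau": dict(self.effects.seasoning_tau),
                "rind_amp": dict(self.effects.rind_amp),
            },
            "sensors": {
                sid: {
                    "amplitude": k.amplitude,
                    "tau_resp_s": k.tau_resp_s,
                    "tau_rec_s": k.tau_rec_s,
                    "baseline_ohm": k.baseline_ohm,
                    "process_amp": dict(k.process_amp),
                }
                for sid, k in self.sensors.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class ResponseCurve:
    """One channel's timed resistance acquisition with phase markers."""

    replica_id: str
    sensor_id: str
    t: np.ndarray  # seconds, uniformly sampled, strictly increasing
    R: np.ndarray  # resistance in ohm, > 0
    exposure_onset_s: float
    exposure_end_s: float
    polarity: str = "n"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.shape != self.R.shape:
            raise ValueError("t and R must have the same length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.R <= 0):
            raise ValueError("resistance must be positive everywhere")


def _amplitude_and_taus(
    spec: SensorSpec, label: SampleLabel, params: GeneratorParams
) -> tuple[float, float, float]:
    try:
        kin = params.sensors[spec.sensor_id]
    except KeyError:
        raise KeyError(
            f"no generator parameters defined for sensor {spec.sensor_id!r}"
        ) from None
    eff = params.effects
    amp = (
        kin.amplitude
        * eff.seasoning_amp[label.seasoning.value]
        * eff.rind_amp[label.rind_class.value]
        * kin.process_amp[label.process.value]
    )
    tau_resp = kin.tau_resp_s * eff.seasoning_tau[label.seasoning.value]
    return amp, tau_resp, kin.tau_rec_s


def _noise_free_ratio(
    t: np.ndarray, amp: float, tau_resp: float, tau_rec: float,
    t_on: float, t_off: float, polarity: str,
) -> np.ndarray:
    """Piecewise first-order response of the normalized resistance R/R0."""
    r = np.ones_like(t)
    expo = (t >= t_on) & (t <= t_off)
    rec = t > t_off
    excursion = amp * (1.0 - np.exp(-(t[expo] - t_on) / tau_resp))
    exc_off = amp * (1.0 - np.exp(-(t_off - t_on) / tau_resp))
    rec_exc = exc_off * np.exp(-(t[rec] - t_off) / tau_rec)
    sign = -1.0 if polarity == "n" else 1.0
    r[expo] += sign * excursion
    r[rec] += sign * rec_exc
    return r


def simulate_curve(
    spec: SensorSpec,
    label: SampleLabel,
    params: GeneratorParams,
    protocol: AcquisitionProtocol,
    rng: np.random.Generator,
    replica_id: str = "replica",
) -> ResponseCurve:
    """Simulate one channel's acquisition for one replica.

    The between-replica lognormal factor (mean 1, CV ``replica_cv``) scales
    the amplitude; relative Gaussian noise of SD ``noise_sd`` is added to R.
    The noise-free normalized curve is piecewise monotone, so its first
    derivative has exactly two extrema of opposite sign (the exposure spike
    and the recovery spike).
    """
    amp, tau_resp, tau_rec = _amplitude_and_taus(spec, label, params)
    if params.replica_cv > 0:
        sigma = float(np.sqrt(np.log1p(params.replica_cv**2)))
        amp *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
    if spec.polarity == "n":
        amp = min(amp, _MAX_N_AMPLITUDE)

    t = protocol.time_grid()
    r = _noise_free_ratio(
        t, amp, tau_resp, tau_rec,
        protocol.exposure_onset_s, protocol.exposure_end_s, spec.polarity,
    )
    kin = params.sensors[spec.sensor_id]
    R = kin.baseline_ohm * r
    if params.noise_sd > 0:
        R = R * (1.0 + rng.normal(0.0, params.noise_sd, size=R.shape))
    R = np.maximum(R, 1e-9 * kin.baseline_ohm)
    return ResponseCurve(
        replica_id=replica_id,
        sensor_id=spec.sensor_id,
        t=t,
        R=R,
        exposure_onset_s=protocol.exposure_onset_s,
        exposure_end_s=protocol.exposure_end_s,
        polarity=spec.polarity,
    )


@dataclass
class SensorDataset:
    """All curves of a simulated (or loaded) acquisition campaign."""

    curves: list[ResponseCurve]
    manifest: DesignManifest
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.curves)

    def to_long_frame(self) -> pd.DataFrame:
        if not self.curves:
            return pd.DataFrame(
                columns=["replica_id", "sensor_id", "time_s", "resistance_ohm"]
            )
        parts = [
            pd.DataFrame(
                {
                    "replica_id": c.replica_id,
                    "sensor_id": c.sensor_id,
                    "time_s": c.t,
                    "resistance_ohm": c.R,
                }
            )
            for c in self.curves
        ]
        return pd.concat(parts, ignore_index=True)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for c in self.curves:
            h.update(c.replica_id.encode())
            h.update(c.sensor_id.encode())
            h.update(np.ascontiguousarray(c.t).tobytes())
            h.update(np.ascontiguousarray(c.R).tobytes())
        return h.hexdigest()

    def write_csv(self, path: str | Path, version: str | None = None) -> None:
        """Write the long-format CSV plus a JSON sidecar recording seed,
        protocol and package version."""
        path = Path(path)
        self.to_long_frame().to_csv(path, index=False)
        from . import __version__

        sidecar = {
            "seed": self.seed,
            "protocol": asdict(self.protocol),
            "package_version": version or __version__,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        manifest: DesignManifest,
        protocol: AcquisitionProtocol,
        array: Sequence[SensorSpec] | None = None,
    ) -> "SensorDataset":
        """Load a long-format CSV (replica_id, sensor_id, time_s,
        resistance_ohm); channel polarity is taken from ``array``."""
        array = list(array) if array is not None else default_sensor_array()
        polarity = {s.sensor_id: s.polarity for s in array}
        frame = pd.read_csv(path)
        curves = []
        for (rid, sid), grp in frame.groupby(["replica_id", "sensor_id"], sort=True):
            grp = grp.sort_values("time_s")
            curves.append(
                ResponseCurve(
                    replica_id=str(rid),
                    sensor_id=str(sid),
                    t=grp["time_s"].to_numpy(),
                    R=grp["resistance_ohm"].to_numpy(),
                    exposure_onset_s=protocol.exposure_onset_s,
                    exposure_end_s=protocol.exposure_end_s,
                    polarity=polarity.get(str(sid), "n"),
                )
            )
        return cls(curves=curves, manifest=manifest, protocol=protocol)


def simulate_dataset(
    manifest: DesignManifest,
    array: Sequence[SensorSpec] | None = None,
    params: GeneratorParams | None = None,
    protocol: AcquisitionProtocol | None = None,
    seed: int = 0,
) -> SensorDataset:
    """Simulate one curve per (replica x sensor).

    Each replica draws its own generator from a counter-based sub-seed
    (``SeedSequence(seed).spawn_key = (replica_index,)``), so the dataset is
    reproducible and independent of generation order.
    """
    array = list(array) if array is not None else default_sensor_array()
    params = params or GeneratorParams.default()
    protocol = protocol or AcquisitionProtocol()
    curves: list[ResponseCurve] = []
    for i, (rid, label) in enumerate(manifest.rows):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for spec in array:
            curves.append(
                simulate_curve(spec, label, params, protocol, rng, replica_id=rid)
            )
    return SensorDataset(curves=curves, manifest=manifest, protocol=protocol, seed=seed)
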