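"""Run configuration: one validated block per pipeline stage.

A config file (YAML or JSON) carries the kinetic scheme, library spec, noise
model, sampling times, analysis window and thresholds, plus the single seed
from which every source of randomness flows.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import RateScheme, RegulatoryGeometry
from .simulate import AnalogSpec, LibrarySpec, NoiseModel

__all__ = ["ConfigError", "Thresholds", "RunConfig", "load_config", "default_config_dict"]


class ConfigError(ValueError):
    """Configuration schema violation; message lists the offending keys."""


@dataclass(frozen=True)
class Thresholds:
    inner_sd: float = 1.0
    outer_sd: float = 2.5
    lambda_threshold: float = 2.5

    def __post_init__(self) -> None:
        if min(self.inner_sd, self.outer_sd, self.lambda_threshold) <= 0:
            raise ConfigError("thresholds must be > 0")
        if self.inner_sd >= self.outer_sd:
            raise ConfigError("inner_sd must be below outer_sd")


@dataclass(frozen=True)
class RunConfig:
    scheme: RateScheme
    library: LibrarySpec
    noise: NoiseModel = NoiseModel()
    geometry: RegulatoryGeometry = RegulatoryGeometry()
    times: tuple[float, ...] = (
        5.0, 10.0, 20.0, 40.0, 80.0, 120.0, 180.0, 260.0, 360.0, 480.0, 600.0, 720.0
    )
    window: tuple[int, int] = (25, 118)
    thresholds: Thresholds = Thresholds()
    naim_extent: float = 0.2
    min_total: float = 0.0
    max_lag: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.window
        if lo > hi:
            raise ConfigError(f"window start {lo} exceeds end {hi}")
        if not 0.0 < self.naim_extent < 1.0:
            raise ConfigError("naim_extent must be in (0, 1)")
        if any(t < 0 for t in self.times):
            raise ConfigError("times must be >= 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {
            "scheme", "library", "noise", "geometry", "times", "window",
            "thresholds", "naim_extent", "min_total", "max_lag", "seed",
        }
        bad = sorted(set(d) - known)
        if bad:
            raise ConfigError(f"unknown config keys: {bad}")
        missing = sorted({"scheme", "library"} - set(d))
        if missing:
            raise ConfigError(f"missing config blocks: {missing}")
        try:
            scheme = RateScheme.from_dict(d["scheme"])
            library = _library_from_dict(d["library"])
            noise = NoiseModel(**d.get("noise", {}))
            geometry = RegulatoryGeometry.from_dict(d.get("geometry", {}))
            thresholds = Thresholds(**d.get("thresholds", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        kwargs = {}
        for key in ("times", "window"):
            if key in d:
                kwargs[key] = tuple(d[key])
        for key in ("naim_extent", "min_total"):
            if key in d:
                kwargs[key] = float(d[key])
        for key in ("max_lag", "seed"):
            if key in d:
                kwargs[key] = int(d[key])
        return cls(
            scheme=scheme, library=library, noise=noise, geometry=geometry,
            thresholds=thresholds, **kwargs,
        )

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.to_dict(),
            "library": _library_to_dict(self.library),
            "noise": {
                "band_cv": self.noise.band_cv,
                "lane_factor_sd": self.noise.lane_factor_sd,
            },
            "geometry": self.geometry.to_dict(),
            "times": list(self.times),
            "window": list(self.window),
            "thresholds": {
                "inner_sd": self.thresholds.inner_sd,
                "outer_sd": self.thresholds.outer_sd,
                "lambda_threshold": self.thresholds.lambda_threshold,
            },
            "naim_extent": self.naim_extent,
            "min_total": self.min_total,
            "max_lag": self.max_lag,
            "seed": self.seed,
        }


def _library_from_dict(d: Mapping) -> LibrarySpec:
    known = {"track_length", "analogs", "n_molecules", "sequence", "cleavage_efficiency"}
    bad = sorted(set(d) - known)
    if bad:
        raise ConfigError(f"unknown library keys: {bad}")
    analogs = []
    for a in d.get("analogs", []):
        a = dict(a)
        pf = a.pop("position_factors", None)
        if pf is not None:
            pf = {int(k): tuple(v) for k, v in pf.items()}
        bases = a.pop("eligible_bases", None)
        analogs.append(
            AnalogSpec(
                analog=a.pop("analog"),
                incorporation_prob=float(a.pop("incorporation_prob", 0.05)),
                eligible_bases=frozenset(bases) if bases else None,
                kU_factor=float(a.pop("kU_factor", 1.0)),
                kD_factor=float(a.pop("kD_factor", 1.0)),
                position_factors=pf,
            )
        )
        if a:
            raise ConfigError(f"unknown analog keys: {sorted(a)}")
    return LibrarySpec(
        track_length=int(d["track_length"]),
        analogs=tuple(analogs),
        n_molecules=int(d.get("n_molecules", 100_000)),
        sequence=d.get("sequence"),
        cleavage_efficiency=float(d.get("cleavage_efficiency", 1.0)),
    )


def _library_to_dict(lib: LibrarySpec) -> dict:
    return {
        "track_length": lib.track_length,
        "n_molecules": lib.n_molecules,
        "sequence": lib.sequence,
        "cleavage_efficiency": lib.cleavage_efficiency,
        "analogs": [
            {
                "analog": a.analog,
                "incorporation_prob": a.incorporation_prob,
                "eligible_bases": sorted(a.eligible_bases) if a.eligible_bases else None,
                "kU_factor": a.kU_factor,
                "kD_factor": a.kD_factor,
                "position_factors": {
                    str(k): list(v) for k, v in (a.position_factors or {}).items()
                } or None,
            }
            for a in lib.analogs
        ],
    }


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return RunConfig.from_dict(data)


def default_config_dict(
    track_length: int = 120,
    n_molecules: int = 100_000,
    seed: int = 0,
) -> dict:
    """A ready-to-edit config covering the default analysis window."""
    return {
        "seed": seed,
        # Steps are fast relative to activation: the whole-chain transit time
        # (n_steps / kU = 0.6 s here) must stay negligible against 1/k_act so
        # the control curve has no detectable lag.
        "scheme": {
            "k_act": 0.02,
            "baseline_amplitude": 0.9,
            "n_steps": track_length,
            "kU": 200.0,
            "kD": 1.0,
        },
        "library": {
            "track_length": track_length,
            "n_molecules": n_molecules,
            "cleavage_efficiency": 0.5,
            "analogs": [
                {"analog": "2'-deoxy-NaS", "incorporation_prob": 0.05}
            ],
        },
        "noise": {"band_cv": 0.10, "lane_factor_sd": 0.05},
        "geometry": {"n_subunits": 6, "period": 7, "offset": 7},
        "times": [5.0, 10.0, 20.0, 40.0, 80.0, 120.0, 180.0, 260.0, 360.0, 480.0, 600.0, 720.0],
        "window": [25, 118],
        "thresholds": {"inner_sd": 1.0, "outer_sd": 2.5, "lambda_threshold": 2.5},
        "naim_extent": 0.2,
    }
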