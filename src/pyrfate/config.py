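"""Model configuration: a strict YAML/JSON schema for chains and runs.

The same schema describes the bundled seasonal fixtures and any
user-defined pollutant/system: state declarations, pathway schedules, the
initial vector, and run settings (step length, threshold, interpretation).
Unknown keys are rejected rather than ignored, so typos fail loudly, and a
serialized fixture deserializes to an identical configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .regimes import RegimeParameterSet
from .schedule import PROBABILITY, ZERO_ORDER, PiecewiseRateSchedule, Segment
from .simulate import DEFAULT_THRESHOLD
from .states import StateSpace, StateVector

SCHEMA_VERSION = 1

_TOP_KEYS = {
    "schema_version",
    "name",
    "description",
    "states",
    "pathways",
    "initial",
    "t0",
    "threshold",
    "horizon",
    "interpretation",
    "seed",
}
_STATE_KEYS = {"label", "kind"}
_PATHWAY_KEYS = {"name", "source", "destination", "units", "segments"}
_SEGMENT_KEYS = {"start", "end", "rate"}


@dataclass(frozen=True)
class ModelConfig:
    """Validated in-memory form of a model configuration file."""

    name: str
    space: StateSpace
    schedules: dict[str, PiecewiseRateSchedule]
    initial: dict[str, float]
    t0: float = 1.0
    threshold: float = DEFAULT_THRESHOLD
    horizon: float | None = None
    interpretation: str = PROBABILITY
    seed: int | None = None
    description: str = ""

    @property
    def parameters(self) -> RegimeParameterSet:
        u0 = [self.initial.get(label, 0.0) for label in self.space.labels]
        return RegimeParameterSet(
            regime=self.name,
            space=self.space,
            schedules=dict(self.schedules),
            u0=StateVector(u0),
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "description": self.description,
            "states": [
                {"label": label, "kind": kind} for label, kind in self.space.states
            ],
            "pathways": [
                {
                    "name": name,
                    "source": s.source,
                    "destination": s.destination,
                    "units": s.units,
                    "segments": [
                        {"start": seg.start, "end": seg.end, "rate": seg.rate}
                        for seg in s.segments
                    ],
                }
                for name, s in self.schedules.items()
            ],
            "initial": dict(self.initial),
            "t0": self.t0,
            "threshold": self.threshold,
            "horizon": self.horizon,
            "interpretation": self.interpretation,
            "seed": self.seed,
        }

    def content_hash(self) -> str:
        """Stable hash of the configuration, for run provenance logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _require_keys(mapping: dict, allowed: set, required: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigurationError(f"{where}: missing key(s) {sorted(missing)}")


def parse_config(raw: dict, origin: str = "<config>") -> ModelConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{origin}: top level must be a mapping")
    _require_keys(raw, _TOP_KEYS, {"name", "states", "pathways", "initial"}, origin)
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"{origin}: unsupported schema_version {version} (expected {SCHEMA_VERSION})"
        )

    states = []
    for i, s in enumerate(raw["states"]):
        _require_keys(s, _STATE_KEYS, _STATE_KEYS, f"{origin}: states[{i}]")
        states.append((str(s["label"]), str(s["kind"])))
    space = StateSpace(states=tuple(states))

    schedules: dict[str, PiecewiseRateSchedule] = {}
    for i, p in enumerate(raw["pathways"]):
        where = f"{origin}: pathways[{i}]"
        _require_keys(p, _PATHWAY_KEYS, {"name", "source", "destination", "segments"}, where)
        segments = []
        for j, seg in enumerate(p["segments"]):
            _require_keys(seg, _SEGMENT_KEYS, {"start", "rate"}, f"{where}: segments[{j}]")
            end = seg.get("end")
            segments.append(
                Segment(
                    start=float(seg["start"]),
                    end=None if end is None else float(end),
                    rate=float(seg["rate"]),
                )
            )
        name = str(p["name"])
        if name in schedules:
            raise ConfigurationError(f"{where}: duplicate pathway name {name!r}")
        for endpoint in (p["source"], p["destination"]):
            space.index(str(endpoint))  # raises on a dangling reference
        schedules[name] = PiecewiseRateSchedule(
            segments=tuple(segments),
            source=str(p["source"]),
            destination=str(p["destination"]),
            units=str(p.get("units", "1/h")),
        )

    initial = {}
    for label, amount in raw["initial"].items():
        space.index(str(label))
        initial[str(label)] = float(amount)

    interpretation = str(raw.get("interpretation", PROBABILITY))
    if interpretation not in (PROBABILITY, ZERO_ORDER):
        raise ConfigurationError(
            f"{origin}: interpretation must be {PROBABILITY!r} or {ZERO_ORDER!r}"
        )
    horizon = raw.get("horizon")
    return ModelConfig(
        name=str(raw["name"]),
        description=str(raw.get("description", "")),
        space=space,
        schedules=schedules,
        initial=initial,
        t0=float(raw.get("t0", 1.0)),
        threshold=float(raw.get("threshold", DEFAULT_THRESHOLD)),
        horizon=None if horizon is None else float(horizon),
        interpretation=interpretation,
        seed=None if raw.get("seed") is None else int(raw["seed"]),
    )


def load_config(path) -> ModelConfig:
    """Load and validate a model configuration from YAML or JSON (by
    extension; anything not ``.json`` is parsed as YAML, of which JSON is a
    subset anyway)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"{path}: cannot parse: {exc}") from exc
    return parse_config(raw, origin=str(path))


def save_config(config: ModelConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
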