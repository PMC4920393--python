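"""Study configuration: packaged defaults, YAML overrides, model-object factories."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .elastance import ElastanceParams, ElastanceShape
from .simulation import ValveParams
from .windkessel import ArterialParams

__all__ = ["StudyConfig", "default_config", "load_config"]


def _deep_update(base: dict, other: Mapping) -> dict:
    for k, v in other.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _default_raw() -> dict:
    text = resources.files("cardioage").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class StudyConfig:
    """Validated study configuration with factories for the model objects."""

    raw: dict = field(default_factory=_default_raw)

    def __post_init__(self) -> None:
        self.validate()

    # -- factories ----------------------------------------------------------
    def elastance_shape(self) -> ElastanceShape:
        s = self.raw["cardiac"]["shape"]
        return ElastanceShape(
            rise_exponent=float(s["rise_exponent"]),
            rise_timescale=float(s["rise_timescale"]),
            decay_exponent=float(s["decay_exponent"]),
            decay_timescale=float(s["decay_timescale"]),
        )

    def cardiac_params(self) -> ElastanceParams:
        c = self.raw["cardiac"]
        return ElastanceParams(
            Ees=float(c["ees_mmhg_per_ml"]),
            Eed=float(c["eed_mmhg_per_ml"]),
            V0=float(c["v0_ml"]),
            period_T=float(c["period_s"]),
            shape=self.elastance_shape(),
        )

    def valve_params(self) -> ValveParams:
        v = self.raw["valves"]
        return ValveParams(
            resistance=float(v["resistance_mmhg_s_per_ml"]),
            inertance=float(v["inertance_mmhg_s2_per_ml"]),
        )

    def arterial_params(self, age: int) -> ArterialParams:
        a = self.raw["arterial"]
        zc = {int(k): float(v) for k, v in a["zc_by_age"].items()}
        if age not in zc:
            raise ValueError(f"age must be one of {sorted(zc)}, got {age!r}")
        frac = (age - 20) / 60.0
        return ArterialParams(
            C=float(a["c_age20"]) + frac * (float(a["c_age80"]) - float(a["c_age20"])),
            R=float(a["r_age20"]) + frac * (float(a["r_age80"]) - float(a["r_age20"])),
            Zc=zc[age],
            L=float(a["inertance"]),
        )

    def ages(self) -> tuple[int, ...]:
        return tuple(sorted(int(k) for k in self.raw["arterial"]["zc_by_age"]))

    # -- scalar accessors ----------------------------------------------------
    @property
    def ped_target(self) -> float:
        return float(self.raw["cardiac"]["ped_target_mmhg"])

    @property
    def dt(self) -> float:
        return float(self.raw["solver"]["dt_s"])

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def amplification_table(self) -> dict[int, float]:
        t = self.raw["comparison"]["amplification_by_age"]
        return {int(k): float(v) for k, v in t.items()}

    def validate(self) -> None:
        c = self.raw["cardiac"]
        if not float(c["period_s"]) > 0:
            raise ValueError("cardiac.period_s must be > 0")
        if not float(c["ees_mmhg_per_ml"]) > float(c["eed_mmhg_per_ml"]) > 0:
            raise ValueError("require ees > eed > 0")
        if not self.dt > 0:
            raise ValueError("solver.dt_s must be > 0")
        for key in ("sv_tol_ml", "pressure_tol_mmhg"):
            if not float(self.raw["solver"][key]) > 0:
                raise ValueError(f"solver.{key} must be > 0")
        ref = self.raw["comparison"].get("reference_csv")
        if ref is not None and not Path(ref).exists():
            raise FileNotFoundError(f"comparison.reference_csv not found: {ref}")
        # construction validates ranges
        self.cardiac_params()
        self.valve_params()
        for age in self.ages():
            self.arterial_params(age)

    def with_overrides(self, overrides: Mapping[str, Any]) -> "StudyConfig":
        raw = copy.deepcopy(self.raw)
        return StudyConfig(_deep_update(raw, overrides))


def default_config() -> StudyConfig:
    """The packaged default configuration."""
    return StudyConfig()


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML config file layered over the packaged defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return default_config().with_overrides(user)
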