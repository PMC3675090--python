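"""Flat, human-editable run configuration.

A run is described by a single flat ``key = value`` file (TOML dialect);
command-line flags override file values.  Angles are degrees and strains
are fractions (``0.10``; the string form ``"10%"`` is also accepted) at
the boundary; radians are used internally.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Union

from .params import ModelParams, ReorientationPolicy, StretchProtocol

__all__ = ["RunConfig", "parse_strain", "ConfigError"]


class ConfigError(ValueError):
    pass


def parse_strain(value: Union[str, float]) -> float:
    """Strain as a fraction; "10%" and 0.10 are equivalent."""
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return float(text[:-1]) / 100.0
        return float(text)
    return float(value)


@dataclass
class RunConfig:
    """All knobs of a simulation run, with Table-style defaults."""

    # model parameters
    c: float = 0.2
    d: float = 0.1
    g0: float = -5.0
    a: float = 3.5
    beta: float = 0.6
    k_hat: float = 15.0
    gamma: float = 0.5
    eps_c: float = 0.04
    nu: float = 0.0
    kon_per_s: float = 6.25
    # stretch protocol
    amplitude: float = 0.10
    frequency_hz: float = 1.0
    waveform: str = "offset"
    linear_substrate: bool = False
    # reorientation policy
    t0: float = 0.2
    dr: float = 5.0e-3
    trial_time: float = 500.0
    xi0: float = 0.3
    zeta0: float = 0.0
    collapse_threshold: float = 0.02
    grace_time: float = 10.0
    table_step_deg: float = 0.5
    # run controls
    seed: int = 0
    tau_end: float = 500.0
    population_tau_end: float = 150000.0
    angle_step_deg: float = 2.0
    n_cells: int = 100
    n_replicates: int = 10
    theta_deg: float = 0.0
    output_dir: str = "."

    def __post_init__(self) -> None:
        self.amplitude = parse_strain(self.amplitude)
        self.eps_c = float(self.eps_c)
        if self.linear_substrate and not math.isinf(self.eps_c) and self.eps_c != 0.04:
            raise ConfigError(
                "conflicting settings: linear_substrate = true but a finite "
                f"eps_c = {self.eps_c} was also given; drop one of the two"
            )
        if self.linear_substrate:
            self.eps_c = math.inf

    # -- construction -------------------------------------------------
    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in fields(cls)}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - cls.field_names()
        if unknown:
            raise ConfigError(
                f"unknown configuration keys: {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data)

    def with_overrides(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        unknown = set(clean) - self.field_names()
        if unknown:
            raise ConfigError(
                f"unknown configuration keys: {', '.join(sorted(unknown))}"
            )
        return dataclasses.replace(self, **clean)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        # TOML has no inf literal; represent the linear substrate by flag.
        if math.isinf(out["eps_c"]):
            out["eps_c"] = 0.04
            out["linear_substrate"] = True
        return out

    def to_file(self, path: Union[str, Path]) -> None:
        lines = []
        for key, value in self.to_dict().items():
            if isinstance(value, bool):
                text = "true" if value else "false"
            elif isinstance(value, str):
                text = f'"{value}"'
            else:
                text = repr(value)
            lines.append(f"{key} = {text}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    # -- adapters ------------------------------------------------------
    def model_params(self, rho_inhibited: bool = False) -> ModelParams:
        return ModelParams(
            c=0.1 if rho_inhibited else self.c,
            d=self.d,
            g0=self.g0,
            a=self.a,
            beta=self.beta,
            k_hat=self.k_hat,
            gamma=self.gamma,
            eps_c=self.eps_c,
            nu=self.nu,
            kon_per_s=self.kon_per_s,
        )

    def protocol(self) -> StretchProtocol:
        return StretchProtocol(
            amplitude=self.amplitude,
            frequency_hz=self.frequency_hz,
            waveform=self.waveform,
            kon_per_s=self.kon_per_s,
        )

    def policy(self) -> ReorientationPolicy:
        return ReorientationPolicy(
            t0=self.t0,
            dr=self.dr,
            trial_time=self.trial_time,
            xi0=self.xi0,
            zeta0=self.zeta0,
            collapse_threshold=self.collapse_threshold,
            grace_time=self.grace_time,
            table_step_deg=self.table_step_deg,
        )
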