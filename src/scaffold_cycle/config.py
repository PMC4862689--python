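"""Run configuration: every tunable of the pipeline, with validated
defaults, YAML round-tripping, and strict unknown-key rejection."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed, unknown-key, or out-of-range configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class StaircaseSection(_Strict):
    baseline: float = Field(10.0 ** -3.5, ge=0)
    levels: tuple[float, float, float] = (10.0 ** -2.5, 10.0 ** -1.5,
                                          10.0 ** -0.5)


class PulseSection(_Strict):
    baseline: float = Field(10.0 ** -1.5, gt=0)
    magnitudes: tuple[float, ...] = (1.0, 10.0, 100.0)
    relative: bool = True           # magnitudes as (I1-I0)/I0 fold changes
    removal: str = "free-first"     # down-step kinase removal policy


class ScoringSection(_Strict):
    ru: float = Field(1.0, gt=0)
    C: float | None = Field(None, gt=0)   # None: direction-wise normalisation
    K_thresh: float | None = Field(None, gt=0)   # None: 0.1 (dimensionless)
    s_cap: float = Field(1e6, gt=0)
    a_prec_cap: float = Field(1e6, gt=0)


class SolverSection(_Strict):
    horizon: float = Field(1e6, gt=0)            # s, relaxation cap
    steady_tol_factor: float = Field(1e-10, gt=0)
    rtol: float = Field(1e-6, gt=0)


class BoundsSection(_Strict):
    concentration: tuple[float, float] = (1e-4, 10.0)
    first_order: tuple[float, float] = (1e-3, 1e3)
    bimolecular: tuple[float, float] = (1e-3, 1e3)


class ScreenSection(_Strict):
    n_samples: int = Field(100_000, ge=0)        # published scale
    desk_n_samples: int = Field(20_000, ge=0)    # desk-scale preset
    regime: str = "saturated"
    seed: int = 0
    sample_T: bool = True
    T_total: float | None = Field(None, gt=0)


class SweepSection(_Strict):
    t_grid: tuple[float, float, int] = (1e-4, 10.0, 64)
    s_totals: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0)
    n_affinity: int = Field(64, ge=1)
    f_threshold: float = Field(0.8, gt=0, le=1)
    w_threshold: float = Field(0.3, gt=0, le=1)


class EvolutionSection(_Strict):
    N: int = Field(1000, ge=2)
    sigma: float = Field(0.5, gt=0)
    mutation_prob: float = Field(0.25, ge=0, le=1)
    steps: int = Field(500, ge=0)
    seed: int = 0
    fitness: str = "ultrasensitivity"


class RunConfig(_Strict):
    """The pipeline's full tunable surface (uM / s units throughout)."""

    schema_version: int = SCHEMA_VERSION
    staircase: StaircaseSection = StaircaseSection()
    pulse: PulseSection = PulseSection()
    scoring: ScoringSection = ScoringSection()
    solver: SolverSection = SolverSection()
    bounds: BoundsSection = BoundsSection()
    screen: ScreenSection = ScreenSection()
    sweep: SweepSection = SweepSection()
    evolution: EvolutionSection = EvolutionSection()
    output_dir: str = "results"

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()),
                           sort_keys=True))


def load_config(path=None) -> RunConfig:
    """Load a YAML config; missing file content or empty file = defaults.

    Unknown keys, malformed YAML, or out-of-range values raise
    ConfigError with the offending location.
    """
    if path is None:
        return RunConfig()
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if payload is None:
        return RunConfig()
    if not isinstance(payload, dict):
        raise ConfigError(f"config root must be a mapping, got "
                          f"{type(payload).__name__}")
    try:
        return RunConfig(**payload)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
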