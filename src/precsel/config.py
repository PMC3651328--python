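"""Run configuration: a flat, typed key-value file with strict validation.

All tunables of the selection strategies live in one :class:`RunConfig`.
Unknown keys are rejected (a typo must fail loudly, not silently fall back
to a default), and every numeric field carries its documented range.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .ips import IPSParams

__all__ = ["RunConfig", "load_config", "dump_config"]


class RunConfig(BaseModel):
    """Validated configuration shared by the CLI subcommands.

    Defaults follow the common LC-MALDI setup the methods were designed
    for: 30 s RT bins, capacity 25 precursors per fraction, 10 ppm match
    tolerance, RT windows of 150 s for predicted peptides, objective
    weights k1=10, k2=1, k3=10 and an identification threshold c=0.95.
    """

    model_config = ConfigDict(extra="forbid")

    # paths
    feature_table: Optional[str] = None
    fasta: Optional[str] = None
    psm_table: Optional[str] = None
    output_dir: str = "."

    # acquisition geometry
    cap: int = Field(default=25, ge=0)
    bin_width: float = Field(default=30.0, gt=0)
    gradient_length: float = Field(default=3000.0, gt=0)

    # matching / scheduling
    ppm: float = Field(default=10.0, ge=0)
    ws: float = Field(default=150.0, gt=0)
    max_list_size: int = Field(default=1000, ge=0)
    missed_cleavages: int = Field(default=1, ge=0)
    exclusion_span: int = Field(default=2, ge=0)

    # iterative selection
    k1: float = Field(default=10.0, ge=0)
    k2: float = Field(default=1.0, ge=0)
    k3: float = Field(default=10.0, ge=0)
    c: float = Field(default=0.95, gt=0, lt=1)
    step_size: int = Field(default=10, ge=1)
    delta: float = Field(default=1e-5, gt=0, lt=1)
    rt_mu: float = 0.0
    rt_sigma: float = Field(default=30.0, gt=0)
    max_iterations: int = Field(default=1000, ge=1)
    max_precursors: Optional[int] = Field(default=None, ge=0)
    efficiency_window: int = Field(default=0, ge=0)
    efficiency_threshold: float = Field(default=0.0, ge=0)

    # simulation
    seed: int = 0
    n_proteins: int = Field(default=50, ge=1)
    noise_fraction: float = Field(default=0.2, ge=0)
    id_success_rate: float = Field(default=0.9, ge=0, le=1)

    solver: str = "highs"

    @field_validator("solver")
    @classmethod
    def _known_solver(cls, v: str) -> str:
        if v != "highs":
            raise ValueError(f"unknown solver backend {v!r}; available: highs")
        return v

    def ips_params(self, sequential: bool = False) -> IPSParams:
        """Project the configuration onto the iterative-selection parameters."""
        return IPSParams(
            k1=self.k1,
            k2=self.k2,
            k3=self.k3,
            c=self.c,
            step_size=self.step_size,
            ppm=self.ppm,
            rt_mu=self.rt_mu,
            rt_sigma=self.rt_sigma,
            delta=self.delta,
            max_iterations=self.max_iterations,
            max_precursors=self.max_precursors,
            efficiency_window=self.efficiency_window,
            efficiency_threshold=self.efficiency_threshold,
            sequential=sequential,
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML key-value file; an empty or missing-path file means defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the full effective configuration (round-trips with load_config)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
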