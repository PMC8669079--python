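"""Experiment configuration schema.

YAML-backed, schema-validated before any compute; unknown keys are
rejected.  A single global seed fans out to per-stage seeds through a
counter-based scheme recorded in provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["ExperimentConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    tissue_size: tuple[float, float] = (4.0, 3.2)
    spacing: float = 0.025
    bath: tuple[float, float] = (1.2, 1.2)
    scar: bool = True
    band_thickness: float = 2.0
    isthmus_width: float = 0.4
    bz_rim: float = 0.05
    ci_bz_fraction: float = 0.375
    islet_width: float = 0.075
    islet_margin: float = 0.12
    fiber_angle: float = 0.0


class ModelsConfig(_Strict):
    base: str = "reduced"  # "reduced" or "tt06-epi"
    bz_reductions: tuple[float, float, float] = (0.65, 0.65, 0.30)


class SolverConfig(_Strict):
    dt: float = 0.1
    dt_shock: float = 0.025
    bz_factor: float = 0.5
    sigma_scar: float = 0.05
    sigma_bath: float = 1.0


class InductionConfig(_Strict):
    s1_bcl: float = 500.0
    n_s1: int = 3
    s2_start: float = 500.0
    decrement: float = 10.0
    floor: float = 200.0


class LibraryConfig(_Strict):
    ci_factors: tuple[float, ...] = (0.6, 1.0, 1.5, 2.5)
    n_cycles: int = 5


class AtpConfig(_Strict):
    enabled: bool = True
    amplitude: float = 50.0
    pulse_duration: float = 2.0
    n_sequences: int = 2
    pulses_per_seq: int = 8


class ShockTherapyConfig(_Strict):
    enabled: bool = True
    step: float = 10.0
    vmax: float = 300.0
    fraction: float = 0.88
    clearance: float = 0.6
    cube_edge: float = 0.5


class BipolarTherapyConfig(_Strict):
    enabled: bool = False
    step: float = 20.0
    vmax: float = 2000.0
    fraction: float = 0.88
    cube_edge: float = 0.4
    spacing: float = 0.4


class TherapiesConfig(_Strict):
    atp: AtpConfig = Field(default_factory=AtpConfig)
    transmural: ShockTherapyConfig = Field(default_factory=ShockTherapyConfig)
    bipolar: BipolarTherapyConfig = Field(default_factory=BipolarTherapyConfig)


class AnalysisConfig(_Strict):
    window_factor: float = 3.0
    capacitance: float = 1.0e-4


class ExperimentConfig(_Strict):
    """Full experiment description (geometry -> library -> therapy matrix)."""

    seed: int = 0
    outdir: str = "results/run"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    models: ModelsConfig = Field(default_factory=ModelsConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    induction: InductionConfig = Field(default_factory=InductionConfig)
    library: LibraryConfig = Field(default_factory=LibraryConfig)
    therapies: TherapiesConfig = Field(default_factory=TherapiesConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    def stage_seed(self, stage: str) -> int:
        """Counter-based per-stage seed derived from the global seed."""
        stages = ["geometry", "induction", "library", "therapy", "analysis"]
        return (self.seed * 1000 + stages.index(stage)) % (2**31 - 1)


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config (unknown keys rejected,
    before any compute)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ExperimentConfig.model_validate(raw)
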