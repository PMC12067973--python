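"""Configuration schema: one YAML file + one seed defines every output.

The schema mirrors the simulation layers: [beam], [pulse], [roi] for the
closed-form beam arithmetic, [track] for the spur surrogate, [diffusion]
and [chemistry] for the SBS engine, [stepper] for the adaptive stepper
and [experiment] for repeat counts and recording.  Unknown keys are
rejected and validation errors name the offending key (pydantic).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .beam import BeamSpotPattern, PulseStructure, ROIGeometry
from .chemistry import (DEFAULT_REACTIONS, DiffusionCoefficients,
                        ReactionTable, StepperSettings)
from .experiments import ExperimentSettings
from .species import LABEL_TO_SPECIES, SPECIES_LABELS, SpeciesKind
from .track import DEFAULT_INITIAL_G, LETTable, TrackParameters

SCHEMA_VERSION = 1


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BeamConfig(_Section):
    sigma_mm: float = Field(3.0, gt=0)
    spot_separation_mm: float = Field(5.0, ge=0)
    spill_charge_nc: float = Field(4.96, gt=0)
    uhdr_dose_rate_gy_s: float = Field(726.3, gt=0)
    cdr_dose_rate_gy_s: float = Field(1.0, gt=0)


class PulseConfig(_Section):
    pulse_width_uhdr_ms: float = Field(50.0, gt=0)
    micropulse_width_ns: float = Field(24.0, gt=0)
    micropulse_period_ns: float = Field(143.0, gt=0)
    interpulse_delay_s: float = Field(2.0, gt=0)
    cdr_pulse_width_max_s: float = Field(8.0, gt=0)


class ROIConfig(_Section):
    face_side_um: float = Field(50.0, gt=0)
    depth_um: float = Field(20.0, gt=0)


def _default_yields() -> dict[str, float]:
    return {SPECIES_LABELS[k]: v for k, v in DEFAULT_INITIAL_G.items()}


class TrackConfig(_Section):
    w_ev: float = Field(TrackParameters().mean_energy_per_event_ev, gt=0)
    spur_sigma_nm: float = Field(TrackParameters().spur_sigma_base_nm, gt=0)
    electron_spread_scale: float = Field(
        TrackParameters().electron_spread_scale, ge=0)
    electron_thermalization_factor: float = Field(
        TrackParameters().electron_thermalization_factor, ge=1)
    cross_section_scale: float = Field(1.0, gt=0)
    species_yield_targets: dict[str, float] = Field(
        default_factory=_default_yields)


def _default_diffusion() -> dict[str, float]:
    from .chemistry import DEFAULT_DIFFUSION_NM2_S
    return {SPECIES_LABELS[k]: v for k, v in DEFAULT_DIFFUSION_NM2_S.items()}


class ReactionConfig(_Section):
    reactants: list[str]
    products: list[str]
    k_per_molar_s: float = Field(gt=0)
    radius_nm: float | None = Field(None, gt=0)


class StepperConfig(_Section):
    ladder_ps: list[float] = Field(
        default_factory=lambda: list(StepperSettings().ladder_ps))
    dt_min_ps: float = Field(0.1, gt=0)
    dt_max_ps: float = Field(1000.0, gt=0)
    record_every_ps: float = Field(2.0, gt=0)
    neighbor_mode: str = "tree"


class ExperimentConfig(_Section):
    repeats: int = Field(100, ge=1)
    repeats_low_energy: int = Field(20, ge=1)
    t_chem_us: float = Field(1.0, gt=0)
    record_log_points: int | None = Field(400, ge=2)
    round_protons: bool = True


class SimulationConfig(_Section):
    """Top-level validated configuration; round-trips losslessly."""

    schema_version: int = SCHEMA_VERSION
    master_seed: int = Field(0, ge=0, lt=2 ** 31)
    beam: BeamConfig = Field(default_factory=BeamConfig)
    pulse: PulseConfig = Field(default_factory=PulseConfig)
    roi: ROIConfig = Field(default_factory=ROIConfig)
    track: TrackConfig = Field(default_factory=TrackConfig)
    diffusion: dict[str, float] = Field(default_factory=_default_diffusion)
    chemistry: list[ReactionConfig] | None = None
    stepper: StepperConfig = Field(default_factory=StepperConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)

    # -- conversion to domain objects -------------------------------------

    def to_pattern(self) -> BeamSpotPattern:
        return BeamSpotPattern(**self.beam.model_dump())

    def to_pulse(self) -> PulseStructure:
        return PulseStructure(**self.pulse.model_dump())

    def to_roi(self) -> ROIGeometry:
        return ROIGeometry(**self.roi.model_dump())

    def to_track_params(self) -> TrackParameters:
        yields = {LABEL_TO_SPECIES[k]: v
                  for k, v in self.track.species_yield_targets.items()}
        full = {k: float(yields.get(k, 0.0)) for k in SpeciesKind}
        return TrackParameters(
            mean_energy_per_event_ev=self.track.w_ev,
            spur_sigma_base_nm=self.track.spur_sigma_nm,
            electron_spread_scale=self.track.electron_spread_scale,
            electron_thermalization_factor=(
                self.track.electron_thermalization_factor),
            initial_g_values=full,
            cross_section_scale=self.track.cross_section_scale)

    def to_diffusion(self) -> DiffusionCoefficients:
        return DiffusionCoefficients({LABEL_TO_SPECIES[k]: v
                                      for k, v in self.diffusion.items()})

    def to_reaction_table(self) -> ReactionTable:
        diffusion = self.to_diffusion()
        if self.chemistry is None:
            return ReactionTable.default(diffusion)
        reactions = []
        overrides = {}
        for rc in self.chemistry:
            reactants = tuple(LABEL_TO_SPECIES[r] for r in rc.reactants)
            products = tuple(LABEL_TO_SPECIES[p] for p in rc.products)
            reactions.append((reactants, products, rc.k_per_molar_s))
            if rc.radius_nm is not None:
                overrides[reactants] = rc.radius_nm
        return ReactionTable.default(diffusion, reactions=tuple(reactions),
                                     radius_overrides=overrides or None)

    def to_stepper(self) -> StepperSettings:
        s = self.stepper
        return StepperSettings(ladder_ps=tuple(s.ladder_ps),
                               dt_min_ps=s.dt_min_ps, dt_max_ps=s.dt_max_ps,
                               record_every_ps=s.record_every_ps,
                               neighbor_mode=s.neighbor_mode)

    def to_experiment_settings(self) -> ExperimentSettings:
        return ExperimentSettings(
            roi=self.to_roi(), pulse=self.to_pulse(),
            track=self.to_track_params(), diffusion=self.to_diffusion(),
            stepper=self.to_stepper(), let_table=LETTable(),
            record_log_points=self.experiment.record_log_points,
            record_every_ps=self.stepper.record_every_ps,
            round_protons=self.experiment.round_protons)

    # -- serialisation ------------------------------------------------------

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                             sort_keys=False))


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration; defaults fill gaps."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if data is None:
        data = {}
    return SimulationConfig.model_validate(data)
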