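"""Validated run configuration.

One nested pydantic model mirrors every tunable of the pipeline; unknown
keys are rejected, every stochastic operation's seed is explicit, and the
resolved (defaulted) configuration can be echoed to YAML for provenance.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field
import yaml

from . import geometry, spectrum as spectrum_mod

__all__ = ["RunConfig", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SourceConfig(_Strict):
    focal_spot_width_mm: float = Field(0.4, ge=0)
    focal_spot_profile: str = "uniform"
    anode_angle_deg: float = Field(10.0, gt=0, lt=90)
    tube_potential_kv: float = Field(160.0, gt=0)
    line_focus: bool = True

    def to_model(self) -> geometry.SourceModel:
        return geometry.SourceModel(
            focal_spot_width=self.focal_spot_width_mm,
            focal_spot_profile=self.focal_spot_profile,
            anode_angle=self.anode_angle_deg,
            tube_potential=self.tube_potential_kv,
            line_focus=self.line_focus,
        )


class CollimatorConfig(_Strict):
    n_slits: int = 49
    slit_width_um: float = Field(50.0, gt=0)
    pitch_exit_um: float = Field(400.0, gt=0)
    slit_length_mm: float = Field(20.0, gt=0)
    thickness_mm: float = Field(5.0, gt=0)
    material: str = "W"
    source_to_entrance_mm: float = Field(70.0, gt=0)

    def to_spec(self) -> geometry.CollimatorSpec:
        return geometry.CollimatorSpec(
            n_slits=self.n_slits,
            slit_width=self.slit_width_um,
            pitch_exit=self.pitch_exit_um,
            slit_length=self.slit_length_mm,
            thickness=self.thickness_mm,
            material=self.material,
            source_to_entrance=self.source_to_entrance_mm,
        )


class PhantomConfig(_Strict):
    material: str = "PMMA"
    lateral_size_mm: float = Field(100.0, gt=0)
    height_mm: float = Field(50.0, gt=0)
    standoff_mm: float = Field(0.0, ge=0)
    scoring_depths_mm: list[float] = Field(default_factory=lambda: [1.0, 5.0, 10.0])

    def to_spec(self) -> geometry.PhantomSpec:
        return geometry.PhantomSpec(
            material=self.material,
            lateral_size=self.lateral_size_mm,
            height=self.height_mm,
            standoff=self.standoff_mm,
            scoring_depths=tuple(self.scoring_depths_mm),
        )


class PerturbationConfig(_Strict):
    angle_error_sd_arcmin: float = Field(0.0, ge=0)
    spacing_error_sd_um: float = Field(0.0, ge=0)
    alternating_angle_offset_arcmin: float = Field(0.0, ge=0)
    seed: int = 0

    def to_spec(self) -> geometry.PerturbationSpec:
        return geometry.PerturbationSpec(
            angle_error_sd=self.angle_error_sd_arcmin,
            spacing_error_sd=self.spacing_error_sd_um,
            alternating_angle_offset=self.alternating_angle_offset_arcmin,
            seed=self.seed,
        )


class SpectrumConfig(_Strict):
    tube_potential_kv: float = Field(160.0, ge=40, le=200)
    filtration: list = Field(
        default_factory=lambda: [["Be", 0.8], ["Al", 1.0]]
    )
    k_line_fraction: float = Field(0.08, ge=0, le=0.3)
    # beam-quality calibration: reproduces the measured HVL 0.31 mm Cu
    inherent_tungsten_um: float = Field(
        spectrum_mod.DEFAULT_INHERENT_W_UM, ge=0
    )
    bin_width_kev: float = Field(1.0, gt=0)

    def generate(self) -> spectrum_mod.Spectrum:
        return spectrum_mod.generate_spectrum(
            tube_potential=self.tube_potential_kv,
            filtration=[(m, t) for m, t in self.filtration],
            k_line_fraction=self.k_line_fraction,
            inherent_tungsten_um=self.inherent_tungsten_um,
            bin_width=self.bin_width_kev,
        )


class TransportConfig(_Strict):
    histories: int = Field(2_000_000, ge=0)
    chunks: int = Field(10, ge=1)
    seed: int = 12345
    splitting: int = Field(4, ge=1)
    cutoff_kev: float = Field(5.0, gt=0)
    roulette_threshold: float = Field(1e-3, ge=0)
    aperture_fraction: float = Field(0.9, ge=0, le=1)
    aperture_margin_um: float = Field(40.0, ge=0)
    source_span_mm: float = Field(12.0, gt=0)
    grid_half_span_um: float = Field(11600.0, gt=0)
    grid_bin_width_um: float = Field(2.0, gt=0)
    coherent_mode: str = "sample"  # "sample" Rayleigh angles or "forward"
    heel_enabled: bool = True
    heel_production_depth_um: float = Field(3.97, ge=0)
    electron_blur_um: float = Field(6.0, ge=0)
    detector_psf_um: float = Field(0.0, ge=0)
    vacuum_mode: bool = False
    max_divergence_records: int = Field(100_000, ge=0)


class MetricsConfig(_Strict):
    expected_pitch_um: float = Field(400.0, gt=0)
    target_penumbra_um: float = Field(20.0, gt=0)


class AlignmentConfig(_Strict):
    horizontal_range_um: float = Field(300.0, gt=0)
    horizontal_step_um: float = Field(25.0, gt=0)
    vertical_range_mm: float = Field(4.0, gt=0)
    vertical_step_mm: float = Field(0.25, gt=0)
    histories_per_point: int = Field(200_000, ge=1)
    threshold: float = Field(0.95, gt=0, lt=1)
    seed: int = 54321


class RunConfig(_Strict):
    source: SourceConfig = Field(default_factory=SourceConfig)
    collimator: CollimatorConfig = Field(default_factory=CollimatorConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    perturbation: PerturbationConfig = Field(default_factory=PerturbationConfig)
    spectrum: SpectrumConfig = Field(default_factory=SpectrumConfig)
    transport: TransportConfig = Field(default_factory=TransportConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    alignment: AlignmentConfig = Field(default_factory=AlignmentConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def default_config(**overrides) -> RunConfig:
    """The canonical setup: 160 kV tube, 49-slit collimator, PMMA phantom."""
    cfg = RunConfig()
    for dotted, value in overrides.items():
        section, _, key = dotted.partition(".")
        setattr(getattr(cfg, section), key, value)
    return cfg
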