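"""Source-collimator-phantom geometry for the divergence-matched multislit
collimator.

Coordinate frame: origin at the focal-spot centre, z up along the central
beam axis, x across the slits (positive toward higher beam numbers, the
wide-penumbra field edge), y along the slits.  The collimator entrance
(beam-facing) surface sits at z = source_to_entrance; the exit (top) surface
at z = source_to_entrance + thickness.  The slit pitch is defined at the exit
surface; every slit axis, extended backwards, passes through the source
point — the divergence-matching property.  Depths are measured upward from
the collimator exit surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SourceModel",
    "CollimatorSpec",
    "SlitGeometry",
    "PhantomSpec",
    "PerturbationSpec",
    "design_collimator",
    "entrance_exit_pitch_difference",
    "perturb_collimator",
    "export_machining_spec",
    "read_machining_spec",
    "ARCMIN_PER_RAD",
]

ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi


class GeometryError(ValueError):
    """Invalid or degenerate geometry specification."""


@dataclass(frozen=True)
class SourceModel:
    """Extended focal spot of the tungsten-anode tube.

    The anode sits on the negative-x (low beam number) side: beams with small
    indices see a smaller projected focal spot and stronger heel filtration.
    """

    focal_spot_width: float = 0.4  # mm, apparent width on the central ray
    focal_spot_profile: str = "uniform"  # or "gaussian" (FWHM = width)
    source_position: tuple = (0.0, 0.0, 0.0)
    anode_angle: float = 10.0  # degrees, takeoff angle of the central ray
    tube_potential: float = 160.0  # kV
    # model the spot as the physical line focus on the tilted anode, so the
    # apparent width varies as sin(takeoff)/sin(anode_angle) across the
    # field; False collapses it to a flat spot in the source plane
    line_focus: bool = True

    def __post_init__(self):
        if self.focal_spot_width < 0:
            raise GeometryError("focal_spot_width must be >= 0")
        if self.tube_potential <= 0:
            raise GeometryError("tube_potential must be > 0")
        if self.focal_spot_profile not in ("uniform", "gaussian"):
            raise GeometryError("focal_spot_profile must be uniform|gaussian")


@dataclass(frozen=True)
class CollimatorSpec:
    """Multislit collimator plate.

    ``pitch_exit`` is the slit spacing at the exit (top) surface; the spacing
    at the beam-facing entrance surface is smaller by
    pitch_exit * thickness / (source_to_entrance + thickness).
    """

    n_slits: int = 49
    slit_width: float = 50.0  # um, perpendicular to the slit axis
    pitch_exit: float = 400.0  # um, at the exit/top surface
    slit_length: float = 20.0  # mm, along y
    thickness: float = 5.0  # mm
    material: str = "W"
    source_to_entrance: float = 70.0  # mm

    def __post_init__(self):
        if self.n_slits < 1 or self.n_slits % 2 == 0:
            raise GeometryError("n_slits must be odd (central slit untilted)")
        if self.pitch_exit <= self.slit_width:
            raise GeometryError("pitch_exit must exceed slit_width")
        if self.thickness <= 0 or self.source_to_entrance <= 0:
            raise GeometryError("thickness and source_to_entrance must be > 0")

    @property
    def source_to_exit(self) -> float:
        """Distance from the focal spot to the exit surface (mm)."""
        return self.source_to_entrance + self.thickness


@dataclass(frozen=True)
class SlitGeometry:
    """One slit of the collimator.

    ``index`` runs 1..n_slits, increasing toward +x (the wide-penumbra field
    edge); ``k`` is the signed offset from the central slit.  Lateral
    positions are in micrometres, the tilt in radians (signed, positive
    toward +x).
    """

    index: int
    k: int
    center_entrance_x: float  # um
    center_exit_x: float  # um
    tilt_angle: float  # rad

    @property
    def tilt_arcmin(self) -> float:
        return self.tilt_angle * ARCMIN_PER_RAD


@dataclass(frozen=True)
class PhantomSpec:
    """Dosimetry phantom resting on the collimator exit surface."""

    material: str = "PMMA"
    lateral_size: float = 100.0  # mm
    height: float = 50.0  # mm
    standoff: float = 0.0  # mm, collimator exit to phantom bottom
    scoring_depths: tuple = (1.0, 5.0, 10.0)  # mm above the exit surface

    def __post_init__(self):
        if self.material not in ("PMMA", "water"):
            raise GeometryError("phantom material must be PMMA or water")
        if self.height <= 0 or self.lateral_size <= 0 or self.standoff < 0:
            raise GeometryError("phantom dimensions must be positive")
        for d in self.scoring_depths:
            if not 0 < d <= self.height + self.standoff:
                raise GeometryError(
                    f"scoring depth {d} mm outside (0, height+standoff]"
                )


@dataclass(frozen=True)
class PerturbationSpec:
    """Manufacturing perturbations of the slit geometry.

    Gaussian angle/spacing errors model the quoted machining tolerances; the
    deterministic alternating angle offset models the alternating wire-cutting
    direction that produces the odd/even beam-intensity pattern.
    """

    angle_error_sd: float = 0.0  # arc min
    spacing_error_sd: float = 0.0  # um
    alternating_angle_offset: float = 0.0  # arc min, + for odd index
    seed: int = 0

    def __post_init__(self):
        if min(self.angle_error_sd, self.spacing_error_sd) < 0:
            raise GeometryError("error magnitudes must be >= 0")
        if self.alternating_angle_offset < 0:
            raise GeometryError("alternating_angle_offset must be >= 0")


def design_collimator(spec: CollimatorSpec) -> list[SlitGeometry]:
    """Compute the divergence-matched slit positions and tilt angles.

    Slit k (signed offset from the centre) has its exit centre at
    k * pitch_exit, tilt arctan(exit_x / source_to_exit), and entrance centre
    scaled back by source_to_entrance / source_to_exit, so that every slit
    axis extended downward passes through the focal-spot centre.
    """
    half = (spec.n_slits - 1) // 2
    l_exit_um = spec.source_to_exit * 1000.0
    # degenerate if the tilt step between neighbours exceeds the angular
    # acceptance of a single slit
    step = math.atan(spec.pitch_exit / l_exit_um)
    acceptance = math.atan((spec.slit_width / 1000.0) / spec.thickness)
    if step > acceptance:
        raise GeometryError(
            "adjacent-slit tilt step exceeds the slit-width acceptance; "
            "collimator is degenerate"
        )
    slits = []
    for k in range(-half, half + 1):
        exit_x = k * spec.pitch_exit
        tilt = math.atan(exit_x / l_exit_um)
        entrance_x = exit_x * spec.source_to_entrance / spec.source_to_exit
        slits.append(
            SlitGeometry(
                index=k + half + 1,
                k=k,
                center_entrance_x=entrance_x,
                center_exit_x=exit_x,
                tilt_angle=tilt,
            )
        )
    return slits


def entrance_exit_pitch_difference(spec: CollimatorSpec) -> float:
    """By how much the entrance-surface pitch is smaller than the exit pitch.

    Returns pitch_exit * thickness / (source_to_entrance + thickness) in um;
    26.67 um for the default collimator.
    """
    return spec.pitch_exit * spec.thickness / spec.source_to_exit


def perturb_collimator(
    slits: list[SlitGeometry], pert: PerturbationSpec
) -> list[SlitGeometry]:
    """Apply manufacturing perturbations; returns a new slit list.

    Gaussian tilt errors (sd in arc min) and exit-spacing errors (sd in um)
    are drawn from a generator seeded by ``pert.seed``; the alternating
    offset is added with + sign for odd, - for even slit index.  Entrance
    centres are recomputed from the perturbed exit centre and tilt so the
    slit stays straight.  With all amplitudes zero the input geometry is
    returned bitwise-identical.
    """
    if (
        pert.angle_error_sd == 0
        and pert.spacing_error_sd == 0
        and pert.alternating_angle_offset == 0
    ):
        return [replace(s) for s in slits]
    rng = np.random.default_rng(pert.seed)
    d_tilt = rng.normal(0.0, pert.angle_error_sd, len(slits)) / ARCMIN_PER_RAD
    d_x = rng.normal(0.0, pert.spacing_error_sd, len(slits))
    alt = pert.alternating_angle_offset / ARCMIN_PER_RAD
    dz_um = _dz_of(slits)
    out = []
    for s, dt, dx in zip(slits, d_tilt, d_x):
        tilt = s.tilt_angle + dt + (alt if s.index % 2 == 1 else -alt)
        exit_x = s.center_exit_x + dx
        out.append(
            replace(
                s,
                tilt_angle=tilt,
                center_exit_x=exit_x,
                center_entrance_x=exit_x - dz_um * math.tan(tilt),
            )
        )
    return out


def _dz_of(slits: list[SlitGeometry]) -> float:
    """Plate thickness in um implied by the unperturbed slit list."""
    for s in slits:
        if s.tilt_angle != 0:
            return (s.center_exit_x - s.center_entrance_x) / math.tan(
                s.tilt_angle
            )
    return 5000.0  # single untilted slit: fall back to the default plate


def export_machining_spec(slits: list[SlitGeometry], path) -> None:
    """Write the machining table: index, entrance x, exit x, tilt (arc min).

    Comma-separated, header row, '.' decimal separator; values rounded to
    0.001 um / 0.001 arc min so a round trip is exact to the stated
    0.01 um / 0.01 arc min.
    """
    df = pd.DataFrame(
        {
            "index": [s.index for s in slits],
            "entrance_x_um": [s.center_entrance_x for s in slits],
            "exit_x_um": [s.center_exit_x for s in slits],
            "tilt_arcmin": [s.tilt_arcmin for s in slits],
        }
    )
    try:
        df.to_csv(path, index=False, float_format="%.3f")
    except OSError as exc:
        raise IOError(f"cannot write machining spec to {path}: {exc}") from exc


def read_machining_spec(path) -> list[SlitGeometry]:
    """Read a machining table written by :func:`export_machining_spec`."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise IOError(f"cannot read machining spec from {path}: {exc}") from exc
    required = {"index", "entrance_x_um", "exit_x_um", "tilt_arcmin"}
    if not required.issubset(df.columns):
        raise GeometryError(f"machining spec missing columns {required}")
    half = (len(df) - 1) // 2
    return [
        SlitGeometry(
            index=int(r["index"]),
            k=int(r["index"]) - half - 1,
            center_entrance_x=float(r["entrance_x_um"]),
            center_exit_x=float(r["exit_x_um"]),
            tilt_angle=float(r["tilt_arcmin"]) / ARCMIN_PER_RAD,
        )
        for _, r in df.iterrows()
    ]
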