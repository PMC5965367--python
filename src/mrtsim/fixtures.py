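"""Synthetic microbeam profile generator with exactly known ground truth.

Builds piecewise-linear trapezoidal microbeam trains on a uniform grid:
each beam rises linearly from zero over ``flank_width``, holds a plateau,
and falls symmetrically; the valley floor is a pedestal that may taper
linearly toward the high-beam-number edge.  Because the construction is
closed-form, every metric (PVDR, penumbra, edge ratio, alternation index)
is known exactly and recorded in the profile metadata, which makes the
metrics layer testable without any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import LateralProfile

__all__ = ["SyntheticProfileSpec", "generate_fixture"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticProfileSpec:
    n_beams: int = 49
    pitch: float = 400.0  # um
    peak_dose: float = 3.0
    valley_dose: float = 0.1
    flank_width: float = 25.0  # um, linear rise 0 -> peak
    plateau_width: float = 30.0  # um
    valley_edge_taper: float = 0.0  # fractional drop of the pedestal at +edge
    odd_even_alternation: float = 0.0  # odd beams scaled by (1 + f)
    noise_sd: float = 0.0  # gaussian noise, fraction of peak dose
    seed: int = 0
    spacing: float = 2.0  # um, sample spacing
    margin: float = 400.0  # um beyond the outer beams

    def __post_init__(self):
        if not self.peak_dose > self.valley_dose > 0:
            raise FixtureError("need peak > valley > 0")
        if self.plateau_width < 10.0:
            raise FixtureError("plateau must be >= 10 um (peak window)")
        flat = self.pitch - self.plateau_width - 2 * self.flank_width
        if flat < 140.0:
            raise FixtureError(
                "flat trough region must be >= 140 um (valley window); "
                f"got {flat:.0f} um"
            )
        if not 0 <= self.valley_edge_taper < 1:
            raise FixtureError("valley_edge_taper must be in [0, 1)")

    @property
    def penumbra_truth(self) -> float:
        """Exact 10-90% width of a linear flank from 0 to the peak dose."""
        return 0.8 * self.flank_width

    @property
    def pvdr_truth(self) -> float:
        return self.peak_dose / self.valley_dose


def generate_fixture(spec: SyntheticProfileSpec) -> LateralProfile:
    """Deterministic synthetic microbeam train with embedded ground truth."""
    half = (spec.n_beams - 1) / 2.0 * spec.pitch
    x = np.arange(-half - spec.margin, half + spec.margin + spec.spacing / 2,
                  spec.spacing)
    centers = (np.arange(spec.n_beams) - (spec.n_beams - 1) / 2.0) * spec.pitch

    dose = np.zeros_like(x)
    ramp_out = spec.plateau_width / 2.0 + spec.flank_width
    for i, c in enumerate(centers):
        amp = spec.peak_dose * (
            1.0 + (spec.odd_even_alternation if (i + 1) % 2 == 1 else 0.0)
        )
        r = np.abs(x - c)
        tri = np.clip((ramp_out - r) / spec.flank_width, 0.0, 1.0)
        dose = np.maximum(dose, amp * tri)

    # valley pedestal, optionally tapering toward the +x (high index) edge;
    # the taper is linear between the second and second-to-last beam centre,
    # so the interior-beam valley (mean of the two adjacent troughs) equals
    # the pedestal at the beam centre and the edge ratio is exactly 1-taper
    pedestal = np.full_like(x, spec.valley_dose)
    if spec.valley_edge_taper > 0:
        if spec.n_beams < 4:
            raise FixtureError("valley taper needs at least 4 beams")
        t = (x - centers[1]) / (centers[-2] - centers[1])  # unclipped
        pedestal = np.maximum(
            spec.valley_dose * (1.0 - spec.valley_edge_taper * t), 0.0
        )
    dose = np.maximum(dose, pedestal)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dose = np.maximum(
            dose + rng.normal(0.0, spec.noise_sd * spec.peak_dose, len(x)),
            0.0,
        )

    odd_amp = 1.0 + spec.odd_even_alternation
    n_odd = (spec.n_beams + 1) // 2
    n_even = spec.n_beams - n_odd
    mean_amp = (n_odd * odd_amp + n_even) / spec.n_beams
    truth = {
        "pvdr": spec.pvdr_truth,
        "peak_dose": spec.peak_dose,
        "valley_dose": spec.valley_dose,
        "penumbra_um": spec.penumbra_truth,
        "edge_ratio_high": 1.0 - spec.valley_edge_taper,
        "alternation_index": abs(odd_amp - 1.0) / mean_amp
        if n_even else 0.0,
    }
    return LateralProfile(
        positions=x,
        dose=dose,
        uncertainty=None,
        depth=0.0,
        metadata={"provenance": "synthetic", "ground_truth": truth,
                  "spec": spec.__dict__.copy()},
    )
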