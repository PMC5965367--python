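"""Filtered x-ray tube spectrum model and beam-quality services.

The bremsstrahlung continuum uses the Kramers thin-target form
N(E) dE ∝ (E_max - E)/E, hardened by an inherent tungsten self-filtration
term (anode self-absorption, the main deviation of real tube spectra from
the Kramers form) plus the explicit filtration stack.  Tungsten K
characteristic lines are added when the tube potential exceeds the W K edge.
The inherent-tungsten thickness is the beam-quality calibration parameter:
its default is set so that the default 160 kV / 0.8 mm Be / 1 mm Al beam has
a first half-value layer of 0.31 mm Cu, the measured beam quality of the
modelled tube; the value lives in the configuration, not in the physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .materials import get_material

__all__ = [
    "Spectrum",
    "generate_spectrum",
    "half_value_layer",
    "transmission",
    "sample_energy",
    "W_K_EDGE_KEV",
    "W_K_LINES",
    "DEFAULT_FILTRATION",
    "DEFAULT_INHERENT_W_UM",
]

W_K_EDGE_KEV = 69.525
# line energy (keV), relative intensity within the K series
W_K_LINES = ((59.32, 0.46), (57.98, 0.27), (67.24, 0.20), (69.10, 0.07))
DEFAULT_FILTRATION = (("Be", 0.8), ("Al", 1.0))
# beam-quality calibration: inherent W self-filtration reproducing the
# measured HVL of 0.31 mm Cu for the default tube settings; equivalent to a
# ~8 um mean bremsstrahlung production depth seen through a 20 deg target
DEFAULT_INHERENT_W_UM = 22.5


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """Binned photon-energy fluence distribution.

    ``energies`` are 1 keV bin centres (or finer if configured); ``fluence``
    is the relative photon fluence per bin, normalised to unit sum.
    """

    energies: np.ndarray  # keV, bin centres, ascending
    fluence: np.ndarray  # relative photons per bin
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.energies.shape != self.fluence.shape:
            raise SpectrumError("energies and fluence must have equal shape")
        if np.any(self.fluence < 0):
            raise SpectrumError("fluence must be >= 0 everywhere")
        if not np.any(self.fluence > 0):
            raise SpectrumError("at least one bin must be positive")
        kvp = self.metadata.get("tube_potential")
        if kvp is not None and np.any(
            self.fluence[self.energies > kvp] > 0
        ):
            raise SpectrumError("fluence above the tube potential must be 0")

    def normalized(self) -> "Spectrum":
        return Spectrum(
            self.energies, self.fluence / self.fluence.sum(), dict(self.metadata)
        )

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy (keV)."""
        return float(
            np.sum(self.energies * self.fluence) / np.sum(self.fluence)
        )

    def attenuated(self, material: str, thickness_mm: float) -> "Spectrum":
        """Spectrum after an additional filtration layer (not renormalised)."""
        mat = get_material(material)
        f = self.fluence * mat.transmission(thickness_mm, self.energies)
        meta = dict(self.metadata)
        meta.setdefault("filtration", [])
        meta["filtration"] = list(meta["filtration"]) + [
            (material, thickness_mm)
        ]
        return Spectrum(self.energies, f, meta)

    def air_kerma(self, per_bin: bool = False):
        """Relative air kerma: fluence * E * (mu_en/rho)_air per bin."""
        k = self.fluence * self.energies * get_material("air").mu_en_rho(
            self.energies
        )
        return k if per_bin else float(k.sum())

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        from .io import write_columns

        write_columns(
            path,
            {"energy_kev": self.energies, "fluence": self.fluence},
            self.metadata,
        )

    @classmethod
    def load(cls, path) -> "Spectrum":
        from .io import read_columns

        df, meta = read_columns(path)
        return cls(df["energy_kev"].to_numpy(), df["fluence"].to_numpy(), meta)


def generate_spectrum(
    tube_potential: float = 160.0,
    filtration=DEFAULT_FILTRATION,
    k_line_fraction: float = 0.08,
    inherent_tungsten_um: float = DEFAULT_INHERENT_W_UM,
    bin_width: float = 1.0,
) -> Spectrum:
    """Generate the filtered tube spectrum.

    Parameters
    ----------
    tube_potential : anode voltage in kV, within [40, 200].
    filtration : iterable of (material id, thickness in mm).
    k_line_fraction : fraction of the unfiltered fluence carried by the W K
        lines (only when the potential exceeds the K edge at 69.5 keV).
    inherent_tungsten_um : anode self-filtration in um of tungsten; the
        beam-quality calibration parameter.
    bin_width : energy bin width in keV (1 keV default).
    """
    if not 40.0 <= tube_potential <= 200.0:
        raise SpectrumError("tube potential must be within [40, 200] kV")
    for m, t in filtration:
        get_material(m)
        if t < 0:
            raise SpectrumError("filtration thickness must be >= 0")
    if inherent_tungsten_um < 0:
        raise SpectrumError("inherent tungsten filtration must be >= 0")

    edges = np.arange(1.0, tube_potential + bin_width * 0.5, bin_width)
    e = edges[:-1] + bin_width / 2.0
    fl = np.maximum(tube_potential - e, 0.0) / e  # Kramers form

    if tube_potential > W_K_EDGE_KEV and k_line_fraction > 0:
        total = fl.sum()
        for line_e, rel in W_K_LINES:
            i = int(np.clip((line_e - edges[0]) // bin_width, 0, len(e) - 1))
            fl[i] += k_line_fraction * rel * total

    stack = [("W", inherent_tungsten_um / 1000.0)] + list(filtration)
    for m, t in stack:
        fl = fl * get_material(m).transmission(t, e)

    meta = {
        "tube_potential": tube_potential,
        "filtration": [(m, t) for m, t in filtration],
        "inherent_tungsten_um": inherent_tungsten_um,
        "k_line_fraction": k_line_fraction,
        "bin_width": bin_width,
    }
    return Spectrum(e, fl, meta).normalized()


def transmission(material: str, thickness_mm: float, energy_kev):
    """Narrow-beam transmission exp(-(mu/rho) rho t); vectorises over energy."""
    return get_material(material).transmission(thickness_mm, energy_kev)


def half_value_layer(
    spec: Spectrum, material: str = "Cu", which: int = 1, tol_mm: float = 1e-4
) -> float:
    """Absorber thickness halving the air kerma of the beam (mm).

    ``which=2`` returns the second HVL (thickness taking the kerma from 1/2
    to 1/4 of its initial value).  Solved by a bracketing root finder on the
    air-kerma-weighted transmission.
    """
    mat = get_material(material)
    k_bin = spec.air_kerma(per_bin=True)
    k0 = k_bin.sum()
    if k0 <= 0:
        raise SpectrumError("spectrum carries no air kerma")
    mu = mat.mu_mm(spec.energies)
    target = k0 / 2.0**which

    def kerma(t):
        return float(np.sum(k_bin * np.exp(-mu * t)))

    if kerma(100.0) > target:
        raise SpectrumError(
            "attenuation cannot reach the target kerma within 100 mm"
        )
    t_hi = brentq(lambda t: kerma(t) - target, 0.0, 100.0, xtol=tol_mm)
    if which == 1:
        return float(t_hi)
    t_lo = brentq(lambda t: kerma(t) - k0 / 2.0, 0.0, 100.0, xtol=tol_mm)
    return float(t_hi - t_lo)


def sample_energy(spec: Spectrum, rng: np.random.Generator, n: int = 1):
    """Draw photon energies from the spectrum by inverse-CDF bin sampling."""
    total = spec.fluence.sum()
    if not np.isfinite(total) or total <= 0:
        raise SpectrumError("spectrum is not normalizable")
    cdf = np.cumsum(spec.fluence) / total
    idx = np.searchsorted(cdf, rng.random(n), side="left")
    return spec.energies[np.minimum(idx, len(cdf) - 1)]
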