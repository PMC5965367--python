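"""Photon interaction data for the materials of the microbeam setup.

Mass attenuation coefficients (and, for dosimetry media, mass energy-absorption
coefficients) are embedded as static tables over 1-200 keV, compiled from the
standard public NIST/XCOM compilations, and interpolated log-log.  Absorption
edges (Cu K, W L/K) are represented by duplicated energy nodes so that the
interpolation never bridges an edge.

For the phantom media the interaction-type split used by the Monte Carlo is
photoelectric / incoherent / coherent.  The incoherent component is the
free-electron Klein-Nishina cross section times the electron density (binding
corrections are negligible above ~20 keV, where nearly all phantom
interactions occur); the coherent component is tabulated; the photoelectric
component is taken as total minus the other two so the total attenuation
always matches the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "get_material",
    "MATERIALS",
    "klein_nishina_total",
    "klein_nishina_mean_scattered_fraction",
]

# classical electron radius^2 * pi, in barn (1 barn = 1e-24 cm^2)
_RE2_PI_BARN = np.pi * (2.8179403262e-13) ** 2 * 1e24
ELECTRON_REST_KEV = 510.99895
AVOGADRO = 6.02214076e23


def klein_nishina_total(energy_kev):
    """Total Klein-Nishina cross section per electron in barn.

    Closed form for a free electron at rest; valid at all energies.
    """
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * _RE2_PI_BARN * (t1 + t2 + t3)


def klein_nishina_mean_scattered_fraction(energy_kev, n_quad=4096):
    """Mean scattered-photon energy fraction <E'/E> for Compton scattering.

    Computed by numerical quadrature of the Klein-Nishina differential cross
    section over scattering angle; serves as the independent oracle for the
    transport module's Compton sampler.
    """
    k = float(energy_kev) / ELECTRON_REST_KEV
    mu = np.linspace(-1.0, 1.0, n_quad)
    eps = 1.0 / (1.0 + k * (1.0 - mu))  # E'/E
    dsig = eps**2 * (eps + 1.0 / eps - (1.0 - mu**2))
    return np.trapezoid(dsig * eps, mu) / np.trapezoid(dsig, mu)


@dataclass(frozen=True)
class Material:
    """Interaction data for one medium.

    Energies in keV, mass coefficients in cm^2/g, density in g/cm^3.
    ``mu_en_rho_table`` and ``coherent_table`` are present only where the
    transport/dosimetry layer needs them.
    """

    name: str
    density: float  # g/cm^3
    z_over_a: float  # mean Z/A (electrons per u)
    energies: np.ndarray  # keV, ascending, duplicated at edges
    mu_rho_table: np.ndarray  # total mass attenuation with coherent, cm^2/g
    mu_en_rho_table: np.ndarray | None = None
    coherent_energies: np.ndarray | None = None
    coherent_table: np.ndarray | None = None
    _log_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def _loglog(self, key, xs, ys, energy):
        try:
            lx, ly = self._log_cache[key]
        except KeyError:
            # nudge duplicated edge nodes apart so log-interp is well defined
            x = np.array(xs, dtype=float)
            for i in range(1, len(x)):
                if x[i] <= x[i - 1]:
                    x[i] = x[i - 1] * (1 + 1e-9)
            lx, ly = np.log(x), np.log(ys)
            self._log_cache[key] = (lx, ly)
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energies[0] - 1e-9) or np.any(e > self.energies[-1] + 1e-9):
            raise ValueError(
                f"energy outside {self.name} table range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV"
            )
        return np.exp(np.interp(np.log(e), lx, ly))

    # -- mass coefficients ------------------------------------------------
    def mu_rho(self, energy_kev):
        """Total mass attenuation coefficient mu/rho (cm^2/g)."""
        return self._loglog("mu", self.energies, self.mu_rho_table, energy_kev)

    def mu_en_rho(self, energy_kev):
        """Mass energy-absorption coefficient mu_en/rho (cm^2/g)."""
        if self.mu_en_rho_table is None:
            raise ValueError(f"no mu_en/rho table for {self.name}")
        return self._loglog("muen", self.energies, self.mu_en_rho_table, energy_kev)

    def mu_rho_incoherent(self, energy_kev):
        """Incoherent (Compton) mass attenuation, free-electron KN (cm^2/g)."""
        sigma = klein_nishina_total(energy_kev) * 1e-24  # cm^2/electron
        return sigma * self.z_over_a * AVOGADRO

    def mu_rho_coherent(self, energy_kev):
        """Coherent (Rayleigh) mass attenuation (cm^2/g)."""
        if self.coherent_table is None:
            raise ValueError(f"no coherent table for {self.name}")
        return self._loglog(
            "coh", self.coherent_energies, self.coherent_table, energy_kev
        )

    def mu_rho_photoelectric(self, energy_kev):
        """Photoelectric mass attenuation = total - incoherent - coherent."""
        pe = (
            self.mu_rho(energy_kev)
            - self.mu_rho_incoherent(energy_kev)
            - self.mu_rho_coherent(energy_kev)
        )
        return np.maximum(pe, 1e-8)

    def partials(self, energy_kev):
        """(photoelectric, incoherent, coherent) mu/rho, renormalised so the
        three components sum exactly to the tabulated total.

        The free-electron Klein-Nishina incoherent term can exceed
        total - coherent by a percent or two at the top of the table; the
        common rescale keeps the interaction mix physical and the total
        attenuation exact.
        """
        tot = self.mu_rho(energy_kev)
        pe = self.mu_rho_photoelectric(energy_kev)
        inc = self.mu_rho_incoherent(energy_kev)
        coh = self.mu_rho_coherent(energy_kev)
        scale = tot / (pe + inc + coh)
        return pe * scale, inc * scale, coh * scale

    # -- linear coefficients ----------------------------------------------
    def mu_mm(self, energy_kev):
        """Linear attenuation coefficient in 1/mm."""
        return self.mu_rho(energy_kev) * self.density / 10.0

    def transmission(self, thickness_mm, energy_kev):
        """Narrow-beam transmission through ``thickness_mm`` of material."""
        t = float(thickness_mm)
        if t < 0:
            raise ValueError("thickness must be >= 0")
        return np.exp(-self.mu_mm(energy_kev) * t)


# ---------------------------------------------------------------------------
# Embedded tables (NIST standard grid; energies keV, coefficients cm^2/g).
# Duplicated nodes mark absorption edges.
# ---------------------------------------------------------------------------

def _m(*rows):
    a = np.array(rows, dtype=float)
    return a[:, 0], a[:, 1:]


_E_W, _T_W = _m(
    # E, mu/rho        (W, Z=74; M/L edge fine structure smoothed below
    # 12 keV — those photons never survive the Be/Al stack; K edge 69.525)
    [1.0, 3683.0],
    [2.0, 3000.0],
    [3.0, 1650.0],
    [4.0, 1020.0],
    [5.0, 570.0],
    [6.0, 355.0],
    [8.0, 168.0],
    [10.0, 96.91],
    [10.2, 92.0],
    [10.2, 230.0],
    [12.0, 215.0],
    [15.0, 139.3],
    [20.0, 65.73],
    [30.0, 22.73],
    [40.0, 10.67],
    [50.0, 5.949],
    [60.0, 3.713],
    [69.525, 2.573],
    [69.525, 11.23],
    [80.0, 7.810],
    [100.0, 4.438],
    [150.0, 1.581],
    [200.0, 0.7844],
)

_E_CU, _T_CU = _m(
    [1.0, 10570.0],
    [2.0, 2154.0],
    [3.0, 748.8],
    [4.0, 347.3],
    [5.0, 189.9],
    [6.0, 118.3],
    [8.0, 52.55],
    [8.979, 38.29],
    [8.979, 278.4],
    [10.0, 215.9],
    [15.0, 74.05],
    [20.0, 33.79],
    [30.0, 10.92],
    [40.0, 4.862],
    [50.0, 2.613],
    [60.0, 1.593],
    [80.0, 0.7630],
    [100.0, 0.4584],
    [150.0, 0.2217],
    [200.0, 0.1559],
)

_E_BE, _T_BE = _m(
    [1.0, 604.1],
    [1.5, 179.7],
    [2.0, 74.69],
    [3.0, 21.27],
    [4.0, 8.685],
    [5.0, 4.369],
    [6.0, 2.527],
    [8.0, 1.124],
    [10.0, 0.6466],
    [15.0, 0.3070],
    [20.0, 0.2251],
    [30.0, 0.1792],
    [40.0, 0.1640],
    [50.0, 0.1554],
    [60.0, 0.1493],
    [80.0, 0.1401],
    [100.0, 0.1328],
    [150.0, 0.1190],
    [200.0, 0.1089],
)

_E_AL, _T_AL = _m(
    [1.0, 1185.0],
    [1.5, 402.2],
    [1.5596, 362.1],
    [1.5596, 3957.0],
    [2.0, 2263.0],
    [3.0, 788.0],
    [4.0, 360.5],
    [5.0, 193.4],
    [6.0, 115.3],
    [8.0, 50.33],
    [10.0, 26.23],
    [15.0, 7.955],
    [20.0, 3.441],
    [30.0, 1.128],
    [40.0, 0.5685],
    [50.0, 0.3681],
    [60.0, 0.2778],
    [80.0, 0.2018],
    [100.0, 0.1704],
    [150.0, 0.1378],
    [200.0, 0.1223],
)

# water: columns mu/rho, mu_en/rho
_E_H2O, _T_H2O = _m(
    [1.0, 4078.0, 4065.0],
    [1.5, 1376.0, 1372.0],
    [2.0, 617.3, 615.2],
    [3.0, 192.9, 191.7],
    [4.0, 82.78, 81.91],
    [5.0, 42.58, 41.88],
    [6.0, 24.64, 23.91],
    [8.0, 10.37, 9.919],
    [10.0, 5.329, 4.944],
    [15.0, 1.673, 1.374],
    [20.0, 0.8096, 0.5503],
    [30.0, 0.3756, 0.1557],
    [40.0, 0.2683, 0.06947],
    [50.0, 0.2269, 0.04223],
    [60.0, 0.2059, 0.03190],
    [80.0, 0.1837, 0.02597],
    [100.0, 0.1707, 0.02546],
    [150.0, 0.1505, 0.02764],
    [200.0, 0.1370, 0.02967],
)

_E_PMMA, _T_PMMA = _m(
    [1.0, 2794.0, 2788.0],
    [1.5, 913.1, 921.0],
    [2.0, 408.8, 406.0],
    [3.0, 127.5, 126.2],
    [4.0, 53.88, 52.90],
    [5.0, 27.51, 26.80],
    [6.0, 16.01, 15.47],
    [8.0, 6.494, 6.191],
    [10.0, 3.357, 3.026],
    [15.0, 1.101, 0.8324],
    [20.0, 0.5714, 0.3328],
    [30.0, 0.3032, 0.09645],
    [40.0, 0.2350, 0.04599],
    [50.0, 0.2074, 0.03067],
    [60.0, 0.1924, 0.02530],
    [80.0, 0.1751, 0.02302],
    [100.0, 0.1641, 0.02368],
    [150.0, 0.1456, 0.02657],
    [200.0, 0.1328, 0.02872],
)

_E_AIR, _T_AIR = _m(
    [1.0, 3606.0, 3599.0],
    [1.5, 1191.0, 1188.0],
    [2.0, 527.9, 526.2],
    [3.0, 162.5, 161.4],
    [4.0, 77.88, 76.36],
    [5.0, 40.27, 39.31],
    [6.0, 23.41, 22.70],
    [8.0, 9.921, 9.446],
    [10.0, 5.120, 4.742],
    [15.0, 1.614, 1.334],
    [20.0, 0.7779, 0.5389],
    [30.0, 0.3538, 0.1537],
    [40.0, 0.2485, 0.06833],
    [50.0, 0.2080, 0.04098],
    [60.0, 0.1875, 0.03041],
    [80.0, 0.1662, 0.02407],
    [100.0, 0.1541, 0.02325],
    [150.0, 0.1356, 0.02496],
    [200.0, 0.1233, 0.02672],
)

# coherent (Rayleigh) mass attenuation for the dosimetry media, cm^2/g
_COH_E = np.array([1, 2, 5, 10, 15, 20, 30, 40, 50, 60, 80, 100, 150, 200.0])
_COH_H2O = np.array(
    [1.37, 0.62, 0.39, 0.18, 0.105, 0.070, 0.0385, 0.0245, 0.0171, 0.0127,
     0.0077, 0.0052, 0.0026, 0.0016]
)
_COH_PMMA = _COH_H2O * 0.78
_COH_AIR = _COH_H2O * 0.92


MATERIALS = {
    "W": Material("W", 19.30, 0.40250, _E_W, _T_W[:, 0]),
    "Cu": Material("Cu", 8.960, 0.45636, _E_CU, _T_CU[:, 0]),
    "Be": Material("Be", 1.848, 0.44384, _E_BE, _T_BE[:, 0]),
    "Al": Material("Al", 2.699, 0.48181, _E_AL, _T_AL[:, 0]),
    "water": Material(
        "water", 1.000, 0.55509, _E_H2O, _T_H2O[:, 0], _T_H2O[:, 1],
        _COH_E, _COH_H2O,
    ),
    "PMMA": Material(
        "PMMA", 1.190, 0.53937, _E_PMMA, _T_PMMA[:, 0], _T_PMMA[:, 1],
        _COH_E, _COH_PMMA,
    ),
    "air": Material(
        "air", 1.205e-3, 0.49919, _E_AIR, _T_AIR[:, 0], _T_AIR[:, 1],
        _COH_E, _COH_AIR,
    ),
}


# ---------------------------------------------------------------------------
# Rayleigh (coherent) angular distribution: independent-atom form factors
# F(x, Z) vs momentum transfer x = sin(theta/2)/lambda in 1/Angstrom.
# ---------------------------------------------------------------------------

_FF_X = np.array(
    [0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.5, 2.0,
     3.0, 5.0, 8.0]
)
_FF = {
    "H": np.array([1.0, 0.95, 0.81, 0.64, 0.48, 0.25, 0.13, 0.071, 0.040,
                   0.015, 0.007, 0.0014, 0.0004, 0.0001, 1e-5, 1e-6]),
    "C": np.array([6.0, 5.86, 5.13, 4.30, 3.58, 2.50, 1.95, 1.69, 1.54,
                   1.26, 1.00, 0.58, 0.35, 0.16, 0.05, 0.015]),
    "O": np.array([8.0, 7.84, 7.25, 6.45, 5.63, 4.09, 3.01, 2.34, 1.94,
                   1.57, 1.37, 0.95, 0.64, 0.30, 0.09, 0.03]),
    "N": np.array([7.0, 6.85, 6.20, 5.39, 4.60, 3.24, 2.40, 1.94, 1.70,
                   1.42, 1.19, 0.77, 0.49, 0.22, 0.07, 0.02]),
}
# atoms per molecule for the media that scatter in the transport
_COMPOSITION = {
    "water": (("H", 2), ("O", 1)),
    "PMMA": (("C", 5), ("H", 8), ("O", 2)),
    "air": (("N", 1.6), ("O", 0.4)),
}


class RayleighSampler:
    """Samples coherent-scattering polar angles for a compound medium.

    The squared molecular form factor (independent-atom approximation,
    F^2 = sum_i n_i F_i^2) is integrated over x^2 once; angles are then
    drawn by inverse-CDF sampling of F^2 d(x^2) restricted to the
    kinematic range, with Thomson-factor (1+cos^2)/2 rejection.
    """

    _HC_KEV_A = 12.39842  # keV * Angstrom

    def __init__(self, material_name: str, n_grid: int = 2048):
        comp = _COMPOSITION[material_name]
        x = np.linspace(0.0, _FF_X[-1], n_grid)
        f2 = np.zeros_like(x)
        for el, n_at in comp:
            f2 += n_at * np.interp(x, _FF_X, _FF[el]) ** 2
        x2 = x**2
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (f2[1:] + f2[:-1]) * np.diff(x2)
        )])
        self._x2 = x2
        self._cdf = cdf

    def sample_cos(self, energy_kev: np.ndarray, rng) -> np.ndarray:
        """Cosine of the coherent scattering angle for each photon."""
        e = np.asarray(energy_kev, dtype=float)
        x_max = e / self._HC_KEV_A  # x at theta = pi
        cdf_max = np.interp(x_max**2, self._x2, self._cdf)
        n = len(e)
        cos_t = np.empty(n)
        todo = np.ones(n, dtype=bool)
        while todo.any():
            m = int(todo.sum())
            u = rng.random(m) * cdf_max[todo]
            x2 = np.interp(u, self._cdf, self._x2)
            sin_half2 = np.minimum(x2 / x_max[todo] ** 2, 1.0)
            c = 1.0 - 2.0 * sin_half2
            acc = rng.random(m) <= 0.5 * (1.0 + c**2)
            sel = np.flatnonzero(todo)[acc]
            cos_t[sel] = c[acc]
            todo[sel] = False
        return cos_t


_RAYLEIGH_CACHE: dict = {}


def get_rayleigh_sampler(material_name: str) -> RayleighSampler:
    if material_name not in _RAYLEIGH_CACHE:
        _RAYLEIGH_CACHE[material_name] = RayleighSampler(material_name)
    return _RAYLEIGH_CACHE[material_name]


def get_material(name: str) -> Material:
    """Look up a material by id (W, Cu, Be, Al, water, PMMA, air)."""
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(MATERIALS)}"
        ) from None
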