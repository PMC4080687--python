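"""Materials, X-ray spectra and attenuation for the CT simulator.

Mass attenuation coefficients (cm^2/g) are tabulated over 40-120 keV at a
handful of energies and interpolated linearly.  The values are approximate
diagnostic-range coefficients for elemental/compound media; fine structure is
omitted -- in particular gold's K-edge near 81 keV is smoothed away so every
table is non-increasing with energy, which is all the beam-hardening model
needs.  The scanner reference energy is 80 keV (mu_water = 0.1837 cm^-1),
which anchors the Hounsfield scale: HU = 1000 (mu - mu_w) / mu_w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "Spectrum",
    "linear_attenuation",
    "hounsfield_from_mu",
    "mu_from_hounsfield",
    "default_materials",
    "REFERENCE_ENERGY_KEV",
    "MU_WATER_REFERENCE",
]

REFERENCE_ENERGY_KEV = 80.0

_ENERGIES = np.array([40.0, 50.0, 60.0, 80.0, 100.0, 120.0])

# mass attenuation (cm^2/g) over _ENERGIES; monotone non-increasing
_MASS_ATTEN = {
    "air": [0.2485, 0.2080, 0.1875, 0.1662, 0.1541, 0.1446],
    "water": [0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1614],
    "solid_water": [0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1614],
    "soft_tissue": [0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1614],
    "bone": [0.6655, 0.4242, 0.3148, 0.2229, 0.1855, 0.1654],
    "titanium": [2.214, 1.213, 0.7661, 0.4052, 0.2721, 0.2139],
    "steel": [3.629, 1.958, 1.205, 0.5952, 0.3717, 0.2883],
    "gold": [10.50, 6.300, 4.528, 2.137, 1.250, 0.800],
}

_DENSITY = {  # g/cm^3
    "air": 0.001205,
    "water": 1.000,
    "solid_water": 1.011,  # water-equivalent plastic, ~11 HU at 80 keV
    "soft_tissue": 1.020,
    "bone": 1.850,
    "titanium": 4.59,
    "steel": 7.90,
    "gold": 19.32,
}


@dataclass
class Material:
    """A simulated scan material: density plus tabulated mass attenuation."""

    name: str
    density: float  # g/cm^3
    energies: np.ndarray  # keV bin centers of the table
    mass_atten: np.ndarray  # cm^2/g, same length as energies

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.mass_atten = np.asarray(self.mass_atten, dtype=np.float64)
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if (self.mass_atten <= 0).any():
            raise ValueError(f"{self.name}: mass attenuation must be strictly positive")
        if (np.diff(self.mass_atten) > 0).any():
            raise ValueError(
                f"{self.name}: mass attenuation must be non-increasing with energy"
            )

    @property
    def reference_hu(self) -> float:
        """Nominal HU at the scanner reference energy."""
        return hounsfield_from_mu(linear_attenuation(self, REFERENCE_ENERGY_KEV))


def linear_attenuation(m: Material, energy_kev: float) -> float:
    """Linear attenuation coefficient (cm^-1) at an energy inside the table.

    density x interpolated mass attenuation; energies outside the tabulated
    range are a hard error (no extrapolation).
    """
    e = float(energy_kev)
    if e < m.energies[0] or e > m.energies[-1]:
        raise ValueError(
            f"{m.name}: energy {e} keV outside tabulated range "
            f"[{m.energies[0]}, {m.energies[-1]}]"
        )
    return m.density * float(np.interp(e, m.energies, m.mass_atten))


def default_materials() -> dict:
    """The built-in material table (air, water, solid water, tissue, bone, Ti, steel, gold)."""
    return {
        name: Material(name, _DENSITY[name], _ENERGIES, np.array(vals))
        for name, vals in _MASS_ATTEN.items()
    }


MU_WATER_REFERENCE = _DENSITY["water"] * float(
    np.interp(REFERENCE_ENERGY_KEV, _ENERGIES, _MASS_ATTEN["water"])
)


def hounsfield_from_mu(mu, mu_water: float = MU_WATER_REFERENCE):
    """HU = 1000 (mu - mu_water) / mu_water."""
    return 1000.0 * (np.asarray(mu) - mu_water) / mu_water


def mu_from_hounsfield(hu, mu_water: float = MU_WATER_REFERENCE):
    """Inverse Hounsfield map, clipped at zero attenuation."""
    return np.clip(mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0), 0.0, None)


@dataclass
class Spectrum:
    """Discrete X-ray spectrum: keV bin centers and normalized fluence weights."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=np.float64))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=np.float64))
        if self.energies.size == 0:
            raise ValueError("spectrum needs at least one energy bin")
        if self.energies.shape != self.weights.shape:
            raise ValueError("energies and weights must have the same length")
        if (self.weights < 0).any() or self.weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.weights = self.weights / self.weights.sum()

    @classmethod
    def monochromatic(cls, energy_kev: float = REFERENCE_ENERGY_KEV) -> "Spectrum":
        return cls(np.array([energy_kev]), np.array([1.0]))

    @classmethod
    def polychromatic(cls) -> "Spectrum":
        """Default 3-bin spectrum (60/80/100 keV) -- the minimum that beam-hardens.

        The weights follow the shape of a filtered 120 kVp tube spectrum,
        whose fluence is bottom-heavy (peak near 60 keV after typical
        aluminum-equivalent filtration), binned into the three bands.
        """
        return cls(np.array([60.0, 80.0, 100.0]), np.array([0.50, 0.30, 0.20]))
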