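"""Tube spectrum, energy-discriminating detector and the bin-count forward model.

The incident spectrum is a Kramers-style bremsstrahlung fluence with
aluminium-equivalent inherent filtration; the exact tube spectrum of a real
scanner is proprietary, so the model is deliberately simple and fully
configurable.  The detector applies five ideal rectangular pulse-height
windows: bin ``i`` collects photons with energy in ``[T_i, T_{i+1})`` and the
last bin extends to the tube voltage.  Pulse pile-up, charge sharing and
spectral tailing are not modelled.

Expected counts for a ray with basis-material areal densities ``a_b`` (g/cm²)
follow the polychromatic Beer–Lambert model

    λ_i(a) = Σ_{E ∈ bin i} S(E) · exp(-Σ_b a_b (μ/ρ)_b(E)),

which is shared verbatim between the scan simulator and the
maximum-likelihood decomposition, so that inversion tests probe the
estimator rather than model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .materials import load_material

__all__ = [
    "Spectrum",
    "DetectorModel",
    "BinCountModel",
    "generate_spectrum",
    "harden_spectrum",
    "expected_bin_counts",
    "hu_of_mixture",
]

#: all spectra are normalised to their photon count above this energy, the
#: noise threshold common to every acquisition configuration
NOISE_THRESHOLD_KEV = 30.0

ENERGY_STEP_KEV = 0.5


@dataclass(frozen=True)
class Spectrum:
    """Incident photon fluence per energy grid point for one ray.

    ``fluence`` holds photons per grid step at the stated ``exposure_scale``
    (the unattenuated counts-per-ray budget above the 30-keV noise
    threshold, the stand-in for mAs).
    """

    kvp: float
    energies: np.ndarray
    fluence: np.ndarray
    exposure_scale: float

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        f = np.asarray(self.fluence, float)
        if np.any(f < 0):
            raise ValueError("fluence must be non-negative")
        if np.any(f[e > self.kvp] > 0):
            raise ValueError("fluence must vanish above the tube voltage")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)

    def total_counts(self, above_keV: float = NOISE_THRESHOLD_KEV) -> float:
        return float(self.fluence[self.energies >= above_keV].sum())


def generate_spectrum(
    kvp: float = 120.0,
    exposure_scale: float = 1.0,
    filtration_mm_al: float = 2.5,
    energy_step_keV: float = ENERGY_STEP_KEV,
) -> Spectrum:
    """Filtered Kramers bremsstrahlung spectrum.

    Photon fluence per unit energy ∝ (kVp/E − 1), attenuated by
    ``filtration_mm_al`` of aluminium, cut off at the tube voltage and
    normalised so the photon count above 30 keV equals ``exposure_scale``.
    Characteristic anode lines are not modelled.
    """
    if kvp not in (80.0, 100.0, 120.0, 80, 100, 120):
        raise ValueError("supported tube voltages are 80, 100 and 120 kVp")
    if exposure_scale <= 0:
        raise ValueError("exposure_scale must be positive")
    e = np.arange(10.0, kvp + energy_step_keV / 2, energy_step_keV)
    w = np.clip(kvp / e - 1.0, 0.0, None)
    al = load_material("aluminium")
    areal = 0.1 * filtration_mm_al * al.density_ref  # g/cm²
    w = w * np.exp(-areal * al.mu(e))
    detected = w[e >= NOISE_THRESHOLD_KEV].sum()
    return Spectrum(float(kvp), e, w * (exposure_scale / detected), exposure_scale)


def harden_spectrum(spectrum: Spectrum, paths_cm: dict[str, float]) -> Spectrum:
    """Spectrum after passing through the given material thicknesses (cm).

    The returned fluence is attenuated in place (its 30-keV normalisation is
    intentionally no longer ``exposure_scale``); used to build the effective
    in-phantom spectrum for attenuation (HU) predictions.
    """
    f = spectrum.fluence.copy()
    for name, length in paths_cm.items():
        table = load_material(name)
        f = f * np.exp(-length * table.density_ref * table.mu(spectrum.energies))
    return replace(spectrum, fluence=f)


@dataclass(frozen=True)
class DetectorModel:
    """Five ascending pulse-height thresholds and the tube-voltage upper limit."""

    thresholds: tuple[float, float, float, float, float]
    upper_limit: float = 120.0

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != 5:
            raise ValueError("exactly five thresholds required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        if t[-1] >= self.upper_limit:
            raise ValueError("highest threshold must lie below the upper limit")
        object.__setattr__(self, "thresholds", t)

    @property
    def noise_threshold(self) -> float:
        return self.thresholds[0]

    @property
    def bin_edges(self) -> np.ndarray:
        return np.array(list(self.thresholds) + [self.upper_limit])

    def bin_index(self, energy_keV) -> np.ndarray:
        """0-based bin per energy; -1 below the noise threshold or above kVp."""
        e = np.atleast_1d(np.asarray(energy_keV, float))
        idx = np.searchsorted(np.asarray(self.thresholds), e, side="right") - 1
        idx[(e < self.noise_threshold) | (e > self.upper_limit)] = -1
        return idx


class BinCountModel:
    """Cached forward model λ(a) for a (spectrum, detector, basis) triple.

    Precomputes the per-bin spectrum matrix and the basis attenuation matrix
    on the detected energy grid; exposes expected counts and their first two
    derivatives with respect to the areal densities, vectorised over rays.
    """

    def __init__(self, spectrum: Spectrum, detector: DetectorModel, materials):
        self.spectrum = spectrum
        self.detector = detector
        self.materials = list(materials)
        e = spectrum.energies
        keep = (e >= detector.noise_threshold) & (e <= detector.upper_limit)
        keep &= spectrum.fluence > 0
        self.energies = e[keep]
        flu = spectrum.fluence[keep]
        idx = detector.bin_index(self.energies)
        # S: (nE, 5) fluence routed to its bin
        self.S = np.zeros((self.energies.size, 5))
        self.S[np.arange(self.energies.size), idx] = flu
        # F: (nE, n_mat) mass attenuation
        self.F = np.column_stack(
            [load_material(m).mu(self.energies) for m in self.materials]
        )

    @property
    def n_materials(self) -> int:
        return len(self.materials)

    def transmission(self, A: np.ndarray) -> np.ndarray:
        """exp(-A F^T): (n_rays, nE) for A of shape (n_rays, n_mat) in g/cm²."""
        A = np.atleast_2d(np.asarray(A, float))
        # clip the optical depth: keeps trial steps of the decomposition
        # optimiser finite without affecting any physical operating point
        return np.exp(-np.clip(A @ self.F.T, -80.0, 80.0))

    def expected(self, A: np.ndarray) -> np.ndarray:
        """Expected counts λ, shape (n_rays, 5)."""
        return self.transmission(A) @ self.S

    def expected_with_derivs(self, A: np.ndarray, pairs=None):
        """λ, ∂λ/∂a_b and ∂²λ/∂a_b∂a_c for the given index pairs.

        Returns ``lam (n,5)``, ``dlam (n, n_mat, 5)`` and ``d2lam`` as a dict
        ``(b, c) -> (n, 5)``; second derivatives only for requested pairs.
        """
        T = self.transmission(A)
        lam = T @ self.S
        nm = self.n_materials
        dlam = np.empty((T.shape[0], nm, 5))
        for b in range(nm):
            dlam[:, b, :] = -(T * self.F[:, b]) @ self.S
        d2lam = {}
        if pairs:
            for b, c in pairs:
                d2lam[(b, c)] = (T * (self.F[:, b] * self.F[:, c])) @ self.S
        return lam, dlam, d2lam


def expected_bin_counts(
    spectrum: Spectrum,
    detector: DetectorModel,
    basis_areal_densities: dict[str, float],
) -> np.ndarray:
    """Expected counts in the five bins for one ray.

    ``basis_areal_densities`` maps material name to areal density in g/cm²
    (negative values are permitted: the decomposition is unconstrained).
    """
    mats = list(basis_areal_densities)
    model = BinCountModel(spectrum, detector, mats)
    a = np.array([[basis_areal_densities[m] for m in mats]], float)
    return model.expected(a)[0]


def hu_of_mixture(
    concentrations_mg_per_ml: dict[str, float],
    spectrum: Spectrum,
    detector: DetectorModel | None = None,
) -> float:
    """CT attenuation (HU) of a dilute aqueous contrast-agent solution.

    Uses the dilute-solution model μ_mix(E) = μ_water(E) + Σ_b c_b (μ/ρ)_b(E)
    (water displacement by the solute is neglected, a ≤1 % effect at the
    concentrations of interest) and weights the linear attenuation by the
    detected photon fluence of ``spectrum``:

        HU = 1000 · (⟨μ_mix⟩_S − ⟨μ_water⟩_S) / ⟨μ_water⟩_S.

    Pass a spectrum hardened to the in-phantom beam (see
    :func:`harden_spectrum`) to predict what a reconstructed conventional
    image of the phantom reads.
    """
    tmin = detector.noise_threshold if detector else NOISE_THRESHOLD_KEV
    tmax = detector.upper_limit if detector else spectrum.kvp
    e = spectrum.energies
    keep = (e >= tmin) & (e <= tmax) & (spectrum.fluence > 0)
    e, w = e[keep], spectrum.fluence[keep]
    water = load_material("water")
    mu_w = water.density_ref * water.mu(e)
    mu_mix = mu_w.copy()
    for name, c in concentrations_mg_per_ml.items():
        if c < 0:
            raise ValueError("concentrations must be non-negative")
        mu_mix = mu_mix + (c / 1000.0) * load_material(name).mu(e)
    ref = float(w @ mu_w)
    return 1000.0 * (float(w @ mu_mix) - ref) / ref
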