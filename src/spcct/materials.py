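"""Energy-resolved mass-attenuation data for the basis and phantom materials.

Tables are bundled as CSV files (``data/attenuation_<material>.csv``) holding
mass-attenuation coefficients (μ/ρ, cm²/g) on an anchor-energy grid between
10 and 150 keV, taken from published photon cross-section compilations.
Materials with a K absorption edge inside the diagnostic range (iodine,
gadolinium, gold) carry a doubled row at the edge energy with a ``side``
marker, so that interpolation never bridges the discontinuity.

Queries between anchors use log-log interpolation, the standard choice for
photon attenuation data, restricted to the edge-delimited segment that
contains the query energy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "MaterialTable",
    "MaterialLookupError",
    "load_material",
    "known_materials",
    "kedge_energy",
    "mass_attenuation",
]

#: reference densities of the pure materials, g/mL
DENSITIES = {
    "water": 1.0,
    "polyoxymethylene": 1.41,
    "aluminium": 2.699,
    "iodine": 4.93,
    "gadolinium": 7.90,
    "gold": 19.32,
}


class MaterialLookupError(KeyError):
    """Unknown material or out-of-range energy query."""


@dataclass(frozen=True)
class MaterialTable:
    """Mass-attenuation table for one material.

    Parameters
    ----------
    material_id : str
        Material name, e.g. ``"gadolinium"``.
    energies : ndarray
        Anchor energies in keV, non-decreasing; a K-edge appears as two
        consecutive identical energies (below-side then above-side row).
    mu_rho : ndarray
        Mass-attenuation coefficients in cm²/g, strictly positive.
    kedge_energy : float or None
        K-edge energy in keV, or ``None`` for edge-free materials.
    density_ref : float
        Density of the pure material in g/mL.
    """

    material_id: str
    energies: np.ndarray
    mu_rho: np.ndarray
    kedge_energy: float | None = None
    density_ref: float = 1.0
    _segments: tuple = field(init=False, repr=False, default=())

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.mu_rho, dtype=float)
        if e.ndim != 1 or e.shape != mu.shape or e.size < 2:
            raise ValueError("energies and mu_rho must be matching 1-D arrays")
        if np.any(np.diff(e) < 0):
            raise ValueError("energies must be non-decreasing")
        if np.any(mu <= 0):
            raise ValueError("mu_rho must be strictly positive")
        dup = np.flatnonzero(np.diff(e) == 0)
        if self.kedge_energy is not None:
            if dup.size != 1 or e[dup[0]] != self.kedge_energy:
                raise ValueError("K-edge material needs one doubled edge row")
            if mu[dup[0] + 1] <= mu[dup[0]]:
                raise ValueError("mu_rho just above K-edge must exceed below")
        elif dup.size:
            raise ValueError("doubled energies only allowed at a K-edge")
        # split into interpolation segments that never bridge the edge
        if dup.size:
            i = dup[0]
            segs = ((e[: i + 1], mu[: i + 1]), (e[i + 1 :], mu[i + 1 :]))
        else:
            segs = ((e, mu),)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_rho", mu)
        object.__setattr__(self, "_segments", segs)

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def mu(self, energy_keV) -> np.ndarray | float:
        """Log-log interpolated μ/ρ (cm²/g) at one or more energies.

        A query exactly at the K-edge is ambiguous (the table holds one-sided
        limits); shift it by ±ε to select a side.
        """
        e = np.asarray(energy_keV, dtype=float)
        scalar = e.ndim == 0
        e = np.atleast_1d(e)
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise MaterialLookupError(
                f"energy outside {self.material_id} table range [{lo}, {hi}] keV"
            )
        if self.kedge_energy is not None and np.any(e == self.kedge_energy):
            raise ValueError(
                "query exactly at the K-edge is ambiguous; offset by +/-eps"
            )
        out = np.empty_like(e)
        if self.kedge_energy is None:
            (se, smu), = self._segments
            out[:] = _loglog_interp(e, se, smu)
        else:
            below = e < self.kedge_energy
            for mask, (se, smu) in zip((below, ~below), self._segments):
                if mask.any():
                    out[mask] = _loglog_interp(e[mask], se, smu)
        return float(out[0]) if scalar else out


def _loglog_interp(e, xe, xmu):
    out = np.exp(np.interp(np.log(e), np.log(xe), np.log(xmu)))
    # snap exact anchor queries to the tabulated value (the exp/log round
    # trip is otherwise off in the last ulp)
    j = np.searchsorted(xe, e)
    j = np.clip(j, 0, xe.size - 1)
    hit = xe[j] == e
    out[hit] = xmu[j[hit]]
    return out


@lru_cache(maxsize=None)
def load_material(name: str) -> MaterialTable:
    """Load a bundled material table by name."""
    try:
        text = (
            resources.files("spcct.data")
            .joinpath(f"attenuation_{name}.csv")
            .read_text()
        )
    except FileNotFoundError as exc:
        raise MaterialLookupError(f"no bundled table for material {name!r}") from exc
    energies, mu, kedge = [], [], None
    for row in csv.DictReader(text.splitlines()):
        energies.append(float(row["energy_keV"]))
        mu.append(float(row["mu_rho_cm2_g"]))
        if row["side"]:
            kedge = float(row["energy_keV"])
    return MaterialTable(
        material_id=name,
        energies=np.array(energies),
        mu_rho=np.array(mu),
        kedge_energy=kedge,
        density_ref=DENSITIES.get(name, 1.0),
    )


def known_materials() -> list[str]:
    files = resources.files("spcct.data")
    return sorted(
        p.name[len("attenuation_") : -len(".csv")]
        for p in files.iterdir()
        if p.name.startswith("attenuation_")
    )


def kedge_energy(material: str) -> float | None:
    """K-edge energy in keV, or ``None`` for edge-free materials."""
    return load_material(material).kedge_energy


def mass_attenuation(table: MaterialTable | str, energy_keV) -> np.ndarray | float:
    """μ/ρ (cm²/g) of a material (table or name) at the given energies."""
    if isinstance(table, str):
        table = load_material(table)
    return table.mu(energy_keV)
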