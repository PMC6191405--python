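"""Phantom geometry and tube-concentration designs.

The phantom is a 13-cm polyoxymethylene cylinder with 12 holes of 1.5 cm
diameter on a single ring, holding centrifuge tubes of contrast agent
diluted in PBS (modelled as water).  Eleven tubes carry the agent series and
the twelfth is the PBS reference.  Mixture designs follow the "spiral"
layout: agent 1 decreases while agent 2 increases across the tube index,
with every tube targeted to the same conventional CT attenuation (280 HU,
the usual CT-angiography level), so that the tubes are indistinguishable on
a conventional image but separate in the material images.

Two design sources exist: the published concentration fixture (tuned to the
original scanner's beam) and designs generated by the HU-targeting solver
under this package's own spectrum model.  Generated designs are the pipeline
default, since the quantification logic only requires equal-attenuation
tubes, not the verbatim concentrations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .beam import DetectorModel, Spectrum, harden_spectrum, hu_of_mixture
from .materials import DENSITIES

__all__ = [
    "PhantomSpec",
    "TubeFill",
    "DesignTable",
    "STUDY_IDS",
    "STUDY_AGENTS",
    "PBS_TUBE_ID",
    "load_table1_fixture",
    "solve_concentration_for_hu",
    "spiral_mixture_series",
    "dilution_series",
    "rasterize_phantom",
    "mean_tube_paths",
    "effective_design_spectrum",
]

STUDY_IDS = ("AuGd_mix", "IGd_mix", "Au_only", "Gd_only", "I_only")

#: agents of each study, in spiral order (agent 1 decreasing)
STUDY_AGENTS = {
    "AuGd_mix": ("gadolinium", "gold"),
    "IGd_mix": ("iodine", "gadolinium"),
    "Au_only": ("gold",),
    "Gd_only": ("gadolinium",),
    "I_only": ("iodine",),
}

PBS_TUBE_ID = 12


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical body with tube holes on a single ring."""

    body_diameter_cm: float = 13.0
    body_material: str = "polyoxymethylene"
    n_holes: int = 12
    hole_diameter_cm: float = 1.5
    ring_radius_cm: float = 4.5
    fov_cm: float = 16.8

    def __post_init__(self):
        r_body = self.body_diameter_cm / 2
        r_hole = self.hole_diameter_cm / 2
        if self.ring_radius_cm + r_hole >= r_body:
            raise ValueError("holes must lie strictly inside the body")
        centres = self.hole_centres_cm
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < self.hole_diameter_cm:
            raise ValueError("holes overlap")

    @property
    def hole_centres_cm(self) -> np.ndarray:
        """(n_holes, 2) centres; tube 1 at twelve o'clock, clockwise."""
        k = np.arange(self.n_holes)
        ang = np.pi / 2 - 2 * np.pi * k / self.n_holes
        return self.ring_radius_cm * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class TubeFill:
    """Contrast concentrations (mg/mL per agent) of one tube."""

    tube_id: int
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class DesignTable:
    """Per-tube fills of one study (11 agent tubes plus the PBS tube)."""

    study_id: str
    fills: tuple[TubeFill, ...]

    def __post_init__(self):
        if self.study_id not in STUDY_IDS:
            raise ValueError(f"unknown study_id {self.study_id!r}")
        ids = [f.tube_id for f in self.fills]
        if ids != sorted(ids) or len(set(ids)) != len(ids):
            raise ValueError("tube ids must be unique and ascending")
        agents = STUDY_AGENTS[self.study_id]
        for f in self.fills:
            extra = set(f.concentrations) - set(agents)
            if extra:
                raise ValueError(f"agents {extra} not part of {self.study_id}")
        if len(agents) == 2:
            a1 = [f.concentrations.get(agents[0], 0.0) for f in self.agent_fills]
            a2 = [f.concentrations.get(agents[1], 0.0) for f in self.agent_fills]
            if np.any(np.diff(a1) > 1e-12) or np.any(np.diff(a2) < -1e-12):
                raise ValueError(
                    "spiral design requires agent 1 non-increasing and "
                    "agent 2 non-decreasing across tubes"
                )

    @property
    def agent_fills(self) -> tuple[TubeFill, ...]:
        return tuple(f for f in self.fills if f.tube_id != PBS_TUBE_ID)

    @property
    def agents(self) -> tuple[str, ...]:
        return STUDY_AGENTS[self.study_id]

    def fill(self, tube_id: int) -> TubeFill:
        for f in self.fills:
            if f.tube_id == tube_id:
                return f
        raise KeyError(tube_id)

    def prepared(self, agent: str) -> np.ndarray:
        """Prepared concentrations (mg/mL) of one agent over the agent tubes."""
        return np.array(
            [f.concentrations.get(agent, 0.0) for f in self.agent_fills]
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["study_id", "tube_id", "agent", "concentration_mg_per_ml"])
            for f in self.agent_fills:
                for agent in self.agents:
                    w.writerow(
                        [self.study_id, f.tube_id, agent,
                         f.concentrations.get(agent, 0.0)]
                    )

    @classmethod
    def from_rows(cls, study_id: str, rows) -> "DesignTable":
        by_tube: dict[int, dict] = {}
        for tube_id, agent, conc in rows:
            by_tube.setdefault(int(tube_id), {})[agent] = float(conc)
        fills = [TubeFill(t, c) for t, c in sorted(by_tube.items())]
        fills.append(TubeFill(PBS_TUBE_ID, {}))
        return cls(study_id, tuple(fills))

    @classmethod
    def from_csv(cls, path_or_text, study_id: str) -> "DesignTable":
        if hasattr(path_or_text, "read"):
            text = path_or_text.read()
        else:
            try:
                with open(path_or_text) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = str(path_or_text)
        rows = []
        for row in csv.DictReader(io.StringIO(text)):
            if row["study_id"] == study_id:
                rows.append(
                    (row["tube_id"], row["agent"], row["concentration_mg_per_ml"])
                )
        if not rows:
            raise KeyError(f"study {study_id!r} not present in design CSV")
        return cls.from_rows(study_id, rows)


def load_table1_fixture(study_id: str) -> DesignTable:
    """The published tube-concentration fixture for one study."""
    if study_id not in STUDY_IDS:
        raise KeyError(f"unknown study_id {study_id!r}")
    text = (
        resources.files("spcct.data").joinpath("table1_concentrations.csv").read_text()
    )
    return DesignTable.from_csv(io.StringIO(text), study_id)


def solve_concentration_for_hu(
    fractions: dict[str, float],
    target_hu: float,
    spectrum: Spectrum,
    detector: DetectorModel | None = None,
    tol_hu: float = 0.1,
) -> dict[str, float]:
    """Scale a relative agent-weight vector so the mixture reads ``target_hu``.

    The dilute-solution attenuation is homogeneous in the overall scale, so a
    bracketed 1-D root solve on the scale factor converges unconditionally
    for non-negative, not-all-zero fractions.
    """
    if any(v < 0 for v in fractions.values()) or not any(fractions.values()):
        raise ValueError("fractions must be non-negative and not all zero")
    if target_hu < 0:
        raise ValueError("target attenuation must be non-negative")
    if target_hu == 0:
        return {k: 0.0 for k in fractions}

    def hu_at(scale: float) -> float:
        conc = {k: scale * v for k, v in fractions.items()}
        return hu_of_mixture(conc, spectrum, detector) - target_hu

    hi = 1.0
    while hu_at(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("HU target unreachable with these fractions")
    scale = brentq(hu_at, 0.0, hi, xtol=1e-12, rtol=1e-12)
    result = {k: scale * v for k, v in fractions.items()}
    if abs(hu_of_mixture(result, spectrum, detector) - target_hu) > tol_hu:
        raise RuntimeError("HU solver did not reach the requested tolerance")
    return result


def spiral_mixture_series(
    agent1: str,
    agent2: str,
    spectrum: Spectrum,
    detector: DetectorModel | None = None,
    n: int = 11,
    target_hu: float = 280.0,
    study_id: str | None = None,
) -> DesignTable:
    """Generate the two-agent spiral design: n equal-attenuation mixtures.

    Tube ``k`` mixes the agents with weight pair ``(1 - f_k, f_k)``,
    ``f_k = (k-1)/(n-1)``, each scaled to the target attenuation, so the
    endpoints are single-agent tubes.
    """
    if agent1 == agent2:
        raise ValueError("the two agents must differ")
    if n < 2:
        raise ValueError("a mixture series needs at least two tubes")
    if study_id is None:
        study_id = next(
            s for s, a in STUDY_AGENTS.items() if a == (agent1, agent2)
        )
    fills = []
    for k in range(1, n + 1):
        f = (k - 1) / (n - 1)
        fractions = {agent1: 1.0 - f, agent2: f}
        fractions = {a: v for a, v in fractions.items() if v > 0}
        conc = solve_concentration_for_hu(fractions, target_hu, spectrum, detector)
        conc = {a: conc.get(a, 0.0) for a in (agent1, agent2)}
        fills.append(TubeFill(k, conc))
    fills.append(TubeFill(PBS_TUBE_ID, {}))
    return DesignTable(study_id, tuple(fills))


def dilution_series(
    agent: str,
    spectrum: Spectrum,
    detector: DetectorModel | None = None,
    n: int = 11,
    target_hu: float = 280.0,
    descending: bool = False,
    study_id: str | None = None,
) -> DesignTable:
    """Single-agent series: attenuation steps linearly from 0 to the target."""
    if n < 2:
        raise ValueError("a dilution series needs at least two tubes")
    if study_id is None:
        study_id = next(s for s, a in STUDY_AGENTS.items() if a == (agent,))
    targets = np.linspace(0.0, target_hu, n)
    if descending:
        targets = targets[::-1]
    fills = []
    for k, t in enumerate(targets, start=1):
        conc = (
            {agent: 0.0}
            if t == 0
            else solve_concentration_for_hu({agent: 1.0}, float(t), spectrum, detector)
        )
        fills.append(TubeFill(k, conc))
    fills.append(TubeFill(PBS_TUBE_ID, {}))
    return DesignTable(study_id, tuple(fills))


def rasterize_phantom(
    spec: PhantomSpec,
    design: DesignTable,
    pixel_size_cm: float,
    n_pixels: int | None = None,
) -> dict[str, np.ndarray]:
    """Centre-sampled per-material concentration maps (mg/mL) plus body mask.

    Returns a dict with one map per material: the body polymer (1410 mg/mL
    inside the body, outside the holes), water (1000 mg/mL inside every
    tube, PBS included) and each contrast agent.  The key ``"_body_mask"``
    holds the boolean body support.  The grid centre sits at index
    ``n // 2`` on both axes (the convention of the projection and
    reconstruction code); the y axis points up.
    """
    if pixel_size_cm <= 0:
        raise ValueError("pixel_size_cm must be positive")
    if n_pixels is None:
        n_pixels = int(np.ceil(spec.fov_cm / pixel_size_cm))
    if n_pixels * pixel_size_cm < spec.body_diameter_cm:
        raise ValueError("grid does not cover the phantom body")
    c = n_pixels // 2
    xy = (np.arange(n_pixels) - c) * pixel_size_cm
    x = xy[None, :]
    y = -xy[:, None]  # row 0 at the top
    r2 = x**2 + y**2
    body = r2 <= (spec.body_diameter_cm / 2) ** 2
    hole_r2 = (spec.hole_diameter_cm / 2) ** 2
    centres = spec.hole_centres_cm
    hole_masks = [
        (x - cx) ** 2 + (y - cy) ** 2 <= hole_r2 for cx, cy in centres
    ]
    any_hole = np.any(hole_masks, axis=0)
    maps = {"water": np.where(any_hole, 1000.0, 0.0)}
    body_map = np.where(body & ~any_hole, 1000.0 * DENSITIES[spec.body_material], 0.0)
    maps[spec.body_material] = maps.get(spec.body_material, 0.0) + body_map
    for agent in design.agents:
        m = np.zeros((n_pixels, n_pixels))
        for f in design.fills:
            conc = f.concentrations.get(agent, 0.0)
            if conc:
                m[hole_masks[f.tube_id - 1]] = conc
        maps[agent] = m
    maps["_body_mask"] = body
    return maps


def mean_tube_paths(spec: PhantomSpec, n_angles: int = 360) -> dict[str, float]:
    """Mean body-polymer and water path lengths (cm) of rays through a tube.

    Averages, over the 11 agent-tube centres and over projection angles, the
    chord of the ray through the body polymer and through the water-filled
    holes.  This is the geometric input to the effective in-phantom spectrum
    used by the HU-targeting design solver.
    """
    r_body = spec.body_diameter_cm / 2
    r_hole = spec.hole_diameter_cm / 2
    centres = spec.hole_centres_cm
    ang = np.pi * np.arange(n_angles) / n_angles
    d = np.column_stack([np.cos(ang), np.sin(ang)])  # ray directions
    pom_tot, wat_tot, n_rays = 0.0, 0.0, 0
    for i in range(min(11, len(centres))):
        p = centres[i]
        # signed distance of each circle centre from the ray through p
        normal = np.column_stack([-d[:, 1], d[:, 0]])
        body_off = normal @ p
        body_chord = 2 * np.sqrt(np.clip(r_body**2 - body_off**2, 0, None))
        water = np.zeros(n_angles)
        for q in centres:
            off = normal @ (p - q)
            water += 2 * np.sqrt(np.clip(r_hole**2 - off**2, 0, None))
        pom_tot += float(np.sum(body_chord - water))
        wat_tot += float(np.sum(water))
        n_rays += n_angles
    return {
        spec.body_material: pom_tot / n_rays,
        "water": wat_tot / n_rays,
    }


def effective_design_spectrum(
    spectrum: Spectrum, spec: PhantomSpec | None = None
) -> Spectrum:
    """Detected spectrum hardened by the mean in-phantom material paths.

    The design solver targets the attenuation a tube exhibits in the
    reconstructed conventional image; rays reaching a tube have traversed
    the phantom body, so the unattenuated tube spectrum over-weights the
    low energies where the contrast agents attenuate most.
    """
    if spec is None:
        spec = PhantomSpec()
    return harden_spectrum(spectrum, mean_tube_paths(spec))
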