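"""Coordinate conventions, cuff geometry and fascicle-to-circle co-registration.

All angular quantities in this package are degrees, measured from the top
(12 o'clock) of the displayed nerve cross-section and increasing clockwise.
A point at angle ``theta`` and radius ``r`` therefore sits at Cartesian
``(x, y) = (r sin(theta), r cos(theta))`` with y pointing up.

The co-registration primitive maps a fascicle from its native millimetre
frame onto the unit-disc template shared by all animals, preserving the
fascicle's polar angle about the nerve centre and its distance to the
nearest cuff electrode (expressed in units of the nerve radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORGAN_LABELS = (
    "laryngeal",
    "pulmonary",
    "cardiac",
    "cardiopulmonary",
    "laryngopulmonary",
)
FIBRE_LABELS = ("afferent", "efferent", "mixed")
TECHNIQUES = ("microct", "svns")


@dataclass(frozen=True)
class Fascicle:
    """One segmented fascicle cross-section with organ and fibre-type labels.

    Coordinates are nerve-local millimetres with the nerve centroid at the
    origin; ``area`` is the fascicle cross-sectional area in mm².
    """

    id: str
    cx: float
    cy: float
    area: float
    organ_label: str
    fibre_label: str

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"fascicle {self.id}: area must be > 0, got {self.area}")
        if self.organ_label not in ORGAN_LABELS:
            raise ValueError(
                f"fascicle {self.id}: unknown organ label {self.organ_label!r}"
            )
        if self.fibre_label not in FIBRE_LABELS:
            raise ValueError(
                f"fascicle {self.id}: unknown fibre label {self.fibre_label!r}"
            )

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.cx, self.cy], dtype=float)

    @property
    def radius(self) -> float:
        """Equivalent disc radius, mm."""
        return float(np.sqrt(self.area / np.pi))


def default_pair_angles(n_pairs: int) -> np.ndarray:
    """Equally spaced pair angles, k*360/n for k = 0..n-1."""
    return np.arange(n_pairs) * 360.0 / n_pairs


@dataclass(frozen=True)
class ElectrodeCuff:
    """Multi-pair epineural cuff geometry.

    The physical array has two longitudinal rings of pads; each stimulating
    pair drives the two pads at the same angular position, so the cuff is
    reduced to one angular coordinate per pair on the nerve boundary circle.
    """

    n_pairs: int = 14
    pair_angles: tuple[float, ...] | None = None
    inner_diameter: float = 2.7  # mm
    pad_width: float = 0.35  # mm
    pad_length: float = 3.00  # mm

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("cuff needs at least 2 electrode pairs")
        if self.pair_angles is None:
            object.__setattr__(
                self, "pair_angles", tuple(default_pair_angles(self.n_pairs))
            )
        angles = np.asarray(self.pair_angles, dtype=float)
        if angles.shape != (self.n_pairs,):
            raise ValueError("pair_angles must have length n_pairs")
        if np.any(angles < 0) or np.any(angles >= 360):
            raise ValueError("pair_angles must lie in [0, 360)")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("pair_angles must be strictly increasing")

    @property
    def angles(self) -> np.ndarray:
        return np.asarray(self.pair_angles, dtype=float)


@dataclass(frozen=True)
class NerveCrossSection:
    """A nerve's mid-cuff cross-section: boundary circle plus labelled fascicles."""

    animal_id: str
    nerve_radius: float  # mm
    fascicles: tuple[Fascicle, ...] = field(default_factory=tuple)
    technique: str = "microct"

    def __post_init__(self) -> None:
        if self.nerve_radius <= 0:
            raise ValueError("nerve_radius must be > 0")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        object.__setattr__(self, "fascicles", tuple(self.fascicles))
        for f in self.fascicles:
            if np.hypot(f.cx, f.cy) > self.nerve_radius * (1 + 1e-9):
                raise ValueError(
                    f"fascicle {f.id} centroid lies outside the nerve boundary"
                )


def angle_to_xy(angle_deg: float | np.ndarray) -> np.ndarray:
    """Unit vector for an angle in the clockwise-from-top convention."""
    rad = np.deg2rad(angle_deg)
    return np.stack([np.sin(rad), np.cos(rad)], axis=-1)


def xy_to_angle(x: float | np.ndarray, y: float | np.ndarray) -> np.ndarray:
    """Angle in [0, 360) of a Cartesian point, clockwise from top."""
    return np.mod(np.rad2deg(np.arctan2(x, y)), 360.0)


def angular_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Wrapped absolute angular separation in [0, 180] degrees."""
    d = np.abs(np.mod(np.asarray(a, dtype=float) - b, 360.0))
    return np.minimum(d, 360.0 - d)


def electrode_positions(cuff: ElectrodeCuff, radius: float = 1.0) -> np.ndarray:
    """(n_pairs, 2) Cartesian electrode positions on a circle of given radius."""
    return radius * angle_to_xy(cuff.angles)


def nearest_electrode(
    fascicle: Fascicle, nerve: NerveCrossSection, cuff: ElectrodeCuff
) -> tuple[int, float]:
    """Index and mm distance of the cuff pair nearest the fascicle centroid.

    Electrodes are modelled as points on the nerve boundary circle at the
    pair angles; ties are broken toward the lowest pair index.
    """
    c = fascicle.centroid
    if np.hypot(*c) > nerve.nerve_radius * (1 + 1e-9):
        raise ValueError(
            f"fascicle {fascicle.id} centroid outside nerve boundary: "
            "invalid segmentation"
        )
    pos = electrode_positions(cuff, nerve.nerve_radius)
    d = np.linalg.norm(pos - c, axis=1)
    # ties (within rounding of the trigonometric placement) break to the
    # lowest pair index
    tol = 1e-9 * nerve.nerve_radius
    idx = int(np.argmax(d <= d.min() + tol))
    return idx, float(d[idx])


def project_to_template(
    fascicle: Fascicle, nerve: NerveCrossSection, cuff: ElectrodeCuff
) -> tuple[float, float, float]:
    """Co-register a fascicle onto the unit-disc template.

    Returns ``(angle_deg, radius, area)`` in template units. The fascicle
    keeps its polar angle about the nerve centre; its template radius is
    chosen so that the distance to the nearest electrode (now on the unit
    circle) equals the original centroid-to-electrode distance divided by
    the nerve radius. Area is rescaled by 1/nerve_radius². For a circular
    nerve this reduces to plain normalization by the nerve radius.
    """
    idx, dist = nearest_electrode(fascicle, nerve, cuff)
    r_nerve = nerve.nerve_radius
    d = dist / r_nerve
    rho0 = float(np.hypot(fascicle.cx, fascicle.cy)) / r_nerve
    if rho0 == 0.0:
        theta = 0.0
    else:
        theta = float(xy_to_angle(fascicle.cx, fascicle.cy))
    # Solve r² − 2 r cosΔ + (1 − d²) = 0 for the template radius along the
    # fascicle's angular ray, Δ being the angle to the nearest electrode.
    cos_delta = float(np.cos(np.deg2rad(theta - cuff.angles[idx])))
    disc = cos_delta**2 - 1.0 + d**2
    if disc < 0:
        # No exact solution (non-circular input geometry); take the closest
        # point on the ray to the electrode.
        r = cos_delta
    else:
        roots = (cos_delta - np.sqrt(disc), cos_delta + np.sqrt(disc))
        r = min(roots, key=lambda t: abs(t - rho0))
    r = float(np.clip(r, 0.0, 1.0))
    area = fascicle.area / r_nerve**2
    return theta, r, area
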