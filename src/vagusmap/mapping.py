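"""Binary fascicle maps on the circular template and cross-animal atlases.

Each labelled cross-section is turned into one binary W×W raster per
functional group (laryngeal, pulmonary, cardiac efferent, cardiac afferent):
pixels covered by a projected fascicle disc of the group are 1, the rest of
the nerve disc is 0. Per-animal maps are rotated so the cardiac-efferent
centre of mass sits at 0° (top), and rotated maps are averaged across
animals into atlases whose value at a pixel is the fraction of animals with
that group present there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    ElectrodeCuff,
    Fascicle,
    NerveCrossSection,
    angle_to_xy,
    project_to_template,
    xy_to_angle,
)

GROUPS = ("laryngeal", "pulmonary", "cardiac_efferent", "cardiac_afferent")

# Organ label -> functional group membership. A cardiopulmonary fascicle
# carries afferent fibres of both cardiac and pulmonary origin, so it
# contributes to both the cardiac-afferent and pulmonary maps; likewise a
# laryngopulmonary fascicle feeds both single-organ maps.
_GROUP_MEMBERSHIP: dict[str, frozenset[str]] = {
    "cardiac": frozenset({"cardiac_efferent"}),
    "cardiopulmonary": frozenset({"cardiac_afferent", "pulmonary"}),
    "pulmonary": frozenset({"pulmonary"}),
    "laryngeal": frozenset({"laryngeal"}),
    "laryngopulmonary": frozenset({"laryngeal", "pulmonary"}),
}


def group_of(fascicle: Fascicle) -> frozenset[str]:
    """Functional group membership of a fascicle, keyed by its organ label."""
    try:
        return _GROUP_MEMBERSHIP[fascicle.organ_label]
    except KeyError:  # pragma: no cover - Fascicle validates labels already
        raise ValueError(f"unknown organ label {fascicle.organ_label!r}") from None


@lru_cache(maxsize=8)
def template_coords(w: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre Cartesian coordinates (x, y) of the W×W template raster.

    Row 0 is the top of the displayed cross-section (y = +1 edge); x runs
    left (−1) to right (+1).
    """
    centers = (np.arange(w) + 0.5) / w * 2.0 - 1.0
    x = np.broadcast_to(centers[None, :], (w, w)).copy()
    y = np.broadcast_to(-centers[:, None], (w, w)).copy()
    return x, y


@lru_cache(maxsize=8)
def unit_disc_mask(w: int) -> np.ndarray:
    x, y = template_coords(w)
    return x**2 + y**2 <= 1.0


@dataclass(frozen=True)
class PixelMap:
    """Raster over the unit-disc template holding one group's map.

    ``grid`` values lie in [0, 1] (exactly {0, 1} for binary fascicle maps);
    pixels outside the nerve disc are 0. ``frame`` records whether the map
    is in the animal's raw orientation or rotated to the common
    cardiac-efferent-at-0° frame.
    """

    grid: np.ndarray
    group: str
    frame: str = "raw"
    animal_id: str = ""
    technique: str = "microct"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("grid must be square")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.frame not in ("raw", "rotated"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("map values must lie in [0, 1]")
        if np.any(g[~unit_disc_mask(g.shape[0])] != 0):
            raise ValueError("values outside the nerve disc must be 0")
        object.__setattr__(self, "grid", g)

    @property
    def w(self) -> int:
        return self.grid.shape[0]

    @property
    def nerve_mask(self) -> np.ndarray:
        return unit_disc_mask(self.w)

    def is_empty(self) -> bool:
        return not np.any(self.grid > 0)


@dataclass(frozen=True)
class AtlasMap(PixelMap):
    """Cross-animal mean of rotated binary maps; 1 ⇔ present in all animals."""

    n_animals: int = 1


def _weighted_com_xy(grid: np.ndarray) -> tuple[float, float]:
    """Value-weighted mean pixel-centre coordinate of a map."""
    w = grid.shape[0]
    x, y = template_coords(w)
    total = grid.sum()
    if total <= 0:
        raise ValueError("cannot compute centre of mass of an empty map")
    return float((grid * x).sum() / total), float((grid * y).sum() / total)


def rasterize_group(
    nerve: NerveCrossSection,
    cuff: ElectrodeCuff,
    group: str,
    w: int = 256,
) -> PixelMap:
    """Binary template map of one functional group for one nerve.

    Fascicles are projected onto the template and drawn as discs of their
    template-scaled equivalent radius; a pixel is 1 iff its centre falls in
    any such disc (and inside the nerve disc).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    x, y = template_coords(w)
    grid = np.zeros((w, w), dtype=float)
    for f in nerve.fascicles:
        if group not in group_of(f):
            continue
        theta, r, area = project_to_template(f, nerve, cuff)
        cx, cy = r * angle_to_xy(theta)
        rf = np.sqrt(area / np.pi)
        grid[(x - cx) ** 2 + (y - cy) ** 2 <= rf**2] = 1.0
    grid[~unit_disc_mask(w)] = 0.0
    return PixelMap(
        grid=grid,
        group=group,
        frame="raw",
        animal_id=nerve.animal_id,
        technique=nerve.technique,
    )


def alignment_angle(cardiac_eff_map: PixelMap) -> float:
    """Centre-of-mass angle of the cardiac-efferent map, degrees.

    Rotating every map of the animal by the negation of this angle places
    the cardiac-efferent centre of mass at 0° (top). When several
    cardiac-efferent fascicles exist the area-weighted centre of mass of the
    whole group map is used.
    """
    if cardiac_eff_map.is_empty():
        raise ValueError("cannot align: cardiac-efferent map is empty")
    cx, cy = _weighted_com_xy(cardiac_eff_map.grid)
    return float(xy_to_angle(cx, cy))


def rotate_map(pixel_map: PixelMap, angle: float, frame: str = "rotated") -> PixelMap:
    """Rotate a map about the template centre by ``angle`` degrees clockwise.

    A feature at polar angle θ moves to θ + angle. Resampling is
    nearest-neighbour so binary maps stay binary; pixels rotated in from
    outside the raster are 0 and the nerve-disc mask is re-applied.
    """
    w = pixel_map.w
    x, y = template_coords(w)
    rad = np.deg2rad(angle)
    # Inverse map: the output pixel at (x, y) samples the input at the
    # location obtained by rotating (x, y) by −angle in the clockwise
    # convention.
    xs = np.cos(rad) * x - np.sin(rad) * y
    ys = np.sin(rad) * x + np.cos(rad) * y
    cols = (xs + 1.0) * w / 2.0 - 0.5
    rows = (1.0 - ys) * w / 2.0 - 0.5
    grid = map_coordinates(
        pixel_map.grid, [rows, cols], order=0, mode="constant", cval=0.0
    )
    grid[~unit_disc_mask(w)] = 0.0
    return replace(pixel_map, grid=grid, frame=frame)


def build_atlas(maps: list[PixelMap]) -> AtlasMap:
    """Pixel-wise mean of rotated same-group maps across animals.

    For binary inputs the mean is already the normalized atlas: a value of 1
    means every animal has the group present at that pixel, 0 means none do.
    """
    if not maps:
        raise ValueError("need at least one map")
    w = maps[0].w
    group = maps[0].group
    for m in maps:
        if m.w != w:
            raise ValueError("maps must share the raster size")
        if m.group != group:
            raise ValueError("maps must share the group")
        if m.frame != "rotated":
            raise ValueError("atlas inputs must be in the rotated frame")
    grid = np.mean([m.grid for m in maps], axis=0)
    return AtlasMap(
        grid=grid,
        group=group,
        frame="rotated",
        technique=maps[0].technique,
        n_animals=len(maps),
    )
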