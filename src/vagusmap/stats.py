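"""Centres of mass, angular group comparisons and area/overlap matrices.

The quantitative layer of the pipeline: polar centres of mass of template
maps, one-way ANOVA with multiple-comparison correction on rotation-aligned
angular locations, pairwise angular separations, and the per-technique
matrices of area fractions (diagonal) and shared-area fractions
(off-diagonal) of the four functional regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .geometry import angular_distance
from .mapping import GROUPS, PixelMap, _weighted_com_xy, unit_disc_mask
from .geometry import xy_to_angle


@dataclass(frozen=True)
class CoM:
    """Polar centre of mass of one group's map for one animal/technique."""

    group: str
    animal_id: str
    technique: str
    angle: float  # degrees in [0, 360)
    radius: float  # unit-normalized, [0, 1]
    degenerate: bool = False  # radius ~ 0: angle is not meaningful

    def __post_init__(self) -> None:
        if not 0.0 <= self.radius <= 1.0:
            raise ValueError("CoM radius must lie in [0, 1]")


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric matrix of nerve-area fractions for the four regions.

    Diagonal entries are each region's fraction of the total nerve
    cross-section; off-diagonal entries are the shared-area fraction of two
    regions, all relative to the whole nerve disc.
    """

    technique: str
    matrix: np.ndarray
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.groups)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match groups")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    def diag(self, group: str) -> float:
        i = self.groups.index(group)
        return float(self.matrix[i, i])

    def offdiag(self, a: str, b: str) -> float:
        return float(self.matrix[self.groups.index(a), self.groups.index(b)])


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise angular-location comparison."""

    group_a: str
    group_b: str
    f_statistic: float
    p_value: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class AngularComparison:
    """One-way ANOVA across groups plus adjusted pairwise comparisons."""

    f_statistic: float
    p_value: float
    pairwise: tuple[ComparisonResult, ...]
    groups: tuple[str, ...]
    method: str


def center_of_mass(pixel_map: PixelMap) -> CoM:
    """Value-weighted centre of mass of a map in polar template coordinates.

    A map that is (near-)rotationally symmetric has a centre of mass at the
    origin, where the angle is undefined; such results carry radius ≈ 0, a
    reported angle of 0 and the ``degenerate`` flag.
    """
    if pixel_map.is_empty():
        raise ValueError("cannot compute centre of mass of an empty map")
    cx, cy = _weighted_com_xy(pixel_map.grid)
    radius = float(np.hypot(cx, cy))
    degenerate = radius < 2.0 / pixel_map.w  # within one pixel of the centre
    angle = 0.0 if degenerate else float(xy_to_angle(cx, cy))
    return CoM(
        group=pixel_map.group,
        animal_id=pixel_map.animal_id,
        technique=pixel_map.technique,
        angle=angle,
        radius=min(radius, 1.0),
        degenerate=degenerate,
    )


def binarize(pixel_map: PixelMap, tau: float) -> np.ndarray:
    """Boolean presence raster: values >= tau inside the nerve disc.

    Use tau = 0.5 for atlases; any tau <= the smallest positive value (e.g.
    a tiny epsilon) reduces to "any positive" for per-animal binary maps.
    """
    return (pixel_map.grid >= tau) & unit_disc_mask(pixel_map.w)


def overlap_matrix(
    group_maps: dict[str, PixelMap], tau: float = 1e-12, technique: str | None = None
) -> OverlapMatrix:
    """Area-fraction matrix of the four regions from same-template maps.

    diag(G) = |pixels(G)| / |nerve disc|; offdiag(G, H) = |pixels(G) ∩
    pixels(H)| / |nerve disc|.
    """
    missing = [g for g in GROUPS if g not in group_maps]
    if missing:
        raise ValueError(f"missing group maps: {missing}")
    w = group_maps[GROUPS[0]].w
    if any(group_maps[g].w != w for g in GROUPS):
        raise ValueError("maps must share the raster size")
    mask_count = int(unit_disc_mask(w).sum())
    masks = {g: binarize(group_maps[g], tau) for g in GROUPS}
    m = np.zeros((len(GROUPS), len(GROUPS)))
    for i, g in enumerate(GROUPS):
        for j, h in enumerate(GROUPS):
            m[i, j] = np.count_nonzero(masks[g] & masks[h]) / mask_count
    if technique is None:
        technique = group_maps[GROUPS[0]].technique
    return OverlapMatrix(technique=technique, matrix=m)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def relative_overlap(m: OverlapMatrix, a: str, b: str) -> int:
    """Percentage of region ``a`` shared with region ``b``, integer percent.

    100 × offdiag(a, b) / diag(a), rounded half-up, matching how relative
    overlaps of the regional maps are conventionally reported.
    """
    diag_a = m.diag(a)
    if diag_a <= 0:
        raise ValueError(f"relative overlap undefined: region {a!r} has zero area")
    return _round_half_up(100.0 * m.offdiag(a, b) / diag_a)


def cross_technique_overlap(
    map_a: PixelMap, map_b: PixelMap, tau: float = 0.5
) -> float:
    """Shared-area fraction of one group's maps from two techniques."""
    if map_a.w != map_b.w:
        raise ValueError("maps must share the template raster")
    mask_count = int(unit_disc_mask(map_a.w).sum())
    inter = binarize(map_a, tau) & binarize(map_b, tau)
    return float(np.count_nonzero(inter)) / mask_count


def wrap_angle(a: float | np.ndarray) -> np.ndarray:
    """Map angles to (−180, 180]."""
    w = np.mod(np.asarray(a, dtype=float), 360.0)
    return np.where(w > 180.0, w - 360.0, w)


def _linearized_angles(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Unwrap each group's angles about its own circular mean.

    The group circular mean is mapped into (−180, 180] and each observation
    is expressed as mean + wrapped deviation, yielding linear values that an
    ordinary ANOVA can compare across groups without splitting clusters
    that straddle the ±180° seam.
    """
    out = {}
    for g, angles in groups.items():
        angles = np.asarray(angles, dtype=float)
        mu = float(sps.circmean(angles, high=360.0, low=0.0))
        mu = float(wrap_angle(mu))
        out[g] = mu + wrap_angle(angles - mu)
    return out


def watson_williams(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Watson–Williams high-concentration F test for equal circular means."""
    rs, ns = [], []
    all_c = all_s = 0.0
    for angles in groups.values():
        rad = np.deg2rad(np.asarray(angles, dtype=float))
        c, s = np.cos(rad).sum(), np.sin(rad).sum()
        rs.append(float(np.hypot(c, s)))
        ns.append(rad.size)
        all_c += c
        all_s += s
    k = len(rs)
    n = int(sum(ns))
    r_all = float(np.hypot(all_c, all_s))
    rw = sum(rs) / n
    # concentration-based correction factor
    kappa = _estimate_kappa(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (sum(rs) - r_all) / (k - 1)
    den = (n - sum(rs)) / (n - k)
    if den <= 0:
        return float("inf"), 0.0
    f = correction * num / den
    p = float(sps.f.sf(f, k - 1, n - k))
    return float(f), p


def _estimate_kappa(rbar: float) -> float:
    """Maximum-likelihood-style estimate of the von Mises concentration."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    if rbar >= 1.0:
        return float("inf")
    return 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def angular_group_comparison(
    coms: list[CoM] | dict[str, np.ndarray],
    method: str = "tukey",
    circular: bool = False,
) -> AngularComparison:
    """Compare angular locations across functional groups.

    Accepts either CoM records (grouped by their ``group`` field) or a
    mapping group → array of angles. Groups with fewer than two
    observations are excluded with a warning. The default analysis is a
    one-way ANOVA on per-group-unwrapped angles with Tukey HSD adjusted
    pairwise comparisons (``method="bonferroni"`` switches the adjustment);
    ``circular=True`` instead runs a Watson–Williams test globally and per
    pair.
    """
    if isinstance(coms, dict):
        grouped = {g: np.asarray(v, dtype=float) for g, v in coms.items()}
    else:
        grouped = {}
        for c in coms:
            grouped.setdefault(c.group, []).append(c.angle)
        grouped = {g: np.asarray(v, dtype=float) for g, v in grouped.items()}

    small = [g for g, v in grouped.items() if v.size < 2]
    for g in small:
        warnings.warn(f"group {g!r} has <2 observations; excluded from ANOVA")
        del grouped[g]
    if len(grouped) < 2:
        raise ValueError("need at least two groups with >=2 observations each")

    names = tuple(sorted(grouped, key=lambda g: GROUPS.index(g) if g in GROUPS else 99))
    if circular:
        f_global, p_global = watson_williams({g: grouped[g] for g in names})
        raw = {}
        for a, b in combinations(names, 2):
            raw[(a, b)] = watson_williams({a: grouped[a], b: grouped[b]})
        method = "watson_williams_bonferroni"
    else:
        lin = _linearized_angles(grouped)
        samples = [lin[g] for g in names]
        f_global, p_global = sps.f_oneway(*samples)
        raw = {}
        for a, b in combinations(names, 2):
            raw[(a, b)] = sps.f_oneway(lin[a], lin[b])

    n_pairs = len(raw)
    pairwise = []
    if method == "tukey" and not circular:
        tk = sps.tukey_hsd(*samples)
        idx = {g: i for i, g in enumerate(names)}
        for (a, b), (f, p) in raw.items():
            p_adj = float(tk.pvalue[idx[a], idx[b]])
            pairwise.append(
                ComparisonResult(a, b, float(f), float(p), p_adj, "tukey")
            )
    else:
        tag = method if circular else "bonferroni"
        for (a, b), (f, p) in raw.items():
            pairwise.append(
                ComparisonResult(
                    a, b, float(f), float(p), float(min(p * n_pairs, 1.0)), tag
                )
            )
    return AngularComparison(
        f_statistic=float(f_global),
        p_value=float(p_global),
        pairwise=tuple(pairwise),
        groups=names,
        method="watson_williams" if circular else f"anova_{method}",
    )


def angular_separation_summary(
    coms_a: list[CoM], coms_b: list[CoM]
) -> tuple[float, float]:
    """Mean ± SD wrapped angular separation between two groups' CoMs.

    Observations are paired per animal; animals present in only one group
    are dropped.
    """
    by_a = {c.animal_id: c for c in coms_a}
    by_b = {c.animal_id: c for c in coms_b}
    shared = sorted(set(by_a) & set(by_b))
    if not shared:
        raise ValueError("no animals shared between the two CoM lists")
    seps = np.array(
        [float(angular_distance(by_a[k].angle, by_b[k].angle)) for k in shared]
    )
    sd = float(seps.std(ddof=1)) if seps.size > 1 else 0.0
    return float(seps.mean()), sd


def circular_mean_separation(coms_a: list[CoM], coms_b: list[CoM]) -> float:
    """Magnitude of the circular mean of per-animal signed angular offsets.

    The per-animal wrapped separations of ``angular_separation_summary`` are
    bounded by 180°, so their arithmetic mean is biased low whenever the
    true separation is near 180° and the per-animal measurements are noisy.
    Taking the circular mean of the signed offsets b − a first, then its
    magnitude, removes that fold bias and is the pipeline's point estimate
    of the group separation.
    """
    by_a = {c.animal_id: c for c in coms_a}
    by_b = {c.animal_id: c for c in coms_b}
    shared = sorted(set(by_a) & set(by_b))
    if not shared:
        raise ValueError("no animals shared between the two CoM lists")
    diffs = np.array([by_b[k].angle - by_a[k].angle for k in shared])
    mu = float(sps.circmean(diffs, high=360.0, low=0.0))
    return float(abs(wrap_angle(mu)))
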