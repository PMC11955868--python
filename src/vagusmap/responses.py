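"""Per-pair response extraction from stimulation traces and sector maps.

The in vivo arm of the pipeline: each electrode pair's physiological
response (% change from the pre-stimulus baseline) is extracted from the
annotated trace, the 75%-of-maximum effective-pair count is computed, and
the 14 per-pair magnitudes are painted onto the circular template as an
angular-sector (back-projection) map, normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .geometry import ElectrodeCuff, angular_distance, xy_to_angle
from .mapping import AtlasMap, PixelMap, build_atlas, template_coords, unit_disc_mask
from .synthetic import CONDITIONS, MODALITIES, PhysioTrace


@dataclass(frozen=True)
class PairResponseSet:
    """% change per electrode pair for one modality and one condition.

    ``values`` has one entry per cuff pair; NaN marks pairs that were not
    stimulated in the session.
    """

    modality: str
    values: np.ndarray
    animal_id: str = ""
    condition: str = "pre_vagotomy"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be a 1-D array, one entry per pair")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if np.any(np.isinf(v)):
            raise ValueError("response values must be finite where present")
        object.__setattr__(self, "values", v)

    @property
    def n_pairs(self) -> int:
        return self.values.size


def response_group(modality: str, condition: str) -> str:
    """Functional group a response map belongs to.

    Heart-rate responses before vagotomy reflect the cardiac-efferent
    pathway; after right distal vagotomy they reflect cardiac afferents.
    """
    if modality == "emg_rms":
        return "laryngeal"
    if modality == "etco2":
        return "pulmonary"
    return "cardiac_efferent" if condition == "pre_vagotomy" else "cardiac_afferent"


def extract_pair_response(
    trace: PhysioTrace,
    pair: int,
    baseline_window: float,
    response_window: float,
    smoothing: float = 2.0,
) -> float:
    """% change from baseline for one pair, averaged over its epochs.

    Per epoch the baseline is the mean raw signal over ``baseline_window``
    seconds immediately preceding stimulation onset, and the response is the
    extremum (the signed value of largest absolute deviation from baseline)
    of the ``smoothing``-second moving-average signal within
    ``[t_on, t_on + response_window]``. The extremum, rather than the window
    mean, accommodates the delayed reflex responses seen after vagotomy.
    Returns NaN when the schedule holds no epoch for the pair.
    """
    epochs = [(t_on, t_off) for p, t_on, t_off in trace.schedule if p == pair]
    if not epochs:
        return float("nan")
    t = trace.time
    fs = 1.0 / float(np.median(np.diff(t)))
    k = max(int(round(smoothing * fs)), 1)
    smoothed = uniform_filter1d(trace.value, size=k, mode="nearest")
    changes = []
    for t_on, _t_off in epochs:
        base_mask = (t >= t_on - baseline_window) & (t < t_on)
        if not np.any(base_mask):
            raise ValueError(f"no samples in the baseline window before t={t_on}")
        baseline = float(trace.value[base_mask].mean())
        if baseline <= 0 and trace.modality in ("hr", "etco2"):
            raise ValueError(
                f"non-positive {trace.modality} baseline ({baseline:.3g}): "
                "invalid physiology"
            )
        resp_mask = (t >= t_on) & (t <= t_on + response_window)
        dev = smoothed[resp_mask] - baseline
        response = baseline + dev[np.argmax(np.abs(dev))]
        changes.append(100.0 * (response - baseline) / baseline)
    return float(np.mean(changes))


def extract_session(
    trace: PhysioTrace,
    cuff: ElectrodeCuff,
    baseline_window: float | None = None,
    response_window: float | None = None,
    smoothing: float = 2.0,
) -> PairResponseSet:
    """PairResponseSet for a whole sweep; unstimulated pairs are NaN.

    Defaults: baseline window = the full preceding off period, response
    window = the on period plus the off period (so delayed reflex responses
    within the inter-stimulus gap are captured).
    """
    if trace.schedule:
        on = trace.schedule[0][2] - trace.schedule[0][1]
        gaps = [trace.schedule[0][1]] + [
            trace.schedule[i + 1][1] - trace.schedule[i][2]
            for i in range(len(trace.schedule) - 1)
        ]
        off = float(min(gaps))
    else:
        on, off = 0.0, 0.0
    if baseline_window is None:
        baseline_window = off
    if response_window is None:
        # Stop short of the next onset so the smoothed neighbour response
        # cannot leak into this pair's window.
        response_window = on + max(off - 2.0 * smoothing, 0.0)
    values = np.full(cuff.n_pairs, np.nan)
    for pair in range(cuff.n_pairs):
        values[pair] = extract_pair_response(
            trace, pair, baseline_window, response_window, smoothing
        )
    return PairResponseSet(
        modality=trace.modality,
        values=values,
        animal_id=trace.animal_id,
        condition=trace.condition,
    )


def effective_pair_count(responses: PairResponseSet, fraction: float = 0.75) -> int:
    """Number of pairs eliciting at least ``fraction`` of the maximal response.

    Magnitudes are compared in absolute value; pairs without a measurement
    are ignored.
    """
    v = responses.values
    present = v[~np.isnan(v)]
    if present.size == 0:
        raise ValueError("no measured pairs")
    vmax = np.max(np.abs(present))
    return int(np.count_nonzero(np.abs(present) >= fraction * vmax))


def noise_floor(trace: PhysioTrace, smoothing: float = 2.0, z: float = 5.0) -> float:
    """% threshold below which an extracted response is indistinguishable
    from measurement noise.

    The sample-to-sample noise SD is estimated robustly from the first
    difference of the trace (MAD-based, insensitive to the step responses),
    scaled down by the smoothing window and up by ``z`` to bound the
    spurious extrema the extremum-based extraction picks up on a null
    epoch, then expressed as % of the signal level.
    """
    t = trace.time
    fs = 1.0 / float(np.median(np.diff(t)))
    diffs = np.diff(trace.value)
    sd = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2.0)
    k = max(int(round(smoothing * fs)), 1)
    level = float(np.median(trace.value))
    if level == 0:
        return 0.0
    return 100.0 * z * sd / np.sqrt(k) / abs(level)


def is_responsive(responses: PairResponseSet, floor: float) -> bool:
    """Whether a sweep shows any response above the trace's noise floor.

    A session in which no fibres of the target group were activated yields
    per-pair magnitudes that are all spurious noise extrema; such sessions
    carry no localizable signal and are excluded from maps and statistics.
    """
    v = np.abs(responses.values)
    present = v[~np.isnan(v)]
    if present.size == 0:
        return False
    return float(present.max()) > floor


def sector_indices(cuff: ElectrodeCuff, w: int) -> np.ndarray:
    """Angular-Voronoi sector index of every template pixel.

    A pixel belongs to the pair whose angle is nearest by wrapped angular
    distance; boundary ties go to the lower pair index.
    """
    x, y = template_coords(w)
    angles = xy_to_angle(x, y)
    dists = angular_distance(angles[..., None], cuff.angles[None, None, :])
    return np.argmin(dists, axis=-1)


def backproject(
    responses: PairResponseSet, cuff: ElectrodeCuff, w: int = 256
) -> PixelMap:
    """Paint |% change| per pair onto its angular sector, normalized to [0, 1].

    Every pixel of sector k (inside the nerve disc) receives
    ``|values[k]| / max|values|``; unstimulated pairs paint 0. Polarity is
    retained in the PairResponseSet, not in the map.
    """
    if responses.n_pairs != cuff.n_pairs:
        raise ValueError("response vector length must equal cuff.n_pairs")
    mags = np.abs(responses.values)
    mags = np.where(np.isnan(mags), 0.0, mags)
    vmax = mags.max()
    scaled = mags / vmax if vmax > 0 else mags
    grid = scaled[sector_indices(cuff, w)]
    grid[~unit_disc_mask(w)] = 0.0
    return PixelMap(
        grid=grid,
        group=response_group(responses.modality, responses.condition),
        frame="raw",
        animal_id=responses.animal_id,
        technique="svns",
    )


def build_response_atlas(maps: list[PixelMap]) -> AtlasMap:
    """Cross-animal response atlas: mean of per-animal [0,1] maps, re-scaled
    so the atlas maximum is 1."""
    atlas = build_atlas(maps)
    peak = atlas.grid.max()
    grid = atlas.grid / peak if peak > 0 else atlas.grid
    return AtlasMap(
        grid=grid,
        group=atlas.group,
        frame="rotated",
        technique="svns",
        n_animals=atlas.n_animals,
    )
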