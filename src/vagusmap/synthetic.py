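"""Synthetic porcine cervical vagus cross-sections and stimulation sessions.

The generator emulates the study conditions every downstream stage is tested
against: nerves of ~2.68 mm² cross-sectional area carrying ~29 fascicles
with the observed per-organ composition (≈1.2 cardiac, 10.2 recurrent
laryngeal, 10.4 pulmonary, 1.4 cardiopulmonary, 6 laryngopulmonary), a
bimodal afferent/efferent angular organization (efferent-type fascicles
clustered about a per-animal axis, afferent-type on the opposite side),
purely cardiac fascicles always efferent and cardiopulmonary fascicles
afferent. Stimulation sessions sweep a 14-pair cuff sequentially and paint
heart-rate, end-tidal-CO2 and laryngeal-EMG responses onto a baseline
trace via a deterministic threshold/Gaussian-selectivity activation model,
with vagotomy state gating the efferent and reflex afferent heart-rate
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    ElectrodeCuff,
    Fascicle,
    NerveCrossSection,
    angular_distance,
    project_to_template,
)
from .mapping import group_of

MODALITIES = ("hr", "etco2", "emg_rms")
CONDITIONS = ("pre_vagotomy", "post_right_vagotomy", "post_bilateral_vagotomy")

# Organ-class composition: mean ± SD fascicle counts per nerve.
DEFAULT_MEAN_COUNTS = {
    "cardiac": 1.2,
    "laryngeal": 10.2,
    "pulmonary": 10.4,
    "cardiopulmonary": 1.4,
    "laryngopulmonary": 6.0,
}
DEFAULT_COUNT_SD = {
    "cardiac": 0.5,
    "laryngeal": 1.8,
    "pulmonary": 1.9,
    "cardiopulmonary": 0.6,
    "laryngopulmonary": 2.0,
}

# Fibre-type mixture per organ class (afferent, efferent, mixed). Purely
# cardiac fascicles are exclusively efferent; cardiopulmonary fascicles are
# afferent; laryngeal fascicles are predominantly efferent and pulmonary
# predominantly afferent.
FIBRE_MIX = {
    "cardiac": (0.0, 1.0, 0.0),
    "cardiopulmonary": (1.0, 0.0, 0.0),
    "laryngeal": (0.0, 0.824, 0.176),
    "pulmonary": (0.885, 0.0, 0.115),
    "laryngopulmonary": (0.567, 0.133, 0.300),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level ground truth for the synthetic generator."""

    n_animals: int = 5
    mean_counts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_COUNTS)
    )
    count_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNT_SD))
    nerve_area: float = 2.68  # mm²
    efferent_axis: float | None = None  # degrees; None → drawn per animal
    afferent_efferent_separation: float = 180.0  # degrees
    angular_spread: float = 25.0  # degrees, SD of each angular cluster
    fascicle_radius_range: tuple[float, float] = (0.06, 0.14)  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if any(v < 0 for v in self.mean_counts.values()):
            raise ValueError("mean counts must be >= 0")
        if not 0 <= self.afferent_efferent_separation < 360:
            raise ValueError("separation must lie in [0, 360)")

    @property
    def nerve_radius(self) -> float:
        return float(np.sqrt(self.nerve_area / np.pi))


@dataclass(frozen=True)
class StimulationProtocol:
    """One trial-and-error stimulation block for one target function."""

    target: str  # laryngeal | pulmonary | cardiac_efferent | cardiac_afferent
    amplitude: float  # mA
    pulse_width: float  # ms
    frequency: float  # Hz
    on_duration: float  # s
    off_duration: float  # s
    pairs_stimulated: tuple[int, ...]

    def __post_init__(self) -> None:
        if min(
            self.amplitude,
            self.pulse_width,
            self.frequency,
            self.on_duration,
            self.off_duration,
        ) <= 0:
            raise ValueError("protocol parameters must be positive")
        if any(p < 0 for p in self.pairs_stimulated):
            raise ValueError("pair indices must be >= 0")


def default_protocol(target: str, n_pairs: int = 14) -> StimulationProtocol:
    """Starting stimulation parameters per target function.

    Cardiac efferent (nerve intact): all pairs, 1 mA, 1 ms, 10 Hz, 15 s
    on/off. Cardiac afferent (post-vagotomy): every 2nd pair, 5 mA, 2 ms,
    10 Hz, 15 s on with 60 s off to accommodate the delayed reflex.
    Pulmonary: all pairs, 0.8 mA, 50 µs, 20 Hz, 15 s on/off. Laryngeal:
    all pairs, 0.2 mA, 50 µs, 20 Hz, 5 s on/off.
    """
    all_pairs = tuple(range(n_pairs))
    presets = {
        "laryngeal": dict(
            amplitude=0.2, pulse_width=0.05, frequency=20.0,
            on_duration=5.0, off_duration=5.0, pairs_stimulated=all_pairs,
        ),
        "pulmonary": dict(
            amplitude=0.8, pulse_width=0.05, frequency=20.0,
            on_duration=15.0, off_duration=15.0, pairs_stimulated=all_pairs,
        ),
        "cardiac_efferent": dict(
            amplitude=1.0, pulse_width=1.0, frequency=10.0,
            on_duration=15.0, off_duration=15.0, pairs_stimulated=all_pairs,
        ),
        "cardiac_afferent": dict(
            amplitude=5.0, pulse_width=2.0, frequency=10.0,
            on_duration=15.0, off_duration=60.0,
            pairs_stimulated=all_pairs[::2],
        ),
    }
    if target not in presets:
        raise ValueError(f"unknown stimulation target {target!r}")
    return StimulationProtocol(target=target, **presets[target])


@dataclass(frozen=True)
class ActivationModel:
    """Deterministic threshold + Gaussian-selectivity response model.

    A fascicle of a responsive group is activated when the pulse amplitude
    reaches its group threshold; its contribution is weighted by
    exp(−Δθ²/(2σ²)) with Δθ the angular distance between fascicle and
    stimulated pair. The response magnitude of a pair is
    gain × Σ(weight × template area), signed by pathway. Laryngeal fibres
    have a far lower threshold than cardiac ones, so cardiac-level
    amplitudes always co-activate the larynx.
    """

    thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "laryngeal": 0.15,
            "pulmonary": 0.8,
            "cardiac_efferent": 1.0,
            "cardiac_afferent": 5.0,
        }
    )  # mA
    angular_sigma: float = 25.0  # degrees
    gains: dict[str, float] = field(
        default_factory=lambda: {"hr": 160.0, "etco2": 900.0, "emg_rms": 400.0}
    )  # % change per unit activated template area
    afferent_delay: float = 10.0  # s, reflex latency post-vagotomy
    afferent_polarity: str = "tachycardia"  # per-animal reflex direction
    vagotomy_state: str = "intact"  # intact | right_distal | right_and_left
    baselines: dict[str, float] = field(
        default_factory=lambda: {"hr": 80.0, "etco2": 40.0, "emg_rms": 1.0}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"hr": 0.5, "etco2": 0.2, "emg_rms": 0.02}
    )
    sample_rate: float = 10.0  # samples/s

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be > 0")
        if self.angular_sigma <= 0:
            raise ValueError("angular_sigma must be > 0")
        if self.afferent_polarity not in ("tachycardia", "bradycardia"):
            raise ValueError(f"unknown polarity {self.afferent_polarity!r}")
        if self.vagotomy_state not in ("intact", "right_distal", "right_and_left"):
            raise ValueError(f"unknown vagotomy state {self.vagotomy_state!r}")


@dataclass(frozen=True)
class PhysioTrace:
    """A uniformly sampled physiological signal with its stimulation schedule."""

    modality: str
    time: np.ndarray  # s
    value: np.ndarray
    schedule: tuple[tuple[int, float, float], ...]  # (pair, t_on, t_off)
    animal_id: str = ""
    condition: str = "pre_vagotomy"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and value must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)
        object.__setattr__(self, "schedule", tuple(tuple(e) for e in self.schedule))


def _animal_rng(seed: int, animal_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(animal_index)]))


def _relax_overlaps(
    xy: np.ndarray,
    rf: np.ndarray,
    r_nerve: float,
    rng: np.random.Generator,
    max_iter: int = 800,
) -> bool:
    """Push overlapping fascicle discs apart until the packing is valid.

    Pairwise overlaps are resolved by moving both discs symmetrically along
    their centre line; discs pushed past the boundary are clamped back
    radially. The symmetric pushes leave the drawn angular distribution
    unbiased. Returns False if the packing has not converged, in which case
    the caller redraws the positions. Modifies ``xy`` in place.
    """
    n = len(rf)
    margin = 1.001
    best = n * n
    stall = 0
    for _ in range(max_iter):
        n_overlap = 0
        touched = np.zeros(n, dtype=bool)
        for i in range(n):
            d = xy[i + 1 :] - xy[i]
            dist = np.hypot(d[:, 0], d[:, 1])
            min_d = (rf[i] + rf[i + 1 :]) * margin
            for off in np.nonzero(dist < min_d)[0]:
                j = i + 1 + off
                if dist[off] < 1e-12:
                    direction = rng.normal(size=2)
                    direction /= np.hypot(*direction)
                else:
                    direction = d[off] / dist[off]
                # slight over-relaxation helps chains of contacts settle
                push = 0.55 * (min_d[off] - dist[off])
                xy[i] -= direction * push
                xy[j] += direction * push
                touched[i] = touched[j] = True
                n_overlap += 1
        r = np.hypot(xy[:, 0], xy[:, 1])
        limit = r_nerve - rf * 1.05
        outside = r > limit
        if np.any(outside):
            xy[outside] *= (limit[outside] / r[outside])[:, None]
        if n_overlap == 0 and not np.any(outside):
            return True
        if n_overlap < best:
            best, stall = n_overlap, 0
        else:
            stall += 1
            if stall >= 40:
                # jammed cycle: jitter the discs still in contact
                jitter = 0.3 * rf[touched, None] * rng.normal(size=(touched.sum(), 2))
                xy[touched] += jitter
                stall = 0
    return False


def generate_cross_section(
    config: SyntheticConfig,
    animal_index: int,
    technique: str = "microct",
    max_restarts: int = 40,
) -> tuple[NerveCrossSection, dict]:
    """Generate one nerve cross-section plus its placement ground truth.

    Fascicle counts are rounded normal draws (floored at 0, cardiac at 1);
    fibre labels follow the per-class mixtures; efferent fascicles cluster
    about the animal's efferent axis, afferent ones about axis + separation,
    mixed ones pick a side at random. Placement is rejection-sampled so
    fascicle discs stay inside the boundary and pairwise non-overlapping.
    """
    rng = _animal_rng(config.seed, animal_index)
    r_nerve = config.nerve_radius
    if config.efferent_axis is None:
        axis = float(rng.uniform(0.0, 360.0))
    else:
        axis = float(config.efferent_axis) % 360.0
    aff_axis = (axis + config.afferent_efferent_separation) % 360.0

    counts: dict[str, int] = {}
    for organ, mean in config.mean_counts.items():
        sd = config.count_sd.get(organ, 0.0)
        n = int(round(rng.normal(mean, sd))) if sd > 0 else int(round(mean))
        n = max(n, 0)
        if organ == "cardiac":
            n = max(n, 1)
        counts[organ] = n

    lo, hi = config.fascicle_radius_range
    specs: list[tuple[str, str, float, float]] = []  # (organ, fibre, mu, rf)
    for organ in sorted(counts):
        p_aff, p_eff, p_mix = FIBRE_MIX[organ]
        for _ in range(counts[organ]):
            fibre = str(
                rng.choice(["afferent", "efferent", "mixed"], p=[p_aff, p_eff, p_mix])
            )
            if fibre == "efferent":
                mu = axis
            elif fibre == "afferent":
                mu = aff_axis
            else:
                mu = axis if rng.random() < 0.5 else aff_axis
            specs.append((organ, fibre, mu, float(rng.uniform(lo, hi))))

    rf = np.array([s[3] for s in specs])
    for _attempt in range(max_restarts):
        theta = np.array(
            [rng.normal(mu, config.angular_spread) for _, _, mu, _ in specs]
        )
        rad = (r_nerve - rf * 1.05) * np.sqrt(rng.uniform(size=len(specs)))
        xy = np.stack(
            [rad * np.sin(np.deg2rad(theta)), rad * np.cos(np.deg2rad(theta))],
            axis=1,
        )
        if _relax_overlaps(xy, rf, r_nerve, rng):
            break
    else:
        raise RuntimeError(
            "fascicle placement failed after bounded retries; "
            "lower the counts or enlarge the nerve"
        )

    fascicles = [
        Fascicle(
            id=f"a{animal_index}_f{k}",
            cx=float(xy[k, 0]),
            cy=float(xy[k, 1]),
            area=float(np.pi * rf[k] ** 2),
            organ_label=organ,
            fibre_label=fibre,
        )
        for k, (organ, fibre, _, _) in enumerate(specs)
    ]

    nerve = NerveCrossSection(
        animal_id=f"animal_{animal_index:02d}",
        nerve_radius=r_nerve,
        fascicles=tuple(fascicles),
        technique=technique,
    )
    ground_truth = {
        "efferent_axis": axis,
        "afferent_axis": aff_axis,
        "separation": config.afferent_efferent_separation,
        "counts": counts,
    }
    return nerve, ground_truth


def generate_cohort(
    config: SyntheticConfig, technique: str = "microct"
) -> tuple[list[NerveCrossSection], list[dict]]:
    """Generate the full cohort of nerves defined by the config."""
    nerves, truths = [], []
    for i in range(config.n_animals):
        nerve, gt = generate_cross_section(config, i, technique=technique)
        nerves.append(nerve)
        truths.append(gt)
    return nerves, truths


def draw_afferent_polarity(seed: int, animal_index: int) -> str:
    """Per-animal reflex direction of afferent stimulation, fixed 6:4 tachy:brady."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(animal_index), 7])
    )
    return "tachycardia" if rng.random() < 0.6 else "bradycardia"


def _responsive_groups(modality: str, model: ActivationModel) -> list[tuple[str, float, float]]:
    """(group, sign, delay) triples driving a modality under the model's state.

    Heart rate: with the nerve intact the direct cardiac-efferent pathway
    produces bradycardia with no appreciable latency. After right distal
    vagotomy the efferent pathway is cut and stimulation instead evokes a
    delayed reflex through cardiac afferents, tachy- or bradycardic per
    animal. After additional left vagotomy the reflex bradycardia (which ran
    through left-vagal efferents) is abolished while reflex tachycardia
    (sympathetically mediated) persists. ETCO2 follows pulmonary fibres and
    laryngeal EMG follows laryngeal fibres irrespective of cervical
    vagotomy state (their pathways are outside the gated loop).
    """
    if modality == "etco2":
        return [("pulmonary", -1.0, 0.0)]
    if modality == "emg_rms":
        return [("laryngeal", +1.0, 0.0)]
    # hr
    state = model.vagotomy_state
    if state == "intact":
        return [("cardiac_efferent", -1.0, 0.0)]
    reflex_sign = 1.0 if model.afferent_polarity == "tachycardia" else -1.0
    if state == "right_distal":
        return [("cardiac_afferent", reflex_sign, model.afferent_delay)]
    # right_and_left: only the sympathetic (tachycardic) reflex survives
    if model.afferent_polarity == "tachycardia":
        return [("cardiac_afferent", reflex_sign, model.afferent_delay)]
    return []


def activated_fascicles(
    nerve: NerveCrossSection,
    cuff: ElectrodeCuff,
    group: str,
    pair: int,
    amplitude: float,
    model: ActivationModel,
) -> list[tuple[Fascicle, float]]:
    """(fascicle, weight) pairs activated by one pair at one amplitude."""
    out = []
    pair_angle = float(cuff.angles[pair])
    for f in nerve.fascicles:
        if group not in group_of(f):
            continue
        if amplitude < model.thresholds[group]:
            continue
        theta, _, _ = project_to_template(f, nerve, cuff)
        dtheta = float(angular_distance(theta, pair_angle))
        out.append(
            (f, float(np.exp(-(dtheta**2) / (2.0 * model.angular_sigma**2))))
        )
    return out


def pair_response_magnitude(
    nerve: NerveCrossSection,
    cuff: ElectrodeCuff,
    modality: str,
    pair: int,
    amplitude: float,
    model: ActivationModel,
) -> tuple[float, float]:
    """Signed % response magnitude and its delay for one pair and modality."""
    magnitude = 0.0
    delay = 0.0
    for group, sign, grp_delay in _responsive_groups(modality, model):
        total = 0.0
        for f, weight in activated_fascicles(nerve, cuff, group, pair, amplitude, model):
            _, _, area = project_to_template(f, nerve, cuff)
            total += weight * area
        if total > 0:
            magnitude += sign * model.gains[modality] * total
            delay = max(delay, grp_delay)
    return magnitude, delay


def _condition_of(model: ActivationModel) -> str:
    return {
        "intact": "pre_vagotomy",
        "right_distal": "post_right_vagotomy",
        "right_and_left": "post_bilateral_vagotomy",
    }[model.vagotomy_state]


def simulate_session(
    nerve: NerveCrossSection,
    cuff: ElectrodeCuff,
    protocol: StimulationProtocol,
    model: ActivationModel,
    seed: int = 0,
    magnitude_override: dict[int, float] | None = None,
) -> list[PhysioTrace]:
    """Simulate one sequential stimulation sweep; one trace per modality.

    The sweep starts with one off period of baseline, then stimulates each
    protocol pair for ``on_duration`` followed by ``off_duration`` of rest.
    During a pair's (possibly delayed) response window the baseline is
    scaled by the pair's % response magnitude; Gaussian noise is added
    throughout. ``magnitude_override`` injects known per-pair % magnitudes
    (applied to every modality) in place of the activation model, for
    round-trip checks.
    """
    if any(p >= cuff.n_pairs for p in protocol.pairs_stimulated):
        raise ValueError("protocol stimulates pairs outside the cuff")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    fs = model.sample_rate
    schedule = []
    t = protocol.off_duration
    for pair in protocol.pairs_stimulated:
        schedule.append((int(pair), t, t + protocol.on_duration))
        t += protocol.on_duration + protocol.off_duration
    total = t + protocol.off_duration  # tail so delayed responses resolve
    n = int(round(total * fs)) + 1
    time = np.arange(n) / fs

    traces = []
    for modality in MODALITIES:
        base = model.baselines[modality]
        value = np.full(n, base, dtype=float)
        for pair, t_on, t_off in schedule:
            if magnitude_override is not None:
                mag = float(magnitude_override.get(pair, 0.0))
                delay = 0.0
            else:
                mag, delay = pair_response_magnitude(
                    nerve, cuff, modality, pair, protocol.amplitude, model
                )
            if mag == 0.0:
                continue
            window = (time >= t_on + delay) & (time < t_off + delay)
            value[window] = base * (1.0 + mag / 100.0)
        sd = model.noise_sd[modality]
        if sd > 0:
            value = value + rng.normal(0.0, sd, size=n)
        traces.append(
            PhysioTrace(
                modality=modality,
                time=time,
                value=value,
                schedule=tuple(schedule),
                animal_id=nerve.animal_id,
                condition=_condition_of(model),
            )
        )
    return traces


def noise_free(model: ActivationModel) -> ActivationModel:
    """Copy of the model with all noise and reflex delay removed."""
    return ActivationModel(
        thresholds=dict(model.thresholds),
        angular_sigma=model.angular_sigma,
        gains=dict(model.gains),
        afferent_delay=0.0,
        afferent_polarity=model.afferent_polarity,
        vagotomy_state=model.vagotomy_state,
        baselines=dict(model.baselines),
        noise_sd={m: 0.0 for m in MODALITIES},
        sample_rate=model.sample_rate,
    )
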