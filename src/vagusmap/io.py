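"""File formats, run configuration and the end-to-end pipeline runner.

Formats are deliberately plain: fascicle tables and traces as CSV with JSON
sidecars, template maps as single-channel float TIFF with JSON metadata,
overlap matrices as CSV, run summaries as JSON. A run is fully determined
by its YAML config and seed; every output carries the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ElectrodeCuff, Fascicle, NerveCrossSection, angular_distance
from .mapping import (
    GROUPS,
    AtlasMap,
    PixelMap,
    alignment_angle,
    build_atlas,
    rasterize_group,
    rotate_map,
)
from .responses import (
    PairResponseSet,
    backproject,
    build_response_atlas,
    effective_pair_count,
    extract_session,
    is_responsive,
    noise_floor,
)
from .stats import (
    OverlapMatrix,
    angular_group_comparison,
    angular_separation_summary,
    center_of_mass,
    circular_mean_separation,
    cross_technique_overlap,
    overlap_matrix,
    relative_overlap,
)
from .synthetic import (
    ActivationModel,
    PhysioTrace,
    SyntheticConfig,
    default_protocol,
    draw_afferent_polarity,
    generate_cross_section,
    simulate_session,
)

FASCICLE_COLUMNS = ["id", "cx_mm", "cy_mm", "area_mm2", "organ_label", "fibre_label"]


# ---------------------------------------------------------------------------
# fascicle tables


def write_fascicle_table(nerve: NerveCrossSection, csv_path: str | Path) -> Path:
    """Write a cross-section as CSV plus a JSON sidecar (canonical formats)."""
    csv_path = Path(csv_path)
    # repr gives the shortest digit string that round-trips the float
    # exactly, so re-serialization is byte-identical
    rows = [
        {
            "id": f.id,
            "cx_mm": repr(f.cx),
            "cy_mm": repr(f.cy),
            "area_mm2": repr(f.area),
            "organ_label": f.organ_label,
            "fibre_label": f.fibre_label,
        }
        for f in nerve.fascicles
    ]
    pd.DataFrame(rows, columns=FASCICLE_COLUMNS).to_csv(csv_path, index=False)
    sidecar = {
        "animal_id": nerve.animal_id,
        "nerve_radius_mm": float(nerve.nerve_radius),
        "technique": nerve.technique,
    }
    csv_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return csv_path


def read_fascicle_table(csv_path: str | Path) -> NerveCrossSection:
    """Read a fascicle CSV + sidecar back into a validated cross-section.

    Row order is preserved; label or geometry problems raise with the
    offending row number.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype=str)
    if list(df.columns) != FASCICLE_COLUMNS:
        raise ValueError(
            f"{csv_path}: expected header {','.join(FASCICLE_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    fascicles = []
    for i, row in df.iterrows():
        try:
            fascicles.append(
                Fascicle(
                    id=str(row["id"]),
                    cx=float(row["cx_mm"]),
                    cy=float(row["cy_mm"]),
                    area=float(row["area_mm2"]),
                    organ_label=str(row["organ_label"]),
                    fibre_label=str(row["fibre_label"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{csv_path} row {i + 2}: {exc}") from exc
    try:
        return NerveCrossSection(
            animal_id=sidecar["animal_id"],
            nerve_radius=float(sidecar["nerve_radius_mm"]),
            fascicles=tuple(fascicles),
            technique=sidecar["technique"],
        )
    except ValueError as exc:
        raise ValueError(f"{csv_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# traces


def write_trace_csv(trace: PhysioTrace, csv_path: str | Path) -> Path:
    """Trace as CSV (time_s, value, pair_index, stim_on) + JSON sidecar."""
    csv_path = Path(csv_path)
    pair_col = np.full(trace.time.size, -1, dtype=int)
    on_col = np.zeros(trace.time.size, dtype=int)
    for pair, t_on, t_off in trace.schedule:
        mask = (trace.time >= t_on) & (trace.time < t_off)
        pair_col[mask] = pair
        on_col[mask] = 1
    pd.DataFrame(
        {
            "time_s": trace.time,
            "value": trace.value,
            "pair_index": pair_col,
            "stim_on": on_col,
        }
    ).to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "modality": trace.modality,
        "animal_id": trace.animal_id,
        "condition": trace.condition,
        "schedule": [[int(p), float(a), float(b)] for p, a, b in trace.schedule],
    }
    csv_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return csv_path


def read_trace_csv(csv_path: str | Path) -> PhysioTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return PhysioTrace(
        modality=sidecar["modality"],
        time=df["time_s"].to_numpy(float),
        value=df["value"].to_numpy(float),
        schedule=tuple((int(p), float(a), float(b)) for p, a, b in sidecar["schedule"]),
        animal_id=sidecar["animal_id"],
        condition=sidecar["condition"],
    )


# ---------------------------------------------------------------------------
# maps and matrices


def write_map(pixel_map: PixelMap, tiff_path: str | Path, **extra) -> Path:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, pixel_map.grid.astype(np.float32))
    meta = {
        "group": pixel_map.group,
        "frame": pixel_map.frame,
        "w": pixel_map.w,
        "animal_id": pixel_map.animal_id,
        "technique": pixel_map.technique,
    }
    if isinstance(pixel_map, AtlasMap):
        meta["n_animals"] = pixel_map.n_animals
    meta.update(extra)
    tiff_path.with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    return tiff_path


def read_map(tiff_path: str | Path) -> PixelMap:
    tiff_path = Path(tiff_path)
    grid = np.asarray(tifffile.imread(tiff_path), dtype=float)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    cls = AtlasMap if "n_animals" in meta else PixelMap
    kwargs = dict(
        grid=grid,
        group=meta["group"],
        frame=meta["frame"],
        animal_id=meta.get("animal_id", ""),
        technique=meta.get("technique", "microct"),
    )
    if cls is AtlasMap:
        kwargs["n_animals"] = meta["n_animals"]
    return cls(**kwargs)


def write_overlap_csv(m: OverlapMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(m.matrix, index=list(m.groups), columns=list(m.groups))
    df.to_csv(path, float_format="%.6g")
    return path


def read_overlap_csv(path: str | Path, technique: str) -> OverlapMatrix:
    df = pd.read_csv(path, index_col=0)
    return OverlapMatrix(
        technique=technique, matrix=df.to_numpy(float), groups=tuple(df.columns)
    )


# ---------------------------------------------------------------------------
# run configuration


def _strict_fields(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    n_microct: int = 5
    n_svns: int = 10
    cuff: ElectrodeCuff = field(default_factory=ElectrodeCuff)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    activation: ActivationModel = field(default_factory=ActivationModel)
    w: int = 256
    tau_atlas: float = 0.5
    smoothing: float = 2.0
    adjust_method: str = "tukey"
    circular: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _strict_fields(
            raw,
            {
                "seed", "cohort", "cuff", "synthetic", "activation",
                "mapping", "stats",
            },
            "config",
        )
        kwargs: dict = {"seed": int(raw.get("seed", 0))}
        cohort = raw.get("cohort", {})
        _strict_fields(cohort, {"n_microct", "n_svns"}, "cohort")
        kwargs["n_microct"] = int(cohort.get("n_microct", 5))
        kwargs["n_svns"] = int(cohort.get("n_svns", 10))
        cuff = dict(raw.get("cuff", {}))
        _strict_fields(
            cuff,
            {"n_pairs", "pair_angles", "inner_diameter", "pad_width", "pad_length"},
            "cuff",
        )
        if "pair_angles" in cuff and cuff["pair_angles"] is not None:
            cuff["pair_angles"] = tuple(float(a) for a in cuff["pair_angles"])
        kwargs["cuff"] = ElectrodeCuff(**cuff)
        syn = dict(raw.get("synthetic", {}))
        _strict_fields(
            syn,
            {f.name for f in dataclasses.fields(SyntheticConfig)},
            "synthetic",
        )
        if "fascicle_radius_range" in syn:
            syn["fascicle_radius_range"] = tuple(syn["fascicle_radius_range"])
        syn.setdefault("seed", kwargs["seed"])
        kwargs["synthetic"] = SyntheticConfig(**syn)
        act = dict(raw.get("activation", {}))
        _strict_fields(
            act,
            {f.name for f in dataclasses.fields(ActivationModel)},
            "activation",
        )
        kwargs["activation"] = ActivationModel(**act)
        mapping = raw.get("mapping", {})
        _strict_fields(mapping, {"w", "tau_atlas", "smoothing"}, "mapping")
        kwargs["w"] = int(mapping.get("w", 256))
        kwargs["tau_atlas"] = float(mapping.get("tau_atlas", 0.5))
        kwargs["smoothing"] = float(mapping.get("smoothing", 2.0))
        stats_blk = raw.get("stats", {})
        _strict_fields(stats_blk, {"adjust_method", "circular"}, "stats")
        kwargs["adjust_method"] = str(stats_blk.get("adjust_method", "tukey"))
        kwargs["circular"] = bool(stats_blk.get("circular", False))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline


def run_microct_arm(config: RunConfig) -> dict:
    """Generate the ex vivo arm: per-animal binary maps, atlases, CoMs."""
    syn = replace(config.synthetic, n_animals=config.n_microct)
    per_animal = []
    for i in range(config.n_microct):
        nerve, truth = generate_cross_section(syn, i, technique="microct")
        raw_maps = {
            g: rasterize_group(nerve, config.cuff, g, config.w) for g in GROUPS
        }
        angle = alignment_angle(raw_maps["cardiac_efferent"])
        rotated = {g: rotate_map(m, -angle) for g, m in raw_maps.items()}
        per_animal.append(
            {
                "nerve": nerve,
                "truth": truth,
                "maps": rotated,
                "alignment_angle": angle,
                "coms": {
                    g: center_of_mass(m)
                    for g, m in rotated.items()
                    if not m.is_empty()
                },
            }
        )
    atlases = {
        g: build_atlas([a["maps"][g] for a in per_animal if not a["maps"][g].is_empty()])
        for g in GROUPS
    }
    return {"per_animal": per_animal, "atlases": atlases}


_SESSION_PLAN = (
    # (target, modality of interest, vagotomy state)
    ("laryngeal", "emg_rms", "intact"),
    ("pulmonary", "etco2", "intact"),
    ("cardiac_efferent", "hr", "intact"),
    ("cardiac_afferent", "hr", "right_distal"),
)


def run_svns_arm(config: RunConfig) -> dict:
    """Simulate the in vivo arm and extract per-animal response maps."""
    syn = replace(config.synthetic, n_animals=config.n_svns)
    per_animal = []
    for i in range(config.n_svns):
        nerve, truth = generate_cross_section(syn, i, technique="svns")
        polarity = draw_afferent_polarity(config.seed, i)
        raw_maps: dict[str, PixelMap] = {}
        responses: dict[str, PairResponseSet] = {}
        responsive: dict[str, bool] = {}
        for target, modality, state in _SESSION_PLAN:
            protocol = default_protocol(target, config.cuff.n_pairs)
            model = replace(
                config.activation,
                vagotomy_state=state,
                afferent_polarity=polarity,
            )
            traces = simulate_session(
                nerve, config.cuff, protocol, model,
                seed=config.seed * 1000 + i,
            )
            trace = next(t for t in traces if t.modality == modality)
            delay = model.afferent_delay if state != "intact" else 0.0
            baseline_window = max(
                protocol.off_duration - delay - 2 * config.smoothing,
                2 * config.smoothing,
            )
            resp = extract_session(
                trace, config.cuff,
                baseline_window=baseline_window,
                smoothing=config.smoothing,
            )
            responses[target] = resp
            responsive[target] = is_responsive(
                resp, noise_floor(trace, smoothing=config.smoothing)
            )
            if responsive[target]:
                raw_maps[target] = backproject(resp, config.cuff, config.w)
            else:
                # no localizable signal: contribute an empty map
                raw_maps[target] = PixelMap(
                    grid=np.zeros((config.w, config.w)),
                    group=target,
                    frame="raw",
                    animal_id=nerve.animal_id,
                    technique="svns",
                )
        angle = alignment_angle(raw_maps["cardiac_efferent"])
        rotated = {g: rotate_map(m, -angle) for g, m in raw_maps.items()}
        per_animal.append(
            {
                "nerve": nerve,
                "truth": truth,
                "polarity": polarity,
                "responses": responses,
                "maps": rotated,
                "alignment_angle": angle,
                "coms": {
                    g: center_of_mass(m)
                    for g, m in rotated.items()
                    if not m.is_empty()
                },
                "effective_pairs": {
                    g: effective_pair_count(r)
                    for g, r in responses.items()
                    if responsive[g]
                },
            }
        )
    atlases = {
        g: build_response_atlas(
            [a["maps"][g] for a in per_animal if not a["maps"][g].is_empty()]
        )
        for g in GROUPS
    }
    return {"per_animal": per_animal, "atlases": atlases}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic-cohort pipeline and return the results bundle.

    The bundle holds both arms (per-animal maps, atlases, CoMs), the angular
    comparisons, CE–CA separation summaries, overlap matrices (per-animal
    mean and atlas-based) and cross-technique overlaps, plus a
    JSON-serializable ``summary``. When ``out_dir`` is given, maps, tables
    and the summary are written beneath it.
    """
    micro = run_microct_arm(config)
    svns = run_svns_arm(config)

    results: dict = {"microct": micro, "svns": svns}
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_microct": config.n_microct,
        "n_svns": config.n_svns,
    }

    for tech, arm in (("microct", micro), ("svns", svns)):
        coms = [c for a in arm["per_animal"] for c in a["coms"].values()]
        comparison = angular_group_comparison(
            coms, method=config.adjust_method, circular=config.circular
        )
        arm["comparison"] = comparison
        ce = [a["coms"]["cardiac_efferent"] for a in arm["per_animal"]
              if "cardiac_efferent" in a["coms"]]
        ca = [a["coms"]["cardiac_afferent"] for a in arm["per_animal"]
              if "cardiac_afferent" in a["coms"]]
        sep_mean, sep_sd = angular_separation_summary(ce, ca)
        arm["ce_ca_separation"] = (sep_mean, sep_sd)
        sep_circ = circular_mean_separation(ce, ca)
        atlas_sep = float(
            angular_distance(
                center_of_mass(arm["atlases"]["cardiac_efferent"]).angle,
                center_of_mass(arm["atlases"]["cardiac_afferent"]).angle,
            )
        )
        arm["ce_ca_separation_circular"] = sep_circ
        arm["ce_ca_separation_atlas"] = atlas_sep

        per_matrices = [
            overlap_matrix(a["maps"], tau=1e-12 if tech == "microct" else 0.5)
            for a in arm["per_animal"]
        ]
        arm["mean_overlap"] = OverlapMatrix(
            technique=tech,
            matrix=np.mean([m.matrix for m in per_matrices], axis=0),
        )
        arm["atlas_overlap"] = overlap_matrix(
            arm["atlases"], tau=config.tau_atlas, technique=tech
        )
        summary[tech] = {
            "anova_F": comparison.f_statistic,
            "anova_p": comparison.p_value,
            "pairwise": {
                f"{c.group_a}|{c.group_b}": {
                    "F": c.f_statistic, "p": c.p_value, "p_adj": c.p_adjusted,
                }
                for c in comparison.pairwise
            },
            "ce_ca_separation_mean_deg": sep_mean,
            "ce_ca_separation_sd_deg": sep_sd,
            "ce_ca_separation_circular_deg": sep_circ,
            "ce_ca_separation_atlas_deg": atlas_sep,
            "mean_overlap": arm["mean_overlap"].matrix.tolist(),
            "atlas_overlap": arm["atlas_overlap"].matrix.tolist(),
            "relative_overlap_pct": {
                f"{a}|{b}": relative_overlap(arm["atlas_overlap"], a, b)
                for a in GROUPS for b in GROUPS
                if a != b and arm["atlas_overlap"].diag(a) > 0
            },
        }

    summary["svns"]["effective_pairs_mean"] = {
        g: float(
            np.mean(
                [
                    a["effective_pairs"][g]
                    for a in svns["per_animal"]
                    if g in a["effective_pairs"]
                ]
            )
        )
        for g in GROUPS
    }
    summary["between_techniques"] = {
        g: cross_technique_overlap(
            micro["atlases"][g], svns["atlases"][g], tau=config.tau_atlas
        )
        for g in GROUPS
    }
    results["summary"] = summary

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stamp = {"seed": config.seed, "config_hash": config.config_hash()}
        for tech, arm in (("microct", micro), ("svns", svns)):
            tech_dir = out_dir / tech
            tech_dir.mkdir(exist_ok=True)
            for a in arm["per_animal"]:
                aid = a["nerve"].animal_id
                write_fascicle_table(a["nerve"], tech_dir / f"{aid}_fascicles.csv")
                for g, m in a["maps"].items():
                    write_map(
                        m, tech_dir / f"{aid}_{g}.tiff",
                        alignment_angle=a["alignment_angle"], **stamp,
                    )
            for g, atlas in arm["atlases"].items():
                write_map(atlas, tech_dir / f"atlas_{g}.tiff", **stamp)
            write_overlap_csv(arm["mean_overlap"], tech_dir / "overlap_mean.csv")
            write_overlap_csv(arm["atlas_overlap"], tech_dir / "overlap_atlas.csv")
            pd.DataFrame(
                [
                    {
                        "animal_id": c.animal_id, "group": c.group,
                        "technique": c.technique, "angle_deg": c.angle,
                        "radius": c.radius, "degenerate": c.degenerate,
                    }
                    for a in arm["per_animal"] for c in a["coms"].values()
                ]
            ).to_csv(tech_dir / "coms.csv", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return results


def replay_reference_overlaps() -> dict:
    """Relative overlaps recomputed from the reference matrices.

    Feeds the reported per-technique area/overlap matrices through
    ``relative_overlap`` and returns the integer percents, keyed
    ``technique -> "A|B"``.
    """
    from .reference import MICROCT_MATRIX, SVNS_MATRIX

    out = {}
    for m in (MICROCT_MATRIX, SVNS_MATRIX):
        out[m.technique] = {
            f"{a}|{b}": relative_overlap(m, a, b)
            for a in GROUPS for b in GROUPS
            if a != b and m.diag(a) > 0
        }
    return out
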