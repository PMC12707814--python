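"""End-to-end runs: configuration, staging, result tables, demo fixtures.

A :class:`RunConfig` (validated, hashable) drives two pipelines:

* imaging — synthetic scene (or supplied stack + filaments) → blob detection
  → restriction to the GFP cell → per-punctum co-localisation calls →
  percentage and dendritic density → tidy CSVs;
* ephys — simulated cohort → membrane test + series-resistance QC →
  phase-plane classification → AEI average/subtract/integrate/fit → tidy CSV
  → group statistics with a nested confirmation.

Result tables are byte-deterministic for a fixed config and seed; wall-clock
timestamps only ever go to the run log, never into result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .errors import StageError, UnevaluablePunctumError
from .ephys_analysis import (
    AnalysisWindow,
    aei_charge,
    classify_waveform,
    fit_decay,
    membrane_test,
    phase_plane,
    qc_series_resistance,
    subtract_conditions,
)
from .puncta_coloc import (
    ColocParams,
    DetectionParams,
    coloc_classify,
    coloc_percentage,
    detect_puncta,
    puncta_density,
)
from .stats_report import choose_and_compare, mean_sem_sentence, nested_compare
from .synth_ephys import (
    CohortSpec,
    Pharmacology,
    aei_protocol,
    make_cohort,
    simulate_aei,
    simulate_membrane_test,
    simulate_spike,
)
from .synth_imaging import (
    GroundTruthScene,
    OpticsNoiseModel,
    RenderParams,
    VoxelGrid,
    make_scene,
)


class GridConfig(BaseModel):
    shape_zyx: tuple[int, int, int] = (4, 600, 600)
    voxel_size_xy: float = Field(0.033, gt=0)
    voxel_size_z: float = Field(0.37, gt=0)

    def build(self) -> VoxelGrid:
        return VoxelGrid(**self.model_dump())


class OpticsConfig(BaseModel):
    psf_sigma_xy: float = Field(0.10, gt=0)
    psf_sigma_z: float = Field(0.30, gt=0)
    background_level: float = Field(10.0, ge=0)
    photon_noise: bool = True
    read_noise_sd: float = Field(2.0, ge=0)

    def build(self, seed: int = 0) -> OpticsNoiseModel:
        return OpticsNoiseModel(seed=seed, **self.model_dump())


class ImagingConfig(BaseModel):
    grid: GridConfig = GridConfig()
    n_branches: int = Field(2, ge=0)
    target_length_um: float = Field(120.0, gt=0)
    density_per_um: float = Field(0.19, ge=0)
    coloc_fraction: float = Field(0.74, ge=0, le=1)
    optics: OpticsConfig = OpticsConfig()
    expected_diameter_um: float = Field(0.5, gt=0)
    quality_threshold: float = Field(300.0, ge=0)
    coloc_window_um: float = Field(1.0, gt=0)
    coloc_background_window_um: float = Field(1.0, gt=0)
    coloc_sd_multiplier: float = Field(1.0, gt=0)
    match_radius_um: float = Field(0.5, gt=0)
    gfp_overlap_threshold: float = Field(10.0, ge=0)
    distractor_density_per_um3: float = Field(0.05, ge=0)


class EphysConfig(BaseModel):
    n_cells_per_subtype: int = Field(10, ge=1)
    n_animals: int = Field(3, ge=1)
    protocol_kind: str = "aei_single"
    cell_cv_scale: float = Field(1.0, ge=0)
    animal_sd_log: float = Field(0.2, ge=0)
    noise_sd_pA: float = Field(5.0, ge=0)
    sipsc_rate_hz: float = Field(2.0, ge=0)
    window: tuple[float, float] = (10.0, 500.0)  # start offset, length (ms)


class StatsConfig(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    welch: str = "auto"


class RunConfig(BaseModel):
    """Validated run configuration; defaults mirror the study's settings
    (0.5 µm punctum, 1 µm windows, 1 SD criterion, 10 ms + 500 ms analysis
    window, 30 MΩ / 30% series-resistance rule, α = 0.05)."""

    seed: int = 0
    imaging: ImagingConfig = ImagingConfig()
    ephys: EphysConfig = EphysConfig()
    stats: StatsConfig = StatsConfig()
    version: str = __version__

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# imaging pipeline


def analyze_scene(
    scene: GroundTruthScene,
    cfg: ImagingConfig,
    use_manifest_centroids: bool = False,
) -> dict:
    """Run detection → restriction → co-localisation → density on one scene.

    With ``use_manifest_centroids`` the co-localisation calls are evaluated at
    the ground-truth centroids instead of the detected ones, emulating the
    workflow where centroids come from a spot-detection export.
    """
    from .puncta_coloc import DetectedPunctum, restrict_to_cell

    volume = scene.volume
    if volume is None:
        raise StageError("analyze_scene", scene.filaments.cell_id, ValueError("scene not rendered"))
    det_params = DetectionParams(
        expected_diameter=cfg.expected_diameter_um,
        quality_threshold=cfg.quality_threshold,
        channel="mRuby",
    )
    detected = detect_puncta(volume, det_params)
    detected = restrict_to_cell(detected, volume, overlap_threshold=cfg.gfp_overlap_threshold)
    if use_manifest_centroids:
        half = cfg.expected_diameter_um / 2.0
        to_call = [
            DetectedPunctum(
                centroid_xyz=p.centroid_xyz,
                quality=np.inf,
                x_extent=(p.centroid_xyz[0] - half, p.centroid_xyz[0] + half),
            )
            for p in scene.puncta
        ]
    else:
        to_call = detected
    coloc_params = ColocParams(
        window=cfg.coloc_window_um,
        background_window=cfg.coloc_background_window_um,
        sd_multiplier=cfg.coloc_sd_multiplier,
    )
    calls, skipped = [], []
    for i, p in enumerate(to_call):
        try:
            calls.append(coloc_classify(volume, p, params=coloc_params, punctum_id=i))
        except UnevaluablePunctumError as exc:
            skipped.append(str(exc))
    summary = coloc_percentage(calls) if calls else None
    dens = puncta_density(detected, scene.filaments, match_radius=cfg.match_radius_um) if detected or True else None
    return {
        "detected": detected,
        "calls": calls,
        "skipped": skipped,
        "coloc": summary,
        "density": dens,
    }


def run_imaging_pipeline(config: RunConfig, outdir, scene: GroundTruthScene | None = None,
                         use_manifest_centroids: bool = False) -> dict:
    """Full imaging run on a synthetic (or supplied) scene; writes tidy CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.imaging
    if scene is None:
        scene = make_scene(
            grid=cfg.grid.build(),
            n_branches=cfg.n_branches,
            target_length=cfg.target_length_um,
            density=cfg.density_per_um,
            coloc_fraction=cfg.coloc_fraction,
            optics=cfg.optics.build(),
            params=RenderParams(distractor_density_per_um3=cfg.distractor_density_per_um3),
            seed=config.seed,
        )
    try:
        res = analyze_scene(scene, cfg, use_manifest_centroids=use_manifest_centroids)
    except Exception as exc:  # pragma: no cover - surfaced with stage context
        raise StageError("imaging_analysis", scene.filaments.cell_id, exc) from exc
    chash = config.config_hash()

    rows = [
        {
            "punctum_id": c.punctum_id,
            "center_mean": c.center_mean,
            "background_mean": c.background_mean,
            "background_sd": c.background_sd,
            "is_coloc": c.is_coloc,
            "config_hash": chash,
        }
        for c in res["calls"]
    ]
    pd.DataFrame(
        rows,
        columns=["punctum_id", "center_mean", "background_mean", "background_sd", "is_coloc", "config_hash"],
    ).to_csv(outdir / "puncta.csv", index=False, float_format="%.9g")

    dens = res["density"]
    summary = {
        "config_hash": chash,
        "version": config.version,
        "cell_id": scene.filaments.cell_id,
        "n_detected": len(res["detected"]),
        "n_calls": len(res["calls"]),
        "n_skipped": len(res["skipped"]),
        "coloc_percent": None if res["coloc"] is None else res["coloc"].percent,
        "coloc_n": None if res["coloc"] is None else [res["coloc"].n_coloc, res["coloc"].n_total],
        "density_per_um": dens.density,
        "total_length_um": dens.total_length,
        "n_matched_puncta": dens.n_puncta,
    }
    pd.DataFrame([summary]).to_csv(outdir / "cells.csv", index=False, float_format="%.9g")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {**res, "summary": summary, "scene": scene}


def demo_imaging_scene(seed: int = 0, n_puncta: int = 53, n_coloc: int = 39) -> GroundTruthScene:
    """Noiseless packaged demo: 53 well-isolated puncta, exactly 39 co-localised.

    Puncta are placed along the dendrite with a minimum 3D separation of
    1.5 µm so every spot is optically resolved and the co-localisation call
    is unambiguous — the fixture demonstrates the workflow's arithmetic, not
    its behaviour under crowding.
    """
    from . import geometry
    from .synth_imaging import GroundTruthPunctum, generate_filaments, render_scene

    grid = VoxelGrid(shape_zyx=(4, 700, 700))
    fil = generate_filaments(grid, n_branches=3, target_length=280.0, seed=seed)
    rng = np.random.default_rng(seed + 1)
    lengths = [geometry.polyline_length(p) for p in fil.polylines]
    total = sum(lengths)
    cum = np.cumsum(lengths)
    placed: list[np.ndarray] = []
    parents: list[int] = []
    guard = 0
    while len(placed) < n_puncta and guard < 100_000:
        guard += 1
        s = rng.uniform(0.0, total)
        j = int(min(np.searchsorted(cum, s, side="right"), len(lengths) - 1))
        pos = geometry.point_at_arclength(fil.polylines[j], s - (cum[j] - lengths[j]))
        if all(np.linalg.norm(pos - q) >= 1.5 for q in placed):
            placed.append(pos)
            parents.append(j)
    if len(placed) < n_puncta:
        raise StageError("demo_fixture", "imaging", RuntimeError("could not isolate puncta"))
    labels = np.zeros(n_puncta, dtype=bool)
    labels[rng.permutation(n_puncta)[:n_coloc]] = True
    puncta = [
        GroundTruthPunctum(centroid_xyz=pos, coloc_label=bool(lab), parent_polyline=par)
        for pos, lab, par in zip(placed, labels, parents)
    ]
    optics = OpticsNoiseModel(background_level=0.0, photon_noise=False, read_noise_sd=0.0, seed=seed)
    volume = render_scene(grid, fil, puncta, optics, RenderParams(distractor_density_per_um3=0.0))
    return GroundTruthScene(grid=grid, filaments=fil, puncta=puncta, volume=volume, jitter_um=0.0)


# ---------------------------------------------------------------------------
# ephys pipeline


def run_ephys_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate a cohort and push every cell through the analysis chain.

    Per cell: membrane test (twice, for the series-resistance history and
    QC), spike classification, AEI pre/gabazine simulation with a shared
    seed, average → subtract → integrate → decay fit.  Cells failing QC are
    excluded from statistics and listed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.ephys
    spec = CohortSpec(animal_sd_log=cfg.animal_sd_log)
    if cfg.cell_cv_scale != 1.0:
        spec = CohortSpec(
            cell_cv={k: v * cfg.cell_cv_scale for k, v in CohortSpec().cell_cv.items()},
            animal_sd_log=cfg.animal_sd_log,
        )
    cohort = make_cohort(cfg.n_cells_per_subtype, cfg.n_animals, seed=config.seed, spec=spec)
    window = AnalysisWindow(start_offset_ms=cfg.window[0], length_ms=cfg.window[1])
    proto = aei_protocol(cfg.protocol_kind)
    rows = []
    seeds = _sub_seeds(config.seed, len(cohort))
    for idx, ((arch, animal), cell_seed) in enumerate(zip(cohort, seeds)):
        arch = dataclasses.replace(arch, noise_sd=cfg.noise_sd_pA, sipsc_rate=cfg.sipsc_rate_hz)
        s = _sub_seeds(cell_seed, 5)
        try:
            mt1 = membrane_test(simulate_membrane_test(arch, seed=s[0]))
            mt2 = membrane_test(simulate_membrane_test(arch, seed=s[1]))
            qc = qc_series_resistance([mt1.R_S, mt2.R_S])
            pre = simulate_aei(arch, proto, Pharmacology(), seed=s[2])
            post = simulate_aei(arch, proto, Pharmacology(gabazine=True), seed=s[2])
            diff = subtract_conditions(pre, post)
            charge = aei_charge(diff, proto, window)
            try:
                k = fit_decay(diff, proto, window).k
            except Exception:
                k = np.nan
            spk = simulate_spike(arch, seed=s[3], noise_mV=0.3)
            pp = phase_plane(spk.sweeps[0], spk.sample_interval_us)
            label = classify_waveform(pp).label
        except Exception as exc:
            raise StageError("ephys_cell", f"cell{idx:03d}", exc) from exc
        rows.append(
            {
                "cell_id": f"cell{idx:03d}",
                "animal_id": animal,
                "subtype_claimed": arch.subtype,
                "label": label,
                "R_S": mt1.R_S,
                "R_I": mt1.R_I,
                "C_M": mt1.C_M,
                "aei_charge_pC": charge,
                "decay_k_per_ms": k,
                "qc_pass": qc.passed,
                "qc_reason": qc.reason,
                "aei_charge_true_pC": arch.aei_charge_true,
                "config_hash": config.config_hash(),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "results.csv", index=False, float_format="%.9g")
    ok = df[df["qc_pass"]]
    an = ok[ok["subtype_claimed"] == "anaxonic"]["aei_charge_pC"]
    ab = ok[ok["subtype_claimed"] == "axon_bearing"]["aei_charge_pC"]
    test = choose_and_compare(an, ab, alpha=config.stats.alpha, welch=config.stats.welch)
    nested = None
    try:
        nested = nested_compare(
            ok.rename(columns={"subtype_claimed": "subtype"}),
            "aei_charge_pC",
            seed=config.seed,
        )
    except Exception:
        pass
    report_lines = [
        "# Auto-evoked inhibition: cohort report",
        "",
        mean_sem_sentence("AEI charge, anaxonic", an, "pC"),
        mean_sem_sentence("AEI charge, axon-bearing", ab, "pC"),
        f"cell-level test: {test.test_name}, statistic={test.statistic:.4g}, p={test.p_value:.4g}",
    ]
    if nested is not None:
        report_lines.append(
            f"nested test: {nested.test_name}, statistic={nested.statistic:.4g}, p={nested.p_value:.4g}"
        )
    excluded = df[~df["qc_pass"]]["cell_id"].tolist()
    report_lines.append(f"excluded by series-resistance QC: {excluded if excluded else 'none'}")
    (outdir / "report.md").write_text("\n".join(report_lines) + "\n")
    summary = {
        "config_hash": config.config_hash(),
        "version": config.version,
        "n_cells": len(df),
        "n_qc_excluded": int((~df["qc_pass"]).sum()),
        "mean_charge_anaxonic_pC": float(an.mean()),
        "mean_charge_axon_bearing_pC": float(ab.mean()),
        "cell_level_p": test.p_value,
        "cell_level_test": test.test_name,
        "nested_p": None if nested is None else nested.p_value,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"table": df, "test": test, "nested": nested, "summary": summary}
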