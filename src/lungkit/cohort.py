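"""Synthetic longitudinal study: cohorts, per-session pipelines, metric table.

Emulates a three-arm bleomycin study (healthy / bleo.+vehicle /
bleo.+nintedanib, days 0-7-14-21): each arm follows a severity trajectory
(fibrosis builds after instillation at day 0, recovers from day 14 only
under treatment, and partially self-resolves in the vehicle arm by day 21),
and every animal/day session is pushed through the *full* measurement
pipelines - planar radiographs -> XLF decay rate, gated rotational
projections -> phase-resolved volumetry, pressure trace -> WBP tidal volume,
and (day 21, ex vivo) porous cubes -> air ratio and SA:V.

Animal-level realism: each animal carries a persistent lung-size factor
(6% SD on volumes, shared by CT and WBP truth - body-size scaling), a
persistent severity offset in the bleomycin arms (4% SD response
heterogeneity), and each session a small tidal-volume state jitter (3% SD)
common to the simultaneously acquired CT and WBP, as in a combined
acquisition set-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gating, srct, wbp, xlf
from .phantom import (BreathingLungPhantom, PhantomSpec, make_alveolar_cube,
                      make_breathing_volume_series, make_gated_projection_set,
                      make_wbp_trace, project_radiographs)

GROUPS = ("healthy", "vehicle", "nintedanib")

SEVERITY_SCHEDULE = {
    "healthy": {0: 0.0, 7: 0.0, 14: 0.0, 21: 0.0},
    "vehicle": {0: 0.0, 7: 0.50, 14: 0.65, 21: 0.55},
    "nintedanib": {0: 0.0, 7: 0.50, 14: 0.20, 21: 0.12},
}


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple = GROUPS
    n_per_group: int = 5
    days: tuple = (0, 7, 14, 21)
    severity_schedule: dict = field(default_factory=lambda: SEVERITY_SCHEDULE)
    size_sd: float = 0.06  # SD of the per-animal volume-scale factor
    severity_sd: float = 0.04  # per-animal response heterogeneity
    session_tv_sd: float = 0.03  # per-session tidal state jitter


@dataclass(frozen=True)
class StudyScale:
    """Problem sizes for the simulated measurements."""

    ct_grid: int = 48
    ct_angles: int = 240
    rotation_time: float = 270.0
    insp_q: float = 85.0
    exp_q: float = 10.0
    smooth_sigma: float = 1.0
    xlf_frames: int = 84
    xlf_fps: float = 14.0
    xlf_photons: float = 5.0e4
    wbp_duration: float = 30.0
    wbp_drift: float = 0.15  # fraction of flow amplitude
    wbp_noise: float = 0.10
    cube_grid: int = 96
    n_cubes: int = 3


# ---------------------------------------------------------------------------
# single-session pipelines


def xlf_session(spec: PhantomSpec, scale: StudyScale) -> xlf.XLFMetrics:
    """Radiographs -> transmission curve -> cycle metrics for one session."""
    series = make_breathing_volume_series(spec, scale.xlf_frames, scale.xlf_fps)
    seq = project_radiographs(series, axis=1, noise_model=scale.xlf_photons,
                              seed=spec.seed)
    roi = BreathingLungPhantom(spec).lung_roi_radiograph()
    curve = xlf.extract_transmission_curve(seq, roi)
    cycles = xlf.detect_cycles(curve, f_min=0.4, f_max=1.5)
    return xlf.summarize_xlf(curve, cycles)


def ct_session(spec: PhantomSpec, scale: StudyScale) -> dict:
    """Gated projections -> phase recon -> segmentation -> V_insp / V_exp (ml)."""
    projset, truth = make_gated_projection_set(
        spec, n_angles=scale.ct_angles, rotation_time=scale.rotation_time)
    phantom = BreathingLungPhantom(spec)
    nz = spec.grid_shape[0]
    line_row = nz // 2 + int(round(spec.geometry.lung_center_z / spec.voxel_size))
    signal = gating.breathing_signal_from_projections(
        projset, line_row, frequency=spec.breathing_frequency)
    signal = gating.as_inspiration_positive(signal)
    assignment = gating.assign_phases(signal, insp_q=scale.insp_q,
                                      exp_q=scale.exp_q)
    # reference background slice: inside the thorax, below the lung fields
    g = spec.geometry
    z_bg = g.lung_center_z - 1.08 * g.lung_semiaxes[0]
    ref_slice = int(np.clip(nz // 2 + round(z_bg / spec.voxel_size), 0, nz - 1))
    mask = phantom.thoracic_mask()
    seeds = phantom.seed_voxels()
    out = {"gating_agreement": phase_agreement(assignment.labels, truth.labels)}
    for phase, key in ((gating.INSPIRATION, "v_insp"), (gating.EXPIRATION, "v_exp")):
        vol = gating.reconstruct_phase(projset, assignment, phase)
        vol = gating.subtract_background_slice(vol, ref_slice)
        vol = gating.smooth_3d(vol, scale.smooth_sigma)
        lung = gating.segment_lung(vol, seeds, "midpoint", thoracic_mask=mask)
        out[key] = gating.lung_volume(lung)
    out["truth"] = truth.ground_truth
    return out


def phase_agreement(pred, true) -> float:
    """Fraction of retained (non-discarded) frames whose labels agree."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    kept = (pred != gating.DISCARDED) & (true != gating.DISCARDED)
    if not kept.any():
        return float("nan")
    return float(np.mean(pred[kept] == true[kept]))


def wbp_session(tidal_volume_ml: float, frequency: float,
                scale: StudyScale, seed: int) -> wbp.WBPSummary:
    """Pressure trace with drift + noise -> reset-integral tidal volume."""
    amp = tidal_volume_ml * np.pi * frequency
    trace, _ = make_wbp_trace(
        tidal_volume_ml, frequency, duration=scale.wbp_duration,
        drift_amp=scale.wbp_drift * amp, noise_amp=scale.wbp_noise * amp,
        seed=seed)
    series = wbp.integrate_reset_cycles(trace)
    return wbp.summarize_wbp(series)


def morphometry_session(severity: float, scale: StudyScale,
                        seed: int) -> dict:
    """Ex-vivo style porous cubes -> mean air ratio and SA:V."""
    ars, savs = [], []
    for i in range(scale.n_cubes):
        vol, gt = make_alveolar_cube(severity, grid_n=scale.cube_grid,
                                     seed=seed + 7 * i)
        cube = srct.CubeROI(volume=vol, side_mm=1.75,
                            voxel_mm=1.75 / scale.cube_grid)
        res = srct.morphometry(cube)
        ars.append(res.air_ratio)
        savs.append(res.sa_v)
    return {"air_ratio": float(np.mean(ars)), "sa_v": float(np.mean(savs))}


# ---------------------------------------------------------------------------
# the full study


def simulate_study(
    design: StudyDesign | None = None,
    scale: StudyScale | None = None,
    seed: int = 0,
    with_morphometry: bool = True,
) -> pd.DataFrame:
    """Run every animal/day session; returns the tidy metric table.

    Columns: animal, group, day, metric, value (plus matching ``*_true``
    rows for ground-truth quantities, metric names suffixed ``_true``).
    """
    design = design or StudyDesign()
    scale = scale or StudyScale()
    rng = np.random.default_rng(seed)
    rows = []
    for group in design.groups:
        for a in range(design.n_per_group):
            animal = f"{group}_{a}"
            size = float(np.exp(rng.normal(0.0, design.size_sd)))
            sev_offset = float(rng.normal(0.0, design.severity_sd))
            for day in design.days:
                base = design.severity_schedule[group][day]
                sev = 0.0 if base == 0.0 else float(np.clip(base + sev_offset, 0.0, 1.0))
                cell_seed = int(rng.integers(2**31 - 1))
                tv_jitter = float(np.exp(rng.normal(0.0, design.session_tv_sd)))
                spec = PhantomSpec.with_grid(
                    scale.ct_grid, severity=sev, volume_scale=size,
                    seed=cell_seed)
                # session state jitter acts on the tidal volume of both
                # simultaneously acquired modalities
                spec_ct = _with_tidal_jitter(spec, tv_jitter)
                res_xlf = xlf_session(_with_tidal_jitter(spec, tv_jitter), scale)
                res_ct = ct_session(spec_ct, scale)
                res_wbp = wbp_session(spec_ct.tidal_volume_eff,
                                      spec.breathing_frequency, scale,
                                      seed=cell_seed + 1)
                truth = res_ct["truth"]
                metrics = {
                    "decay_rate": res_xlf.decay_rate,
                    "peak_transmission": res_xlf.peak_transmission,
                    "expiratory_baseline": res_xlf.expiratory_baseline,
                    "auc": res_xlf.auc,
                    "v_insp": res_ct["v_insp"],
                    "v_exp": res_ct["v_exp"],
                    "tidal_ct": res_ct["v_insp"] - res_ct["v_exp"],
                    "tv_wbp": res_wbp.tv_mean,
                    "gating_agreement": res_ct["gating_agreement"],
                    "severity_true": sev,
                    "decay_rate_true": truth.decay_rate,
                    "v_insp_true": truth.air_volume_insp,
                    "tv_true": truth.tidal_volume,
                }
                if with_morphometry and day == design.days[-1]:
                    res_m = morphometry_session(sev, scale, seed=cell_seed + 2)
                    metrics.update(res_m)
                for name, value in metrics.items():
                    rows.append({"animal": animal, "group": group, "day": day,
                                 "metric": name, "value": value})
    return pd.DataFrame(rows)


def _with_tidal_jitter(spec: PhantomSpec, jitter: float) -> PhantomSpec:
    from dataclasses import replace

    return replace(spec, tidal_air_volume=spec.tidal_air_volume * jitter)


def group_day_mean(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Convenience pivot: mean metric value per (group, day)."""
    sub = table[table.metric == metric]
    return sub.pivot_table(index="group", columns="day", values="value",
                           aggfunc="mean")
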