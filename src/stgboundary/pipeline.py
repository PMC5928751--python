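"""End-to-end orchestration: simulate -> analyze -> report.

``run_pipeline`` executes the full dual-modality study on synthetic data:
per-participant ECoG recordings are preprocessed and quantified as
high-gamma percent change; per-hemisphere BOLD sessions are fit voxelwise,
the clear-vs-noisy t profile is binned along the gyrus and the functional
boundary localized; boundary-relative ROIs provide deconvolved (FIR)
response timecourses; the ECoG grand means are pushed through the
hemodynamic forward model and scaled to the fMRI curves; and mixed-effects
models summarize both modalities.  All randomness derives from one seed via
named child seeds, so stages are individually reproducible and the report is
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary as bnd
from . import ecog as ec
from . import forward as fwd
from . import glm
from . import io as sio
from . import stats as gstats
from .synthetic import (
    CLEAR_CONDITIONS,
    CONDITIONS,
    NOISY_CONDITIONS,
    GyrusModel,
    SimulationParams,
    make_event_schedule,
    make_gyrus,
    simulate_behavior,
    simulate_bold,
    simulate_ecog,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "stage_seed"]


@dataclass
class PipelineConfig:
    """All tunables of the simulate-analyze-report pipeline."""

    seed: int = 0
    out_dir: str = "stg_out"

    # cohort structure
    n_fmri_participants: int = 6
    hemispheres_per_participant: int = 2
    n_ecog_participants: int = 5
    ecog_trials_per_condition: int = 40

    # gyrus geometry and inter-hemisphere variability
    gyrus_length_mm: float = 100.0
    landmark_mean_mm: float = 75.0
    landmark_sd_mm: float = 5.0
    boundary_offset_mean_mm: float = -2.0
    boundary_offset_sd_mm: float = 4.0
    standard_offset_mm: float = 45.0

    # electrode montage, relative to each participant's anatomical landmark
    electrode_offsets_mm: tuple = (-27.0, -21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0)
    n_reference_channels: int = 54

    # fMRI acquisition
    n_runs: int = 5
    trials_per_condition_per_run: int = 12
    tr_s: float = 1.5
    volumes_per_run: int = 160
    voxel_spacing_mm: float = 1.0
    n_depth: int = 3

    # analysis parameters
    band: tuple = (70.0, 110.0)
    baseline_ms: tuple = (-500.0, -100.0)
    response_ms: tuple = (0.0, 500.0)
    inclusion_alpha: float = 1e-3
    f_threshold: float = 5.0
    roi_extents_mm: tuple = (30.0, 15.0)
    tent_window_s: tuple = (0.0, 15.0)
    tent_knots: int = 11
    hrf_peak_s: float = 6.0
    hrf_undershoot_offset_s: float = 10.0
    hrf_ratio: float = 4.0

    sim_params: dict = field(default_factory=dict)

    def make_sim_params(self) -> SimulationParams:
        return SimulationParams(**self.sim_params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.make_sim_params()
        if self.n_fmri_participants < 1 or self.n_ecog_participants < 1:
            raise ValueError("need at least one participant per modality")
        if self.tent_knots < 2:
            raise ValueError("tent basis needs at least 2 knots")
        if not 0 < self.inclusion_alpha < 1:
            raise ValueError("inclusion alpha must be in (0, 1)")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(base_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed for a named pipeline stage.

    Hashes (base seed, stage name, index) so any stage can be re-run in
    isolation with exactly the seed the full pipeline would use.  Values stay
    below 2**31.
    """
    h = hashlib.sha256(f"{base_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _participant_gyrus(cfg: PipelineConfig, rng: np.random.Generator) -> GyrusModel:
    """Draw per-hemisphere anatomy: landmark position and functional-boundary
    offset vary across hemispheres; the boundary is kept inside the posterior
    third with room for the posterior ROI."""
    landmark = rng.normal(cfg.landmark_mean_mm, cfg.landmark_sd_mm)
    offset = rng.normal(cfg.boundary_offset_mean_mm, cfg.boundary_offset_sd_mm)
    boundary = landmark + offset
    lo = 2.0 * cfg.gyrus_length_mm / 3.0 + 1.0
    hi = cfg.gyrus_length_mm - cfg.roi_extents_mm[1] - 1.0
    boundary = float(np.clip(boundary, lo, hi))
    landmark = float(np.clip(landmark, 5.0, cfg.gyrus_length_mm - 5.0))
    return make_gyrus(
        length_mm=cfg.gyrus_length_mm,
        anatomical_landmark_mm=landmark,
        true_boundary_mm=boundary,
        standard_offset_mm=cfg.standard_offset_mm,
    )


def _analyze_ecog_participant(
    cfg: PipelineConfig, params: SimulationParams, pid: int
) -> tuple[pd.DataFrame, dict]:
    """Simulate and quantify one ECoG participant.

    Returns (response table rows, per-region condition-mean timecourses).
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "ecog-anatomy", pid))
    gyrus = _participant_gyrus(cfg, rng)
    positions = np.array(cfg.electrode_offsets_mm) + gyrus.anatomical_landmark_mm
    positions = positions[(positions > 0) & (positions < gyrus.length_mm)]
    rec = simulate_ecog(
        gyrus,
        positions,
        cfg.ecog_trials_per_condition,
        params,
        seed=stage_seed(cfg.seed, "ecog-recording", pid),
        n_reference_channels=cfg.n_reference_channels,
        band=cfg.band,
    )
    rec = ec.common_average_reference(rec)
    rec = ec.remove_line_noise(rec)
    epochs = ec.epoch_trials(rec)
    strip = rec.channels.dropna(subset=["position_mm"])
    tcs = ec.multitaper_highgamma(
        epochs,
        band=cfg.band,
        baseline_ms=cfg.baseline_ms,
        channels=list(strip["channel"]),
    )
    inclusion = ec.select_responsive_electrodes(
        tcs, alpha=cfg.inclusion_alpha, response_ms=cfg.response_ms
    )
    included = set(inclusion.loc[inclusion["included"], "electrode"])
    pos_by_ch = dict(zip(strip["channel"], strip["position_mm"]))

    rows = []
    tc_accum: dict[tuple[str, str], list[np.ndarray]] = {}
    for ch, tc in tcs.items():
        if ch not in included:
            continue
        location = "anterior" if pos_by_ch[ch] < gyrus.anatomical_landmark_mm else "posterior"
        for cond in CONDITIONS:
            sel = tc.conditions == cond
            rows.append(
                {
                    "unit": f"P{pid}:{ch}",
                    "participant": f"ecogP{pid}",
                    "location": location,
                    "auditory": "noisy" if cond in NOISY_CONDITIONS else "clear",
                    "visual": "blurred" if cond.endswith("Vblur") else "clear",
                    "response": float(
                        tc.trial_window_means(cfg.response_ms)[sel].mean()
                    ),
                }
            )
        for label, conds in (("clear", CLEAR_CONDITIONS), ("noisy", NOISY_CONDITIONS)):
            key = (location, label)
            tc_accum.setdefault(key, []).append(tc.condition_mean(list(conds)))
    grand = {
        key: {"times_ms": tcs[next(iter(tcs))].times_ms, "mean": np.mean(v, axis=0)}
        for key, v in tc_accum.items()
    }
    return pd.DataFrame(rows), grand


def _analyze_fmri_hemisphere(
    cfg: PipelineConfig, params: SimulationParams, hemi: int
) -> dict:
    """Simulate and analyze one fMRI hemisphere end to end."""
    rng = np.random.default_rng(stage_seed(cfg.seed, "fmri-anatomy", hemi))
    gyrus = _participant_gyrus(cfg, rng)
    schedule = make_event_schedule(
        n_runs=cfg.n_runs,
        trials_per_condition_per_run=cfg.trials_per_condition_per_run,
        tr_s=cfg.tr_s,
        volumes_per_run=cfg.volumes_per_run,
        seed=stage_seed(cfg.seed, "fmri-schedule", hemi),
    )
    session = simulate_bold(
        gyrus,
        schedule,
        params,
        seed=stage_seed(cfg.seed, "fmri-session", hemi),
        voxel_spacing_mm=cfg.voxel_spacing_mm,
        n_depth=cfg.n_depth,
    )
    y = glm.scale_to_psc(session.data)
    block = glm.build_block_design(schedule, session.motion)
    block_fit = glm.fit_glm(y, block)
    _, t_map = glm.contrast_clear_vs_noisy(block_fit)
    f_map = block_fit.f_omnibus

    # t volume (position x depth) -> surface nodes -> 1 mm profile
    positions = np.unique(session.voxels["position_mm"])
    n_depth = int(session.voxels["depth"].max()) + 1
    t_vol = t_map.reshape(positions.size, n_depth)
    node_pos = gyrus.node_positions
    node_t = bnd.sample_volume_to_surface(t_vol, positions, node_pos)
    profile = bnd.bin_profile(node_t, node_pos, gyrus.length_mm)
    est = bnd.estimate_boundary(profile, gyrus)

    roi_boundary = est.functional_mm if est.found else est.anatomical_mm
    rois = bnd.define_rois(
        roi_boundary,
        session.voxels["position_mm"].to_numpy(),
        f_map,
        gyrus.length_mm,
        extents_mm=cfg.roi_extents_mm,
        f_threshold=cfg.f_threshold,
    )
    tent = glm.build_tent_design(
        schedule, session.motion, window_s=cfg.tent_window_s, n_knots=cfg.tent_knots
    )
    tent_fit = glm.fit_glm(y, tent)
    fir = {}
    amp = {}
    for cond in CONDITIONS:
        times, betas = glm.estimate_hrf_tent(tent_fit, cond)
        fir[cond] = {
            "times_s": times,
            "anterior": betas[rois.anterior_mask].mean(axis=0)
            if not rois.anterior_empty
            else np.full(times.size, np.nan),
            "posterior": betas[rois.posterior_mask].mean(axis=0)
            if not rois.posterior_empty
            else np.full(times.size, np.nan),
        }
        peak_knots = tuple(
            t for t in (4.5, 6.0, 7.5) if any(np.isclose(times, t))
        )
        for region in ("anterior", "posterior"):
            amp[(region, cond)] = float(
                glm.localizer_response(times, fir[cond][region][None, :], at_s=peak_knots)[0]
            )
    return {
        "gyrus": gyrus,
        "profile": profile,
        "estimate": est,
        "fir": fir,
        "amplitudes": amp,
        "rois": rois,
    }


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute every stage and return (and optionally write) the report."""
    config.validate()
    params = config.make_sim_params()
    out_dir = Path(config.out_dir)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    # --- ECoG arm -----------------------------------------------------------
    ecog_tables = []
    grand_accum: dict[tuple[str, str], list[np.ndarray]] = {}
    grand_times: np.ndarray | None = None
    for pid in range(config.n_ecog_participants):
        tab, grand = _analyze_ecog_participant(config, params, pid)
        ecog_tables.append(tab)
        for key, v in grand.items():
            grand_accum.setdefault(key, []).append(v["mean"])
            grand_times = v["times_ms"]
    ecog_table = pd.concat(ecog_tables, ignore_index=True)
    ecog_lme = gstats.fit_lme(ecog_table)
    report["ecog"] = {
        "n_units": int(ecog_table["unit"].nunique()),
        "lme": _effects_to_dict(ecog_lme),
        "condition_means": {
            loc: {
                aud: float(
                    ecog_table.loc[
                        (ecog_table["location"] == loc)
                        & (ecog_table["auditory"] == aud),
                        "response",
                    ].mean()
                )
                for aud in ("clear", "noisy")
            }
            for loc in ("anterior", "posterior")
        },
    }

    # --- fMRI arm -----------------------------------------------------------
    n_hemis = config.n_fmri_participants * config.hemispheres_per_participant
    hemi_results = [
        _analyze_fmri_hemisphere(config, params, h) for h in range(n_hemis)
    ]
    estimates = [h["estimate"] for h in hemi_results]
    report["boundary"] = bnd.boundary_report(estimates)
    report["boundary"]["per_hemisphere"] = [
        {
            "functional_mm": e.functional_mm,
            "anatomical_mm": e.anatomical_mm,
            "functional_y": e.functional_y,
            "anatomical_y": e.anatomical_y,
            "true_boundary_mm": h["gyrus"].true_boundary_mm,
            "abs_error_mm": abs(e.functional_mm - h["gyrus"].true_boundary_mm)
            if e.found
            else None,
        }
        for e, h in zip(estimates, hemi_results)
    ]

    fmri_rows = []
    for h, res in enumerate(hemi_results):
        pid = h // config.hemispheres_per_participant
        for (region, cond), val in res["amplitudes"].items():
            if not np.isfinite(val):
                continue
            fmri_rows.append(
                {
                    "unit": f"hemi{h}",
                    "participant": f"fmriP{pid}",
                    "location": region,
                    "auditory": "noisy" if cond in NOISY_CONDITIONS else "clear",
                    "visual": "blurred" if cond.endswith("Vblur") else "clear",
                    "response": val,
                }
            )
    fmri_table = (
        pd.DataFrame(fmri_rows)
        .groupby(["unit", "participant", "location", "auditory", "visual"], as_index=False)[
            "response"
        ]
        .mean()
    )
    fmri_lme = gstats.fit_lme(fmri_table)
    report["fmri"] = {"n_hemispheres": n_hemis, "lme": _effects_to_dict(fmri_lme)}

    # --- behavior -----------------------------------------------------------
    behav = []
    for pid in range(config.n_fmri_participants):
        sched = make_event_schedule(
            n_runs=config.n_runs,
            trials_per_condition_per_run=config.trials_per_condition_per_run,
            tr_s=config.tr_s,
            volumes_per_run=config.volumes_per_run,
            seed=stage_seed(config.seed, "behavior-schedule", pid),
        )
        behav.append(
            simulate_behavior(
                sched,
                params,
                seed=stage_seed(config.seed, "behavior", pid),
                participant=f"fmriP{pid}",
            )
        )
    behav_table = pd.concat(behav, ignore_index=True)
    behav_res = gstats.behavioral_accuracy(behav_table)
    report["behavior"] = {
        "accuracy": {k: float(v) for k, v in behav_res["accuracy"].items()},
    }
    if "visual_benefit" in behav_res:
        vb = behav_res["visual_benefit"]
        report["behavior"]["visual_benefit"] = {
            "t": None if np.isnan(vb.t) else vb.t,
            "df": vb.df,
            "p": None if np.isnan(vb.p) else vb.p,
        }

    # --- forward model ------------------------------------------------------
    hrf = fwd.make_double_gamma_hrf(
        peak_time_s=config.hrf_peak_s,
        undershoot_offset_s=config.hrf_undershoot_offset_s,
        ratio=config.hrf_ratio,
    )
    n_knots = config.tent_knots
    fits = []
    forward_out = {}
    for (region, label), curves in sorted(grand_accum.items()):
        mean_tc = np.mean(curves, axis=0)
        post_onset = mean_tc[grand_times >= 0]
        predicted = fwd.predict_bold_from_ecog(post_onset, hrf, tr_s=config.tr_s, n_out=n_knots)
        # Rescale the prediction to preserve the high-gamma peak amplitude, so
        # the fitted scale factor reads directly as peak ECoG% per BOLD%.
        if predicted.max() > 0 and post_onset.max() > 0:
            predicted = predicted * (post_onset.max() / predicted.max())
        conds = CLEAR_CONDITIONS if label == "clear" else NOISY_CONDITIONS
        actual_curves = [
            np.mean([h["fir"][c][region] for c in conds], axis=0)
            for h in hemi_results
            if np.isfinite(h["fir"][conds[0]][region]).all()
        ]
        actual = np.mean(actual_curves, axis=0)
        fit = fwd.fit_scale_factor(predicted, actual, condition=label, region=region)
        fits.append(fit)
        forward_out[f"{region}_{label}"] = {
            "scale_factor": fit.scale_factor,
            "pearson_r": fit.pearson_r,
            "reliable": fit.reliable,
        }
    forward_out["mean_scale_factor"] = fwd.aggregate_scale_factors(fits)
    report["forward_model"] = forward_out

    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        (out_dir / "report.json").write_text(_stable_json(report))
        ecog_table.to_csv(out_dir / "ecog_responses.tsv", sep="\t", index=False)
        fmri_table.to_csv(out_dir / "fmri_responses.tsv", sep="\t", index=False)
        ecog_lme.effects.to_csv(out_dir / "ecog_lme.tsv", sep="\t")
        fmri_lme.effects.to_csv(out_dir / "fmri_lme.tsv", sep="\t")
        for h, res in enumerate(hemi_results):
            res["profile"].to_frame().to_csv(
                out_dir / f"profile_hemi{h}.tsv", sep="\t", index=False
            )
        logger.info("report written to %s", out_dir / "report.json")
    return report


def _effects_to_dict(lme: gstats.LmeResult) -> dict:
    d = {
        name: {
            "estimate": float(row["Estimate"]),
            "se": float(row["StdError"]),
            "df": float(row["DF"]),
            "t": float(row["t"]),
            "p": float(row["p"]),
        }
        for name, row in lme.effects.iterrows()
    }
    d["singular"] = lme.singular
    return d


def _stable_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    return json.dumps(obj, indent=1, sort_keys=True, default=default)


def make_fixtures(output_dir: Path | str, seed: int = 0) -> Path:
    """Write a miniature session bundle for tests and demos (well under 10 MB).

    One fMRI run with the standard 12 trials per condition, 8 strip
    electrodes with 6 trials per condition, and a coarse voxel grid.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    gyrus = make_gyrus()
    params = SimulationParams()

    schedule = make_event_schedule(n_runs=1, seed=stage_seed(seed, "fixture-schedule"))
    session = simulate_bold(
        gyrus,
        schedule,
        params,
        seed=stage_seed(seed, "fixture-bold"),
        voxel_spacing_mm=2.0,
        n_depth=2,
    )
    sio.write_bold(session, out, stem="bold")

    electrode_pos = np.array([43.0, 49.0, 55.0, 61.0, 67.0, 73.0, 79.0, 85.0])
    rec = simulate_ecog(
        gyrus,
        electrode_pos,
        n_trials_per_condition=6,
        params=params,
        seed=stage_seed(seed, "fixture-ecog"),
        n_reference_channels=6,
    )
    sio.write_ecog(rec, out / "ecog")
    sio.write_electrode_table(rec.channels, out / "electrodes.tsv")

    behav = simulate_behavior(schedule, params, seed=stage_seed(seed, "fixture-behavior"))
    behav.to_csv(out / "behavior.tsv", sep="\t", index=False)
    return out
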