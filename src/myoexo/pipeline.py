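"""End-to-end protocol analysis: simulate -> control -> analyze -> stats.

Six analysis windows per subject mirror the session protocol: the last 30
strides of Boots Only, Unpowered, Powered (PoweredEnd) and Deadaptation
(D2), and the first 30 strides of Powered (PoweredStart) and Deadaptation
(D1).  Per subject the stages are: stride events from vertical GRF,
controller calibration on the Unpowered bout, commanded torque over the
Powered bout, time-normalized cycle ensembles, EMG normalization to Boots
Only, stance/swing RMS, and the ankle moment/power decomposition.  Group
stage: percent changes, standardized mean differences, one-way ANOVA with
Tukey post-hocs, permutation SPM over the cycle, and the angle-source
range-of-motion comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from . import biomech, emg_metrics, stats
from .controller import ControllerConfig, MyoelectricController, preprocess_emg
from .signals import CycleEnsemble, SampledSignal, StrideEvents
from .synthetic import (
    MUSCLES,
    GeneratorConfig,
    TrialRecording,
    generate_trial,
)

#: window label -> (condition, which end of the bout)
ANALYSIS_WINDOWS = (
    ("BootsOnly", "BootsOnly", "last"),
    ("Unpowered", "Unpowered", "last"),
    ("PoweredStart", "Powered", "first"),
    ("PoweredEnd", "Powered", "last"),
    ("D1", "Deadaptation", "first"),
    ("D2", "Deadaptation", "last"),
)

POWERED_WINDOWS = ("PoweredStart", "PoweredEnd")

#: muscles scored on stance-phase RMS; the dorsiflexor is scored on swing
RMS_PHASE = {"sol": "stance", "mg": "stance", "lg": "stance", "ta": "swing"}


class PipelineConfig(BaseModel):
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    n_strides: int = Field(30, ge=2)
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    run_spm: bool = True
    spm_permutations: int = Field(300, ge=100)
    repeated_measures: bool = True
    use_exo_angle: bool = False
    grf_threshold_n: float = 20.0


@dataclass
class SubjectResult:
    subject_id: str
    rms_rows: list[dict]
    norm_emg_curves: dict[str, dict[str, np.ndarray]]   # muscle -> window -> mean curve
    mech_curves: dict[str, dict[str, np.ndarray]]       # channel -> window -> mean curve
    rom_extremes: dict[str, dict[str, tuple[float, float]]]  # window -> source -> (DF, PF)
    decomposition: dict[str, dict]                      # powered window -> summary
    calibration: dict = field(default_factory=dict)


def _window_events(
    trials: dict[str, TrialRecording], cfg: PipelineConfig
) -> dict[str, StrideEvents]:
    """Detected stride events restricted to each analysis window."""
    detected = {
        cond: biomech.detect_events(tr.channels["grf_v"], cfg.grf_threshold_n)
        for cond, tr in trials.items()
    }
    out = {}
    for label, cond, end in ANALYSIS_WINDOWS:
        if cond not in trials:
            continue
        out[label] = biomech.select_window(detected[cond], end, cfg.n_strides)
    out["_unpowered_full"] = detected["Unpowered"]
    return out


def analyze_subject(
    trials: dict[str, TrialRecording], cfg: Optional[PipelineConfig] = None
) -> SubjectResult:
    """Full single-subject analysis over the protocol's six windows."""
    cfg = cfg or PipelineConfig()
    windows = _window_events(trials, cfg)
    subject_id = next(iter(trials.values())).subject_id

    # --- controller: calibrate on Unpowered, command torque over Powered ---
    ctl = MyoelectricController(cfg.controller)
    unp_cal_events = biomech.select_window(windows["_unpowered_full"], "last", cfg.n_strides)
    ctl.calibrate_from_raw(trials["Unpowered"].channels["emg_sol"], unp_cal_events)
    powered_out = ctl.apply(
        trials["Powered"].channels["emg_sol"], trials["Powered"].channels["exo_angle"]
    )

    # --- envelopes for every muscle, once per trial ---
    envelopes = {
        cond: {
            m: preprocess_emg(tr.channels[f"emg_{m}"], cfg.controller) for m in MUSCLES
        }
        for cond, tr in trials.items()
    }

    # --- per-window cycle ensembles ---
    emg_ens: dict[str, dict[str, CycleEnsemble]] = {m: {} for m in MUSCLES}
    mech_curves: dict[str, dict[str, np.ndarray]] = {}
    rom: dict[str, dict[str, tuple[float, float]]] = {}
    decomp: dict[str, dict] = {}

    for label, cond, _end in ANALYSIS_WINDOWS:
        ev = windows[label]
        tr = trials[cond]
        for m in MUSCLES:
            emg_ens[m][label] = biomech.time_normalize(envelopes[cond][m], ev)

        ankle_angle = tr.channels["ankle_angle"]          # dorsiflexion-positive deg
        exo_angle = tr.channels["exo_angle"]
        pf_angle = SampledSignal(ankle_angle.rate, -ankle_angle.values, "deg")
        pf_exo_angle = SampledSignal(exo_angle.rate, -exo_angle.values, "deg")
        ang_ens = biomech.time_normalize(ankle_angle, ev)
        exo_ang_ens = biomech.time_normalize(exo_angle, ev)
        rom[label] = {
            "bio": biomech.angle_extremes(ang_ens),
            "exo": biomech.angle_extremes(exo_ang_ens),
        }
        for ch in ("ankle_angle", "ankle_moment", "knee_angle", "knee_moment",
                   "hip_angle", "hip_moment"):
            mech_curves.setdefault(ch, {})[label] = biomech.time_normalize(
                tr.channels[ch], ev).mean

        if label in POWERED_WINDOWS:
            total_m = biomech.time_normalize(tr.channels["ankle_moment"], ev)
            exo_tau = biomech.time_normalize(powered_out.torque, ev)
            vel = biomech.velocity_from_signal(pf_angle, ev)
            dec = biomech.decompose_ankle(
                total_m, exo_tau, cfg.generator.body_mass,
                biomech.time_normalize(pf_angle, ev),
                exo_angle=biomech.time_normalize(pf_exo_angle, ev),
                velocity=vel, use_exo_angle=cfg.use_exo_angle,
            )
            decomp[label] = {
                "peak_power_share": dec.peak_power_share,
                "peak_moment_share": dec.peak_moment_share,
                "positive_work_share": dec.positive_work_share,
                "peak_exo_power_w_per_kg": float(dec.exo_power.mean.max()),
                "peak_total_power_w_per_kg": float(dec.total_power.mean.max()),
                "peak_exo_moment_nm_per_kg": float(dec.exo_moment.mean.max()),
                "peak_total_moment_nm_per_kg": float(dec.total_moment.mean.max()),
                "work_pos_j_per_kg": dec.work_pos,
                "work_neg_j_per_kg": dec.work_neg,
            }

    # --- EMG normalization + RMS rows ---
    rms_rows = []
    norm_curves: dict[str, dict[str, np.ndarray]] = {}
    for m in MUSCLES:
        norm = emg_metrics.normalize_emg(emg_ens[m], reference="BootsOnly")
        norm_curves[m] = {label: ens.mean for label, ens in norm.items()}
        for label, ens in norm.items():
            rms_rows.append({
                "subject": subject_id,
                "muscle": m.upper(),
                "condition": label,
                "phase": RMS_PHASE[m],
                "rms": emg_metrics.phase_rms(ens, RMS_PHASE[m]),
            })

    return SubjectResult(
        subject_id=subject_id,
        rms_rows=rms_rows,
        norm_emg_curves=norm_curves,
        mech_curves=mech_curves,
        rom_extremes=rom,
        decomposition=decomp,
        calibration={
            "gain_a_per_unit": ctl.calibration.gain,
            "threshold": ctl.calibration.threshold,
            "method": ctl.calibration.method,
        },
    )


def _scalar_result_json(r: stats.ScalarTestResult) -> dict:
    return {
        "F": r.F, "df": list(r.df), "p": r.p, "kind": r.kind,
        "posthoc": [
            {"pair": list(pair), "mean_diff": md, "p_adj": p}
            for pair, md, p in r.posthoc
        ],
    }


def _spm_result_json(r: stats.SPMResult) -> dict:
    return {
        "threshold": r.threshold,
        "p_max": r.p_max,
        "n_perm": r.n_perm,
        "clusters": [
            {"start_pct": s, "end_pct": e, "p": p} for s, e, p in r.clusters
        ],
        "significant": r.significant,
    }


def group_analysis(subjects: list[SubjectResult], cfg: PipelineConfig) -> dict:
    """Group-level outcomes across all subjects."""
    df = emg_metrics.rms_table([row for s in subjects for row in s.rms_rows])
    labels = [w[0] for w in ANALYSIS_WINDOWS]
    report: dict = {"n_subjects": len(subjects), "windows": labels}

    # percent change + SMD, Boots Only -> PoweredEnd
    pct, smd_vals, anova = {}, {}, {}
    for m in MUSCLES:
        sub = df[df.muscle == m.upper()].pivot(
            index="subject", columns="condition", values="rms")
        per_subject = [
            emg_metrics.percent_change(a, b)
            for a, b in zip(sub["BootsOnly"], sub["PoweredEnd"])
        ]
        pct[m] = {
            "per_subject": per_subject,
            "mean": float(np.mean(per_subject)),
            "min": float(np.min(per_subject)),
            "max": float(np.max(per_subject)),
            "fraction_decreasing": float(np.mean(np.asarray(per_subject) < 0)),
        }
        s = emg_metrics.smd(
            sub["BootsOnly"].mean(), sub["PoweredEnd"].mean(),
            sub["BootsOnly"].std(ddof=1), sub["PoweredEnd"].std(ddof=1),
        )
        smd_vals[m] = {"value": float(s), "label": emg_metrics.smd_label(s)}
        groups = {lab: sub[lab].to_numpy() for lab in labels}
        anova[m] = _scalar_result_json(
            stats.oneway_anova(groups, cfg.repeated_measures, cfg.alpha))
    report["percent_change"] = pct
    report["smd"] = smd_vals
    report["rms_anova"] = anova

    # permutation SPM over the cycle: EMG and joint curves
    if cfg.run_spm:
        spm: dict[str, dict] = {}
        for m in MUSCLES:
            ens = {
                lab: np.vstack([s.norm_emg_curves[m][lab] for s in subjects])
                for lab in labels
            }
            spm[f"emg_{m}"] = _spm_result_json(stats.spm_anova_permutation(
                ens, cfg.spm_permutations, cfg.alpha,
                seed=cfg.generator.seed + 17))
        for ch in ("ankle_angle", "ankle_moment", "knee_angle", "knee_moment",
                   "hip_angle", "hip_moment"):
            ens = {
                lab: np.vstack([s.mech_curves[ch][lab] for s in subjects])
                for lab in labels
            }
            spm[ch] = _spm_result_json(stats.spm_anova_permutation(
                ens, cfg.spm_permutations, cfg.alpha,
                seed=cfg.generator.seed + 29))
        report["spm"] = spm

    # ankle decomposition, group means over subjects
    dec = {}
    for w in POWERED_WINDOWS:
        keys = subjects[0].decomposition[w]
        dec[w] = {
            k: float(np.mean([s.decomposition[w][k] for s in subjects]))
            for k in keys if not isinstance(keys[k], dict)
        }
        for wk in ("work_pos_j_per_kg", "work_neg_j_per_kg"):
            dec[w][wk] = {
                comp: float(np.mean([s.decomposition[w][wk][comp] for s in subjects]))
                for comp in ("exo", "bio", "total")
            }
    report["decomposition"] = dec

    # angle-source ROM comparison over the device-worn conditions
    rom_windows = ("Unpowered", "PoweredStart", "PoweredEnd")
    bio_ext = [
        tuple(np.mean([s.rom_extremes[w]["bio"] for s in subjects], axis=0))
        for w in rom_windows
    ]
    exo_ext = [
        tuple(np.mean([s.rom_extremes[w]["exo"] for s in subjects], axis=0))
        for w in rom_windows
    ]
    diffs, avg = biomech.rom_comparison(bio_ext, exo_ext)
    report["rom_comparison"] = {
        "windows": list(rom_windows),
        "bio_extremes_deg": [list(x) for x in bio_ext],
        "exo_extremes_deg": [list(x) for x in exo_ext],
        "difference_deg": diffs.tolist(),
        "average_difference_deg": float(avg),
    }
    return report


def run_pipeline(cfg: Optional[PipelineConfig] = None) -> dict:
    """Simulate the full protocol and return the complete report."""
    from .io import config_hash

    cfg = cfg or PipelineConfig()
    gen = cfg.generator
    subjects = []
    for si in range(gen.n_subjects):
        trials = {
            e.condition: generate_trial(gen, si, e.condition) for e in gen.timeline
        }
        subjects.append(analyze_subject(trials, cfg))

    report = {
        "config_hash": config_hash(cfg.model_dump(mode="json")),
        "seed": gen.seed,
        "subjects": {
            s.subject_id: {
                "rms": s.rms_rows,
                "calibration": s.calibration,
                "decomposition": s.decomposition,
            }
            for s in subjects
        },
        "group": group_analysis(subjects, cfg),
    }
    return report
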