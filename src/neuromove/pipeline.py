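"""End-to-end orchestration: generate -> extract -> summarize -> test.

``run_pipeline`` turns a configured synthetic cohort into tidy metric
tables, the study's mixed-ANOVA and correlation results, and a
ground-truth-vs-recovered comparison, all written as CSV/JSON into a
results directory.  Every output carries the configuration hash so a run
can be reproduced bit-identically from its own manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import feeg, fnirs, io, kinematics, stats, synthetic
from .types import CONDITIONS, HANDS

__all__ = ["RunConfig", "PipelineResult", "extract_subject", "run_pipeline", "import_session"]

log = logging.getLogger("neuromove")


@dataclass
class RunConfig:
    """Validated run configuration; fully serialized into the output dir."""

    output_dir: str = "results"
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    seed: int | None = None  # overrides cohort.seed when set
    export_raw: bool = False  # write per-session CSV directories (large)
    alpha: float = 0.05

    def resolved(self) -> "RunConfig":
        if self.seed is not None:
            self.cohort.seed = int(self.seed)
        self.cohort.validate()
        return self

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "cohort": self.cohort.to_dict(),
            "seed": self.seed,
            "export_raw": self.export_raw,
            "alpha": self.alpha,
        }

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        d = self.to_dict()
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


#: ANOVA designs run per metric: metric -> (task, within factors)
ANOVA_DESIGNS: dict[str, tuple[str, tuple[str, ...]]] = {
    "ipe": ("steer", ("hand",)),
    "mt": ("steer", ("hand",)),
    "bias": ("steer", ("hand",)),
    "trunk_flexion_range@steer": ("steer", ("hand",)),
    "elbow_extension_range@steer": ("steer", ("hand",)),
    "panu": ("reach", ("hand",)),
    "hand_mean_velocity": ("reach", ("hand", "condition")),
    "trunk_flexion_range@reach": ("reach", ("hand", "condition")),
    "elbow_extension_range@reach": ("reach", ("hand", "condition")),
    "hbo_peak@steer": ("steer", ("hand", "hemisphere")),
    "hbo_peak@reach": ("reach", ("hand", "condition", "hemisphere")),
    "alpha_erd@steer": ("steer", ("hand", "hemisphere")),
    "beta_erd@steer": ("steer", ("hand", "hemisphere")),
    "alpha_ers@steer": ("steer", ("hand", "hemisphere")),
    "beta_ers@steer": ("steer", ("hand", "hemisphere")),
    "alpha_erd@reach": ("reach", ("hand", "condition", "hemisphere")),
    "beta_erd@reach": ("reach", ("hand", "condition", "hemisphere")),
    "alpha_ers@reach": ("reach", ("hand", "condition", "hemisphere")),
    "beta_ers@reach": ("reach", ("hand", "condition", "hemisphere")),
}

#: Spearman correlations computed in the stroke group with the paretic hand:
#: (task, condition, movement metric, brain metric, hemisphere role)
CORRELATION_SPECS = [
    ("steer", None, "trunk_flexion_range", "alpha_erd", "contralateral"),
    ("steer", None, "trunk_flexion_range", "alpha_erd", "ipsilateral"),
    ("steer", None, "ipe", "beta_ers", "ipsilateral"),
    ("steer", None, "ipe", "beta_ers", "contralateral"),
    ("steer", None, "mt", "beta_ers", "ipsilateral"),
    ("reach", "MAU", "elbow_extension_range", "hbo_peak", "ipsilateral"),
    ("reach", "MAU", "elbow_extension_range", "hbo_peak", "contralateral"),
    ("reach", "SAU", "elbow_extension_range", "beta_ers", "ipsilateral"),
    ("reach", "SAU", "elbow_extension_range", "beta_ers", "contralateral"),
    ("steer", None, "FM_UE", "alpha_erd", "ipsilateral"),
    ("steer", None, "FM_UE", "alpha_erd", "contralateral"),
    ("reach", "MAU", "FM_UE", "hbo_peak", "ipsilateral"),
    ("reach", "MAU", "FM_UE", "hbo_peak", "contralateral"),
]


def extract_subject(subject: synthetic.Subject) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Movement and brain metrics for every session cell of one subject.

    Returns (movement_rows, brain_rows) as tidy frames.  Brain rows carry
    a ``hemisphere`` factor (contralateral/ipsilateral relative to the
    moving hand) plus the stroke lesion role when applicable.
    """
    mov_rows, brain_rows = [], []
    reach_au: dict[str, dict[str, float]] = {h: {} for h in HANDS}
    base = {"subject": subject.subject_id, "group": subject.group}
    for (task, hand, condition), sess in subject.sessions.items():
        cell = base | {"task": task, "hand": hand, "condition": condition}
        if task == "reach":
            rm = kinematics.reach_metrics(sess.skeleton, sess.schedule)
            reach_au[hand][condition] = rm.arm_use
            mov_rows.append(cell | {
                "trunk_flexion_range": rm.trunk_flexion_range,
                "elbow_extension_range": rm.elbow_extension_range,
                "hand_mean_velocity": rm.hand_mean_velocity,
                "arm_use": rm.arm_use,
            })
        else:
            sm = kinematics.steering_metrics_blocks(sess.cursor, sess.schedule)
            trunk_r, elbow_r = kinematics.posture_ranges(sess.skeleton, sess.schedule)
            mov_rows.append(cell | {
                "ipe": sm.ipe, "ide": sm.ide, "mt": sm.mt, "speed": sm.speed,
                "bias": sm.bias, "error_rate": sm.error_rate,
                "R": sm.R, "sigma": sm.sigma,
                "trunk_flexion_range": trunk_r, "elbow_extension_range": elbow_r,
            })
        # fNIRS
        hemo = fnirs.od_to_hemoglobin(sess.optical)
        hemo = fnirs.preprocess_hemo(hemo, raw=sess.optical)
        epochs = fnirs.block_average(hemo, sess.schedule)
        peaks = fnirs.peak_hbo2(epochs)
        side = subject.hand_side(hand)
        roles = fnirs.hemisphere_summary(
            peaks, hemo.hemispheres, side, subject.lesion_side, hemo.quality
        )
        # EEG
        rec = feeg.preprocess_eeg(sess.eeg)
        emap = feeg.ersp(rec, sess.schedule)
        summary = feeg.band_erd_ers(emap, sess.schedule)
        eeg_roles = feeg.hemisphere_summary_eeg(
            summary, rec.hemispheres, side, subject.lesion_side
        )
        for role, peak in roles.items():
            hemi_factor = role.split("/")[0]
            row = cell | {"hemisphere": hemi_factor, "role": role, "hbo_peak": peak}
            for measure, per_role in eeg_roles.items():
                row[measure] = per_role[role]
            brain_rows.append(row)
    # PANU per hand from the two reaching conditions
    for hand in HANDS:
        au = reach_au[hand]
        if "SAU" in au and "MAU" in au:
            mov_rows.append(base | {
                "task": "reach", "hand": hand, "condition": None,
                "panu": au["MAU"] - au["SAU"],
            })
    return pd.DataFrame(mov_rows), pd.DataFrame(brain_rows)


def _anova_table_for(metric: str, movement: pd.DataFrame, brain: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    name, _, task = metric.partition("@")
    if not task:
        task = ANOVA_DESIGNS[metric][0]
    source = brain if name in ("hbo_peak", "alpha_erd", "beta_erd", "alpha_ers", "beta_ers") else movement
    sub = source[source["task"] == task].copy()
    return sub, name


def run_statistics(
    movement: pd.DataFrame, brain: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mixed ANOVAs, post-hoc tables and stroke-group correlations."""
    anova_rows, posthoc_frames = [], []
    for metric, (task, within) in ANOVA_DESIGNS.items():
        sub, dv = _anova_table_for(metric, movement, brain)
        if dv not in sub.columns:
            continue
        sub = sub.dropna(subset=[dv])
        try:
            res = stats.mixed_anova(sub, dv=dv, between="group", within=within)
        except (ValueError, NotImplementedError) as exc:
            log.warning("ANOVA skipped for %s: %s", metric, exc)
            continue
        for _, r in res.table.iterrows():
            anova_rows.append({"metric": metric, "task": task, **r.to_dict()})
        # BH-corrected pairwise follow-ups for significant factors
        for _, r in res.table.iterrows():
            if r["p"] < alpha and r["eta2p"] > 0.02 and ":" not in r["effect"]:
                factor = r["effect"]
                ph = stats.posthoc_pairwise(sub, dv=dv, factor=factor)
                ph.insert(0, "metric", metric)
                ph.insert(1, "factor", factor)
                posthoc_frames.append(ph)
    anova = pd.DataFrame(anova_rows)
    posthoc = pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else pd.DataFrame()

    corr_rows = []
    stroke_mov = movement[(movement["group"] == "stroke") & (movement["hand"] == "nondominant")]
    stroke_brain = brain[(brain["group"] == "stroke") & (brain["hand"] == "nondominant")]
    for task, condition, xm, ym, hemi in CORRELATION_SPECS:
        bsub = stroke_brain[(stroke_brain["task"] == task) & (stroke_brain["hemisphere"] == hemi)]
        if condition is not None:
            bsub = bsub[bsub["condition"] == condition]
        if xm == "FM_UE":
            xs = clinical.set_index("subject")["FM_UE"]
        else:
            msub = stroke_mov[stroke_mov["task"] == task]
            if condition is not None:
                msub = msub[msub["condition"] == condition]
            if xm not in msub.columns:
                continue
            xs = msub.set_index("subject")[xm]
        if ym not in bsub.columns:
            continue
        ys = bsub.set_index("subject")[ym]
        common = xs.index.intersection(ys.index)
        if len(common) < 4:
            continue
        try:
            cr = stats.spearman_partial(
                xs.loc[common], ys.loc[common], x_name=xm, y_name=ym
            )
        except ValueError:
            continue
        corr_rows.append({
            "task": task, "condition": condition, "x": xm, "y": ym,
            "hemisphere": hemi, "rho": cr.rho, "r_s2": cr.r_s2, "p": cr.p,
            "n": cr.n, "reported": cr.reported, "method": "spearman (no covariates)",
        })
    return anova, posthoc, pd.DataFrame(corr_rows)


def recovery_table(movement: pd.DataFrame, brain: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Injected vs recovered parameters per subject and cell."""
    rows = []
    key = ["subject", "task", "hand", "condition"]
    mov = movement.copy()
    contra = brain[brain["hemisphere"] == "contralateral"].copy()
    truth = truth.copy()
    for df in (mov, contra, truth):
        df["condition"] = df["condition"].astype(object).where(pd.notna(df["condition"]), "")
    merged = truth.merge(mov, on=key, how="left", suffixes=("_true", "")) \
                  .merge(contra[key + ["hbo_peak", "beta_erd"]], on=key, how="left")
    for _, r in merged.iterrows():
        pairs = [
            ("trunk_range_deg", r.get("trunk_range_deg"), r.get("trunk_flexion_range")),
            ("elbow_range_deg", r.get("elbow_range_deg"), r.get("elbow_extension_range")),
            ("radial_sd_mm", r.get("radial_sd_mm"), r.get("sigma")),
            ("lap_rate", r.get("lap_rate"), r.get("speed")),
            ("hrf_amp_contra_um", r.get("hrf_amp_contra_um"), r.get("hbo_peak")),
            ("beta_erd_contra_db", r.get("beta_erd_contra_db"), r.get("beta_erd")),
        ]
        for name, inj, rec in pairs:
            if inj is None or rec is None or pd.isna(inj) or pd.isna(rec):
                continue
            rows.append({
                "subject": r["subject"], "task": r["task"], "hand": r["hand"],
                "condition": r["condition"], "parameter": name,
                "injected": float(inj), "recovered": float(rec),
                "error": float(rec) - float(inj),
            })
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    output_dir: Path
    movement: pd.DataFrame
    brain: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    correlations: pd.DataFrame
    recovery: pd.DataFrame
    manifest: dict


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full synthetic study; see the module docstring."""
    config = config.resolved()
    t_start = _time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    captured: list[str] = []
    try:
        log.info("config hash %s; generating cohort (n=%d/group, seed=%d)",
                 cfg_hash, config.cohort.n_per_group, config.cohort.seed)
        subjects, truth = synthetic.generate_cohort(config.cohort)
        mov_frames, brain_frames, clin_rows, failures = [], [], [], []
        for subj in subjects:
            try:
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    mv, br = extract_subject(subj)
                captured.extend(f"{subj.subject_id}: {w.message}" for w in wlist)
                mov_frames.append(mv)
                brain_frames.append(br)
                clin_rows.append({"subject": subj.subject_id, "group": subj.group,
                                  "lesion_side": subj.lesion_side, **subj.clinical})
                if config.export_raw:
                    for cell, sess in subj.sessions.items():
                        label = "-".join(str(c) for c in cell if c)
                        io.write_session(sess, out / "sessions" / subj.subject_id / label)
            except Exception as exc:  # stage-level isolation per subject
                log.error("subject %s failed: %s", subj.subject_id, exc)
                failures.append({"subject": subj.subject_id, "error": str(exc)})
        if not mov_frames:
            raise RuntimeError("all subjects failed extraction")
        movement = pd.concat(mov_frames, ignore_index=True)
        brain = pd.concat(brain_frames, ignore_index=True)
        clinical = pd.DataFrame(clin_rows)
        log.info("extracted %d movement rows, %d brain rows", len(movement), len(brain))
        anova, posthoc, correlations = run_statistics(movement, brain, clinical, config.alpha)
        recov = recovery_table(movement, brain, truth)

        _write_csv(movement, out / "movement_metrics.csv", cfg_hash)
        _write_csv(brain, out / "brain_metrics.csv", cfg_hash)
        _write_csv(clinical, out / "clinical.csv", cfg_hash)
        _write_csv(anova, out / "anova.csv", cfg_hash)
        _write_csv(posthoc, out / "posthoc.csv", cfg_hash)
        _write_csv(correlations, out / "correlations.csv", cfg_hash)
        _write_csv(recov, out / "recovery.csv", cfg_hash)
        _write_csv(truth, out / "ground_truth.csv", cfg_hash)
        manifest = {
            "config_hash": cfg_hash,
            "config": config.to_dict(),
            "n_subjects": len(subjects),
            "n_failed": len(failures),
            "failures": failures,
            "warnings": captured,
            "provenance": {
                "fnirs_band_hz": [0.01, 0.1],
                "fnirs_baseline_s": [-2.0, 0.0],
                "fnirs_peak_window_s": [0.0, 20.0],
                "eeg_band_hz": [1.0, 40.0],
                "ersp_window_s": 1.0,
                "ersp_overlap": 0.9,
                "erd_window": "0-2 s after each cue (reach) / task block (steer)",
                "ers_window": "2-4 s after each cue (reach) / 0-4 s post block (steer)",
                "ers_origin": "post-movement latency",
                "correlation_method": "spearman, no covariates",
            },
            "elapsed_s": round(_time.time() - t_start, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, default=float))
        log.info("pipeline complete in %.1fs", manifest["elapsed_s"])
        return PipelineResult(out, movement, brain, anova, posthoc, correlations, recov, manifest)
    finally:
        log.removeHandler(handler)
        handler.close()


def import_session(path: str | Path, format: str = "csv_dir") -> "synthetic.Session":
    """Load one recorded session bundle from disk.

    Only the canonical CSV-directory layout is supported; see
    :mod:`neuromove.io` for the format.
    """
    if format == "csv_dir":
        p = Path(path)
        missing = [f for f in ("schedule.json", "od.csv", "eeg.csv") if not (p / f).exists()]
        if missing:
            found = sorted(x.name for x in p.glob("*")) if p.exists() else []
            raise FileNotFoundError(
                f"session at {p} is missing {missing}; found streams: {found}"
            )
        return io.read_session(p)
    raise ValueError(f"unsupported session format {format!r}; use 'csv_dir'")
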