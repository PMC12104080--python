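"""End-to-end pipeline: simulate → classify → tfs → derive → analyze.

Every stage is a pure function of its declared CSV inputs; outputs carry a
provenance header (package version, stage, seed, config hash) as ``#``
comment lines, so re-running with an identical configuration reproduces
byte-identical files.
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

from . import __version__
from .biomarkers import derive_table
from .cohort import CohortConfig, cohort_frames, generate_cohort, write_cohort
from .errors import DerivationError, DgfKineticsError, PipelineError, SeparationError
from .fdgf import CreatinineSeries, classify, classify_cohort
from .renography import RenogramCurve, fit_curve_tfs
from .stats import (
    ROC_MARKERS,
    build_cohort_table,
    complete_case,
    group_summary,
    linear_diff,
    logistic_or,
    pearson,
    roc_auc,
)

log = logging.getLogger("dgf_kinetics")

__all__ = ["PipelineConfig", "run_pipeline", "analyze_table", "cohort_to_table"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run."""

    out_dir: str | Path = "results"
    seed: int = 0
    cohort: CohortConfig | None = None       #: None → default profile with `seed`
    input_dir: str | Path | None = None      #: pre-existing cohort dir (skips simulate)
    spontaneity_rule: str = "exclude-post-dialysis"
    followup_end: int | None = None
    tfs_window: tuple[float, float] = (0.0, 120.0)
    tfs_method: str = "auto"
    tfs_fixed_breakpoint_s: float | None = None
    ci_method: str = "delong"
    n_boot: int = 2000
    complete_case: bool = False

    def resolved_cohort(self) -> CohortConfig:
        return self.cohort if self.cohort is not None else CohortConfig(seed=self.seed)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded, so
        identical analyses in different directories hash identically)."""
        def _enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            return str(obj)
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("input_dir", None)
        payload = json.dumps(payload, default=_enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(cfg: PipelineConfig, stage: str) -> list[str]:
    return [
        f"dgf-kinetics {__version__} stage={stage}",
        f"seed={cfg.seed} config_sha256={cfg.config_hash()}",
    ]


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in _provenance(cfg, stage):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, cohort_dir: Path) -> None:
    cohort_cfg = cfg.resolved_cohort()
    log.info("simulate: n=%d seed=%d -> %s", cohort_cfg.n_patients, cohort_cfg.seed,
             cohort_dir)
    try:
        cohort = generate_cohort(cohort_cfg)
    except DgfKineticsError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    write_cohort(cohort, cohort_dir, header_lines=_provenance(cfg, "simulate"))


def stage_classify(cfg: PipelineConfig, cohort_dir: Path, out_dir: Path) -> None:
    creatinine = _read(cohort_dir / "creatinine.csv")
    rows = []
    for pid, sub in creatinine.groupby("patient_id", sort=True):
        try:
            res = classify(CreatinineSeries.from_frame(sub),
                           cfg.spontaneity_rule, cfg.followup_end)
        except DgfKineticsError as exc:
            raise PipelineError("fdgf", str(exc), patient_id=str(pid)) from exc
        rows.append({
            "patient_id": pid, "present": res.present,
            "by_dialysis": res.by_dialysis, "index_day": res.resolution_index_day,
            "duration_days": res.duration_days, "censored": res.censored,
            "group": res.group,
        })
    _write(pd.DataFrame(rows), out_dir / "fdgf.csv", cfg, "fdgf")


def stage_tfs(cfg: PipelineConfig, cohort_dir: Path, out_dir: Path) -> None:
    meta = _read(cohort_dir / "renogram_meta.csv")
    rows = []
    for _, m in meta.iterrows():
        pid, pod = str(m["patient_id"]), int(m["pod"])
        frames = _read(cohort_dir / f"renogram_{pid}_{pod}.csv")
        curve = RenogramCurve(
            t=frames["t_seconds"].to_numpy(dtype=float),
            graft_counts=frames["graft_counts"].to_numpy(dtype=float),
            background_counts=frames["background_counts"].to_numpy(dtype=float),
            dose_mbq=float(m["dose_mbq"]),
            extravasation_fraction=float(m["extravasation_fraction"]),
            roi_area_ratio=float(m["roi_area_ratio"]),
            counts_per_mbq_s=float(m.get("counts_per_mbq_s", 1.0)),
        )
        try:
            res = fit_curve_tfs(curve, window_s=cfg.tfs_window, method=cfg.tfs_method,
                                fixed_breakpoint_s=cfg.tfs_fixed_breakpoint_s)
        except DgfKineticsError as exc:
            raise PipelineError("tfs", str(exc), patient_id=pid, pod=pod) from exc
        rows.append({
            "patient_id": pid, "pod": pod,
            "tfs_slope_units": res.tfs_slope_units,
            "breakpoint_s": res.breakpoint_s,
            "phase1_slope_units": res.phase1_slope / 1e-3,
            "fit_sse": res.fit_sse,
            "n_frames_phase2": res.n_frames_phase2,
        })
    _write(pd.DataFrame(rows), out_dir / "tfs.csv", cfg, "tfs")


def stage_derive(cfg: PipelineConfig, cohort_dir: Path, out_dir: Path) -> None:
    biomarkers = _read(cohort_dir / "biomarkers.csv")
    try:
        derived = derive_table(biomarkers)
    except DgfKineticsError as exc:
        raise PipelineError("derive", str(exc)) from exc
    _write(derived, out_dir / "derived.csv", cfg, "derive")


#: Quantities summarized in the Table-1/Figure-2 style group-summary output.
SUMMARY_QUANTITIES = ROC_MARKERS

_KDRI_COLLAPSE = {"<1": "<1", "1-1.5": "1-1.5", "1.5-2": ">=1.5", ">=2": ">=1.5"}
_FDGF_COLLAPSE = {"no": "no", "mild": "mild_moderate", "moderate": "mild_moderate",
                  "severe": "severe"}


def _or_rows(table, outcome, exposure, reference, levels, risk_factor):
    try:
        ests = logistic_or(table, outcome, exposure, reference, levels)
        note = ""
    except SeparationError:
        # the ML odds ratio diverges; report unbounded estimates explicitly
        ests = None
        note = "separation"
    rows = []
    if ests is None:
        for lev in [reference] + list(levels):
            rows.append({"risk_factor": risk_factor, "level": lev,
                         "odds_ratio": 1.0 if lev == reference else np.inf,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "n_used": np.nan, "note": note})
    else:
        for e in ests:
            rows.append({"risk_factor": risk_factor, "level": e.level,
                         "odds_ratio": e.odds_ratio, "ci_low": e.ci95[0],
                         "ci_high": e.ci95[1], "n_used": e.n_used, "note": note})
    return rows


def analyze_table(table: pd.DataFrame, cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run analysis steps 1-6 on an assembled cohort table.

    Returns the Table 1–4 analogues plus the TFS correlation table.
    """
    if cfg.complete_case:
        table = complete_case(table)
    rng = np.random.default_rng(cfg.seed + 1)

    # -- step 4: group summaries
    t1 = []
    for q in SUMMARY_QUANTITIES:
        for pod in (1, 4, 10):
            gs = group_summary(table, q, pod).reset_index()
            gs.insert(0, "pod", pod)
            gs.insert(0, "quantity", q)
            t1.append(gs)
    table1 = pd.concat(t1, ignore_index=True)

    # -- step 2: IF/TA vs KDRI and fDGF severity
    t2_table = table.copy()
    t2_table["kdri_cat"] = t2_table["kdri_category"].map(_KDRI_COLLAPSE)
    t2_table["fdgf_cat"] = t2_table["group"].map(_FDGF_COLLAPSE)
    t2_table["fdgf_yes"] = np.where(table["group"].isna(), None,
                                    np.where(table["group"] == "no", "no", "yes"))
    rows = []
    rows += _or_rows(t2_table, "ifta_present", "kdri_cat", "<1",
                     ["1-1.5", ">=1.5"], "kdri")
    rows += _or_rows(t2_table, "ifta_present", "fdgf_yes", "no", ["yes"], "fdgf")
    rows += _or_rows(t2_table, "ifta_present", "fdgf_cat", "no",
                     ["mild_moderate", "severe"], "fdgf_severity")
    table2 = pd.DataFrame(rows)

    # -- step 3: fDGF duration vs ECC at 6 weeks / 12 months
    rows = []
    for tp, col in (("6wk", "ecc_6wk_ml_min"), ("12mo", "ecc_12mo_ml_min")):
        sub = t2_table.copy()
        sub["ecc_low"] = (sub[col] < 40.0).where(sub[col].notna())
        rows += [dict(r, timepoint=tp, analysis="or_ecc_lt40")
                 for r in _or_rows(sub, "ecc_low", "fdgf_cat", "no",
                                   ["mild_moderate", "severe"], "fdgf_severity")]
        try:
            diffs = linear_diff(sub, col, "group", "no",
                                ["mild", "moderate", "severe"]).reset_index()
            for _, d in diffs.iterrows():
                rows.append({"risk_factor": "fdgf_group", "level": d["level"],
                             "odds_ratio": np.nan, "ci_low": d["ci_low"],
                             "ci_high": d["ci_high"], "n_used": d["n_used"],
                             "note": f"mean_diff={d['difference']:.6g}",
                             "timepoint": tp, "analysis": "mean_diff_ecc"})
        except DerivationError as exc:
            rows.append({"risk_factor": "fdgf_group", "level": "", "odds_ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "n_used": np.nan,
                         "note": str(exc), "timepoint": tp, "analysis": "mean_diff_ecc"})
    table3 = pd.DataFrame(rows)

    # -- step 5: Pearson correlations with TFS per POD
    rows = []
    for q in [m for m in ROC_MARKERS if m != "tfs"]:
        for pod in (1, 4, 10):
            col = f"{q}_pod{pod}"
            try:
                r, p = pearson(table[col], table[f"tfs_pod{pod}"])
                n = int((table[col].notna() & table[f"tfs_pod{pod}"].notna()).sum())
                rows.append({"quantity": q, "pod": pod, "r": r, "p": p, "n": n})
            except (DerivationError, KeyError):
                rows.append({"quantity": q, "pod": pod, "r": np.nan, "p": np.nan,
                             "n": 0})
    correlations = pd.DataFrame(rows)

    # -- step 6: ROC AUCs (presence at PODs 1/4, severity at POD 10)
    rows = []
    for marker in ROC_MARKERS:
        for pod, contrast in ((1, "fdgf_yes_vs_no"), (4, "fdgf_yes_vs_no"),
                              (10, "severe_vs_mild_moderate")):
            try:
                est = roc_auc(table, marker, pod, contrast,
                              ci_method=cfg.ci_method, n_boot=cfg.n_boot, rng=rng)
            except (DerivationError, KeyError) as exc:
                rows.append({"marker": marker, "pod": pod, "contrast": contrast,
                             "auc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "ci_low_raw": np.nan, "ci_high_raw": np.nan,
                             "n_pos": 0, "n_neg": 0, "note": str(exc)})
                continue
            lo_d, hi_d = est.ci95_display
            rows.append({"marker": marker, "pod": pod, "contrast": contrast,
                         "auc": est.auc, "ci_low": lo_d, "ci_high": hi_d,
                         "ci_low_raw": est.ci95[0], "ci_high_raw": est.ci95[1],
                         "n_pos": est.n_pos, "n_neg": est.n_neg, "note": ""})
    table4 = pd.DataFrame(rows)

    return {"table1": table1, "table2": table2, "table3": table3,
            "table4": table4, "correlations": correlations}


def cohort_to_table(
    cohort,
    spontaneity_rule: str = "exclude-post-dialysis",
    followup_end: int | None = None,
    tfs_window: tuple[float, float] = (0.0, 120.0),
    tfs_method: str = "auto",
) -> pd.DataFrame:
    """Run classify → tfs → derive in memory and assemble the analysis table.

    Equivalent to the file-based stages for a cohort of
    :class:`~dgf_kinetics.cohort.PatientRecord` objects.
    """
    frames = cohort_frames(cohort)
    fdgf = classify_cohort(frames["creatinine"], spontaneity_rule, followup_end)
    tfs_rows = []
    for rec in cohort:
        for pod in sorted(rec.renograms):
            res = fit_curve_tfs(rec.renograms[pod], window_s=tfs_window,
                                method=tfs_method)
            tfs_rows.append({"patient_id": rec.patient_id, "pod": pod,
                             "tfs_slope_units": res.tfs_slope_units})
    tfs = pd.DataFrame(tfs_rows, columns=["patient_id", "pod", "tfs_slope_units"])
    derived = derive_table(frames["biomarkers"])
    return build_cohort_table(frames["patients"], fdgf, tfs, derived)


def load_cohort_table(cohort_dir: Path, out_dir: Path) -> pd.DataFrame:
    """Assemble the analysis table from the stage CSV outputs."""
    return build_cohort_table(
        patients=_read(cohort_dir / "patients.csv"),
        fdgf=_read(out_dir / "fdgf.csv"),
        tfs=_read(out_dir / "tfs.csv"),
        derived=_read(out_dir / "derived.csv"),
    )


def stage_analyze(cfg: PipelineConfig, cohort_dir: Path, out_dir: Path) -> None:
    try:
        table = load_cohort_table(cohort_dir, out_dir)
        results = analyze_table(table, cfg)
    except DgfKineticsError as exc:
        raise PipelineError("analyze", str(exc)) from exc
    for name, df in results.items():
        _write(df, out_dir / f"{name}.csv", cfg, "analyze")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; returns the result directory."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.input_dir is not None:
        cohort_dir = Path(cfg.input_dir)
    else:
        cohort_dir = out_dir / "cohort"
        stage_simulate(cfg, cohort_dir)
    stage_classify(cfg, cohort_dir, out_dir)
    stage_tfs(cfg, cohort_dir, out_dir)
    stage_derive(cfg, cohort_dir, out_dir)
    stage_analyze(cfg, cohort_dir, out_dir)
    return out_dir
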