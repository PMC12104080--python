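"""Comparative statistics ranking biomarkers against the tubular function slope.

Implements the study's six analysis steps on the assembled patient-level
table: (1) baseline summaries, (2) logistic regression for IF/TA presence by
KDRI or fDGF severity, (3) logistic regression for ECC < 40 mL/min and linear
regression for ECC change, (4) median (IQR) per group and POD, (5) Pearson
correlations of markers with TFS, and (6) ROC AUCs for fDGF presence
(PODs 1/4) and severity (POD 10), with a complete-case sensitivity mode.

The AUC is the Mann–Whitney concordance P(marker_case > marker_control) with
half-credit for ties; its default confidence interval is DeLong's, with a
seeded stratified bootstrap as the opt-in alternative.  AUC is invariant
under any strictly monotone transform of the marker, so SD-standardization
(applied before regressions for scale comparability) cannot change it.

Missing-data policy: pairwise deletion per marker/POD for correlations and
ROC; listwise deletion within each regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr, rankdata

from .biomarkers import ANALYTES
from .errors import DerivationError, SeparationError
from .fdgf import GROUPS

__all__ = [
    "OrEstimate",
    "AucEstimate",
    "build_cohort_table",
    "group_summary",
    "logistic_or",
    "linear_diff",
    "pearson",
    "mann_whitney_auc",
    "roc_auc",
    "complete_case",
    "CONTRASTS",
]

CONTRASTS = ("fdgf_yes_vs_no", "severe_vs_mild_moderate")

#: Markers entering Table-4-style ROC comparisons (column stem per POD).
ROC_MARKERS = (
    ["tfs", "u_creatinine", "pcr"]
    + [f"{a}_cr" for a in ANALYTES]
    + ["fe_ngal", "fe_b2m", "ngal_over_timp2", "b2m_over_timp2"]
)


@dataclass(frozen=True)
class OrEstimate:
    """Odds ratio with Wald 95% CI from an indicator-coded logistic fit."""

    level: str
    reference_level: str
    odds_ratio: float
    ci95: tuple[float, float]
    n_used: int

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.odds_ratio <= hi):
            raise ValueError("CI must bracket the odds ratio")


@dataclass(frozen=True)
class AucEstimate:
    """Mann–Whitney AUC with CI; raw CI bounds are kept un-truncated."""

    marker: str
    pod: int
    contrast: str
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    ci_method: str = "delong"

    @property
    def ci95_display(self) -> tuple[float, float]:
        """CI truncated to [0, 1] for tabular display."""
        lo, hi = self.ci95
        return (max(lo, 0.0), min(hi, 1.0))


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def build_cohort_table(
    patients: pd.DataFrame,
    fdgf: pd.DataFrame,
    tfs: pd.DataFrame,
    derived: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the one-row-per-patient analysis table.

    Inputs follow the pipeline CSV contracts (`patients.csv`, `fdgf.csv`,
    `tfs.csv`, `derived.csv`).  Output columns: fDGF group/presence and
    duration, ``tfs_pod{1,4,10}`` in slope units, every derived quantity as
    ``{quantity}_pod{pod}``, IF/TA, KDRI category and ECC outcomes.
    """
    table = patients.set_index("patient_id").copy()
    if "ifta_present" in table.columns:
        table["ifta_present"] = table["ifta_present"].map(
            {True: 1.0, False: 0.0, "True": 1.0, "False": 0.0})
    table = table.join(fdgf.set_index("patient_id")
                       [["present", "by_dialysis", "index_day",
                         "duration_days", "censored", "group"]])

    tfs_wide = tfs.pivot(index="patient_id", columns="pod", values="tfs_slope_units")
    tfs_wide.columns = [f"tfs_pod{int(p)}" for p in tfs_wide.columns]
    table = table.join(tfs_wide)

    drv = derived.pivot(index="patient_id", columns=["quantity", "pod"], values="value")
    drv.columns = [f"{q}_pod{int(p)}" for q, p in drv.columns]
    table = table.join(drv)
    return table


# ---------------------------------------------------------------------------
# step 4: group summaries
# ---------------------------------------------------------------------------

def group_summary(table: pd.DataFrame, quantity: str, pod: int | None = None) -> pd.DataFrame:
    """Median (IQR) of a quantity per fDGF group and overall.

    Quartiles use the linear-interpolation convention.  An empty group is
    reported as missing, not an error.
    """
    col = quantity if pod is None else f"{quantity}_pod{pod}"
    rows = []
    for name in ("all",) + GROUPS:
        vals = table[col] if name == "all" else table.loc[table["group"] == name, col]
        vals = vals.dropna().to_numpy(dtype=float)
        if vals.size == 0:
            rows.append({"group": name, "n": 0, "median": np.nan,
                         "q1": np.nan, "q3": np.nan})
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"group": name, "n": int(vals.size), "median": med,
                         "q1": q1, "q3": q3})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# steps 2-3: regressions
# ---------------------------------------------------------------------------

def _design(sub: pd.DataFrame, exposure: str, levels, reference: str):
    X = np.column_stack(
        [np.ones(len(sub))]
        + [(sub[exposure] == lev).to_numpy(dtype=float) for lev in levels]
    )
    return X


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Jeffreys-prior-penalized logistic fit (Firth); returns (beta, se)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        pi = expit(X @ beta)
        w = np.clip(pi * (1.0 - pi), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        root_w = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,jk,ik->i", root_w, info_inv, root_w)
        score = X.T @ (y - pi + h * (0.5 - pi))
        delta = info_inv @ score
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break
    pi = expit(X @ beta)
    w = np.clip(pi * (1.0 - pi), 1e-12, None)
    info = X.T @ (X * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def logistic_or(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    reference: str,
    levels: list[str] | None = None,
    firth: bool = False,
) -> list[OrEstimate]:
    """Odds ratios per exposure level vs. a reference, with Wald 95% CIs.

    Maximum-likelihood logistic regression with indicator coding and
    listwise deletion.  Perfect or quasi-separation raises
    :class:`SeparationError` (no silent fallback); ``firth=True`` opts into
    the Jeffreys-penalized fit, which is always finite.
    """
    import statsmodels.api as sm

    sub = table[[outcome, exposure]].dropna()
    if levels is None:
        levels = [lev for lev in sub[exposure].unique() if lev != reference]
        levels = sorted(levels)
    y = sub[outcome].astype(bool).astype(float).to_numpy()
    if len(set(y)) < 2:
        raise SeparationError(f"outcome {outcome!r} has a single class after deletion")
    X = _design(sub, exposure, levels, reference)

    if firth:
        params, bse = _firth_logit(X, y)
    else:
        from statsmodels.tools.sm_exceptions import (
            ConvergenceWarning,
            PerfectSeparationWarning,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                # separation is re-detected below and raised as SeparationError
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", PerfectSeparationWarning)
                res = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
        except (np.linalg.LinAlgError, RuntimeWarning, Exception) as exc:
            if isinstance(exc, (np.linalg.LinAlgError, RuntimeWarning)) or \
                    "Separation" in type(exc).__name__ or "separation" in str(exc).lower():
                raise SeparationError(
                    f"logistic fit for {outcome!r} ~ {exposure!r} did not converge "
                    "(perfect or quasi-separation); use firth=True for a finite estimate"
                ) from exc
            raise
        if (not res.mle_retvals.get("converged", False)
                or np.any(np.abs(res.params) > 15)):
            raise SeparationError(
                f"logistic fit for {outcome!r} ~ {exposure!r} did not converge "
                "(perfect or quasi-separation); use firth=True for a finite estimate"
            )
        params, bse = res.params, res.bse

    out = [OrEstimate(level=reference, reference_level=reference,
                      odds_ratio=1.0, ci95=(1.0, 1.0), n_used=len(sub))]
    for j, lev in enumerate(levels, start=1):
        coef, se = params[j], bse[j]
        out.append(OrEstimate(
            level=str(lev),
            reference_level=reference,
            odds_ratio=float(np.exp(coef)),
            ci95=(float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))),
            n_used=len(sub),
        ))
    return out


def linear_diff(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    reference: str,
    levels: list[str] | None = None,
) -> pd.DataFrame:
    """Mean differences vs. a reference level with t-based 95% CIs (OLS)."""
    import statsmodels.api as sm

    sub = table[[outcome, exposure]].dropna()
    if levels is None:
        levels = sorted(lev for lev in sub[exposure].unique() if lev != reference)
    for lev in list(levels) + [reference]:
        if (sub[exposure] == lev).sum() < 2:
            raise DerivationError(f"exposure level {lev!r} has fewer than 2 rows")
    y = sub[outcome].astype(float).to_numpy()
    X = _design(sub, exposure, levels, reference)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    rows = [{"level": reference, "difference": 0.0, "ci_low": 0.0, "ci_high": 0.0,
             "n_used": len(sub)}]
    for j, lev in enumerate(levels, start=1):
        rows.append({"level": str(lev), "difference": float(res.params[j]),
                     "ci_low": float(ci[j, 0]), "ci_high": float(ci[j, 1]),
                     "n_used": len(sub)})
    return pd.DataFrame(rows).set_index("level")


# ---------------------------------------------------------------------------
# step 5: correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DerivationError("Pearson correlation needs >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DerivationError("Pearson correlation undefined: zero variance")
    r, p = pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# step 6: ROC
# ---------------------------------------------------------------------------

def mann_whitney_auc(pos, neg) -> float:
    """AUC = P(pos > neg) + 0.5 * P(tie), via midranks."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DerivationError("AUC needs both classes non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from structural components."""
    m, n = len(pos), len(neg)
    ranks_all = rankdata(np.concatenate([pos, neg]))
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    auc = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks_all[:m] - ranks_pos) / n        # per-case placement values
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m  # per-control placement values
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def delong_ci(pos, neg, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC and its DeLong Wald CI (raw, not truncated to [0, 1])."""
    from scipy.stats import norm

    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    auc, var = _delong(pos, neg)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (auc - half, auc + half)


def bootstrap_ci(pos, neg, n_boot: int = 2000, level: float = 0.95,
                 rng: np.random.Generator | None = None) -> tuple[float, tuple[float, float]]:
    """AUC with a stratified-bootstrap percentile CI (seeded)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    auc = mann_whitney_auc(pos, neg)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = mann_whitney_auc(
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return auc, (float(lo), float(hi))


def _contrast_labels(table: pd.DataFrame, contrast: str) -> pd.Series:
    if contrast == "fdgf_yes_vs_no":
        return (table["group"] != "no").astype(int)
    if contrast == "severe_vs_mild_moderate":
        sub = table["group"].where(table["group"] != "no")
        return (sub == "severe").astype(float).where(sub.notna())
    raise ValueError(f"contrast must be one of {CONTRASTS}")


def roc_auc(
    table: pd.DataFrame,
    marker: str,
    pod: int,
    contrast: str,
    ci_method: str = "delong",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> AucEstimate:
    """ROC AUC of a marker at a POD for an fDGF contrast.

    Orientation is fixed so that a *higher* marker predicts fDGF; TFS is
    auto-negated (lower tubular extraction means worse function).  The
    severe contrast compares severe vs. mild–moderate, excluding patients
    without fDGF.  Pairwise deletion on the marker.
    """
    col = marker if marker in table.columns else f"{marker}_pod{pod}"
    if col not in table.columns:
        raise KeyError(f"marker column {col!r} not in table")
    values = table[col].astype(float)
    if marker.startswith("tfs"):
        values = -values
    labels = _contrast_labels(table, contrast)
    ok = values.notna() & labels.notna()
    pos = values[ok & (labels == 1)].to_numpy()
    neg = values[ok & (labels == 0)].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise DerivationError(
            f"single-class input for contrast {contrast!r} at POD {pod} "
            f"(n_pos={len(pos)}, n_neg={len(neg)})"
        )
    if ci_method == "delong":
        auc, ci = delong_ci(pos, neg)
    elif ci_method == "bootstrap":
        auc, ci = bootstrap_ci(pos, neg, n_boot=n_boot, rng=rng)
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    return AucEstimate(marker=marker, pod=pod, contrast=contrast, auc=auc,
                       ci95=ci, n_pos=len(pos), n_neg=len(neg), ci_method=ci_method)


# ---------------------------------------------------------------------------
# complete-case sensitivity
# ---------------------------------------------------------------------------

def default_complete_case_fields() -> list[str]:
    """The declared analysis set: all ROC markers + TFS at PODs 4 and 10."""
    return [f"{m}_pod{p}" for p in (4, 10) for m in ROC_MARKERS]


def complete_case(table: pd.DataFrame, fields: list[str] | None = None) -> pd.DataFrame:
    """Retain rows complete on the declared analysis set."""
    if fields is None:
        fields = default_complete_case_fields()
    fields = [f for f in fields if f in table.columns]
    out = table.dropna(subset=fields)
    if out.empty:
        raise DerivationError("complete-case filter removed every patient")
    return out
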