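"""Urinary biomarker derivations.

From paired urine/serum measurements at a postoperative day this module
derives: creatinine-corrected analyte ratios (dilution correction),
protein-to-creatinine ratio (PCR), fractional excretions of NGAL and B2M
(computed like the fractional excretion of sodium), marker/TIMP2 ratios
(TIMP2 as an alternative glomerular-filtration denominator),
endogenous creatinine clearance from a 24-h collection, and the
SD-standardized versions used in regressions and ROC analyses.

Unit canon: analytes in µg/L, creatinine in µmol/L (ratios are expressed per
mmol creatinine), total protein in g/L, 24-h urine volume in L, FE in
percent, ECC in mL/min.  Missing inputs propagate to missing outputs — a
derived quantity is never fabricated from a partial panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DerivationError

__all__ = [
    "ANALYTES",
    "FE_ANALYTES",
    "BiomarkerPanel",
    "DerivedPanel",
    "fractional_excretion",
    "creatinine_ratio",
    "pcr",
    "ecc",
    "standardize",
    "derive_panel",
    "derive_table",
]

#: Urinary analytes quantified by the multiplex panel (µg/L).
ANALYTES = ("ngal", "b2m", "timp2", "igfbp7", "kim1", "cxcl9", "umod")

#: Analytes with a paired serum measurement, enabling fractional excretion.
FE_ANALYTES = ("ngal", "b2m")

MINUTES_PER_DAY = 1440.0


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def _check_positive(name: str, x: float) -> None:
    if x <= 0:
        raise DerivationError(f"{name} must be positive, got {x}")


def fractional_excretion(u_x, s_x, u_cr, s_cr):
    """Fractional excretion of analyte X in percent.

    FE_X = 100 * (U_X * S_cr) / (S_X * U_cr): the fraction of the filtered
    analyte load that escapes tubular reabsorption, computed exactly like
    the fractional excretion of sodium.  Urine and serum analyte must share
    units, as must urine and serum creatinine; the quotient is unit-free.
    Any missing input yields a missing result (never zero).
    """
    if any(_is_missing(v) for v in (u_x, s_x, u_cr, s_cr)):
        return np.nan
    for name, v in (("urine analyte", u_x), ("serum analyte", s_x),
                    ("urine creatinine", u_cr), ("serum creatinine", s_cr)):
        _check_positive(name, v)
    return 100.0 * (u_x * s_cr) / (s_x * u_cr)


def creatinine_ratio(u_x, u_cr_umol_l):
    """Analyte per mmol of urinary creatinine (dilution correction)."""
    if _is_missing(u_x) or _is_missing(u_cr_umol_l):
        return np.nan
    _check_positive("urine analyte", u_x)
    _check_positive("urine creatinine", u_cr_umol_l)
    return u_x / (u_cr_umol_l / 1000.0)


def pcr(u_tp_g_l, u_cr_umol_l):
    """Protein-to-creatinine ratio in g per mmol creatinine."""
    return creatinine_ratio(u_tp_g_l, u_cr_umol_l)


def ecc(u_cr, v_24h_l, s_cr):
    """Endogenous creatinine clearance from a 24-h collection, in mL/min.

    ECC = (U_cr * V * 1000 / 1440) / S_cr with urine and serum creatinine
    in identical units and V the 24-h urine volume in litres.
    """
    if any(_is_missing(v) for v in (u_cr, v_24h_l, s_cr)):
        return np.nan
    _check_positive("urine creatinine", u_cr)
    _check_positive("urine volume", v_24h_l)
    _check_positive("serum creatinine", s_cr)
    return (u_cr * v_24h_l * 1000.0 / MINUTES_PER_DAY) / s_cr


def standardize(values) -> np.ndarray:
    """Divide values by their sample SD (ddof=1) over non-missing entries.

    Published regressions and ROC analyses divide each marker by its
    cohort SD at that POD to normalize its scale; this implements exactly
    that (no centering).  Missing entries stay missing.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise DerivationError("standardization needs >= 2 non-missing values")
    sd = np.std(finite, ddof=1)
    if sd == 0:
        raise DerivationError("standardization undefined: zero SD")
    return arr / sd


@dataclass(frozen=True)
class BiomarkerPanel:
    """Paired urine/serum measurements for one patient at one POD.

    ``urine_conc`` maps analyte → µg/L; ``serum_conc`` carries NGAL and B2M
    (required for fractional excretions).  Creatinine in µmol/L, total
    protein in g/L, 24-h volume in L; ``None``/NaN marks missing.
    """

    pod: int
    urine_conc: Mapping[str, float]
    serum_conc: Mapping[str, float] = field(default_factory=dict)
    urine_creatinine_umol_l: float | None = None
    serum_creatinine_umol_l: float | None = None
    urine_total_protein_g_l: float | None = None
    urine_volume_24h_l: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "urine_conc", dict(self.urine_conc))
        object.__setattr__(self, "serum_conc", dict(self.serum_conc))


@dataclass(frozen=True)
class DerivedPanel:
    """All per-POD derived biomarker quantities for one patient.

    ``standardized`` is only populated by cohort-level derivation
    (:func:`derive_table`), since the SD is a cohort property.
    """

    pod: int
    marker_cr: Mapping[str, float]
    pcr: float
    fe: Mapping[str, float]
    over_timp2: Mapping[str, float]
    ecc: float
    urine_creatinine_mmol_l: float


def _ratio_or_nan(num, den):
    if _is_missing(num) or _is_missing(den):
        return np.nan
    _check_positive("numerator", num)
    _check_positive("denominator", den)
    return num / den


def derive_panel(panel: BiomarkerPanel) -> DerivedPanel:
    """Derive all per-POD quantities for a single panel."""
    u = panel.urine_conc
    u_cr = panel.urine_creatinine_umol_l
    marker_cr = {a: creatinine_ratio(u.get(a), u_cr) for a in ANALYTES}
    fe = {
        a: fractional_excretion(
            u.get(a), panel.serum_conc.get(a),
            u_cr, panel.serum_creatinine_umol_l,
        )
        for a in FE_ANALYTES
    }
    over_timp2 = {a: _ratio_or_nan(u.get(a), u.get("timp2")) for a in FE_ANALYTES}
    return DerivedPanel(
        pod=panel.pod,
        marker_cr=marker_cr,
        pcr=pcr(panel.urine_total_protein_g_l, u_cr),
        fe=fe,
        over_timp2=over_timp2,
        ecc=ecc(u_cr, panel.urine_volume_24h_l, panel.serum_creatinine_umol_l),
        urine_creatinine_mmol_l=(np.nan if _is_missing(u_cr) else u_cr / 1000.0),
    )


#: Order of quantities in `derived.csv`.
DERIVED_QUANTITIES = (
    ["u_creatinine", "pcr"]
    + [f"{a}_cr" for a in ANALYTES]
    + [f"fe_{a}" for a in FE_ANALYTES]
    + [f"{a}_over_timp2" for a in FE_ANALYTES]
    + ["ecc"]
)


def _panel_row(pid, dp: DerivedPanel) -> list[dict]:
    flat = {"u_creatinine": dp.urine_creatinine_mmol_l, "pcr": dp.pcr, "ecc": dp.ecc}
    flat.update({f"{a}_cr": dp.marker_cr[a] for a in ANALYTES})
    flat.update({f"fe_{a}": dp.fe[a] for a in FE_ANALYTES})
    flat.update({f"{a}_over_timp2": dp.over_timp2[a] for a in FE_ANALYTES})
    return [
        {"patient_id": pid, "pod": dp.pod, "quantity": q, "value": flat[q]}
        for q in DERIVED_QUANTITIES
    ]


def derive_table(biomarkers: pd.DataFrame) -> pd.DataFrame:
    """Derive quantities for a whole cohort from a long biomarkers table.

    ``biomarkers`` follows the `biomarkers.csv` contract (one row per
    patient × POD × analyte with the shared per-panel columns repeated).
    Serum creatinine travels as the ``creatinine`` analyte row's
    ``serum_conc``.  Returns the long `derived.csv` frame: patient_id, pod,
    quantity, value, standardized_value — the last divided by the per-POD
    cohort SD of that quantity over all patients with a non-missing value.
    """
    rows: list[dict] = []
    for (pid, pod), sub in biomarkers.groupby(["patient_id", "pod"], sort=True):
        first = sub.iloc[0]
        serum = {a: v for a, v in zip(sub["analyte"], sub["serum_conc"])
                 if not pd.isna(v)}
        panel = BiomarkerPanel(
            pod=int(pod),
            urine_conc=dict(zip(sub["analyte"], sub["urine_conc"])),
            serum_conc=serum,
            urine_creatinine_umol_l=first["urine_creatinine_umol_l"],
            serum_creatinine_umol_l=serum.get("creatinine", np.nan),
            urine_total_protein_g_l=first["urine_total_protein_g_l"],
            urine_volume_24h_l=first["urine_volume_24h_l"],
        )
        rows.extend(_panel_row(pid, derive_panel(panel)))
    out = pd.DataFrame(rows)

    def _std(group: pd.Series) -> pd.Series:
        finite = group.dropna()
        if len(finite) < 2 or finite.std(ddof=1) == 0:
            return pd.Series(np.nan, index=group.index)
        return group / finite.std(ddof=1)

    out["standardized_value"] = (
        out.groupby(["pod", "quantity"])["value"].transform(_std)
    )
    return out
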