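"""Matsuda insulin-sensitivity index, fold change, and responder classification.

The whole-body insulin-sensitivity index of Matsuda and DeFronzo combines
fasting and OGTT-mean glucose and insulin:

    ISI = 10000 / sqrt(G0 * I0 * Gmean * Imean)

with glucose in mg/dL and insulin in uU/mL.  A cohort member whose index
rises by 15% or more over the intervention (fold change post/pre >= 1.15)
is a high responder (RES); everyone else is a low responder (LRE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from responderomics.errors import DataError
from responderomics.io_formats import SampleSheet

#: mmol/L -> mg/dL for glucose (molar mass of glucose / 10)
GLUCOSE_MMOL_TO_MGDL = 18.016
#: pmol/L -> uU/mL for insulin (1 uU/mL = 6.0 pmol/L)
INSULIN_PMOL_PER_UU = 6.0

RESPONDER_FC_THRESHOLD = 1.15


@dataclass(frozen=True)
class PhenotypeRecord:
    subject_id: str
    isi_pre: float
    isi_post: float
    fc: float
    group: str

    def __post_init__(self) -> None:
        if self.isi_pre <= 0 or self.isi_post <= 0:
            raise DataError(f"non-positive Matsuda index for {self.subject_id!r}")
        if abs(self.fc - self.isi_post / self.isi_pre) > 1e-9:
            raise DataError(f"fc inconsistent with isi_post/isi_pre for {self.subject_id!r}")


def matsuda_index(
    g_fast: float,
    i_fast: float,
    g_mean: float,
    i_mean: float,
    *,
    glucose_unit: str = "mg/dL",
    insulin_unit: str = "uU/mL",
    glucose_factor: float = GLUCOSE_MMOL_TO_MGDL,
    insulin_divisor: float = INSULIN_PMOL_PER_UU,
) -> float:
    """Matsuda-DeFronzo index from fasting and mean OGTT glucose/insulin.

    Parameters
    ----------
    g_fast, g_mean
        Fasting and OGTT-mean glucose, in ``glucose_unit`` ("mg/dL" or "mmol/L").
    i_fast, i_mean
        Fasting and OGTT-mean insulin, in ``insulin_unit`` ("uU/mL" or "pmol/L").
    glucose_factor, insulin_divisor
        Unit-conversion constants applied when inputs are declared in SI
        units; overridable for labs using different conventions.
    """
    vals = [g_fast, i_fast, g_mean, i_mean]
    if any((not math.isfinite(v)) or v <= 0 for v in vals):
        raise DataError(f"matsuda_index requires positive finite inputs, got {vals}")
    if glucose_unit == "mmol/L":
        g_fast *= glucose_factor
        g_mean *= glucose_factor
    elif glucose_unit != "mg/dL":
        raise DataError(f"unknown glucose unit {glucose_unit!r}")
    if insulin_unit == "pmol/L":
        i_fast /= insulin_divisor
        i_mean /= insulin_divisor
    elif insulin_unit != "uU/mL":
        raise DataError(f"unknown insulin unit {insulin_unit!r}")
    return 10000.0 / math.sqrt(g_fast * i_fast * g_mean * i_mean)


def classify_responder(subject_id: str, isi_pre: float, isi_post: float) -> PhenotypeRecord:
    """Classify one subject as RES (fc >= 1.15, boundary inclusive) or LRE."""
    if isi_pre <= 0 or isi_post <= 0:
        raise DataError(f"non-positive Matsuda index for {subject_id!r}")
    fc = isi_post / isi_pre
    group = "RES" if fc >= RESPONDER_FC_THRESHOLD else "LRE"
    return PhenotypeRecord(subject_id, isi_pre, isi_post, fc, group)


def classify_cohort(sheet: SampleSheet) -> pd.DataFrame:
    """Classify every subject in a sample sheet from its Matsuda columns.

    Returns a DataFrame (subject_id, isi_pre, isi_post, fc, group) in
    subject order of first appearance.  Raises if Matsuda values are absent
    or if the classification contradicts the sheet's recorded group.
    """
    rows = []
    for _, r in sheet.table.drop_duplicates("subject_id").iterrows():
        pre, post = r["matsuda_pre"], r["matsuda_post"]
        if pd.isna(pre) or pd.isna(post):
            raise DataError(f"subject {r['subject_id']!r} lacks Matsuda pre/post values")
        rec = classify_responder(r["subject_id"], float(pre), float(post))
        rows.append(
            {
                "subject_id": rec.subject_id,
                "isi_pre": rec.isi_pre,
                "isi_post": rec.isi_post,
                "fc": rec.fc,
                "group": rec.group,
            }
        )
    return pd.DataFrame(rows)
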