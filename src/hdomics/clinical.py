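"""Cohort bookkeeping: disease-burden score, stage classification, summaries.

The disease burden score (DBS) is the cumulative exposure to the expanded
CAG tract, ``(CAG - 35.5) * age``; carriers are staged as pre-manifest
(pre-HD) when their diagnostic confidence level (DCL, 0-4) is 2 or less,
and as early manifest (early-HD) when clinically diagnosed (DCL > 2) with
a total functional capacity (TFC, 0-13) of 7-13, i.e. TFC stages 1-2.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

CAG_OFFSET = 35.5

#: TFC range corresponding to TFC stages 1-2 (early manifest disease).
EARLY_HD_TFC_RANGE = (7, 13)


def compute_dbs(cag_long: float, age: float) -> float:
    """Disease burden score ``(CAG - 35.5) * age``.

    Controls carry no expanded allele and have no DBS; passing a missing
    ``cag_long`` raises.
    """
    if cag_long is None or (isinstance(cag_long, float) and math.isnan(cag_long)):
        raise ValueError("DBS requires the expanded (long) CAG allele; "
                         "controls have no DBS")
    if not cag_long > 0:
        raise ValueError("cag_long must be > 0")
    if not age > 0:
        raise ValueError("age must be > 0")
    return (cag_long - CAG_OFFSET) * age


def classify_stage(is_carrier: bool, dcl: int | None = None,
                   tfc: int | None = None) -> str:
    """Assign a participant to control / pre-HD / early-HD.

    Non-carriers are controls. Carriers with DCL <= 2 are pre-HD. Carriers
    with DCL > 2 and TFC in 7-13 (stages 1-2) are early-HD. A carrier with
    DCL > 2 but TFC below 7 falls outside the study strata and is returned
    as ``"unclassified"``.
    """
    if not is_carrier:
        return "control"
    if dcl is None or not (0 <= dcl <= 4):
        raise ValueError("carriers require a DCL score in 0-4")
    if dcl <= 2:
        return "pre-HD"
    if tfc is None or not (0 <= tfc <= 13):
        raise ValueError("carriers require a TFC score in 0-13")
    lo, hi = EARLY_HD_TFC_RANGE
    if lo <= tfc <= hi:
        return "early-HD"
    return "unclassified"


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean / min / max of every numeric field.

    Returns a table with one row per group and a (field, stat) column
    MultiIndex, the descriptive shape of a cohort summary table. Groups
    with no observed values for a field get NaN cells.
    """
    if records.empty:
        raise ValueError("cannot summarize an empty cohort")
    numeric = records.select_dtypes(include=[np.number]).columns
    out = records.groupby("group", sort=False)[list(numeric)].agg(
        ["mean", "min", "max"])
    return out


def read_participants(path) -> pd.DataFrame:
    """Read a participant metadata TSV (columns as written by
    :func:`hdomics.synthetic.gen_cohort_metadata`)."""
    return pd.read_csv(path, sep="\t")


def write_participants(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
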