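"""Foxp3 TSDR demethylation percentage from methylation-specific qPCR.

Two reactions are run on bisulfite-converted DNA: one whose primers
amplify the methylated TSDR sequence and one specific for the
demethylated sequence.  The demethylation percentage is computed from
the two cycle thresholds as

    percent = 100 / (1 + 2**(Ct_meth − Ct_demeth))

(the ``as_printed`` convention, the formula exactly as the assay
protocol states it).  Note the sign: a fully demethylated template
amplifies earlier in the demethylation-specific reaction, making
ΔCt = Ct_meth − Ct_demeth large and positive and the expression above
*small*; protocols are not consistent about which Ct is subtracted from
which, so the ``flipped`` convention (exponent ``Ct_demeth − Ct_meth``)
is provided and the convention used is recorded in the output.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["demethylation_percent", "batch_tsdr"]

CONVENTIONS = ("as_printed", "flipped")


def demethylation_percent(
    ct_meth, ct_demeth, convention: str = "as_printed"
):
    """Demethylation percentage from a Ct pair (vectorized).

    Returns values strictly inside (0, 100); strictly decreasing in
    ``ct_meth − ct_demeth`` under ``as_printed``.  Non-finite Ct values
    are an input error; use :func:`batch_tsdr` for tables with missing
    entries.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    ct_meth = np.asarray(ct_meth, dtype=float)
    ct_demeth = np.asarray(ct_demeth, dtype=float)
    if not (np.isfinite(ct_meth).all() and np.isfinite(ct_demeth).all()):
        raise ValueError("Ct values must be finite")
    dct = ct_meth - ct_demeth
    if convention == "flipped":
        dct = -dct
    out = 100.0 / (1.0 + np.exp2(dct))
    return float(out) if out.ndim == 0 else out


def batch_tsdr(
    table: pd.DataFrame | str | Path,
    convention: str = "as_printed",
    group_column: str | None = None,
) -> pd.DataFrame:
    """Row-wise demethylation percentages for a sample table.

    Expects columns ``sample_id, ct_meth, ct_demeth``.  Malformed rows
    (missing or non-numeric Ct) yield NaN with a logged warning naming
    the row; processing continues.  Adds ``demethylation_percent`` and
    ``convention`` columns.  When ``group_column`` names an existing
    column, per-group mean/SD/count are attached as a ``.attrs["group_summary"]``
    DataFrame.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    required = {"sample_id", "ct_meth", "ct_demeth"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    out = table.copy()
    percents = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        cm = pd.to_numeric(getattr(row, "ct_meth"), errors="coerce")
        cd = pd.to_numeric(getattr(row, "ct_demeth"), errors="coerce")
        if pd.isna(cm) or pd.isna(cd):
            logger.warning(
                "row %d (sample %s): missing or non-numeric Ct, skipped",
                i,
                getattr(row, "sample_id"),
            )
            continue
        percents[i] = demethylation_percent(cm, cd, convention)
    out["demethylation_percent"] = percents
    out["convention"] = convention
    if group_column and group_column in out.columns:
        out.attrs["group_summary"] = (
            out.groupby(group_column)["demethylation_percent"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
    return out
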