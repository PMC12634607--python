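"""Collapse multi-version safety reports to one report per case.

Spontaneous-report databases re-issue a case every time it is amended, so a
single CASEID can appear under several PRIMARYIDs.  The deduplication rule
applied here follows FDA guidance: within a CASEID keep the version with
the latest FDA receipt date (FDA_DT); if receipt dates tie, keep the
highest PRIMARYID.  A missing or unparseable FDA_DT sorts before any
present date, so a dated version always beats an undated one.

PRIMARYIDs are compared numerically when every id in a tie group is a
digit string (the FAERS convention); otherwise the comparison falls back
to lexicographic order and a warning is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .util import percentage

logger = logging.getLogger("pvsignal")

__all__ = ["deduplicate", "dedup_summary"]


def _fda_sort_key(fda_dt: pd.Series) -> pd.Series:
    """Numeric sort key for FDA_DT tokens; missing/invalid sorts earliest."""
    key = pd.to_numeric(fda_dt, errors="coerce")
    n_missing = int(key.isna().sum())
    if n_missing:
        logger.warning("deduplicate: %d report(s) with missing/invalid FDA_DT "
                       "treated as earliest", n_missing)
    return key.fillna(-1.0)


def _pid_sort_key(primaryid: pd.Series) -> pd.Series:
    """Numeric PRIMARYID key with lexicographic fallback for non-digit ids."""
    if primaryid.str.fullmatch(r"\d+").all():
        return pd.to_numeric(primaryid)
    logger.warning("deduplicate: non-numeric PRIMARYID present; "
                   "falling back to lexicographic comparison")
    order = np.argsort(primaryid.to_numpy(), kind="stable")
    rank = np.empty(len(primaryid), dtype=np.int64)
    rank[order] = np.arange(len(primaryid))
    return pd.Series(rank, index=primaryid.index)


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, int, pd.DataFrame]:
    """Keep one DEMO row per CASEID.

    Parameters
    ----------
    demo
        DEMO table with at least ``primaryid``, ``caseid``, ``fda_dt``.

    Returns
    -------
    kept : DataFrame
        One row per caseid, maximising (FDA_DT, then PRIMARYID).  Original
        row order is irrelevant: the result is sorted by caseid.
    removed : int
        ``len(demo) - len(kept)``.
    audit : DataFrame
        One row per caseid that had >1 version: caseid, n_versions,
        kept_primaryid.
    """
    if demo.empty:
        raise ValueError("deduplicate: empty DEMO table")
    work = demo.copy()
    work["_fda"] = _fda_sort_key(work["fda_dt"])
    work["_pid"] = _pid_sort_key(work["primaryid"])
    work = work.sort_values(["caseid", "_fda", "_pid"], kind="stable")
    kept = work.groupby("caseid", sort=True).tail(1)

    sizes = work.groupby("caseid").size()
    multi = sizes[sizes > 1]
    audit = pd.DataFrame({
        "caseid": multi.index,
        "n_versions": multi.to_numpy(),
        "kept_primaryid": kept.set_index("caseid").loc[multi.index, "primaryid"].to_numpy(),
    }).reset_index(drop=True)

    kept = kept.drop(columns=["_fda", "_pid"]).reset_index(drop=True)
    removed = len(demo) - len(kept)
    logger.info("deduplicate: %d -> %d reports (%d removed)",
                len(demo), len(kept), removed)
    return kept, removed, audit


def dedup_summary(before: int, removed: int) -> dict:
    """Summary record of a deduplication pass.

    ``removed_pct`` is rounded half-up to one decimal, matching how such
    reductions are conventionally reported; it is ``None`` when ``before``
    is zero.
    """
    if removed > before:
        raise ValueError("removed exceeds before")
    return {
        "before": before,
        "removed": removed,
        "kept": before - removed,
        "removed_pct": percentage(removed, before, ndigits=1),
    }
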