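"""Primary-suspect cohort construction and 2x2 contingency tables.

The analysis unit is the deduplicated report.  Each report contributes at
most one (report, drug) unit to the background: the drug with role code PS
(primary suspect).  Secondary-suspect, interacting and concomitant
mentions contribute nothing — neither to drug-of-interest counts nor to
the comparator background — which keeps the disproportionality comparison
between primary-suspect exposures only.

A report is an event case when any of its reaction preferred terms equals
the target PT (default "Headache") exactly, case- and whitespace-
insensitively.  Subtype terms such as "Migraine" or "Tension headache" do
not match: the comparison is exact-string, never substring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import normalize_drug_name

logger = logging.getLogger("pvsignal")

__all__ = [
    "ContingencyTable",
    "build_background",
    "flag_headache",
    "add_event_flag",
    "build_contingency",
    "contingency_counts",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts for one drug (or drug class) versus the event.

    a: drug of interest AND event; b: drug of interest AND other events;
    c: other drugs AND event; d: other drugs AND other events.
    """

    a: int
    b: int
    c: int
    d: int
    drug: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def build_background(
    demo_kept: pd.DataFrame,
    drug: pd.DataFrame,
    synonym_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One (report, PS drug) unit per deduplicated report.

    Drug names are canonicalized (and brand names resolved) on the way in.
    Reports without any PS mention are excluded and counted; a report with
    several PS rows keeps the lowest drug-sequence row and increments an
    ambiguity counter.

    Returns
    -------
    background : DataFrame with columns primaryid, caseid, ps_drug.
    counters : {"no_ps_excluded": int, "multi_ps_resolved": int}
    """
    kept_ids = demo_kept[["primaryid", "caseid"]]
    ps = drug.loc[drug["role_cod"] == "PS",
                  ["primaryid", "drug_seq", "drugname"]].copy()
    ps = ps.merge(kept_ids, on="primaryid", how="inner")

    seq = pd.to_numeric(ps["drug_seq"], errors="coerce").fillna(float("inf"))
    ps = ps.assign(_seq=seq).sort_values(["primaryid", "_seq"], kind="stable")
    multi = int((ps.groupby("primaryid").size() > 1).sum())
    ps = ps.groupby("primaryid", sort=False).head(1)
    if multi:
        logger.warning("build_background: %d report(s) had multiple PS rows; "
                       "kept lowest drug_seq", multi)

    canon = {n: normalize_drug_name(n, synonym_map)
             for n in ps["drugname"].unique()}
    ps = ps.copy()
    ps["ps_drug"] = ps["drugname"].map(canon)
    background = ps[["primaryid", "caseid", "ps_drug"]].reset_index(drop=True)
    no_ps = len(demo_kept) - len(background)
    counters = {"no_ps_excluded": no_ps, "multi_ps_resolved": multi}
    logger.info("build_background: %d report(s) in background, %d excluded "
                "without a PS drug", len(background), no_ps)
    return background, counters


def flag_headache(reac: pd.DataFrame, pt: str = "Headache") -> set[str]:
    """PRIMARYIDs of reports carrying the target preferred term.

    Exact match after trimming and case folding; subtype PTs do not count.
    """
    target = pt.strip().casefold()
    hits = reac["pt"].str.strip().str.casefold() == target
    return set(reac.loc[hits, "primaryid"])


def add_event_flag(background: pd.DataFrame, reac: pd.DataFrame,
                   pt: str = "Headache") -> pd.DataFrame:
    """Background with a boolean ``event`` column for the target PT."""
    flagged = flag_headache(reac, pt)
    out = background.copy()
    out["event"] = out["primaryid"].isin(flagged)
    return out


def contingency_counts(background: pd.DataFrame) -> pd.DataFrame:
    """Per-drug a/b counts plus background margins, in one pass.

    ``background`` must carry the ``event`` flag (see :func:`add_event_flag`).
    Returns a DataFrame indexed by ps_drug with columns a, b, c, d.
    """
    if "event" not in background.columns:
        raise ValueError("background lacks the 'event' flag; "
                         "call add_event_flag first")
    grouped = background.groupby("ps_drug")["event"]
    a = grouped.sum().astype(int)
    n = grouped.size().astype(int)
    b = n - a
    total_event = int(background["event"].sum())
    total = len(background)
    out = pd.DataFrame({"a": a, "b": b})
    out["c"] = total_event - out["a"]
    out["d"] = (total - total_event) - out["b"]
    return out.sort_index()


def build_contingency(drug: str, background: pd.DataFrame) -> ContingencyTable:
    """2x2 table for one canonical drug name against the PS background."""
    if "event" not in background.columns:
        raise ValueError("background lacks the 'event' flag; "
                         "call add_event_flag first")
    mask = background["ps_drug"] == drug
    if not mask.any():
        logger.warning("build_contingency: drug %r absent from background", drug)
    a = int(background.loc[mask, "event"].sum())
    b = int(mask.sum()) - a
    c = int(background["event"].sum()) - a
    d = len(background) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d, drug=drug)
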