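"""Time-to-onset: days from therapy start to the adverse event, in five bins.

Onset is the calendar-day difference between the event date and the
primary-suspect drug's start date.  Only complete date pairs (both at day
resolution) qualify; month- or year-resolution tokens and negative
differences are excluded, each under its own counter, so completeness is
auditable.  Same-day onset (0 days) falls in the first bin.

The start date prefers the DRUG row's START_DT for the PS mention and
falls back to the THER row matching that drug sequence when the DRUG
token is not a complete date.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .io import FaersDate, parse_faers_date
from .util import percentage

logger = logging.getLogger("pvsignal")

__all__ = [
    "BIN_LABELS",
    "bin_onset",
    "onset_days",
    "compute_onsets",
    "tto_distribution",
    "tto_by_atc",
]

#: Ordered bin labels partitioning the non-negative integers.
BIN_LABELS = ("≤7", "8–28", "29–60", "61–90", ">90")

_BIN_UPPER = (7, 28, 60, 90)  # inclusive upper edges of the first four bins


def bin_onset(days: int) -> str:
    """Bin label for a non-negative onset in days."""
    if days < 0:
        raise ValueError("onset days must be non-negative")
    for upper, label in zip(_BIN_UPPER, BIN_LABELS):
        if days <= upper:
            return label
    return BIN_LABELS[-1]


def onset_days(start: FaersDate, event: FaersDate) -> tuple[int | None, str | None]:
    """Calendar-day difference event - start, or an exclusion reason.

    Returns ``(days, None)`` when both dates are complete and the
    difference is non-negative, else ``(None, reason)`` with reason one of
    ``incomplete_start``, ``incomplete_event``, ``negative``.
    """
    if not start.is_complete:
        return None, "incomplete_start"
    if not event.is_complete:
        return None, "incomplete_event"
    days = (event.value - start.value).days
    if days < 0:
        return None, "negative"
    return days, None


def compute_onsets(
    background: pd.DataFrame,
    demo_kept: pd.DataFrame,
    drug: pd.DataFrame,
    ther: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Onset records for every background (report, PS drug) unit.

    Returns
    -------
    records : DataFrame with columns primaryid, drug, onset_days, bin —
        one row per complete case.
    exclusions : counts {"incomplete_start", "incomplete_event", "negative"};
        together with ``len(records)`` these sum to ``len(background)``.
    """
    ps = drug.loc[drug["role_cod"] == "PS",
                  ["primaryid", "drug_seq", "start_dt"]]
    ps = ps.groupby("primaryid", sort=False).head(1)

    ther_start = ther.rename(columns={"dsg_drug_seq": "drug_seq",
                                      "start_dt": "ther_start_dt"})
    ther_start = ther_start[["primaryid", "drug_seq", "ther_start_dt"]]
    ther_start = ther_start.groupby(["primaryid", "drug_seq"], sort=False).head(1)

    units = background.merge(ps, on="primaryid", how="left")
    units = units.merge(ther_start, on=["primaryid", "drug_seq"], how="left")
    units = units.merge(demo_kept[["primaryid", "event_dt"]],
                        on="primaryid", how="left")

    records = []
    exclusions = {"incomplete_start": 0, "incomplete_event": 0, "negative": 0}
    for row in units.itertuples(index=False):
        start = parse_faers_date(row.start_dt)
        if not start.is_complete:
            fallback = parse_faers_date(row.ther_start_dt)
            if fallback.is_complete:
                start = fallback
        event = parse_faers_date(row.event_dt)
        days, reason = onset_days(start, event)
        if reason is not None:
            exclusions[reason] += 1
            continue
        records.append((row.primaryid, row.ps_drug, days, bin_onset(days)))

    frame = pd.DataFrame(records,
                         columns=["primaryid", "drug", "onset_days", "bin"])
    logger.info("compute_onsets: %d complete case(s), exclusions=%s",
                len(frame), exclusions)
    return frame, exclusions


def tto_distribution(records: pd.DataFrame, group_col: str = "drug",
                     ndigits: int = 1) -> pd.DataFrame:
    """Per-group five-bin counts and percentages.

    One row per group: total complete cases ``n``, then for each bin its
    count and percentage (half-up, one decimal by default).  Percentages
    are computed independently per bin from its own count — they are not
    renormalized to force a 100.0 sum.  Empty groups are simply absent.
    """
    if records.empty:
        logger.warning("tto_distribution: no complete onset records")
        return pd.DataFrame(columns=[group_col, "n"])
    counts = (records.groupby([group_col, "bin"]).size()
              .unstack(fill_value=0)
              .reindex(columns=list(BIN_LABELS), fill_value=0))
    out = pd.DataFrame({group_col: counts.index,
                        "n": counts.sum(axis=1).to_numpy()})
    for label in BIN_LABELS:
        k = counts[label].to_numpy()
        out[f"count {label}"] = k
        out[f"pct {label}"] = [percentage(x, n, ndigits)
                               for x, n in zip(k, out["n"])]
    return out.reset_index(drop=True)


def tto_by_atc(records: pd.DataFrame,
               atc_map: Mapping[str, str]) -> pd.DataFrame:
    """Five-bin distribution pooled by ATC class, with member-drug counts."""
    mapped = records.assign(atc=records["drug"].map(
        lambda d: atc_map.get(d) if isinstance(atc_map.get(d), str)
        else (atc_map.get(d)[0] if atc_map.get(d) else None)))
    mapped = mapped.dropna(subset=["atc"])
    dist = tto_distribution(mapped, group_col="atc")
    n_drugs = mapped.groupby("atc")["drug"].nunique()
    dist.insert(1, "n_drugs", dist["atc"].map(n_drugs).to_numpy())
    return dist
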