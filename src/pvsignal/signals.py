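"""Disproportionality estimators: ROR and PRR with Wald 95% intervals.

For a 2x2 table (a, b, c, d) of event/non-event reports for the drug of
interest versus all other drugs:

    ROR = (a * d) / (b * c)
    SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)

    PRR = (a / (a + b)) / (c / (c + d))
    SE(ln PRR) = sqrt(1/a - 1/(a + b) + 1/c - 1/(c + d))

    95% CI = exp(ln(point) +/- 1.96 * SE)

A drug is flagged as a positive signal when both point estimates exceed 1
and both lower confidence bounds exceed 1.

Zero cells make the ROR (and its interval) undefined; no Haldane-Anscombe
0.5 continuity correction is applied — the estimate is reported as
undefined with a zero-cell flag, because a silent correction changes
rankings without leaving a trace.  The PRR tolerates b = 0 or d = 0 but is
undefined when a = 0 or c = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cohort import ContingencyTable, contingency_counts
from .util import round_half_up

logger = logging.getLogger("pvsignal")

__all__ = [
    "Z_95",
    "SignalEstimate",
    "SignalVerdict",
    "ror",
    "prr",
    "classify_signal",
    "rank_top_n",
    "atc_aggregate",
    "drug_signal_frame",
    "atc_signal_frame",
]

Z_95 = 1.96  # normal quantile for the 95% interval


@dataclass(frozen=True)
class SignalEstimate:
    """Point estimate with 95% CI on the ratio scale.

    Undefined estimates (zero cells) carry ``None`` in every numeric field
    and ``zero_cell=True``; undefined is a value here, not an error.
    """

    measure: str  # "ROR" | "PRR"
    point: float | None
    ci_low: float | None
    ci_high: float | None
    log_se: float | None
    table: ContingencyTable
    zero_cell: bool = False

    @property
    def defined(self) -> bool:
        return self.point is not None


@dataclass(frozen=True)
class SignalVerdict:
    drug: str
    ror: SignalEstimate
    prr: SignalEstimate
    is_signal: bool = field(init=False)

    def __post_init__(self) -> None:
        flag = (
            self.ror.defined and self.prr.defined
            and self.ror.point > 1.0 and self.prr.point > 1.0
            and self.ror.ci_low > 1.0 and self.prr.ci_low > 1.0
        )
        object.__setattr__(self, "is_signal", bool(flag))


def _wald(measure: str, point: float, log_se: float,
          table: ContingencyTable) -> SignalEstimate:
    log_point = math.log(point)
    return SignalEstimate(
        measure=measure,
        point=point,
        ci_low=math.exp(log_point - Z_95 * log_se),
        ci_high=math.exp(log_point + Z_95 * log_se),
        log_se=log_se,
        table=table,
    )


def _undefined(measure: str, table: ContingencyTable) -> SignalEstimate:
    return SignalEstimate(measure=measure, point=None, ci_low=None,
                          ci_high=None, log_se=None, table=table,
                          zero_cell=True)


def ror(table: ContingencyTable) -> SignalEstimate:
    """Reporting odds ratio with 95% Wald CI; undefined on any zero cell."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return _undefined("ROR", table)
    point = (a * d) / (b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return _wald("ROR", point, log_se, table)


def prr(table: ContingencyTable) -> SignalEstimate:
    """Proportional reporting ratio with 95% Wald CI.

    Undefined when a = 0 or c = 0 (no event reports on one side); b = 0 is
    legal — a drug reported exclusively with the event.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0 or c == 0:
        return _undefined("PRR", table)
    point = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    log_se = math.sqrt(max(var, 0.0))
    return _wald("PRR", point, log_se, table)


def classify_signal(ror_est: SignalEstimate, prr_est: SignalEstimate) -> SignalVerdict:
    """Combine ROR and PRR estimates for one table into a verdict."""
    return SignalVerdict(drug=ror_est.table.drug, ror=ror_est, prr=prr_est)


def rank_top_n(verdicts: Sequence[SignalVerdict], n: int = 100) -> list[SignalVerdict]:
    """Top-n verdicts by event-report frequency (the ``a`` cell).

    Descending by a; ties broken alphabetically by drug name.
    """
    ordered = sorted(verdicts, key=lambda v: (-v.ror.table.a, v.drug))
    return ordered[: max(n, 0)]


def atc_aggregate(
    background: pd.DataFrame,
    atc_map: Mapping[str, str | Sequence[str]],
) -> list[tuple[str, ContingencyTable, int]]:
    """Pool per-drug counts into ATC level-2 class tables.

    ``atc_map`` maps canonical drug names to a level-2 code (or a sequence
    of codes; a multi-class drug contributes to each of its classes, which
    makes class tables overlap — a warning is logged).  Unmapped background
    drugs are excluded from class tables but still counted in the
    complement margins.  Returns (class, table, n_drugs) sorted by class.
    """
    per_drug = contingency_counts(background)
    total_event = int(background["event"].sum())
    total = len(background)

    members: dict[str, list[str]] = {}
    multi_class = 0
    for drug in per_drug.index:
        codes = atc_map.get(drug)
        if codes is None:
            continue
        if isinstance(codes, str):
            codes = [codes]
        if len(codes) > 1:
            multi_class += 1
        for code in codes:
            members.setdefault(code, []).append(drug)
    if multi_class:
        logger.warning("atc_aggregate: %d drug(s) map to multiple ATC classes; "
                       "class tables overlap", multi_class)
    unmapped = len(per_drug.index) - sum(1 for d in per_drug.index if d in atc_map)
    if unmapped:
        logger.info("atc_aggregate: %d background drug(s) without ATC mapping "
                    "excluded from class tables", unmapped)

    out = []
    for code in sorted(members):
        sub = per_drug.loc[members[code]]
        a, b = int(sub["a"].sum()), int(sub["b"].sum())
        table = ContingencyTable(a=a, b=b, c=total_event - a,
                                 d=(total - total_event) - b, drug=code)
        out.append((code, table, len(members[code])))
    return out


# ---------------------------------------------------------------------------
# Report frames (drug-level and class-level signal tables)
# ---------------------------------------------------------------------------

def _fmt(est: SignalEstimate) -> tuple:
    if not est.defined:
        return (None, None, None)
    return (round_half_up(est.point, 3), round_half_up(est.ci_low, 3),
            round_half_up(est.ci_high, 3))


def drug_signal_frame(background: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """Per-drug signal table: frequency, ROR, PRR, 95% CIs, signal flag.

    Ranked by event frequency (descending, alphabetical tie-break),
    truncated to ``top_n``.  Estimates are rounded half-up to 3 decimals.
    """
    per_drug = contingency_counts(background)
    verdicts = []
    for drug, row in per_drug.iterrows():
        table = ContingencyTable(a=int(row["a"]), b=int(row["b"]),
                                 c=int(row["c"]), d=int(row["d"]), drug=drug)
        verdicts.append(classify_signal(ror(table), prr(table)))
    top = rank_top_n(verdicts, top_n)
    records = []
    for v in top:
        r3, rlo, rhi = _fmt(v.ror)
        p3, plo, phi = _fmt(v.prr)
        records.append({
            "drug": v.drug, "frequency": v.ror.table.a,
            "ror": r3, "ror_ci_low": rlo, "ror_ci_high": rhi,
            "prr": p3, "prr_ci_low": plo, "prr_ci_high": phi,
            "signal": v.is_signal,
        })
    return pd.DataFrame(records, columns=[
        "drug", "frequency", "ror", "ror_ci_low", "ror_ci_high",
        "prr", "prr_ci_low", "prr_ci_high", "signal"])


def atc_signal_frame(background: pd.DataFrame,
                     atc_map: Mapping[str, str | Sequence[str]]) -> pd.DataFrame:
    """Per-ATC-class signal table with member-drug counts."""
    records = []
    for code, table, n_drugs in atc_aggregate(background, atc_map):
        v = classify_signal(ror(table), prr(table))
        r3, rlo, rhi = _fmt(v.ror)
        p3, plo, phi = _fmt(v.prr)
        records.append({
            "atc": code, "n_drugs": n_drugs, "frequency": table.a,
            "ror": r3, "ror_ci_low": rlo, "ror_ci_high": rhi,
            "prr": p3, "prr_ci_low": plo, "prr_ci_high": phi,
            "signal": v.is_signal,
        })
    return pd.DataFrame(records, columns=[
        "atc", "n_drugs", "frequency", "ror", "ror_ci_low", "ror_ci_high",
        "prr", "prr_ci_low", "prr_ci_high", "signal"])
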