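"""Synthetic FAERS-like bundle generator with planted association strengths.

Emulates the statistical structure of spontaneous-report data at desk
scale so every downstream stage — deduplication, primary-suspect cohort
construction, disproportionality estimation, time-to-onset binning and
demographic summaries — is testable without any download:

* each case carries exactly one primary-suspect (PS) drug drawn from a
  configurable panel, plus occasional secondary-suspect mentions;
* the event ("Headache" as a MedDRA preferred-term string) is planted on
  the odds scale: a case whose PS drug has planted reporting odds ratio R
  gets the event with odds R times the background odds, so the ROR
  estimator is consistent for R;
* a configurable fraction of cases is emitted as multiple report versions
  sharing a CASEID with distinct PRIMARYIDs and FDA receipt dates, with
  occasional date ties, to exercise both deduplication tie-break rules;
* start/event dates are YYYYMMDD tokens, a fraction of which is truncated
  to YYYYMM or YYYY the way real reporters truncate them;
* demographics are drawn from realistic categorical distributions with
  configurable missingness.

Alongside the four tables the generator emits a hidden per-case truth
table (kept PRIMARYID, PS drug, event flag, onset) that tests compare
pipeline output against; the pipeline itself never reads it.

Default rates mirror large-scale US spontaneous-report data: ~3.3%
background event rate, 36.6% / 10.1% / 73.3% missing age / sex / weight,
and a duplicate-version share sized so roughly a fifth of raw report rows
are removed by deduplication.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import QuarterBundle

logger = logging.getLogger("pvsignal")

__all__ = [
    "ConfigError",
    "DrugSpec",
    "GeneratorConfig",
    "default_config",
    "generate_bundle",
    "inject_duplicates",
    "default_atc_map",
]

EVENT_PT = "Headache"

#: Default five-bin onset mixture (shares of ≤7 / 8–28 / 29–60 / 61–90 / >90
#: days), shaped like an immunosuppressant-type profile: a large early mode
#: and a substantial late tail.
DEFAULT_ONSET_MIXTURE = (0.45, 0.13, 0.08, 0.04, 0.30)

_OTHER_PTS = ("Nausea", "Fatigue", "Dizziness", "Rash", "Migraine",
              "Pyrexia", "Arthralgia")

# (label, probability) categorical distributions for demographics,
# patterned on US-dominated spontaneous-report data.
_OCCP = (("CN", 0.5472), ("HP", 0.1593), ("MD", 0.1490), ("PH", 0.0520),
         ("LW", 0.0051), ("OT", 0.0649), ("", 0.0225))
_COUNTRY = (("UNITED STATES", 0.6587), ("CANADA", 0.1206),
            ("UNITED KINGDOM", 0.0412), ("DENMARK", 0.0236),
            ("COUNTRY NOT SPECIFIED", 0.0264), ("FRANCE", 0.0400),
            ("GERMANY", 0.0360), ("JAPAN", 0.0300), ("BRAZIL", 0.0235))
# Age-band shares conditional on age being reported, with sampling ranges.
_AGE_BANDS = (((1, 17), 0.0462), ((18, 30), 0.0880), ((31, 50), 0.2860),
              ((51, 65), 0.3366), ((66, 95), 0.2432))
# Weight-band shares conditional on weight being reported (kg).
_WT_BANDS = (((30, 50), 0.0782), ((51, 100), 0.7955), ((101, 160), 0.1263))


class ConfigError(ValueError):
    """Generator configuration violates an invariant; message names the field."""


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the synthetic panel.

    ``target_ror`` is the planted reporting odds ratio for the event;
    ``marginal_share`` the fraction of reports carrying the drug as PS;
    ``atc_code`` its ATC level-2 class (e.g. "L04").
    """

    name: str
    target_ror: float = 1.0
    marginal_share: float = 0.05
    atc_code: str = ""

    def validate(self) -> None:
        if not self.name or self.name != self.name.strip().upper():
            raise ConfigError(f"DrugSpec.name: {self.name!r} must be nonempty "
                              "and uppercase-canonical")
        if not self.target_ror > 0:
            raise ConfigError(f"DrugSpec.target_ror: {self.target_ror} must be > 0")
        if not 0 < self.marginal_share < 1:
            raise ConfigError(f"DrugSpec.marginal_share: {self.marginal_share} "
                              "must be in (0,1)")


@dataclass(frozen=True)
class GeneratorConfig:
    n_cases: int = 50_000
    drugs: tuple[DrugSpec, ...] = ()
    background_headache_rate: float = 0.033
    dup_fraction: float = 0.25
    missing_age_rate: float = 0.3657
    missing_sex_rate: float = 0.1005
    missing_weight_rate: float = 0.7332
    partial_date_rate: float = 0.30
    #: per-drug mixture weights over the five onset bins; drugs not listed
    #: use DEFAULT_ONSET_MIXTURE.
    onset_mixture: Mapping[str, Sequence[float]] = field(default_factory=dict)
    seed: int = 0
    #: filler drugs (target_ror=1) absorbing the PS share not claimed by
    #: ``drugs``, so every case has a primary suspect.
    n_background_drugs: int = 12

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigError(f"n_cases: {self.n_cases} must be >= 1")
        if not 0 < self.background_headache_rate < 1:
            raise ConfigError("background_headache_rate: "
                              f"{self.background_headache_rate} must be in (0,1)")
        if not 0 <= self.dup_fraction < 1:
            raise ConfigError(f"dup_fraction: {self.dup_fraction} must be in [0,1)")
        for name in ("missing_age_rate", "missing_sex_rate",
                     "missing_weight_rate", "partial_date_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}: {v} must be in [0,1]")
        if self.n_background_drugs < 1:
            raise ConfigError("n_background_drugs: must be >= 1")
        share = 0.0
        for spec in self.drugs:
            spec.validate()
            share += spec.marginal_share
        if share >= 1 - 1e-9:
            raise ConfigError(f"drugs: marginal_share sum {share:.4f} must be < 1 "
                              "(the remainder goes to background drugs)")
        for drug, weights in self.onset_mixture.items():
            w = np.asarray(list(weights), dtype=float)
            if len(w) != 5 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError(f"onset_mixture[{drug!r}]: five non-negative "
                                  "weights summing to 1 required")


def default_config(n_cases: int = 50_000, seed: int = 0) -> GeneratorConfig:
    """Study-default panel: 20 named drugs, 3 planted positive signals.

    The planted drugs span strong to moderate association (ROR 4.0, 3.0,
    2.0); the remaining named drugs are null (ROR 1.0) so false-positive
    behaviour is observable.  Onset mixtures give the strongest signal an
    early-onset profile and one null drug a late-onset profile.
    """
    planted = [
        DrugSpec("OFATUMUMAB", 4.0, 0.020, "L04"),
        DrugSpec("GLECAPREVIR\\PIBRENTASVIR", 3.0, 0.015, "J05"),
        DrugSpec("ABALOPARATIDE", 2.0, 0.015, "H05"),
    ]
    nulls = [
        DrugSpec("ADALIMUMAB", 1.0, 0.030, "L04"),
        DrugSpec("APREMILAST", 1.0, 0.025, "L04"),
        DrugSpec("TREPROSTINIL", 1.0, 0.020, "B01"),
        DrugSpec("DUPILUMAB", 1.0, 0.020, "D11"),
        DrugSpec("SECUKINUMAB", 1.0, 0.020, "L04"),
        DrugSpec("METHOTREXATE", 1.0, 0.020, "L04"),
        DrugSpec("RITUXIMAB", 1.0, 0.015, "L04"),
        DrugSpec("INFLIXIMAB", 1.0, 0.015, "L04"),
        DrugSpec("SEMAGLUTIDE", 1.0, 0.015, "A10"),
        DrugSpec("APIXABAN", 1.0, 0.015, "B01"),
        DrugSpec("ACETAMINOPHEN", 1.0, 0.015, "N02"),
        DrugSpec("IBUPROFEN", 1.0, 0.015, "M01"),
        DrugSpec("SERTRALINE", 1.0, 0.010, "N06"),
        DrugSpec("AMLODIPINE BESYLATE", 1.0, 0.010, "C08"),
        DrugSpec("LEVOTHYROXINE SODIUM", 1.0, 0.010, "H03"),
        DrugSpec("CIPROFLOXACIN", 1.0, 0.010, "J01"),
        DrugSpec("METFORMIN", 1.0, 0.010, "A10"),
    ]
    onset_mixture = {
        "OFATUMUMAB": (0.78, 0.09, 0.04, 0.01, 0.08),
        "TREPROSTINIL": (0.16, 0.14, 0.06, 0.05, 0.59),
    }
    return GeneratorConfig(n_cases=n_cases, drugs=tuple(planted + nulls),
                           onset_mixture=onset_mixture, seed=seed)


def default_atc_map(config: GeneratorConfig) -> dict[str, str]:
    """ATC level-2 map covering the configured drugs (fillers unmapped)."""
    return {spec.name: spec.atc_code for spec in config.drugs if spec.atc_code}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _date_tokens(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD string tokens."""
    d = pd.DatetimeIndex(dates)
    ymd = (d.year * 10000 + d.month * 100 + d.day).to_numpy(dtype=np.int64)
    return ymd.astype("U8")


def _truncate_tokens(tokens: np.ndarray, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Truncate a fraction of YYYYMMDD tokens to YYYYMM or YYYY."""
    tokens = tokens.astype("U8").copy()
    hit = rng.random(len(tokens)) < rate
    to_month = hit & (rng.random(len(tokens)) < 0.7)
    to_year = hit & ~to_month
    tokens[to_month] = tokens[to_month].astype("U6")
    tokens[to_year] = tokens[to_year].astype("U4")
    return tokens


def _categorical(rng: np.random.Generator, n: int,
                 table: Sequence[tuple[object, float]]) -> np.ndarray:
    labels = [t[0] for t in table]
    probs = np.array([t[1] for t in table], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=n, p=probs)
    return np.array(labels, dtype=object)[idx]


def _sample_onset_days(rng: np.random.Generator, drugs: np.ndarray,
                       mixtures: Mapping[str, Sequence[float]]) -> np.ndarray:
    """Per-case onset days from each PS drug's five-bin mixture."""
    edges = [(0, 7), (8, 28), (29, 60), (61, 90), (91, 365)]
    n = len(drugs)
    bins = np.empty(n, dtype=np.int64)
    default_w = np.asarray(DEFAULT_ONSET_MIXTURE)
    # draw bin index per case with the drug-specific mixture
    u = rng.random(n)
    for drug in np.unique(drugs):
        w = np.asarray(list(mixtures.get(drug, default_w)), dtype=float)
        cdf = np.cumsum(w / w.sum())
        mask = drugs == drug
        bins[mask] = np.searchsorted(cdf, u[mask], side="right")
    bins = np.clip(bins, 0, 4)
    lo = np.array([edges[b][0] for b in bins])
    hi = np.array([edges[b][1] for b in bins])
    return lo + (rng.random(n) * (hi - lo + 1)).astype(np.int64)


def generate_bundle(config: GeneratorConfig) -> QuarterBundle:
    """Generate a linked DEMO/DRUG/REAC/THER bundle plus a truth table.

    Deterministic for a fixed config (the seed is part of the config).
    Every DRUG/REAC/THER row joins to a DEMO row on PRIMARYID; each case
    has exactly one PS drug; the event is Bernoulli with odds equal to the
    background odds times the PS drug's planted ROR.  Duplicate versions
    are injected afterwards via :func:`inject_duplicates`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    # --- drug panel including fillers that absorb the unclaimed PS share
    specs = list(config.drugs)
    claimed = sum(s.marginal_share for s in specs)
    filler_share = (1.0 - claimed) / config.n_background_drugs
    fillers = [DrugSpec(f"BACKGROUND DRUG {i + 1:02d}", 1.0, filler_share)
               for i in range(config.n_background_drugs)]
    panel = specs + fillers
    names = np.array([s.name for s in panel], dtype=object)
    shares = np.array([s.marginal_share for s in panel], dtype=float)
    rors = np.array([s.target_ror for s in panel], dtype=float)

    ps_idx = rng.choice(len(panel), size=n, p=shares / shares.sum())
    ps_drug = names[ps_idx]

    # --- plant the event on the odds scale
    p0 = config.background_headache_rate
    odds = (p0 / (1 - p0)) * rors[ps_idx]
    p_event = odds / (1 + odds)
    event = rng.random(n) < p_event

    # --- dates: therapy start, onset by drug mixture, event and receipt
    start = (np.datetime64("2018-01-01") +
             rng.integers(0, 2465, n).astype("timedelta64[D]"))  # through 2024-09
    onset = _sample_onset_days(rng, ps_drug, config.onset_mixture)
    negative = rng.random(n) < 0.02  # data-entry errors: event precedes start
    onset = np.where(negative, -rng.integers(1, 30, n), onset)
    event_date = start + onset.astype("timedelta64[D]")
    fda_date = event_date + rng.integers(0, 90, n).astype("timedelta64[D]")

    caseid = np.char.add("3", np.char.zfill(
        np.arange(1, n + 1).astype("U9"), 8))
    primaryid = np.char.add(caseid, "1")  # FAERS-style caseid+version

    start_tok = _truncate_tokens(_date_tokens(start), config.partial_date_rate, rng)
    event_tok = _truncate_tokens(_date_tokens(event_date), config.partial_date_rate, rng)
    fda_tok = _date_tokens(fda_date)

    # --- demographics
    age_band = _categorical(rng, n, [(b, p) for b, p in _AGE_BANDS])
    age_lo = np.array([b[0] for b in age_band])
    age_hi = np.array([b[1] for b in age_band])
    age_years = age_lo + (rng.random(n) * (age_hi - age_lo + 1)).astype(np.int64)
    age = age_years.astype("U3").astype(object)
    age_cod = np.full(n, "YR", dtype=object)
    in_months = (age_years < 18) & (rng.random(n) < 0.2)
    age[in_months] = (age_years[in_months] * 12).astype("U4")
    age_cod[in_months] = "MON"
    miss_age = rng.random(n) < config.missing_age_rate
    age[miss_age] = ""
    age_cod[miss_age] = ""

    sex = _categorical(rng, n, [("F", 0.7421), ("M", 0.2567), ("UNK", 0.0012)])
    sex[rng.random(n) < config.missing_sex_rate] = ""

    wt_band = _categorical(rng, n, [(b, p) for b, p in _WT_BANDS])
    wt_lo = np.array([b[0] for b in wt_band])
    wt_hi = np.array([b[1] for b in wt_band])
    wt = (wt_lo + (rng.random(n) * (wt_hi - wt_lo + 1)).astype(np.int64))
    wt = wt.astype("U3").astype(object)
    wt_cod = np.full(n, "KG", dtype=object)
    miss_wt = rng.random(n) < config.missing_weight_rate
    wt[miss_wt] = ""
    wt_cod[miss_wt] = ""

    occp = _categorical(rng, n, _OCCP)
    country = _categorical(rng, n, _COUNTRY)

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_tok,
        "event_dt": event_tok, "age": age, "age_cod": age_cod, "sex": sex,
        "wt": wt, "wt_cod": wt_cod, "occp_cod": occp,
        "reporter_country": country,
    }).astype(str)

    # --- drug rows: the PS mention plus occasional SS mentions
    drug_rows = [pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid,
        "drug_seq": "1", "role_cod": "PS",
        "drugname": ps_drug, "start_dt": start_tok,
    })]
    has_ss = rng.random(n) < 0.30
    ss_drug = names[rng.integers(0, len(panel), n)]
    drug_rows.append(pd.DataFrame({
        "primaryid": primaryid[has_ss], "caseid": caseid[has_ss],
        "drug_seq": "2", "role_cod": "SS",
        "drugname": ss_drug[has_ss], "start_dt": "",
    }))
    drug = pd.concat(drug_rows, ignore_index=True).astype(str)

    # --- reactions: the event PT for event cases, plus other PTs
    reac_rows = [pd.DataFrame({
        "primaryid": primaryid[event], "caseid": caseid[event],
        "pt": EVENT_PT,
    })]
    other_pt = np.array(_OTHER_PTS, dtype=object)[
        rng.integers(0, len(_OTHER_PTS), n)]
    reac_rows.append(pd.DataFrame({  # every case reports one non-event PT
        "primaryid": primaryid, "caseid": caseid, "pt": other_pt,
    }))
    reac = pd.concat(reac_rows, ignore_index=True).astype(str)

    ther = pd.DataFrame({  # therapy dates truncate independently of DRUG's
        "primaryid": primaryid, "caseid": caseid, "dsg_drug_seq": "1",
        "start_dt": _truncate_tokens(_date_tokens(start),
                                     config.partial_date_rate, rng),
        "end_dt": _date_tokens(start + np.maximum(onset, 1).astype("timedelta64[D]")),
    }).astype(str)

    truth = pd.DataFrame({
        "caseid": caseid, "kept_primaryid": primaryid, "n_versions": 1,
        "ps_drug": ps_drug, "target_ror": rors[ps_idx], "headache": event,
        "onset_days": onset,
    })

    bundle = QuarterBundle(demo=demo, drug=drug, reac=reac, ther=ther,
                           truth=truth)
    if config.dup_fraction > 0:
        dup_seed = int(rng.integers(0, 2**31 - 1))
        bundle = inject_duplicates(bundle, config.dup_fraction, dup_seed)
    return bundle


# ---------------------------------------------------------------------------
# Duplicate-version injection
# ---------------------------------------------------------------------------

def inject_duplicates(bundle: QuarterBundle, dup_fraction: float,
                      seed: int) -> QuarterBundle:
    """Emit a fraction of cases as k>=2 report versions.

    Versions of a case share its CASEID under distinct PRIMARYIDs; extra
    versions carry earlier (or, with 15% probability, tied) FDA receipt
    dates.  For half of the duplicated cases the PRIMARYIDs are swapped
    between versions so that the latest-dated version does not always hold
    the highest id — exercising both deduplication tie-breaks.  The truth
    table's ``kept_primaryid`` marks the version the dedup rules should
    retain, computed here by direct (FDA_DT, PRIMARYID) maximisation,
    independent of the dedup module.
    """
    if not 0 <= dup_fraction < 1:
        raise ConfigError(f"dup_fraction: {dup_fraction} must be in [0,1)")
    if dup_fraction == 0:
        return bundle
    rng = np.random.default_rng(seed)
    demo = bundle.demo
    n = len(demo)

    sel = rng.random(n) < dup_fraction
    sel_rows = np.flatnonzero(sel)
    if len(sel_rows) == 0:
        return bundle
    k_extra = 1 + (rng.random(len(sel_rows)) < 0.10)  # 10% get 3 versions
    rep = np.repeat(sel_rows, k_extra.astype(int))

    extra = demo.iloc[rep].copy().reset_index(drop=True)
    base_fda = pd.to_datetime(extra["fda_dt"], format="%Y%m%d")
    back = rng.integers(1, 121, len(extra))
    tie = rng.random(len(extra)) < 0.15
    back[tie] = 0
    extra["fda_dt"] = _date_tokens(
        (base_fda - pd.to_timedelta(back, unit="D")).to_numpy())

    max_pid = pd.to_numeric(demo["primaryid"]).max()
    extra["primaryid"] = (max_pid + 1 + np.arange(len(extra))).astype(np.int64).astype(str)

    # swap ids between the base version and its first extra version for
    # half the duplicated cases, decorrelating id order from date order
    first_extra = np.unique(rep, return_index=True)[1]
    swap_case = rng.random(len(sel_rows)) < 0.5
    base_pids = demo["primaryid"].to_numpy().copy()
    extra_pids = extra["primaryid"].to_numpy().copy()
    rows, exts = sel_rows[swap_case], first_extra[swap_case]
    base_pids[rows], extra_pids[exts] = extra_pids[exts], base_pids[rows].copy()
    new_demo = demo.copy()
    new_demo["primaryid"] = base_pids
    extra["primaryid"] = extra_pids

    demo_all = pd.concat([new_demo, extra], ignore_index=True)

    # child rows follow each version's primaryid: re-key copies by caseid
    versions = demo_all[["primaryid", "caseid"]]

    def expand(child: pd.DataFrame) -> pd.DataFrame:
        content = child.drop(columns=["primaryid"])
        return versions.merge(content, on="caseid", how="inner")[child.columns]

    drug_all = expand(bundle.drug)
    reac_all = expand(bundle.reac)
    ther_all = expand(bundle.ther)

    # truth: kept version maximises (FDA_DT, numeric PRIMARYID)
    key = demo_all.assign(
        _fda=pd.to_numeric(demo_all["fda_dt"], errors="coerce").fillna(-1),
        _pid=pd.to_numeric(demo_all["primaryid"]),
    ).sort_values(["caseid", "_fda", "_pid"])
    kept = key.groupby("caseid").tail(1).set_index("caseid")["primaryid"]
    n_versions = demo_all.groupby("caseid").size()

    truth = bundle.truth
    if truth is None:
        truth = pd.DataFrame({"caseid": sorted(kept.index)})
    else:
        truth = truth.copy()
    truth["kept_primaryid"] = truth["caseid"].map(kept).to_numpy()
    truth["n_versions"] = truth["caseid"].map(n_versions).to_numpy()

    logger.info("inject_duplicates: %d case(s) duplicated, %d extra version(s)",
                len(sel_rows), len(extra))
    return dataclasses.replace(bundle, demo=demo_all, drug=drug_all,
                               reac=reac_all, ther=ther_all, truth=truth)
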