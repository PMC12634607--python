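"""Demographic summaries and the end-to-end pipeline driver.

The pipeline runs ingest -> deduplication -> primary-suspect cohort ->
disproportionality (per drug and per ATC class) -> time-to-onset ->
demographics, writing each result table as TSV plus a JSON manifest that
records row counts at every stage so the flow can be audited.

No multiple-testing adjustment is applied to the signal tables; the
manifest notes this caveat.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .cohort import add_event_flag, build_background
from .dedup import dedup_summary, deduplicate
from .io import QuarterBundle, concat_bundles, read_quarter, read_two_column_map
from .signals import atc_signal_frame, drug_signal_frame
from .tto import compute_onsets, tto_by_atc, tto_distribution
from .util import percentage

logger = logging.getLogger("pvsignal")

__all__ = ["demographic_summary", "run_pipeline", "age_in_years"]

AGE_BANDS = ("<18", "18–30", "31–50", "51–65", ">65")
WEIGHT_BANDS = ("≤50 kg", ">50–≤100 kg", ">100 kg")

_OCCP_LABELS = {
    "CN": "Consumer", "HP": "Health Professional", "MD": "Medical Doctor",
    "PH": "Pharmacist", "LW": "Other Work", "OT": "Others",
}
_NAMED_COUNTRIES = ("UNITED STATES", "CANADA", "UNITED KINGDOM", "DENMARK",
                    "COUNTRY NOT SPECIFIED")
_COUNTRY_LABELS = {
    "UNITED STATES": "United States", "CANADA": "Canada",
    "UNITED KINGDOM": "United Kingdom", "DENMARK": "Denmark",
    "COUNTRY NOT SPECIFIED": "Country Not Specified",
}

# FAERS age units -> years. An unrecognised unit leaves age missing.
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 7 / 365.25,
                "DY": 1 / 365.25, "HR": 1 / (24 * 365.25)}


def age_in_years(value: object, code: object) -> float | None:
    """Convert a FAERS (age, unit-code) pair to years; None when missing."""
    token = str(value).strip()
    if not token:
        return None
    try:
        age = float(token)
    except ValueError:
        return None
    factor = _AGE_FACTORS.get(str(code).strip().upper())
    if factor is None:
        return None
    years = age * factor
    return years if years >= 0 else None


def _age_band(years: float | None) -> str:
    if years is None:
        return "Missing"
    if years < 18:
        return "<18"
    if years <= 30:
        return "18–30"
    if years <= 50:
        return "31–50"
    if years <= 65:
        return "51–65"
    return ">65"


def _weight_band(value: object, code: object) -> str:
    token = str(value).strip()
    if not token:
        return "Missing"
    try:
        wt = float(token)
    except ValueError:
        return "Missing"
    unit = str(code).strip().upper()
    if unit == "LBS":
        wt *= 0.45359237
    elif unit not in {"KG", ""}:
        return "Missing"
    if wt <= 0:
        return "Missing"
    if wt <= 50:
        return "≤50 kg"
    if wt <= 100:
        return ">50–≤100 kg"
    return ">100 kg"


def _sex_label(value: object) -> str:
    token = str(value).strip().upper()
    if token == "F":
        return "Female"
    if token == "M":
        return "Male"
    if token == "UNK":
        return "Unknown"
    return "Missing"


def demographic_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-characteristic category counts over the event cohort.

    ``cohort`` is the DEMO subset of cohort reports (one row per report).
    Ages are normalised to years from their unit codes before banding;
    age 18 falls in "18–30" and age 65 in "51–65" (the outer bands are
    strictly below 18 / strictly above 65).  Missing and Unknown are
    explicit categories, so per-characteristic counts always sum to the
    cohort size.  Countries outside the individually named set pool into
    "Others".

    Returns a DataFrame (characteristic, category, count, pct) with pct
    rounded half-up to 2 decimals.
    """
    if cohort.empty:
        raise ValueError("demographic_summary: empty cohort")
    total = len(cohort)

    years = [age_in_years(v, c) for v, c in zip(cohort["age"], cohort["age_cod"])]
    rows: list[tuple[str, str, int]] = []

    def tally(characteristic: str, labels: pd.Series, order: list[str]) -> None:
        counts = labels.value_counts()
        for cat in order:
            rows.append((characteristic, cat, int(counts.get(cat, 0))))

    tally("Age", pd.Series([_age_band(y) for y in years]),
          list(AGE_BANDS) + ["Missing"])
    tally("Sex", cohort["sex"].map(_sex_label),
          ["Female", "Male", "Missing", "Unknown"])
    tally("Weight",
          pd.Series([_weight_band(v, c)
                     for v, c in zip(cohort["wt"], cohort["wt_cod"])]),
          list(WEIGHT_BANDS) + ["Missing"])
    occp = cohort["occp_cod"].str.strip().str.upper().map(
        lambda c: _OCCP_LABELS.get(c, "Not Available" if c == "" else "Others"))
    tally("Occupation Reporter", occp,
          ["Consumer", "Health Professional", "Medical Doctor", "Pharmacist",
           "Other Work", "Others", "Not Available"])
    country = cohort["reporter_country"].str.strip().str.upper().map(
        lambda c: _COUNTRY_LABELS.get(c, "Others"))
    tally("Reporter Country", country,
          [_COUNTRY_LABELS[c] for c in _NAMED_COUNTRIES] + ["Others"])

    out = pd.DataFrame(rows, columns=["characteristic", "category", "count"])
    out["pct"] = [percentage(k, total, 2) for k in out["count"]]
    return out


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Execute the full analysis and write result tables plus a manifest.

    ``config`` keys:

    - ``bundles``: list of quarter directories (or file lists) to ingest
      — or ``bundle_objects``: in-memory :class:`QuarterBundle` list;
    - ``synonyms`` / ``atc_map``: optional two-column TSV paths (or an
      in-memory mapping under ``atc_map_object``);
    - ``event_pt`` (default "Headache"), ``top_n`` (default 100),
      ``tto_top_k`` (default 50).

    Writes demographics.tsv, signals_drug.tsv, signals_atc.tsv,
    tto_drug.tsv, tto_atc.tsv, dedup_audit.tsv, cohort.tsv and
    manifest.json into ``outdir`` and returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    synonym_map = None
    if config.get("synonyms"):
        synonym_map = read_two_column_map(config["synonyms"])
    atc_map: Mapping[str, str] | None = config.get("atc_map_object")
    if atc_map is None and config.get("atc_map"):
        atc_map = read_two_column_map(config["atc_map"])

    bundles: list[QuarterBundle] = list(config.get("bundle_objects") or [])
    for path in config.get("bundles", []):
        bundles.append(read_quarter(path))
    if not bundles:
        raise ValueError("run_pipeline: no input bundles configured")
    bundle = concat_bundles(bundles) if len(bundles) > 1 else bundles[0]

    manifest: dict = {
        "tool": "pvsignal",
        "version": __version__,
        "config_hash": _config_hash({k: v for k, v in config.items()
                                     if not k.endswith("_object")
                                     and k != "bundle_objects"}),
        "caveats": ["no multiple-testing adjustment applied"],
        "stages": {},
    }
    manifest["stages"]["ingest"] = {
        "rows": bundle.n_rows(), "dropped": bundle.dropped,
        "join_violations": bundle.join_violations(),
    }

    kept, removed, audit = deduplicate(bundle.demo)
    manifest["stages"]["dedup"] = dedup_summary(len(bundle.demo), removed)
    audit.to_csv(outdir / "dedup_audit.tsv", sep="\t", index=False)

    background, counters = build_background(kept, bundle.drug, synonym_map)
    event_pt = config.get("event_pt", "Headache")
    background = add_event_flag(background, bundle.reac, event_pt)
    cohort_size = int(background["event"].sum())
    manifest["stages"]["cohort"] = {
        "background_reports": len(background),
        "event_reports": cohort_size,
        **counters,
    }
    background.to_csv(outdir / "cohort.tsv", sep="\t", index=False)

    top_n = int(config.get("top_n", 100))
    drug_frame = drug_signal_frame(background, top_n=top_n)
    drug_frame.to_csv(outdir / "signals_drug.tsv", sep="\t", index=False)
    if atc_map:
        atc_frame = atc_signal_frame(background, atc_map)
        atc_frame.to_csv(outdir / "signals_atc.tsv", sep="\t", index=False)
        manifest["stages"]["signals"] = {
            "drugs_ranked": len(drug_frame), "atc_classes": len(atc_frame)}
    else:
        manifest["stages"]["signals"] = {"drugs_ranked": len(drug_frame)}

    event_units = background.loc[background["event"]]
    onsets, exclusions = compute_onsets(event_units, kept, bundle.drug,
                                        bundle.ther)
    tto_top_k = int(config.get("tto_top_k", 50))
    dist = tto_distribution(onsets)
    if not dist.empty:
        dist = dist.sort_values(["n", "drug"], ascending=[False, True],
                                kind="stable").head(tto_top_k)
    dist.to_csv(outdir / "tto_drug.tsv", sep="\t", index=False)
    if atc_map:
        tto_by_atc(onsets, atc_map).to_csv(outdir / "tto_atc.tsv",
                                           sep="\t", index=False)
    manifest["stages"]["tto"] = {
        "complete_cases": len(onsets), "exclusions": exclusions}

    cohort_demo = kept[kept["primaryid"].isin(event_units["primaryid"])]
    if len(cohort_demo):
        demographic_summary(cohort_demo).to_csv(
            outdir / "demographics.tsv", sep="\t", index=False)
    manifest["stages"]["demographics"] = {"cohort_reports": len(cohort_demo)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run_pipeline: outputs written to %s", outdir)
    return manifest
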