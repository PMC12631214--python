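"""FAERS-dialect ingestion: parsing, drug-name normalization, cohort selection.

The seven quarterly tables are ``$``-delimited ASCII files linked by
``primaryid``.  Parsing never silently drops data: malformed rows and
unparseable fields are counted in an ingestion log.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import dates
from .errors import ConfigurationError, FormatError

MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("primaryid",),
    "DRUG": ("primaryid", "drugname"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid",),
    "THER": ("primaryid",),
    "INDI": ("primaryid",),
    "RPSR": ("primaryid",),
}

#: conversion of FAERS age-unit codes to years
AGE_UNIT_YEARS: dict[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

WEIGHT_UNIT_KG: dict[str, float] = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237}

#: reporter occupation codes
REPORTER_LABELS: dict[str, str] = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "HP": "health-professional-unspecified",
}

#: outcome codes counted as serious in aggregate views
#: (death / life-threatening / disability / congenital anomaly)
DEATH_CODES = {"DE"}
SERIOUS_CODES = {"LT", "DS", "CA"}

REGION_OF_COUNTRY: dict[str, str] = {
    "US": "North America", "CA": "North America", "MX": "North America",
    "BR": "South America", "AR": "South America", "CO": "South America",
    "CL": "South America", "PE": "South America",
    "DE": "Europe", "FR": "Europe", "GB": "Europe", "IT": "Europe",
    "ES": "Europe", "NL": "Europe", "PL": "Europe", "SE": "Europe",
    "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia", "TW": "Asia",
    "AU": "Oceania", "NZ": "Oceania",
    "ZA": "Africa", "EG": "Africa", "NG": "Africa",
}

OTHER_REGION = "Other/Unknown"


@dataclass
class RawTables:
    """The seven linked tables as string DataFrames plus an ingestion log."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    rpsr: pd.DataFrame
    log: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name.lower())


def read_quarter(paths: Mapping[str, str | Path]) -> RawTables:
    """Read one quarter's tables.

    ``paths`` maps table names (``DEMO`` ... ``RPSR``) to file paths.
    Rows with the wrong number of fields are counted per table in
    ``log['malformed_rows']`` and skipped; a missing mandatory column
    raises :class:`FormatError` naming the file and column.
    """
    frames: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    for name in MANDATORY_COLUMNS:
        if name not in paths:
            raise FormatError(f"missing path for table {name}")
        path = Path(paths[name])
        if not path.exists():
            raise FormatError(f"{path}: file does not exist")
        bad = [0]

        def _on_bad(row, _bad=bad):  # noqa: ANN001 - pandas callback
            _bad[0] += 1
            return None

        frame = pd.read_csv(
            path,
            sep="$",
            dtype=str,
            keep_default_na=False,
            engine="python",
            on_bad_lines=_on_bad,
        )
        frame.columns = [c.strip().lower() for c in frame.columns]
        for col in MANDATORY_COLUMNS[name]:
            if col not in frame.columns:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        frames[name] = frame
        malformed[name] = bad[0]
    return RawTables(
        demo=frames["DEMO"],
        drug=frames["DRUG"],
        reac=frames["REAC"],
        outc=frames["OUTC"],
        ther=frames["THER"],
        indi=frames["INDI"],
        rpsr=frames["RPSR"],
        log={"malformed_rows": malformed},
    )


# ---------------------------------------------------------------------------
# drug-name normalization
# ---------------------------------------------------------------------------

_PUNCT = re.compile(r"[^A-Z0-9]+")


def clean_name(name: str) -> str:
    """Uppercase and strip punctuation for fuzzy matching."""
    return _PUNCT.sub(" ", str(name).upper()).strip()


def default_name_table() -> pd.DataFrame:
    """Generic ↔ brand synonym table for the CDK4/6 inhibitor class."""
    rows = [
        ("Palbociclib", "Palbociclib"),
        ("Ibrance", "Palbociclib"),
        ("Ribociclib", "Ribociclib"),
        ("Kisqali", "Ribociclib"),
        ("Abemaciclib", "Abemaciclib"),
        ("Verzenio", "Abemaciclib"),
    ]
    return pd.DataFrame(rows, columns=["synonym", "generic"])


def normalize_drug_names(
    exposures: pd.DataFrame, name_table: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Fill ``generic_name`` by case-insensitive substring match.

    A raw name matches a generic when any of that generic's synonyms occurs
    as a substring of the punctuation-stripped, uppercased raw name.  Names
    matching synonyms of two different generics are left unresolved and
    counted as ambiguous.  A synonym mapped to two generics in the table is
    a configuration error.
    """
    tbl = name_table.copy()
    tbl["synonym_clean"] = tbl["synonym"].map(clean_name)
    dup = tbl.groupby("synonym_clean")["generic"].nunique()
    bad = dup[dup > 1]
    if len(bad):
        raise ConfigurationError(
            f"name_table: synonyms mapped to multiple generics: {list(bad.index)}"
        )

    out = exposures.copy()
    cleaned = out["drugname"].map(clean_name)
    match_count = np.zeros(len(out), dtype=int)
    generic = np.full(len(out), "", dtype=object)
    for gen, group in tbl.groupby("generic"):
        hit = np.zeros(len(out), dtype=bool)
        for syn in group["synonym_clean"]:
            if syn:
                hit |= cleaned.str.contains(syn, regex=False).to_numpy()
        generic[hit & (match_count == 0)] = gen
        match_count += hit.astype(int)
    ambiguous = match_count > 1
    generic[ambiguous] = ""
    out["generic_name"] = generic
    log = {
        "n_matched": int(((match_count == 1)).sum()),
        "n_ambiguous": int(ambiguous.sum()),
    }
    return out, log


# ---------------------------------------------------------------------------
# case-level table
# ---------------------------------------------------------------------------


def _parse_age_years(age: pd.Series, unit: pd.Series, log: dict) -> pd.Series:
    value = pd.to_numeric(age.mask(age.str.strip() == ""), errors="coerce")
    factor = unit.str.strip().str.upper().map(AGE_UNIT_YEARS)
    unknown_unit = value.notna() & unit.str.strip().ne("") & factor.isna()
    log["unparseable_age_unit"] = int(unknown_unit.sum())
    # a present age with a blank unit code is conventionally in years
    factor = factor.where(unit.str.strip().ne(""), 1.0)
    years = value * factor
    out_of_range = years.notna() & ((years < 0) | (years > 130))
    log["age_out_of_range"] = int(out_of_range.sum())
    return years.where(~out_of_range)


def _parse_weight_kg(wt: pd.Series, unit: pd.Series, log: dict) -> pd.Series:
    value = pd.to_numeric(wt.mask(wt.str.strip() == ""), errors="coerce")
    factor = unit.str.strip().str.upper().map(WEIGHT_UNIT_KG)
    factor = factor.where(unit.str.strip().ne(""), 1.0)
    kg = value * factor
    out_of_range = kg.notna() & ((kg < 20) | (kg > 400))
    log["weight_out_of_range"] = int(out_of_range.sum())
    return kg.where(~out_of_range)


def _outcome_class(outc: pd.DataFrame) -> pd.Series:
    """Per-report outcome with precedence death > serious > non-serious."""
    if outc.empty:
        return pd.Series(dtype=object)
    codes = outc.copy()
    codes["outc_cod"] = codes["outc_cod"].str.strip().str.upper()
    codes["rank"] = np.select(
        [codes["outc_cod"].isin(DEATH_CODES), codes["outc_cod"].isin(SERIOUS_CODES)],
        [2, 1],
        default=0,
    )
    best = codes.groupby("primaryid")["rank"].max()
    return best.map({2: "death", 1: "serious", 0: "non_serious"})


def build_case_table(raw: RawTables) -> pd.DataFrame:
    """Assemble one row per report with normalized demographic fields.

    Columns: ``primaryid, caseid, sex, age_years, weight_kg, country,
    region, reporter_type, report_year, event_date, event_precision,
    fda_date, outcome_class``.
    """
    demo = raw.demo
    log: dict = {}
    cases = pd.DataFrame({"primaryid": demo["primaryid"].str.strip()})
    cases["caseid"] = demo.get(
        "caseid", pd.Series("", index=demo.index)
    ).str.strip()

    sex = demo.get("sex", pd.Series("", index=demo.index)).str.strip().str.upper()
    cases["sex"] = sex.where(sex.isin(["F", "M"]), "")

    cases["age_years"] = _parse_age_years(
        demo.get("age", pd.Series("", index=demo.index)),
        demo.get("age_cod", pd.Series("", index=demo.index)),
        log,
    )
    cases["weight_kg"] = _parse_weight_kg(
        demo.get("wt", pd.Series("", index=demo.index)),
        demo.get("wt_cod", pd.Series("", index=demo.index)),
        log,
    )

    country = (
        demo.get("occr_country", pd.Series("", index=demo.index))
        .str.strip()
        .str.upper()
    )
    cases["country"] = country
    cases["region"] = country.map(REGION_OF_COUNTRY).fillna(OTHER_REGION)
    cases.loc[country == "", "region"] = OTHER_REGION

    occp = demo.get("occp_cod", pd.Series("", index=demo.index)).str.strip().str.upper()
    cases["reporter_type"] = occp.map(REPORTER_LABELS).fillna("")

    event = dates.parse_dates(demo.get("event_dt", pd.Series("", index=demo.index)))
    cases["event_date"] = event["date"]
    cases["event_precision"] = event["precision"]
    fda = dates.parse_dates(demo.get("fda_dt", pd.Series("", index=demo.index)))
    cases["fda_date"] = fda["date"]
    rept = dates.parse_dates(demo.get("rept_dt", pd.Series("", index=demo.index)))
    year = rept["date"].dt.year.fillna(fda["date"].dt.year)
    cases["report_year"] = year.astype("Int64")

    outcome = _outcome_class(raw.outc)
    cases["outcome_class"] = (
        cases["primaryid"].map(outcome).fillna("missing")
    )
    cases.attrs["log"] = log
    return cases


def build_exposures(raw: RawTables, name_table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """DRUG rows with normalized generic names and therapy start dates."""
    drug = raw.drug.copy()
    drug["primaryid"] = drug["primaryid"].str.strip()
    drug["drug_seq"] = pd.to_numeric(
        drug.get("drug_seq", pd.Series("", index=drug.index)), errors="coerce"
    ).astype("Int64")
    drug["role_cod"] = (
        drug.get("role_cod", pd.Series("", index=drug.index)).str.strip().str.upper()
    )
    drug, log = normalize_drug_names(drug, name_table)

    ther = raw.ther.copy()
    if "start_dt" in ther.columns and len(ther):
        ther["primaryid"] = ther["primaryid"].str.strip()
        key = "dsg_drug_seq" if "dsg_drug_seq" in ther.columns else "drug_seq"
        ther["drug_seq"] = pd.to_numeric(ther[key], errors="coerce").astype("Int64")
        parsed = dates.parse_dates(ther["start_dt"])
        ther = pd.concat(
            [ther[["primaryid", "drug_seq"]], parsed.add_prefix("start_")], axis=1
        )
        ther = ther.rename(columns={"start_date": "start_date"})
        ther = ther.drop_duplicates(["primaryid", "drug_seq"])
        drug = drug.merge(ther, on=["primaryid", "drug_seq"], how="left")
    if "start_date" not in drug.columns:
        drug["start_date"] = pd.NaT
        drug["start_precision"] = dates.PRECISION_NONE
    drug["start_precision"] = drug["start_precision"].fillna(dates.PRECISION_NONE)
    return drug, log


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Analysis-ready case/exposure/event sets.

    ``cases`` covers every report (cohort and comparator) and carries the
    boolean ``in_cohort`` plus, for cohort members, the assigned target
    ``drug``, ``n_concomitant`` and ``letrozole_use``.
    """

    cases: pd.DataFrame
    exposures: pd.DataFrame
    events: pd.DataFrame
    target_generics: tuple[str, ...]
    log: dict = field(default_factory=dict)

    @property
    def cohort_cases(self) -> pd.DataFrame:
        return self.cases[self.cases["in_cohort"]]

    @property
    def background_cases(self) -> pd.DataFrame:
        return self.cases[~self.cases["in_cohort"]]


def select_cohort(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    events: pd.DataFrame,
    target_generics: Sequence[str],
    role_filter: Sequence[str] = ("PS",),
    indication_terms: Sequence[str] | None = None,
) -> Cohort:
    """Restrict to reports with a target drug in a qualifying role.

    A report enters the cohort iff it carries ≥1 exposure whose
    ``generic_name`` is a target and whose role is in ``role_filter``
    (primary suspect by default).  When ``indication_terms`` is given, the
    whole case set is first restricted to reports whose INDI-derived
    indication matches any term (case-insensitive substring).
    """
    if not list(target_generics):
        raise ConfigurationError("target_generics must be non-empty")
    targets = list(target_generics)

    cases = cases.copy()
    if indication_terms is not None:
        if "indication" not in cases.columns:
            raise ConfigurationError(
                "indication filtering requires an 'indication' column on cases"
            )
        terms = [t.upper() for t in indication_terms]
        ind = cases["indication"].fillna("").str.upper()
        keep = np.zeros(len(cases), dtype=bool)
        for t in terms:
            keep |= ind.str.contains(t, regex=False).to_numpy()
        cases = cases[keep]
        exposures = exposures[exposures["primaryid"].isin(cases["primaryid"])]
        events = events[events["primaryid"].isin(cases["primaryid"])]

    qual = exposures[
        exposures["generic_name"].isin(targets)
        & exposures["role_cod"].isin(list(role_filter))
    ]
    # assigned drug: the qualifying row with the lowest drug_seq
    qual = qual.sort_values(["primaryid", "drug_seq"], kind="stable")
    assigned = qual.drop_duplicates("primaryid").set_index("primaryid")["generic_name"]

    cases["in_cohort"] = cases["primaryid"].isin(assigned.index)
    cases["drug"] = cases["primaryid"].map(assigned)

    # concomitant burden: distinct non-target drug names on the report
    exp = exposures.copy()
    exp["name_clean"] = exp["drugname"].map(clean_name)
    non_target = exp[~exp["generic_name"].isin(targets)]
    n_conco = non_target.groupby("primaryid")["name_clean"].nunique()
    cases["n_concomitant"] = (
        cases["primaryid"].map(n_conco).fillna(0).astype(int)
    )
    letro = exp[exp["name_clean"].str.contains("LETROZOLE", regex=False)]
    cases["letrozole_use"] = cases["primaryid"].isin(letro["primaryid"])

    events = events[events["primaryid"].isin(cases["primaryid"])].copy()
    log = {
        "n_reports": int(len(cases)),
        "n_cohort": int(cases["in_cohort"].sum()),
        "n_background": int((~cases["in_cohort"]).sum()),
    }
    return Cohort(
        cases=cases,
        exposures=exposures,
        events=events,
        target_generics=tuple(targets),
        log=log,
    )


def attach_indication(cases: pd.DataFrame, indi: pd.DataFrame) -> pd.DataFrame:
    """Join the concatenated INDI terms onto the case table."""
    cases = cases.copy()
    if indi.empty or "indi_pt" not in indi.columns:
        cases["indication"] = ""
        return cases
    terms = (
        indi.assign(primaryid=indi["primaryid"].str.strip())
        .groupby("primaryid")["indi_pt"]
        .agg(lambda s: "; ".join(sorted(set(s))))
    )
    cases["indication"] = cases["primaryid"].map(terms).fillna("")
    return cases
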