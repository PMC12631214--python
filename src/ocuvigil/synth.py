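"""Synthetic spontaneous-report database generator.

Emulates the FAERS quarterly-extract layout — seven ``$``-delimited tables
(DEMO, DRUG, REAC, OUTC, THER, INDI, RPSR) linked by ``primaryid`` — with a
fully known ground truth so that every downstream stage (ingestion,
deduplication, disproportionality, onset analysis, regression) can be
validated without any external download.

The generative model, per report:

* one primary-suspect drug drawn from configured marketing shares;
* adverse events drawn independently per Preferred Term with probability
  ``background × rate_ratio(drug, PT)`` capped at 1, so a planted pair
  ``(drug, PT, RR)`` has conditional reporting frequency exactly
  ``min(RR × background, 1)``; reports drawing no event receive the filler
  reaction "Drug ineffective" so that planted conditional frequencies are
  undisturbed;
* demographics (sex, age group, country, reporter, weight) from categorical
  profiles, with per-field missingness applied independently;
* therapy start dates and onset delays from a log-normal time-to-onset
  model parameterised by (median, IQR) in days; dates are emitted in mixed
  FAERS precision (``YYYYMMDD`` / ``YYYYMM`` / ``YYYY``);
* a configurable fraction of reports re-emitted as near-duplicate clones
  perturbed strictly within the duplicate-matching tolerances (same 10-char
  caseid prefix, start-date shift ≤ 7 days, age shift ≤ 5 years, same
  sex / country / PT set), logged as the known positive set for the
  deduplication stage.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

FILLER_PT = "Drug ineffective"

#: window covered by the simulated reports (first marketing approval of the
#: drug class through the last complete extract quarter)
WINDOW_START = np.datetime64("2015-01-01")
WINDOW_END = np.datetime64("2024-09-30")
WINDOW_DAYS = int((WINDOW_END - WINDOW_START) / np.timedelta64(1, "D"))

AGE_BINS: tuple[tuple[str, int, int], ...] = (
    ("<18", 5, 17),
    ("18-29", 18, 29),
    ("30-49", 30, 49),
    ("50-64", 50, 64),
    ("65-75", 65, 75),
    ("76-85", 76, 85),
    (">85", 86, 95),
)

CONCOMITANT_POOL: tuple[str, ...] = (
    "ANASTROZOLE", "EXEMESTANE", "FULVESTRANT", "TAMOXIFEN", "GOSERELIN",
    "DENOSUMAB", "ZOLEDRONIC ACID", "TRASTUZUMAB", "CAPECITABINE",
    "EVEROLIMUS", "ASPIRIN", "METFORMIN", "OMEPRAZOLE", "ATORVASTATIN",
    "AMLODIPINE", "LEVOTHYROXINE", "HYDROXYCHLOROQUINE", "PREDNISONE",
    "GABAPENTIN", "ONDANSETRON", "LORATADINE", "VITAMIN D", "CALCIUM",
    "METOPROLOL", "LISINOPRIL", "FUROSEMIDE", "SERTRALINE", "DULOXETINE",
    "PANTOPRAZOLE", "IBUPROFEN", "PARACETAMOL", "CLOPIDOGREL",
    "ALENDRONATE", "LETROZOLE PLACEHOLDER UNUSED", "CETIRIZINE",
    "MELATONIN", "FISH OIL", "MULTIVITAMIN", "RAMIPRIL", "SIMVASTATIN",
)

_DOSE_SUFFIXES = (" 125MG CAPSULE", " 200 MG", " TABLET", " 600MG", "")


@dataclass(frozen=True)
class DrugSpec:
    """One marketed drug: generic name, brand synonyms, marketing share."""

    generic: str
    brands: tuple[str, ...]
    share: float


@dataclass(frozen=True)
class EventSpec:
    """One Preferred Term with its background reporting probability."""

    pt: str
    background: float


@dataclass
class SynthConfig:
    """Full parameterisation of one synthetic database.

    ``planted_signals`` maps ``(generic, pt)`` to a rate ratio; a ratio of 1
    (the implicit default for every unlisted pair) means no association.
    ``missingness`` gives the per-field fraction of reports whose value is
    withheld.  ``onset_model`` maps ``"default"`` or ``(generic, pt)`` to a
    ``(median_days, (q1, q3))`` log-normal specification.
    """

    n_reports: int
    drugs: tuple[DrugSpec, ...]
    events: tuple[EventSpec, ...]
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    duplicate_rate: float = 0.05
    missingness: dict[str, float] = field(default_factory=dict)
    demographic_profile: dict[str, dict[str, float]] = field(default_factory=dict)
    onset_model: dict = field(default_factory=dict)
    concomitant_model: dict[str, float] = field(default_factory=dict)
    start_date_precision: dict[str, float] = field(
        default_factory=lambda: {"day": 0.85, "month": 0.10, "year": 0.05}
    )
    event_date_precision: dict[str, float] = field(
        default_factory=lambda: {"day": 0.92, "month": 0.05, "year": 0.03}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.missingness = {**DEFAULT_MISSINGNESS, **self.missingness}
        self.demographic_profile = {
            **DEFAULT_DEMOGRAPHIC_PROFILE,
            **self.demographic_profile,
        }
        self.onset_model = {**DEFAULT_ONSET_MODEL, **self.onset_model}
        self.concomitant_model = {
            **DEFAULT_CONCOMITANT_MODEL,
            **self.concomitant_model,
        }

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigurationError("n_reports must be >= 0")
        if not self.drugs:
            raise ConfigurationError("drugs must be non-empty")
        share_sum = sum(d.share for d in self.drugs)
        if abs(share_sum - 1.0) > 1e-9:
            raise ConfigurationError(
                f"drugs: marketing shares sum to {share_sum!r}, expected 1"
            )
        for d in self.drugs:
            if not 0 <= d.share <= 1:
                raise ConfigurationError(f"drugs: share of {d.generic} not in [0,1]")
        for e in self.events:
            if not 0 < e.background < 1:
                raise ConfigurationError(
                    f"events: background of {e.pt!r} not in (0,1)"
                )
        generics = {d.generic for d in self.drugs}
        pts = {e.pt for e in self.events}
        for drug, pt, rr in self.planted_signals:
            if drug not in generics:
                raise ConfigurationError(f"planted_signals: unknown drug {drug!r}")
            if pt not in pts:
                raise ConfigurationError(f"planted_signals: unknown event {pt!r}")
            if rr < 0:
                raise ConfigurationError(
                    f"planted_signals: rate_ratio for ({drug}, {pt}) is negative"
                )
        if not 0 <= self.duplicate_rate < 1:
            raise ConfigurationError("duplicate_rate must be in [0,1)")
        for name, frac in self.missingness.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"missingness[{name!r}] not in [0,1]")
        for name, dist in self.demographic_profile.items():
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"demographic_profile[{name!r}] does not sum to 1"
                )
        for prec in (self.start_date_precision, self.event_date_precision):
            if abs(sum(prec.values()) - 1.0) > 1e-6:
                raise ConfigurationError("date precision mix must sum to 1")

    # -- helpers ---------------------------------------------------------
    def rate_ratio(self, drug: str, pt: str) -> float:
        for d, p, rr in self.planted_signals:
            if d == drug and p == pt:
                return rr
        return 1.0

    def to_jsonable(self) -> dict:
        cfg = asdict(self)
        cfg["onset_model"] = {
            (k if isinstance(k, str) else "|".join(k)): v
            for k, v in self.onset_model.items()
        }
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Defaults: the simulated study conditions.  Marketing shares follow the
# relative report volumes of the drug cohort (Palbociclib ≫ Ribociclib >
# Abemaciclib, together ~30% of a breast-cancer reporting stream); the
# demographic profile, missingness and onset model follow the marginal
# distributions of the real-world ocular-event cohort (predominantly female,
# age skew above 50, ~63% missing weight, ~12% missing age, ~69% of reports
# without a computable onset, overall median onset 122 days with IQR 28–414).
# ---------------------------------------------------------------------------

DEFAULT_DRUGS: tuple[DrugSpec, ...] = (
    DrugSpec("Palbociclib", ("Ibrance",), 0.218),
    DrugSpec("Ribociclib", ("Kisqali",), 0.052),
    DrugSpec("Abemaciclib", ("Verzenio",), 0.032),
    DrugSpec("Tamoxifen", (), 0.22),
    DrugSpec("Anastrozole", (), 0.13),
    DrugSpec("Fulvestrant", (), 0.10),
    DrugSpec("Capecitabine", (), 0.09),
    DrugSpec("Trastuzumab", (), 0.088),
    DrugSpec("Exemestane", (), 0.05),
    DrugSpec("Everolimus", (), 0.02),
)

DEFAULT_EVENTS: tuple[EventSpec, ...] = (
    # ocular Preferred Terms (background reporting probabilities per report)
    EventSpec("Visual impairment", 0.008),
    EventSpec("Vision blurred", 0.007),
    EventSpec("Lacrimation increased", 0.005),
    EventSpec("Cataract", 0.004),
    EventSpec("Dry eye", 0.004),
    EventSpec("Blindness", 0.002),
    EventSpec("Eye disorder", 0.002),
    EventSpec("Eye pain", 0.002),
    EventSpec("Diplopia", 0.002),
    EventSpec("Eye swelling", 0.0015),
    EventSpec("Eye pruritus", 0.0015),
    EventSpec("Glaucoma", 0.0008),
    EventSpec("Dark circles under eyes", 0.0005),
    EventSpec("Eyelid disorder", 0.0005),
    EventSpec("Keratitis", 0.0005),
    EventSpec("Myopia", 0.0004),
    # common non-ocular terms
    EventSpec("Nausea", 0.12),
    EventSpec("Fatigue", 0.10),
    EventSpec("Diarrhoea", 0.08),
    EventSpec("Headache", 0.06),
    EventSpec("Neutropenia", 0.05),
    EventSpec("Vomiting", 0.05),
    EventSpec("Rash", 0.04),
    EventSpec("Arthralgia", 0.04),
    EventSpec("Dizziness", 0.04),
    EventSpec("Alopecia", 0.03),
    EventSpec("Anaemia", 0.03),
    EventSpec("Pyrexia", 0.03),
    EventSpec("Dyspnoea", 0.03),
    EventSpec("Hot flush", 0.02),
    EventSpec("Leukopenia", 0.02),
)

DEFAULT_PLANTED: tuple[tuple[str, str, float], ...] = (
    ("Palbociclib", "Cataract", 2.4),
    ("Palbociclib", "Blindness", 2.3),
    ("Palbociclib", "Lacrimation increased", 1.4),
    ("Ribociclib", "Visual impairment", 3.3),
    ("Ribociclib", "Dark circles under eyes", 23.0),
    ("Ribociclib", "Eye disorder", 4.2),
    ("Ribociclib", "Myopia", 8.0),
    ("Abemaciclib", "Visual impairment", 0.45),
)

DEFAULT_MISSINGNESS: dict[str, float] = {
    "sex": 0.812,
    "age": 0.124,
    "weight": 0.626,
    "country": 0.0,
    "reporter": 0.007,
    "outcome": 0.278,
    "start_date": 0.55,
    "event_date": 0.05,
    "concomitant": 0.05,
}

DEFAULT_DEMOGRAPHIC_PROFILE: dict[str, dict[str, float]] = {
    "sex": {"F": 0.986, "M": 0.014},
    "age_group": {
        "<18": 0.0017, "18-29": 0.0012, "30-49": 0.0983, "50-64": 0.3145,
        "65-75": 0.3647, "76-85": 0.1907, ">85": 0.0289,
    },
    "country": {
        "US": 0.599, "CA": 0.055, "DE": 0.05, "FR": 0.047, "JP": 0.025,
        "CN": 0.024, "BR": 0.10, "AR": 0.061, "ZA": 0.007, "AU": 0.001,
        "XX": 0.031,
    },
    "reporter": {"CN": 0.528, "HP": 0.139, "MD": 0.129, "OT": 0.131, "PH": 0.073},
    "outcome": {"non_serious": 0.906, "serious": 0.073, "death": 0.021},
}

DEFAULT_ONSET_MODEL: dict = {
    "default": (122.0, (28.0, 414.0)),
    ("Palbociclib", "Cataract"): (437.5, (154.0, 811.8)),
    ("Abemaciclib", "Lacrimation increased"): (27.0, (7.0, 66.0)),
}

DEFAULT_CONCOMITANT_MODEL: dict[str, float] = {
    "mean": 4.4,
    "dispersion": 0.8,
    "letrozole_prob": 0.35,
}


def default_config(n_reports: int = 50_000, seed: int = 0, **overrides) -> SynthConfig:
    """The default study conditions (see module docstring)."""
    kwargs = dict(
        n_reports=n_reports,
        drugs=DEFAULT_DRUGS,
        events=DEFAULT_EVENTS,
        planted_signals=DEFAULT_PLANTED,
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


# ---------------------------------------------------------------------------


@dataclass
class SynthDatabase:
    """Generated tables plus the generator's internal log."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    duplicate_log: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SynthConfig

    def write(self, outdir: str | Path, quarter: str = "24Q3") -> dict[str, Path]:
        """Write the seven ``$``-delimited tables plus ground truth/manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, frame in self.tables.items():
            path = outdir / f"{name}{quarter}.txt"
            frame.to_csv(path, sep="$", index=False)
            paths[name] = path
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        self.duplicate_log.to_csv(outdir / "duplicate_log.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )
        return paths


def ground_truth(config: SynthConfig) -> pd.DataFrame:
    """One row per (drug, PT) with the planted rate ratio and signal flag."""
    rows = [
        {
            "drug": d.generic,
            "pt": e.pt,
            "true_rate_ratio": config.rate_ratio(d.generic, e.pt),
        }
        for d in config.drugs
        for e in config.events
    ]
    out = pd.DataFrame(rows, columns=["drug", "pt", "true_rate_ratio"])
    out["is_signal"] = out["true_rate_ratio"] > 1
    return out


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal from its median and quartiles."""
    q1, q3 = iqr
    sigma = math.log(q3 / q1) / (2 * 0.674489750196082)
    return math.log(median), sigma


def _categorical(rng, dist: Mapping[str, float], n: int) -> np.ndarray:
    keys = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), size=n, p=probs)]


def _format_partial(full: np.ndarray, precision: np.ndarray) -> np.ndarray:
    """Render datetime64[D] values at mixed precision; '' where masked."""
    s = pd.Series(full.astype("datetime64[ns]"))
    out = np.where(
        precision == "day", s.dt.strftime("%Y%m%d"),
        np.where(
            precision == "month", s.dt.strftime("%Y%m"),
            np.where(precision == "year", s.dt.strftime("%Y"), ""),
        ),
    )
    return out.astype(object)


def generate_database(config: SynthConfig) -> SynthDatabase:
    """Generate the seven linked FAERS-dialect tables.

    Deterministic: identical ``config`` (including ``seed``) yields
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    generics = np.array([d.generic for d in config.drugs], dtype=object)
    shares = np.array([d.share for d in config.drugs], dtype=float)
    shares = shares / shares.sum()
    pts = np.array([e.pt for e in config.events], dtype=object)
    bg = np.array([e.background for e in config.events], dtype=float)
    n_ev = len(pts)

    drug_idx = rng.choice(len(generics), size=n, p=shares)

    # --- report keys: unique 10-digit caseids, primaryid = caseid + version
    increments = rng.integers(1, 40, size=n)
    caseid_num = 1_000_000_000 + np.cumsum(increments)
    caseid = np.char.mod("%010d", caseid_num).astype(object)
    primaryid = np.char.add(caseid.astype(str), "1").astype(object)

    # --- adverse events: independent Bernoulli per PT, planted RR multipliers
    prob = np.tile(bg, (n, 1))
    for drug, pt, rr in config.planted_signals:
        didx = int(np.where(generics == drug)[0][0])
        eidx = int(np.where(pts == pt)[0][0])
        prob[drug_idx == didx, eidx] *= rr
    np.clip(prob, 0.0, 1.0, out=prob)
    occ = rng.random((n, n_ev)) < prob
    no_event = ~occ.any(axis=1)  # filler PT keeps planted probabilities exact

    # --- demographics
    miss = config.missingness
    profile = config.demographic_profile

    sex = _categorical(rng, profile["sex"], n)
    sex_missing = rng.random(n) < miss["sex"]

    group = _categorical(rng, profile["age_group"], n)
    lo = np.empty(n)
    hi = np.empty(n)
    for label, a, b in AGE_BINS:
        m = group == label
        lo[m], hi[m] = a, b
    age_years = rng.integers(0, 10**9, size=n) % (hi - lo + 1).astype(int) + lo
    age_years = age_years.astype(int)
    age_missing = rng.random(n) < miss["age"]
    age_unit = _categorical(rng, {"YR": 0.90, "DEC": 0.05, "MON": 0.05}, n)
    age_value = np.where(
        age_unit == "YR", age_years.astype(float),
        np.where(age_unit == "DEC", np.round(age_years / 10.0, 1), age_years * 12.0),
    )

    weight = np.clip(rng.normal(73.4, 21.5, size=n), 27.0, 250.0).round(1)
    weight_missing = rng.random(n) < miss["weight"]
    wt_unit = np.where(rng.random(n) < 0.10, "LBS", "KG")
    wt_value = np.where(wt_unit == "LBS", np.round(weight / 0.45359237, 1), weight)

    country = _categorical(rng, profile["country"], n)
    country_missing = rng.random(n) < miss["country"]
    reporter = _categorical(rng, profile["reporter"], n)
    reporter_missing = rng.random(n) < miss["reporter"]

    outcome = _categorical(rng, profile["outcome"], n)
    outcome_missing = rng.random(n) < miss["outcome"]

    # --- therapy start / event onset dates
    mu_def, sg_def = _lognormal_params(*config.onset_model["default"])
    mu = np.full(n, mu_def)
    sg = np.full(n, sg_def)
    for key, spec in config.onset_model.items():
        if key == "default":
            continue
        drug, pt = key
        if drug not in generics or pt not in pts:
            continue
        didx = int(np.where(generics == drug)[0][0])
        eidx = int(np.where(pts == pt)[0][0])
        m = (drug_idx == didx) & occ[:, eidx]
        mu_k, sg_k = _lognormal_params(*spec)
        mu[m], sg[m] = mu_k, sg_k
    tto = np.minimum(
        np.round(rng.lognormal(mean=mu, sigma=sg)), WINDOW_DAYS - 1
    ).astype(int)
    start_full = WINDOW_START + (
        rng.integers(0, 10**9, size=n) % (WINDOW_DAYS - tto)
    ).astype("timedelta64[D]")
    event_full = start_full + tto.astype("timedelta64[D]")
    fda_full = np.minimum(
        event_full + rng.integers(0, 61, size=n).astype("timedelta64[D]"),
        WINDOW_END,
    )

    start_prec = _categorical(rng, config.start_date_precision, n)
    start_prec[rng.random(n) < miss["start_date"]] = "none"
    event_prec = _categorical(rng, config.event_date_precision, n)
    event_prec[rng.random(n) < miss["event_date"]] = "none"

    # --- concomitant medications
    cm = config.concomitant_model
    r = cm["dispersion"]
    p_nb = r / (r + cm["mean"])
    m_total = rng.negative_binomial(r, p_nb, size=n)
    letro = rng.random(n) < cm["letrozole_prob"]
    conco_masked = rng.random(n) < miss["concomitant"]
    pool = np.array(
        [d for d in CONCOMITANT_POOL if "PLACEHOLDER" not in d], dtype=object
    )
    k_other = np.clip(m_total - letro.astype(int), 0, len(pool))
    k_other[conco_masked] = 0
    letro = letro & ~conco_masked
    perm = np.argsort(rng.random((n, len(pool))), axis=1)
    sel_mask = np.arange(len(pool))[None, :] < k_other[:, None]

    # a small fraction of reports carry a secondary-suspect row for a target
    # drug, exercising the primary-suspect role filter downstream
    target_generics = [d.generic for d in config.drugs if d.brands]
    ss_mask = rng.random(n) < (0.02 if target_generics else 0.0)
    ss_drug = (
        _categorical(
            rng, {g: 1 / len(target_generics) for g in target_generics}, n
        )
        if target_generics
        else np.full(n, "", dtype=object)
    )

    # --- duplicate injection: clones perturbed within matching tolerances.
    # Source reports are forced complete on the matched fields so the
    # injected pairs are a guaranteed-linkable positive set.
    k_dup = int(round(config.duplicate_rate * n))
    dup_src = (
        rng.choice(n, size=k_dup, replace=False) if k_dup else np.array([], int)
    )
    dup_src.sort()
    sex_missing[dup_src] = False
    age_missing[dup_src] = False
    country_missing[dup_src] = False
    start_prec[dup_src] = "day"

    dup_age = np.clip(
        age_years[dup_src] + rng.integers(-5, 6, size=k_dup), 0, 120
    )
    dup_start = start_full[dup_src] + rng.integers(-7, 8, size=k_dup).astype(
        "timedelta64[D]"
    )
    dup_fda = np.minimum(
        fda_full[dup_src] + rng.integers(1, 91, size=k_dup).astype("timedelta64[D]"),
        WINDOW_END,
    )
    dup_primaryid = np.char.add(caseid[dup_src].astype(str), "2").astype(object)
    dup_keep_weight = rng.random(k_dup) < 0.5

    # --- assemble DEMO ---------------------------------------------------
    def blank(values, missing):
        out = values.astype(object).copy()
        out[missing] = ""
        return out

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "caseversion": "1",
            "fda_dt": pd.Series(fda_full.astype("datetime64[ns]")).dt.strftime("%Y%m%d"),
            "rept_dt": pd.Series(fda_full.astype("datetime64[ns]")).dt.strftime("%Y%m%d"),
            "event_dt": _format_partial(event_full, event_prec),
            "age": blank(np.char.mod("%g", age_value).astype(object), age_missing),
            "age_cod": blank(age_unit, age_missing),
            "sex": blank(sex, sex_missing),
            "wt": blank(np.char.mod("%g", wt_value).astype(object), weight_missing),
            "wt_cod": blank(wt_unit, weight_missing),
            "occr_country": blank(country, country_missing),
            "occp_cod": blank(reporter, reporter_missing),
        }
    )

    dup_demo = demo.iloc[dup_src].copy()
    dup_demo["primaryid"] = dup_primaryid
    dup_demo["caseversion"] = "2"
    dup_demo["fda_dt"] = pd.Series(
        dup_fda.astype("datetime64[ns]")
    ).dt.strftime("%Y%m%d").to_numpy()
    dup_demo["rept_dt"] = dup_demo["fda_dt"]
    dup_demo["age"] = np.char.mod("%d", dup_age).astype(object)
    dup_demo["age_cod"] = "YR"
    w = dup_demo["wt"].to_numpy(object)
    w[~dup_keep_weight] = ""
    dup_demo["wt"] = w
    wc = dup_demo["wt_cod"].to_numpy(object)
    wc[~dup_keep_weight] = ""
    dup_demo["wt_cod"] = wc
    demo_all = pd.concat([demo, dup_demo], ignore_index=True)

    # --- DRUG / THER / INDI rows ----------------------------------------
    brand_of = {d.generic: d.brands for d in config.drugs}

    style = rng.random(n)
    suffix = np.array(_DOSE_SUFFIXES, dtype=object)[
        rng.integers(0, len(_DOSE_SUFFIXES), size=n)
    ]
    ps_name = np.empty(n, dtype=object)
    for i_d, g in enumerate(generics):
        m = drug_idx == i_d
        brands = brand_of[g]
        base = np.where(
            (style[m] < 0.45) & (len(brands) > 0),
            (brands[0].upper() if brands else g.upper()),
            g.upper(),
        )
        ps_name[m] = np.char.add(base.astype(str), suffix[m].astype(str))

    ps_rows = pd.DataFrame(
        {
            "primaryid": primaryid,
            "drug_seq": 1,
            "role_cod": "PS",
            "drugname": ps_name,
        }
    )
    letro_idx = np.flatnonzero(letro)
    letro_rows = pd.DataFrame(
        {
            "primaryid": primaryid[letro_idx],
            "drug_seq": 2,
            "role_cod": "C",
            "drugname": "LETROZOLE",
        }
    )
    conco_case = np.repeat(np.arange(n), k_other)
    conco_names = pool[perm[sel_mask]]
    conco_seq = (
        np.concatenate([np.arange(k) for k in k_other]) + 2 + letro[conco_case]
        if len(conco_case)
        else np.array([], int)
    )
    conco_rows = pd.DataFrame(
        {
            "primaryid": primaryid[conco_case],
            "drug_seq": conco_seq,
            "role_cod": "C",
            "drugname": conco_names,
        }
    )
    ss_idx = np.flatnonzero(ss_mask)
    ss_rows = pd.DataFrame(
        {
            "primaryid": primaryid[ss_idx],
            "drug_seq": 90,
            "role_cod": "SS",
            "drugname": np.char.upper(ss_drug[ss_idx].astype(str)).astype(object),
        }
    )
    drug_tbl = pd.concat([ps_rows, letro_rows, conco_rows, ss_rows], ignore_index=True)
    dup_drug = drug_tbl[drug_tbl["primaryid"].isin(primaryid[dup_src])].copy()
    dup_map = dict(zip(primaryid[dup_src], dup_primaryid))
    dup_drug["primaryid"] = dup_drug["primaryid"].map(dup_map)
    drug_all = pd.concat([drug_tbl, dup_drug], ignore_index=True)
    drug_all = drug_all.sort_values(
        ["primaryid", "drug_seq"], kind="stable"
    ).reset_index(drop=True)

    # REAC
    case_i, ev_i = np.nonzero(occ)
    reac = pd.DataFrame({"primaryid": primaryid[case_i], "pt": pts[ev_i]})
    filler = pd.DataFrame(
        {"primaryid": primaryid[no_event], "pt": FILLER_PT}
    )
    reac = pd.concat([reac, filler], ignore_index=True)
    dup_reac = reac[reac["primaryid"].isin(primaryid[dup_src])].copy()
    dup_reac["primaryid"] = dup_reac["primaryid"].map(dup_map)
    reac_all = pd.concat([reac, dup_reac], ignore_index=True).sort_values(
        ["primaryid", "pt"], kind="stable"
    ).reset_index(drop=True)

    # OUTC
    outc_code = np.where(
        outcome == "death",
        "DE",
        np.where(
            outcome == "serious",
            _categorical(rng, {"LT": 0.5, "DS": 0.4, "CA": 0.1}, n),
            _categorical(rng, {"HO": 0.6, "OT": 0.4}, n),
        ),
    )
    has_outc = ~outcome_missing
    outc = pd.DataFrame(
        {"primaryid": primaryid[has_outc], "outc_cod": outc_code[has_outc]}
    )
    dup_outc = outc[outc["primaryid"].isin(primaryid[dup_src])].copy()
    dup_outc["primaryid"] = dup_outc["primaryid"].map(dup_map)
    outc_all = pd.concat([outc, dup_outc], ignore_index=True)

    # THER: start date of the suspect drug
    start_str = _format_partial(start_full, start_prec)
    has_start = start_prec != "none"
    ther = pd.DataFrame(
        {
            "primaryid": primaryid[has_start],
            "dsg_drug_seq": 1,
            "start_dt": start_str[has_start],
        }
    )
    dup_start_str = pd.Series(
        dup_start.astype("datetime64[ns]")
    ).dt.strftime("%Y%m%d").to_numpy(object)
    dup_ther = pd.DataFrame(
        {"primaryid": dup_primaryid, "dsg_drug_seq": 1, "start_dt": dup_start_str}
    )
    ther_all = pd.concat([ther, dup_ther], ignore_index=True)

    # INDI
    indi_pt = _categorical(
        rng,
        {"Breast cancer": 0.90, "Breast cancer metastatic": 0.05, "Lung cancer": 0.05},
        n,
    )
    indi = pd.DataFrame(
        {"primaryid": primaryid, "indi_drug_seq": 1, "indi_pt": indi_pt}
    )
    dup_indi = indi[indi["primaryid"].isin(primaryid[dup_src])].copy()
    dup_indi["primaryid"] = dup_indi["primaryid"].map(dup_map)
    indi_all = pd.concat([indi, dup_indi], ignore_index=True)

    # RPSR
    has_rpsr = rng.random(n) < 0.8
    rpsr_cod = _categorical(rng, {"FGN": 0.4, "HP": 0.3, "CSM": 0.2, "LIT": 0.1}, n)
    rpsr = pd.DataFrame(
        {"primaryid": primaryid[has_rpsr], "rpsr_cod": rpsr_cod[has_rpsr]}
    )
    dup_rpsr = rpsr[rpsr["primaryid"].isin(primaryid[dup_src])].copy()
    dup_rpsr["primaryid"] = dup_rpsr["primaryid"].map(dup_map)
    rpsr_all = pd.concat([rpsr, dup_rpsr], ignore_index=True)

    tables = {
        "DEMO": demo_all,
        "DRUG": drug_all,
        "REAC": reac_all,
        "OUTC": outc_all,
        "THER": ther_all,
        "INDI": indi_all,
        "RPSR": rpsr_all,
    }
    tables = {name: frame.astype(str) for name, frame in tables.items()}

    duplicate_log = pd.DataFrame(
        {
            "original_primaryid": primaryid[dup_src].astype(str),
            "duplicate_primaryid": dup_primaryid.astype(str),
            "caseid": caseid[dup_src].astype(str),
        }
    )

    ps_counts = pd.Series(generics[drug_idx]).value_counts().to_dict()
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_cases": int(n),
        "n_duplicates": int(k_dup),
        "table_rows": {name: int(len(frame)) for name, frame in tables.items()},
        "ps_case_counts": {str(k): int(v) for k, v in ps_counts.items()},
        "filler_reports": int(no_event.sum()),
    }

    return SynthDatabase(
        tables=tables,
        manifest=manifest,
        duplicate_log=duplicate_log,
        ground_truth=ground_truth(config),
        config=config,
    )
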