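"""End-to-end orchestration: ingest → dedup → standardize → cohort →
signals → onset → regression → sensitivity → report.

Every run is a pure function of its configuration (one top-level seed);
the manifest records row counts after each stage plus the configuration
hash, so identical configs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dedup, io_faers, meddra, onset, riskmodel, report, sensitivity, signals
from .errors import ConfigurationError, OcuvigilError
from .synth import SynthConfig, SynthDatabase, generate_database

STAGES = (
    "ingest",
    "dedup",
    "standardize",
    "cohort",
    "signals",
    "onset",
    "regression",
    "sensitivity",
    "report",
)

TARGET_GENERICS = ("Palbociclib", "Ribociclib", "Abemaciclib")
COMBINED_LABEL = "CDK4/6 inhibitors"


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``synth`` (generate the database in-process) or
    ``input_dir`` (read previously written FAERS-dialect tables) must be
    set.
    """

    synth: SynthConfig | None = None
    input_dir: str | Path | None = None
    target_generics: tuple[str, ...] = TARGET_GENERICS
    indication_terms: tuple[str, ...] | None = None
    dedup_rule: dedup.DuplicateRule = field(default_factory=dedup.DuplicateRule)
    signal_rules: signals.SignalRules = field(default_factory=signals.SignalRules)
    regression_spec: riskmodel.RegressionSpec = field(
        default_factory=riskmodel.RegressionSpec
    )
    unknown_term_policy: str = "passthrough"
    top_k_events: int = 20
    split_year: int = 2020
    ocular_risk_drugs: tuple[str, ...] = sensitivity.DEFAULT_OCULAR_RISK_DRUGS
    seed: int = 0

    def config_hash(self) -> str:
        parts = {
            "synth": self.synth.to_jsonable() if self.synth else None,
            "input_dir": str(self.input_dir) if self.input_dir else None,
            "targets": self.target_generics,
            "indication": self.indication_terms,
            "dedup": vars(self.dedup_rule),
            "rules": vars(self.signal_rules),
            "reg": vars(self.regression_spec),
            "policy": self.unknown_term_policy,
            "top_k": self.top_k_events,
            "split_year": self.split_year,
            "codrugs": self.ocular_risk_drugs,
            "seed": self.seed,
        }
        blob = json.dumps(parts, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineState:
    """Everything a completed (or partially completed) run produced."""

    config: PipelineConfig
    manifest: dict
    raw: io_faers.RawTables | None = None
    cases: pd.DataFrame | None = None
    exposures: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    dedup_log: pd.DataFrame | None = None
    unmapped_terms: pd.DataFrame | None = None
    cohort: io_faers.Cohort | None = None
    signal_results: pd.DataFrame | None = None
    onset_records: pd.DataFrame | None = None
    tto_by_drug: pd.DataFrame | None = None
    tto_by_pt: pd.DataFrame | None = None
    pyramid: pd.DataFrame | None = None
    regression: riskmodel.RegressionResult | None = None
    sensitivity_results: dict = field(default_factory=dict)
    demographics: pd.DataFrame | None = None
    numeric_summaries: pd.DataFrame | None = None

    # -- shared derived views -------------------------------------------
    @property
    def ocular_pts(self) -> set[str]:
        return meddra.default_term_map().ocular_pts()

    def cohort_frame(self) -> pd.DataFrame:
        """Cohort cases with the binary ocular-event outcome attached."""
        cc = self.cohort.cohort_cases.copy()
        ocular_ids = set(
            self.events.loc[
                self.events["soc"] == meddra.OCULAR_SOC, "primaryid"
            ]
        )
        cc["oae"] = cc["primaryid"].isin(ocular_ids).astype(int)
        return cc


def _load_tables(config: PipelineConfig) -> tuple[io_faers.RawTables, dict]:
    if (config.synth is None) == (config.input_dir is None):
        raise ConfigurationError("set exactly one of synth or input_dir")
    if config.synth is not None:
        db: SynthDatabase = generate_database(config.synth)
        frames = {k: v for k, v in db.tables.items()}
        raw = io_faers.RawTables(
            demo=frames["DEMO"], drug=frames["DRUG"], reac=frames["REAC"],
            outc=frames["OUTC"], ther=frames["THER"], indi=frames["INDI"],
            rpsr=frames["RPSR"], log={"source": "synth"},
        )
        return raw, db.manifest
    indir = Path(config.input_dir)
    paths = {}
    for name in io_faers.MANDATORY_COLUMNS:
        matches = sorted(indir.glob(f"{name}*.txt"))
        if not matches:
            raise ConfigurationError(f"{indir}: no {name}*.txt file found")
        paths[name] = matches[0]
    return io_faers.read_quarter(paths), {}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    last_stage: str = "report",
) -> PipelineState:
    """Run the pipeline through ``last_stage`` (inclusive).

    A stage failure aborts with the stage name; the partial manifest is
    still attached to the raised error (and written when ``outdir`` is
    set).
    """
    if last_stage not in STAGES:
        raise ConfigurationError(f"unknown stage {last_stage!r}")
    state = PipelineState(
        config=config,
        manifest={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": {},
        },
    )
    stop = STAGES.index(last_stage)
    try:
        for stage in STAGES[: stop + 1]:
            _STAGE_FUNCS[stage](state)
            state.manifest["stages"][stage] = _stage_counts(state)
    except Exception as exc:
        state.manifest["failed_stage"] = stage
        if outdir is not None:
            _write_artifacts(state, outdir)
        raise OcuvigilError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    if outdir is not None:
        _write_artifacts(state, outdir)
    return state


def _stage_counts(state: PipelineState) -> dict:
    counts = {}
    if state.cases is not None:
        counts["reports"] = int(len(state.cases))
    if state.events is not None:
        counts["event_rows"] = int(len(state.events))
    if state.cohort is not None:
        counts["cohort_reports"] = int(state.cohort.cases["in_cohort"].sum())
    if state.signal_results is not None:
        counts["signal_pairs"] = int(len(state.signal_results))
    return counts


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_ingest(state: PipelineState) -> None:
    raw, synth_manifest = _load_tables(state.config)
    state.raw = raw
    if synth_manifest:
        state.manifest["synth"] = {
            k: v for k, v in synth_manifest.items() if k != "table_rows"
        } | {"table_rows": synth_manifest.get("table_rows", {})}
    cases = io_faers.build_case_table(raw)
    exposures, name_log = io_faers.build_exposures(raw, io_faers.default_name_table())
    cases = io_faers.attach_indication(cases, raw.indi)
    state.cases = cases
    state.exposures = exposures
    state.events = raw.reac[["primaryid", "pt"]].copy()
    state.events["primaryid"] = state.events["primaryid"].str.strip()
    state.manifest["ingest_log"] = {**raw.log, **name_log, **cases.attrs.get("log", {})}


def _stage_dedup(state: PipelineState) -> None:
    cases, exposures, events, log = dedup.drop_duplicates(
        state.cases, state.exposures, state.events, state.config.dedup_rule
    )
    state.cases, state.exposures, state.events = cases, exposures, events
    state.dedup_log = log
    state.manifest["n_duplicates_removed"] = int(
        log["cluster_size"].sum() - len(log)
    ) if len(log) else 0


def _stage_standardize(state: PipelineState) -> None:
    std, unmapped = meddra.standardize_events(
        state.events, meddra.default_term_map(), state.config.unknown_term_policy
    )
    state.events = std
    state.unmapped_terms = unmapped


def _stage_cohort(state: PipelineState) -> None:
    state.cohort = io_faers.select_cohort(
        state.cases,
        state.exposures,
        state.events,
        state.config.target_generics,
        indication_terms=state.config.indication_terms,
    )


def _stage_signals(state: PipelineState) -> None:
    ocular = sorted(
        set(state.events.loc[state.events["soc"] == meddra.OCULAR_SOC, "pt"])
    )
    tables = signals.contingency_tables(
        state.cohort.cohort_cases,
        state.events,
        state.cohort.background_cases,
        pts=ocular,
        combined_label=COMBINED_LABEL,
    )
    state.signal_results = signals.disproportionality(
        tables, state.config.signal_rules, seed=state.config.seed
    )


def _stage_onset(state: PipelineState) -> None:
    ocular_events = state.events[state.events["soc"] == meddra.OCULAR_SOC]
    rec = onset.compute_tto(
        state.cohort.cohort_cases,
        state.cohort.exposures,
        ocular_events,
        state.config.target_generics,
    )
    state.onset_records = rec
    # per-drug summary over reports (one record per report, not per PT)
    per_report = rec.drop_duplicates("primaryid")
    state.tto_by_drug = onset.summarize_tto(per_report, "drug")
    state.tto_by_pt = onset.summarize_tto(rec, "pt")
    state.pyramid = onset.severity_pyramid(
        state.cohort.cohort_cases, ocular_events, state.config.top_k_events
    )


def _stage_regression(state: PipelineState) -> None:
    state.regression = riskmodel.fit_logistic(
        state.cohort_frame(), state.config.regression_spec
    )


def _stage_sensitivity(state: PipelineState) -> None:
    state.sensitivity_results = {
        "missingness_exclusion": sensitivity.run_missingness_exclusion(state),
        "period_stratification": sensitivity.run_period_stratification(
            state, split_year=state.config.split_year
        ),
        "codrug_exclusion": sensitivity.run_codrug_exclusion(
            state, state.config.ocular_risk_drugs
        ),
    }


def _stage_report(state: PipelineState) -> None:
    cc = state.cohort.cohort_cases
    tto = state.onset_records.drop_duplicates("primaryid")[["primaryid", "tto_days"]]
    state.demographics, state.numeric_summaries = report.demographic_table(
        cc, tto, combined_label=COMBINED_LABEL
    )


_STAGE_FUNCS = {
    "ingest": _stage_ingest,
    "dedup": _stage_dedup,
    "standardize": _stage_standardize,
    "cohort": _stage_cohort,
    "signals": _stage_signals,
    "onset": _stage_onset,
    "regression": _stage_regression,
    "sensitivity": _stage_sensitivity,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def _write_artifacts(state: PipelineState, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(
        json.dumps(state.manifest, indent=2, default=str)
    )
    frames = {
        "dedup_log.csv": state.dedup_log,
        "unmapped_terms.csv": state.unmapped_terms,
        "signal_results.csv": state.signal_results,
        "tto_by_drug.csv": state.tto_by_drug,
        "tto_by_pt.csv": state.tto_by_pt,
        "severity_pyramid.csv": state.pyramid,
        "demographics.csv": state.demographics,
        "numeric_summaries.csv": state.numeric_summaries,
    }
    for name, frame in frames.items():
        if frame is not None:
            frame.to_csv(outdir / name, index=False)
    if state.regression is not None:
        riskmodel.forest_table(state.regression).to_csv(
            outdir / "forest_plot.csv", index=False
        )
        (outdir / "regression_manifest.json").write_text(
            json.dumps(
                {
                    "n_used": state.regression.n_used,
                    "n_excluded": state.regression.n_excluded,
                    "converged": state.regression.converged,
                    "vif": state.regression.vif.to_dict(),
                    "hl_statistic": state.regression.hl_statistic,
                    "hl_p": state.regression.hl_p,
                    "warnings": state.regression.warnings,
                },
                indent=2,
                default=str,
            )
        )
    for name, res in state.sensitivity_results.items():
        drift = res.get("drift")
        if isinstance(drift, pd.DataFrame):
            drift.to_csv(outdir / f"sensitivity_{name}.csv", index=False)
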