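"""Table readers/writers, schema validation, and the end-to-end pipeline driver.

All on-disk artifacts are tab-separated text with a header row.  Sample IDs
are formed as ``<subject_id>_<visit_id>`` and must cross-reference between
the phenotype table and the expression/call matrices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIAGNOSES = ("BP", "MDD", "SZ", "SZA", "PTSD", "PSYCH", "MOOD")
GENDERS = ("M", "F")
CALLS = ("A", "M", "P")
EVIDENCE_CATEGORIES = (
    "human_genetic",
    "human_nervous",
    "human_peripheral",
    "nonhuman_genetic",
    "nonhuman_nervous",
    "nonhuman_peripheral",
)

VISIT_COLUMNS = (
    "subject_id",
    "visit_id",
    "day",
    "gender",
    "diagnosis",
    "pain_vas",
    "sf36_21",
    "sf36_22",
)
FOLLOWUP_COLUMNS = ("subject_id", "index_visit_day", "ed_pain_event_days", "last_note_day")
EVIDENCE_COLUMNS = ("gene_symbol", "category", "citation_tag")


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


def sample_id(subject_id, visit_id) -> str:
    return f"{subject_id}_{visit_id}"


@dataclass
class ExpressionBundle:
    """Paired linear-scale intensity and A/M/P detection-call matrices.

    Both matrices are probesets x samples, sharing index and columns.
    Intensities are non-negative and on the linear (de-logged) scale.
    """

    intensity: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self):
        if not self.intensity.index.equals(self.calls.index):
            raise SchemaError("intensity and calls must share probeset index")
        if not self.intensity.columns.equals(self.calls.columns):
            raise SchemaError("intensity and calls must share sample columns")
        if (self.intensity.to_numpy() < 0).any():
            raise SchemaError("intensities must be non-negative")
        bad = ~self.calls.isin(CALLS)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise SchemaError(
                f"invalid detection call {self.calls.iat[r, c]!r} at probeset "
                f"{self.calls.index[r]!r}, sample {self.calls.columns[c]!r}"
            )

    @property
    def probeset_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensity.columns

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionBundle":
        return ExpressionBundle(self.intensity[list(samples)], self.calls[list(samples)])


def validate_visits(visits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise SchemaError(f"visits table missing columns: {missing}")
    v = visits.copy()
    dup = v.duplicated(subset=["subject_id", "visit_id"])
    if dup.any():
        raise SchemaError(f"duplicate (subject_id, visit_id) at rows {list(v.index[dup])}")
    if not v["gender"].isin(GENDERS).all():
        bad = v.loc[~v["gender"].isin(GENDERS)].index[0]
        raise SchemaError(f"visits row {bad}: gender must be one of {GENDERS}")
    if not v["diagnosis"].isin(DIAGNOSES).all():
        bad = v.loc[~v["diagnosis"].isin(DIAGNOSES)].index[0]
        raise SchemaError(f"visits row {bad}: diagnosis must be one of {DIAGNOSES}")
    if ((v["pain_vas"] < 0) | (v["pain_vas"] > 10)).any():
        raise SchemaError("pain_vas must be in [0, 10]")
    for sub, grp in v.groupby("subject_id"):
        if not grp["day"].is_monotonic_increasing:
            raise SchemaError(f"visit days not non-decreasing for subject {sub!r}")
    if "sample_id" not in v.columns:
        v["sample_id"] = [sample_id(s, vi) for s, vi in zip(v["subject_id"], v["visit_id"])]
    return v


def validate_followup(followup: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FOLLOWUP_COLUMNS if c not in followup.columns]
    if missing:
        raise SchemaError(f"followup table missing columns: {missing}")
    f = followup.copy()
    f["ed_pain_event_days"] = f["ed_pain_event_days"].apply(_parse_event_days)
    if (f["last_note_day"] < 0).any():
        raise SchemaError("last_note_day must be >= 0")
    for i, days in f["ed_pain_event_days"].items():
        if any(d < 0 for d in days):
            raise SchemaError(f"followup row {i}: negative event day")
        if list(days) != sorted(days):
            raise SchemaError(f"followup row {i}: event days must be sorted ascending")
    return f


def _parse_event_days(value) -> list:
    if isinstance(value, (list, tuple)):
        return list(value)
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return [float(x) for x in str(value).split(";") if x != ""]


def validate_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise SchemaError(f"evidence table missing columns: {missing}")
    if not evidence["category"].isin(EVIDENCE_CATEGORIES).all():
        bad = evidence.loc[~evidence["category"].isin(EVIDENCE_CATEGORIES)].index[0]
        raise SchemaError(f"evidence row {bad}: unknown category")
    if (evidence["citation_tag"].astype(str).str.len() == 0).any():
        raise SchemaError("citation_tag must be non-empty")
    return evidence.copy()


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probeset_id"
    return df


def read_tables(
    visits_path,
    expression_path=None,
    calls_path=None,
    followup_path=None,
    evidence_path=None,
) -> dict:
    """Load and cross-validate the pipeline input tables.

    Returns a dict with keys ``visits`` and, when the corresponding path was
    given, ``bundle``, ``followup`` and ``evidence``.  Raises
    :class:`SchemaError` naming the offending file/row/column on any
    violation, including expression samples with no matching visit row.
    """
    out: dict = {}
    visits = validate_visits(pd.read_csv(visits_path, sep="\t"))
    out["visits"] = visits
    logger.info("read %d visit rows over %d subjects from %s",
                len(visits), visits["subject_id"].nunique(), visits_path)
    if expression_path is not None:
        if calls_path is None:
            raise SchemaError("expression matrix requires a matching calls matrix")
        intensity = _read_matrix(expression_path)
        calls = _read_matrix(calls_path)
        bundle = ExpressionBundle(intensity, calls)
        orphans = set(bundle.sample_ids) - set(visits["sample_id"])
        if orphans:
            raise SchemaError(
                f"expression samples with no visit row: {sorted(orphans)[:5]}"
            )
        out["bundle"] = bundle
        logger.info("read %d probesets x %d samples", *bundle.intensity.shape)
    if followup_path is not None:
        out["followup"] = validate_followup(pd.read_csv(followup_path, sep="\t"))
    if evidence_path is not None:
        out["evidence"] = validate_evidence(pd.read_csv(evidence_path, sep="\t"))
    return out


def write_followup(followup: pd.DataFrame, path) -> None:
    f = followup.copy()
    f["ed_pain_event_days"] = f["ed_pain_event_days"].apply(
        lambda days: ";".join(f"{d:g}" for d in days)
    )
    f.to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """End-to-end run configuration; every knob of the pipeline in one place."""

    visits: str
    expression: str
    calls: str
    followup: str | None = None
    evidence: str | None = None
    probe_gene_map: str | None = None
    out_dir: str = "painmarkers_out"
    fold_threshold: float = 1.2
    cfg_weights: Mapping[str, float] | None = None
    bonferroni_n: str = "auto"  # "auto" or "fixed:<k>"
    alpha: float = 0.05
    strata: Sequence[str] = ("all", "gender", "gender_dx")
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def bonferroni_denominator(self, n_auto: int) -> int:
        if self.bonferroni_n == "auto":
            return n_auto
        if self.bonferroni_n.startswith("fixed:"):
            return int(self.bonferroni_n.split(":", 1)[1])
        raise ValueError(f"bonferroni_n policy {self.bonferroni_n!r} not understood")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run discovery -> prioritization -> validation -> testing -> CFE.

    Persists every stage table under ``config.out_dir`` plus a
    ``run_report.json`` with per-stage counts; re-running with identical
    config and inputs is byte-identical.  Returns the in-memory tables.
    """
    from painmarkers.model import BiomarkerStudy

    tables = read_tables(
        config.visits, config.expression, config.calls,
        followup_path=config.followup, evidence_path=config.evidence,
    )
    probe_gene_map = None
    if config.probe_gene_map is not None:
        pg = pd.read_csv(config.probe_gene_map, sep="\t")
        probe_gene_map = dict(zip(pg["probeset_id"], pg["gene_symbol"]))

    study = BiomarkerStudy(
        tables["visits"],
        tables["bundle"],
        followup=tables.get("followup"),
        evidence=tables.get("evidence"),
        probe_gene_map=probe_gene_map,
        fold_threshold=config.fold_threshold,
        cfg_weights=config.cfg_weights,
        alpha=config.alpha,
        bonferroni_n=config.bonferroni_n,
    )
    res = study.fit()

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "discovery.tsv": res.discovery_,
        "cfg.tsv": res.cfg_,
        "validation.tsv": res.validation_,
        "predictions.tsv": res.predictions_,
        "cfe.tsv": res.cfe_,
    }
    for name, df in artifacts.items():
        if df is not None:
            df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6g")

    report = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "python": platform.python_version(),
        "n_subjects": int(tables["visits"]["subject_id"].nunique()),
        "n_samples": int(len(tables["visits"])),
        "n_probesets": int(len(tables["bundle"].probeset_ids)),
        "stage_counts": {
            name: (0 if df is None else int(len(df))) for name, df in artifacts.items()
        },
    }
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", report["stage_counts"])
    return {"results": res, "report": report}
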