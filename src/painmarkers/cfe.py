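"""Steps 5-6 bookkeeping — Convergent Functional Evidence (CFE) tabulation.

Each biomarker's evidence across the pipeline is tabulated into one score:
discovery (up to 6), CFG prioritization (up to 12), validation (up to 6),
and three testing outcomes (state, first-year trait, all-years trait; up to
8 points each: 8 if it significantly predicts in all subjects, 6 at the
gender level, 4 at the gender-by-diagnosis level).  The maximum is 48, of
which 36 come from the study's own data and 12 from literature — a
deliberate 3:1 weighting of empirical over literature evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MAX_TOTAL = 48.0
MAX_INTERNAL_SUBTOTAL = 36.0
MAX_LITERATURE_SUBTOTAL = 12.0

#: CFE points by the best stratum level at which a marker predicts an outcome
TESTING_POINTS = {"all": 8, "gender": 6, "gender_dx": 4}

_DISCRETE_STEPS = (0, 2, 4, 6)
_TESTING_STEPS = (0, 4, 6, 8)


@dataclass(frozen=True)
class StepScores:
    """Per-biomarker points from each pipeline step feeding the CFE total."""

    probeset_id: str
    discovery_points: int
    cfg_points: float
    validation_points: int
    state_points: int
    trait_year1_points: int
    trait_all_points: int

    def __post_init__(self):
        if self.discovery_points not in _DISCRETE_STEPS:
            raise ValueError(f"discovery_points must be one of {_DISCRETE_STEPS}")
        if not 0 <= self.cfg_points <= MAX_LITERATURE_SUBTOTAL:
            raise ValueError("cfg_points must be in [0, 12]")
        if self.validation_points not in _DISCRETE_STEPS:
            raise ValueError(f"validation_points must be one of {_DISCRETE_STEPS}")
        for f in ("state_points", "trait_year1_points", "trait_all_points"):
            if getattr(self, f) not in _TESTING_STEPS:
                raise ValueError(f"{f} must be one of {_TESTING_STEPS}")


@dataclass(frozen=True)
class CFEReport:
    probeset_id: str
    steps: StepScores
    total: float
    internal_subtotal: float     # everything except literature CFG
    literature_subtotal: float


def testing_points(results: pd.DataFrame, alpha: float = 0.05) -> int:
    """CFE points for one marker and one outcome from its prediction rows.

    8 if any significant all-subjects row, else 6 for any significant gender
    row, else 4 for any significant gender-by-diagnosis row, else 0.
    Cross-sectional and longitudinal rows both qualify.
    """
    if len(results) == 0:
        return 0
    sig = results[results["significant"].astype(bool) & (results["p"] < alpha)]
    for klass in ("all", "gender", "gender_dx"):
        if (sig["stratum_class"] == klass).any():
            return TESTING_POINTS[klass]
    return 0


def cfe_total(steps: StepScores) -> CFEReport:
    """Tabulate one biomarker's CFE report from its per-step points."""
    total = (
        steps.discovery_points + steps.cfg_points + steps.validation_points
        + steps.state_points + steps.trait_year1_points + steps.trait_all_points
    )
    return CFEReport(
        probeset_id=steps.probeset_id,
        steps=steps,
        total=float(total),
        internal_subtotal=float(total - steps.cfg_points),
        literature_subtotal=float(steps.cfg_points),
    )


def rank_biomarkers(reports) -> pd.DataFrame:
    """Rank CFE reports: descending total, ties by internal subtotal, then ID."""
    if len(reports) == 0:
        raise ValueError("at least one report is required")
    rows = []
    for r in reports:
        s = r.steps
        rows.append({
            "probeset_id": r.probeset_id,
            "discovery_points": s.discovery_points,
            "cfg_points": s.cfg_points,
            "validation_points": s.validation_points,
            "state_points": s.state_points,
            "trait_year1_points": s.trait_year1_points,
            "trait_all_points": s.trait_all_points,
            "internal_subtotal": r.internal_subtotal,
            "literature_subtotal": r.literature_subtotal,
            "total": r.total,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["total", "internal_subtotal", "probeset_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def cfe_table(
    discovery: pd.DataFrame,
    cfg: pd.DataFrame,
    validation: pd.DataFrame,
    predictions: pd.DataFrame,
    markers: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble and rank CFE reports from the four stage tables.

    Discovery points per probeset are the maximum internal score across the
    AP and DE rows; validation points likewise the best row per probeset.
    """
    if markers is None:
        markers = list(predictions["marker"].unique())
    disc = discovery.groupby("probeset_id")["points"].max()
    ext = cfg.set_index("probeset_id")["external_points"]
    val = (
        validation.groupby("probeset_id")["points"].max()
        if len(validation) else pd.Series(dtype=int)
    )
    outcome_field = {
        "state_high_pain": "state_points",
        "trait_ed_year1": "trait_year1_points",
        "trait_ed_all": "trait_all_points",
    }
    reports = []
    for m in markers:
        kwargs = {
            "probeset_id": m,
            "discovery_points": int(disc.get(m, 0)),
            "cfg_points": float(ext.get(m, 0.0)),
            "validation_points": int(val.get(m, 0)),
        }
        for outcome, field_name in outcome_field.items():
            rows = predictions[
                (predictions["marker"] == m) & (predictions["outcome"] == outcome)
            ]
            kwargs[field_name] = testing_points(rows, alpha=alpha)
        reports.append(cfe_total(StepScores(**kwargs)))
    return rank_biomarkers(reports)
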