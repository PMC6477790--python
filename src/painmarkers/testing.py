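"""Step 4 — independent-cohort state and trait prediction.

Markers (single probesets or panels) are evaluated against three outcomes:

* **state**: is a testing visit a High-Pain visit (VAS >= 6)?
* **trait, first year**: any emergency-department (ED) pain visit within
  365 days of the subject's index visit;
* **trait, all years**: any future ED pain visit over the whole follow-up.

Marker values are z-scored by gender and diagnosis, oriented so that higher
always means higher risk (increased markers as-is, decreased markers
negated; panels sum increased-marker z minus decreased-marker z), and run
cross-sectionally (one value per visit) and longitudinally (a composite of
last level, maximum level, last slope and maximum slope over a subject's
visit series).  Metrics: ROC AUC with a one-sided Mann-Whitney p, one-tailed
Welch t-test, one-tailed Pearson correlation, Cox proportional-hazards
regression (censored at 365 days or the last clinical note), and a logistic
odds ratio per z unit.  Hazard and odds ratios are reported on the oriented
score, so a value > 1 always reads as increased risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

YEAR_DAYS = 365.0

OUTCOMES = ("state_high_pain", "trait_ed_year1", "trait_ed_all")
MODES = ("cross_sectional", "longitudinal")

#: permissive floor guarding degenerate fits in small strata
MIN_CASES = 2
MIN_CONTROLS = 2

_LONG_FEATURES = ("last_level", "max_level", "last_slope", "max_slope")


def orient(z, direction: str):
    """Risk-orient a marker's z values: I as-is, D negated."""
    if direction == "I":
        return z
    if direction == "D":
        return -z
    raise ValueError(f"direction must be 'I' or 'D', got {direction!r}")


def risk_oriented_score(z: pd.DataFrame, directions: Mapping[str, str]) -> pd.Series:
    """Panel composite: sum of increased-marker z minus decreased-marker z.

    ``z`` is samples x markers.  Samples missing any member marker are
    dropped (NaN) and the drop count logged.
    """
    missing = [m for m in directions if m not in z.columns]
    if missing:
        raise ValueError(f"markers absent from z table: {missing}")
    oriented = pd.DataFrame(
        {m: orient(z[m], d) for m, d in directions.items()}, index=z.index
    )
    score = oriented.sum(axis=1, skipna=False)
    n_dropped = int(score.isna().sum())
    if n_dropped:
        logger.info("risk_oriented_score: %d samples dropped for missing markers", n_dropped)
    return score


def longitudinal_features(days: Sequence[float], z: Sequence[float]) -> dict:
    """Per-subject longitudinal summary of a marker's z series.

    Returns last level, maximum level, slope into the most recent visit and
    maximum between-visit slope (z units per day); single-visit subjects get
    zero slopes.  Days must be strictly increasing.
    """
    days = np.asarray(days, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(days) != len(z) or len(days) == 0:
        raise ValueError("days and z must be equal-length, non-empty")
    if len(days) > 1 and not (np.diff(days) > 0).all():
        raise ValueError("visit days must be strictly increasing")
    if len(days) == 1:
        slopes = np.array([0.0])
    else:
        slopes = np.diff(z) / np.diff(days)
    return {
        "last_level": float(z[-1]),
        "max_level": float(np.max(z)),
        "last_slope": float(slopes[-1]),
        "max_slope": float(np.max(slopes)),
    }


def longitudinal_composite(features: pd.DataFrame) -> pd.Series:
    """Equal-weight composite of the four longitudinal features.

    Each feature column is z-scored across subjects first (constant columns
    contribute 0), then averaged.
    """
    parts = []
    for col in _LONG_FEATURES:
        x = features[col].astype(float)
        sd = x.std(ddof=1)
        parts.append((x - x.mean()) / sd if sd > 0 else pd.Series(0.0, index=x.index))
    return sum(parts) / len(parts)


def roc_auc(scores, case_labels) -> tuple[float, float]:
    """ROC AUC and one-sided p (cases score higher), rank-based.

    The AUC is the Mann-Whitney U statistic scaled by n_case * n_control
    with ties counted half; the p-value uses the tie-corrected normal
    approximation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(case_labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs at least one case and one control")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    p = stats.mannwhitneyu(
        scores[labels], scores[~labels], alternative="greater", method="asymptotic"
    ).pvalue
    return float(auc), float(p)


def state_tests(scores: pd.Series, high_labels: pd.Series, pain_vas: pd.Series) -> dict:
    """State-prediction statistics for one marker in one stratum.

    ROC AUC with one-sided p, one-tailed Welch t-test (High Pain vs rest),
    and one-tailed Pearson correlation with the pain VAS.
    """
    keep = scores.notna()
    s = scores[keep].to_numpy(dtype=float)
    y = high_labels[keep].to_numpy(dtype=bool)
    vas = pain_vas[keep].to_numpy(dtype=float)
    auc, auc_p = roc_auc(s, y)
    t_p = float(stats.ttest_ind(s[y], s[~y], equal_var=False, alternative="greater").pvalue)
    r, r_p = stats.pearsonr(s, vas, alternative="greater")
    return {
        "auc": auc, "p": auc_p, "t_p": t_p,
        "pearson_r": float(r), "pearson_p": float(r_p),
        "n_cases": int(y.sum()), "n_total": int(len(y)),
    }


def _followup_frame(scores: pd.Series, followup: pd.DataFrame) -> pd.DataFrame:
    fu = followup.set_index("subject_id")
    df = pd.DataFrame({"score": scores}).join(fu, how="inner")
    df = df[df["last_note_day"] > 0]
    if df.empty:
        raise ValueError("no subjects with positive follow-up")
    df["first_event"] = df["ed_pain_event_days"].apply(
        lambda d: float(d[0]) if len(d) else np.inf
    )
    df["n_events"] = df["ed_pain_event_days"].apply(len)
    return df.dropna(subset=["score"])


def _cox_hr(durations, events, score) -> tuple[float, float]:
    """Cox HR per score unit and one-sided p (risk direction)."""
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"T": durations, "E": events, "score": score})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    beta = float(cph.params_["score"])
    p2 = float(cph.summary.loc["score", "p"])
    p1 = p2 / 2 if beta > 0 else 1 - p2 / 2
    return float(np.exp(beta)), p1


def trait_year1(scores: pd.Series, followup: pd.DataFrame) -> dict:
    """First-year trait prediction from index-visit marker scores.

    Case: any ED pain visit within 365 days of the index visit.  Reports
    ROC/t/Pearson statistics (Pearson against the ED visit frequency,
    events per year of follow-up) plus a Cox hazard ratio with censoring at
    365 days.  Subjects with zero follow-up are excluded.
    """
    df = _followup_frame(scores, followup)
    case = df["first_event"] <= YEAR_DAYS
    auc, auc_p = roc_auc(df["score"], case)
    t_p = float(stats.ttest_ind(
        df.loc[case, "score"], df.loc[~case, "score"],
        equal_var=False, alternative="greater",
    ).pvalue)
    freq = df["n_events"] / df["last_note_day"] * YEAR_DAYS
    r, r_p = stats.pearsonr(df["score"], freq, alternative="greater")
    durations = np.minimum(df["first_event"], YEAR_DAYS)
    hr, cox_p = _cox_hr(durations, case.to_numpy(), df["score"].to_numpy())
    return {
        "auc": auc, "p": auc_p, "t_p": t_p,
        "pearson_r": float(r), "pearson_p": float(r_p),
        "hazard_ratio": hr, "cox_p": cox_p,
        "n_cases": int(case.sum()), "n_total": int(len(df)),
    }


def trait_all_years(scores: pd.Series, followup: pd.DataFrame) -> dict:
    """All-years trait prediction: logistic odds ratio and full-follow-up Cox.

    Case: any future ED pain visit.  The odds ratio is per z unit of the
    oriented marker from a logistic regression (one-sided p); the Cox model
    censors non-cases at the last clinical note, accounting for the varying
    follow-up length.
    """
    import statsmodels.api as sm

    df = _followup_frame(scores, followup)
    case = (df["n_events"] > 0).to_numpy()
    if case.all() or not case.any():
        raise ValueError("degenerate outcome: all or no subjects are cases")
    x = sm.add_constant(df["score"].to_numpy())
    fit = sm.Logit(case.astype(float), x).fit(disp=0)
    beta = float(fit.params[1])
    p2 = float(fit.pvalues[1])
    p1 = p2 / 2 if beta > 0 else 1 - p2 / 2
    durations = np.where(case, df["first_event"], df["last_note_day"])
    hr, cox_p = _cox_hr(durations, case, df["score"].to_numpy())
    return {
        "odds_ratio": float(np.exp(beta)), "p": p1,
        "hazard_ratio": hr, "cox_p": cox_p,
        "n_cases": int(case.sum()), "n_total": int(len(df)),
    }


# ---------------------------------------------------------------------------
# stratified driver

def strata_plan(visits: pd.DataFrame, levels: Sequence[str] = ("all", "gender", "gender_dx")):
    """Yield (stratum name, stratum class, visit mask) per the analysis plan.

    Gender-by-diagnosis strata include the pooled PSYCHOSIS group
    (schizophrenia and schizoaffective combined).
    """
    if "all" in levels:
        yield "all", "all", pd.Series(True, index=visits.index)
    if "gender" in levels:
        for g in ("M", "F"):
            yield g, "gender", visits["gender"] == g
    if "gender_dx" in levels:
        dx_groups = {dx: [dx] for dx in visits["diagnosis"].unique()}
        dx_groups["PSYCHOSIS"] = ["SZ", "SZA"]
        for g in ("M", "F"):
            for name, members in sorted(dx_groups.items()):
                mask = (visits["gender"] == g) & visits["diagnosis"].isin(members)
                yield f"{g}-{name}", "gender_dx", mask


@dataclass(frozen=True)
class MarkerPredictor:
    """One evaluable predictor: a probeset (or panel) with known direction(s)."""

    marker_id: str
    directions: Mapping[str, str]  # member probeset -> "I"/"D"


def _marker_scores(z: pd.DataFrame, predictor: MarkerPredictor) -> pd.Series:
    if len(predictor.directions) == 1:
        ((pid, d),) = predictor.directions.items()
        return orient(z[pid], d)
    return risk_oriented_score(z, predictor.directions)


def _subject_composite(scores: pd.Series, visits: pd.DataFrame) -> pd.Series:
    """Longitudinal composite per subject from per-visit oriented scores."""
    v = visits.set_index("sample_id")
    feats = {}
    for sub, grp in v.groupby("subject_id", sort=True):
        grp = grp.sort_values("day")
        s = scores.reindex(grp.index).dropna()
        if s.empty:
            continue
        d = grp.loc[s.index, "day"].astype(float)
        d = d + np.arange(len(d)) * 1e-9  # guard exact same-day duplicates
        feats[sub] = longitudinal_features(d.to_numpy(), s.to_numpy())
    fdf = pd.DataFrame.from_dict(feats, orient="index")
    return longitudinal_composite(fdf)


def stratified_run(
    predictors: Sequence[MarkerPredictor],
    z: pd.DataFrame,
    visits: pd.DataFrame,
    followup: pd.DataFrame | None = None,
    outcomes: Sequence[str] = OUTCOMES,
    modes: Sequence[str] = MODES,
    strata: Sequence[str] = ("all", "gender", "gender_dx"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate every marker x outcome x stratum x mode combination.

    ``z`` is samples x probesets of stratified z-scores for the test cohort.
    Trait outcomes need ``followup``; they are evaluated at each subject's
    index visit (cross-sectional) or over the visit series (longitudinal).
    Strata with fewer than 2 cases or 2 controls are emitted as skipped rows
    with a reason, never silently dropped.
    """
    v = visits.set_index("sample_id")
    high = v["pain_vas"] >= 6
    index_visit = visits.groupby("subject_id", sort=True).tail(1).set_index("subject_id")

    rows = []
    for pred in predictors:
        per_visit = _marker_scores(z, pred)
        per_subject_cs = pd.Series(
            per_visit.reindex(index_visit["sample_id"]).to_numpy(),
            index=index_visit.index,
        )
        per_subject_long = _subject_composite(per_visit, visits)
        for outcome in outcomes:
            for name, klass, mask in strata_plan(visits, strata):
                sub_visits = visits[mask]
                sub_subjects = sub_visits["subject_id"].unique()
                for mode in modes:
                    row = {
                        "marker": pred.marker_id, "outcome": outcome,
                        "stratum": name, "stratum_class": klass, "mode": mode,
                        "metric": "", "value": np.nan, "p": np.nan,
                        "n_cases": 0, "n_total": 0,
                        "significant": False, "skip_reason": "",
                    }
                    try:
                        with warnings.catch_warnings():
                            # tiny strata routinely trip separation /
                            # convergence warnings; results stay reported
                            warnings.simplefilter("ignore")
                            row_update = _evaluate_cell(
                                outcome, mode, sub_visits, sub_subjects,
                                per_visit, per_subject_cs, per_subject_long,
                                high, v, index_visit, followup,
                            )
                        row.update(row_update)
                        row["significant"] = bool(row["p"] < alpha)
                    except (_Skip, ValueError) as e:
                        row["skip_reason"] = str(e)
                    except Exception as e:  # degenerate fits in tiny strata
                        row["skip_reason"] = f"fit failed: {e}"
                    rows.append(row)
    return pd.DataFrame(rows)


def _evaluate_cell(outcome, mode, sub_visits, sub_subjects, per_visit,
                   per_subject_cs, per_subject_long, high, v, index_visit,
                   followup) -> dict:
    if outcome == "state_high_pain":
        if mode == "cross_sectional":
            samples = sub_visits["sample_id"]
            s = per_visit.reindex(samples).dropna()
            y = high.reindex(s.index)
            _check_counts(y)
            res = state_tests(s, y, v.loc[s.index, "pain_vas"])
        else:
            s = per_subject_long.reindex(sub_subjects).dropna()
            y = index_visit.loc[s.index, "pain_vas"] >= 6
            _check_counts(y)
            res = state_tests(s, y, index_visit.loc[s.index, "pain_vas"])
        return dict(metric="auc", value=res["auc"], p=res["p"],
                    n_cases=res["n_cases"], n_total=res["n_total"])
    if followup is None:
        raise _Skip("no follow-up table")
    s = per_subject_cs if mode == "cross_sectional" else per_subject_long
    s = s.reindex(sub_subjects).dropna()
    if s.empty:
        raise _Skip("no scored subjects")
    if outcome == "trait_ed_year1":
        res = trait_year1(s, followup)
        _check_counts_n(res["n_cases"], res["n_total"])
        return dict(metric="auc", value=res["auc"], p=res["p"],
                    n_cases=res["n_cases"], n_total=res["n_total"])
    res = trait_all_years(s, followup)
    _check_counts_n(res["n_cases"], res["n_total"])
    return dict(metric="odds_ratio", value=res["odds_ratio"], p=res["p"],
                n_cases=res["n_cases"], n_total=res["n_total"])


class _Skip(Exception):
    pass


def _check_counts(labels: pd.Series):
    n1 = int(pd.Series(labels).sum())
    n0 = int(len(labels) - n1)
    _check_counts_n(n1, n1 + n0)


def _check_counts_n(n_cases: int, n_total: int):
    if n_cases < MIN_CASES or (n_total - n_cases) < MIN_CONTROLS:
        raise _Skip(
            f"stratum below minimum size ({n_cases} cases / {n_total - n_cases} controls)"
        )
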