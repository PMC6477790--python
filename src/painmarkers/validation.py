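"""Step 3 — validation against clinically severe pain.

Candidate biomarkers are tested for a stepwise change in expression across
three groups — Low Pain, High Pain (without severe clinical pain), and
Clinically Severe Pain (VAS >= 6 with SF-36 items 21 + 22 summing to 10 or
more) — after z-scoring within gender-by-diagnosis strata.  Strata in which
a probeset shows no variance (or a single sample) are excluded rather than
zeroed.  A probeset is *stepwise* when its three group means are strictly
ordered in its discovery direction; stepwise probesets get a one-way ANOVA
p-value and score 2 (stepwise only), 4 (nominally significant) or
6 (Bonferroni-significant over the number of biomarkers tested) points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from painmarkers.discovery import AP_ENCODING, label_pain_state

VALIDATION_GROUPS = ("Low", "High", "Severe")


def delog(log2_value):
    """Linear intensity from a log2 expression value: 2**x."""
    return np.power(2.0, log2_value)


def clinically_severe(visits: pd.DataFrame) -> pd.Series:
    """Clinically-severe-pain flag per visit: VAS >= 6 and SF-36 21+22 >= 10.

    Missing SF-36 items make a visit non-severe (with a warning).
    """
    sf_sum = visits["sf36_21"] + visits["sf36_22"]
    if sf_sum.isna().any():
        warnings.warn(
            f"{int(sf_sum.isna().sum())} visits missing SF-36 items; treated as not severe"
        )
    return (visits["pain_vas"] >= 6) & (sf_sum >= 10)


def assign_validation_group(visits: pd.DataFrame) -> pd.Series:
    """Per-visit validation group: Low / High (non-severe) / Severe / NaN."""
    severe = clinically_severe(visits)
    state = visits["pain_vas"].map(label_pain_state)
    group = pd.Series(pd.NA, index=visits.index, dtype="object")
    group[state == "Low"] = "Low"
    group[(state == "High") & ~severe] = "High"
    group[severe] = "Severe"
    return group


def zscore_by_stratum(values: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Z-score each probeset within each stratum of samples.

    ``values`` is probesets x samples; ``strata`` maps each sample (column)
    to its stratum key (e.g. a gender-diagnosis tuple).  Within a stratum,
    z = (x - mean) / sd with sample sd (ddof=1).  Zero-variance and
    single-sample strata yield missing values (NaN), never zeros.
    """
    if not set(values.columns) <= set(strata.index):
        missing = set(values.columns) - set(strata.index)
        raise ValueError(f"samples without stratum assignment: {sorted(missing)[:5]}")
    z = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    for key, cols in strata.groupby(strata).groups.items():
        cols = [c for c in cols if c in values.columns]
        if not cols:
            continue
        sub = values[cols].astype(float)
        if len(cols) < 2:
            warnings.warn(f"stratum {key!r} has a single sample; excluded from z-scoring")
            continue
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        zi = sub.sub(mu, axis=0).div(sd, axis=0)
        zi[sd == 0] = np.nan  # zero-variance rule: exclude, do not zero
        z[cols] = zi
    return z


def zscore_series(values: pd.Series, strata: pd.Series) -> pd.Series:
    """Stratified z-scoring of a single per-sample series."""
    return zscore_by_stratum(values.to_frame().T, strata).iloc[0]


@dataclass(frozen=True)
class ValidationOutcome:
    probeset_id: str
    group_means: tuple          # (Low, High, Severe) in z units
    stepwise: bool
    anova_p: float
    bonferroni_sig: bool
    points: int                 # 0 / 2 / 4 / 6
    testable: bool = True


def stepwise_anova(
    z: pd.Series,
    group: pd.Series,
    direction: str,
    n_tests: int = 1,
    alpha: float = 0.05,
    probeset_id: str = "",
) -> ValidationOutcome:
    """Stepwise-change test with one-way ANOVA over Low/High/Severe.

    ``z`` holds the stratified z-scores per sample, ``group`` the validation
    group per sample, ``direction`` the probeset's discovery direction
    ("I": expect Low < High < Severe; "D": the reverse, strictly).
    Bonferroni significance uses ``alpha / n_tests``.
    """
    if direction not in ("I", "D"):
        raise ValueError(f"direction must be 'I' or 'D', got {direction!r}")
    vals = {
        g: z[group[group == g].index.intersection(z.index)].dropna()
        for g in VALIDATION_GROUPS
    }
    if any(len(v) == 0 for v in vals.values()):
        return ValidationOutcome(
            probeset_id, (np.nan, np.nan, np.nan), False, np.nan, False, 0, testable=False
        )
    means = tuple(float(vals[g].mean()) for g in VALIDATION_GROUPS)
    if direction == "I":
        stepwise = means[0] < means[1] < means[2]
    else:
        stepwise = means[0] > means[1] > means[2]
    anova_p = float(stats.f_oneway(*(vals[g] for g in VALIDATION_GROUPS)).pvalue)
    bonf = bool(anova_p < alpha / n_tests)
    if stepwise and bonf:
        points = 6
    elif stepwise and anova_p < alpha:
        points = 4
    elif stepwise:
        points = 2
    else:
        points = 0
    return ValidationOutcome(probeset_id, means, stepwise, anova_p, bonf, points)


def validation_table(
    bundle,
    visits: pd.DataFrame,
    candidates: pd.DataFrame,
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Validate candidate probesets over a cohort containing all three groups.

    ``candidates`` needs columns probeset_id, method and direction (the
    discovery rows to validate, one per probeset/method).  DE rows are
    scored on stratum-z-scored linear intensities; AP rows on the 0/0.5/1
    call encoding, z-scored the same way.  ``n_tests`` defaults to the
    number of candidate rows (the Bonferroni denominator).
    """
    v = visits.set_index("sample_id")
    group = assign_validation_group(v.reset_index()).set_axis(v.index)
    strata = pd.Series(
        list(zip(v["gender"], v["diagnosis"])), index=v.index
    )
    in_group = group.notna()
    cols = v.index[in_group]

    z_de = zscore_by_stratum(bundle.intensity[cols], strata[cols])
    ap_numeric = bundle.calls[cols].apply(lambda s: s.map(AP_ENCODING))
    z_ap = zscore_by_stratum(ap_numeric, strata[cols])

    if n_tests is None:
        n_tests = len(candidates)
    rows = []
    for _, cand in candidates.iterrows():
        pid, method, direction = cand["probeset_id"], cand["method"], cand["direction"]
        z = (z_de if method == "DE" else z_ap).loc[pid]
        out = stepwise_anova(
            z, group[cols], direction, n_tests=n_tests, alpha=alpha, probeset_id=pid
        )
        rows.append({
            "probeset_id": pid,
            "method": method,
            "direction": direction,
            "mean_low": out.group_means[0],
            "mean_high": out.group_means[1],
            "mean_severe": out.group_means[2],
            "stepwise": out.stepwise,
            "anova_p": out.anova_p,
            "bonferroni_sig": out.bonferroni_sig,
            "points": out.points,
            "testable": out.testable,
        })
    return pd.DataFrame(rows)
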