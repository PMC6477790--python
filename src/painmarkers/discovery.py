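"""Step 1 — within-subject longitudinal discovery scoring.

For every subject with at least one diametric pain change, all within-subject
(Low Pain, High Pain) visit pairs are enumerated and each probeset is scored
for concordant change across those comparisons, by two methods:

* **AP** (Absent/Present): a comparison is concordant-increased if the
  detection call switches A (Low visit) -> P (High visit), concordant-
  decreased for P -> A; Marginal calls never count as a switch.
* **DE** (differential expression): concordant-increased if the linear
  intensity ratio High/Low meets the fold threshold, concordant-decreased
  if it falls below its reciprocal.

The winning direction's concordant fraction maps onto the 0/2/4/6-point
internal score: >= 1/3 -> 2, >= 50% -> 4, >= 80% -> 6 points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOW_VAS_MAX = 2
HIGH_VAS_MIN = 6

AP_ENCODING = {"A": 0.0, "M": 0.5, "P": 1.0}

_EPS = 1e-12
# (minimum winning-direction concordant fraction, internal points)
POINT_THRESHOLDS = ((0.80, 6), (0.50, 4), (1.0 / 3.0, 2))

TOP_FRACTION = 0.90  # discovery long-list cutoff on the concordant fraction


def label_pain_state(pain_vas) -> str:
    """Map a 0-10 pain VAS onto {Low, Intermediate, High} (Low <= 2, High >= 6)."""
    v = float(pain_vas)
    if not 0 <= v <= 10:
        raise ValueError(f"pain VAS must be in [0, 10], got {pain_vas}")
    if v <= LOW_VAS_MAX:
        return "Low"
    if v >= HIGH_VAS_MIN:
        return "High"
    return "Intermediate"


def encode_ap(call: str) -> float:
    """Numeric encoding of a detection call: A -> 0, M -> 0.5, P -> 1."""
    try:
        return AP_ENCODING[call]
    except KeyError:
        raise ValueError(f"unknown detection call {call!r}") from None


def enumerate_comparisons(visits: pd.DataFrame) -> pd.DataFrame:
    """All within-subject (Low, High) visit pairs, both temporal orders.

    Subjects lacking either state contribute no comparisons.  Returns a frame
    with subject_id, low/high visit ids and low/high sample ids.
    """
    v = visits.copy()
    v["state"] = v["pain_vas"].map(label_pain_state)
    out = []
    for sub, grp in v.groupby("subject_id", sort=True):
        lows = grp[grp["state"] == "Low"]
        highs = grp[grp["state"] == "High"]
        for _, lo in lows.iterrows():
            for _, hi in highs.iterrows():
                out.append({
                    "subject_id": sub,
                    "low_visit_id": lo["visit_id"],
                    "high_visit_id": hi["visit_id"],
                    "low_sample_id": lo["sample_id"],
                    "high_sample_id": hi["sample_id"],
                })
    return pd.DataFrame(
        out,
        columns=["subject_id", "low_visit_id", "high_visit_id",
                 "low_sample_id", "high_sample_id"],
    )


@dataclass(frozen=True)
class DiscoveryScore:
    probeset_id: str
    method: str                  # "AP" or "DE"
    direction: str | None        # "I", "D", or None on a tie
    concordance_fraction: float
    internal_points: int
    n_comparisons: int


def points_from_fraction(fraction: float) -> int:
    for cutoff, pts in POINT_THRESHOLDS:
        if fraction >= cutoff - _EPS:
            return pts
    return 0


def _concordance_counts(comparisons, intensity, calls, method, fold_threshold):
    """Per-probeset counts of concordant-increased / -decreased comparisons."""
    lo_cols = comparisons["low_sample_id"].to_numpy()
    hi_cols = comparisons["high_sample_id"].to_numpy()
    if method == "DE":
        lo = intensity[lo_cols].to_numpy(dtype=float)
        hi = intensity[hi_cols].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = hi / lo
        # zero Low with nonzero High: ratio -> inf, concordant-increased;
        # both zero: no change in either direction
        conc_i = (ratio >= fold_threshold) | ((lo == 0) & (hi > 0))
        conc_d = (ratio <= 1.0 / fold_threshold) & (lo > 0)
    elif method == "AP":
        lo = calls[lo_cols].to_numpy()
        hi = calls[hi_cols].to_numpy()
        conc_i = (lo == "A") & (hi == "P")
        conc_d = (lo == "P") & (hi == "A")
    else:
        raise ValueError(f"method must be 'AP' or 'DE', got {method!r}")
    return conc_i.sum(axis=1), conc_d.sum(axis=1)


def score_probeset(
    probeset_id: str,
    comparisons: pd.DataFrame,
    bundle,
    method: str,
    fold_threshold: float = 1.2,
) -> DiscoveryScore:
    """Score one probeset over the given within-subject comparisons.

    The direction (I = increased in High Pain, D = decreased) is the one with
    the larger concordant count; ties score 0 points with no direction.
    """
    if len(comparisons) == 0:
        raise ValueError("at least one comparison is required")
    n_i, n_d = _concordance_counts(
        comparisons,
        bundle.intensity.loc[[probeset_id]],
        bundle.calls.loc[[probeset_id]],
        method,
        fold_threshold,
    )
    return _summarize(probeset_id, method, int(n_i[0]), int(n_d[0]), len(comparisons))


def _summarize(probeset_id, method, n_i, n_d, n) -> DiscoveryScore:
    if n_i == n_d:
        frac = n_i / n
        return DiscoveryScore(probeset_id, method, None, frac, 0, n)
    direction = "I" if n_i > n_d else "D"
    frac = max(n_i, n_d) / n
    return DiscoveryScore(probeset_id, method, direction, frac, points_from_fraction(frac), n)


def discovery_table(
    bundle,
    visits: pd.DataFrame,
    fold_threshold: float = 1.2,
    top_fraction: float = TOP_FRACTION,
) -> pd.DataFrame:
    """Score every probeset by both methods over all within-subject comparisons.

    Returns one row per (probeset, method) with direction, concordant
    fraction, internal points, and the discovery long-list flag
    (``top_flag``: directed and fraction >= ``top_fraction``).
    """
    comparisons = enumerate_comparisons(visits)
    if len(comparisons) == 0:
        raise ValueError("no within-subject Low/High comparisons in this cohort")
    frames = []
    n = len(comparisons)
    for method in ("AP", "DE"):
        n_i, n_d = _concordance_counts(
            comparisons, bundle.intensity, bundle.calls, method, fold_threshold
        )
        tie = n_i == n_d
        direction = np.where(tie, "", np.where(n_i > n_d, "I", "D"))
        frac = np.maximum(n_i, n_d) / n
        points = np.where(tie, 0, [points_from_fraction(f) for f in frac])
        frames.append(pd.DataFrame({
            "probeset_id": bundle.probeset_ids,
            "method": method,
            "direction": direction,
            "fraction": frac,
            "points": points.astype(int),
            "n_comparisons": n,
            "top_flag": (~tie) & (frac >= top_fraction - _EPS),
        }))
    return pd.concat(frames, ignore_index=True)
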