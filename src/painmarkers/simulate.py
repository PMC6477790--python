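"""Synthetic longitudinal cohorts with planted pain biomarkers.

The generator emulates the statistical structure the analysis assumes: each
discovery-eligible subject shows at least one diametric pain change (a
Low-Pain visit, VAS 0-2, and a High-Pain visit, VAS 6-10); planted
"algogenes" rise in expression with pain state and planted pain-suppressor
genes fall; Absent/Marginal/Present detection calls follow intensity; and
future emergency-department (ED) pain visits arrive as a Poisson process
whose rate is tilted by the planted trait markers.

Intensities are log2-normal: log2 values are drawn around a probeset
baseline with Gaussian noise and exponentiated to the linear scale, matching
the microarray convention the downstream 2**x de-log step assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from painmarkers.io import (
    DIAGNOSES,
    EVIDENCE_CATEGORIES,
    ExpressionBundle,
    sample_id,
)

# Pain-state multipliers on the planted expression shift.  Clinically severe
# visits carry a larger shift than plain High-Pain so that planted markers
# show the Low < High < Severe stepwise gradient validation looks for.
_STATE_LEVEL = {"Low": 0.0, "Intermediate": 0.5, "High": 1.0, "Severe": 1.5}

#: Literature-evidence category sizes of the curated pain databases
#: (human genetic; human nervous tissue; human peripheral tissue/fluids;
#: non-human genetic; non-human nervous tissue; non-human peripheral).
EVIDENCE_CATEGORY_COUNTS: Mapping[str, int] = {
    "human_genetic": 212,
    "human_nervous": 3,
    "human_peripheral": 57,
    "nonhuman_genetic": 26,
    "nonhuman_nervous": 48,
    "nonhuman_peripheral": 9,
}


def _default_diagnosis_weights() -> dict:
    # Roughly the test-cohort diagnostic mix: mood and psychotic disorders
    # dominate, PTSD and unspecified categories are minorities.
    return {
        "BP": 0.25, "MDD": 0.20, "SZ": 0.20, "SZA": 0.20,
        "PTSD": 0.09, "PSYCH": 0.03, "MOOD": 0.03,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-cohort world.

    Defaults mirror the study design: ~1/3 female subjects, 2-5 visits per
    subject, a mean follow-up horizon of about 5.6 years, and a baseline ED
    pain-visit rate giving roughly a 35% first-year event fraction.
    """

    n_subjects: int = 50
    visits_min: int = 2
    visits_max: int = 5
    p_female: float = 0.32
    diagnosis_weights: Mapping[str, float] = field(default_factory=_default_diagnosis_weights)
    n_probesets: int = 1000
    n_algogenes: int = 20
    n_suppressors: int = 20
    effect_size: float = 1.5        # standardized (z-unit) High-vs-Low shift
    noise_sd: float = 0.5           # log2-intensity units
    baseline_log2: float = 7.0      # location of null intensities
    trait_hazard_beta: float = 0.5  # log-hazard per z of the planted composite
    base_ed_rate: float = 0.0012    # ED pain visits per day at z = 0
    followup_days: int = 2030
    p_intermediate: float = 0.0     # chance extra visits are Intermediate
    p_severe_given_high: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects, self.n_probesets) <= 0:
            raise ValueError("counts must be positive")
        if self.n_algogenes < 0 or self.n_suppressors < 0:
            raise ValueError("planted marker counts must be >= 0")
        if self.n_algogenes + self.n_suppressors > self.n_probesets:
            raise ValueError("planted markers exceed n_probesets")
        if not 0 <= self.p_female <= 1 or not 0 <= self.p_intermediate <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.p_severe_given_high <= 1:
            raise ValueError("p_severe_given_high must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.visits_min < 2:
            raise ValueError(
                "visits_min < 2 admits subjects without a diametric pain change"
            )
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max must be >= visits_min")
        if not math.isclose(sum(self.diagnosis_weights.values()), 1.0, abs_tol=1e-9):
            raise ValueError("diagnosis_weights must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


class SyntheticCohort(NamedTuple):
    visits: pd.DataFrame
    bundle: ExpressionBundle
    followup: pd.DataFrame
    truth: pd.DataFrame


def _draw_states(n_visits: int, rng: np.random.Generator, p_intermediate: float) -> list:
    """Visit state sequence with a guaranteed Low and High visit."""
    first_two = ["Low", "High"] if rng.random() < 0.5 else ["High", "Low"]
    states = list(first_two)
    for _ in range(n_visits - 2):
        if rng.random() < p_intermediate:
            states.append("Intermediate")
        else:
            states.append("Low" if rng.random() < 0.5 else "High")
    rng.shuffle(states)
    return states


def _draw_vas(state: str, rng: np.random.Generator) -> int:
    if state == "Low":
        return int(rng.integers(0, 3))
    if state == "High":
        return int(rng.integers(6, 11))
    return int(rng.integers(3, 6))


def _draw_sf36(state: str, severe: bool, rng: np.random.Generator) -> tuple:
    # item 21 in 1-6, item 22 in 1-5; severe requires the sum >= 10
    if state == "High" and severe:
        i21 = int(rng.integers(5, 7))
        i22 = max(10 - i21, int(rng.integers(4, 6)))
        return i21, min(i22, 5)
    if state == "High":
        return int(rng.integers(3, 5)), int(rng.integers(2, 5))  # sum <= 8
    if state == "Intermediate":
        return int(rng.integers(2, 4)), int(rng.integers(2, 4))
    return int(rng.integers(1, 3)), int(rng.integers(1, 3))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one synthetic cohort under ``config``.

    Returns visit phenotypes, the paired intensity/call matrices, per-subject
    ED follow-up records, and the planted-marker truth table
    (``probeset_id``, ``role`` in {algogene, suppressor, null},
    ``direction`` in {I, D, ``""``}).  Identical configs (including seed)
    produce identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    width = max(4, len(str(config.n_subjects)))
    rows = []
    for i in range(config.n_subjects):
        sub = f"S{i + 1:0{width}d}"
        gender = "F" if rng.random() < config.p_female else "M"
        dx = str(rng.choice(list(config.diagnosis_weights),
                            p=list(config.diagnosis_weights.values())))
        n_visits = int(rng.integers(config.visits_min, config.visits_max + 1))
        states = _draw_states(n_visits, rng, config.p_intermediate)
        day = 0
        for v, state in enumerate(states, start=1):
            severe = state == "High" and rng.random() < config.p_severe_given_high
            i21, i22 = _draw_sf36(state, severe, rng)
            rows.append({
                "subject_id": sub, "visit_id": f"V{v}", "day": day,
                "gender": gender, "diagnosis": dx,
                "pain_vas": _draw_vas(state, rng),
                "sf36_21": i21, "sf36_22": i22,
                "_state": state if not severe else "Severe",
            })
            day += int(rng.integers(20, 120))
    visits = pd.DataFrame(rows)
    visits["sample_id"] = [sample_id(s, v) for s, v in zip(visits["subject_id"], visits["visit_id"])]

    bundle, truth, log2 = _expression_for(visits["_state"], visits["sample_id"], config, rng)

    # --- follow-up --------------------------------------------------------
    # Hazard is tilted by the risk-oriented composite of planted markers at
    # each subject's index (last) visit, z-scored across subjects.
    idx_rows = visits.groupby("subject_id", sort=True).tail(1)
    orient = np.where(truth["direction"] == "I", 1.0,
                      np.where(truth["direction"] == "D", -1.0, 0.0))
    planted = orient != 0
    if planted.any():
        vals = log2[np.ix_(planted, visits.index.get_indexer(idx_rows.index))]
        comp = (orient[planted][:, None] * vals).sum(axis=0)
        sd = comp.std(ddof=1) if len(comp) > 1 else 0.0
        z = (comp - comp.mean()) / sd if sd > 0 else np.zeros_like(comp)
    else:
        z = np.zeros(len(idx_rows))

    fu_rows = []
    for (_, row), zi in zip(idx_rows.iterrows(), z):
        last_note = int(rng.integers(365, config.followup_days + 1))
        rate = config.base_ed_rate * math.exp(config.trait_hazard_beta * zi)
        n_ev = rng.poisson(rate * last_note)
        events = sorted(float(round(d, 1)) for d in rng.uniform(1, last_note, size=n_ev))
        fu_rows.append({
            "subject_id": row["subject_id"],
            "index_visit_day": int(row["day"]),
            "ed_pain_event_days": events,
            "last_note_day": last_note,
        })
    followup = pd.DataFrame(fu_rows)

    visits = visits.drop(columns="_state")
    return SyntheticCohort(visits, bundle, followup, truth)


def _expression_for(states, sample_ids, config: SimConfig, rng) -> tuple:
    """Intensity/call matrices with planted markers for given visit states."""
    n_p = config.n_probesets
    pw = max(5, len(str(n_p)))
    probesets = pd.Index([f"PS{j + 1:0{pw}d}" for j in range(n_p)], name="probeset_id")
    roles = np.array(["null"] * n_p, dtype=object)
    roles[: config.n_algogenes] = "algogene"
    roles[config.n_algogenes: config.n_algogenes + config.n_suppressors] = "suppressor"
    rng.shuffle(roles)
    orient = np.where(roles == "algogene", 1.0, np.where(roles == "suppressor", -1.0, 0.0))

    base = rng.uniform(config.baseline_log2 - 3.0, config.baseline_log2 + 3.0, size=n_p)
    # planted markers sit in the Marginal band so state shifts can flip calls
    base[orient != 0] = config.baseline_log2 - 0.5

    level = pd.Series(states).map(_STATE_LEVEL).to_numpy()
    shift = config.effect_size * config.noise_sd
    log2 = (
        base[:, None]
        + orient[:, None] * shift * level[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n_p, len(level)))
    )
    intensity = pd.DataFrame(2.0 ** log2, index=probesets, columns=np.asarray(sample_ids))
    calls_arr = np.where(
        log2 < config.baseline_log2 - 1.0, "A",
        np.where(log2 > config.baseline_log2, "P", "M"),
    )
    calls = pd.DataFrame(calls_arr, index=probesets, columns=intensity.columns)
    truth = pd.DataFrame({
        "probeset_id": probesets,
        "role": roles,
        "direction": np.where(orient > 0, "I", np.where(orient < 0, "D", "")),
    })
    return ExpressionBundle(intensity, calls), truth, log2


def expression_for(visits: pd.DataFrame, config: SimConfig) -> tuple:
    """Synthesize an expression bundle for an existing visit table.

    Visit states are derived from the phenotypes (pain VAS cutoffs plus the
    clinically-severe rule), so planted markers track the recorded pain
    states.  Returns ``(ExpressionBundle, truth table)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    severe = (visits["pain_vas"] >= 6) & (visits["sf36_21"] + visits["sf36_22"] >= 10)
    state = pd.Series(
        np.where(visits["pain_vas"] <= 2, "Low",
                 np.where(visits["pain_vas"] >= 6,
                          np.where(severe, "Severe", "High"), "Intermediate")),
        index=visits.index,
    )
    sample_ids = visits["sample_id"] if "sample_id" in visits.columns else [
        sample_id(s, v) for s, v in zip(visits["subject_id"], visits["visit_id"])
    ]
    bundle, truth, _ = _expression_for(state, sample_ids, config, rng)
    return bundle, truth


# Deterministic design cohort: visit counts of the 28-subject longitudinal
# discovery design (3 subjects x 5 visits, 1 x 4, 12 x 3, 12 x 2 = 79 visits,
# 19 male / 9 female), each subject alternating Low and High Pain.
_DESIGN_VISIT_COUNTS = (5, 5, 5, 4) + (3,) * 12 + (2,) * 12


def reference_cohort() -> pd.DataFrame:
    """The canonical 28-subject / 79-visit within-subject discovery design.

    Every subject alternates diametrically between Low Pain (VAS 1) and High
    Pain (VAS 7) visits 60 days apart, so each has at least one diametric
    pain change.  Deterministic; no expression attached.
    """
    rows = []
    for i, n_visits in enumerate(_DESIGN_VISIT_COUNTS):
        sub = f"S{i + 1:04d}"
        gender = "F" if i % 3 == 1 else "M"  # 9 of 28 female
        dx = DIAGNOSES[i % len(DIAGNOSES)]
        for v in range(1, n_visits + 1):
            high = (v + i) % 2 == 0
            rows.append({
                "subject_id": sub, "visit_id": f"V{v}", "day": (v - 1) * 60,
                "gender": gender, "diagnosis": dx,
                "pain_vas": 7 if high else 1,
                "sf36_21": 5 if high else 1, "sf36_22": 4 if high else 1,
            })
    visits = pd.DataFrame(rows)
    visits["sample_id"] = [sample_id(s, v) for s, v in zip(visits["subject_id"], visits["visit_id"])]
    return visits


def reference_evidence(
    category_counts: Mapping[str, int] | None = None,
    n_genes: int = 120,
) -> pd.DataFrame:
    """Literature-evidence table matching the curated pain-database census.

    One row per paper, 355 rows total by default, distributed round-robin
    over ``n_genes`` synthetic gene symbols.  Pass an empty mapping to get
    the no-evidence variant (every gene scores an external 0).
    """
    counts = EVIDENCE_CATEGORY_COUNTS if category_counts is None else category_counts
    genes = [f"SYNG{j + 1:04d}" for j in range(n_genes)]
    rows = []
    k = 0
    for cat in EVIDENCE_CATEGORIES:
        for i in range(int(counts.get(cat, 0))):
            rows.append({
                "gene_symbol": genes[k % n_genes],
                "category": cat,
                "citation_tag": f"{cat}_{i + 1}",
            })
            k += 1
    return pd.DataFrame(rows, columns=["gene_symbol", "category", "citation_tag"])
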