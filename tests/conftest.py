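import numpy as np
import pandas as pd
import pytest

from painmarkers import SimConfig, generate_cohort
from painmarkers.io import ExpressionBundle, sample_id


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-marker cohort shared across read-only tests."""
    config = SimConfig(
        n_subjects=30, n_probesets=200, n_algogenes=15, n_suppressors=15,
        effect_size=2.0, p_severe_given_high=0.4, seed=11,
    )
    return generate_cohort(config)


def make_visits(rows):
    """Visit table from (subject, visit, day, vas) tuples with default phenotypes."""
    df = pd.DataFrame(rows, columns=["subject_id", "visit_id", "day", "pain_vas"])
    df["gender"] = "M"
    df["diagnosis"] = "MDD"
    df["sf36_21"] = 3
    df["sf36_22"] = 3
    df["sample_id"] = [sample_id(s, v) for s, v in zip(df["subject_id"], df["visit_id"])]
    return df


def make_bundle(intensity: dict, calls: dict | None = None) -> ExpressionBundle:
    """Bundle from {probeset: {sample: value}} dicts; calls default to P."""
    inten = pd.DataFrame(intensity).T
    inten.index.name = "probeset_id"
    if calls is None:
        calls_df = pd.DataFrame("P", index=inten.index, columns=inten.columns)
    else:
        calls_df = pd.DataFrame(calls).T
        calls_df.index.name = "probeset_id"
    return ExpressionBundle(inten.astype(float), calls_df)


def one_low_many_high(n_high: int, high_ratios):
    """One subject with a single Low visit (intensity 1) and n_high High visits.

    Yields exactly n_high within-subject comparisons whose DE ratios are
    ``high_ratios``; handy for dialling an exact concordant fraction.
    """
    rows = [("S1", "V0", 0, 1)]
    rows += [("S1", f"V{i + 1}", (i + 1) * 10, 7) for i in range(n_high)]
    visits = make_visits(rows)
    values = {"S1_V0": 1.0}
    values.update({f"S1_V{i + 1}": float(r) for i, r in enumerate(high_ratios)})
    bundle = make_bundle({"PS1": values})
    return visits, bundle


@pytest.fixture
def rng():
    return np.random.default_rng(42)
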