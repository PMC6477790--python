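"""Step 2 — Convergent Functional Genomics (CFG) prioritization.

Prior literature evidence for a gene's involvement in pain is tallied over
six categories (human/non-human x genetic / nervous tissue / peripheral
tissue-fluids).  Each category with at least one record contributes a fixed
weight (default 2 points, six categories, cap 12); multiplicity within a
category adds nothing.  The external score plus the 0-6 internal discovery
score gives the combined score (max 18); genes with combined >= 6 — an
empirical cutoff of 33.3% of the maximum external score, which deliberately
admits novel genes carrying maximal internal evidence and none external —
are carried into validation.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from painmarkers.io import EVIDENCE_CATEGORIES, validate_evidence

#: Uniform per-category weights; 6 x 2 reproduces the 12-point external cap.
DEFAULT_WEIGHTS: Mapping[str, float] = {c: 2.0 for c in EVIDENCE_CATEGORIES}

MAX_EXTERNAL = 12.0
MAX_INTERNAL = 6.0
CARRY_FORWARD_MIN = 6.0   # combined-score cutoff into validation
LONG_LIST_EXTERNAL_MIN = 8.0  # prioritization long-list cutoff (external score)


def external_score(
    gene_symbol: str,
    evidence: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    cap: float = MAX_EXTERNAL,
) -> float:
    """External CFG points for one gene: per-category weight, capped.

    A gene absent from the evidence table scores 0; duplicate records within
    a category do not add points.
    """
    weights = DEFAULT_WEIGHTS if weights is None else weights
    recs = evidence[evidence["gene_symbol"] == gene_symbol]
    cats = set(recs["category"])
    return min(cap, sum(weights.get(c, 0.0) for c in cats))


def combine(internal_points: float, external_points: float) -> tuple[float, bool]:
    """Combined 0-18 score and the carry-into-validation flag (>= 6)."""
    if not 0 <= internal_points <= MAX_INTERNAL:
        raise ValueError(f"internal points must be in [0, {MAX_INTERNAL:g}]")
    if not 0 <= external_points <= MAX_EXTERNAL:
        raise ValueError(f"external points must be in [0, {MAX_EXTERNAL:g}]")
    total = internal_points + external_points
    return total, total >= CARRY_FORWARD_MIN


def cfg_table(
    discovery: pd.DataFrame,
    evidence: pd.DataFrame,
    probe_gene_map: Mapping[str, str] | None = None,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-probeset CFG scoring table.

    The internal score is each probeset's best (max) points across the AP
    and DE discovery rows; external scores attach to gene symbols and
    propagate to every probeset mapped to that gene.  With no map, probeset
    IDs are used as gene symbols directly.
    """
    evidence = validate_evidence(evidence)
    internal = (
        discovery.groupby("probeset_id", sort=True)["points"].max().rename("internal_points")
    )
    genes = {
        p: (probe_gene_map or {}).get(p, p) for p in internal.index
    }
    ext_cache: dict[str, float] = {}
    rows = []
    for probeset, ipts in internal.items():
        g = genes[probeset]
        if g not in ext_cache:
            ext_cache[g] = external_score(g, evidence, weights)
        total, flag = combine(float(ipts), ext_cache[g])
        rows.append({
            "probeset_id": probeset,
            "gene_symbol": g,
            "internal_points": float(ipts),
            "external_points": ext_cache[g],
            "combined": total,
            "carry_forward": flag,
        })
    return pd.DataFrame(rows)


def assemble_long_list(
    discovery_top: Iterable[str],
    cfg_top: Iterable[str],
    validated_nominal: Iterable[str],
) -> list[str]:
    """Candidate long list: union of the three step-wise top sets.

    Order is stable — discovery picks first, then prioritization additions,
    then validation additions — with duplicates dropped on first occurrence.
    """
    out: list[str] = []
    seen: set[str] = set()
    for group in (discovery_top, cfg_top, validated_nominal):
        for item in group:
            if item not in seen:
                seen.add(item)
                out.append(item)
    return out
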