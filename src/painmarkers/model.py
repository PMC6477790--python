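"""Top-level model/results surface over the six-step pipeline.

``BiomarkerStudy`` is built from a cohort (visit phenotypes plus paired
expression/call matrices, optionally follow-up records, a literature
evidence table and a probeset-to-gene map); ``fit()`` runs discovery,
CFG prioritization, validation, independent-cohort testing and CFE
tabulation, and returns a ``BiomarkerStudyResults`` carrying every stage
table and a ``summary()`` report of the top-ranked biomarkers.

When no separate test cohort is supplied the study cohort doubles as the
test cohort, which is only meaningful for synthetic or exploratory data —
the design intends an independent cohort for Step 4.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from painmarkers import cfe as cfe_mod
from painmarkers import cfg as cfg_mod
from painmarkers import discovery as disc_mod
from painmarkers import testing as test_mod
from painmarkers import validation as val_mod
from painmarkers.io import ExpressionBundle, validate_evidence, validate_followup, validate_visits

logger = logging.getLogger(__name__)


class BiomarkerStudy:
    """Six-step blood-biomarker study over a longitudinal cohort.

    Parameters
    ----------
    visits, bundle
        Discovery/validation cohort phenotypes and expression.
    followup
        Per-subject ED pain-visit follow-up records (trait outcomes).
    evidence
        Literature evidence table for CFG scoring; omitted -> external 0.
    probe_gene_map
        probeset_id -> gene_symbol; omitted -> probeset IDs used as genes.
    test_visits, test_bundle, test_followup
        Independent testing cohort; defaults to the study cohort.
    """

    def __init__(
        self,
        visits: pd.DataFrame,
        bundle: ExpressionBundle,
        followup: pd.DataFrame | None = None,
        evidence: pd.DataFrame | None = None,
        probe_gene_map: Mapping[str, str] | None = None,
        test_visits: pd.DataFrame | None = None,
        test_bundle: ExpressionBundle | None = None,
        test_followup: pd.DataFrame | None = None,
        fold_threshold: float = 1.2,
        cfg_weights: Mapping[str, float] | None = None,
        alpha: float = 0.05,
        bonferroni_n: str = "auto",
        strata: Sequence[str] = ("all", "gender", "gender_dx"),
        modes: Sequence[str] = test_mod.MODES,
    ):
        self.visits = validate_visits(visits)
        self.bundle = bundle
        self.followup = None if followup is None else validate_followup(followup)
        self.evidence = (
            pd.DataFrame(columns=["gene_symbol", "category", "citation_tag"])
            if evidence is None else validate_evidence(evidence)
        )
        self.probe_gene_map = probe_gene_map
        self.test_visits = self.visits if test_visits is None else validate_visits(test_visits)
        self.test_bundle = bundle if test_bundle is None else test_bundle
        self.test_followup = (
            self.followup if test_followup is None else validate_followup(test_followup)
        )
        self.fold_threshold = fold_threshold
        self.cfg_weights = cfg_weights
        self.alpha = alpha
        self.bonferroni_n = bonferroni_n
        self.strata = tuple(strata)
        self.modes = tuple(modes)

    @classmethod
    def from_tables(
        cls,
        visits_path,
        expression_path,
        calls_path,
        followup_path=None,
        evidence_path=None,
        **kwargs,
    ) -> "BiomarkerStudy":
        from painmarkers.io import read_tables

        t = read_tables(visits_path, expression_path, calls_path,
                        followup_path=followup_path, evidence_path=evidence_path)
        return cls(t["visits"], t["bundle"], followup=t.get("followup"),
                   evidence=t.get("evidence"), **kwargs)

    def fit(self) -> "BiomarkerStudyResults":
        """Run all pipeline stages and return the results object."""
        discovery = disc_mod.discovery_table(
            self.bundle, self.visits, fold_threshold=self.fold_threshold
        )
        logger.info("discovery: %d probesets scored", discovery["probeset_id"].nunique())

        cfg = cfg_mod.cfg_table(
            discovery, self.evidence, probe_gene_map=self.probe_gene_map,
            weights=self.cfg_weights,
        )

        # validation candidates: combined score >= 6, best directed row per
        # probeset/method carried forward
        carried = set(cfg.loc[cfg["carry_forward"], "probeset_id"])
        cand = discovery[
            discovery["probeset_id"].isin(carried) & (discovery["direction"] != "")
            & (discovery["points"] > 0)
        ][["probeset_id", "method", "direction"]].reset_index(drop=True)
        if self.bonferroni_n == "auto":
            n_tests = max(len(cand), 1)
        else:
            n_tests = int(self.bonferroni_n.split(":", 1)[1])
        validation = (
            val_mod.validation_table(
                self.bundle, self.visits, cand, n_tests=n_tests, alpha=self.alpha
            )
            if len(cand)
            else pd.DataFrame(columns=["probeset_id", "method", "direction", "points",
                                       "stepwise", "anova_p", "bonferroni_sig", "testable"])
        )

        # long list: discovery top set, CFG external >= 8, validated nominal
        disc_top = (
            discovery[discovery["top_flag"]]
            .sort_values(["fraction", "probeset_id"], ascending=[False, True])
            ["probeset_id"].drop_duplicates().tolist()
        )
        cfg_top = (
            cfg[cfg["external_points"] >= cfg_mod.LONG_LIST_EXTERNAL_MIN]
            .sort_values(["external_points", "probeset_id"], ascending=[False, True])
            ["probeset_id"].drop_duplicates().tolist()
        )
        val_nominal = (
            validation[validation["stepwise"] & (validation["anova_p"] < self.alpha)]
            ["probeset_id"].drop_duplicates().tolist()
            if len(validation) else []
        )
        long_list = cfg_mod.assemble_long_list(disc_top, cfg_top, val_nominal)
        logger.info("long list: %d probesets (%d discovery, %d CFG, %d validation)",
                    len(long_list), len(disc_top), len(cfg_top), len(val_nominal))

        # testing: direction per marker = best-scoring directed discovery row
        directed = discovery[discovery["direction"] != ""]
        best_dir = (
            directed.sort_values(["points", "fraction"], ascending=False)
            .drop_duplicates("probeset_id")
            .set_index("probeset_id")["direction"]
        )
        markers = [m for m in long_list if m in best_dir.index]
        predictors = [
            test_mod.MarkerPredictor(m, {m: best_dir[m]}) for m in markers
        ]
        if len(markers) > 1:
            predictors.append(test_mod.MarkerPredictor(
                "PANEL_LONG", {m: best_dir[m] for m in markers}
            ))
        short_list = [m for m in val_nominal if m in best_dir.index]
        if len(short_list) > 1:
            predictors.append(test_mod.MarkerPredictor(
                "PANEL_VALIDATED", {m: best_dir[m] for m in short_list}
            ))

        if predictors:
            tv = self.test_visits.set_index("sample_id")
            strata_key = pd.Series(
                list(zip(tv["gender"], tv["diagnosis"])), index=tv.index
            )
            z = val_mod.zscore_by_stratum(
                self.test_bundle.intensity, strata_key
            ).T  # samples x probesets
            predictions = test_mod.stratified_run(
                predictors, z, self.test_visits, followup=self.test_followup,
                modes=self.modes, strata=self.strata, alpha=self.alpha,
            )
        else:
            predictions = pd.DataFrame(
                columns=["marker", "outcome", "stratum", "stratum_class", "mode",
                         "metric", "value", "p", "n_cases", "n_total",
                         "significant", "skip_reason"]
            )

        cfe = (
            cfe_mod.cfe_table(discovery, cfg, validation, predictions, markers=markers,
                              alpha=self.alpha)
            if markers else pd.DataFrame()
        )

        return BiomarkerStudyResults(
            model=self,
            discovery_=discovery,
            cfg_=cfg,
            validation_=validation,
            predictions_=predictions,
            cfe_=cfe,
            long_list_=long_list,
            short_list_=val_nominal,
        )


class BiomarkerStudyResults:
    """Fitted pipeline results: one table per stage plus the ranked CFE."""

    def __init__(self, model, discovery_, cfg_, validation_, predictions_, cfe_,
                 long_list_, short_list_):
        self.model = model
        self.discovery_ = discovery_
        self.cfg_ = cfg_
        self.validation_ = validation_
        self.predictions_ = predictions_
        self.cfe_ = cfe_
        self.long_list_ = long_list_
        self.short_list_ = short_list_

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the top-ranked biomarkers."""
        lines = [
            "Blood biomarker study for pain — convergent evidence summary",
            "=" * 62,
            f"Subjects: {self.model.visits['subject_id'].nunique()}   "
            f"Visits: {len(self.model.visits)}   "
            f"Probesets: {len(self.model.bundle.probeset_ids)}",
            f"Discovery rows: {len(self.discovery_)}   "
            f"Carried to validation: {int(self.cfg_['carry_forward'].sum())}   "
            f"Long list: {len(self.long_list_)}   "
            f"Validated (nominal): {len(self.short_list_)}",
            "",
        ]
        if len(self.cfe_):
            lines.append(f"Top {min(top, len(self.cfe_))} biomarkers by CFE score (max 48):")
            cols = ["rank", "probeset_id", "discovery_points", "cfg_points",
                    "validation_points", "state_points", "trait_year1_points",
                    "trait_all_points", "total"]
            lines.append(self.cfe_[cols].head(top).to_string(index=False))
        else:
            lines.append("No biomarkers reached the testing step.")
        return "\n".join(lines)

    def __repr__(self):
        n = len(self.cfe_) if self.cfe_ is not None else 0
        return f"<BiomarkerStudyResults: {n} biomarkers tabulated>"
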