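"""Kinome-wide screening of kinase-inhibition / adverse-event associations.

One survival forest is fitted per customized AE term on the time to first
onset of that term; permutation VIMP and minimal depth rank every predictor
(kinase-inhibition features plus demographic covariates).  A large VIMP — the
increase in out-of-bag prediction error when the predictor is permuted —
marks a strong kinase-AE association, as does a small minimal depth.

``stratify_km`` reproduces the median-split visualization: patients are split
at the median of one kinase's inhibition feature, the forest-predicted
ensemble survival curves are averaged pointwise within each stratum, and a
95% pointwise normal-approximation band is attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AnalysisDataset
from .forest import ForestConfig, SurvivalForest, fit_forest

logger = logging.getLogger(__name__)

__all__ = ["VIMPTable", "StratifiedCurves", "screen_ae", "screen_all", "stratify_km"]


@dataclass
class VIMPTable:
    """Per-AE predictor ranking by permutation importance and minimal depth."""

    ae_term: str
    table: pd.DataFrame  # predictor, vimp, minimal_depth, rank
    n_events: int
    fitted: bool = True
    forest: SurvivalForest | None = field(default=None, repr=False)

    def top(self, k: int = 25) -> pd.DataFrame:
        return self.table.head(k)


@dataclass
class StratifiedCurves:
    """Median-split mean ensemble survival curves with pointwise 95% bands."""

    kinase: str
    ae_term: str
    curves: pd.DataFrame  # time, stratum, mean_S, lower, upper
    stratum_sizes: dict[str, int]
    median: float


def screen_ae(
    dataset: AnalysisDataset,
    ae_term: str,
    forest_config: ForestConfig | None = None,
    top_k: int = 25,
    seed: int = 0,
    vimp_repeats: int = 1,
    strict: bool = True,
) -> VIMPTable:
    """Fit one forest on time-to-this-AE and rank all predictors.

    Ranks are by VIMP descending (ties broken by predictor order, so the
    output is stable under re-runs with the same seed).  Terms with zero
    events are skipped with a logged warning and returned flagged unfitted.
    """
    if ae_term not in dataset.ae_terms and strict:
        raise KeyError(f"AE term {ae_term!r} not present in dataset")
    outcome = dataset.outcome(ae_term)
    n_events = int(outcome["event"].sum())
    if n_events == 0:
        logger.warning("AE term %r has zero events; skipping fit", ae_term)
        empty = pd.DataFrame(
            columns=["ae_term", "predictor", "vimp", "minimal_depth", "rank"]
        )
        return VIMPTable(ae_term=ae_term, table=empty, n_events=0, fitted=False)
    forest = fit_forest(
        dataset.features,
        outcome["time_days"].to_numpy(),
        outcome["event"].to_numpy(),
        config=forest_config,
        seed=seed,
    )
    vimp = forest.permutation_vimp_all(repeats=vimp_repeats)
    mdepth = forest.minimal_depth_all()
    table = pd.DataFrame(
        {
            "ae_term": ae_term,
            "predictor": dataset.predictors,
            "vimp": vimp,
            "minimal_depth": mdepth,
        }
    )
    table = table.sort_values(
        ["vimp", "predictor"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return VIMPTable(
        ae_term=ae_term, table=table, n_events=n_events, fitted=True, forest=forest
    )


def screen_all(
    dataset: AnalysisDataset,
    ae_terms: list[str] | None = None,
    forest_config: ForestConfig | None = None,
    top_k: int = 25,
    seed: int = 0,
) -> tuple[dict[str, VIMPTable], dict]:
    """Screen every AE term; returns per-term tables and a run summary.

    The summary reports the total number of evaluated kinase-AE pairs,
    n_kinases x n_ae_terms, counting every term (terms without events are
    still evaluated — their table is flagged "not fitted").
    """
    terms = ae_terms if ae_terms is not None else dataset.ae_terms
    ss = np.random.SeedSequence(seed)
    tables: dict[str, VIMPTable] = {}
    for term, child in zip(terms, ss.spawn(len(terms))):
        term_seed = int(np.random.default_rng(child).integers(0, 2**31 - 1))
        tables[term] = screen_ae(
            dataset,
            term,
            forest_config=forest_config,
            top_k=top_k,
            seed=term_seed,
            strict=False,  # terms without any recorded event are flagged, not errors
        )
    summary = {
        "n_kinases": len(dataset.kinases),
        "n_ae_terms": len(terms),
        "n_pairs_evaluated": len(dataset.kinases) * len(terms),
        "n_terms_fitted": sum(t.fitted for t in tables.values()),
        "n_terms_skipped": sum(not t.fitted for t in tables.values()),
    }
    return tables, summary


def stratify_km(
    dataset: AnalysisDataset,
    forest: SurvivalForest,
    kinase: str,
    ae_term: str,
    ci_z: float = 1.96,
) -> StratifiedCurves:
    """Median-split stratified mean ensemble survival curves.

    Patients above the median of the kinase feature form the "higher
    inhibition" stratum, the rest (ties included) the "lower inhibition"
    stratum.  Each stratum's curve is the pointwise mean of the forest's
    per-patient ensemble survival functions, with mean +/- 1.96 SE bands
    pooled across the stratum's patients.
    """
    if kinase not in dataset.features.columns:
        raise KeyError(f"kinase {kinase!r} is not a feature")
    x = dataset.features[kinase].to_numpy(dtype=float)
    med = float(np.median(x))
    higher = x > med
    if not higher.any() or higher.all():
        raise ValueError(
            f"feature {kinase!r} cannot be median-split (constant or degenerate)"
        )
    surv = forest.predict_survival(dataset.features)
    rows = []
    sizes = {}
    for label, mask in (("higher inhibition", higher), ("lower inhibition", ~higher)):
        s = surv[mask]
        mean = s.mean(axis=0)
        se = s.std(axis=0, ddof=1) / np.sqrt(mask.sum()) if mask.sum() > 1 else np.zeros_like(mean)
        sizes[label] = int(mask.sum())
        for t, m, e in zip(forest.grid, mean, se):
            rows.append((float(t), label, float(m), float(m - ci_z * e), float(m + ci_z * e)))
    curves = pd.DataFrame(rows, columns=["time", "stratum", "mean_S", "lower", "upper"])
    return StratifiedCurves(
        kinase=kinase,
        ae_term=ae_term,
        curves=curves,
        stratum_sizes=sizes,
        median=med,
    )
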