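"""Performance evaluation: concordance, cross-validation, external validation,
and reporting-odds-ratio disproportionality.

Harrell's C-index is the fraction of censoring-permissible patient pairs whose
predicted risk ordering agrees with the observed event-time ordering; 0.5 is
random, 1.0 perfect.  A pair (i, j) is permissible when the earlier time is an
event (ties in time are permissible only when exactly one of the two is an
event); ties in risk score count 1/2.

Two cross-validation protocols mirror the time-to-adverse-event study design:

* ``bootstrap_cv`` — repeated 80/20 splits drawn WITHOUT replacement, one
  forest per iteration, C-index on the held-out 20%; the summary is the mean
  and the empirical central 90% interval of the C distribution.
* ``loo_cv`` — leave-one-out: n forests, held-out risk scores pooled into a
  single C over all patients.

External validation applies trained per-AE forests to an independent cohort,
converts survival at a horizon into a predicted AE probability, and compares
predicted vs observed incidence at a threshold (default 10%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forest import ForestConfig, SurvivalForest, fit_forest

logger = logging.getLogger(__name__)

__all__ = [
    "harrell_c",
    "bootstrap_cv",
    "draw_cv_split",
    "loo_cv",
    "external_validate",
    "summarize_validation",
    "null_concordance_simulation",
    "ror",
    "CVResult",
    "ExternalValidationReport",
    "ContingencyCounts",
    "RORResult",
]


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------


def harrell_c(times, events, risk_scores) -> float:
    """Harrell's censoring-aware concordance index.

    Concordant = higher risk score on the member of the pair that fails
    earlier; ties in risk contribute 1/2.  Raises when no permissible pair
    exists (e.g. fully censored data).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risk_scores, dtype=float)
    if not (t.shape == e.shape == r.shape):
        raise ValueError("times, events and risk_scores must have equal length")
    # pairwise, vectorized: permissible (i, j) with i the earlier event
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    ej = e[None, :]
    permissible = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    ri, rj = r[:, None], r[None, :]
    concordant = permissible & (ri > rj)
    tied = permissible & (ri == rj)
    n_perm = int(permissible.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs: concordance undefined")
    return (int(concordant.sum()) + 0.5 * int(tied.sum())) / n_perm


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Bootstrap cross-validation C-index distribution for one AE term."""

    ae_term: str
    c_values: np.ndarray
    seeds: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.c_values))

    @property
    def interval90(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.c_values, [5.0, 95.0])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.interval90
        return {
            "ae_term": self.ae_term,
            "n_iterations": int(self.c_values.size),
            "c_mean": self.mean,
            "c_p05": lo,
            "c_p95": hi,
        }


def draw_cv_split(
    rng: np.random.Generator,
    n: int,
    n_train: int,
    events: np.ndarray,
    max_redraws: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a disjoint, covering train/test split without replacement,
    redrawing (logged) until both sides contain at least one event."""
    for _ in range(max_redraws):
        train = rng.choice(n, size=n_train, replace=False)
        test = np.setdiff1d(np.arange(n), train)
        if events[train].sum() > 0 and events[test].sum() > 0:
            return train, test
        logger.warning("redrawing split without events on one side")
    raise ValueError("could not draw a split with events on both sides")


def bootstrap_cv(
    features: pd.DataFrame,
    times,
    events,
    ae_term: str = "",
    config: ForestConfig | None = None,
    B: int = 500,
    train_frac: float = 0.8,
    seed: int = 0,
    max_redraws: int = 100,
) -> CVResult:
    """Repeated-split cross-validation of the survival forest.

    Each of the B iterations draws ``train_frac`` of the patients without
    replacement as the training set, fits a forest, scores the disjoint
    held-out remainder by ensemble mortality and records Harrell's C.  Splits
    leaving either side without events are redrawn (logged).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(t)
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise ValueError("train_frac leaves an empty training or testing set")
    ss = np.random.SeedSequence(seed)
    c_values = []
    seeds = []
    for b, child in enumerate(ss.spawn(B)):
        rng = np.random.default_rng(child)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        train, test = draw_cv_split(rng, n, n_train, e, max_redraws=max_redraws)
        forest = fit_forest(
            features.iloc[train], t[train], e[train], config=config, seed=fit_seed
        )
        risk = forest.predict_mortality(features.iloc[test])
        c_values.append(harrell_c(t[test], e[test], risk))
        seeds.append(fit_seed)
    return CVResult(ae_term=ae_term, c_values=np.asarray(c_values), seeds=seeds)


def loo_cv(
    features: pd.DataFrame,
    times,
    events,
    config: ForestConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validation.

    Fits n forests, each without one patient, predicts that patient's risk
    (ensemble mortality), and returns the per-patient predictions together
    with a single pooled C-index over all held-out scores.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(t)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 patients")
    ss = np.random.SeedSequence(seed)
    risks = np.empty(n)
    for i, child in enumerate(ss.spawn(n)):
        keep = np.arange(n) != i
        fit_seed = int(np.random.default_rng(child).integers(0, 2**31 - 1))
        forest = fit_forest(
            features.iloc[keep], t[keep], e[keep], config=config, seed=fit_seed
        )
        risks[i] = forest.predict_mortality(features.iloc[[i]])[0]
    preds = pd.DataFrame(
        {
            "patient_id": features.index,
            "risk": risks,
            "time_days": t,
            "event": e,
        }
    )
    return preds, harrell_c(t, e, risks)


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------


@dataclass
class ExternalValidationReport:
    """Predicted vs observed AE incidence on an independent cohort."""

    table: pd.DataFrame  # ae_term, predicted, observed
    threshold: float
    horizon: float
    sensitivity: float
    specificity: float
    pearson_r: float
    pearson_p: float

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "horizon": self.horizon,
            "n_ae_terms": int(len(self.table)),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
        }


def external_validate(
    trained_models: dict[str, SurvivalForest],
    external_features: pd.DataFrame,
    external_outcomes: dict[str, pd.DataFrame],
    threshold: float = 0.10,
    horizon: float | None = None,
) -> ExternalValidationReport:
    """Validate trained per-AE forests against an independent cohort.

    For each AE term the predicted probability is the mean over external
    patients of 1 - S(horizon) under the trained forest; the observed
    incidence is the fraction of external patients with the event by the
    horizon.  Terms are classified at ``threshold`` on both axes to yield
    sensitivity (frequently reported terms predicted frequent) and specificity
    (rare terms predicted rare).  Pearson's r (two-sided) is computed between
    predicted probability and observed incidence over the frequently reported
    terms (observed >= threshold), as in incidence-calibration scatter plots.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    rows = []
    for term, forest in trained_models.items():
        if term not in external_outcomes:
            continue
        out = external_outcomes[term]
        h = horizon if horizon is not None else float(out["time_days"].max())
        grid_max = float(forest.grid[-1])
        if h > grid_max:
            logger.warning(
                "horizon %.0f beyond model grid; clipped to %.0f", h, grid_max
            )
            h = grid_max
        surv = forest.predict_survival(external_features)
        idx = np.searchsorted(forest.grid, h, side="right") - 1
        s_h = surv[:, idx] if idx >= 0 else np.ones(len(external_features))
        predicted = float(np.mean(1.0 - s_h))
        observed = float(
            np.mean((out["event"] == 1) & (out["time_days"] <= h))
        )
        rows.append((term, predicted, observed))
    table = pd.DataFrame(rows, columns=["ae_term", "predicted", "observed"])
    if table.empty:
        raise ValueError("no AE term shared between models and external outcomes")
    sensitivity, specificity, r, p = summarize_validation(table, threshold)
    h_used = horizon if horizon is not None else float(
        max(o["time_days"].max() for o in external_outcomes.values())
    )
    return ExternalValidationReport(
        table=table,
        threshold=threshold,
        horizon=h_used,
        sensitivity=sensitivity,
        specificity=specificity,
        pearson_r=r,
        pearson_p=p,
    )


def summarize_validation(
    table: pd.DataFrame, threshold: float
) -> tuple[float, float, float, float]:
    """Sensitivity, specificity and Pearson (r, p) for a predicted/observed
    incidence table classified at ``threshold`` on both axes.

    Pearson's r is computed over the frequently reported terms only
    (observed incidence >= threshold), two-sided; with fewer than two such
    terms (or degenerate variance) r is 1.0 for exact agreement and NaN
    otherwise.
    """
    pred_pos = table["predicted"] >= threshold
    obs_pos = table["observed"] >= threshold
    tp = int((pred_pos & obs_pos).sum())
    fn = int((~pred_pos & obs_pos).sum())
    tn = int((~pred_pos & ~obs_pos).sum())
    fp = int((pred_pos & ~obs_pos).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    frequent = table[obs_pos]
    if (
        len(frequent) >= 2
        and frequent["predicted"].nunique() > 1
        and frequent["observed"].nunique() > 1
    ):
        r, p = stats.pearsonr(frequent["predicted"], frequent["observed"])
    elif len(frequent) >= 1 and np.allclose(frequent["predicted"], frequent["observed"]):
        r, p = 1.0, 0.0  # degenerate perfect agreement
    else:
        r, p = float("nan"), float("nan")
    return float(sensitivity), float(specificity), float(r), float(p)


def null_concordance_simulation(
    n: int = 500,
    censoring_fraction: float = 0.30,
    replicates: int = 100,
    seed: int = 0,
) -> float:
    """Mean Harrell's C of an uninformative predictor, by simulation.

    Each replicate draws exponential event times with independent exponential
    censoring tuned to the requested censoring fraction, assigns independent
    uniform risk scores, and computes Harrell's C; the mean over replicates
    estimates the concordance of a random model (theoretically 0.5).
    """
    ss = np.random.SeedSequence(seed)
    # censoring rate c with event rate 1: P(censored) = c / (1 + c)
    c_rate = censoring_fraction / (1.0 - censoring_fraction)
    values = []
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        t_event = rng.exponential(1.0, size=n)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        risk = rng.uniform(size=n)
        values.append(harrell_c(time, event, risk))
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# reporting odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 drug-by-AE report counts.

    a: AE reports with the drug of interest; b: non-AE reports with the drug;
    c: AE reports with comparator drugs; d: non-AE reports with comparators.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


@dataclass(frozen=True)
class RORResult:
    value: float
    corrected: bool
    ci_low: float
    ci_high: float


def ror(counts: ContingencyCounts, ci_level: float = 0.95) -> RORResult:
    """Reporting odds ratio (a/b)/(c/d) = ad/bc with 95% log-normal CI.

    A ROR above 1 means the AE is reported more often with the drug of
    interest than with the comparators.  Any zero cell triggers the
    Haldane-Anscombe +0.5 correction on all four cells (flagged in the
    result); an all-zero table is an error.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if a == b == c == d == 0:
        raise ValueError("all-zero contingency table")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return RORResult(
        value=float(value),
        corrected=corrected,
        ci_low=float(math.exp(math.log(value) - z * se)),
        ci_high=float(math.exp(math.log(value) + z * se)),
    )
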