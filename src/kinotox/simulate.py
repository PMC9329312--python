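"""Synthetic integrated kinome-exposure-AE datasets with known causal truth.

The generator emulates the statistical structure the screening pipeline
assumes: a sparse drug x kinase Kd panel (each compound binds a small target
set, log-uniform over 1-1000 nM, and is unobserved elsewhere; causal kinases
are broadly engaged with potencies tracking a per-compound potency ladder),
per-patient log-normal steady-state exposures with configurable
inter-individual CV, demographics, and per-AE-term proportional-hazards
outcomes driven by the *inhibition features* of designated causal kinases:

    h_i = h0 * exp( sum_k beta_k * log1p(C_ave,ss_i / Kd_{drug(i),k}) )

with an exponential or Weibull baseline, administrative censoring at the end
of follow-up, and onset times rounded up to whole days.  The log1p link keeps
the zero-inhibition case well defined and makes effects multiplicative on the
hazard.  Ground truth (causal kinases and coefficients) is written alongside
the dataset so recovery can be scored.

Everything descends deterministically from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    AETermMap,
    AnalysisDataset,
    KinomePanel,
    integrate,
    save_dataset,
)
from .forest import ForestConfig

__all__ = [
    "AETermSpec",
    "SimulationConfig",
    "simulate_kinome",
    "simulate_exposures",
    "simulate_outcomes",
    "simulate_dataset",
    "generate_dataset",
    "benchmark_config",
    "BENCHMARK_FOREST_CONFIG",
]


@dataclass(frozen=True)
class AETermSpec:
    """Generative model of one customized AE term.

    ``causal`` maps kinase id -> log-hazard coefficient per unit
    log1p(inhibition feature); empty means a pure-noise term.  ``raw_synonyms``
    lets the generator emit raw preferred terms that the consolidation map
    folds back into this term, exercising the term-mapping stage.
    """

    name: str
    causal: dict[str, float] = field(default_factory=dict)
    baseline: str = "exponential"  # or "weibull"
    baseline_rate: float = 5e-5  # events / day for the zero-inhibition patient
    weibull_shape: float = 1.0
    target_incidence: float | None = None  # calibrate h0 to this marginal event fraction
    min_hr_per_sd: float | None = None  # floor on each causal kinase's per-SD hazard ratio
    raw_synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark (all fields overridable)."""

    n_drugs: int = 8
    n_kinases: int = 200
    patients_per_drug: int = 75
    kd_sparsity: float = 0.97  # fraction of drug-kinase pairs left missing
    kd_log10_range: tuple[float, float] = (0.0, 3.0)  # observed Kd 1-1000 nM
    causal_coverage: float = 1.0  # fraction of drugs forced to bind each causal kinase
    drug_potency_decades: float = 0.35  # half-range of per-compound potency scale
    causal_kd_center_range: tuple[float, float] = (1.0, 2.0)  # log10 nM per causal kinase
    causal_kd_jitter_decades: float = 0.35  # drug-specific deviation around the trend
    exposure_median_nm: float = 500.0
    exposure_cv: float = 0.5  # log-normal inter-individual CV of C_ave,ss
    age_mean: float = 60.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (18.0, 90.0)
    sex_prob: float = 0.5  # P(sex == 1)
    followup_days: int = 365
    ae_terms: tuple[AETermSpec, ...] = (
        AETermSpec(
            name="hypertension",
            causal={f"KIN{k:03d}": 1.0 for k in range(1, 6)},
            target_incidence=0.45,
            min_hr_per_sd=2.0,
            raw_synonyms=("hypertension", "blood pressure increased"),
        ),
        AETermSpec(
            name="vomiting/nausea",
            causal={},
            baseline_rate=1.5e-3,
            raw_synonyms=("vomiting", "nausea"),
        ),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        kinases = set(self.kinase_ids())
        for term in self.ae_terms:
            unknown = set(term.causal) - kinases
            if unknown:
                raise ValueError(
                    f"causal kinases {sorted(unknown)} of term {term.name!r} "
                    "not in the kinase list"
                )
            if not all(np.isfinite(list(term.causal.values()) or [0.0])):
                raise ValueError(f"non-finite coefficient in term {term.name!r}")
        if self.followup_days < 1:
            raise ValueError("followup_days must be >= 1")

    def kinase_ids(self) -> list[str]:
        return [f"KIN{k:03d}" for k in range(1, self.n_kinases + 1)]

    def drug_ids(self) -> list[str]:
        return [f"DRUG{j:02d}" for j in range(1, self.n_drugs + 1)]


def simulate_kinome(config: SimulationConfig, rng: np.random.Generator) -> KinomePanel:
    """Sparse Kd panel: each drug binds ~(1 - sparsity) of the kinome.

    Non-causal entries are drawn log-uniformly over ``kd_log10_range`` for a
    random target set per drug.  Causal kinases (union over AE terms) are
    additionally forced into the target set of a ``causal_coverage`` fraction
    of drugs, with Kd following a per-compound potency scale:

        log10 Kd(drug j, kinase k) = c_k - potency_j + jitter

    where c_k is the kinase's typical potency and potency_j a per-drug shift:
    the compounds span the potency scale evenly (a randomly assigned, evenly
    spaced ladder over +/- ``drug_potency_decades``), with kinase-specific
    Gaussian jitter on top.  Broadly-engaged kinases whose potency tracks the
    compound's overall potency are what make kinase-level attribution
    identifiable from a small number of compounds; see the methods note.
    """
    kinases = config.kinase_ids()
    drugs = config.drug_ids()
    m = config.n_kinases
    lo, hi = config.kd_log10_range
    kd = np.full((config.n_drugs, m), np.nan)
    causal_union = sorted({k for t in config.ae_terms for k in t.causal})
    causal_pos = [kinases.index(k) for k in causal_union]
    n_targets = int(round((1.0 - config.kd_sparsity) * m))
    for j in range(config.n_drugs):
        if n_targets > 0:
            targets = rng.choice(m, size=n_targets, replace=False)
            kd[j, targets] = 10.0 ** rng.uniform(lo, hi, size=n_targets)
    potency = np.linspace(
        -config.drug_potency_decades, config.drug_potency_decades, config.n_drugs
    )[rng.permutation(config.n_drugs)]
    centers = rng.uniform(*config.causal_kd_center_range, size=len(causal_pos))
    for c_k, pos in zip(centers, causal_pos):
        n_cover = int(round(config.causal_coverage * config.n_drugs))
        cover = rng.choice(config.n_drugs, size=n_cover, replace=False)
        for j in cover:
            log_kd = c_k - potency[j] + rng.normal(0.0, config.causal_kd_jitter_decades)
            kd[j, pos] = 10.0 ** float(np.clip(log_kd, lo, hi))
    return KinomePanel(pd.DataFrame(kd, index=drugs, columns=kinases))


def simulate_exposures(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Patient table: log-normal C_ave,ss per drug, truncated-normal ages,
    Bernoulli sex, common administrative follow-up."""
    sigma = float(np.sqrt(np.log1p(config.exposure_cv**2)))
    mu = float(np.log(config.exposure_median_nm))
    rows = []
    for drug in config.drug_ids():
        n = config.patients_per_drug
        cave = np.exp(rng.normal(mu, sigma, size=n))
        age = np.clip(
            rng.normal(config.age_mean, config.age_sd, size=n), *config.age_bounds
        )
        sex = (rng.random(n) < config.sex_prob).astype(int)
        for i in range(n):
            rows.append((f"P{len(rows) + 1:05d}", drug, round(float(age[i]), 1),
                         int(sex[i]), float(cave[i]), config.followup_days))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "drug_id", "age", "sex", "cave_ss", "followup_days"],
    )


def effective_betas(features: pd.DataFrame, term: AETermSpec) -> dict[str, float]:
    """Per-kinase log-hazard coefficients actually applied.

    When ``min_hr_per_sd`` is set, each coefficient is floored at the value
    that makes the hazard ratio per standard deviation of the realized
    log1p(feature) equal to that floor, guaranteeing the stated effect size
    on every generated dataset.
    """
    out: dict[str, float] = {}
    for kinase, beta in term.causal.items():
        if term.min_hr_per_sd is not None:
            sd = float(np.log1p(features[kinase].to_numpy(dtype=float)).std())
            if sd > 0:
                beta = max(beta, float(np.log(term.min_hr_per_sd)) / sd)
        out[kinase] = float(beta)
    return out


def _calibrated_rate(term: AETermSpec, lp: np.ndarray, followup: int) -> float:
    """Baseline rate; calibrated by bisection when a target incidence is set.

    Solves mean_i P(T_i <= followup) = target under the term's baseline
    family, so the marginal event fraction is stable across kinome and
    exposure draws.  Deterministic given the linear predictors.
    """
    if term.target_incidence is None:
        return term.baseline_rate
    target = term.target_incidence
    if not 0 < target < 1:
        raise ValueError("target_incidence must lie strictly between 0 and 1")
    scale = np.exp(lp)

    def frac(rate: float) -> float:
        if term.baseline == "exponential":
            h = rate * followup * scale
        else:
            h = scale * (rate * followup) ** term.weibull_shape
        return float(np.mean(-np.expm1(-h)))

    lo, hi = 1e-300, 1e3
    for _ in range(300):
        mid = float(np.sqrt(lo * hi))
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_outcomes(
    features: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-term proportional-hazards event times and emit raw AE records.

    Returns a raw-record table (patient_id, term, onset_day, grade) holding
    one record per simulated event; censored patients simply lack a record
    for the term.  Onset days are the ceiling of the continuous event time
    (>= 1); events after follow-up are censored administratively.
    """
    records = []
    followup = config.followup_days
    for term in config.ae_terms:
        lp = np.zeros(len(features))
        for kinase, beta in effective_betas(features, term).items():
            lp += beta * np.log1p(features[kinase].to_numpy(dtype=float))
        if not np.isfinite(lp).all():
            bad = features.index[~np.isfinite(lp)][0]
            raise ValueError(f"non-finite linear predictor for patient {bad!r}")
        scale_factor = np.exp(lp)
        rate = _calibrated_rate(term, lp, followup)
        e_std = rng.exponential(1.0, size=len(features))
        if term.baseline == "exponential":
            t_cont = e_std / (rate * scale_factor)
        elif term.baseline == "weibull":
            # PH Weibull: H0(t) = (rate * t)^shape
            t_cont = (e_std / scale_factor) ** (1.0 / term.weibull_shape) / rate
        else:
            raise ValueError(f"unknown baseline family {term.baseline!r}")
        onset = np.maximum(np.ceil(t_cont), 1.0).astype(int)
        synonyms = term.raw_synonyms or (term.name,)
        raw_choice = rng.integers(0, len(synonyms), size=len(features))
        grades = rng.choice([1, 2, 3, 4], size=len(features), p=[0.4, 0.3, 0.2, 0.1])
        for i, pid in enumerate(features.index):
            if onset[i] <= followup:
                records.append(
                    (pid, synonyms[raw_choice[i]], int(onset[i]), int(grades[i]))
                )
    return pd.DataFrame(records, columns=["patient_id", "term", "onset_day", "grade"])


def _term_map(config: SimulationConfig) -> AETermMap:
    mapping = {}
    for term in config.ae_terms:
        for raw in term.raw_synonyms:
            mapping[raw] = term.name
    return AETermMap(mapping)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[KinomePanel, pd.DataFrame, pd.DataFrame, AETermMap, dict]:
    """Chain kinome -> exposures -> features -> outcomes; return raw inputs
    plus the ground-truth dictionary (causal kinases and coefficients)."""
    ss = np.random.SeedSequence(config.seed)
    rng_kinome, rng_expo, rng_out = (np.random.default_rng(c) for c in ss.spawn(3))
    panel = simulate_kinome(config, rng_kinome)
    patients = simulate_exposures(config, rng_expo)
    from .data_model import compute_inhibition_features, impute_kd

    features = compute_inhibition_features(patients, impute_kd(panel))
    raw_records = simulate_outcomes(features, config, rng_out)
    ground_truth = {
        "seed": config.seed,
        "ae_terms": {
            t.name: {
                "causal_kinases": sorted(t.causal),
                "beta": effective_betas(features, t),
            }
            for t in config.ae_terms
        },
    }
    return panel, patients, raw_records, _term_map(config), ground_truth


def generate_dataset(config: SimulationConfig, directory: str | Path) -> AnalysisDataset:
    """Generate, write the CSV layout + ground_truth.json, and return the
    integrated dataset."""
    panel, patients, raw_records, term_map, truth = simulate_dataset(config)
    d = save_dataset(
        panel,
        patients,
        raw_records,
        term_map,
        directory,
        metadata={"seed": config.seed, "generator": "kinotox.simulate"},
    )
    (d / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return integrate(panel, patients, raw_records, term_map,
                     metadata={"seed": config.seed})


def benchmark_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The versioned benchmark: 600 patients on 8 drugs, 200 kinases, one AE
    term with 5 causal kinases (per-SD hazard ratios >= 2 by construction)
    plus one pure-noise term."""
    return SimulationConfig(seed=seed, **overrides)


BENCHMARK_FOREST_CONFIG = ForestConfig(n_trees=100, min_node_size=15, min_node_events=3)
"""Forest settings used with the benchmark in examples and validation runs."""


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "ae_terms" in d:
        d["ae_terms"] = tuple(
            AETermSpec(**{**t, "raw_synonyms": tuple(t.get("raw_synonyms", ()))})
            for t in (dict(t) for t in d["ae_terms"])
        )
    for key in ("kd_log10_range", "age_bounds"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
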