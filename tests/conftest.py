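"""Shared fixtures: tiny hand-built datasets and brute-force survival oracles.

The oracle functions re-derive the survival statistics by direct enumeration
of the defining sums, independently of the package's vectorized code paths,
so agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from kinotox.data_model import AETermMap, KinomePanel
from kinotox.simulate import AETermSpec, SimulationConfig


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_logrank(times, events, left) -> float:
    """Standardized log-rank statistic by direct evaluation of the
    hypergeometric observed-minus-expected and variance sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    left = np.asarray(left, bool)
    num = var = 0.0
    for tk in sorted(set(times[events == 1])):
        d = sum(1 for t, e in zip(times, events) if t == tk and e == 1)
        dl = sum(1 for t, e, l in zip(times, events, left) if t == tk and e == 1 and l)
        y = sum(1 for t in times if t >= tk)
        yl = sum(1 for t, l in zip(times, left) if t >= tk and l)
        num += dl - d * yl / y
        if y > 1:
            var += (yl / y) * (1 - yl / y) * ((y - d) / (y - 1)) * d
    return 0.0 if var <= 0 else abs(num) / var**0.5


def oracle_nelson_aalen(times, events):
    """(event_times, H) by accumulating d_k / n_k term by term."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    tks = sorted(set(times[events == 1]))
    h = 0.0
    out = []
    for tk in tks:
        d = sum(1 for t, e in zip(times, events) if t == tk and e == 1)
        n = sum(1 for t in times if t >= tk)
        h += d / n
        out.append(h)
    return np.asarray(tks), np.asarray(out)


def oracle_kaplan_meier(times, events):
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    tks = sorted(set(times[events == 1]))
    s = 1.0
    out = []
    for tk in tks:
        d = sum(1 for t, e in zip(times, events) if t == tk and e == 1)
        n = sum(1 for t in times if t >= tk)
        s *= 1 - d / n
        out.append(s)
    return np.asarray(tks), np.asarray(out)


def oracle_harrell_c(times, events, risk) -> float:
    """Harrell's C by exhaustive enumeration of ordered pairs."""
    conc = perm = 0.0
    n = len(times)
    for i, j in itertools.permutations(range(n), 2):
        if events[i] != 1:
            continue
        if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
            perm += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                conc += 0.5
    if perm == 0:
        raise ValueError("no permissible pairs")
    return conc / perm


def random_survival_instances(n_instances=30, max_n=10, seed=1234):
    """Small random censored-survival instances (with ties) for oracle checks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_instances):
        n = rng.integers(3, max_n + 1)
        times = rng.integers(1, 6, size=n).astype(float)  # forces ties
        events = rng.integers(0, 2, size=n)
        if events.sum() == 0:
            events[rng.integers(0, n)] = 1
        out.append((times, events))
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def tiny_panel() -> KinomePanel:
    kd = pd.DataFrame(
        {
            "ABL1": [3.2, 150.0, np.nan],
            "KIT": [np.nan, 12.0, 40.0],
            "VEGFR2": [25.0, np.nan, 5.0],
        },
        index=["drugA", "drugB", "drugC"],
    )
    return KinomePanel(kd)


@pytest.fixture
def tiny_patients() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4"],
            "drug_id": ["drugA", "drugA", "drugB", "drugC"],
            "age": [61.0, 55.0, 70.0, 48.0],
            "sex": [0, 1, 1, 0],
            "cave_ss": [100.0, 50.0, 200.0, 80.0],
            "followup_days": [100, 100, 80, 120],
        }
    )


@pytest.fixture
def tiny_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p3", "p4"],
            "term": ["mouth ulceration", "stomatitis", "nausea", "vomiting", "rash"],
            "onset_day": [12, 5, 30, 7, 45],
            "grade": [2, 1, 3, 2, 1],
        }
    )


@pytest.fixture
def tiny_term_map() -> AETermMap:
    return AETermMap(
        {
            "mouth ulceration": "stomatitis",
            "oral mucosal eruption": "stomatitis",
            "stomatitis": "stomatitis",
            "vomiting": "vomiting/nausea",
            "nausea": "vomiting/nausea",
        }
    )


def small_sim_config(seed=0, **overrides) -> SimulationConfig:
    """Scaled-down simulation for fast tests: 120 patients, 30 kinases,
    2 causal kinases on one AE term plus one pure-noise term."""
    defaults = dict(
        n_drugs=4,
        n_kinases=30,
        patients_per_drug=30,
        ae_terms=(
            AETermSpec(
                name="hypertension",
                causal={"KIN001": 1.0, "KIN002": 1.0},
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
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """Integrated dataset from the scaled-down generator (session-cached)."""
    import kinotox as kt

    cfg = small_sim_config(seed=3)
    panel, patients, records, term_map, truth = kt.simulate_dataset(cfg)
    return kt.integrate(panel, patients, records, term_map), truth
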