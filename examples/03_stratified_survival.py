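"""Median-split stratified ensemble survival curves.

Patients are split at the median of one kinase's inhibition feature; the
forest-predicted survival (probability of remaining AE-free) is averaged
within each stratum.  For a causal kinase the higher-inhibition stratum's
curve lies below the lower-inhibition one at every time point.
"""

from kinotox import ForestConfig, fit_forest, integrate, simulate_dataset, stratify_km
from kinotox.simulate import AETermSpec, SimulationConfig

config = SimulationConfig(
    n_drugs=4, n_kinases=30, patients_per_drug=30,
    ae_terms=(
        AETermSpec(name="hypertension", causal={"KIN001": 1.0, "KIN002": 1.0},
                   target_incidence=0.45, min_hr_per_sd=2.0),
    ),
    seed=3,
)
dataset = integrate(*simulate_dataset(config)[:4])
outcome = dataset.outcome("hypertension")
forest = fit_forest(
    dataset.features,
    outcome["time_days"].to_numpy(),
    outcome["event"].to_numpy(),
    config=ForestConfig(n_trees=60),
    seed=1,
)

strata = stratify_km(dataset, forest, "KIN001", "hypertension")
print(f"median KIN001 inhibition: {strata.median:.3f}; sizes {strata.stratum_sizes}\n")
wide = strata.curves.pivot(index="time", columns="stratum", values="mean_S")
print(wide.iloc[::12].round(3))
print(
    "\nEach row is the mean ensemble AE-free probability at that day;"
    " the higher-inhibition stratum stays lower throughout, i.e. earlier"
    " hypertension onset under stronger KIN001 engagement."
)
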