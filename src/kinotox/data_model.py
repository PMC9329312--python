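"""Integrated analysis dataset: kinome panel, patients, adverse-event outcomes.

The central quantity is the per-patient, per-kinase *kinase-inhibition feature*

    KI(i, k) = C_ave,ss(i) / Kd(drug(i), k)

a dimensionless empirical inhibition measure built from the patient's
steady-state average plasma concentration (nM) and the dissociation constant
(nM) of their drug against kinase k.  Because the feature depends on the drug
only through its Kd vector, the drug label itself carries no information and
patients on different drugs become directly comparable ("drug-agnostic").

Missing Kd entries denote kinases the drug was not observed to bind; they are
imputed with a single large constant (1e4 nM) representing negligible binding,
so every imputed feature is small but finite.

Units: Kd and C_ave,ss are both nM throughout, so the feature is dimensionless.
Times are integer days, 1-based from treatment start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

KD_IMPUTE_VALUE = 1e4
"""Dissociation constant (nM) assigned to unobserved drug-kinase pairs."""

DEMOGRAPHIC_COLUMNS = ("age", "sex")


class ValidationError(ValueError):
    """Raised when an input table violates a dataset invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinomePanel:
    """Drug x kinase dissociation-constant matrix (nM); NaN marks missing."""

    kd: pd.DataFrame  # index: drug ids, columns: kinase ids

    def __post_init__(self) -> None:
        if self.kd.index.duplicated().any():
            raise ValidationError("duplicate drug identifiers in kinome panel")
        if self.kd.columns.duplicated().any():
            raise ValidationError("duplicate kinase identifiers in kinome panel")
        bad = (self.kd.to_numpy(dtype=float) <= 0) & ~np.isnan(
            self.kd.to_numpy(dtype=float)
        )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive Kd for drug {self.kd.index[i]!r}, "
                f"kinase {self.kd.columns[j]!r}"
            )

    @property
    def drugs(self) -> list[str]:
        return list(self.kd.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.kd.columns)

    @property
    def n_missing(self) -> int:
        return int(self.kd.isna().to_numpy().sum())


@dataclass(frozen=True)
class AETermMap:
    """Many-to-one map from raw adverse-event terms to customized preferred
    terms.  Raw terms absent from the map pass through unchanged."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for raw, custom in self.mapping.items():
            if not isinstance(custom, str) or not custom:
                raise ValidationError(
                    f"customized term for {raw!r} must be a non-empty string"
                )

    def __call__(self, raw_term: str) -> str:
        return self.mapping.get(raw_term, raw_term)


def validate_patients(patients: pd.DataFrame, panel: KinomePanel) -> None:
    """Check the patient table invariants against a kinome panel."""
    required = {"patient_id", "drug_id", "age", "sex", "cave_ss", "followup_days"}
    missing = required - set(patients.columns)
    if missing:
        raise ValidationError(f"patient table missing columns: {sorted(missing)}")
    if patients["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id in patient table")
    if (patients["cave_ss"].to_numpy(dtype=float) <= 0).any():
        raise ValidationError("cave_ss must be positive for every patient")
    if (patients["followup_days"].to_numpy() < 1).any():
        raise ValidationError("followup_days must be >= 1 for every patient")
    unknown = set(patients["drug_id"]) - set(panel.drugs)
    if unknown:
        raise ValidationError(f"patients assigned to drugs absent from panel: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def impute_kd(panel: KinomePanel, value: float = KD_IMPUTE_VALUE) -> KinomePanel:
    """Replace every missing Kd entry with the imputation constant (1e4 nM).

    Observed entries are untouched; the operation is idempotent.
    """
    return KinomePanel(panel.kd.fillna(value))


def compute_inhibition_features(
    patients: pd.DataFrame,
    panel: KinomePanel,
    demographics: Sequence[str] = DEMOGRAPHIC_COLUMNS,
) -> pd.DataFrame:
    """Build the patients x predictors feature matrix.

    Kinase columns hold C_ave,ss / Kd for the patient's assigned drug;
    demographic covariates (by default age and sex) are appended unchanged.
    The panel must already be imputed (no missing Kd).
    """
    if panel.n_missing:
        raise ValidationError("panel contains missing Kd entries; impute first")
    validate_patients(patients, panel)
    kd = panel.kd.loc[patients["drug_id"].to_numpy()]
    feats = patients["cave_ss"].to_numpy(dtype=float)[:, None] / kd.to_numpy(dtype=float)
    out = pd.DataFrame(feats, index=patients["patient_id"].to_numpy(), columns=panel.kinases)
    for col in demographics:
        if col not in patients.columns:
            raise ValidationError(f"demographic column {col!r} absent from patient table")
        out[col] = patients[col].to_numpy(dtype=float)
    if not np.isfinite(out.to_numpy()).all():
        raise ValidationError("non-finite feature value encountered")
    out.index.name = "patient_id"
    return out


def map_ae_terms(raw_records: pd.DataFrame, term_map: AETermMap) -> pd.DataFrame:
    """Consolidate raw AE terms to customized preferred terms.

    Input columns: patient_id, term, onset_day and optionally grade.  Records
    of a patient whose raw terms map to the same customized term are merged,
    keeping the earliest onset (and the grade recorded at that onset; the
    maximum grade among merged records is kept as ``max_grade``).
    """
    rec = raw_records.copy()
    rec["ae_term"] = rec["term"].map(term_map)
    rec = rec.sort_values(["patient_id", "ae_term", "onset_day"], kind="stable")
    grouped = rec.groupby(["patient_id", "ae_term"], sort=False)
    first = grouped.first().reset_index()
    if "grade" in rec.columns:
        first["max_grade"] = grouped["grade"].max().to_numpy()
    return first[[c for c in ("patient_id", "ae_term", "onset_day", "grade", "max_grade") if c in first.columns]]


def extract_time_to_event(
    mapped_records: pd.DataFrame,
    patient: pd.Series,
    ae_term: str,
) -> tuple[int, int]:
    """Time-to-first-onset for one patient and customized term.

    Returns ``(earliest onset day, 1)`` if the term occurred, else
    ``(followup_days, 0)`` — censoring at end of follow-up.
    """
    followup = int(patient["followup_days"])
    mask = (mapped_records["patient_id"] == patient["patient_id"]) & (
        mapped_records["ae_term"] == ae_term
    )
    hits = mapped_records.loc[mask, "onset_day"]
    if hits.empty:
        return followup, 0
    onset = int(hits.min())
    if onset > followup:
        raise ValidationError(
            f"onset day {onset} after follow-up {followup} for patient "
            f"{patient['patient_id']!r}, term {ae_term!r}"
        )
    return onset, 1


def build_outcome_table(
    mapped_records: pd.DataFrame,
    patients: pd.DataFrame,
    ae_term: str,
    min_grade: int | None = None,
) -> pd.DataFrame:
    """Per-patient (time_days, event) table for one customized term.

    ``min_grade`` restricts events to records whose grade reaches the cutoff
    (severity-filtered analyses); lower-grade occurrences are treated as
    non-events.
    """
    rec = mapped_records[mapped_records["ae_term"] == ae_term]
    if min_grade is not None:
        grade_col = "max_grade" if "max_grade" in rec.columns else "grade"
        rec = rec[rec[grade_col].fillna(0) >= min_grade]
    onset = rec.groupby("patient_id")["onset_day"].min()
    rows = []
    for _, p in patients.iterrows():
        pid = p["patient_id"]
        followup = int(p["followup_days"])
        if pid in onset.index:
            t = int(onset.loc[pid])
            if t > followup:
                raise ValidationError(
                    f"onset day {t} after follow-up {followup} for patient {pid!r}"
                )
            rows.append((pid, t, 1))
        else:
            rows.append((pid, followup, 0))
    return pd.DataFrame(rows, columns=["patient_id", "time_days", "event"])


# ---------------------------------------------------------------------------
# integrated dataset + CSV layout
# ---------------------------------------------------------------------------


@dataclass
class AnalysisDataset:
    """Feature matrix plus outcome bookkeeping for every customized AE term."""

    features: pd.DataFrame  # patients x predictors
    patients: pd.DataFrame
    mapped_records: pd.DataFrame
    kinases: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kinases:
            self.kinases = [
                c for c in self.features.columns if c not in DEMOGRAPHIC_COLUMNS
            ]

    @property
    def ae_terms(self) -> list[str]:
        return sorted(self.mapped_records["ae_term"].unique())

    @property
    def predictors(self) -> list[str]:
        return list(self.features.columns)

    def outcome(self, ae_term: str, min_grade: int | None = None) -> pd.DataFrame:
        return build_outcome_table(
            self.mapped_records, self.patients, ae_term, min_grade=min_grade
        )

    def n_events(self, ae_term: str) -> int:
        return int(self.outcome(ae_term)["event"].sum())


def integrate(
    panel: KinomePanel,
    patients: pd.DataFrame,
    raw_records: pd.DataFrame,
    term_map: AETermMap,
    metadata: dict | None = None,
) -> AnalysisDataset:
    """Full integration pipeline: impute Kd, build features, consolidate AEs."""
    imputed = impute_kd(panel)
    features = compute_inhibition_features(patients, imputed)
    mapped = map_ae_terms(raw_records, term_map)
    meta = {
        "units": {"kd": "nM", "cave_ss": "nM", "time": "days"},
        "sex_encoding": {"0": "female", "1": "male"},
        "kd_impute_value": KD_IMPUTE_VALUE,
    }
    meta.update(metadata or {})
    return AnalysisDataset(
        features=features,
        patients=patients.reset_index(drop=True),
        mapped_records=mapped,
        kinases=imputed.kinases,
        metadata=meta,
    )


def read_kinome_csv(path: str | Path) -> KinomePanel:
    """Kinome panel CSV: first column drug id, remaining columns kinase ids,
    empty cell = missing."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return KinomePanel(df.astype(float))


def write_kinome_csv(panel: KinomePanel, path: str | Path) -> None:
    panel.kd.to_csv(path, index_label="drug_id")


def read_term_map_csv(path: str | Path) -> AETermMap:
    df = pd.read_csv(path)
    return AETermMap(dict(zip(df["raw_term"].astype(str), df["ae_term"].astype(str))))


def write_term_map_csv(term_map: AETermMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(term_map.mapping.items()), columns=["raw_term", "ae_term"]
    ).to_csv(path, index=False)


def load_dataset(directory: str | Path) -> AnalysisDataset:
    """Load the serialized CSV layout written by :func:`save_dataset`."""
    d = Path(directory)
    panel = read_kinome_csv(d / "kinome.csv")
    patients = pd.read_csv(d / "patients.csv")
    patients["patient_id"] = patients["patient_id"].astype(str)
    records = pd.read_csv(d / "ae_records.csv")
    records["patient_id"] = records["patient_id"].astype(str)
    term_map = read_term_map_csv(d / "term_map.csv")
    meta_path = d / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return integrate(panel, patients, records, term_map, metadata=metadata)


def save_dataset(
    panel: KinomePanel,
    patients: pd.DataFrame,
    raw_records: pd.DataFrame,
    term_map: AETermMap,
    directory: str | Path,
    metadata: dict | None = None,
) -> Path:
    """Write the raw-input CSV layout plus a JSON metadata file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_kinome_csv(panel, d / "kinome.csv")
    patients.to_csv(d / "patients.csv", index=False)
    raw_records.to_csv(d / "ae_records.csv", index=False)
    write_term_map_csv(term_map, d / "term_map.csv")
    meta = {
        "units": {"kd": "nM", "cave_ss": "nM", "time": "days"},
        "sex_encoding": {"0": "female", "1": "male"},
        "kd_impute_value": KD_IMPUTE_VALUE,
    }
    meta.update(metadata or {})
    (d / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return d
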