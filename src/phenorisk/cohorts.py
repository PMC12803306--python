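"""Cohort roles and deployment stratification.

Roles are genotype-driven: confirmed variant carriers are *cases*,
sequencing-confirmed non-carriers are *controls*, and everyone else — the
patients whose genotype is simply unknown — forms the *training* cohort
used solely to estimate feature frequencies. This keeps weight estimation
disjoint from the labelled test set and prevents target leakage.

Deployment stratification mirrors how a score is actually rolled out for
an adult-onset, ancestry-skewed disease: restrict to patients old enough
for the phenotype to have emerged (age at last diagnosis), to the
population carrying the variant burden (verbatim race/ethnicity labels),
and to a clinical context (e.g. at least one heart-failure diagnosis) —
while dropping the corresponding feature from the score to avoid
circularity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

ROLES = ("case", "control", "training", "excluded")

_STATUS_TO_ROLE = {
    "carrier": "case",
    "noncarrier_confirmed": "control",
    "unknown": "training",
}


def assign_roles(genotypes: pd.Series) -> pd.Series:
    """Map genotype status to cohort role (carrier -> case, confirmed
    non-carrier -> control, unknown -> training)."""
    bad = ~genotypes.isin(_STATUS_TO_ROLE)
    if bad.any():
        raise ValidationError(
            f"unknown genotype status value(s): {sorted(genotypes[bad].unique())}"
        )
    roles = genotypes.map(_STATUS_TO_ROLE)
    roles.name = "role"
    return roles


def age_at_last_diagnosis(diagnoses: pd.DataFrame, demographics: pd.DataFrame) -> pd.Series:
    """Calendar-year age at each patient's most recent diagnosis.

    Returns a float Series indexed like ``demographics``; NaN marks
    patients without any diagnosis (they fail any age stratum rather than
    erroring, since genotyped patients without ICD data are expected).
    """
    if len(diagnoses):
        last_year = (
            pd.to_datetime(diagnoses["event_date"]).dt.year.groupby(
                diagnoses["patient_id"].to_numpy()
            ).max()
        )
    else:
        last_year = pd.Series(dtype=float)
    age = last_year.reindex(demographics.index) - demographics["birth_year"]
    age.name = "age_at_last_dx"
    return age


@dataclass
class StratificationSpec:
    """Which deployment filters to apply; all optional, combined by AND."""

    min_age_at_last_dx: int | None = None
    race_ethnicity_values: set[str] | None = None
    require_feature_history: str | None = None
    exclude_feature_from_score: str | None = None

    @classmethod
    def from_dict(cls, d: dict | None) -> "StratificationSpec":
        d = dict(d or {})
        race = d.get("race_ethnicity_values")
        return cls(
            min_age_at_last_dx=d.get("min_age_at_last_dx"),
            race_ethnicity_values=set(race) if race else None,
            require_feature_history=d.get("require_feature_history"),
            exclude_feature_from_score=d.get("exclude_feature_from_score"),
        )


def apply_strata(
    patients,
    demographics: pd.DataFrame,
    presence: pd.DataFrame,
    diagnoses: pd.DataFrame,
    spec: StratificationSpec,
) -> tuple[pd.Index, dict[str, int]]:
    """Intersect all active filters over ``patients``.

    Returns the surviving patient index (original order preserved) and a
    per-filter attrition count for logging. Filters are independent set
    intersections, so they are idempotent and order-free.
    """
    surviving = pd.Index(patients)
    attrition: dict[str, int] = {}

    if spec.min_age_at_last_dx is not None:
        ages = age_at_last_diagnosis(diagnoses, demographics)
        ok = ages.reindex(surviving) >= spec.min_age_at_last_dx  # NaN -> False
        attrition["min_age_at_last_dx"] = int((~ok).sum())
        surviving = surviving[ok.to_numpy()]

    if spec.race_ethnicity_values is not None:
        labels = demographics["race_ethnicity"].reindex(surviving)
        ok = labels.isin(spec.race_ethnicity_values)
        attrition["race_ethnicity"] = int((~ok).sum())
        surviving = surviving[ok.to_numpy()]
        if len(surviving) == 0:
            warnings.warn(
                "race/ethnicity filter matched no patients "
                f"(accepted labels: {sorted(spec.race_ethnicity_values)})",
                UserWarning,
                stacklevel=2,
            )

    if spec.require_feature_history is not None:
        fid = spec.require_feature_history
        if fid not in presence.columns:
            raise ValidationError(
                f"require_feature_history references unknown feature {fid!r}"
            )
        ok = presence[fid].reindex(surviving).fillna(0).astype(bool)
        attrition["require_feature_history"] = int((~ok).sum())
        surviving = surviving[ok.to_numpy()]

    logger.info("stratification kept %d of %d patients (attrition %s)",
                len(surviving), len(pd.Index(patients)), attrition)
    return surviving, attrition


def subsample_training(assignment: pd.Series, target_size: int, seed: int) -> pd.Series:
    """Keep a uniform random subset of the training cohort.

    Non-selected training patients become ``excluded``; case/control roles
    are untouched. Deterministic given ``seed`` regardless of input order.
    """
    pool = assignment.index[assignment == "training"]
    if target_size > len(pool):
        raise ValidationError(
            f"target_size {target_size} exceeds training pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    ordered = np.sort(pool.to_numpy())
    keep = set(rng.choice(ordered, size=target_size, replace=False))
    out = assignment.copy()
    drop = [p for p in pool if p not in keep]
    out.loc[drop] = "excluded"
    return out
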