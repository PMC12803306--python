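"""Synthetic EHR cohort generator.

Emulates the statistical structure the scoring pipeline assumes, so every
stage is testable without access to restricted biobank data:

* a rare carrier genotype at prevalence ``pi`` (around 1.3% in the
  bundled preset, matching the cohort prevalence of the motivating
  transthyretin-amyloidosis variant);
* per-phenotype baseline presence probabilities in non-carriers;
* carrier relative risks that switch on only above an onset age —
  incomplete, age-dependent penetrance. The default gate is a hard
  threshold at 60 years (carriers younger than onset look exactly like
  non-carriers); a smooth logistic ramp is available via
  ``age_gating="logistic"``.

Present features emit ``1 + Poisson(lambda)`` raw diagnosis events, with
codes drawn uniformly from the feature's code group and dates uniform
over the patient's adult years, so ingestion, normalisation and the
presence rule are all exercised end to end. Everything is deterministic
given the seed.

The generator captures case/control/training structure, rare-feature
weighting and age-gated penetrance; it does **not** model longitudinal
disease progression, coding-intensity confounding, or demographic
realism beyond a configurable categorical race/ethnicity mix.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .features import FeatureMap, PhenotypeFeature
from . import ehr_io

_EPOCH_ORDINAL = _dt.date(1970, 1, 1).toordinal()


@dataclass
class SynthConfig:
    """Full generative specification for one simulated cohort.

    ``baseline_probs`` and ``carrier_odds_ratios`` are keyed by feature_id
    and must align exactly with the feature map passed to
    :func:`generate_cohort`. Carrier effects act on the odds scale:
    presence odds = baseline odds x OR for carriers at or above
    ``penetrance_onset_age`` (below onset the OR is 1 under hard gating).
    """

    n_patients: int
    carrier_prevalence: float
    baseline_probs: dict[str, float]
    carrier_odds_ratios: dict[str, float]
    confirmed_noncarrier_fraction: float = 0.5
    age_mean: float = 65.0
    age_sd: float = 17.0
    penetrance_onset_age: float = 60.0
    age_gating: str = "hard"  # or "logistic"
    age_ramp_years: float = 5.0
    codes_per_feature_lambda: float = 1.5
    reference_year: int = 2024
    race_ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: {
            "BLACK OR AFRICAN AMERICAN": 0.22,
            "HISPANIC OR LATINO": 0.18,
            "WHITE": 0.29,
            "OTHERS": 0.31,
        }
    )
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"Female": 0.59, "Male": 0.41}
    )
    seed: int = 0

    def validate(self, fmap: FeatureMap) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not (0 <= self.carrier_prevalence < 1):
            raise ValidationError("carrier_prevalence must be in [0, 1)")
        if not (0 <= self.confirmed_noncarrier_fraction <= 1):
            raise ValidationError("confirmed_noncarrier_fraction must be in [0, 1]")
        if self.age_gating not in ("hard", "logistic"):
            raise ValidationError("age_gating must be 'hard' or 'logistic'")
        ids = set(fmap.feature_ids)
        for name, table in (("baseline_probs", self.baseline_probs),
                            ("carrier_odds_ratios", self.carrier_odds_ratios)):
            if set(table) != ids:
                raise ValidationError(
                    f"{name} keys do not match the feature map "
                    f"(missing {sorted(ids - set(table))[:5]}, "
                    f"extra {sorted(set(table) - ids)[:5]})"
                )
        for fid, p in self.baseline_probs.items():
            if not (0 < p < 1):
                raise ValidationError(f"baseline_probs[{fid!r}] must be in (0, 1)")
        for fid, r in self.carrier_odds_ratios.items():
            if r <= 0:
                raise ValidationError(f"carrier_odds_ratios[{fid!r}] must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SynthCohort:
    """Generated tables plus the latent truth used only by oracle tests."""

    diagnoses: pd.DataFrame
    demographics: pd.DataFrame
    genotypes: pd.Series
    truth: pd.DataFrame  # patients x features latent presence indicators

    @property
    def patients(self) -> pd.Index:
        return self.demographics.index


def generate_cohort(config: SynthConfig, fmap: FeatureMap) -> SynthCohort:
    """Simulate one cohort under ``config``; deterministic given its seed."""
    config.validate(fmap)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    feature_ids = fmap.feature_ids

    patient_ids = pd.Index([f"S{i:06d}" for i in range(n)], name="patient_id")

    carrier = rng.random(n) < config.carrier_prevalence

    lo, hi = 18.0, 100.0
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    ages = np.floor(
        stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                            size=n, random_state=rng)
    ).astype(int)
    birth_year = config.reference_year - ages

    # age gate on the carrier effect: multiplier on the log-odds-ratio
    if config.age_gating == "hard":
        gate = (ages >= config.penetrance_onset_age).astype(float)
    else:
        gate = 1.0 / (1.0 + np.exp(-(ages - config.penetrance_onset_age)
                                   / config.age_ramp_years))

    presence = np.zeros((n, len(feature_ids)), dtype=np.int8)
    for j, fid in enumerate(feature_ids):
        p0 = config.baseline_probs[fid]
        log_odds = np.log(p0 / (1 - p0)) + carrier * gate * np.log(
            config.carrier_odds_ratios[fid]
        )
        p = 1.0 / (1.0 + np.exp(-log_odds))
        presence[:, j] = rng.random(n) < p
    truth = pd.DataFrame(presence, index=patient_ids, columns=feature_ids)

    diagnoses = _emit_events(rng, config, fmap, presence, birth_year, patient_ids)

    race = rng.choice(list(config.race_ethnicity_probs),
                      p=_normed(config.race_ethnicity_probs), size=n)
    sex = rng.choice(list(config.sex_probs), p=_normed(config.sex_probs), size=n)
    demographics = pd.DataFrame(
        {"birth_year": birth_year, "sex": sex, "race_ethnicity": race},
        index=patient_ids,
    )

    confirmed = rng.random(n) < config.confirmed_noncarrier_fraction
    status = np.where(carrier, "carrier",
                      np.where(confirmed, "noncarrier_confirmed", "unknown"))
    genotypes = pd.Series(status, index=patient_ids, name="status")

    return SynthCohort(diagnoses, demographics, genotypes, truth)


def _normed(probs: dict[str, float]) -> np.ndarray:
    p = np.asarray(list(probs.values()), dtype=float)
    return p / p.sum()


def _emit_events(rng, config, fmap, presence, birth_year, patient_ids) -> pd.DataFrame:
    """Raw diagnosis events for every present (patient, feature) pair."""
    pi_idx, fi_idx = np.nonzero(presence)
    if pi_idx.size == 0:
        return pd.DataFrame(
            {"patient_id": pd.Series(dtype=str),
             "icd_code": pd.Series(dtype=str),
             "icd_version": pd.Series(dtype=int),
             "event_date": pd.Series(dtype="datetime64[ns]")}
        )
    counts = 1 + rng.poisson(config.codes_per_feature_lambda, size=pi_idx.size)
    rep_p = np.repeat(pi_idx, counts)
    rep_f = np.repeat(fi_idx, counts)

    # dates uniform over adult years (calendar-year resolution of adulthood)
    start_ord = np.array(
        [_dt.date(int(y) + 18, 1, 1).toordinal() for y in birth_year]
    )
    end_ord = _dt.date(config.reference_year, 12, 31).toordinal()
    ev_ord = rng.integers(start_ord[rep_p], end_ord + 1)
    dates = pd.to_datetime(ev_ord - _EPOCH_ORDINAL, unit="D")

    code_arrays = []
    for f in fmap.features:
        ordered = sorted(f.codes, key=lambda cv: (cv[1], cv[0]))
        code_arrays.append(
            (np.array([c for c, _ in ordered]), np.array([v for _, v in ordered]))
        )
    codes = np.empty(rep_p.size, dtype=object)
    versions = np.empty(rep_p.size, dtype=int)
    for j in range(len(fmap.features)):
        mask = rep_f == j
        if not mask.any():
            continue
        code_str, code_ver = code_arrays[j]
        pick = rng.integers(0, len(code_str), size=int(mask.sum()))
        codes[mask] = code_str[pick]
        versions[mask] = code_ver[pick]

    return pd.DataFrame(
        {
            "patient_id": patient_ids.to_numpy()[rep_p],
            "icd_code": codes,
            "icd_version": versions,
            "event_date": dates,
        }
    )


def write_cohort(cohort: SynthCohort, outdir) -> dict[str, Path]:
    """Write the cohort in the exact CSV dialects the ingestion layer reads.

    The latent truth table goes to its own file; it exists for oracle
    tests only and is never an input to scoring or evaluation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "diagnoses": outdir / "diagnoses.csv",
        "demographics": outdir / "demographics.csv",
        "genotypes": outdir / "genotypes.csv",
        "truth": outdir / "truth.csv",
    }
    ehr_io.write_diagnoses(cohort.diagnoses, paths["diagnoses"])
    ehr_io.write_demographics(cohort.demographics, paths["demographics"])
    ehr_io.write_genotypes(cohort.genotypes, paths["genotypes"])
    cohort.truth.rename_axis("patient_id").reset_index().to_csv(paths["truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# bundled preset
# ---------------------------------------------------------------------------

#: (feature_id, human label, baseline presence probability, carrier OR above onset)
#: Baselines are order-of-magnitude realistic adult health-system lifetime
#: frequencies for each manifestation; ORs reflect a strongly but
#: incompletely penetrant cardiac amyloidosis-like profile.
_PRESET_FEATURES: list[tuple[str, str, float, float]] = [
    ("heart_failure", "Heart failure", 0.120, 3.5),
    ("cardiomyopathy", "Cardiomyopathy", 0.020, 6.0),
    ("atrial_fibrillation", "Atrial fibrillation / flutter", 0.080, 3.0),
    ("carpal_tunnel", "Carpal tunnel syndrome", 0.030, 5.0),
    ("polyneuropathy", "Polyneuropathy", 0.035, 5.0),
    ("conduction_disorder", "Cardiac conduction disorder", 0.025, 4.0),
    ("orthostatic_hypotension", "Orthostatic hypotension", 0.015, 4.5),
    ("other_arrhythmia", "Other cardiac arrhythmia", 0.060, 3.0),
    ("pleural_effusion", "Pleural effusion", 0.030, 3.5),
    ("spinal_stenosis", "Lumbar spinal stenosis", 0.025, 3.5),
    ("biceps_tendon_rupture", "Spontaneous biceps tendon rupture", 0.003, 8.0),
    ("gi_dysmotility", "Gastrointestinal dysmotility", 0.020, 4.0),
    ("peripheral_edema", "Peripheral edema", 0.070, 3.0),
    ("cardiomegaly", "Cardiomegaly", 0.015, 4.5),
    ("heart_block", "Atrioventricular block", 0.010, 5.0),
    ("autonomic_neuropathy", "Autonomic neuropathy", 0.005, 7.0),
    ("proteinuria", "Proteinuria / nephropathy", 0.030, 3.0),
    ("vitreous_opacity", "Vitreous opacities", 0.002, 8.0),
    ("restrictive_cm", "Restrictive cardiomyopathy", 0.002, 8.0),
    ("dyspnea", "Dyspnea", 0.100, 3.0),
    ("cachexia", "Unintentional weight loss / cachexia", 0.020, 4.0),
]

#: feature flagged as the heart-failure-like phenotype for stratified runs
PRESET_HF_FEATURE = "heart_failure"


def attrv_like_preset(n_patients: int = 35_000, seed: int = 0) -> tuple[SynthConfig, FeatureMap]:
    """Self-consistent config + feature map echoing a hereditary-amyloidosis
    case-finding study: 21 phenotype features over 292 codes, carrier
    prevalence 0.013, penetrance onset at age 60, every carrier odds ratio
    >= 3 above onset.

    The map is **synthetic**: code strings (``SYN####``) carry no real ICD
    semantics and exist only so the full pipeline — ingestion, hierarchy
    handling, presence, weighting, scoring, stratification — runs on data
    with the right shape and magnitudes.
    """
    features: list[PhenotypeFeature] = []
    baseline: dict[str, float] = {}
    odds_ratio: dict[str, float] = {}
    # 19 features x 14 codes + 2 x 13 = 292 codes total
    for i, (fid, name, p0, orr) in enumerate(_PRESET_FEATURES):
        n_codes = 13 if fid in ("vitreous_opacity", "restrictive_cm") else 14
        codes = frozenset(
            (f"SYN{i:02d}{j:02d}", 9 if j % 2 == 0 else 10) for j in range(n_codes)
        )
        features.append(PhenotypeFeature(fid, name, codes))
        baseline[fid] = p0
        odds_ratio[fid] = orr
    fmap = FeatureMap("attrv_like_synthetic", features)

    config = SynthConfig(
        n_patients=n_patients,
        carrier_prevalence=0.013,
        baseline_probs=baseline,
        carrier_odds_ratios=odds_ratio,
        confirmed_noncarrier_fraction=0.5,
        age_mean=65.0,
        age_sd=17.0,
        penetrance_onset_age=60.0,
        codes_per_feature_lambda=1.5,
        seed=seed,
    )
    return config, fmap


def null_config(config: SynthConfig) -> SynthConfig:
    """Zero-effect copy of a config: every carrier odds ratio set to 1.

    Useful for calibration checks — under this config carrier status is
    independent of every phenotype.
    """
    return replace(config, carrier_odds_ratios={k: 1.0 for k in config.carrier_odds_ratios})
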