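"""Phenotype feature maps: expert-curated groups of ICD codes.

A *feature* (phenotype) is a named set of version-qualified ICD codes that
together represent one clinical manifestation, e.g. carpal tunnel syndrome
or heart failure. A :class:`FeatureMap` is the ordered collection of
features defining one disease's phenotypic profile. A patient *has* a
feature if at least one of the feature's codes appears anywhere in their
record (lifetime presence; no time window).

Hierarchy expansion works against a user-supplied :class:`CodeCatalog` —
the set of codes that actually exist in the user's coding-system extract.
A code ``B`` is a descendant of seed ``A`` when both share the ICD version
and the normalised string of ``B`` starts with that of ``A``; this
reproduces the dot-hierarchy semantics of ICD without bundling licensed
tabular data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr_io import ICD_VERSIONS, normalize_icd
from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

Code = tuple[str, int]  # (normalised code string, ICD version)


@dataclass(frozen=True)
class PhenotypeFeature:
    """One clinical feature: a non-empty set of (code, version) pairs."""

    feature_id: str
    feature_name: str
    codes: frozenset[Code]

    def __post_init__(self):
        if not self.codes:
            raise ValidationError(f"feature {self.feature_id!r} has an empty code set")


@dataclass
class FeatureMap:
    """Ordered collection of phenotype features for one disease.

    By default (``strict``) no (code, version) pair may belong to more than
    one feature; overlaps can be permitted explicitly, in which case they
    are logged rather than silently accepted.
    """

    disease_name: str
    features: list[PhenotypeFeature] = field(default_factory=list)

    def __post_init__(self):
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate feature_id(s): {dupes}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> PhenotypeFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def __contains__(self, feature_id: str) -> bool:
        return any(f.feature_id == feature_id for f in self.features)

    # -- derived views -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def n_codes(self) -> int:
        return sum(len(f.codes) for f in self.features)

    def all_codes(self) -> set[Code]:
        out: set[Code] = set()
        for f in self.features:
            out |= f.codes
        return out

    def code_to_feature(self) -> dict[Code, str]:
        """Mapping (code, version) -> feature_id; later features win overlaps."""
        lookup: dict[Code, str] = {}
        for f in self.features:
            for c in f.codes:
                lookup[c] = f.feature_id
        return lookup

    def check_disjoint(self, strict: bool = True) -> list[Code]:
        """Return codes appearing in >1 feature; raise in strict mode."""
        seen: dict[Code, str] = {}
        overlaps: list[Code] = []
        for f in self.features:
            for c in f.codes:
                if c in seen and seen[c] != f.feature_id:
                    overlaps.append(c)
                seen[c] = f.feature_id
        if overlaps:
            if strict:
                raise ValidationError(
                    f"code(s) shared across features (strict mode): {sorted(overlaps)[:10]}"
                )
            logger.warning(
                "feature map %r: %d code(s) appear in more than one feature",
                self.disease_name,
                len(overlaps),
            )
        return overlaps


@dataclass(frozen=True)
class CodeCatalog:
    """All (code, version) pairs that exist in the user's coding extract."""

    entries: frozenset[Code]

    def __post_init__(self):
        if not self.entries:
            raise ValidationError("code catalog is empty")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs) -> "CodeCatalog":
        return cls(frozenset((normalize_icd(c, v), v) for c, v in pairs))

    @classmethod
    def from_csv(cls, path) -> "CodeCatalog":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("version", "code"):
            if col not in df.columns:
                raise SchemaError(f"{path}: catalog CSV needs columns version,code")
        return cls.from_pairs(zip(df["code"], pd.to_numeric(df["version"]).astype(int)))


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def load_feature_map(path, strict: bool = True) -> FeatureMap:
    """Load a feature map from JSON (nested) or CSV (long format).

    JSON schema::

        {"disease_name": str,
         "features": [{"feature_id": str, "feature_name": str,
                       "codes": [{"version": 9|10, "code": str}]}]}

    CSV columns: ``feature_id,feature_name,icd_version,code`` (one code per
    row). Codes are normalised on load; in strict mode a code shared by two
    features is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        fmap = _load_feature_map_json(path)
    else:
        fmap = _load_feature_map_csv(path)
    fmap.check_disjoint(strict=strict)
    logger.info(
        "loaded feature map %r: %d features, %d codes",
        fmap.disease_name, len(fmap), fmap.n_codes,
    )
    return fmap


def _load_feature_map_json(path) -> FeatureMap:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    features = []
    for feat in doc.get("features", []):
        codes = frozenset(
            (normalize_icd(c["code"], int(c["version"])), int(c["version"]))
            for c in feat["codes"]
        )
        features.append(
            PhenotypeFeature(feat["feature_id"], feat.get("feature_name", feat["feature_id"]), codes)
        )
    return FeatureMap(doc.get("disease_name", path.stem), features)


def _load_feature_map_csv(path) -> FeatureMap:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["feature_id", "feature_name", "icd_version", "code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: feature-map CSV missing column(s) {missing}")
    features = []
    for fid, grp in df.groupby("feature_id", sort=False):
        codes = frozenset(
            (normalize_icd(code, int(ver)), int(ver))
            for code, ver in zip(grp["code"], pd.to_numeric(grp["icd_version"]).astype(int))
        )
        features.append(PhenotypeFeature(str(fid), str(grp["feature_name"].iloc[0]), codes))
    return FeatureMap(Path(path).stem, features)


def save_feature_map(fmap: FeatureMap, path) -> None:
    """Serialise a feature map to the JSON schema read by :func:`load_feature_map`."""
    doc = {
        "disease_name": fmap.disease_name,
        "features": [
            {
                "feature_id": f.feature_id,
                "feature_name": f.feature_name,
                "codes": [
                    {"version": v, "code": c} for c, v in sorted(f.codes, key=lambda cv: (cv[1], cv[0]))
                ],
            }
            for f in fmap.features
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# hierarchy expansion and disease-code exclusion
# ---------------------------------------------------------------------------

def expand_hierarchy(seed_codes, catalog: CodeCatalog) -> set[Code]:
    """Expand seed codes to all catalog descendants (string-prefix rule).

    A catalog entry matches a seed when it shares the ICD version and its
    normalised code string starts with the seed's. A seed present in the
    catalog is included itself; a seed absent from the catalog contributes
    only its descendants (with a warning if it has none).
    """
    if not catalog.entries:
        raise ValidationError("cannot expand against an empty catalog")
    out: set[Code] = set()
    for code, version in seed_codes:
        hits = {
            (c, v) for c, v in catalog.entries if v == version and c.startswith(code)
        }
        if not hits:
            warnings.warn(
                f"seed code ({code!r}, v{version}) matched nothing in the catalog",
                UserWarning,
                stacklevel=2,
            )
        out |= hits
    return out


def exclude_disease_codes(
    fmap: FeatureMap, disease_seed_codes, catalog: CodeCatalog
) -> FeatureMap:
    """Remove a disease's own diagnosis codes (and descendants) from a map.

    Scoring a disease with codes that directly encode its diagnosis would
    leak the label; this removes ``expand_hierarchy(disease_seed_codes)``
    from every feature. Features left without codes are dropped with a
    warning. The input map is not modified.
    """
    excluded = expand_hierarchy(disease_seed_codes, catalog)
    kept: list[PhenotypeFeature] = []
    for f in fmap.features:
        remaining = f.codes - excluded
        if not remaining:
            warnings.warn(
                f"feature {f.feature_id!r} lost all its codes to disease-code "
                "exclusion and was dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        kept.append(replace(f, codes=frozenset(remaining)) if remaining != f.codes else f)
    return FeatureMap(fmap.disease_name, kept)


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

def presence_matrix(diagnoses: pd.DataFrame, fmap: FeatureMap, patients) -> pd.DataFrame:
    """Binary patients x features phenotype-presence matrix.

    Entry (i, p) is 1 iff patient i has at least one diagnosis whose
    (code, version) belongs to feature p. Duplicate events have no effect;
    patients with no mapped diagnoses get an all-zero row. Diagnoses of
    patients outside ``patients`` are ignored.
    """
    index = pd.Index(patients, name="patient_id")
    if index.has_duplicates:
        raise ValidationError("patient list for presence_matrix contains duplicates")
    mat = pd.DataFrame(0, index=index, columns=fmap.feature_ids, dtype=np.int8)
    if len(diagnoses) == 0 or len(fmap) == 0:
        return mat

    lookup = fmap.code_to_feature()
    keys = pd.MultiIndex.from_arrays(
        [diagnoses["icd_code"], diagnoses["icd_version"]]
    )
    feature_of = pd.Series(lookup)
    feature_of.index = pd.MultiIndex.from_tuples(feature_of.index)
    hit = pd.DataFrame(
        {
            "patient_id": diagnoses["patient_id"].to_numpy(),
            "feature_id": feature_of.reindex(keys).to_numpy(),
        }
    ).dropna()
    hit = hit[hit["patient_id"].isin(index)]
    if len(hit):
        pairs = hit.drop_duplicates()
        mat_np = mat.to_numpy()
        row = index.get_indexer(pairs["patient_id"])
        col = pd.Index(fmap.feature_ids).get_indexer(pairs["feature_id"])
        mat_np[row, col] = 1
        mat = pd.DataFrame(mat_np, index=index, columns=fmap.feature_ids, dtype=np.int8)
    return mat
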