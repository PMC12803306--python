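"""Phenotype-risk-score weights and scoring.

The score follows the classic inverse-frequency construction: each
phenotype feature *p* receives weight

    w_p = log(1 / f_p)

where f_p is the feature's frequency in a dedicated *training* population
(disjoint from the cases and controls being scored), so rarer phenotypes
weigh more. A patient's score is the sum of weights over the features
present in their record.

Frequencies are continuity-corrected with a symmetric pseudocount ``a``:

    f_p = (c_p + a) / (n_train + 2 a)

with a = 0.5 by default, so that features never observed in training keep a
finite, large weight instead of being dropped — in expert-curated maps the
rare features are exactly the informative ones. With ``a = 0`` a
zero-count feature is an error.

Three scoring variants are supported:

``standard``
    score_i = sum of w_p over present, non-excluded features.
``negative_weights``
    additionally penalises absence: score_i = sum_{present} w_p
    + sum_{absent} log(1 - f_p); requires frequencies with f_p < 1.
``precomputed``
    same arithmetic as ``standard`` but with an externally supplied weight
    table (e.g. weights fitted in a different health system).

The logarithm base is configurable (natural log by default); changing it
rescales every score by a constant and leaves rankings, AUC and
precision-at-k untouched.

The estimator :class:`PheRSScorer` is the primary interface and follows
scikit-learn conventions (``fit`` on the training presence matrix,
``score_samples``/``transform`` on the cohort to score, ``get_params`` /
``set_params``, trailing-underscore fitted attributes). The module-level
functions :func:`fit_weights` and :func:`score_cohort` are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import SchemaError, ValidationError

VARIANTS = ("standard", "negative_weights", "precomputed")


@dataclass
class WeightTable:
    """Per-feature weights, with training frequencies when fitted.

    ``table`` is indexed by feature_id with columns ``weight`` and
    ``frequency`` (``frequency`` is NaN for precomputed tables that omit
    it, which disables the negative-weights variant).
    """

    table: pd.DataFrame
    n_train: int | None = None
    pseudocount: float | None = None
    provenance: str = "fitted"
    log_base: float = math.e

    def __post_init__(self):
        if "weight" not in self.table.columns:
            raise SchemaError("weight table needs a 'weight' column")
        if "frequency" not in self.table.columns:
            self.table = self.table.assign(frequency=np.nan)
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValidationError(f"duplicate feature_id(s) in weight table: {dupes}")
        if self.provenance not in ("fitted", "precomputed"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]

    @property
    def frequencies(self) -> pd.Series:
        return self.table["frequency"]

    @property
    def has_frequencies(self) -> bool:
        return bool(self.table["frequency"].notna().all())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        if self.n_train is not None:
            out["n_train"] = self.n_train
        out.rename_axis("feature_id").reset_index().to_csv(path, index=False)


@dataclass
class ScoreSet:
    """Per-patient scores plus the presence vectors behind them."""

    scores: pd.Series
    presence: pd.DataFrame
    variant: str
    excluded_features: frozenset[str] = field(default_factory=frozenset)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.scores.index, "score": self.scores.to_numpy(),
             "variant": self.variant}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class PheRSScorer(TransformerMixin, BaseEstimator):
    """Inverse-log-frequency phenotype risk scorer.

    Parameters
    ----------
    variant : {'standard', 'negative_weights', 'precomputed'}
        Scoring rule; see the module docstring. ``precomputed`` requires
        construction via :meth:`from_weight_table`.
    pseudocount : float, default 0.5
        Symmetric continuity correction added to feature counts when
        fitting frequencies. Must be >= 0.
    log_base : float, default e
        Base of the logarithm in ``w = log(1/f)``.
    excluded_features : tuple of str, default ()
        Feature ids that contribute nothing to the score under any
        variant (e.g. the heart-failure feature when deploying among
        heart-failure patients, to avoid circularity).

    Attributes
    ----------
    weight_table_ : WeightTable
        Fitted (or supplied) per-feature frequencies and weights.
    feature_names_in_ : ndarray of str
        Feature ids seen at fit time.
    n_features_in_ : int
    n_train_ : int or None
        Training-cohort size (None for precomputed tables without one).

    Examples
    --------
    >>> import pandas as pd
    >>> train = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 1, 1, 1]})
    >>> test = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
    >>> scorer = PheRSScorer(pseudocount=0).fit(train)
    >>> scorer.score_samples(test)  # w_a = ln 2, w_b = 0
    array([0.69314718, 0.        ])
    """

    def __init__(self, variant: str = "standard", pseudocount: float = 0.5,
                 log_base: float = math.e, excluded_features: tuple = ()):
        self.variant = variant
        self.pseudocount = pseudocount
        self.log_base = log_base
        self.excluded_features = excluded_features

    # -- fitting -------------------------------------------------------------
    def fit(self, X, y=None):
        """Estimate per-feature frequencies and weights from a training
        presence matrix ``X`` (n_train x n_features, binary)."""
        self._validate_params_()
        X = self._as_frame(X)
        n = len(X)
        if n == 0:
            raise ValidationError("training set is empty")
        a = float(self.pseudocount)
        counts = X.sum(axis=0).astype(float)
        if a == 0 and (counts == 0).any():
            zero = list(counts.index[counts == 0])
            raise ValidationError(
                f"feature(s) {zero} never occur in training and pseudocount is 0; "
                "their weight log(1/0) is undefined"
            )
        freq = (counts + a) / (n + 2 * a)
        weights = np.log(1.0 / freq) / math.log(self.log_base)
        self.weight_table_ = WeightTable(
            pd.DataFrame({"frequency": freq, "weight": weights}),
            n_train=n,
            pseudocount=a,
            provenance="fitted",
            log_base=self.log_base,
        )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.n_train_ = n
        return self

    @classmethod
    def from_weight_table(cls, weight_table: WeightTable, variant: str = "precomputed",
                          excluded_features: tuple = ()) -> "PheRSScorer":
        """Build an already-fitted scorer around an external weight table."""
        est = cls(variant=variant, excluded_features=excluded_features,
                  log_base=weight_table.log_base)
        est._validate_params_()
        est.weight_table_ = weight_table
        est.feature_names_in_ = np.asarray(weight_table.feature_ids, dtype=object)
        est.n_features_in_ = len(weight_table.feature_ids)
        est.n_train_ = weight_table.n_train
        return est

    # -- scoring ---------------------------------------------------------------
    def score_samples(self, X) -> np.ndarray:
        """Phenotype risk score for each row of the presence matrix ``X``."""
        check_is_fitted(self, "weight_table_")
        X = self._as_frame(X, default_names=self.feature_names_in_)
        excluded = frozenset(self.excluded_features or ())
        wt = self.weight_table_

        active = [c for c in X.columns if c not in excluded]
        missing = [c for c in active if c not in wt.table.index]
        if missing:
            raise ValidationError(
                f"feature(s) {missing} in the presence matrix have no weight "
                "(and are not excluded)"
            )
        P = X[active].to_numpy(dtype=float)
        w = wt.weights.loc[active].to_numpy(dtype=float)
        scores = P @ w
        if self.variant == "negative_weights":
            f = wt.frequencies.loc[active].to_numpy(dtype=float)
            if np.isnan(f).any():
                raise ValidationError(
                    "negative_weights variant needs per-feature frequencies; "
                    "this weight table does not carry them"
                )
            if (f >= 1).any():
                raise ValidationError(
                    "negative_weights variant undefined for features with "
                    "frequency 1 (log(1-f) diverges)"
                )
            absence = np.log1p(-f) / math.log(self.log_base)
            scores = scores + (1.0 - P) @ absence
        return scores

    def transform(self, X) -> np.ndarray:
        """Scores as an (n, 1) column, for pipeline composition."""
        return self.score_samples(X).reshape(-1, 1)

    def score_cohort(self, X) -> ScoreSet:
        """Score a presence DataFrame, keeping patient ids and provenance."""
        X = self._as_frame(X)
        scores = pd.Series(self.score_samples(X), index=X.index, name="score")
        return ScoreSet(scores, X, self.variant, frozenset(self.excluded_features or ()))

    # -- helpers ---------------------------------------------------------------
    def _validate_params_(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.log_base <= 1:
            raise ValidationError("log_base must be > 1")

    @staticmethod
    def _as_frame(X, default_names=None) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = np.asarray(X)
            if arr.ndim != 2:
                raise ValidationError("presence matrix must be 2-dimensional")
            cols = default_names if default_names is not None else [
                f"x{i}" for i in range(arr.shape[1])
            ]
            frame = pd.DataFrame(arr, columns=list(cols))
        bad = ~frame.isin([0, 1]).all()
        if bad.any():
            raise ValidationError(
                f"presence matrix must be binary; non-binary column(s) "
                f"{list(frame.columns[bad])[:5]}"
            )
        return frame


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_weights(presence: pd.DataFrame, training_ids, pseudocount: float = 0.5,
                log_base: float = math.e) -> WeightTable:
    """Fit a weight table on the training rows of a presence matrix.

    ``training_ids`` must be a non-empty subset of ``presence.index``.
    """
    ids = pd.Index(training_ids)
    if len(ids) == 0:
        raise ValidationError("training set is empty")
    missing = ids.difference(presence.index)
    if len(missing):
        raise ValidationError(
            f"training id(s) absent from the presence matrix: {list(missing[:5])}"
        )
    est = PheRSScorer(pseudocount=pseudocount, log_base=log_base).fit(presence.loc[ids])
    return est.weight_table_


def score_cohort(presence: pd.DataFrame, weights: WeightTable,
                 variant: str = "standard", excluded_features=()) -> ScoreSet:
    """Score every row of a presence matrix under a given variant."""
    est = PheRSScorer.from_weight_table(
        weights, variant=variant, excluded_features=tuple(excluded_features)
    )
    return est.score_cohort(presence)


def load_precomputed_weights(path) -> WeightTable:
    """Load an externally computed weight table from CSV.

    Header ``feature_id,weight[,frequency[,n_train]]``; frequency is
    optional but required later for the negative-weights variant.
    """
    df = pd.read_csv(path)
    for col in ("feature_id", "weight"):
        if col not in df.columns:
            raise SchemaError(f"{path}: weight CSV needs columns feature_id,weight")
    if df["feature_id"].duplicated().any():
        dupes = sorted(df.loc[df["feature_id"].duplicated(), "feature_id"].unique())
        raise ValidationError(f"{path}: duplicate feature_id(s) {dupes}")
    weight = pd.to_numeric(df["weight"], errors="coerce")
    if weight.isna().any():
        raise ValidationError(f"{path}: non-numeric weight value(s)")
    table = pd.DataFrame(
        {"weight": weight.to_numpy()},
        index=pd.Index(df["feature_id"].astype(str), name="feature_id"),
    )
    if "frequency" in df.columns:
        table["frequency"] = pd.to_numeric(df["frequency"], errors="coerce").to_numpy()
    n_train = None
    if "n_train" in df.columns and df["n_train"].notna().any():
        n_train = int(pd.to_numeric(df["n_train"]).dropna().iloc[0])
    return WeightTable(table, n_train=n_train, provenance="precomputed")
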