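"""Ensemble presence/pseudo-absence model of sampling representativeness.

Only presences (field sampling locations) are observed, so an equal number of
pseudo-absences is drawn uniformly from domain pixels without a presence.
Three binary-probability learners — a smooth additive (GAM-type) logistic
model, a random forest, and gradient-boosted trees — are trained on the
presence/absence table after a pairwise-correlation screen (|r| < 0.70), and
their per-pixel *median* probability maps how well a pixel's environmental
conditions resemble those of sampled locations.  Probability > 0.5 classifies
conditions as "covered" by current sampling; performance is assessed by
repeated random 70/30 splits scored with ROC AUC.

The screen and ensemble follow the scikit-learn estimator API
(``fit`` / ``transform`` / ``predict_proba`` / ``get_params``) and compose
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer
from sklearn.utils.validation import check_is_fitted

from .raster import CovariateStack, RasterGrid, extract_at_points

__all__ = [
    "MODEL_COVARIATES",
    "PresenceAbsenceTable",
    "CVResult",
    "CollinearityFilter",
    "SamplingEnsemble",
    "make_pseudo_absences",
    "predict_map",
    "coverage_area",
    "auc",
    "cross_validate",
]

#: Covariates entering the representativeness model by default (climate,
#: soil, vegetation, biodiversity).
MODEL_COVARIATES: tuple[str, ...] = (
    "MAT", "MAP", "SOC", "LAI", "plant_rich", "animal_rich",
)


@dataclass
class PresenceAbsenceTable:
    """Rows of covariates with a binary label (1 presence, 0 pseudo-absence)."""

    frame: pd.DataFrame
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if "label" not in self.frame.columns:
            raise ValueError("frame must carry a 'label' column")
        missing = [c for c in self.covariates if c not in self.frame.columns]
        if missing:
            raise ValueError(f"frame missing covariates {missing}")
        if self.frame[list(self.covariates)].isna().any().any():
            raise ValueError("retained rows must have complete covariates")

    @property
    def n_presence(self) -> int:
        return int((self.frame["label"] == 1).sum())

    @property
    def n_absence(self) -> int:
        return int((self.frame["label"] == 0).sum())

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.covariates)]

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)


@dataclass
class CVResult:
    """AUC distribution over repeated random train/test splits."""

    auc_values: list[float]
    n_permutations: int
    train_fraction: float
    seed: int | None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def min_auc(self) -> float:
        return float(np.min(self.auc_values))

    @property
    def max_auc(self) -> float:
        return float(np.max(self.auc_values))

    def to_dict(self) -> dict:
        return {
            "auc_values": [float(a) for a in self.auc_values],
            "mean_auc": self.mean_auc,
            "min_auc": self.min_auc,
            "max_auc": self.max_auc,
            "n_permutations": self.n_permutations,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------

def make_pseudo_absences(
    stack: CovariateStack,
    presence_lon: Sequence[float],
    presence_lat: Sequence[float],
    seed: int | np.random.Generator | None = None,
    covariates: Sequence[str] = MODEL_COVARIATES,
    exclude_presence_cells: bool = True,
) -> PresenceAbsenceTable:
    """Build the balanced presence / pseudo-absence modeling table.

    Pseudo-absences are drawn uniformly without replacement from domain cells
    with complete covariates (and, by default, not containing any presence),
    in the same number as the retained presences.  Presences falling on
    missing covariates are dropped first so class parity holds exactly.
    """
    covariates = tuple(covariates)
    rng = np.random.default_rng(seed)
    ref = stack.reference
    pres = extract_at_points(stack, presence_lon, presence_lat, covariates)
    ok = pres[list(covariates)].notna().all(axis=1).to_numpy()
    pres = pres[ok].reset_index(drop=True)
    lon = np.asarray(presence_lon, dtype=float)[ok]
    lat = np.asarray(presence_lat, dtype=float)[ok]
    n = len(pres)
    if n == 0:
        raise ValueError("no presence rows with complete covariates")

    candidate = stack.complete_mask(covariates)
    if exclude_presence_cells:
        prow, pcol, inside = ref.index_of(lon, lat)
        candidate = candidate.copy()
        candidate[prow[inside], pcol[inside]] = False
    idx = np.flatnonzero(candidate)
    if idx.size < n:
        raise ValueError(
            f"only {idx.size} candidate absence cells for {n} presences"
        )
    chosen = rng.choice(idx, size=n, replace=False)
    arow, acol = np.unravel_index(chosen, ref.shape)
    absent = stack.values_at(arow, acol, covariates)

    pres_frame = pres[list(covariates)].copy()
    pres_frame["longitude"], pres_frame["latitude"] = lon, lat
    pres_frame["label"] = 1
    abs_frame = absent.copy()
    abs_frame["longitude"] = ref.lon_centers[acol]
    abs_frame["latitude"] = ref.lat_centers[arow]
    abs_frame["label"] = 0
    frame = pd.concat([pres_frame, abs_frame], ignore_index=True)
    return PresenceAbsenceTable(frame=frame, covariates=covariates)


# ---------------------------------------------------------------------------
# collinearity screen (sklearn transformer)
# ---------------------------------------------------------------------------

class CollinearityFilter(TransformerMixin, BaseEstimator):
    """Iteratively drop covariates until all pairwise |r| < threshold.

    Of an offending pair the member with the larger mean absolute correlation
    to all other retained covariates is dropped (ties: the later column).
    Constant columns have undefined correlations and are dropped with a
    warning.  Fitted attributes: ``retained_``, ``dropped_``, ``corr_``.
    """

    def __init__(self, threshold: float = 0.70):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least two covariates to screen")
        names = [str(c) for c in X.columns]
        X.columns = names
        dropped: list[str] = []

        const = [c for c in names if X[c].nunique(dropna=True) <= 1]
        if const:
            warnings.warn(
                f"dropping constant covariates {const} (undefined correlation)",
                stacklevel=2,
            )
            dropped.extend(const)
        retained = [c for c in names if c not in dropped]
        corr = X[retained].corr(method="pearson")
        self.corr_ = corr.copy()

        while len(retained) > 1:
            sub = corr.loc[retained, retained].abs().to_numpy()
            np.fill_diagonal(sub, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] < self.threshold:
                break
            mean_i = sub[i].sum() / (len(retained) - 1)
            mean_j = sub[j].sum() / (len(retained) - 1)
            victim = retained[j] if mean_j >= mean_i else retained[i]
            dropped.append(victim)
            retained = [c for c in retained if c != victim]

        self.retained_ = list(retained)
        self.dropped_ = dropped
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        return X[self.retained_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "retained_")
        return np.asarray(self.retained_, dtype=object)

    def report(self) -> dict:
        check_is_fitted(self, "retained_")
        return {
            "threshold": self.threshold,
            "retained": self.retained_,
            "dropped": self.dropped_,
            "correlation": {
                c: {d: float(self.corr_.loc[c, d]) for d in self.corr_.columns}
                for c in self.corr_.index
            },
        }


# ---------------------------------------------------------------------------
# ensemble classifier
# ---------------------------------------------------------------------------

class SamplingEnsemble(ClassifierMixin, BaseEstimator):
    """Median-probability ensemble of GAM-type, random-forest and boosted trees.

    Members:

    * a smooth additive logistic model (per-covariate B-spline basis with
      constant extrapolation, fitted by ridge-penalized logistic regression);
    * a random forest (``rf_n_estimators`` trees, default feature
      subsampling);
    * gradient-boosted trees (``gbt_n_estimators`` trees, learning rate
      ``gbt_learning_rate``, depth ``gbt_max_depth``).

    ``predict_proba`` returns the element-wise median of the three members'
    presence probabilities, which is therefore bounded by the member min and
    max.  All stochastic members derive their seeds from ``random_state``.
    """

    def __init__(
        self,
        gam_n_knots: int = 8,
        gam_degree: int = 3,
        gam_C: float = 1.0,
        rf_n_estimators: int = 500,
        gbt_n_estimators: int = 1000,
        gbt_learning_rate: float = 0.01,
        gbt_max_depth: int = 3,
        random_state: int | None = None,
    ):
        self.gam_n_knots = gam_n_knots
        self.gam_degree = gam_degree
        self.gam_C = gam_C
        self.rf_n_estimators = rf_n_estimators
        self.gbt_n_estimators = gbt_n_estimators
        self.gbt_learning_rate = gbt_learning_rate
        self.gbt_max_depth = gbt_max_depth
        self.random_state = random_state

    def _members(self):
        rs = self.random_state
        gam = make_pipeline(
            SplineTransformer(
                n_knots=self.gam_n_knots,
                degree=self.gam_degree,
                extrapolation="constant",
            ),
            LogisticRegression(C=self.gam_C, max_iter=2000),
        )
        rf = RandomForestClassifier(
            n_estimators=self.rf_n_estimators, random_state=rs, n_jobs=1
        )
        gbt = GradientBoostingClassifier(
            n_estimators=self.gbt_n_estimators,
            learning_rate=self.gbt_learning_rate,
            max_depth=self.gbt_max_depth,
            random_state=None if rs is None else rs + 1,
        )
        return {"gam": gam, "rf": rf, "gbt": gbt}

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        Xv = X.to_numpy(dtype=float)
        y = np.asarray(y)
        if not np.isfinite(Xv).all():
            raise ValueError("covariates must be finite")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present")
        if Xv.shape[0] < Xv.shape[1] + 1:
            raise ValueError("fewer rows than covariates + 1")
        self.members_ = {}
        for name, est in self._members().items():
            self.members_[name] = est.fit(Xv, y)
        return self

    def member_proba(self, X) -> pd.DataFrame:
        """Per-member presence probability, one column per member."""
        check_is_fitted(self, "members_")
        Xv = pd.DataFrame(X).to_numpy(dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} covariates, got {Xv.shape[1]}"
            )
        return pd.DataFrame(
            {name: est.predict_proba(Xv)[:, 1] for name, est in self.members_.items()}
        )

    def predict_proba(self, X):
        probs = self.member_proba(X).to_numpy()
        p = np.median(probs, axis=1)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p > 0.5).astype(int)]


# ---------------------------------------------------------------------------
# mapping, coverage, validation
# ---------------------------------------------------------------------------

def predict_map(
    model: SamplingEnsemble,
    stack: CovariateStack,
    covariates: Sequence[str] | None = None,
    chunk: int = 200_000,
) -> RasterGrid:
    """Ensemble median probability for every domain cell with full covariates."""
    names = list(covariates or getattr(model, "feature_names_in_", MODEL_COVARIATES))
    mask = stack.complete_mask(names)
    ref = stack.reference
    out = np.full(ref.shape, np.nan)
    rows, cols = np.nonzero(mask)
    for start in range(0, len(rows), chunk):
        r = rows[start : start + chunk]
        c = cols[start : start + chunk]
        X = stack.values_at(r, c, names)
        out[r, c] = model.predict_proba(X)[:, 1]
    return RasterGrid(
        out, x0=ref.x0, y0=ref.y0, dx=ref.dx, dy=ref.dy,
        name="representativeness", units="probability",
    )


def coverage_area(
    probability: RasterGrid,
    cell_areas: np.ndarray | RasterGrid | None = None,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Fraction and km2 of valid area with probability strictly above threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if cell_areas is None:
        areas = probability.cell_areas_km2()
    elif isinstance(cell_areas, RasterGrid):
        if not cell_areas.same_grid(probability):
            raise ValueError("cell-area grid is not co-registered")
        areas = cell_areas.data
    else:
        areas = np.asarray(cell_areas, dtype=float)
        if areas.shape != probability.shape:
            raise ValueError("cell-area grid shape mismatch")
    valid = probability.mask
    total = float(areas[valid].sum())
    covered = float(areas[valid & (probability.data > threshold)].sum())
    fraction = covered / total if total > 0 else 0.0
    return fraction, covered


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC: P(random positive outscores random negative), ties count half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cross_validate(
    table: PresenceAbsenceTable,
    model: SamplingEnsemble | None = None,
    n_perm: int = 99,
    train_frac: float = 0.7,
    seed: int | None = None,
) -> CVResult:
    """Repeated stratified random 70/30 splits scored with ensemble-median AUC.

    Each of the ``n_perm`` permutations refits a clone of ``model`` on the
    training fraction and computes AUC of the ensemble median probability on
    the held-out rows.  Stratification guarantees both classes in every
    partition.
    """
    if model is None:
        model = SamplingEnsemble(random_state=seed)
    X, y = table.X, table.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    splitter = StratifiedShuffleSplit(
        n_splits=n_perm, train_size=train_frac, random_state=seed
    )
    aucs: list[float] = []
    for k, (train, test) in enumerate(splitter.split(X, y)):
        member = clone(model)
        if model.random_state is not None:
            member.set_params(random_state=model.random_state + 1000 + 2 * k)
        member.fit(X.iloc[train], y[train])
        scores = member.predict_proba(X.iloc[test])[:, 1]
        aucs.append(auc(scores, y[test]))
    return CVResult(
        auc_values=aucs, n_permutations=n_perm,
        train_fraction=train_frac, seed=seed,
    )
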