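"""Two-step machine-learning model of capsule dissolution.

Step one is a ridge-stabilized logistic regression over (pressure, timing)
that predicts whether a stress event opens the capsule, returning the class
plus a confidence z = 100 * P(open).  Step two is a random-forest regressor
over long-format instances (class, pressure, timing, sampling time) that
predicts the dissolved amount at every sampling time; chaining the two yields
a full predicted dissolution profile for any stress condition.  The same pair
of models drives dense grid simulation over untested stress conditions and
the susceptibility map of z over the (timing, pressure) plane.

The training classes are typically linearly separable, so the unpenalized
logistic likelihood has no maximizer; a tiny ridge penalty plus an iteration
cap keeps the weights finite, at the price of a very sharp z transition
across the decision boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold

from .design import DesignMatrix
from .exceptions import (
    CVConfigError,
    DegenerateTrainingError,
    InputError,
    NotFittedError,
)
from .protocol import (
    ClassLabel,
    DissolutionProfile,
    labels_by_id,
    standard_sampling_schedule,
)

FEATURES = ("state", "pressure", "timing", "time_min")


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted logistic open/closed classifier with natural-unit weights.

    logit P(open) = intercept + w_pressure * p + w_timing * t
    """

    intercept: float
    w_pressure: float
    w_timing: float
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.intercept, self.w_pressure, self.w_timing])):
            raise NotFittedError("classifier weights must be finite")

    def prob_open(self, pressure, timing):
        logit = self.intercept + self.w_pressure * np.asarray(pressure) + self.w_timing * np.asarray(timing)
        return 1.0 / (1.0 + np.exp(-logit))

    def boundary_timing(self, pressure: float) -> float:
        """Timing at which P(open) = 0.5 for the given pressure (linear logit)."""
        if self.w_timing == 0:
            raise NotFittedError("timing weight is zero; no timing boundary exists")
        return -(self.intercept + self.w_pressure * pressure) / self.w_timing

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "w_pressure": self.w_pressure,
                    "w_timing": self.w_timing,
                    "ridge": self.ridge,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["intercept"], d["w_pressure"], d["w_timing"], d["ridge"])


def fit_classifier(
    design: DesignMatrix,
    labels: Iterable[ClassLabel],
    ridge: float = 1e-8,
    max_iter: int = 200,
) -> ClassifierModel:
    """Penalized-ML logistic fit of P(open | pressure, timing).

    Features are standardized internally for the optimizer; the reported
    weights are back-transformed to natural units (mbar, min).
    """
    lab = labels_by_id(labels)
    missing = [r.test_id for r in design if r.test_id not in lab]
    if missing:
        raise InputError(f"missing labels for runs: {missing}")
    X = np.asarray(design.settings(), dtype=float)
    y = np.array([1 if lab[r.test_id].is_open else 0 for r in design])
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    clf = LogisticRegression(C=1.0 / ridge, max_iter=max_iter, random_state=0)
    with warnings.catch_warnings():
        # Separable classes drive the weights to the iteration cap by design.
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xs, y)
    w = clf.coef_[0] / sd
    b = float(clf.intercept_[0] - np.dot(clf.coef_[0], mu / sd))
    return ClassifierModel(b, float(w[0]), float(w[1]), ridge=ridge)


def predict_open(model: ClassifierModel, pressure: float, timing: float) -> tuple[str, float]:
    """Class plus confidence z in [0, 100] on the open axis (z = 100 P(open);
    closed regions score near 0, open regions near 100).  Ties (P = 0.5) are
    assigned to open."""
    if not isinstance(model, ClassifierModel):
        raise NotFittedError("predict_open requires a fitted ClassifierModel")
    p = float(model.prob_open(pressure, timing))
    return ("open" if p >= 0.5 else "closed"), 100.0 * p


def build_training_table(
    profiles: Sequence[DissolutionProfile],
    labels: Iterable[ClassLabel],
    design: DesignMatrix,
) -> pd.DataFrame:
    """Long-format regression table: one instance per (run, sampling time)
    with features (state encoded open=1/closed=0, pressure, timing, time)
    and target dissolved %."""
    lab = labels_by_id(labels)
    runs = {r.test_id: r for r in design}
    rows = []
    for prof in profiles:
        if prof.test_id not in lab or prof.test_id not in runs:
            raise InputError(f"no label or design run for profile {prof.test_id!r}")
        run = runs[prof.test_id]
        state = 1 if lab[prof.test_id].is_open else 0
        for tm, dv in zip(prof.times, prof.dissolved):
            rows.append(
                {
                    "test_id": prof.test_id,
                    "state": state,
                    "pressure": run.stress.pressure,
                    "timing": run.stress.timing,
                    "time_min": float(tm),
                    "dissolved": float(dv),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RfParams:
    """Random-forest hyperparameters (bagged trees, one candidate feature per
    split, leaves grown to single instances, 100% bag fraction)."""

    n_trees: int = 5000
    max_features: int = 1
    min_samples_leaf: int = 1
    seed: int = 1


@dataclass(frozen=True)
class CvReport:
    """Grouped cross-validation summary; folds never split a run."""

    mae: float
    rmse: float
    n_folds: int
    fold_of_run: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True, eq=False)
class RfModel:
    """Fitted profile regressor; prediction is the ensemble mean."""

    params: RfParams
    regressor: RandomForestRegressor
    target_range: tuple[float, float]
    cv_report: CvReport | None = None

    def predict_values(self, state: int, pressure: float, timing: float,
                       times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        X = np.column_stack(
            [
                np.full_like(times, float(state)),
                np.full_like(times, float(pressure)),
                np.full_like(times, float(timing)),
                times,
            ]
        )
        return self.regressor.predict(X)


def _make_regressor(params: RfParams) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )


def fit_rf(
    table: pd.DataFrame, params: RfParams = RfParams(), cv_folds: int | None = 10
) -> RfModel:
    """Fit the random forest on a training table; optionally assess it with
    run-grouped k-fold cross-validation (MAE/RMSE over held-out runs).

    Raises CVConfigError when fewer distinct runs than folds are available;
    pass ``cv_folds=None`` to fit without cross-validation.
    """
    if table.empty:
        raise InputError("training table is empty")
    X = table.loc[:, ["state", "pressure", "timing", "time_min"]].to_numpy(dtype=float)
    y = table["dissolved"].to_numpy(dtype=float)
    groups = table["test_id"].to_numpy()

    cv_report = None
    if cv_folds is not None:
        n_runs = len(np.unique(groups))
        if n_runs < cv_folds:
            raise CVConfigError(f"{n_runs} runs cannot form {cv_folds} grouped folds")
        gkf = GroupKFold(n_splits=cv_folds)
        errors = np.empty_like(y)
        fold_of_run: dict[str, int] = {}
        for k, (tr, te) in enumerate(gkf.split(X, y, groups)):
            reg = _make_regressor(params)
            reg.fit(X[tr], y[tr])
            errors[te] = reg.predict(X[te]) - y[te]
            for run in np.unique(groups[te]):
                fold_of_run[str(run)] = k
        cv_report = CvReport(
            mae=float(np.mean(np.abs(errors))),
            rmse=float(np.sqrt(np.mean(errors**2))),
            n_folds=cv_folds,
            fold_of_run=fold_of_run,
        )

    reg = _make_regressor(params)
    reg.fit(X, y)
    return RfModel(params, reg, (float(y.min()), float(y.max())), cv_report)


def predict_profile(
    classifier: ClassifierModel,
    rf: RfModel,
    pressure: float,
    timing: float,
    sampling_times: Sequence[float] | None = None,
    test_id: str | None = None,
) -> tuple[DissolutionProfile, str, float]:
    """Two-step prediction: classify the stress condition, then regress the
    profile conditioned on the predicted class."""
    if not isinstance(rf, RfModel):
        raise NotFittedError("predict_profile requires a fitted RfModel")
    state, z = predict_open(classifier, pressure, timing)
    times = np.asarray(
        sampling_times if sampling_times is not None else standard_sampling_schedule(),
        dtype=float,
    )
    values = rf.predict_values(1 if state == "open" else 0, pressure, timing, times)
    tid = test_id if test_id is not None else f"sim p={pressure:g} t={timing:g}"
    return DissolutionProfile(tid, times, np.clip(values, 0.0, 110.0)), state, z


@dataclass(frozen=True)
class GridSpec:
    """Union of rectangular (pressures x timings) sub-grids; duplicate
    (pressure, timing) pairs across sub-grids are simulated once."""

    subgrids: tuple[tuple[tuple[float, ...], tuple[float, ...]], ...]

    def pairs(self) -> list[tuple[float, float]]:
        seen: dict[tuple[float, float], None] = {}
        for pressures, timings in self.subgrids:
            for p in pressures:
                for t in timings:
                    seen.setdefault((round(float(p), 9), round(float(t), 9)), None)
        return list(seen)


def default_grid_spec() -> GridSpec:
    """The study's customizable-stress grids: a pressure sweep (100-200 mbar
    in 20-mbar steps at 9 stress timings) and a timing sweep (9-15 min in
    0.5-min steps at 100, 160 and 200 mbar)."""
    pressure_sweep = (
        tuple(float(p) for p in range(100, 201, 20)),
        (9.0, 9.5, 10.0, 10.5, 11.0, 12.0, 13.0, 14.0, 15.0),
    )
    timing_sweep = (
        (100.0, 160.0, 200.0),
        tuple(9.0 + 0.5 * k for k in range(13)),
    )
    return GridSpec((pressure_sweep, timing_sweep))


@dataclass(frozen=True, eq=False)
class GridPrediction:
    pressure: float
    timing: float
    state: str
    z: float
    profile: DissolutionProfile


def simulate_grid(
    classifier: ClassifierModel, rf: RfModel, grid_spec: GridSpec
) -> list[GridPrediction]:
    """One predicted profile per distinct (pressure, timing) pair of the grid."""
    pairs = grid_spec.pairs()
    if not pairs:
        raise InputError("grid specification contains no points")
    out = []
    for p, t in pairs:
        prof, state, z = predict_profile(classifier, rf, p, t)
        out.append(GridPrediction(p, t, state, z, prof))
    return out


#: Profiles whose mean absolute difference stays below this many % of dose
#: are considered aligned.  10% is the classical f2 = 50 similarity boundary
#: used throughout dissolution testing.
ALIGNMENT_TOLERANCE = 10.0


def max_pairwise_mae(predictions: Sequence[GridPrediction]) -> float:
    """Largest mean absolute difference [% of dose] between any two predicted
    profiles of the collection; 0 for fewer than two profiles."""
    worst = 0.0
    for i, a in enumerate(predictions):
        for b in predictions[i + 1:]:
            worst = max(worst, float(np.mean(np.abs(a.profile.dissolved - b.profile.dissolved))))
    return worst


def grid_frame(predictions: Sequence[GridPrediction]) -> pd.DataFrame:
    rows = []
    for g in predictions:
        for tm, dv in zip(g.profile.times, g.profile.dissolved):
            rows.append(
                {
                    "pressure_mbar": g.pressure,
                    "timing_min": g.timing,
                    "state": g.state,
                    "z": g.z,
                    "time_min": float(tm),
                    "dissolved_pct": float(dv),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True, eq=False)
class SusceptibilityMap:
    """z = 100 P(open) over a rectangular (pressure, timing) grid;
    z[i, j] corresponds to (timings[i], pressures[j])."""

    pressures: np.ndarray
    timings: np.ndarray
    z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.timings):
            for j, p in enumerate(self.pressures):
                rows.append(
                    {"pressure_mbar": float(p), "timing_min": float(t), "z": float(self.z[i, j])}
                )
        return pd.DataFrame(rows)


def susceptibility_map(
    classifier: ClassifierModel,
    pressure_grid: Sequence[float],
    timing_grid: Sequence[float],
) -> SusceptibilityMap:
    """Capsule susceptibility toward stress events: per grid cell the
    confidence z that the condition opens the capsule (0 = surely closed,
    100 = surely open)."""
    pressures = np.asarray(pressure_grid, dtype=float)
    timings = np.asarray(timing_grid, dtype=float)
    tt, pp = np.meshgrid(timings, pressures, indexing="ij")
    z = 100.0 * np.asarray(classifier.prob_open(pp, tt), dtype=float)
    return SusceptibilityMap(pressures, timings, z)
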