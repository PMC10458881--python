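"""Per-timepoint quadratic response-surface model.

At every sampling time i the dissolved amount D_i is modeled as a full
quadratic in the stress factors, pressure p [mbar] and timing t [min]:

    D_i = b_i0 + b_i1 p + b_i2 t + b_i12 p t + b_i11 p^2 + b_i22 t^2

fitted by ordinary least squares on the basic-design runs.  Each coefficient
carries a two-sided t-test p-value; coefficients with p < 0.05 are flagged
significant.  Factors stay in natural units; columns are rescaled to unit
norm internally purely for conditioning (pure column scaling leaves the
natural-unit t statistics, hence p-values, unchanged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DesignMatrix
from .exceptions import InputError, NotFittedError, SingularFitError
from .protocol import DissolutionProfile

TERMS = ("intercept", "p", "t", "p:t", "p^2", "t^2")

ALPHA = 0.05


def _design_columns(pressure: np.ndarray, timing: np.ndarray) -> np.ndarray:
    p = np.asarray(pressure, dtype=float)
    t = np.asarray(timing, dtype=float)
    return np.column_stack([np.ones_like(p), p, t, p * t, p**2, t**2])


@dataclass(frozen=True)
class RsmModel:
    """Bank of fitted quadratics: one coefficient vector per sampling time."""

    sampling_times: tuple[float, ...]
    coefficients: np.ndarray  # (n_times, 6), natural units
    pvalues: np.ndarray  # (n_times, 6)

    @property
    def significant(self) -> np.ndarray:
        """Boolean flags, elementwise p-value < 0.05."""
        return self.pvalues < ALPHA

    def predict_raw(self, pressure: float, timing: float) -> np.ndarray:
        """Unclipped polynomial values at every sampling time (diagnostics)."""
        x = _design_columns(np.array([pressure]), np.array([timing]))[0]
        return self.coefficients @ x

    def to_json(self, path) -> None:
        payload = {
            "sampling_times": list(self.sampling_times),
            "terms": list(TERMS),
            "coefficients": self.coefficients.tolist(),
            "pvalues": self.pvalues.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RsmModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["sampling_times"]),
            np.asarray(payload["coefficients"], dtype=float),
            np.asarray(payload["pvalues"], dtype=float),
        )


def fit_rsm(profiles: Sequence[DissolutionProfile], design: DesignMatrix) -> RsmModel:
    """Fit the quadratic bank by OLS on the given runs (one profile per run).

    Center replicates enter as separate rows, preserving pure-error degrees
    of freedom.  Requires at least 7 runs (6 coefficients + 1 residual df)
    and a full-rank factor layout.
    """
    if len(profiles) != len(design):
        raise InputError(f"{len(profiles)} profiles for {len(design)} design runs")
    if len(design) < 7:
        raise InputError("need at least 7 runs to fit 6 coefficients with residual df")
    by_id = {p.test_id: p for p in profiles}
    if set(by_id) != {r.test_id for r in design}:
        raise InputError("profile test ids do not match the design")
    times = np.asarray(design[0].sampling_times, dtype=float)
    for p in profiles:
        if p.times.shape != times.shape or not np.allclose(p.times, times):
            raise InputError(f"profile {p.test_id} is not on the design's sampling schedule")

    settings = np.asarray(design.settings(), dtype=float)
    X = _design_columns(settings[:, 0], settings[:, 1])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("factor layout is rank deficient for the quadratic model")
    norms = np.linalg.norm(X, axis=0)
    Xs = X / norms

    Y = np.vstack([by_id[r.test_id].dissolved for r in design])  # (n_runs, n_times)
    coefs = np.empty((len(times), len(TERMS)))
    pvals = np.empty_like(coefs)
    for j in range(len(times)):
        res = sm.OLS(Y[:, j], Xs).fit()
        coefs[j] = res.params / norms
        pvals[j] = res.pvalues
    return RsmModel(tuple(times.tolist()), coefs, pvals)


def predict_rsm(model: RsmModel, pressure: float, timing: float,
                test_id: str = "rsm-prediction") -> DissolutionProfile:
    """Evaluate the polynomial bank at (pressure, timing); reported values are
    clipped to [0, 100] (use `model.predict_raw` for the unclipped values)."""
    if not isinstance(model, RsmModel):
        raise NotFittedError("predict_rsm requires a fitted RsmModel")
    raw = model.predict_raw(pressure, timing)
    if not np.all(np.isfinite(raw)):
        raise NotFittedError("model produced non-finite predictions; was it fitted?")
    return DissolutionProfile(
        test_id, np.asarray(model.sampling_times, dtype=float), np.clip(raw, 0.0, 100.0)
    )


def significance_table(model: RsmModel) -> pd.DataFrame:
    """Long-format table: one row per (sampling time, term)."""
    rows = []
    for i, tm in enumerate(model.sampling_times):
        for j, term in enumerate(TERMS):
            rows.append(
                {
                    "time_min": tm,
                    "term": term,
                    "coefficient": model.coefficients[i, j],
                    "p_value": model.pvalues[i, j],
                    "significant": bool(model.pvalues[i, j] < ALPHA),
                }
            )
    return pd.DataFrame(rows)
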