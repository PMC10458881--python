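"""Verification of predicted dissolution profiles against observed ones.

The apparatus delivers the medium through a peristaltic loop, so an observed
point carries flow-rate uncertainty: the amount observed at sampling time i
is bracketed by its neighbors, D_obs,i-1 to D_obs,i+1.  Replicate variability
is summarized as the maximal per-timepoint SD of the center-point replicates
within each of three profile sections (before the stress event, between
stress and gastric emptying, after gastric emptying).  The acceptance band
at point i is then [D_obs,i-1 - 2 SD_sec, D_obs,i+1 + 2 SD_sec]; predictions
are scored by the fraction of points falling outside their bands plus pooled
MAE and RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .exceptions import InputError
from .protocol import DissolutionProfile


class SectionSds(NamedTuple):
    """Maximal replicate SD per profile section [% of dose]."""

    before: float
    between: float
    after: float


def section_sd(
    center_profiles: Sequence[DissolutionProfile], is_timing: float, ge_time: float
) -> SectionSds:
    """Per-timepoint sample SD across replicates, maximized within each
    section.  Sections are half-open: [0, is_timing), [is_timing, ge_time),
    [ge_time, inf) — a sample exactly on a boundary belongs to the later
    section.  Requires >= 2 replicates on one shared schedule."""
    if len(center_profiles) < 2:
        raise InputError("need at least 2 replicate profiles")
    times = center_profiles[0].times
    for p in center_profiles[1:]:
        if p.times.shape != times.shape or not np.allclose(p.times, times):
            raise InputError("replicates must share one sampling schedule")
    values = np.vstack([p.dissolved for p in center_profiles])
    sds = values.std(axis=0, ddof=1)
    out = []
    for lo, hi in ((0.0, is_timing), (is_timing, ge_time), (ge_time, np.inf)):
        mask = (times >= lo) & (times < hi)
        out.append(float(sds[mask].max()) if mask.any() else 0.0)
    return SectionSds(*out)


def sd_at(sds: SectionSds, time: float, is_timing: float, ge_time: float) -> float:
    if time < is_timing:
        return sds.before
    if time < ge_time:
        return sds.between
    return sds.after


@dataclass(frozen=True, eq=False)
class AcceptanceBands:
    """Per-sampling-time acceptance interval for one observed profile."""

    test_id: str
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    is_timing: float
    ge_time: float

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise InputError("acceptance bands must satisfy lower <= upper")


def acceptance_bands(
    observed: DissolutionProfile, sds: SectionSds, is_timing: float, ge_time: float
) -> AcceptanceBands:
    """Band at point i: [D_obs,i-1 - 2 SD_sec(i), D_obs,i+1 + 2 SD_sec(i)],
    with the point's own value substituted for the missing neighbor at the
    first and last points; lower edges are floored at 0.

    Cumulative dissolution is monotone up to assay noise; where noise makes
    the observed pair locally decreasing the two neighbors are ordered first,
    which keeps every band non-empty and leaves monotone data untouched."""
    d = observed.dissolved
    prev = np.concatenate([[d[0]], d[:-1]])
    nxt = np.concatenate([d[1:], [d[-1]]])
    lo_neighbor = np.minimum(prev, nxt)
    hi_neighbor = np.maximum(prev, nxt)
    two_sd = 2.0 * np.array(
        [sd_at(sds, float(t), is_timing, ge_time) for t in observed.times]
    )
    lower = np.maximum(lo_neighbor - two_sd, 0.0)
    upper = hi_neighbor + two_sd
    return AcceptanceBands(observed.test_id, observed.times.copy(), lower, upper, is_timing, ge_time)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-test outside-band fractions plus pooled error metrics."""

    per_test_outside: dict[str, float] = field(default_factory=dict)
    outside_fraction: float = 0.0
    mae: float = 0.0
    rmse: float = 0.0
    n_points: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_test_outside": self.per_test_outside,
                    "outside_fraction": self.outside_fraction,
                    "mae": self.mae,
                    "rmse": self.rmse,
                    "n_points": self.n_points,
                },
                fh,
                indent=1,
            )


def evaluate_predictions(
    predicted: Sequence[DissolutionProfile],
    observed: Sequence[DissolutionProfile],
    bands: Mapping[str, AcceptanceBands],
) -> EvaluationReport:
    """Score predictions against observations and their acceptance bands.

    A point is outside when it lies strictly below the lower or strictly
    above the upper band edge.  MAE and RMSE pool every sampled point of
    every test into single values.
    """
    obs_by_id = {p.test_id: p for p in observed}
    if {p.test_id for p in predicted} != set(obs_by_id):
        raise InputError("predicted and observed test ids do not match")
    per_test: dict[str, float] = {}
    abs_err: list[np.ndarray] = []
    n_outside = 0
    n_total = 0
    for pred in predicted:
        obs = obs_by_id[pred.test_id]
        if pred.times.shape != obs.times.shape or not np.allclose(pred.times, obs.times):
            raise InputError(f"schedules differ for test {pred.test_id!r}")
        band = bands[pred.test_id]
        if not np.allclose(band.times, obs.times):
            raise InputError(f"bands for test {pred.test_id!r} are on a different schedule")
        outside = (pred.dissolved < band.lower) | (pred.dissolved > band.upper)
        per_test[pred.test_id] = float(outside.mean())
        n_outside += int(outside.sum())
        n_total += outside.size
        abs_err.append(np.abs(pred.dissolved - obs.dissolved))
    err = np.concatenate(abs_err)
    return EvaluationReport(
        per_test_outside=per_test,
        outside_fraction=n_outside / n_total,
        mae=float(err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        n_points=n_total,
    )
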