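"""Synthetic soft-capsule dissolution simulator.

A phenomenological generator standing in for wet-lab runs so the whole
modeling workflow is testable end to end.  It encodes the qualitative
behavior of a pressure-sensitive soft gelatin capsule in a gastric-phase
dissolution cell:

* a capsule *opens* during the stress event iff the applied pressure reaches
  a time-dependent threshold that decays as the shell softens in the medium
  (logistic in time: very early waves never open it, late waves always do);
* the recorded dissolved amount reacts with a ~2-min observation delay after
  any pressure event (sampling-site transit);
* an opened capsule releases drug first-order toward a pre-GE plateau below
  100% (apparent loss to local precipitation at gastric pH), at a slower rate
  when the pressure only marginally exceeded the threshold (partial shell
  disruption) than when it comfortably exceeded it (burst opening);
* a closed capsule only leaks a trace amount until gastric emptying;
* the GE burst at 30 min drives every curve first-order to complete
  dissolution;
* sampled profiles carry additive Gaussian assay noise, truncated to
  [0, 110] %.

The threshold parameters are fixtures chosen so the generator reproduces the
observed open/closed outcome of every run in the standard 20-run matrix; the
rate and plateau parameters are configuration knobs, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable

import numpy as np
from scipy.optimize import brentq

from .design import DesignMatrix
from .exceptions import InputError
from .protocol import (
    ClassLabel,
    DissolutionProfile,
    MAX_DISSOLVED,
    StressEvent,
    TestProtocol,
)

#: Runs of the standard matrix whose capsules stayed closed; all other
#: basic/additional/verification runs opened.
CLOSED_TESTS = frozenset({"Test 6", "Test 11", "Test 12", "Test 14"})


def reported_labels(design: DesignMatrix) -> list[ClassLabel]:
    """Observed open/closed outcomes for runs of the standard matrix,
    keyed by their standard test ids."""
    return [
        ClassLabel(r.test_id, "closed" if r.test_id in CLOSED_TESTS else "open")
        for r in design
    ]


@dataclass(frozen=True)
class CapsuleParams:
    """Generator configuration.

    The opening threshold [mbar] at stress time t [min] is
    ``threshold_floor + threshold_block / (1 + exp(threshold_steepness * (t - threshold_t50)))``:
    monotone non-increasing, ~``floor + block`` for early waves and ~``floor``
    for late ones.
    """

    threshold_t50: float = 9.9  # min; midpoint of the shell-softening transition
    threshold_steepness: float = 4.0  # 1/min
    threshold_floor: float = 60.0  # mbar; late-time threshold
    threshold_block: float = 200.0  # mbar; extra resistance at early times
    observation_delay: float = 2.0  # min between a pressure event and its sampled response
    release_rate_full: float = 0.5  # 1/min; burst-like opening
    release_rate_partial: float = 0.15  # 1/min; partial shell disruption
    partial_band: float = 40.0  # mbar margin above threshold below which opening is partial
    stiff_margin: float = 10.0  # mbar; partial opening only while threshold exceeds floor by more
    plateau_fraction: float = 0.70  # pre-GE asymptote as fraction of the dose
    ge_burst_rate: float = 0.35  # 1/min; post-GE approach to complete dissolution
    closed_leak: float = 1.0  # % of dose leaking from an intact capsule
    noise_sd: float = 2.7  # % of dose; additive assay noise
    seed: int = 0
    stochastic_boundary: bool = False  # Bernoulli opening near the threshold
    boundary_scale: float = 10.0  # mbar; logistic scale of the stochastic boundary

    def __post_init__(self) -> None:
        if min(self.release_rate_full, self.release_rate_partial, self.ge_burst_rate) <= 0:
            raise InputError("all release rates must be positive")
        if not 0 < self.plateau_fraction <= 1:
            raise InputError("plateau_fraction must lie in (0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


def opening_threshold(timing: float, params: CapsuleParams) -> float:
    """Minimum pressure [mbar] that opens the capsule at stress time `timing`."""
    z = params.threshold_steepness * (timing - params.threshold_t50)
    return params.threshold_floor + params.threshold_block / (1.0 + np.exp(z))


def threshold_crossing_timing(
    pressure: float, params: CapsuleParams, bracket: tuple[float, float] = (0.5, 29.5)
) -> float:
    """Earliest stress timing [min] at which `pressure` opens the capsule
    (root of threshold(t) = pressure); raises ValueError if never crossed
    inside `bracket`."""
    f = lambda t: opening_threshold(t, params) - pressure
    return float(brentq(f, *bracket))


def _opens(pressure: float, timing: float, params: CapsuleParams) -> bool:
    thr = opening_threshold(timing, params)
    if params.stochastic_boundary:
        # One reproducible draw per (seed, pressure, timing) so labels and
        # curves of the same run always agree.
        rng = np.random.default_rng(
            [params.seed, int(round(pressure * 1000)), int(round(timing * 1000))]
        )
        p_open = 1.0 / (1.0 + np.exp(-(pressure - thr) / params.boundary_scale))
        return bool(rng.random() < p_open)
    return pressure >= thr


def is_open(protocol: TestProtocol, params: CapsuleParams) -> ClassLabel:
    """Ground-truth open/closed label; deterministic under the default
    (non-stochastic) boundary."""
    state = "open" if _opens(protocol.stress.pressure, protocol.stress.timing, params) else "closed"
    return ClassLabel(protocol.test_id, state)


def _first_order(t: np.ndarray, t0: float, start: float, asymptote: float, rate: float) -> np.ndarray:
    return asymptote - (asymptote - start) * np.exp(-rate * (t - t0))


def true_curve(protocol: TestProtocol, params: CapsuleParams) -> Callable[[np.ndarray], np.ndarray]:
    """Noiseless dissolved-% curve for one protocol.

    Continuous, monotone non-decreasing, with limit 100 at large times.  The
    observation delay shifts both the post-stress rise and the post-GE burst.
    """
    opened = _opens(protocol.stress.pressure, protocol.stress.timing, params)
    base = min(params.closed_leak, MAX_DISSOLVED)
    t_ge = protocol.ge_time + params.observation_delay
    plateau = max(100.0 * params.plateau_fraction, base)
    if opened:
        # Gradual (partial-disruption) opening is a stiff-shell phenomenon:
        # it requires both a modest margin over the threshold and a shell
        # that has not yet softened (threshold still elevated above its
        # floor).  Once softened, any supra-threshold wave opens the capsule
        # fully, so late-stress profiles align regardless of pressure.
        thr = opening_threshold(protocol.stress.timing, params)
        shell_stiff = thr - params.threshold_floor > params.stiff_margin
        partial = shell_stiff and protocol.stress.pressure < thr + params.partial_band
        rate = params.release_rate_partial if partial else params.release_rate_full
        t_open = protocol.stress.timing + params.observation_delay

        def curve(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            pre_ge = np.where(
                t < t_open, base, _first_order(np.maximum(t, t_open), t_open, base, plateau, rate)
            )
            level_at_ge = (
                base
                if t_ge < t_open
                else float(_first_order(np.array([t_ge]), t_open, base, plateau, rate)[0])
            )
            post = _first_order(np.maximum(t, t_ge), t_ge, level_at_ge, 100.0, params.ge_burst_rate)
            return np.where(t < t_ge, pre_ge, post)

    else:

        def curve(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            post = _first_order(np.maximum(t, t_ge), t_ge, base, 100.0, params.ge_burst_rate)
            return np.where(t < t_ge, base, post)

    return curve


def simulate_profile(
    protocol: TestProtocol, params: CapsuleParams, replicate_seed: int = 0
) -> DissolutionProfile:
    """Sample the noiseless curve on the protocol's schedule and add
    independent N(0, noise_sd^2) assay noise, truncated to [0, 110] %.

    Reproducible for a fixed (params.seed, replicate_seed) pair.
    """
    times = np.asarray(protocol.sampling_times, dtype=float)
    values = true_curve(protocol, params)(times)
    if params.noise_sd > 0:
        rng = np.random.default_rng([params.seed, replicate_seed])
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, MAX_DISSOLVED)
    return DissolutionProfile(protocol.test_id, times, values)


def simulate_dataset(
    design: DesignMatrix, params: CapsuleParams
) -> tuple[list[DissolutionProfile], list[ClassLabel]]:
    """One noisy profile plus its ground-truth label per design run
    (replicate seed = run index)."""
    profiles = [simulate_profile(run, params, replicate_seed=i) for i, run in enumerate(design)]
    labels = [is_open(run, params) for run in design]
    return profiles, labels


def with_seed(params: CapsuleParams, seed: int) -> CapsuleParams:
    return replace(params, seed=int(seed))


def max_center_rsd(
    params: CapsuleParams,
    n_replicates: int = 5,
    mean_floor: float = 10.0,
) -> float:
    """Replicate variability statistic at the design center (150 mbar, 12 min):
    the maximum over sampling times of the relative SD [%] across
    `n_replicates` simulated replicates.

    Times whose replicate mean falls below `mean_floor` % of dose are
    excluded: with additive assay noise the relative SD at a near-zero mean
    is unbounded and carries no information about assay repeatability.
    """
    proto = TestProtocol("center", stress=StressEvent(timing=12.0, pressure=150.0))
    reps = [simulate_profile(proto, params, replicate_seed=i) for i in range(n_replicates)]
    values = np.vstack([r.dissolved for r in reps])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    mask = mean >= mean_floor
    return float(np.max(sd[mask] / mean[mask]) * 100.0)
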