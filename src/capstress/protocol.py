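"""Domain types for biorelevant dissolution test scenarios.

A scenario subjects an immediate-release capsule to a single intragastric
stress (IS) pressure wave of given timing [min] and magnitude [mbar] inside a
simulated gastric phase, followed by gastric emptying (GE, a pressure-wave
sequence plus elevated flow) at a fixed time, after which the medium is
intestinal and dissolution runs to completion.  Dissolved amounts are % of the
labeled dose sampled on a fixed schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InvalidProtocolError

#: Valid run-group tags.
GROUPS = ("basic", "additional", "verification", "simulated")

#: Gastric emptying time [min] used throughout the study design.
DEFAULT_GE_TIME = 30.0

#: Upper cap on a dissolved amount [%]; tolerates analytical overshoot.
MAX_DISSOLVED = 110.0


def standard_sampling_schedule() -> tuple[float, ...]:
    """Sampling times [min]: 3 and 6, every minute from 9 to 30, then every
    3 min up to 60 (34 points in total)."""
    early = (3.0, 6.0)
    gastric = tuple(float(m) for m in range(9, 31))
    intestinal = tuple(float(m) for m in range(33, 61, 3))
    return early + gastric + intestinal


@dataclass(frozen=True)
class StressEvent:
    """A single intragastric pressure wave."""

    timing: float  # min from test start
    pressure: float  # mbar

    def __post_init__(self) -> None:
        if not self.timing > 0:
            raise InvalidProtocolError(f"stress timing must be > 0, got {self.timing}")
        if not self.pressure > 0:
            raise InvalidProtocolError(f"stress pressure must be > 0, got {self.pressure}")


@dataclass(frozen=True)
class TestProtocol:
    """One dissolution scenario: stress event, GE time and sampling schedule."""

    test_id: str
    stress: StressEvent
    ge_time: float = DEFAULT_GE_TIME
    sampling_times: tuple[float, ...] = field(default_factory=standard_sampling_schedule)
    group: str = "simulated"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sampling_times)
        object.__setattr__(self, "sampling_times", times)
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidProtocolError("sampling_times must be strictly increasing")
        if not self.stress.timing < self.ge_time:
            raise InvalidProtocolError(
                f"stress at {self.stress.timing} min must precede gastric emptying "
                f"at {self.ge_time} min"
            )
        if not self.ge_time < times[-1]:
            raise InvalidProtocolError("gastric emptying must precede the last sample")
        if self.group not in GROUPS:
            raise InvalidProtocolError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass(frozen=True, eq=False)
class DissolutionProfile:
    """Paired sampling times [min] and dissolved amounts [% of dose] for one run."""

    test_id: str
    times: np.ndarray
    dissolved: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dissolved = np.asarray(self.dissolved, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "dissolved", dissolved)
        if times.shape != dissolved.shape or times.ndim != 1:
            raise InvalidProtocolError("times and dissolved must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise InvalidProtocolError("profile times must be strictly increasing")
        if np.any(dissolved < 0) or np.any(dissolved > MAX_DISSOLVED):
            raise InvalidProtocolError(f"dissolved amounts must lie in [0, {MAX_DISSOLVED}]")

    @property
    def samples(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.dissolved.tolist()))

    def allclose(self, other: "DissolutionProfile", atol: float = 1e-12) -> bool:
        return (
            self.test_id == other.test_id
            and np.allclose(self.times, other.times, atol=atol)
            and np.allclose(self.dissolved, other.dissolved, atol=atol)
        )


@dataclass(frozen=True)
class ClassLabel:
    """Observed or simulated capsule outcome: did the shell start disintegrating
    during the stress event (open) or stay intact until GE (closed)?"""

    test_id: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in ("open", "closed"):
            raise InvalidProtocolError(f"state must be 'open' or 'closed', got {self.state!r}")

    @property
    def is_open(self) -> bool:
        return self.state == "open"


def make_protocol(
    test_id: str,
    pressure: float,
    timing: float,
    group: str = "simulated",
    ge_time: float = DEFAULT_GE_TIME,
    sampling_times: Sequence[float] | None = None,
) -> TestProtocol:
    """Build a protocol with the standard schedule and GE at `ge_time`.

    Raises
    ------
    InvalidProtocolError
        If the stress does not precede gastric emptying, or any field is
        non-physical.
    """
    times = tuple(sampling_times) if sampling_times is not None else standard_sampling_schedule()
    return TestProtocol(
        test_id=test_id,
        stress=StressEvent(timing=float(timing), pressure=float(pressure)),
        ge_time=float(ge_time),
        sampling_times=times,
        group=group,
    )


def labels_by_id(labels: Iterable[ClassLabel]) -> dict[str, ClassLabel]:
    return {lab.test_id: lab for lab in labels}
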