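"""Design of the dissolution-test matrix.

The study space is two factors — intragastric stress pressure [mbar] and
timing [min] — covered by a *modified* central composite design (CCD): four
factorial points, four axial (star) points with a per-factor axial distance,
and replicated center runs interleaved through the run order.  The axial
distances differ between factors (pressure alpha = 70/50, timing alpha = 4/3),
so the generator takes explicit offsets rather than a single rotatability
alpha.  Three additional runs probe the critical 10-min timing, and four
verification runs at intermediate settings are held out for model assessment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import InvalidDesignError
from .protocol import DEFAULT_GE_TIME, TestProtocol, make_protocol


@dataclass(frozen=True)
class CcdSpec:
    """Modified two-factor CCD specification in natural units (mbar, min)."""

    center: tuple[float, float] = (150.0, 12.0)  # (pressure, timing)
    factorial_offset: tuple[float, float] = (50.0, 3.0)
    axial_offset: tuple[float, float] = (70.0, 4.0)
    n_center_replicates: int = 5

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (*self.factorial_offset, *self.axial_offset)):
            raise InvalidDesignError("all design offsets must be positive")
        if (
            self.axial_offset[0] < self.factorial_offset[0]
            or self.axial_offset[1] < self.factorial_offset[1]
        ):
            raise InvalidDesignError("axial offsets must dominate factorial offsets")
        if self.n_center_replicates < 1:
            raise InvalidDesignError("need at least one center replicate")


@dataclass(frozen=True)
class DesignMatrix:
    """An ordered set of protocol runs sharing one sampling schedule."""

    runs: tuple[TestProtocol, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [r.test_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise InvalidDesignError("run ids must be unique")
        schedules = {r.sampling_times for r in self.runs}
        if len(schedules) > 1:
            raise InvalidDesignError("all runs must share one sampling schedule")

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    def __getitem__(self, i: int) -> TestProtocol:
        return self.runs[i]

    def concat(self, other: "DesignMatrix") -> "DesignMatrix":
        return DesignMatrix(self.runs + other.runs)

    def settings(self) -> list[tuple[float, float]]:
        """(pressure, timing) per run, in run order."""
        return [(r.stress.pressure, r.stress.timing) for r in self.runs]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test_id": [r.test_id for r in self.runs],
                "group": [r.group for r in self.runs],
                "pressure_mbar": [r.stress.pressure for r in self.runs],
                "timing_min": [r.stress.timing for r in self.runs],
            }
        )


def _checked_protocol(test_id: str, pressure: float, timing: float, group: str) -> TestProtocol:
    if pressure <= 0 or timing <= 0 or timing >= DEFAULT_GE_TIME:
        raise InvalidDesignError(
            f"design point (pressure={pressure} mbar, timing={timing} min) is infeasible"
        )
    return make_protocol(test_id, pressure, timing, group=group)


def generate_ccd(
    spec: CcdSpec, group: str = "basic", id_prefix: str = "Test ", id_start: int = 1
) -> DesignMatrix:
    """Generate the modified CCD.

    Non-center points follow the published run order (axial timing+,
    factorial -+, factorial ++, factorial +-, axial pressure+, axial
    pressure-, factorial --, axial timing-); center replicates are
    interleaved at every third position starting with run 1, so with five
    replicates they fall at runs 1, 4, 7, 10 and 13.
    """
    cp, ct = spec.center
    dp, dt = spec.factorial_offset
    ap, at = spec.axial_offset
    others = [
        (cp, ct + at),
        (cp - dp, ct + dt),
        (cp + dp, ct + dt),
        (cp + dp, ct - dt),
        (cp + ap, ct),
        (cp - ap, ct),
        (cp - dp, ct - dt),
        (cp, ct - at),
    ]
    total = len(others) + spec.n_center_replicates
    points: list[tuple[float, float]] = []
    c = o = 0
    for i in range(total):
        if (i % 3 == 0 and c < spec.n_center_replicates) or o >= len(others):
            points.append((cp, ct))
            c += 1
        else:
            points.append(others[o])
            o += 1
    runs = tuple(
        _checked_protocol(f"{id_prefix}{id_start + i}", p, t, group)
        for i, (p, t) in enumerate(points)
    )
    return DesignMatrix(runs)


def additional_points(id_prefix: str = "Test ", id_start: int = 14) -> DesignMatrix:
    """The three fixed-timing (10 min) runs probing the pressure threshold."""
    pts = [(80.0, 10.0), (150.0, 10.0), (220.0, 10.0)]
    return DesignMatrix(
        tuple(
            _checked_protocol(f"{id_prefix}{id_start + i}", p, t, "additional")
            for i, (p, t) in enumerate(pts)
        )
    )


def verification_points() -> DesignMatrix:
    """The four held-out runs at intermediate pressure and timing."""
    pts = [(175.0, 10.5), (175.0, 13.5), (125.0, 13.5), (125.0, 10.5)]
    return DesignMatrix(
        tuple(
            _checked_protocol(f"Test V{i + 1}", p, t, "verification")
            for i, (p, t) in enumerate(pts)
        )
    )


def full_factorial(spec: CcdSpec, group: str = "simulated") -> DesignMatrix:
    """5-level full factorial over the same per-factor levels, for comparing
    experimental effort against the CCD (25 runs for distinct levels)."""
    levels = []
    for k in range(2):
        c = spec.center[k]
        f = spec.factorial_offset[k]
        a = spec.axial_offset[k]
        levels.append(sorted({c - a, c - f, c, c + f, c + a}))
    runs = tuple(
        _checked_protocol(f"FF {i + 1}", p, t, group)
        for i, (p, t) in enumerate(itertools.product(levels[0], levels[1]))
    )
    return DesignMatrix(runs)


def table1_design() -> tuple[DesignMatrix, DesignMatrix, DesignMatrix]:
    """The study's standard matrix: (basic 13, additional 3, verification 4)."""
    return generate_ccd(CcdSpec()), additional_points(), verification_points()
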