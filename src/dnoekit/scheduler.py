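"""Experiment time schedules and delay-adequacy checks.

A NOE measurement is characterized by the recycle delay before the
reference sequence (RD1), the recycle delay before the saturation period
(RD2), the proton saturation period (D_sat) and the static field B0; the
compact descriptor ``(RD1-RD2-D_sat)/B0`` names one such setup, e.g.
``(10-10-8)/16.4``.

Adequacy of the delays is judged by exponential recovery factors:
``exp(-RD1*R1W)`` must fall below a threshold (default 0.02) for the
reference spectrum to start from water/amide equilibrium, and
``exp(-D_sat*R1N)`` must fall below the same threshold for the nitrogen
polarization to reach its saturation steady state.  Dynamic NOE
measurements additionally need ``exp(-RD2*R1W)`` below threshold because
each buildup point must restart from thermal equilibrium; steady-state
NOE tolerates RD2 = 0.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .peak_io import SampleRates

__all__ = [
    "Schedule",
    "ScheduleReport",
    "DEFAULT_THRESHOLD",
    "DSAT_GRID_11",
    "DSAT_GRID_7",
    "DSAT_GRID_4",
    "min_delay",
    "check_schedule",
    "recommend_dsat_grid",
    "parse_descriptor",
]

#: Default adequacy threshold for recovery/saturation factors.  The value
#: is a common-sense limit, admittedly somewhat arbitrary, and is
#: configurable everywhere it is used.
DEFAULT_THRESHOLD = 0.02

#: Validated saturation-delay designs (seconds) for DNOE buildup series:
#: the full 11-point grid and its 7- and 4-point reductions, which were
#: shown not to deteriorate fitted NOE values or their accuracies.
DSAT_GRID_11 = (0.0, 0.11, 0.22, 0.35, 0.55, 0.66, 0.79, 1.10, 1.30, 3.00, 4.00)
DSAT_GRID_7 = (0.0, 0.11, 0.35, 0.55, 0.79, 1.30, 4.00)
DSAT_GRID_4 = (0.0, 0.35, 0.79, 4.00)

_DESCRIPTOR_RE = re.compile(
    r"^\((\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)\)/(\d+(?:\.\d+)?)$"
)


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass
class Schedule:
    """One NOE experiment schedule.

    ``dsat`` is a single saturation period for steady-state NOE or a
    delay grid (containing 0, strictly increasing) for dynamic NOE.
    """

    rd1: float
    rd2: float
    dsat: float | tuple[float, ...]
    b0: float
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.rd1 < 0 or self.rd2 < 0:
            raise ValueError("recycle delays must be >= 0")
        if self.b0 <= 0:
            raise ValueError("B0 must be > 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if isinstance(self.dsat, (list, tuple, np.ndarray)):
            grid = tuple(sorted(float(d) for d in self.dsat))
            if not grid or grid[0] != 0.0:
                raise ValueError("DNOE saturation grid must contain 0")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError("DNOE saturation grid must be strictly increasing")
            self.dsat = grid
        elif self.dsat < 0:
            raise ValueError("D_sat must be >= 0")

    @property
    def is_grid(self) -> bool:
        return isinstance(self.dsat, tuple)

    @property
    def dsat_max(self) -> float:
        return max(self.dsat) if self.is_grid else float(self.dsat)

    @property
    def descriptor(self) -> str:
        """The ``(RD1-RD2-D_sat)/B0`` form; a grid is named by its longest delay."""
        return f"({_fmt(self.rd1)}-{_fmt(self.rd2)}-{_fmt(self.dsat_max)})/{_fmt(self.b0)}"

    def with_dsat(self, dsat: float | Sequence[float]) -> "Schedule":
        dsat = tuple(dsat) if isinstance(dsat, (list, tuple, np.ndarray)) else float(dsat)
        return Schedule(self.rd1, self.rd2, dsat, self.b0, self.threshold)


def parse_descriptor(text: str, threshold: float = DEFAULT_THRESHOLD) -> Schedule:
    """Parse a ``(RD1-RD2-D_sat)/B0`` descriptor into a :class:`Schedule`.

    Numbers are plain non-negative decimals; B0 is in Tesla; no unit
    suffixes are accepted.
    """
    m = _DESCRIPTOR_RE.match(text.strip())
    if m is None:
        raise FormatError(
            f"malformed schedule descriptor {text!r}; expected '(RD1-RD2-Dsat)/B0', "
            "e.g. '(10-10-8)/16.4'"
        )
    rd1, rd2, dsat, b0 = (float(g) for g in m.groups())
    return Schedule(rd1=rd1, rd2=rd2, dsat=dsat, b0=b0, threshold=threshold)


def min_delay(rate: float, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Smallest delay t with exp(-t*rate) == threshold.

    This is the boundary of the adequacy condition exp(-t*rate) < threshold;
    the boundary itself is counted as passing (equality-tolerant
    convention, since published setups sit essentially on it).
    """
    if rate <= 0 or not math.isfinite(rate):
        raise ValueError(f"rate must be finite and > 0, got {rate!r}")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold!r}")
    return -math.log(threshold) / rate


@dataclass
class CheckRow:
    """One sample-level adequacy check."""

    name: str
    delay: float
    rate: float
    factor: float
    threshold: float
    passed: bool


@dataclass
class ScheduleReport:
    """Adequacy report: sample-level checks plus a per-residue table."""

    schedule: Schedule
    mode: str
    sample_checks: list[CheckRow]
    residues: pd.DataFrame = field(repr=False)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.sample_checks) and bool(
            self.residues["passed"].all()
        )


# tiny slack so that schedules built exactly from min_delay() pass
_BOUNDARY_RTOL = 1e-12


def _passes(factor: float, threshold: float) -> bool:
    return factor <= threshold * (1.0 + _BOUNDARY_RTOL)


def check_schedule(s: Schedule, rates: SampleRates, mode: str) -> ScheduleReport:
    """Evaluate every delay-adequacy condition of a schedule.

    The report is always produced; inadequate delays appear as failed
    rows, never as exceptions.  For dynamic NOE, RD2 = 0 is always
    flagged: each buildup point must restart from thermal equilibrium.
    """
    mode_norm = mode.strip().lower()
    if mode_norm not in {"ssnoe", "dnoe"}:
        raise ValueError(f"mode must be 'ssNOE' or 'DNOE', got {mode!r}")
    thr = s.threshold
    checks = []
    f_rd1 = math.exp(-s.rd1 * rates.r1w)
    checks.append(CheckRow("rd1_water_recovery", s.rd1, rates.r1w, f_rd1, thr,
                           _passes(f_rd1, thr)))
    if mode_norm == "dnoe":
        f_rd2 = math.exp(-s.rd2 * rates.r1w)
        checks.append(CheckRow("rd2_equilibrium_restart", s.rd2, rates.r1w, f_rd2, thr,
                               _passes(f_rd2, thr)))
    rows = []
    for res, r1n in rates.r1n.items():
        f = math.exp(-s.dsat_max * r1n)
        rows.append({"residue": res, "r1n": r1n, "dsat": s.dsat_max,
                     "factor": f, "threshold": thr, "passed": _passes(f, thr)})
    residues = pd.DataFrame(rows, columns=["residue", "r1n", "dsat", "factor",
                                           "threshold", "passed"])
    return ScheduleReport(schedule=s, mode=mode_norm, sample_checks=checks,
                          residues=residues)


def recommend_dsat_grid(
    r1n: float,
    epsilon_guess: float,
    n: int = 4,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Saturation-delay grid sampling the buildup curve uniformly in intensity.

    The first delay is 0 (yielding S0) and the last is the adequacy
    boundary ``min_delay(r1n, threshold)``.  Interior delays are placed so
    that the model intensities S(t) = S0[eps + (1-eps)exp(-r1n t)] are
    equally spaced — the buildup is sampled uniformly in signal, not in
    time.  At least four delays are required, the smallest validated
    design.
    """
    if n < 4:
        raise ValueError(f"a saturation grid needs at least 4 delays, got n={n}")
    t_max = min_delay(r1n, threshold)
    if abs(1.0 - epsilon_guess) < 1e-9:
        warnings.warn(
            "epsilon ~ 1: buildup curve is flat, falling back to uniform time spacing",
            stacklevel=2,
        )
        return np.linspace(0.0, t_max, n)
    # relative intensity runs from 1 at t=0 to eps + (1-eps)*threshold at t_max
    levels = np.linspace(1.0, epsilon_guess + (1.0 - epsilon_guess) * threshold, n)
    grid = -np.log((levels - epsilon_guess) / (1.0 - epsilon_guess)) / r1n
    grid[0] = 0.0
    grid[-1] = t_max
    return grid
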