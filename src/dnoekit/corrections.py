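"""Analytic corrections for NOE errors caused by mis-set delays.

Too-short recycle delays leave water and amide protons (and hence the
reference nitrogen polarization) short of equilibrium, while a too-short
saturation period leaves the nitrogen polarization short of its
saturation steady state.  Four published correction factors X address
these systematic errors:

* ``R1W_recovery`` ("5A"):  X = exp(-RD*R1W), incomplete water recovery;
* ``R1H_recovery`` ("5B"):  X = exp(-RD*R1H), incomplete amide-proton recovery;
* ``R1H_R1N_joint`` ("5C"): X = R1N/(R1N-R1H) *
  (exp(-RD*R1N) - exp(-RD*R1H)) / (exp(-RD*R1N) - 1), joint inconsistency
  of both rates with the recycle delay;
* ``DSAT_truncation`` ("6"): X = exp(-D_sat*R1N), truncated buildup.

The first three enter the rational recovery form

    eps = (1 - X) * eps_app / (1 - X * eps_app)

while the truncation correction is the linear form

    eps = (eps_app - X) / (1 - X)

which exactly inverts a buildup curve cut off at D_sat when it started
from equilibrium.  No correction substitutes for a properly designed
experiment; corrected values are therefore always labelled as such and
errors are not re-propagated through the correction (the original d_eps
is kept, a documented limitation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .errors import DnoekitError, MissingRateError, SingularCorrectionError
from .peak_io import SampleRates
from .ssnoe import NOEResult

__all__ = [
    "CorrectionKind",
    "CorrectionFactor",
    "factor",
    "correct",
    "invert",
    "correct_table",
    "compensation_efficiency",
    "evaluate_corrections",
]

_SINGULAR_TOL = 1e-12


class CorrectionKind(str, Enum):
    """Which systematic error a correction factor compensates."""

    R1W_RECOVERY = "5A"
    R1H_RECOVERY = "5B"
    R1H_R1N_JOINT = "5C"
    DSAT_TRUNCATION = "6"


#: Kinds corrected with the rational (recovery) form rather than the
#: linear truncation form.
_RATIONAL_KINDS = frozenset(
    {CorrectionKind.R1W_RECOVERY, CorrectionKind.R1H_RECOVERY, CorrectionKind.R1H_R1N_JOINT}
)


@dataclass(frozen=True)
class CorrectionFactor:
    """A computed correction factor and the inputs it came from."""

    kind: CorrectionKind
    x: float
    delay: float
    residue: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.x < 1.0:
            raise ValueError(f"correction factor must lie in [0, 1), got {self.x!r}")


def _joint_factor(rd: float, r1n: float, r1h: float) -> float:
    """Joint R1N/R1H recovery factor, with its R1N -> R1H analytic limit."""
    if abs(r1n - r1h) < 1e-6 * r1n:
        # removable singularity: X -> R1N*RD*exp(-R1N*RD) / (1 - exp(-R1N*RD))
        e = math.exp(-rd * r1n)
        return r1n * rd * e / (1.0 - e)
    en, eh = math.exp(-rd * r1n), math.exp(-rd * r1h)
    return r1n / (r1n - r1h) * (en - eh) / (en - 1.0)


def factor(
    kind: CorrectionKind | str,
    rd_or_dsat: float,
    rates: SampleRates,
    residue: str | None = None,
) -> CorrectionFactor:
    """Compute the correction factor of the named kind for one delay.

    ``rd_or_dsat`` is the recycle delay (recovery kinds) or the
    saturation period (truncation kind), in seconds.  The joint and
    truncation kinds need the residue's R1N rate.
    """
    kind = CorrectionKind(kind)
    if rd_or_dsat <= 0 or not math.isfinite(rd_or_dsat):
        raise ValueError(f"delay must be finite and > 0, got {rd_or_dsat!r}")
    if kind is CorrectionKind.R1W_RECOVERY:
        x = math.exp(-rd_or_dsat * rates.r1w)
    elif kind is CorrectionKind.R1H_RECOVERY:
        x = math.exp(-rd_or_dsat * rates.r1h)
    elif kind is CorrectionKind.R1H_R1N_JOINT:
        if residue is None:
            raise MissingRateError(f"correction {kind.value} needs a residue label for R1N")
        x = _joint_factor(rd_or_dsat, rates.r1n_for(residue), rates.r1h)
    else:  # DSAT_TRUNCATION
        if residue is None:
            raise MissingRateError(f"correction {kind.value} needs a residue label for R1N")
        x = math.exp(-rd_or_dsat * rates.r1n_for(residue))
    return CorrectionFactor(kind=kind, x=x, delay=rd_or_dsat, residue=residue)


def correct(epsilon_app: float, f: CorrectionFactor) -> float:
    """Apply the correction matching ``f.kind`` to an apparent NOE value."""
    if f.kind in _RATIONAL_KINDS:
        denom = 1.0 - f.x * epsilon_app
        if abs(denom) < _SINGULAR_TOL:
            raise SingularCorrectionError(
                f"correction {f.kind.value}: 1 - X*eps_app is numerically zero"
            )
        return (1.0 - f.x) * epsilon_app / denom
    denom = 1.0 - f.x
    if abs(denom) < _SINGULAR_TOL:
        raise SingularCorrectionError(
            f"correction {f.kind.value}: 1 - X is numerically zero"
        )
    return (epsilon_app - f.x) / denom


def invert(epsilon: float, f: CorrectionFactor) -> float:
    """Apparent NOE that would be observed for a true ``epsilon``.

    Exact algebraic inverse of :func:`correct`; for the truncation kind
    this is the equilibrium-start buildup cut off at D_sat:
    eps_app = eps + (1 - eps)*X.
    """
    if f.kind in _RATIONAL_KINDS:
        denom = 1.0 - f.x + f.x * epsilon
        if abs(denom) < _SINGULAR_TOL:
            raise SingularCorrectionError(
                f"correction {f.kind.value}: inverse denominator is numerically zero"
            )
        return epsilon / denom
    return epsilon + (1.0 - epsilon) * f.x


def correct_table(
    results: Iterable[NOEResult],
    kind: CorrectionKind | str,
    rd_or_dsat: float,
    rates: SampleRates,
) -> list[NOEResult]:
    """Apply one correction kind to a whole result table.

    Each corrected value is labelled ``source='corrected'`` with the kind
    recorded in its flags; d_eps is carried over unchanged.
    """
    kind = CorrectionKind(kind)
    out = []
    for r in results:
        f = factor(kind, rd_or_dsat, rates, residue=r.residue)
        out.append(
            NOEResult(
                residue=r.residue,
                epsilon=correct(r.epsilon, f),
                d_epsilon=r.d_epsilon,
                source="corrected",
                flags=r.flags + (f"corrected_{kind.value}",),
            )
        )
    return out


def _aligned(values: Mapping[str, float] | Iterable[float]) -> np.ndarray:
    if isinstance(values, Mapping):
        return np.array([values[k] for k in sorted(values)], dtype=float)
    return np.asarray(list(values), dtype=float)


def compensation_efficiency(eps_app, eps_corrected, eps_ref) -> float:
    """How much of a delay mis-setting a correction removed, in percent.

    100 * (1 - mean|eps_corrected - eps_ref| / mean|eps_app - eps_ref|),
    using means of absolute residue-wise differences against a reference
    measurement free of the systematic error.
    """
    app = _aligned(eps_app)
    corr = _aligned(eps_corrected)
    ref = _aligned(eps_ref)
    if not (app.shape == corr.shape == ref.shape):
        raise ValueError("eps_app, eps_corrected and eps_ref must align")
    baseline = float(np.mean(np.abs(app - ref)))
    if baseline == 0.0:
        raise DnoekitError("compensation efficiency undefined: no baseline discrepancy")
    return 100.0 * (1.0 - float(np.mean(np.abs(corr - ref))) / baseline)


def evaluate_corrections(
    eps_app: Mapping[str, float],
    eps_ref: Mapping[str, float],
    rd: float,
    rates: SampleRates,
    kinds: Iterable[CorrectionKind | str] = ("5A", "5B", "5C"),
) -> dict[CorrectionKind, float]:
    """Compensation efficiency of each recovery correction on one scenario.

    The efficiencies are reported for the user to rank; no "best"
    correction is chosen automatically.
    """
    if set(eps_app) != set(eps_ref):
        raise ValueError("apparent and reference tables must share residues")
    residues = sorted(eps_app)
    out: dict[CorrectionKind, float] = {}
    for kind in kinds:
        kind = CorrectionKind(kind)
        corrected = {
            res: correct(eps_app[res], factor(kind, rd, rates, residue=res))
            for res in residues
        }
        out[kind] = compensation_efficiency(
            {r: eps_app[r] for r in residues},
            corrected,
            {r: eps_ref[r] for r in residues},
        )
    return out
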