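"""Steady-state NOE values, SNR-propagated errors, and replicate statistics.

The steady-state NOE is the intensity ratio eps = S_sat/S_ref between the
proton-saturated and reference spectra (the *effect*, not the enhancement
eta = eps - 1).  Its thermal-noise error is propagated from the two
signal-to-noise ratios as

    d_eps = |eps| * sqrt(SNR_sat^-2 + SNR_ref^-2)

which is reliable when thermal noise dominates, but systematically
underestimates the error when eps is close to zero because of the |eps|
factor; such residues are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, UndefinedNOEError

__all__ = [
    "SSNOEPair",
    "NOEResult",
    "NEAR_ZERO_NOE",
    "snr_error",
    "compute_ssnoe",
    "compute_ssnoe_table",
    "replicate_stats",
    "ReplicateSummary",
]

#: |eps| below which the SNR-based error is flagged as underestimated.
NEAR_ZERO_NOE = 0.1


@dataclass
class SSNOEPair:
    """Saturated/reference intensity pair of one residue."""

    residue: str
    s_sat: float
    s_ref: float
    snr_sat: float
    snr_ref: float


@dataclass
class NOEResult:
    """One residue's NOE value with its error and provenance."""

    residue: str
    epsilon: float
    d_epsilon: float
    source: str = "ssNOE"  # one of {"ssNOE", "DNOE", "corrected"}
    flags: tuple[str, ...] = ()

    @property
    def eta(self) -> float:
        """Nuclear Overhauser enhancement, eta = eps - 1."""
        return self.epsilon - 1.0

    def to_record(self) -> dict:
        return {
            "residue": self.residue,
            "epsilon": self.epsilon,
            "d_epsilon": self.d_epsilon,
            "mode": self.source,
        }


def snr_error(epsilon: float, snr_sat: float, snr_ref: float) -> float:
    """Thermal-noise NOE error |eps|*sqrt(SNR_sat^-2 + SNR_ref^-2)."""
    if snr_sat <= 0 or snr_ref <= 0:
        raise ValueError(f"SNR values must be > 0, got {snr_sat!r}, {snr_ref!r}")
    return abs(epsilon) * math.sqrt(snr_sat ** -2 + snr_ref ** -2)


def is_near_zero(epsilon: float, threshold: float = NEAR_ZERO_NOE) -> bool:
    """Whether |eps| is small enough for the SNR error to be underestimated."""
    return abs(epsilon) < threshold


def compute_ssnoe(pair: SSNOEPair, near_zero_threshold: float = NEAR_ZERO_NOE) -> NOEResult:
    """Steady-state NOE of one residue with its SNR-propagated error."""
    if pair.s_ref == 0:
        raise UndefinedNOEError(f"{pair.residue}: reference intensity is zero")
    eps = pair.s_sat / pair.s_ref
    d_eps = snr_error(eps, pair.snr_sat, pair.snr_ref)
    flags = ("near_zero_noe",) if is_near_zero(eps, near_zero_threshold) else ()
    return NOEResult(residue=pair.residue, epsilon=eps, d_epsilon=d_eps,
                     source="ssNOE", flags=flags)


def compute_ssnoe_table(
    pairs: Sequence[SSNOEPair],
    near_zero_threshold: float = NEAR_ZERO_NOE,
) -> list[NOEResult]:
    """Steady-state NOE per residue; undefined residues are flagged, not fatal."""
    out = []
    for pair in pairs:
        if pair.s_ref == 0:
            out.append(NOEResult(residue=pair.residue, epsilon=math.nan,
                                 d_epsilon=math.nan, source="ssNOE",
                                 flags=("undefined_noe",)))
        else:
            out.append(compute_ssnoe(pair, near_zero_threshold))
    return out


@dataclass
class ReplicateSummary:
    """Grand means of the two error estimates over all residues."""

    n_replicates: int
    grand_mean_sd: float
    grand_mean_snr_error: float

    @property
    def difference(self) -> float:
        return self.grand_mean_sd - self.grand_mean_snr_error


def replicate_stats(
    measurements: Sequence[Sequence[NOEResult] | Mapping[str, NOEResult]],
) -> tuple[pd.DataFrame, ReplicateSummary]:
    """Per-residue statistics over a series of repeated NOE measurements.

    Returns a frame with the sample mean and standard deviation (n-1
    denominator) of eps across replicates plus the mean of the
    per-replicate SNR-based errors, and a summary holding the grand means
    of both error estimates.  Comparing the two is the standard check
    that SNR-propagated errors are trustworthy.
    """
    if len(measurements) < 2:
        raise ValueError("replicate statistics need at least 2 measurement tables")
    tables: list[dict[str, NOEResult]] = []
    for table in measurements:
        if isinstance(table, Mapping):
            tables.append(dict(table))
        else:
            tables.append({r.residue: r for r in table})
    residues = list(tables[0])
    ref_set = set(residues)
    for i, t in enumerate(tables[1:], start=2):
        if set(t) != ref_set:
            offenders = sorted(set(t) ^ ref_set)
            raise AlignmentError(
                f"replicate table {i} has a different residue set; offenders: {offenders}"
            )
    rows = []
    for res in residues:
        eps = np.array([t[res].epsilon for t in tables])
        d_eps = np.array([t[res].d_epsilon for t in tables])
        rows.append({
            "residue": res,
            "mean_epsilon": float(np.mean(eps)),
            "sd_epsilon": float(np.std(eps, ddof=1)),
            "mean_d_epsilon": float(np.mean(d_eps)),
            "n": len(tables),
        })
    df = pd.DataFrame(rows, columns=["residue", "mean_epsilon", "sd_epsilon",
                                     "mean_d_epsilon", "n"])
    summary = ReplicateSummary(
        n_replicates=len(tables),
        grand_mean_sd=float(df["sd_epsilon"].mean()),
        grand_mean_snr_error=float(df["mean_d_epsilon"].mean()),
    )
    return df, summary
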