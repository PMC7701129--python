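"""Peak-intensity tables, rate configs, and result tables.

Everything handled here is already-extracted cross-peak data from 2D
¹⁵N/¹H correlation spectra: one row per (residue, saturation delay) with
the intensity and either the spectral noise RMS or the signal-to-noise
ratio.  Spectral processing (Fourier transform, phasing, peak picking) is
upstream of this package and out of scope.

The canonical table schema is::

    residue  delay_s  intensity  noise_rms|snr

as UTF-8 delimited text (TSV by default, CSV optional), with ``#`` comment
lines.  A ``sparky_heights`` dialect accepts SPARKY-style ``Assignment``
and ``Height`` column names for the residue label and intensity.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    MissingRateError,
)

__all__ = [
    "Experiment",
    "IntensityPoint",
    "IntensitySeries",
    "SampleRates",
    "read_intensity_table",
    "write_intensity_table",
    "series_from_arrays",
    "estimate_noise_rms",
    "read_results",
    "write_results",
    "read_rates",
    "write_rates",
    "RESULT_COLUMNS",
    "MIN_BASELINE_SAMPLES",
]

#: Result-table schema shared by all fitting and steady-state commands.
RESULT_COLUMNS = ("residue", "epsilon", "d_epsilon", "r1", "d_r1", "corr_eps_r1", "mode")

#: Minimum number of baseline samples for a stable noise-RMS estimate.
MIN_BASELINE_SAMPLES = 32

_DIALECT_SEP = {"tsv": "\t", "csv": ",", "sparky_heights": "\t"}
_SPARKY_ALIASES = {"Assignment": "residue", "Height": "intensity"}


class Experiment(str, Enum):
    """Which experiment a series of intensity points belongs to."""

    DNOE = "DNOE"
    R1 = "R1"
    SSNOE_SAT = "SSNOE_SAT"
    SSNOE_REF = "SSNOE_REF"


@dataclass
class IntensityPoint:
    """One (delay, intensity) observation with its noise level.

    ``snr`` and ``noise_rms`` are kept mutually consistent: whichever is
    missing is derived from the other via ``snr = |intensity|/noise_rms``.
    """

    delay: float
    intensity: float
    noise_rms: float | None = None
    snr: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.delay) or self.delay < 0:
            raise ValueError(f"delay must be finite and >= 0, got {self.delay!r}")
        if not math.isfinite(self.intensity):
            raise ValueError(f"intensity must be finite, got {self.intensity!r}")
        if self.noise_rms is not None and self.noise_rms <= 0:
            raise ValueError(f"noise_rms must be > 0, got {self.noise_rms!r}")
        if self.snr is not None and self.snr <= 0:
            raise ValueError(f"snr must be > 0, got {self.snr!r}")
        if self.noise_rms is None and self.snr is not None:
            self.noise_rms = abs(self.intensity) / self.snr
        elif self.snr is None and self.noise_rms is not None:
            self.snr = abs(self.intensity) / self.noise_rms


@dataclass
class IntensitySeries:
    """All intensity points of one residue from one experiment.

    Duplicate delays are allowed and treated as replicate observations.
    """

    residue: str
    experiment: Experiment = Experiment.DNOE
    points: list[IntensityPoint] = field(default_factory=list)

    @property
    def delays(self) -> np.ndarray:
        return np.array([p.delay for p in self.points], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points], dtype=float)

    @property
    def noise_rms(self) -> np.ndarray:
        return np.array(
            [p.noise_rms if p.noise_rms is not None else np.nan for p in self.points],
            dtype=float,
        )

    def n_distinct_delays(self) -> int:
        return int(np.unique(self.delays).size)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SampleRates:
    """Sample-level longitudinal rates governing the NOE time schedule.

    Parameters
    ----------
    r1w : float
        Longitudinal relaxation rate of water protons, s^-1.
    r1h : float
        Mean longitudinal relaxation rate of amide protons, s^-1.
    r1n : mapping residue -> float
        Per-residue amide 15N longitudinal relaxation rates, s^-1.
    r1n_sd : mapping residue -> float, optional
        Standard deviations of the per-residue rates.
    k_exchange : float
        Chemical exchange rate between amide and water protons, s^-1
        (0 allowed).
    """

    r1w: float
    r1h: float
    r1n: dict[str, float] = field(default_factory=dict)
    r1n_sd: dict[str, float] = field(default_factory=dict)
    k_exchange: float = 0.0

    def __post_init__(self) -> None:
        for name, val in (("r1w", self.r1w), ("r1h", self.r1h)):
            if not math.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {val!r}")
        if not math.isfinite(self.k_exchange) or self.k_exchange < 0:
            raise ValueError(f"k_exchange must be finite and >= 0, got {self.k_exchange!r}")
        for res, val in self.r1n.items():
            if not math.isfinite(val) or val <= 0:
                raise ValueError(f"r1n[{res!r}] must be finite and > 0, got {val!r}")

    def r1n_for(self, residue: str) -> float:
        try:
            return self.r1n[residue]
        except KeyError:
            raise MissingRateError(
                f"no R1N rate available for residue {residue!r}"
            ) from None


def series_from_arrays(
    residue: str,
    delays: Sequence[float],
    intensities: Sequence[float],
    noise_rms: float | Sequence[float] | None = None,
    experiment: Experiment = Experiment.DNOE,
) -> IntensitySeries:
    """Build an :class:`IntensitySeries` from plain arrays."""
    delays = np.asarray(delays, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if delays.shape != intensities.shape:
        raise ValueError("delays and intensities must have the same length")
    if noise_rms is None:
        rms = [None] * delays.size
    elif np.isscalar(noise_rms):
        rms = [float(noise_rms)] * delays.size
    else:
        rms = [float(v) for v in np.asarray(noise_rms, dtype=float)]
    pts = [
        IntensityPoint(delay=float(t), intensity=float(y), noise_rms=r)
        for t, y, r in zip(delays, intensities, rms)
    ]
    return IntensitySeries(residue=residue, experiment=experiment, points=pts)


def _atomic_to_csv(df: pd.DataFrame, path: str | os.PathLike, sep: str) -> None:
    """Write a frame so that the target file is never partially written.

    No float_format is forced: pandas falls back to the shortest
    round-trip repr, so numeric fields survive a write/read cycle bit
    for bit.
    """
    tmp = f"{os.fspath(path)}.tmp"
    df.to_csv(tmp, sep=sep, index=False, na_rep="NA")
    os.replace(tmp, path)


def _require_columns(df: pd.DataFrame, path: str | os.PathLike) -> None:
    for col in ("residue", "delay_s", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if "noise_rms" not in df.columns and "snr" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'noise_rms' or 'snr'")


def _to_numeric(df: pd.DataFrame, col: str, path: str | os.PathLike) -> pd.Series:
    # per-value float(): exact round-trip parsing (pandas' fast parser can
    # be off by half an ulp), and unparseable rows are an error, not a drop
    values, bad = [], []
    for i, raw in df[col].items():
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or not str(raw).strip():
            values.append(math.nan)
            continue
        try:
            values.append(float(raw))
        except ValueError:
            bad.append(i)
            values.append(math.nan)
    if bad:
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise FormatError(
            f"{path}: column {col!r} has unparseable numeric values (file lines {rows})"
        )
    return pd.Series(values, index=df.index, dtype=float)


def read_intensity_table(
    path: str | os.PathLike,
    dialect: str = "tsv",
    experiment: Experiment = Experiment.DNOE,
) -> dict[str, IntensitySeries]:
    """Read a delimited intensity table into one series per residue.

    Rows with unparseable numerics raise :class:`FormatError` rather than
    being silently dropped.  Residue ordering follows the input file.
    """
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_SEP)}")
    df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], comment="#", dtype=str,
                     skip_blank_lines=True)
    if dialect == "sparky_heights":
        df = df.rename(columns=_SPARKY_ALIASES)
    _require_columns(df, path)
    if df.empty:
        raise EmptyInputError(f"{path}: table contains no data rows")
    delays = _to_numeric(df, "delay_s", path)
    intens = _to_numeric(df, "intensity", path)
    rms = _to_numeric(df, "noise_rms", path) if "noise_rms" in df.columns else None
    snr = _to_numeric(df, "snr", path) if "snr" in df.columns else None

    out: dict[str, IntensitySeries] = {}
    for i in df.index:
        res = str(df.at[i, "residue"])
        point = IntensityPoint(
            delay=float(delays[i]),
            intensity=float(intens[i]),
            noise_rms=None if rms is None or pd.isna(rms[i]) else float(rms[i]),
            snr=None if snr is None or pd.isna(snr[i]) else float(snr[i]),
        )
        out.setdefault(res, IntensitySeries(residue=res, experiment=experiment)).points.append(point)
    return out


def write_intensity_table(
    series_map: Mapping[str, IntensitySeries],
    path: str | os.PathLike,
    dialect: str = "tsv",
) -> None:
    """Write series back to the canonical schema at full float precision."""
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_SEP)}")
    rows = []
    for series in series_map.values():
        for p in series.points:
            rows.append(
                {
                    "residue": series.residue,
                    "delay_s": p.delay,
                    "intensity": p.intensity,
                    "noise_rms": p.noise_rms,
                    "snr": p.snr,
                }
            )
    df = pd.DataFrame(rows, columns=["residue", "delay_s", "intensity", "noise_rms", "snr"])
    if dialect == "sparky_heights":
        df = df.rename(columns={v: k for k, v in _SPARKY_ALIASES.items()})
    _atomic_to_csv(df, path, _DIALECT_SEP[dialect])


def estimate_noise_rms(baseline_samples: Iterable[float]) -> float:
    """Root-mean-square of signal-free baseline samples, taken about zero.

    Spectra are assumed baseline-corrected, so the estimator is the plain
    RMS a user can verify by hand, not a standard deviation about the
    sample mean.  At least :data:`MIN_BASELINE_SAMPLES` samples are
    required; fewer makes the estimate too unstable to trust.
    """
    x = np.asarray(list(baseline_samples), dtype=float)
    if x.size < MIN_BASELINE_SAMPLES:
        raise InsufficientDataError(
            f"noise RMS needs >= {MIN_BASELINE_SAMPLES} baseline samples, got {x.size}"
        )
    return float(np.sqrt(np.mean(np.square(x))))


def write_results(records: Iterable[Mapping | object], path: str | os.PathLike) -> None:
    """Write result rows as TSV with the canonical result schema.

    ``records`` may be mappings or objects exposing a ``to_record()``
    method (fit and NOE results do).  Missing fields are written as NA.
    """
    rows = []
    for rec in records:
        if hasattr(rec, "to_record"):
            rec = rec.to_record()
        rows.append({col: rec.get(col, np.nan) for col in RESULT_COLUMNS})
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    _atomic_to_csv(df, path, "\t")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read a result TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if "residue" not in df.columns or "epsilon" not in df.columns:
        raise FormatError(f"{path}: not a dnoekit result table (missing residue/epsilon)")
    df["residue"] = df["residue"].astype(str)
    return df


def read_rates(path: str | os.PathLike) -> SampleRates:
    """Read a :class:`SampleRates` config (flat YAML key/value file).

    Expected keys: ``r1w``, ``r1h``, ``k_exchange`` (optional) and a
    per-residue ``r1n`` mapping whose values are either a rate or a
    ``[rate, sd]`` pair.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: rates config must be a key/value mapping")
    for key in ("r1w", "r1h"):
        if key not in data:
            raise FormatError(f"{path}: missing mandatory key {key!r}")
    r1n: dict[str, float] = {}
    r1n_sd: dict[str, float] = {}
    for res, val in (data.get("r1n") or {}).items():
        if isinstance(val, (list, tuple)):
            r1n[str(res)] = float(val[0])
            if len(val) > 1:
                r1n_sd[str(res)] = float(val[1])
        else:
            r1n[str(res)] = float(val)
    return SampleRates(
        r1w=float(data["r1w"]),
        r1h=float(data["r1h"]),
        r1n=r1n,
        r1n_sd=r1n_sd,
        k_exchange=float(data.get("k_exchange", 0.0)),
    )


def write_rates(rates: SampleRates, path: str | os.PathLike) -> None:
    """Write a :class:`SampleRates` config as YAML."""
    data: dict = {
        "r1w": float(rates.r1w),
        "r1h": float(rates.r1h),
        "k_exchange": float(rates.k_exchange),
        "r1n": {
            res: ([val, rates.r1n_sd[res]] if res in rates.r1n_sd else val)
            for res, val in rates.r1n.items()
        },
    }
    tmp = f"{os.fspath(path)}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    os.replace(tmp, path)
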