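"""Nonlinear least-squares fitting of NOE buildup and R1 decay curves.

The dynamic NOE buildup model is

    S(t) = S0 * [eps + (1 - eps) * exp(-R1 * t)]

where t is the proton saturation period: the curve starts at the
equilibrium intensity S0 and relaxes toward the steady-state intensity
S0*eps with the nitrogen longitudinal rate R1.  Three data-reduction
modes are supported:

* mode A (sequential): R1 is fixed from a dedicated R1 measurement and
  only (S0, eps) are fitted;
* mode B (simultaneous): the buildup series and the R1 decay series are
  fitted jointly, sharing one R1;
* mode C (standalone): (S0, eps, R1) are all fitted from the buildup
  series alone.  eps comes out as accurate as in the other modes, but R1
  is roughly an order of magnitude less precise than from a dedicated
  decay experiment.

Error convention: when every point carries a noise RMS (the usual case
— spectral noise is measured), residuals are weighted by 1/noise_rms
and standard errors come from the *unscaled* covariance (J^T J)^-1 of
the weighted problem, i.e. known-noise chi-square fitting.  This keeps
fitted errors tied to the measured noise floor, the same basis as the
SNR error propagation of steady-state NOEs, and makes them insensitive
to per-fit residual fluctuations.  Without noise information the fit
falls back to unweighted least squares with the covariance scaled by
the residual variance.  ``weighted=True/False`` forces either
convention; the default ``None`` picks automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    AlignmentError,
    ConvergenceError,
    IllPosedFitError,
    InsufficientDataError,
)
from .peak_io import IntensitySeries

__all__ = [
    "FitMode",
    "FitResult",
    "R1Fit",
    "ModeComparison",
    "dnoe_model",
    "r1_model",
    "fit_r1",
    "fit_dnoe",
    "fit_dnoe_table",
    "mode_a_sensitivity",
    "compare_modes",
    "reduced_grid_report",
]


class FitMode(str, Enum):
    A_SEQUENTIAL = "A"
    B_SIMULTANEOUS = "B"
    C_STANDALONE = "C"


def dnoe_model(t, s0, epsilon, r1):
    """NOE buildup curve S(t) = S0[eps + (1-eps)exp(-R1 t)]."""
    t = np.asarray(t, dtype=float)
    return s0 * (epsilon + (1.0 - epsilon) * np.exp(-r1 * t))


def r1_model(t, amplitude, r1):
    """Two-parameter longitudinal decay A*exp(-R1 t) (no offset)."""
    t = np.asarray(t, dtype=float)
    return amplitude * np.exp(-r1 * t)


@dataclass
class R1Fit:
    """Result of a dedicated R1 decay fit."""

    residue: str
    r1: float
    d_r1: float
    amplitude: float
    d_amplitude: float
    reduced_chi2: float
    n_points: int
    non_decaying: bool = False
    offset: float | None = None

    def to_record(self) -> dict:
        return {"residue": self.residue, "r1": self.r1, "d_r1": self.d_r1, "mode": "R1"}


@dataclass
class FitResult:
    """Fitted NOE buildup parameters of one residue.

    In mode A, ``r1``/``d_r1`` record the fixed rate and its supplied
    standard deviation; ``corr_eps_r1`` is defined only where R1 is
    fitted (modes B and C).
    """

    residue: str
    mode: FitMode
    epsilon: float
    d_epsilon: float
    s0: float
    d_s0: float
    r1: float
    d_r1: float
    corr_eps_r1: float | None
    reduced_chi2: float
    n_points: int
    r1_was_fixed: bool = False

    def to_record(self) -> dict:
        return {
            "residue": self.residue,
            "epsilon": self.epsilon,
            "d_epsilon": self.d_epsilon,
            "r1": self.r1,
            "d_r1": self.d_r1,
            "corr_eps_r1": np.nan if self.corr_eps_r1 is None else self.corr_eps_r1,
            "mode": self.mode.value,
        }


def _run_least_squares(residual, p0, n_obs, scale_cov):
    """Levenberg–Marquardt solve with tight tolerances and covariance.

    ``scale_cov=False`` is the known-noise convention (residuals already
    in noise units, covariance is (J^T J)^-1); ``scale_cov=True``
    estimates the noise from the residual variance instead.
    """
    res = least_squares(
        residual,
        np.asarray(p0, dtype=float),
        method="lm",
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=200 * (len(p0) + 1),
    )
    if res.status == 0:
        raise ConvergenceError(
            f"fit did not converge within iteration budget; last iterate {res.x.tolist()}"
        )
    n_par = res.x.size
    ssr = float(2.0 * res.cost)
    dof = n_obs - n_par
    jtj = res.jac.T @ res.jac
    try:
        unscaled_cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        raise IllPosedFitError("singular normal equations at the optimum") from None
    red_chi2 = ssr / dof if dof > 0 else math.nan
    if scale_cov:
        cov = unscaled_cov * red_chi2 if dof > 0 else np.full_like(unscaled_cov, math.nan)
    else:
        cov = unscaled_cov
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return res, unscaled_cov, sd, red_chi2


def _weights(series: IntensitySeries, weighted: bool | None) -> np.ndarray | None:
    """1/noise_rms weights, or None for an unweighted fit.

    ``weighted=None`` (auto) weights whenever every point has a noise RMS.
    """
    rms = series.noise_rms
    have_noise = not np.isnan(rms).any()
    if weighted is None:
        weighted = have_noise
    if not weighted:
        return None
    if not have_noise:
        raise ValueError("weighted fit requested but noise_rms is missing for some points")
    return 1.0 / rms


def fit_r1(
    series: IntensitySeries,
    with_offset: bool = False,
    weighted: bool | None = None,
) -> R1Fit:
    """Fit A*exp(-R1 t) (optionally plus a constant offset) to a decay series.

    Non-decaying data (best-fit R1 <= 0, e.g. a constant series) is
    returned flagged rather than clamped.  The offset variant is off by
    default: the experiment drives the decay to zero, and an offset term
    mostly absorbs artifacts.
    """
    t, y = series.delays, series.intensities
    if np.unique(t).size < 3:
        raise InsufficientDataError(
            f"{series.residue}: R1 fit needs >= 3 distinct delays, got {np.unique(t).size}"
        )
    if np.ptp(y) == 0.0:
        return R1Fit(residue=series.residue, r1=0.0, d_r1=math.nan,
                     amplitude=float(y[0]), d_amplitude=math.nan,
                     reduced_chi2=math.nan, n_points=t.size, non_decaying=True)
    w = _weights(series, weighted)
    a0 = float(y[np.argmin(t)]) or float(np.max(np.abs(y)))
    pos = t[t > 0]
    r10 = 1.0 / float(np.median(pos)) if pos.size else 1.0

    if with_offset:
        def residual(p):
            r = r1_model(t, p[0], p[1]) + p[2] - y
            return r * w if w is not None else r
        p0 = (a0, r10, 0.0)
    else:
        def residual(p):
            r = r1_model(t, p[0], p[1]) - y
            return r * w if w is not None else r
        p0 = (a0, r10)

    res, _, sd, red_chi2 = _run_least_squares(residual, p0, t.size, scale_cov=w is None)
    return R1Fit(
        residue=series.residue,
        r1=float(res.x[1]),
        d_r1=float(sd[1]),
        amplitude=float(res.x[0]),
        d_amplitude=float(sd[0]),
        reduced_chi2=red_chi2,
        n_points=int(t.size),
        non_decaying=bool(res.x[1] <= 0),
        offset=float(res.x[2]) if with_offset else None,
    )


def _unpack_r1_fixed(r1_fixed) -> tuple[float, float]:
    if isinstance(r1_fixed, R1Fit):
        return r1_fixed.r1, r1_fixed.d_r1
    if isinstance(r1_fixed, (tuple, list)):
        value, sd = r1_fixed
        return float(value), float(sd)
    return float(r1_fixed), math.nan


def fit_dnoe(
    series: IntensitySeries,
    mode: FitMode | str,
    r1_fixed=None,
    r1_series: IntensitySeries | None = None,
    weighted: bool | None = None,
) -> FitResult:
    """Fit the NOE buildup model in one of the three data-reduction modes.

    Parameters
    ----------
    series : IntensitySeries
        The buildup series (intensity vs saturation period).
    mode : {"A", "B", "C"}
        Data-reduction mode; see the module docstring.
    r1_fixed : float, (value, sd) or R1Fit, mode A only
        The externally determined rate (and optionally its SD, recorded
        in the result and used by :func:`mode_a_sensitivity`).
    r1_series : IntensitySeries, mode B only
        The dedicated R1 decay series fitted jointly with the buildup.
    """
    mode = FitMode(mode)
    t, y = series.delays, series.intensities
    n_distinct = np.unique(t).size
    if n_distinct < 2:
        raise IllPosedFitError(f"{series.residue}: all saturation delays are equal")
    w = _weights(series, weighted)

    s00 = float(y[np.argmin(t)]) or float(np.max(np.abs(y))) or 1.0
    eps0 = float(y[np.argmax(t)]) / s00
    pos = t[t > 0]
    r10 = 1.0 / float(np.median(pos)) if pos.size else 1.0

    if mode is FitMode.A_SEQUENTIAL:
        if r1_fixed is None:
            raise ValueError("mode A requires r1_fixed from a dedicated R1 measurement")
        r1v, r1sd = _unpack_r1_fixed(r1_fixed)

        def residual(p):
            r = dnoe_model(t, p[0], p[1], r1v) - y
            return r * w if w is not None else r

        res, ucov, sd, red_chi2 = _run_least_squares(residual, (s00, eps0), t.size,
                                                     scale_cov=w is None)
        return FitResult(
            residue=series.residue, mode=mode,
            epsilon=float(res.x[1]), d_epsilon=float(sd[1]),
            s0=float(res.x[0]), d_s0=float(sd[0]),
            r1=r1v, d_r1=r1sd, corr_eps_r1=None,
            reduced_chi2=red_chi2, n_points=int(t.size), r1_was_fixed=True,
        )

    if mode is FitMode.C_STANDALONE:
        if n_distinct < 3:
            raise InsufficientDataError(
                f"{series.residue}: standalone fit needs >= 3 distinct delays"
            )

        def residual(p):
            r = dnoe_model(t, p[0], p[1], p[2]) - y
            return r * w if w is not None else r

        res, ucov, sd, red_chi2 = _run_least_squares(residual, (s00, eps0, r10), t.size,
                                                     scale_cov=w is None)
        corr = float(ucov[1, 2] / math.sqrt(ucov[1, 1] * ucov[2, 2]))
        return FitResult(
            residue=series.residue, mode=mode,
            epsilon=float(res.x[1]), d_epsilon=float(sd[1]),
            s0=float(res.x[0]), d_s0=float(sd[0]),
            r1=float(res.x[2]), d_r1=float(sd[2]), corr_eps_r1=corr,
            reduced_chi2=red_chi2, n_points=int(t.size),
        )

    # mode B: joint fit of buildup and decay sharing one R1
    if r1_series is None:
        raise ValueError("mode B requires the dedicated R1 decay series (r1_series)")
    tr, yr = r1_series.delays, r1_series.intensities
    if np.unique(tr).size < 2:
        raise IllPosedFitError(f"{series.residue}: all R1 delays are equal")
    wr = _weights(r1_series, weighted)
    a0 = float(yr[np.argmin(tr)]) or float(np.max(np.abs(yr))) or 1.0
    posr = tr[tr > 0]
    r10 = 1.0 / float(np.median(posr)) if posr.size else r10

    def residual(p):
        r_d = dnoe_model(t, p[0], p[1], p[2]) - y
        r_r = r1_model(tr, p[3], p[2]) - yr
        if w is not None:
            r_d = r_d * w
        if wr is not None:
            r_r = r_r * wr
        return np.concatenate([r_d, r_r])

    n_obs = t.size + tr.size
    res, ucov, sd, red_chi2 = _run_least_squares(residual, (s00, eps0, r10, a0), n_obs,
                                                 scale_cov=w is None or wr is None)
    corr = float(ucov[1, 2] / math.sqrt(ucov[1, 1] * ucov[2, 2]))
    return FitResult(
        residue=series.residue, mode=mode,
        epsilon=float(res.x[1]), d_epsilon=float(sd[1]),
        s0=float(res.x[0]), d_s0=float(sd[0]),
        r1=float(res.x[2]), d_r1=float(sd[2]), corr_eps_r1=corr,
        reduced_chi2=red_chi2, n_points=int(n_obs),
    )


def mode_a_sensitivity(
    series: IntensitySeries,
    r1_value: float,
    r1_sd: float,
    weighted: bool | None = None,
) -> float:
    """Sensitivity of the mode-A NOE error to the fixed R1 value.

    Refits with R1 fixed at r1_value +/- r1_sd and returns the largest
    change in d_eps.  R1-error propagation into the NOE is typically
    negligible (changes below 1e-5) except for residues with eps below
    about 0.4, where the intensity range is large and eps couples more
    strongly to R1.
    """
    base = fit_dnoe(series, FitMode.A_SEQUENTIAL, r1_fixed=r1_value, weighted=weighted)
    deltas = []
    for r1 in (r1_value - r1_sd, r1_value + r1_sd):
        alt = fit_dnoe(series, FitMode.A_SEQUENTIAL, r1_fixed=r1, weighted=weighted)
        deltas.append(abs(alt.d_epsilon - base.d_epsilon))
    return max(deltas)


def fit_dnoe_table(
    series_map: Mapping[str, IntensitySeries],
    mode: FitMode | str,
    r1_table: Mapping[str, object] | None = None,
    r1_series_map: Mapping[str, IntensitySeries] | None = None,
    weighted: bool | None = None,
) -> list[FitResult]:
    """Fit every residue of a table in one mode.

    ``r1_table`` (mode A) maps residue -> rate, (rate, sd) or R1Fit;
    ``r1_series_map`` (mode B) maps residue -> decay series.
    """
    mode = FitMode(mode)
    out = []
    for res, series in series_map.items():
        kwargs = {}
        if mode is FitMode.A_SEQUENTIAL:
            if r1_table is None or res not in r1_table:
                raise AlignmentError(f"no R1 value available for residue {res!r}")
            kwargs["r1_fixed"] = r1_table[res]
        elif mode is FitMode.B_SIMULTANEOUS:
            if r1_series_map is None or res not in r1_series_map:
                raise AlignmentError(f"no R1 series available for residue {res!r}")
            kwargs["r1_series"] = r1_series_map[res]
        out.append(fit_dnoe(series, mode, weighted=weighted, **kwargs))
    return out


@dataclass
class ModeComparison:
    """Pairwise agreement and error-ratio statistics between two result lists."""

    n_residues: int
    pairwise_rmsd_eps: float
    pairwise_rmsd_r1: float
    mean_sigma_eps_a: float
    mean_sigma_eps_b: float
    mean_sigma_r1_a: float
    mean_sigma_r1_b: float

    @property
    def error_ratio_eps(self) -> float:
        """Mean d_eps of the second list over the first."""
        return self.mean_sigma_eps_b / self.mean_sigma_eps_a

    @property
    def error_ratio_r1(self) -> float:
        """Mean d_R1 of the second list over the first."""
        return self.mean_sigma_r1_b / self.mean_sigma_r1_a


def _result_map(results: Sequence) -> dict[str, object]:
    return {r.residue: r for r in results}


def compare_modes(results_a: Sequence, results_b: Sequence) -> ModeComparison:
    """Residue-wise comparison of two fit-result lists (e.g. two modes)."""
    map_a, map_b = _result_map(results_a), _result_map(results_b)
    if set(map_a) != set(map_b):
        offenders = sorted(set(map_a) ^ set(map_b))
        raise AlignmentError(f"residue sets differ; offenders: {offenders}")
    residues = [r.residue for r in results_a]
    eps_a = np.array([map_a[r].epsilon for r in residues])
    eps_b = np.array([map_b[r].epsilon for r in residues])
    d_eps_a = np.array([map_a[r].d_epsilon for r in residues])
    d_eps_b = np.array([map_b[r].d_epsilon for r in residues])
    r1_a = np.array([map_a[r].r1 for r in residues], dtype=float)
    r1_b = np.array([map_b[r].r1 for r in residues], dtype=float)
    d_r1_a = np.array([map_a[r].d_r1 for r in residues], dtype=float)
    d_r1_b = np.array([map_b[r].d_r1 for r in residues], dtype=float)

    both_r1 = ~np.isnan(r1_a) & ~np.isnan(r1_b)
    rmsd_r1 = (
        float(np.sqrt(np.mean((r1_a[both_r1] - r1_b[both_r1]) ** 2)))
        if both_r1.any()
        else math.nan
    )
    return ModeComparison(
        n_residues=len(residues),
        pairwise_rmsd_eps=float(np.sqrt(np.mean((eps_a - eps_b) ** 2))),
        pairwise_rmsd_r1=rmsd_r1,
        mean_sigma_eps_a=float(np.mean(d_eps_a)),
        mean_sigma_eps_b=float(np.mean(d_eps_b)),
        mean_sigma_r1_a=float(np.nanmean(d_r1_a)),
        mean_sigma_r1_b=float(np.nanmean(d_r1_b)),
    )


def reduced_grid_report(
    series_map: Mapping[str, IntensitySeries],
    subgrids: Sequence[Sequence[float]],
    mode: FitMode | str = FitMode.C_STANDALONE,
    r1_table: Mapping[str, object] | None = None,
    weighted: bool | None = None,
) -> pd.DataFrame:
    """Per-residue eps differences between full and curtailed delay grids.

    Each subgrid must be a subset of the full delay grid, contain 0 and
    the maximal delay, and have at least 4 delays (the smallest validated
    design).  Returns rows (residue, subgrid, eps_full, d_eps_full,
    eps_sub, d_eps_sub, delta_eps) with delta_eps = eps(full) - eps(sub).
    """
    mode = FitMode(mode)
    # validate subgrids against the common full grid
    all_delays = np.unique(np.concatenate([s.delays for s in series_map.values()]))
    t_max = all_delays.max()
    clean_grids = []
    for g in subgrids:
        g = np.unique(np.asarray(g, dtype=float))
        if g.size < 4:
            raise ValueError(
                f"subgrid {g.tolist()} refused: fewer than 4 delays is under-determined"
            )
        if not np.isclose(g, 0.0).any() or not np.isclose(g, t_max).any():
            raise ValueError(
                f"subgrid {g.tolist()} must contain 0 and the maximal delay {t_max}"
            )
        for d in g:
            if not np.isclose(all_delays, d).any():
                raise ValueError(f"subgrid delay {d} is not part of the full grid")
        clean_grids.append(g)

    def _fit(series):
        kwargs = {}
        if mode is FitMode.A_SEQUENTIAL:
            kwargs["r1_fixed"] = r1_table[series.residue]
        return fit_dnoe(series, mode, weighted=weighted, **kwargs)

    rows = []
    for res, series in series_map.items():
        full_fit = _fit(series)
        for gi, g in enumerate(clean_grids):
            keep = [p for p in series.points if np.isclose(g, p.delay).any()]
            sub = IntensitySeries(residue=res, experiment=series.experiment, points=keep)
            sub_fit = _fit(sub)
            rows.append({
                "residue": res,
                "subgrid": gi,
                "n_delays_sub": int(g.size),
                "eps_full": full_fit.epsilon,
                "d_eps_full": full_fit.d_epsilon,
                "eps_sub": sub_fit.epsilon,
                "d_eps_sub": sub_fit.d_epsilon,
                "delta_eps": full_fit.epsilon - sub_fit.epsilon,
            })
    return pd.DataFrame(rows)
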