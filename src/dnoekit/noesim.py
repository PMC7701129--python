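"""Synthetic NOE data generation and a three-pool relaxation simulator.

Two generators live here:

* an *ideal* generator producing buildup intensities exactly from
  S(t) = S0[eps + (1-eps)exp(-R1 t)] plus controlled Gaussian noise, and
* a *pool* simulator of the coupled longitudinal magnetizations of amide
  ¹⁵N, amide ¹H and water protons, used to reproduce the systematic
  errors that mis-set recycle and saturation delays create.

The pool model is the minimal Solomon-type system that shows every
qualitative effect of interest: heteronuclear cross relaxation sigma_NH
builds the NOE, chemical exchange with the huge, slowly relaxing water
pool transfers saturation into the amide protons, and a short recycle
delay leaves the reference nitrogen polarization short of equilibrium.
In deviation-from-equilibrium coordinates d = M - M_eq it is the linear
ODE d' = -L d with

        | R1N     lam      0       |
    L = | lam     R1H+k   -k/p     |
        | 0       -k       R1W+k/p |

where lam = sigma_NH * sign(gamma_H/gamma_N) (the negative nitrogen
magnetogyric ratio is carried by the coupling so that equilibrium
magnetizations can be kept positive: M_N = 1, M_H = |gamma_H/gamma_N|,
M_W = |gamma_H/gamma_N| * p), k is the amide-water exchange rate and
p the water:amide proton pool-size ratio (its appearance on both
exchange off-diagonals enforces detailed balance).  Homonuclear
water-amide NOE is folded into k.  Transverse relaxation, CSA and
DD/CSA cross-correlation are not modelled.

The cross-relaxation rate is implied by the target NOE: at the proton
saturation steady state eps = 1 + (gamma_H/gamma_N) * sigma_NH / R1N,
so sigma_NH = (eps - 1) * R1N / (gamma_H/gamma_N).  With exchange off
the N pool under proton saturation reduces *exactly* to the buildup
model with rate R1N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .peak_io import Experiment, IntensityPoint, IntensitySeries, SampleRates
from .scheduler import Schedule

__all__ = [
    "GAMMA_RATIO_HN",
    "DEFAULT_POOL_RATIO",
    "R1_DELAY_GRID",
    "SpinSystem",
    "NoiseModel",
    "SSNOESimResult",
    "make_spin_system",
    "evolve",
    "simulate_ssnoe",
    "simulate_dnoe_curve",
    "draw_residue_params",
    "generate_dnoe",
    "generate_r1",
]

#: gamma_H / gamma_N for 15N; negative because gamma_N < 0.
GAMMA_RATIO_HN = -9.866

#: Water:amide proton pool-size ratio for a dilute protein sample.
DEFAULT_POOL_RATIO = 1.0e4

#: Stand-in delay grid (s) for a dedicated R1 decay experiment:
#: 10 log-spaced recovery delays covering ~3/R1 for typical amide rates.
R1_DELAY_GRID = tuple(float(f"{t:.4g}") for t in np.geomspace(0.02, 3.0, 10))

_N, _H, _W = 0, 1, 2


@dataclass
class SpinSystem:
    """Three-pool (¹⁵N, amide ¹H, water) longitudinal relaxation system.

    Parameters
    ----------
    epsilon_true : float
        Target steady-state NOE under proton saturation; fixes sigma_NH.
    r1n, r1h, r1w : float
        Longitudinal rates of the three pools, s^-1.
    k_exchange : float
        Amide-water proton exchange rate, s^-1 (0 decouples water).
    gamma_ratio : float
        gamma_H/gamma_N (negative for 15N).
    pool_ratio : float
        Water:amide proton pool-size ratio.
    """

    epsilon_true: float
    r1n: float
    r1h: float
    r1w: float
    k_exchange: float = 0.0
    gamma_ratio: float = GAMMA_RATIO_HN
    pool_ratio: float = DEFAULT_POOL_RATIO
    nonphysical: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        for name, val in (("r1n", self.r1n), ("r1h", self.r1h), ("r1w", self.r1w)):
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val!r}")
        if self.k_exchange < 0:
            raise ValueError(f"k_exchange must be >= 0, got {self.k_exchange!r}")
        if self.gamma_ratio == 0 or self.pool_ratio <= 0:
            raise ValueError("gamma_ratio must be nonzero and pool_ratio > 0")
        self.nonphysical = self.sigma_nh ** 2 >= self.r1n * self.r1h

    @property
    def sigma_nh(self) -> float:
        """Cross-relaxation rate implied by the target steady-state NOE."""
        return (self.epsilon_true - 1.0) * self.r1n / self.gamma_ratio

    @property
    def eq_mags(self) -> np.ndarray:
        """Equilibrium magnetizations (N, H, W) with M_N^eq = 1."""
        g = abs(self.gamma_ratio)
        return np.array([1.0, g, g * self.pool_ratio])

    def relaxation_matrix(self) -> np.ndarray:
        """The 3x3 rate matrix L of d' = -L d (deviation coordinates)."""
        lam = self.sigma_nh * (1.0 if self.gamma_ratio > 0 else -1.0)
        k = self.k_exchange
        kp = k / self.pool_ratio
        return np.array([
            [self.r1n, lam, 0.0],
            [lam, self.r1h + k, -kp],
            [0.0, -k, self.r1w + kp],
        ])


def make_spin_system(
    epsilon_true: float,
    r1n: float,
    r1h: float,
    r1w: float,
    k_exchange: float = 0.0,
    gamma_ratio: float = GAMMA_RATIO_HN,
    pool_ratio: float = DEFAULT_POOL_RATIO,
) -> SpinSystem:
    """Build a :class:`SpinSystem`, warning if the implied coupling is non-physical.

    A |sigma_NH| at or above sqrt(R1N*R1H) would make the N-H relaxation
    block indefinite; the system is still returned (useful in parameter
    scans) but carries the ``nonphysical`` flag.
    """
    sys_ = SpinSystem(
        epsilon_true=epsilon_true, r1n=r1n, r1h=r1h, r1w=r1w,
        k_exchange=k_exchange, gamma_ratio=gamma_ratio, pool_ratio=pool_ratio,
    )
    if sys_.nonphysical:
        warnings.warn(
            f"implied |sigma_NH|={abs(sys_.sigma_nh):.4g} violates the coupling bound "
            f"sqrt(R1N*R1H)={math.sqrt(r1n * r1h):.4g}; simulation permitted but "
            "auto-relaxation rates are inconsistent",
            stacklevel=2,
        )
    return sys_


# condition-number bound above which the eigenbasis is considered unreliable
_EIG_COND_MAX = 1e8


def _propagate(L: np.ndarray, d0: np.ndarray, t: float) -> np.ndarray:
    """exp(-L t) @ d0 via eigen-decomposition, matrix-exponential fallback."""
    w, v = np.linalg.eig(L)
    if np.linalg.cond(v) < _EIG_COND_MAX:
        out = v @ (np.exp(-w * t) * np.linalg.solve(v, d0.astype(complex)))
        return np.real_if_close(out).real
    return expm(-L * t) @ d0


def evolve(
    sys: SpinSystem,
    duration: float,
    saturate_h: bool = False,
    saturate_w: bool = False,
    initial: Sequence[float] | None = None,
) -> np.ndarray:
    """Evolve the pool magnetizations for ``duration`` seconds.

    Saturated pools are clamped to zero and removed from the evolving
    subsystem; their equilibrium pull shifts the fixed point of the
    remaining pools (this is how proton saturation drives the nitrogen
    polarization to eps * M_N^eq).  ``initial`` defaults to thermal
    equilibrium; the all-zero state models the worst-case
    post-acquisition condition.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration!r}")
    eq = sys.eq_mags
    m = eq.copy() if initial is None else np.asarray(initial, dtype=float).copy()
    if m.shape != (3,):
        raise ValueError("initial state must have 3 components (N, H, W)")
    if duration == 0:
        return m
    clamped = [i for i, on in ((_H, saturate_h), (_W, saturate_w)) if on]
    free = [i for i in (_N, _H, _W) if i not in clamped]
    L = sys.relaxation_matrix()
    Lff = L[np.ix_(free, free)]
    d0 = m[free] - eq[free]
    if clamped:
        # clamped pools sit at M=0, i.e. delta_c = -eq_c, a constant forcing
        Lfc = L[np.ix_(free, clamped)]
        shift = np.linalg.solve(Lff, Lfc @ eq[clamped])
    else:
        shift = np.zeros(len(free))
    d_t = shift + _propagate(Lff, d0 - shift, duration)
    out = np.zeros(3)
    out[free] = eq[free] + d_t
    return out


@dataclass
class SSNOESimResult:
    """Apparent intensities and NOE from a simulated steady-state measurement."""

    s_sat_app: float
    s_ref_app: float
    epsilon_app: float


def simulate_ssnoe(
    sys: SpinSystem,
    s: Schedule,
    initial: Sequence[float] | None = None,
) -> SSNOESimResult:
    """Simulate one steady-state NOE measurement under a given schedule.

    Both branches start from the post-acquisition state (all pools
    zeroed — the worst case — unless ``initial`` is given).  The
    reference branch recovers for RD1 without saturation; the saturation
    branch recovers for RD2 and is then proton-saturated for D_sat.  The
    apparent NOE is the ratio of the two nitrogen readings.
    """
    start = np.zeros(3) if initial is None else np.asarray(initial, dtype=float)
    dsat = s.dsat_max
    s_ref = evolve(sys, s.rd1, initial=start)[_N]
    m = evolve(sys, s.rd2, initial=start)
    s_sat = evolve(sys, dsat, saturate_h=True, initial=m)[_N]
    return SSNOESimResult(s_sat_app=float(s_sat), s_ref_app=float(s_ref),
                          epsilon_app=float(s_sat / s_ref))


def simulate_dnoe_curve(sys: SpinSystem, s: Schedule) -> np.ndarray:
    """Nitrogen readings of a simulated buildup series (relative to M_N^eq).

    Each point restarts from the post-acquisition all-zero state,
    recovers for RD2, and is proton-saturated for its D_sat.
    """
    grid = s.dsat if s.is_grid else (float(s.dsat),)
    out = []
    for d in grid:
        m = evolve(sys, s.rd2, initial=np.zeros(3))
        out.append(evolve(sys, d, saturate_h=True, initial=m)[_N])
    return np.array(out)


@dataclass
class NoiseModel:
    """Gaussian intensity noise defined by an SNR at the largest |signal|.

    ``snr=None`` means noiseless.  The noise RMS is max|S|/snr, constant
    across delays of a series, matching a fixed spectral noise floor.
    """

    snr: float | None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError(f"snr must be > 0, got {self.snr!r}")


def draw_residue_params(
    n_residues: int,
    rng: np.random.Generator,
    eps_range: tuple[float, float] = (-0.9, 0.9),
    r1n_range: tuple[float, float] = (1.0, 1.6),
    prefix: str = "A",
) -> pd.DataFrame:
    """Draw per-residue true parameters (residue, epsilon_true, r1n)."""
    eps = rng.uniform(*eps_range, size=n_residues)
    r1n = rng.uniform(*r1n_range, size=n_residues)
    return pd.DataFrame({
        "residue": [f"{prefix}{i + 1}" for i in range(n_residues)],
        "epsilon_true": eps,
        "r1n": r1n,
    })


def _noisy_series(
    residue: str,
    delays: np.ndarray,
    signal: np.ndarray,
    noise: NoiseModel | None,
    rng: np.random.Generator,
    experiment: Experiment,
) -> IntensitySeries:
    if noise is None or noise.snr is None:
        pts = [IntensityPoint(delay=float(t), intensity=float(v))
               for t, v in zip(delays, signal)]
    else:
        rms = float(np.max(np.abs(signal))) / noise.snr
        vals = signal + rng.normal(0.0, rms, size=signal.shape)
        pts = [IntensityPoint(delay=float(t), intensity=float(v), noise_rms=rms)
               for t, v in zip(delays, vals)]
    return IntensitySeries(residue=residue, experiment=experiment, points=pts)


def generate_dnoe(
    schedule: Schedule,
    truth: pd.DataFrame,
    noise: NoiseModel | None,
    mode: str = "ideal",
    s0: float = 100.0,
    sample_rates: SampleRates | None = None,
    pool_ratio: float = DEFAULT_POOL_RATIO,
    rng: np.random.Generator | None = None,
) -> dict[str, IntensitySeries]:
    """Generate per-residue buildup tables for the residues in ``truth``.

    ``truth`` is a frame with columns (residue, epsilon_true, r1n), e.g.
    from :func:`draw_residue_params`.  In ``ideal`` mode intensities come
    exactly from the buildup model; in ``pools`` mode from the three-pool
    simulator (requires ``sample_rates`` for R1H, R1W and k).  A fixed
    noise seed reproduces tables bit for bit.
    """
    if mode not in {"ideal", "pools"}:
        raise ValueError(f"mode must be 'ideal' or 'pools', got {mode!r}")
    if not schedule.is_grid:
        raise ValueError("generate_dnoe needs a DNOE schedule with a saturation-delay grid")
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else 0)
    delays = np.asarray(schedule.dsat, dtype=float)
    if mode == "pools":
        if sample_rates is None:
            raise ValueError("pool mode needs sample_rates (r1h, r1w, k_exchange)")
        f_rd2 = math.exp(-schedule.rd2 * sample_rates.r1w)
        if f_rd2 > schedule.threshold:
            warnings.warn(
                f"RD2={schedule.rd2} s is inadequate for equilibrium restart "
                f"(exp(-RD2*R1W)={f_rd2:.3g} > {schedule.threshold}); buildup "
                "points will carry systematic errors",
                stacklevel=2,
            )
    out: dict[str, IntensitySeries] = {}
    for row in truth.itertuples(index=False):
        if mode == "ideal":
            signal = s0 * (row.epsilon_true
                           + (1.0 - row.epsilon_true) * np.exp(-row.r1n * delays))
        else:
            sys_ = make_spin_system(
                epsilon_true=float(row.epsilon_true), r1n=float(row.r1n),
                r1h=sample_rates.r1h, r1w=sample_rates.r1w,
                k_exchange=sample_rates.k_exchange, pool_ratio=pool_ratio,
            )
            signal = s0 * simulate_dnoe_curve(sys_, schedule)
        out[row.residue] = _noisy_series(row.residue, delays, signal, noise, rng,
                                         Experiment.DNOE)
    return out


def generate_r1(
    truth: pd.DataFrame,
    noise: NoiseModel | None,
    delays: Sequence[float] = R1_DELAY_GRID,
    amplitude: float = 100.0,
    rng: np.random.Generator | None = None,
) -> dict[str, IntensitySeries]:
    """Generate dedicated R1 decay tables A*exp(-R1N t) for ``truth`` residues."""
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else 0)
    t = np.asarray(delays, dtype=float)
    out: dict[str, IntensitySeries] = {}
    for row in truth.itertuples(index=False):
        signal = amplitude * np.exp(-row.r1n * t)
        out[row.residue] = _noisy_series(row.residue, t, signal, noise, rng,
                                         Experiment.R1)
    return out
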