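"""Mean-square displacement, Einstein-relation self-diffusion, and
Arrhenius diagnostics.

MSD must be computed on unwrapped coordinates (``Frame.unwrapped``); a
wrapped-only trajectory raises.  The diffusive window is detected from the
local log-log slope beta: D is fit only where |beta - 1| <= beta_tol, and
ballistic or glassy inputs raise ``NoDiffusiveRegimeError`` instead of
reporting a spurious coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .core import Trajectory

__all__ = [
    "MSDSeries",
    "DiffusionEstimate",
    "ArrheniusResult",
    "NoDiffusiveRegimeError",
    "compute_msd",
    "fit_diffusion",
    "arrhenius_analysis",
    "R_GAS",
]

R_GAS = 8.31446261815324e-3   # kJ / (mol K)


class NoDiffusiveRegimeError(RuntimeError):
    pass


@dataclass
class MSDSeries:
    lag: np.ndarray        # ps
    msd: np.ndarray        # Å^2
    n_samples: np.ndarray  # origin-particle samples per lag
    species: str = ""


@dataclass
class DiffusionEstimate:
    D: float                     # Å^2/ps
    window: tuple[float, float]  # ps
    beta: float                  # mean log-log slope in window
    stderr: float


@dataclass
class ArrheniusResult:
    activation_energy: float     # kJ/mol
    prefactor: float             # Å^2/ps
    r_squared: float
    residuals: dict[float, float]   # T -> residual of ln D
    excluded: list[float]


def _com_series(traj: Trajectory, species: str) -> np.ndarray:
    """(n_frames, n_molecules, 3) centre-of-mass series from unwrapped coords."""
    top = traj.topology
    sel = np.flatnonzero(top.molecule_type == species)
    if len(sel) == 0:
        raise ValueError(f"no molecules of type {species!r}")
    mol_of = top.molecule_id[sel]
    mols, inverse = np.unique(mol_of, return_inverse=True)
    masses = top.mass[sel]
    total = np.zeros(len(mols))
    np.add.at(total, inverse, masses)
    out = np.empty((traj.n_frames, len(mols), 3))
    for t, fr in enumerate(traj.frames):
        if fr.unwrapped is None:
            raise ValueError(
                "trajectory has no unwrapped coordinates; MSD on wrapped "
                "coordinates is invalid — regenerate or unwrap first")
        weighted = fr.unwrapped[sel] * masses[:, None]
        acc = np.zeros((len(mols), 3))
        np.add.at(acc, inverse, weighted)
        out[t] = acc / total[:, None]
    return out


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one (T, 3) track via the FFT identity."""
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    s2 = np.zeros(n)
    for axis in range(x.shape[1]):
        f = np.fft.rfft(x[:, axis], nfft)
        acf = np.fft.irfft(f * f.conj(), nfft)[:n]
        s2 += acf
    d = (x ** 2).sum(axis=1)
    sumsq = np.concatenate([[0.0], np.cumsum(d)])
    # S1(tau) = sum over valid origins t of (d[t] + d[t+tau])
    total = sumsq[-1]
    tau = np.arange(n)
    s1 = sumsq[n - tau] + (total - sumsq[tau])
    counts = n - tau
    return (s1 - 2.0 * s2) / counts


def compute_msd(traj: Trajectory, species: str,
                max_lag: float | None = None) -> MSDSeries:
    """MSD(tau) averaged over all time origins and molecular centres of mass."""
    dt = traj.uniform_dt()
    com = _com_series(traj, species)
    n_frames, n_mol, _ = com.shape
    span = (n_frames - 1) * dt
    if max_lag is None:
        max_lag = span
    n_lags = min(n_frames, int(round(max_lag / dt)) + 1)
    msd = np.zeros(n_frames)
    for m in range(n_mol):
        msd += _msd_fft(com[:, m, :])
    msd /= n_mol
    msd = np.clip(msd, 0.0, None)     # FFT round-off at lag 0
    lags = np.arange(n_lags) * dt
    counts = (n_frames - np.arange(n_lags)) * n_mol
    return MSDSeries(lag=lags, msd=msd[:n_lags], n_samples=counts,
                     species=species)


def fit_diffusion(msd: MSDSeries, beta_tol: float = 0.1,
                  smooth: int = 5) -> DiffusionEstimate:
    """Einstein-relation D from the longest lag window with log-log slope ~ 1."""
    if len(msd.lag) < 10:
        raise ValueError("need at least 10 lag points")
    lag = msd.lag[1:]
    val = msd.msd[1:]
    if np.max(msd.msd) < 1e-12:
        # static system: MSD identically zero
        return DiffusionEstimate(D=0.0, window=(float(lag[0]), float(lag[-1])),
                                 beta=0.0, stderr=0.0)
    positive = val > 0
    if positive.sum() < 5:
        raise NoDiffusiveRegimeError(
            "no diffusive regime: too few nonzero MSD points")
    beta = np.full(len(lag), np.nan)
    logl = np.log(lag[positive])
    logm = np.log(val[positive])
    grad = np.gradient(logm, logl)
    grad = uniform_filter1d(grad, size=min(smooth, len(grad)))
    beta[positive] = grad
    ok = np.abs(beta - 1.0) <= beta_tol
    # longest contiguous run
    best_len, best_start, run_start = 0, -1, None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < 2:
        raise NoDiffusiveRegimeError(
            "no diffusive regime found (|beta - 1| never within tolerance); "
            "a longer trajectory may be needed")
    sel = slice(best_start, best_start + best_len)
    res = stats.linregress(lag[sel], val[sel])
    D = max(res.slope / 6.0, 0.0)
    return DiffusionEstimate(
        D=float(D),
        window=(float(lag[sel][0]), float(lag[sel][-1])),
        beta=float(np.nanmean(beta[sel])),
        stderr=float(res.stderr / 6.0) if res.stderr is not None else 0.0,
    )


def arrhenius_analysis(D_by_T: dict[float, float]) -> ArrheniusResult:
    """ln D vs 1/T linear fit: activation energy, prefactor, R², residuals.

    Non-positive D values are excluded with a warning; per-point residuals
    are the deviation diagnostic for non-Arrhenius transport.
    """
    excluded = sorted(t for t, d in D_by_T.items() if d <= 0)
    if excluded:
        warnings.warn(f"excluding temperatures with D <= 0: {excluded}")
    pts = sorted((t, d) for t, d in D_by_T.items() if d > 0)
    if len(pts) < 2:
        raise ValueError("need at least 2 temperatures with D > 0")
    if len(pts) == 2:
        warnings.warn("only 2 points: fit is exact, no degrees of freedom")
    temps = np.array([p[0] for p in pts])
    lnd = np.log([p[1] for p in pts])
    inv_t = 1.0 / temps
    res = stats.linregress(inv_t, lnd)
    pred = res.intercept + res.slope * inv_t
    r2 = 1.0 if len(pts) == 2 else float(res.rvalue ** 2)
    return ArrheniusResult(
        activation_energy=float(-res.slope * R_GAS),
        prefactor=float(np.exp(res.intercept)),
        r_squared=r2,
        residuals={float(t): float(l - p) for t, l, p in zip(temps, lnd, pred)},
        excluded=[float(t) for t in excluded],
    )
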