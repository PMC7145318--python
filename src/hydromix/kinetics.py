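"""Reactive-flux hydrogen-bond kinetics.

Uses the intermittent bond population operator h(t): c(t) is the probability
a pair bonded at a time origin is bonded a lag t later; n(t) is the
probability it is broken but still adjacent (within ``pair_cutoff``).  The
transient rate k(t) = -dc/dt is fit to the two-channel law

    k(t) = k_forward * c(t) - k_backward * n(t)

over a configurable window, giving the dissociation and reformation rate
constants and their reciprocal lifetimes.  The literature names the method
without printing equations; this forward/backward rate system is the
standard reading and is stated here explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .core import Trajectory, minimum_image
from .hbonds import HBondCriteria, attached_hydrogens, detect_hbonds

__all__ = [
    "BondPopulationSeries",
    "CorrelationCurves",
    "KineticsResult",
    "build_population_series",
    "compute_correlations",
    "fit_reactive_flux",
]


@dataclass
class BondPopulationSeries:
    """Binary bond presence per tracked donor-acceptor pair on a uniform grid."""

    h: np.ndarray              # (n_pairs, n_frames) bool
    present: np.ndarray        # (n_pairs, n_frames) bool: separation <= cutoff
    dt: float                  # ps
    pairs: list[tuple[int, int]]
    bond_class: str = "ALL"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=bool)
        self.present = np.asarray(self.present, dtype=bool)
        if self.h.shape != self.present.shape:
            raise ValueError("h and present must have the same shape")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_pairs(self) -> int:
        return self.h.shape[0]

    @property
    def n_frames(self) -> int:
        return self.h.shape[1]


@dataclass
class CorrelationCurves:
    t: np.ndarray
    c: np.ndarray
    n: np.ndarray


@dataclass
class KineticsResult:
    k_forward: float           # ps^-1
    k_backward: float          # ps^-1
    tau_forward: float         # ps
    tau_backward: float        # ps
    window: tuple[float, float]
    residual: float
    curves: CorrelationCurves | None = None


def build_population_series(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    class_filter: str = "ALL",
    pair_cutoff: float | None = None,
    *,
    include_ring_oxygens: bool = False,
    one_acceptor_per_hydrogen: bool = True,
    reuse_hydrogen_map: bool = True,
) -> BondPopulationSeries:
    """Track every donor-acceptor pair bonded in at least one frame.

    ``pair_cutoff`` (default: the distance criterion) defines the auxiliary
    "still adjacent" indicator used for n(t): reformation after destruction
    requires the pair to remain within reach.
    """
    dt = traj.uniform_dt()
    if pair_cutoff is None:
        pair_cutoff = criteria.d_max
    top = traj.topology
    hmap = attached_hydrogens(traj.frames[0], top) if reuse_hydrogen_map else None
    bonded_sets: list[set[tuple[int, int]]] = []
    for i, fr in enumerate(traj.frames):
        recs = detect_hbonds(
            fr, top, criteria, include_ring_oxygens=include_ring_oxygens,
            one_acceptor_per_hydrogen=one_acceptor_per_hydrogen,
            frame_index=i, hydrogen_map=hmap)
        frame_pairs = {(r.donor, r.acceptor) for r in recs
                       if class_filter in ("ALL", r.bond_class)}
        bonded_sets.append(frame_pairs)
    pairs = sorted(set().union(*bonded_sets))
    if not pairs:
        raise ValueError("no bonded pairs found for the requested class")
    index = {p: k for k, p in enumerate(pairs)}
    n_frames = traj.n_frames
    h = np.zeros((len(pairs), n_frames), dtype=bool)
    for t, frame_pairs in enumerate(bonded_sets):
        for p in frame_pairs:
            h[index[p], t] = True
    donors = np.array([p[0] for p in pairs])
    acceptors = np.array([p[1] for p in pairs])
    present = np.zeros_like(h)
    for t, fr in enumerate(traj.frames):
        d = minimum_image(fr.coordinates[donors] - fr.coordinates[acceptors],
                          fr.box)
        present[:, t] = np.linalg.norm(d, axis=1) <= pair_cutoff
    return BondPopulationSeries(h=h, present=present, dt=dt, pairs=pairs,
                                bond_class=class_filter)


def compute_correlations(series: BondPopulationSeries,
                         t_max: float | None = None) -> CorrelationCurves:
    """Intermittent correlation functions averaged over all time origins.

    c(t)  = sum_pairs <h(0) h(t)>       / sum_pairs <h(0)>
    n(t)  = sum_pairs <h(0) (1 - h(t)) present(t)> / sum_pairs <h(0)>

    with the origin average restricted, per lag, to origins that fit in the
    trajectory; c(0) = 1, n(0) = 0 for binary h.
    """
    h = series.h.astype(float)
    n_frames = series.n_frames
    span = (n_frames - 1) * series.dt
    if t_max is None:
        t_max = span
    if t_max > span + 1e-9:
        raise ValueError("t_max exceeds the trajectory span")
    n_lags = int(round(t_max / series.dt)) + 1

    nfft = 1 << int(np.ceil(np.log2(2 * n_frames)))
    fh = np.fft.rfft(h, nfft, axis=1)
    # numerator of c: sum over pairs and origins of h(t0) h(t0+lag)
    num_c = np.fft.irfft(fh.conj() * fh, nfft, axis=1)[:, :n_lags].sum(axis=0)
    g = (1.0 - h) * series.present
    fg = np.fft.rfft(g, nfft, axis=1)
    num_n = np.fft.irfft(fh.conj() * fg, nfft, axis=1)[:, :n_lags].sum(axis=0)

    # denominator: bonded-origin count per lag
    s = h.sum(axis=0)
    cum = np.concatenate([[0.0], np.cumsum(s)])
    denom = cum[n_frames - np.arange(n_lags)]
    if denom[0] <= 0:
        raise ValueError("no bonded origin events")
    valid = denom > 0
    c = np.where(valid, num_c / np.where(valid, denom, 1.0), np.nan)
    n = np.where(valid, num_n / np.where(valid, denom, 1.0), np.nan)
    # FFT round-off can leave tiny negatives
    c = np.clip(c, 0.0, None)
    n = np.clip(n, 0.0, None)
    t = np.arange(n_lags) * series.dt
    return CorrelationCurves(t=t, c=c, n=n)


def fit_reactive_flux(
    curves: CorrelationCurves,
    window: tuple[float, float] | None = None,
) -> KineticsResult:
    """Least-squares fit of k(t) = k_f c(t) - k_b n(t) with nonnegative rates.

    k(t) is obtained by central differences of c.  The default window is
    decay-adaptive: it ends where c(t) has relaxed to within 5% of its tail
    plateau and starts shortly after lag zero (skipping transients).  A
    fixed fraction of the trajectory span would drown fast decays in
    plateau noise when the span far exceeds the relaxation time.
    """
    t, c, n = curves.t, curves.c, curves.n
    if len(t) < 5:
        raise ValueError("need at least 5 lag points")
    t_max = t[-1]
    dt0 = t[1] - t[0]
    if window is None:
        tail = c[-max(5, len(c) // 10):]
        c_inf = float(np.nanmean(tail))
        amp = c[0] - c_inf
        if amp > 0:
            decayed = np.flatnonzero(c - c_inf <= 0.05 * amp)
            t2 = float(t[decayed[0]]) if len(decayed) else t_max
        else:
            t2 = t_max
        t2 = max(t2, 10.0 * dt0)          # keep enough points to regress
        t2 = min(t2, t_max)
        window = (max(dt0, 0.05 * t2), t2)
    t1, t2 = window
    if not (0.0 <= t1 < t2 <= t_max + 1e-9):
        raise ValueError(f"fit window {window} outside the curves")
    dt = t[1] - t[0]
    k = np.empty(len(t))
    k[1:-1] = -(c[2:] - c[:-2]) / (2.0 * dt)
    k[0] = -(c[1] - c[0]) / dt
    k[-1] = -(c[-1] - c[-2]) / dt
    sel = (t >= t1) & (t <= t2) & np.isfinite(c) & np.isfinite(n) & np.isfinite(k)
    sel[0] = sel[-1] = False          # one-sided differences excluded
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than 2 usable points")
    if not np.any(np.diff(c[sel]) < 0):
        raise ValueError("c(t) is not decreasing anywhere in the fit window")
    design = np.stack([c[sel], -n[sel]], axis=1)
    if np.allclose(n[sel], 0.0) and np.ptp(c[sel]) < 1e-12:
        raise ValueError("singular design: n == 0 and c constant in window")
    coef, rnorm = nnls(design, k[sel])
    k_f, k_b = float(coef[0]), float(coef[1])
    residual = float(rnorm / np.sqrt(sel.sum()))
    if k_f == 0.0:
        warnings.warn("k_forward fitted to zero; tau_forward is infinite")
        tau_f = np.inf
    else:
        tau_f = 1.0 / k_f
    if k_b == 0.0:
        warnings.warn("k_backward fitted to zero; tau_backward is infinite")
        tau_b = np.inf
    else:
        tau_b = 1.0 / k_b
    return KineticsResult(k_forward=k_f, k_backward=k_b,
                          tau_forward=tau_f, tau_backward=tau_b,
                          window=(float(t1), float(t2)), residual=residual,
                          curves=curves)
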