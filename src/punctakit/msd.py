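"""Mean-squared-displacement analysis and confined-diffusion model fitting.

The motion model fitted to MSD curves is

    MSD(t) = A (1 - exp(-t/tau)) + 4 D t + v^2 t^2

with confinement area ``A`` (µm²), relaxation time ``tau`` (s), a linear
diffusion coefficient ``D`` (µm²/s) and active-transport speed ``v``
(µm/s). The reported effective diffusion coefficient is defined as
``D_eff = A / (4 tau)``; the fitted linear coefficient is kept separately
as ``linear_D``.

The fitting surface follows the model/results convention: build a
:class:`ConfinedDiffusionModel` from a curve, call :meth:`fit`, and read
estimates off the returned :class:`MSDFit`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .tracking import Trajectory

__all__ = [
    "MSDCurve",
    "MSDFit",
    "ConfinedDiffusionModel",
    "compute_msd",
    "average_msd",
    "fit_msd_model",
]


@dataclass
class MSDCurve:
    """Lag time vs mean-squared displacement.

    ``n_pairs`` counts the displacement pairs contributing at each lag (for
    a single track) or the contributing tracks (for an averaged curve, in
    ``n_tracks``). Lags are strictly ascending starting at one frame
    interval.
    """

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    sem_um2: np.ndarray | None = None
    n_tracks: np.ndarray | None = None
    source_track_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, float)
        self.msd_um2 = np.asarray(self.msd_um2, float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly ascending")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be non-negative")

    def __len__(self) -> int:
        return len(self.lags_s)

    def plot(self, ax=None, **kwargs):
        """Plot the curve (error bars = SEM when available); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        yerr = self.sem_um2 if self.sem_um2 is not None else None
        ax.errorbar(self.lags_s, self.msd_um2, yerr=yerr, fmt="o-", ms=3, **kwargs)
        ax.set_xlabel("lag time (s)")
        ax.set_ylabel(r"MSD ($\mu m^2$)")
        return ax


def compute_msd(traj: Trajectory, max_lag_frames: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    For lag ``l`` the MSD is the mean squared displacement over all sample
    pairs ``l`` frames apart. Pairs spanning a bridged detection gap are
    excluded, so only displacements observed over fully sampled intervals
    contribute.
    """
    if len(traj) < 2:
        raise ValueError("compute_msd requires at least 2 samples")
    frames = np.asarray(traj.frames)
    pos = traj.positions()
    span = int(frames[-1] - frames[0])
    if max_lag_frames is None:
        max_lag_frames = span
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")
    if max_lag_frames > span:
        warnings.warn(
            f"max_lag_frames={max_lag_frames} exceeds track span {span}; truncating",
            stacklevel=2,
        )
        max_lag_frames = span

    present = set(int(f) for f in frames)
    gap_free_upto: dict[int, int] = {}
    # for each sample, the largest frame reachable without crossing a
    # missing frame (pairs spanning bridged gaps are excluded)
    sorted_frames = sorted(present)
    runs: list[tuple[int, int]] = []
    run_start = sorted_frames[0]
    prev = sorted_frames[0]
    for f in sorted_frames[1:]:
        if f != prev + 1:
            runs.append((run_start, prev))
            run_start = f
        prev = f
    runs.append((run_start, prev))
    run_of = {}
    for ri, (a, b) in enumerate(runs):
        for f in range(a, b + 1):
            run_of[f] = ri

    dt = np.diff(traj.times).min() / np.diff(frames).min() if len(traj) > 1 else 0.2
    frame_to_idx = {int(f): i for i, f in enumerate(frames)}
    lags, msds, counts = [], [], []
    for lag in range(1, max_lag_frames + 1):
        sq = []
        for f in sorted_frames:
            g = f + lag
            if g in present and run_of[f] == run_of[g]:
                i, j = frame_to_idx[f], frame_to_idx[g]
                d = pos[j] - pos[i]
                sq.append(d @ d)
        if sq:
            lags.append(lag * dt)
            msds.append(float(np.mean(sq)))
            counts.append(len(sq))
    return MSDCurve(
        np.array(lags), np.array(msds), np.array(counts), source_track_ids=[traj.track_id]
    )


def average_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Ensemble average of per-track MSD curves.

    Per-lag unweighted mean across the tracks that reach that lag, with the
    SEM over contributing tracks and the contributing-track count reported
    per lag — fewer tracks reach longer lags, which is the usual source of
    noise at the curve tail.
    """
    if not curves:
        raise ValueError("average_msd requires at least one curve")
    by_lag: dict[float, list[float]] = {}
    for c in curves:
        for lag, v in zip(c.lags_s, c.msd_um2):
            by_lag.setdefault(round(float(lag), 12), []).append(float(v))
    lags = np.array(sorted(by_lag))
    means = np.array([np.mean(by_lag[l]) for l in lags])
    ns = np.array([len(by_lag[l]) for l in lags])
    sems = np.array(
        [np.std(by_lag[l], ddof=1) / np.sqrt(len(by_lag[l])) if len(by_lag[l]) > 1 else 0.0 for l in lags]
    )
    ids = sorted({tid for c in curves for tid in c.source_track_ids})
    return MSDCurve(lags, means, ns.copy(), sem_um2=sems, n_tracks=ns, source_track_ids=ids)


def msd_model(t: np.ndarray, a: float, tau: float, d: float, v: float) -> np.ndarray:
    """Confined + diffusive + directed MSD: A(1-e^{-t/tau}) + 4Dt + v²t²."""
    t = np.asarray(t, float)
    if tau > 0:
        conf = a * (1.0 - np.exp(-t / tau))
    else:
        conf = np.full_like(t, a)  # tau -> 0 limit: instantaneous plateau
    return conf + 4.0 * d * t + v * v * t * t


@dataclass
class MSDFit:
    """Fitted motion-model parameters and diagnostics.

    ``d_eff`` is always ``a / (4 tau)`` (the reported effective diffusion
    coefficient); ``linear_d`` is the fitted coefficient of the 4Dt term.
    """

    a: float
    tau: float
    linear_d: float
    v: float
    rss: float
    fit_range: tuple[int, int]
    n_lags_used: int
    boundary_warning: str | None = None

    @property
    def d_eff(self) -> float:
        if self.tau > 0:
            return self.a / (4.0 * self.tau)
        return float("inf") if self.a > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "Confined-diffusion MSD fit",
            "--------------------------",
            f"A (confinement area) : {self.a:.6g} um^2",
            f"tau (relaxation time): {self.tau:.6g} s",
            f"D_eff = A/(4 tau)    : {self.d_eff:.6g} um^2/s",
            f"linear D (4Dt term)  : {self.linear_d:.6g} um^2/s",
            f"v (transport speed)  : {self.v:.6g} um/s",
            f"residual sum sq      : {self.rss:.6g}",
            f"lags used            : {self.fit_range[0]}..{self.fit_range[1]} ({self.n_lags_used})",
        ]
        if self.boundary_warning:
            lines.append(f"warning              : {self.boundary_warning}")
        return "\n".join(lines)

    def plot(self, curve: "MSDCurve", ax=None):
        """Overlay the fitted model on a measured curve; returns the axes."""
        ax = curve.plot(ax=ax, label="measured")
        t = np.linspace(curve.lags_s[0], curve.lags_s[-1], 200)
        ax.plot(t, msd_model(t, self.a, self.tau, self.linear_d, self.v), "r-", label="fit")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "A": self.a,
            "tau": self.tau,
            "D_eff": self.d_eff,
            "linear_D": self.linear_d,
            "v": self.v,
            "rss": self.rss,
            "fit_range": list(self.fit_range),
        }


class ConfinedDiffusionModel:
    """Nonlinear least-squares fit of the motion model to an MSD curve.

    Parameters
    ----------
    curve : MSDCurve
        Typically an ensemble-averaged curve.
    fit_fraction : float
        Fraction of the shortest lags used for fitting (default 0.25); MSD
        tails are dominated by few long-lag pairs and statistical
        artifacts, so fits are restricted to the curve head.
    constrain_v_zero : bool
        Fix the transport term at zero (pure confined + diffusive motion).
    weighted : bool
        Weight residuals per lag (default). Ensemble curves carrying a
        cross-track SEM are weighted by 1/SEM (inverse-variance weighting);
        otherwise sqrt(n_pairs) serves as a proxy, since short lags average
        many more displacement pairs than long ones. The solution is
        unchanged on noise-free curves.
    """

    def __init__(
        self,
        curve: MSDCurve,
        fit_fraction: float = 0.25,
        constrain_v_zero: bool = False,
        weighted: bool = True,
    ) -> None:
        if not (0 < fit_fraction <= 1):
            raise ValueError("fit_fraction must lie in (0, 1]")
        self.curve = curve
        self.fit_fraction = fit_fraction
        self.constrain_v_zero = constrain_v_zero
        self.weighted = weighted

    def _initial_guess(self, t: np.ndarray, y: np.ndarray) -> np.ndarray:
        n = len(t)
        a0 = float(np.mean(y[-max(1, n // 4) :]))  # plateau from last quartile
        a0 = max(a0, 1e-12)
        above = np.nonzero(y >= (1.0 - 1.0 / np.e) * a0)[0]
        tau0 = float(t[above[0]]) if len(above) else float(t[n // 2])
        tau0 = max(tau0, 1e-6)
        d0 = max(float((y[1] - y[0]) / (t[1] - t[0]) / 4.0), 0.0) if n > 1 else 0.0
        return np.array([a0, tau0, d0, 0.0])

    def fit(self) -> MSDFit:
        curve = self.curve
        n_use = max(4, int(round(self.fit_fraction * len(curve))))
        n_use = min(n_use, len(curve))
        if n_use < 4:
            raise ValueError("need at least 4 usable lags to fit the MSD model")
        t = curve.lags_s[:n_use]
        y = curve.msd_um2[:n_use]
        w = np.ones(n_use)
        if self.weighted:
            sem = None if curve.sem_um2 is None else np.asarray(curve.sem_um2[:n_use], float)
            if sem is not None and np.any(sem > 0):
                sem = np.where(sem > 0, sem, sem[sem > 0].min())
                w = 1.0 / sem
            else:
                w = np.sqrt(curve.n_pairs[:n_use].astype(float))
            w = w / w.max()

        p0 = self._initial_guess(t, y)

        if self.constrain_v_zero:
            def resid(p):
                return w * (msd_model(t, p[0], p[1], p[2], 0.0) - y)
            x0, lb, ub = p0[:3], [0.0, 1e-9, 0.0], [np.inf] * 3
        else:
            def resid(p):
                return w * (msd_model(t, *p) - y)
            x0, lb, ub = p0, [0.0, 1e-9, 0.0, 0.0], [np.inf] * 4

        x0 = np.clip(x0, lb, ub)
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise RuntimeError(
                f"MSD model fit failed: {sol.message}; x0={x0}, final residual norm="
                f"{np.linalg.norm(sol.fun):.3g}"
            )
        if self.constrain_v_zero:
            a, tau, d = sol.x
            v = 0.0
        else:
            a, tau, d, v = sol.x
        warning = None
        if tau <= 1e-8 and a > 0:
            warning = "tau at lower boundary with A > 0: plateau timescale unresolved"
            warnings.warn(warning, stacklevel=2)
        # report the plain (unweighted) residual sum of squares
        rss = float(np.sum((msd_model(t, a, tau, d, v) - y) ** 2))
        return MSDFit(
            a=float(a),
            tau=float(tau),
            linear_d=float(d),
            v=float(v),
            rss=rss,
            fit_range=(0, n_use - 1),
            n_lags_used=n_use,
            boundary_warning=warning,
        )


def fit_msd_model(
    curve: MSDCurve,
    fit_fraction: float = 0.25,
    constrain_v_zero: bool = False,
    weighted: bool = True,
) -> MSDFit:
    """Functional wrapper around :class:`ConfinedDiffusionModel`."""
    return ConfinedDiffusionModel(curve, fit_fraction, constrain_v_zero, weighted).fit()
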