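"""Photobleaching-recovery (FRAP) curve processing.

Raw ROI traces are double-normalized against a reference region (to
correct acquisition bleaching) and the nuclear background (to remove
offset):

    N(t) = [ (ROI(t) - BG(t)) / (REF(t) - BG(t)) ]
           x [ (mean_pre(REF) - mean_pre(BG)) / (mean_pre(ROI) - mean_pre(BG)) ]

so the pre-bleach mean of N is 1 by construction (exactly, when
noise-free). Frames acquired during the bleach pulse are instrument
artifacts and are excluded from the normalized curve.

Recovery is summarized by a single-exponential fit, following the
model/results convention: :class:`RecoveryModel` fits, :class:`RecoverySummary`
carries the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic import FrapSeries

__all__ = ["NormalizedFrapCurve", "RecoverySummary", "RecoveryModel", "double_normalize", "recovery_summary"]


@dataclass
class NormalizedFrapCurve:
    """Double-normalized recovery curve (bleach frames excluded).

    ``n_bleach_frame`` keeps the normalized intensity of the (excluded)
    bleach frame when it could be computed: it anchors the post-bleach
    floor of the recovery fit, which is otherwise unidentifiable for fast
    recoveries.
    """

    time: np.ndarray
    intensity: np.ndarray
    phase: np.ndarray  # 'pre' | 'post'
    bleach_time: float
    n_bleach_frame: float | None = None

    def pre(self) -> np.ndarray:
        return self.intensity[self.phase == "pre"]

    def post(self) -> np.ndarray:
        return self.intensity[self.phase == "post"]

    def post_times_since_bleach(self) -> np.ndarray:
        return self.time[self.phase == "post"] - self.bleach_time

    def plot(self, ax=None, **kwargs):
        """Plot the normalized recovery curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time, self.intensity, "o-", ms=3, **kwargs)
        ax.axvline(self.bleach_time, color="gray", ls="--", lw=0.8)
        ax.axhline(1.0, color="gray", ls=":", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized intensity")
        return ax


def double_normalize(series: FrapSeries) -> NormalizedFrapCurve:
    """Apply reference- and background-corrected, pre-bleach-anchored
    normalization to a three-phase FRAP series."""
    pre = series.phase == "pre"
    bleach = series.phase == "bleach"
    ref_bg = series.ref - series.bg
    analyzed = ~bleach
    bad = np.nonzero(analyzed & (ref_bg <= 0))[0]
    if len(bad):
        raise ValueError(
            f"reference minus background is non-positive at frame(s) {bad.tolist()}"
        )
    pre_ref = float(np.mean(series.ref[pre]) - np.mean(series.bg[pre]))
    pre_roi = float(np.mean(series.roi[pre]) - np.mean(series.bg[pre]))
    if pre_roi <= 0:
        raise ValueError("pre-bleach ROI minus background must be positive")
    n = (series.roi - series.bg) / ref_bg * (pre_ref / pre_roi)

    n_bleach_frame = None
    if bleach.any():
        bleach_time = float(series.time[bleach][-1])
        last_bleach = np.nonzero(bleach)[0][-1]
        if ref_bg[last_bleach] > 0:
            n_bleach_frame = float(n[last_bleach])
    else:
        bleach_time = float(series.time[pre][-1])
    keep = analyzed
    return NormalizedFrapCurve(
        time=series.time[keep],
        intensity=n[keep],
        phase=series.phase[keep],
        bleach_time=bleach_time,
        n_bleach_frame=n_bleach_frame,
    )


@dataclass
class RecoverySummary:
    """Single-exponential recovery estimates.

    ``mobile_fraction = (plateau - n_bleach) / (1 - n_bleach)`` — the
    fraction of the bleached population that exchanges; ``half_time =
    ln 2 / k``.
    """

    plateau: float
    n_bleach: float
    rate: float
    mobile_fraction: float
    half_time: float
    rss: float
    fit_failed: bool = False

    def summary(self) -> str:
        lines = [
            "FRAP recovery fit",
            "-----------------",
            f"post-bleach floor N_b : {self.n_bleach:.4f}",
            f"plateau               : {self.plateau:.4f}",
            f"rate k                : {self.rate:.6g} 1/s",
            f"half-time ln2/k       : {self.half_time:.6g} s",
            f"mobile fraction       : {self.mobile_fraction:.4f}",
            f"residual sum sq       : {self.rss:.4g}",
        ]
        if self.fit_failed:
            lines.append("warning               : exponential fit failed; plateau from last-quartile mean")
        return "\n".join(lines)


class RecoveryModel:
    """Fit ``N(t) = N_b + (plateau - N_b)(1 - e^{-k t})`` to post-bleach frames.

    When the curve carries a normalized bleach-frame value, the floor
    ``N_b`` is fixed to it and only (plateau, k) are fitted; otherwise all
    three parameters are free.
    """

    def __init__(self, curve: NormalizedFrapCurve, n_bleach: float | None = None) -> None:
        if np.sum(curve.phase == "post") < 4:
            raise ValueError("recovery fit requires at least 4 post-bleach frames")
        self.curve = curve
        self.n_bleach = n_bleach if n_bleach is not None else curve.n_bleach_frame

    def fit(self) -> RecoverySummary:
        t = self.curve.post_times_since_bleach()
        y = self.curve.post()

        nb_fixed = self.n_bleach
        nb0 = float(y[0]) if nb_fixed is None else float(nb_fixed)
        plateau0 = float(np.mean(y[-max(1, len(y) // 4) :]))
        k0 = 1.0 / max(float(t[-1]) / 3.0, 1e-6)

        if nb_fixed is None:
            def resid(p):
                nb, plateau, k = p
                return nb + (plateau - nb) * (1.0 - np.exp(-k * t)) - y
            x0 = [nb0, max(plateau0, nb0), max(k0, 1e-6)]
            lb, ub = [-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]
        else:
            def resid(p):
                plateau, k = p
                return nb0 + (plateau - nb0) * (1.0 - np.exp(-k * t)) - y
            x0 = [max(plateau0, nb0), max(k0, 1e-6)]
            lb, ub = [-np.inf, 1e-9], [np.inf, np.inf]

        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
            ok = sol.success
        except Exception:
            ok = False
        if not ok:
            warnings.warn("recovery fit did not converge; reporting last-quartile plateau", stacklevel=2)
            plateau = plateau0
            nb, k = nb0, float("nan")
            rss = float("nan")
            failed = True
        else:
            if nb_fixed is None:
                nb, plateau, k = map(float, sol.x)
            else:
                plateau, k = map(float, sol.x)
                nb = nb0
            rss = float(np.sum(sol.fun**2))
            failed = False
        denom = 1.0 - nb
        mobile = (plateau - nb) / denom if denom > 0 else float("nan")
        half = float(np.log(2.0) / k) if k and k > 0 else float("inf")
        return RecoverySummary(
            plateau=plateau,
            n_bleach=nb,
            rate=k,
            mobile_fraction=mobile,
            half_time=half,
            rss=rss,
            fit_failed=failed,
        )


def recovery_summary(curve: NormalizedFrapCurve) -> RecoverySummary:
    """Functional wrapper around :class:`RecoveryModel`."""
    return RecoveryModel(curve).fit()
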