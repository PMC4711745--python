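"""Vascular pharmacokinetics: background subtraction, vessel time-series
extraction and single-phase exponential-decay fitting.

The circulating half-life of an intravenously injected agent is read out
from the intravascular fluorescence time course: per-voxel background
(the pre-injection frames) is subtracted, the mean intensity inside a
vessel mask is extracted per frame, and the series is fit by nonlinear
least squares to

    I(t) = I0 * exp(-lambda * t),        t_half = ln 2 / lambda.

:class:`ExponentialDecay` follows the model/results idiom: build the
model from a series, call :meth:`~ExponentialDecay.fit`, and read the
estimates off the returned :class:`DecayFit`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .model import LabelVolume, ValidationError, VoxelGrid

#: Fitted decay rates below this (min^-1) are treated as "no decay".
LAMBDA_TOL = 1e-6


class FitError(RuntimeError):
    """Raised when the decay fit fails (constant or non-decaying series)."""


@dataclass
class DecayFit:
    """Results of an exponential-decay fit.

    ``t_half`` is exactly ``ln 2 / lam`` (minutes).  ``i0_se`` /
    ``lam_se`` are asymptotic standard errors from the least-squares
    covariance; ``offset`` is present only for the offset variant.
    """

    i0: float
    lam: float  # min^-1
    r_squared: float
    residual_se: float
    n_points: int
    i0_se: float = float("nan")
    lam_se: float = float("nan")
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise FitError(f"fitted decay rate must be > 0, got {self.lam}")

    @property
    def t_half(self) -> float:
        """Half-life in minutes, ln2 / lambda."""
        return float(np.log(2.0) / self.lam)

    @property
    def t_half_se(self) -> float:
        return float(np.log(2.0) * self.lam_se / self.lam**2)

    def predict(self, times) -> np.ndarray:
        return self.offset + self.i0 * np.exp(-self.lam * np.asarray(times, dtype=float))

    def to_dict(self) -> dict:
        return {
            "I0": self.i0,
            "I0_se": self.i0_se,
            "lambda_per_min": self.lam,
            "lambda_se_per_min": self.lam_se,
            "t_half_min": self.t_half,
            "t_half_se_min": self.t_half_se,
            "offset": self.offset,
            "r_squared": self.r_squared,
            "residual_se": self.residual_se,
            "n_points": self.n_points,
        }

    def summary(self) -> str:
        lines = [
            "Exponential decay fit  I(t) = I0 exp(-lambda t)"
            + (" + C" if self.offset else ""),
            f"  n points     : {self.n_points}",
            f"  I0           : {self.i0:.4g} (se {self.i0_se:.3g}) a.u.",
            f"  lambda       : {self.lam:.5g} (se {self.lam_se:.3g}) 1/min",
            f"  t_half       : {self.t_half:.4g} (se {self.t_half_se:.3g}) min",
            f"  R^2          : {self.r_squared:.4f}",
            f"  residual s.e.: {self.residual_se:.4g} a.u.",
        ]
        if self.offset:
            lines.insert(4, f"  offset C     : {self.offset:.4g} a.u.")
        return "\n".join(lines)

    def plot(self, times=None, series=None, ax=None):
        """Overlay the fitted curve on the data (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if times is not None and series is not None:
            ax.plot(times, series, "o", label="data")
        tt = np.linspace(0, times[-1] if times is not None else 3 * self.t_half, 200)
        ax.plot(tt, self.predict(tt), "-", label=f"fit, t½={self.t_half:.1f} min")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax


class ExponentialDecay:
    """Single-phase exponential decay model for an intensity series.

    Parameters
    ----------
    series, times:
        Intensity values (a.u.) and acquisition times (min); at least 4
        points, at least one positive value.
    with_offset:
        Fit ``I0 exp(-lambda t) + C`` instead of the pure decay.  Useful
        when a released-payload floor remains after background
        subtraction; off by default.
    """

    def __init__(self, series, times, with_offset: bool = False):
        self.series = np.asarray(series, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.with_offset = bool(with_offset)
        if self.series.ndim != 1 or self.series.shape != self.times.shape:
            raise ValidationError("series and times must be equal-length 1-D arrays")
        if len(self.series) < 4:
            raise ValidationError("need at least 4 time points")
        if not np.any(self.series > 0):
            raise ValidationError("series has no positive values")

    def _initial_guess(self) -> tuple[float, float]:
        # log-linear regression on the positive values only
        pos = self.series > 0
        t, y = self.times[pos], np.log(self.series[pos])
        if len(t) >= 2 and np.ptp(t) > 0:
            slope, intercept = np.polyfit(t, y, 1)
        else:
            slope, intercept = 0.0, y.mean()
        lam0 = max(-slope, 10 * LAMBDA_TOL)
        return float(np.exp(intercept)), float(lam0)

    def fit(self) -> DecayFit:
        """Nonlinear least squares; raises :class:`FitError` if the
        best-fit rate is non-positive or below tolerance."""
        i0_0, lam0 = self._initial_guess()
        t, y = self.times, self.series
        if self.with_offset:
            f = lambda tt, i0, lam, c: i0 * np.exp(-lam * tt) + c
            p0 = [max(i0_0 - y.min(), 1e-12), lam0, float(y.min())]
        else:
            f = lambda tt, i0, lam: i0 * np.exp(-lam * tt)
            p0 = [i0_0, lam0]
        try:
            popt, pcov = optimize.curve_fit(f, t, y, p0=p0, maxfev=20000)
        except RuntimeError as err:
            raise FitError(f"decay fit did not converge: {err}") from None
        lam = float(popt[1])
        if lam <= LAMBDA_TOL:
            raise FitError(
                f"series does not decay (lambda = {lam:.3g}/min <= {LAMBDA_TOL})"
            )
        resid = y - f(t, *popt)
        dof = max(len(y) - len(popt), 1)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
        return DecayFit(
            i0=float(popt[0]),
            lam=lam,
            r_squared=min(max(r2, 0.0), 1.0),
            residual_se=float(np.sqrt(ss_res / dof)),
            n_points=len(y),
            i0_se=float(se[0]),
            lam_se=float(se[1]),
            offset=float(popt[2]) if self.with_offset else 0.0,
        )


def fit_decay(series, times, with_offset: bool = False) -> DecayFit:
    """Functional wrapper: fit ``I(t) = I0 exp(-lambda t)`` to a series."""
    return ExponentialDecay(series, times, with_offset=with_offset).fit()


# ---------------------------------------------------------------------------
# image-side operations


def subtract_background(grid: VoxelGrid, pre_injection_frames) -> tuple[VoxelGrid, np.ndarray]:
    """Subtract the per-voxel mean of the pre-injection frames.

    Negatives are clipped to zero.  All frames, including the
    pre-injection ones, are retained; the returned boolean array flags
    which frames were used as background.
    """
    if not grid.is_timelapse:
        raise ValidationError("background subtraction needs a time-lapse grid")
    idx = np.atleast_1d(np.asarray(pre_injection_frames, dtype=int))
    if idx.size == 0:
        raise ValidationError("need at least one pre-injection frame")
    if idx.min() < 0 or idx.max() >= grid.n_frames:
        raise ValidationError(f"pre-injection frame index out of range 0..{grid.n_frames - 1}")
    background = grid.data[idx].mean(axis=0)  # (c, z, y, x)
    corrected = np.clip(grid.data - background[None], 0.0, None)
    flags = np.zeros(grid.n_frames, dtype=bool)
    flags[idx] = True
    return grid.with_data(corrected), flags


def extract_vessel_series(grid: VoxelGrid, vessel_mask: LabelVolume, channel: str):
    """Mean intensity per frame inside each vessel label.

    Returns ``(per_vessel, average)`` where ``per_vessel`` maps label ->
    series and ``average`` is the unweighted across-vessel mean series
    (each vessel counts equally regardless of size).
    """
    labels = vessel_mask.labels
    if not (labels > 0).any():
        raise ValidationError("vessel mask is empty")
    data = grid.channel(channel)
    if data.ndim == 3:
        data = data[None]
    ids = [int(l) for l in np.unique(labels) if l > 0]
    per_vessel = {}
    for l in ids:
        m = labels == l
        per_vessel[l] = data[:, m].mean(axis=1)
    average = np.mean([per_vessel[l] for l in ids], axis=0)
    return per_vessel, average


def vessel_mask_from_tracer(grid: VoxelGrid, threshold: float | None = None) -> LabelVolume:
    """Segment vessels from the vascular-tracer channel.

    The tracer is averaged over time and thresholded (Otsu by default);
    connected components become vessel labels.
    """
    tracer = grid.channel("vascular")
    if tracer.ndim == 4:
        tracer = tracer.mean(axis=0)
    thr = threshold_otsu(tracer) if threshold is None else threshold
    labels = cc_label(tracer > thr, connectivity=3)
    return LabelVolume(labels.astype(np.int32), provenance="vessel_mask_from_tracer")
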