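"""Melt-curve analysis: smoothed negative derivative and windowed peak calls.

The screening assay reads out as up to three peaks in ``-dF/dT``: SMN1
(~63 degC), SMN2 (~56 degC) and the Q quantity fragment (~49 degC).  The
derivative is estimated with a cubic Savitzky-Golay filter, which keeps the
peak-height bias of a logistic transition below 2% over the assay's
transition widths while strongly attenuating high-frequency fluorescence
noise.  A peak is "present" when its windowed maximum is a genuine local
maximum strictly inside the window and exceeds a robust noise floor by a
configurable factor; window-edge maxima are recorded but treated as absent,
so a neighbouring transition's shoulder (or a variant-shifted peak sliding
out of its window) never counts as a peak.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs, savgol_filter

from .synth import MeltCurve

__all__ = [
    "PeakWindow",
    "DEFAULT_WINDOWS",
    "DerivativeCurve",
    "MeltPeak",
    "PeakSet",
    "derivative",
    "call_peaks",
    "peaksets_to_frame",
]


class PeakWindow(str, enum.Enum):
    SMN1 = "SMN1"
    SMN2 = "SMN2"
    Q = "Q"


#: Temperature windows (degC) searched for each peak.  The windows are
#: asymmetric on purpose: each lower edge sits a full 6 degC above the next
#: cooler transition, where that transition's sigmoidal shoulder has decayed
#: well below any sane presence threshold.  The guard is only needed on the
#: low side — genetic variation under the probe can only *lower* a melting
#: temperature, so a variant-shifted SMN1 peak (shift beyond ~1 degC) drops
#: out of its window and the sample fails safe toward second-tier referral,
#: never toward a missed case.
DEFAULT_WINDOWS: dict[PeakWindow, tuple[float, float]] = {
    PeakWindow.SMN1: (62.0, 64.5),
    PeakWindow.SMN2: (55.0, 57.5),
    PeakWindow.Q: (47.5, 50.5),
}

DEFAULT_SMOOTHING_WINDOW_C = 3.0
DEFAULT_PRESENCE_FACTOR = 6.0
#: The noise floor is estimated only >= this far (degC) outside every peak
#: window, so transition shoulders cannot inflate it.
NOISE_FLOOR_MARGIN_C = 3.0


@dataclass(frozen=True)
class DerivativeCurve:
    """Negative first derivative of a melt curve on its temperature grid.

    ``noise_sd`` is the standard deviation of the derivative's noise
    component, propagated from a robust estimate of the fluorescence noise
    through the differentiation filter's exact noise gain.  It is 0 for
    directly constructed (e.g. analytic) curves.
    """

    sample_id: str
    temperatures_c: np.ndarray
    neg_dfdt: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.neg_dfdt.shape != self.temperatures_c.shape:
            raise ValueError("grid/derivative length mismatch")
        if not np.isfinite(self.neg_dfdt).all():
            raise ValueError("derivative must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class MeltPeak:
    window: PeakWindow
    apex_temperature_c: float
    height: float
    present: bool

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be non-negative")
        if not self.present and self.height != 0:
            raise ValueError("absent peaks carry height 0")


@dataclass(frozen=True)
class PeakSet:
    """Exactly one (possibly absent) peak per window, plus the noise floor."""

    sample_id: str
    peaks: dict[PeakWindow, MeltPeak]
    noise_floor: float

    def __post_init__(self) -> None:
        if set(self.peaks) != set(PeakWindow):
            raise ValueError("PeakSet must cover all three windows exactly once")
        if self.noise_floor < 0:
            raise ValueError("noise floor must be non-negative")

    def __getitem__(self, window: PeakWindow) -> MeltPeak:
        return self.peaks[window]

    def height(self, window: PeakWindow) -> float:
        return self.peaks[window].height

    def present(self, window: PeakWindow) -> bool:
        return self.peaks[window].present


def derivative(curve: MeltCurve,
               smoothing_window_c: float = DEFAULT_SMOOTHING_WINDOW_C,
               polyorder: int = 3) -> DerivativeCurve:
    """Smoothed ``-dF/dT`` via a local-polynomial (Savitzky-Golay) filter.

    The filter fits a polynomial of order ``polyorder`` in a sliding window
    of width ``smoothing_window_c`` and differentiates the fit, so the
    result is shift-equivariant: adding a constant to the fluorescence
    leaves the derivative unchanged.
    """
    step = curve.step_c
    if smoothing_window_c < step:
        raise ValueError("smoothing window must be >= the grid step")
    npts = int(round(smoothing_window_c / step))
    if npts % 2 == 0:
        npts += 1
    npts = max(npts, polyorder + 1 + (polyorder % 2 == 0))
    if npts > curve.temperatures_c.size:
        raise ValueError("curve is shorter than the smoothing window")
    neg = -savgol_filter(curve.fluorescence, npts, polyorder, deriv=1,
                         delta=step)
    # Fluorescence noise from robust second differences (a smooth melt
    # transition contributes ~0 to the median of |d2F|), propagated through
    # the filter: sd(noise in -dF/dT) = sd(noise in F) * ||filter coeffs||.
    d2 = np.diff(curve.fluorescence, 2)
    sigma_f = 1.4826 * float(np.median(np.abs(d2 - np.median(d2)))) / np.sqrt(6)
    gain = float(np.linalg.norm(savgol_coeffs(npts, polyorder, deriv=1,
                                              delta=step)))
    return DerivativeCurve(curve.sample_id, curve.temperatures_c, neg,
                           noise_sd=sigma_f * gain)


def _robust_noise_floor(dcurve: DerivativeCurve,
                        windows: dict[PeakWindow, tuple[float, float]],
                        margin_c: float = NOISE_FLOOR_MARGIN_C) -> float:
    """MAD-based dispersion of -dF/dT over window-free grid regions.

    Regions within ``margin_c`` of any window are excluded as well: a
    transition sitting at a window centre still has sigmoidal shoulders
    just outside the window, and those must not masquerade as noise.
    """
    t = dcurve.temperatures_c
    mask = np.ones(t.size, dtype=bool)
    for lo, hi in windows.values():
        mask &= ~((t >= lo - margin_c) & (t <= hi + margin_c))
    vals = dcurve.neg_dfdt[mask]
    if vals.size == 0:
        raise ValueError("windows leave no grid region for the noise floor")
    mad = np.median(np.abs(vals - np.median(vals)))
    return float(1.4826 * mad)


def call_peaks(dcurve: DerivativeCurve,
               windows: dict[PeakWindow, tuple[float, float]] | None = None,
               presence_factor: float = DEFAULT_PRESENCE_FACTOR) -> PeakSet:
    """Call the SMN1 / SMN2 / Q peaks from a derivative curve.

    For each window the apex is the highest point that is both strictly
    inside the window and a local maximum of the full derivative curve (so
    a monotone shoulder leaking in from a neighbouring transition, whose
    windowed maximum sits on the window edge, never qualifies).  The peak
    is present iff such an apex exists and exceeds ``presence_factor``
    times the noise floor.
    The floor is the larger of two robust dispersion estimates of the
    derivative's noise: the MAD over window-free grid regions, and the
    filter-propagated ``dcurve.noise_sd`` (the regional MAD alone rests on
    few, strongly autocorrelated points and occasionally collapses).
    Absent peaks report height 0.
    """
    windows = dict(DEFAULT_WINDOWS if windows is None else windows)
    if presence_factor <= 0:
        raise ValueError("presence_factor must be > 0")
    spans = sorted(windows.values())
    for (_, hi), (lo, _) in zip(spans, spans[1:]):
        if lo <= hi:
            raise ValueError("windows must be disjoint")
    t = dcurve.temperatures_c
    d = dcurve.neg_dfdt
    floor = max(_robust_noise_floor(dcurve, windows), dcurve.noise_sd)
    # epsilon keeps float-level junk on noiseless curves from registering
    # as peaks (1e-9 of the derivative's span, 1e-12 absolute)
    threshold = max(presence_factor * floor,
                    1e-9 * float(d.max() - d.min()), 1e-12)
    peaks: dict[PeakWindow, MeltPeak] = {}
    for window, (lo, hi) in windows.items():
        idx = np.flatnonzero((t >= lo) & (t <= hi))
        if idx.size == 0:
            raise ValueError(f"window {window.value} lies outside the grid")
        interior = idx[(idx > idx[0]) & (idx < idx[-1])
                       & (idx > 0) & (idx < t.size - 1)]
        local_max = interior[(d[interior] >= d[interior - 1])
                             & (d[interior] >= d[interior + 1])]
        if local_max.size:
            apex = local_max[int(np.argmax(d[local_max]))]
        else:  # pure shoulder: windowed max sits on the window edge
            apex = idx[int(np.argmax(d[idx]))]
        value = float(d[apex])
        present = bool(local_max.size and value > threshold)
        peaks[window] = MeltPeak(window, float(t[apex]),
                                 value if present else 0.0, present)
    return PeakSet(dcurve.sample_id, peaks, floor)


def peaksets_to_frame(peaksets) -> pd.DataFrame:
    rows = [{"sample_id": ps.sample_id, "window": w.value,
             "apex_c": ps.peaks[w].apex_temperature_c,
             "height": ps.peaks[w].height, "present": ps.peaks[w].present,
             "noise_floor": ps.noise_floor}
            for ps in peaksets for w in PeakWindow]
    return pd.DataFrame(rows)
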