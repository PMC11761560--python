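"""Conventional time-domain ERG features.

The photopic flash ERG is summarised clinically by four numbers: the time to
peak and amplitude of the a-wave (the initial cornea-negative deflection,
photoreceptor-driven) and of the b-wave (the subsequent cornea-positive peak,
bipolar-cell-driven).  Amplitude conventions follow standard clinical
reporting: the a-wave is measured from the pre-stimulus baseline to the
trough, the b-wave from the a-wave trough to the b-wave peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TDFeatures", "SearchWindows", "NoDetectablePeaks", "extract_td_features"]


class NoDetectablePeaks(ValueError):
    """Raised when a waveform is too flat to carry an a-wave/b-wave pair."""


@dataclass(frozen=True)
class SearchWindows:
    """Search windows (ms after flash onset) for peak localisation.

    Defaults reflect standard photopic practice: the a-wave trough falls
    between roughly 10 and 20 ms and the b-wave peak between 25 and 45 ms,
    so generous windows of 5-25 ms and 15-70 ms are used.
    """

    a_window: tuple[float, float] = (5.0, 25.0)
    b_window: tuple[float, float] = (15.0, 70.0)
    baseline: tuple[float, float] = (0.0, 5.0)
    #: minimum peak-to-trough excursion (uV) below which the waveform is
    #: declared degenerate
    min_prominence: float = 0.5


@dataclass(frozen=True)
class TDFeatures:
    """a-wave / b-wave timing (ms) and amplitude (uV) descriptors."""

    Ta: float
    Aa: float
    Tb: float
    Ab: float

    def as_dict(self) -> dict[str, float]:
        return {"Ta": self.Ta, "Aa": self.Aa, "Tb": self.Tb, "Ab": self.Ab}


def _window_slice(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.nonzero((times >= lo) & (times <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"recording does not span the {lo}-{hi} ms window")
    return idx

def extract_td_features(rec, search: SearchWindows | None = None) -> TDFeatures:
    """Locate the a-wave trough and b-wave peak of a recording.

    Parameters
    ----------
    rec
        An :class:`~ergml.erg_io.ERGRecording`; ``rec.times_ms`` must span the
        search windows.
    search
        Window configuration; defaults to :class:`SearchWindows`.

    Returns
    -------
    TDFeatures
        ``Ta``/``Tb`` at sample resolution (0.5 ms at 2 kHz); ``Aa`` measured
        baseline-to-trough, ``Ab`` trough-to-peak.

    Raises
    ------
    NoDetectablePeaks
        If the peak-to-trough excursion inside the search region is below
        ``search.min_prominence``.
    """
    search = search or SearchWindows()
    t = rec.times_ms
    x = np.asarray(rec.samples, dtype=float)

    a_idx = _window_slice(t, *search.a_window)
    b_idx = _window_slice(t, *search.b_window)
    base_idx = _window_slice(t, *search.baseline)

    span = x[a_idx[0] : b_idx[-1] + 1]
    if span.size == 0 or (span.max() - span.min()) < search.min_prominence:
        raise NoDetectablePeaks(
            "waveform excursion below prominence threshold "
            f"({search.min_prominence} uV) in the search region"
        )

    i_trough = a_idx[np.argmin(x[a_idx])]
    # b-wave peak strictly after the trough
    b_after = b_idx[b_idx > i_trough]
    if b_after.size == 0:
        raise NoDetectablePeaks("no samples after the a-wave trough in the b-window")
    i_peak = b_after[np.argmax(x[b_after])]

    baseline = float(np.mean(x[base_idx]))
    Ta = float(t[i_trough])
    Tb = float(t[i_peak])
    Aa = abs(baseline - float(x[i_trough]))
    Ab = float(x[i_peak] - x[i_trough])
    return TDFeatures(Ta=Ta, Aa=Aa, Tb=Tb, Ab=max(Ab, 0.0))
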