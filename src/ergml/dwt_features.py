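"""Haar discrete-wavelet-transform descriptors of the ERG.

The recording is decomposed with an orthonormal Haar DWT; detail level ``j``
covers fs/2^(j+1) to fs/2^j Hz, so at 2 kHz:

====== ================= ==========================
level  band (Hz)         physiological label
====== ================= ==========================
d1+d2  250-1000          high band (noise/OP tail)
d3     125-250           OP160 (oscillatory potentials)
d4     62.5-125          OP80 (oscillatory potentials)
d5     31.25-62.5        b-wave band
d6     15.6-31.25        a-wave band
====== ================= ==========================

Per recording 34 descriptors are emitted: band-limited energies in equal
time bins across the analysis window (12 high-band bins, 8 bins per OP band),
whole-window band energy sums for the OP bands, and b-band max / time of max
/ sum plus the a-band sum.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["haar_dwt", "extract_dwt_features", "DWT_FEATURE_NAMES"]

_LEVELS = 6
_N_BANDHIGH_BINS = 12
_N_OP_BINS = 8

DWT_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"dwt_bandhigh_{i}" for i in range(1, _N_BANDHIGH_BINS + 1))
    + tuple(f"dwt_OP160_{i}" for i in range(1, _N_OP_BINS + 1))
    + ("dwt_sum_OP160",)
    + tuple(f"dwt_OP80_{i}" for i in range(1, _N_OP_BINS + 1))
    + ("dwt_sum_OP80",)
    + ("dwt_b_max", "dwt_b_tmax", "dwt_sum_b", "dwt_sum_a")
)
assert len(DWT_FEATURE_NAMES) == 34


def haar_dwt(samples: np.ndarray, levels: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Orthonormal Haar DWT.

    Returns ``(details, approx)`` where ``details[j-1]`` holds the level-j
    detail coefficients (j = 1 is the finest scale, fs/4-fs/2 Hz).  Signals
    whose length is not a multiple of ``2**levels`` are symmetrically padded
    up to the next multiple; with L2 (orthonormal) scaling Parseval's
    identity holds on the padded signal, exactly on power-of-two inputs.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    block = 2**levels
    if x.size < block or x.size % block:
        target = max(block, int(np.ceil(x.size / block)) * block)
        pad = target - x.size
        x = np.pad(x, (0, pad), mode="symmetric")
    coeffs = pywt.wavedec(x, "haar", mode="periodization", level=levels)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # d1 (finest) ... d_levels
    return details, approx


def _bin_energies(
    coeff_list: list[tuple[np.ndarray, int]],
    fs: float,
    window_ms: float,
    n_bins: int,
) -> tuple[np.ndarray, float]:
    """Sum squared coefficients into equal time bins over [0, window_ms).

    ``coeff_list`` pairs each coefficient array with its level; a level-j
    coefficient spans 2^j samples and is assigned to the bin containing its
    temporal centre.  Coefficients whose centre falls in the padding beyond
    the window are discarded.
    """
    bins = np.zeros(n_bins)
    total = 0.0
    width = window_ms / n_bins
    for coeffs, level in coeff_list:
        step = 2**level
        centers = (np.arange(coeffs.size) + 0.5) * step * 1000.0 / fs
        keep = centers < window_ms
        e = coeffs[keep] ** 2
        idx = np.minimum((centers[keep] / width).astype(int), n_bins - 1)
        np.add.at(bins, idx, e)
        total += float(e.sum())
    return bins, total


def extract_dwt_features(rec, window: tuple[float, float] = (0.0, 100.0)) -> dict[str, float]:
    """Compute the 34 Haar-DWT descriptors of one recording.

    The analysis window (default 0-100 ms post flash) covers the a-wave
    through the b-wave and its oscillatory potentials.
    """
    t = rec.times_ms
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty analysis window")
    sel = (t >= lo) & (t < hi)
    x = np.asarray(rec.samples, dtype=float)[sel]
    window_ms = hi - lo
    min_bin = window_ms / _N_BANDHIGH_BINS
    if x.size * 1000.0 / rec.fs < min_bin:
        raise ValueError("analysis window shorter than the bin grid")

    details, approx = haar_dwt(x, _LEVELS)
    d = {j: details[j - 1] for j in range(1, _LEVELS + 1)}

    feats: dict[str, float] = {}
    hi_bins, _ = _bin_energies([(d[1], 1), (d[2], 2)], rec.fs, window_ms, _N_BANDHIGH_BINS)
    for i, v in enumerate(hi_bins, start=1):
        feats[f"dwt_bandhigh_{i}"] = float(v)

    for band, level in (("OP160", 3), ("OP80", 4)):
        bins, total = _bin_energies([(d[level], level)], rec.fs, window_ms, _N_OP_BINS)
        for i, v in enumerate(bins, start=1):
            feats[f"dwt_{band}_{i}"] = float(v)
        feats[f"dwt_sum_{band}"] = total

    # b-band (d5): max |coefficient|, its time, and band energy
    step5 = 2**5
    centers5 = (np.arange(d[5].size) + 0.5) * step5 * 1000.0 / rec.fs
    keep5 = centers5 < window_ms
    c5 = d[5][keep5]
    if c5.size and np.max(np.abs(c5)) > 0:
        i_max = int(np.argmax(np.abs(c5)))
        feats["dwt_b_max"] = float(np.abs(c5[i_max]))
        feats["dwt_b_tmax"] = float(lo + centers5[keep5][i_max])
    else:
        feats["dwt_b_max"] = 0.0
        feats["dwt_b_tmax"] = float(lo)  # degenerate convention: window start
    feats["dwt_sum_b"] = float(np.sum(c5**2))

    step6 = 2**6
    centers6 = (np.arange(d[6].size) + 0.5) * step6 * 1000.0 / rec.fs
    c6 = d[6][centers6 < window_ms]
    feats["dwt_sum_a"] = float(np.sum(c6**2))

    assert set(feats) == set(DWT_FEATURE_NAMES)
    return {name: feats[name] for name in DWT_FEATURE_NAMES}
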