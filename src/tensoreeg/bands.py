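"""Daubechies-4 discrete wavelet sub-band decomposition of EEG channels.

Each channel is split into six reconstructed detail series corresponding
approximately to the canonical EEG bands (delta, theta, alpha, beta,
gamma, gamma+).  The dyadic detail level j spans roughly
(fs / 2**(j+1), fs / 2**j) Hz; at fs = 500 Hz this assigns
D7 -> delta, D6 -> theta, D5 -> alpha, D4 -> beta, D3 -> gamma,
D2 -> gamma+, with D1 (>125 Hz) and the coarse approximation collected
into a residual.  For other sampling rates the level of each named band
is re-derived so its dyadic interval best matches the canonical range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

#: ordered band names, low to high frequency
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma", "gamma+")

#: canonical band edges in Hz (upper edge drives the dyadic level choice)
CANONICAL_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 60.0),
    "gamma+": (60.0, 120.0),
}


def band_levels(fs: float) -> dict[str, int]:
    """Detail level per named band at sampling rate ``fs``.

    The level j whose dyadic interval (fs/2**(j+1), fs/2**j) is centred
    nearest the canonical upper edge is chosen: j = round(log2(fs / f_hi)).
    At 500 Hz this yields the D7..D2 assignment documented above.
    """
    levels = {}
    for band, (_, f_hi) in CANONICAL_EDGES.items():
        j = int(round(np.log2(fs / f_hi)))
        levels[band] = max(j, 1)
    if len(set(levels.values())) != len(levels):
        raise ValueError(
            f"sampling rate {fs} Hz does not separate the six canonical bands "
            f"into distinct dyadic levels: {levels}"
        )
    return levels


@dataclass
class BandSignals:
    """Reconstructed per-band sub-signals for one channel.

    ``bands[name]`` has the length of the input signal; ``residual`` holds
    the coarse approximation plus any discarded detail levels, so that
    ``sum(bands.values()) + residual`` reconstructs the input.
    """

    bands: dict[str, np.ndarray]
    residual: np.ndarray
    fs: float
    level_map: dict[str, int]
    wavelet: str = "db4"
    band_names: tuple[str, ...] = BAND_NAMES

    def total(self) -> np.ndarray:
        return sum(self.bands.values()) + self.residual


def decompose_bands(
    signal: np.ndarray,
    fs: float,
    wavelet: str = "db4",
    n_levels: int | None = None,
    band_map: dict[str, int] | None = None,
) -> BandSignals:
    """Decompose one channel into the six canonical sub-band series.

    Uses a periodized orthogonal DWT so that the reconstructed details and
    approximation are mutually orthogonal and sum exactly to the input
    (perfect reconstruction).

    Parameters
    ----------
    signal : 1-D array
    fs : sampling rate, Hz (> 0)
    wavelet : discrete wavelet name, default Daubechies-4
    n_levels : decomposition depth; default = deepest level required by the
        band map
    band_map : explicit band -> detail level override
    """
    x = np.asarray(signal, dtype=float).ravel()
    if not fs > 0:
        raise ValueError("fs must be positive")
    level_map = dict(band_map) if band_map else band_levels(fs)
    depth = n_levels if n_levels is not None else max(level_map.values())
    if max(level_map.values()) > depth:
        raise ValueError("n_levels shallower than the requested band map")
    if len(x) < 2**depth:
        raise ValueError(
            f"signal of {len(x)} samples too short for a depth-{depth} DWT"
        )
    mode = "periodization"
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=depth)
    # coeffs = [cA_depth, cD_depth, ..., cD_1]
    def reconstruct(keep: set[int], keep_approx: bool) -> np.ndarray:
        c = [arr if (keep_approx and i == 0) or (i > 0 and depth - i + 1 in keep)
             else np.zeros_like(arr)
             for i, arr in enumerate(coeffs)]
        rec = pywt.waverec(c, wavelet, mode=mode)
        return rec[: len(x)]

    bands = {
        name: reconstruct({level_map[name]}, keep_approx=False)
        for name in BAND_NAMES
    }
    discarded = set(range(1, depth + 1)) - set(level_map.values())
    residual = reconstruct(discarded, keep_approx=True)
    return BandSignals(
        bands=bands,
        residual=residual,
        fs=fs,
        level_map=level_map,
        wavelet=wavelet,
    )
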