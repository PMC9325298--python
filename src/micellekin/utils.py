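"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Conversion factor: 1 nm^3 expressed in litres.
NM3_TO_L = 1e-24


def counts_to_molar(n: float | np.ndarray, volume_nm3: float) -> float | np.ndarray:
    """Convert a particle count in a box of ``volume_nm3`` nm^3 to molarity (M).

    54 monomers in a 7.4 nm cubic box come out at ~0.22 M, the concentration
    regime used throughout the accretion simulations.
    """
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    return np.asarray(n) / (AVOGADRO * volume_nm3 * NM3_TO_L)


def moving_average(y: np.ndarray, window_steps: int) -> np.ndarray:
    """Centred moving average with edge truncation.

    At the edges the window shrinks to the available points, so the output has
    the same length as the input.  ``window_steps`` <= 1 returns the input
    unchanged.  NaNs are ignored within each window.
    """
    y = np.asarray(y, dtype=float)
    if window_steps <= 1 or y.size == 0:
        return y.copy()
    half = window_steps // 2
    out = np.empty_like(y)
    for i in range(y.size):
        lo = max(0, i - half)
        hi = min(y.size, i + window_steps - half)
        seg = y[lo:hi]
        good = ~np.isnan(seg)
        out[i] = seg[good].mean() if good.any() else np.nan
    return out


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary periodic cell [0, box)."""
    box = np.asarray(box, dtype=float)
    w = np.mod(coords, box)
    # guard against w == box from floating-point round-off
    return np.where(w >= box, 0.0, w)
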