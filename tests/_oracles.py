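"""Independent brute-force oracles shared by the test modules.

Each oracle is deliberately naive (exhaustive enumeration or plain
finite differences) and shares no code path with the implementation it
checks.
"""

import numpy as np

from leafchl.spectra import Spectrum


def chord_oracle_continuum(wl, values):
    """O(n^2) upper-hull oracle: hull at i is the maximum over all chords
    (j, k) with j <= i <= k of the chord evaluated at wl[i]."""
    n = len(wl)
    hull = np.array(values, dtype=float)
    for i in range(n):
        best = values[i]
        for j in range(0, i + 1):
            for k in range(i, n):
                if j == k:
                    continue
                y = values[j] + (values[k] - values[j]) * (wl[i] - wl[j]) / (wl[k] - wl[j])
                best = max(best, y)
        hull[i] = best
    return hull


def brute_force_max_d1(s: Spectrum) -> float:
    """Oracle: argmax of plain finite differences in the red-edge window."""
    i0, i1 = s.grid.index_of(670), s.grid.index_of(800)
    d = np.diff(s.values[i0 : i1 + 1])
    return float(s.grid.wavelengths[i0 + np.argmax(d)]) + 0.5


def grid_search_gaussian_reip(s: Spectrum) -> float:
    """Oracle: exhaustive (center, width) grid for the inverted-Gaussian fit,
    with the two amplitude parameters solved linearly at each grid point."""
    g = s.grid
    i0, i1 = g.index_of(670), g.index_of(800)
    wl = g.wavelengths[i0 : i1 + 1].astype(float)
    seg = s.values[i0 : i1 + 1]
    best = (np.inf, np.nan)
    for l0 in np.arange(680.0, 780.5, 1.0):
        for sig in np.arange(5.0, 60.5, 1.0):
            e = np.exp(-((wl - l0) ** 2) / (2 * sig**2))
            A = np.vstack([1 - e, e]).T
            coef, res, *_ = np.linalg.lstsq(A, seg, rcond=None)
            sse = float(res[0]) if len(res) else float(((A @ coef - seg) ** 2).sum())
            if sse < best[0]:
                best = (sse, l0 + sig)
    return best[1]
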