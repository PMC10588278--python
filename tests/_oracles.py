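"""Independent brute-force gamma oracle for the test suite.

Exhaustively minimizes the gamma quantity per reference pixel over every
evaluated sample position (same lattice definition as the engine: step
``interp_step_fraction * DTA``, disc of radius ``search_radius_factor *
DTA``), with its own nested-loop bilinear interpolation.  Deliberately
simple and slow; kept independent of the optimized engine it checks.
"""
import numpy as np


def brute_gamma(ref, ev, row_spacing_mm, col_spacing_mm, criteria):
    ref = np.asarray(ref, dtype=float)
    ev = np.asarray(ev, dtype=float)
    nr, nc = ref.shape
    norm = ref.max()
    thr = criteria.low_dose_threshold_percent / 100.0 * norm
    if criteria.normalization == "global":
        tol_of = lambda r, c: criteria.dose_tol_percent / 100.0 * norm
    else:
        tol_of = lambda r, c: criteria.dose_tol_percent / 100.0 * ref[r, c]

    h = criteria.interp_step_fraction * criteria.dta_mm
    radius = criteria.search_radius_factor * criteria.dta_mm
    n = int(np.floor(radius / h + 1e-9))
    offs = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            d2 = (i * h) ** 2 + (j * h) ** 2
            if d2 <= radius ** 2 * (1 + 1e-12):
                offs.append((i * h, j * h, d2))
    offs = np.asarray(offs)
    dy, dx, d2 = offs[:, 0], offs[:, 1], offs[:, 2]

    gamma = np.full(ref.shape, np.nan)
    for r in range(nr):
        for c in range(nc):
            if ref[r, c] < thr:
                continue
            y = r + dy / row_spacing_mm
            x = c + dx / col_spacing_mm
            ok = (y >= 0) & (y <= nr - 1) & (x >= 0) & (x <= nc - 1)
            yv, xv = y[ok], x[ok]
            y0 = np.clip(np.floor(yv).astype(int), 0, nr - 2)
            x0 = np.clip(np.floor(xv).astype(int), 0, nc - 2)
            fy, fx = yv - y0, xv - x0
            val = (
                (1 - fy) * (1 - fx) * ev[y0, x0]
                + (1 - fy) * fx * ev[y0, x0 + 1]
                + fy * (1 - fx) * ev[y0 + 1, x0]
                + fy * fx * ev[y0 + 1, x0 + 1]
            )
            tol = tol_of(r, c)
            g2 = d2[ok] / criteria.dta_mm ** 2 + ((val - ref[r, c]) / tol) ** 2
            gamma[r, c] = np.sqrt(g2.min())
    return gamma
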