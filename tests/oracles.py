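"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles with different
code paths than the package (explicit summation formulas instead of lstsq,
dense scans instead of analytic derivatives) so the two routes stay
independent.
"""

import numpy as np


def ols_closed_form(x, y):
    """Textbook least-squares line via explicit sums."""
    n = len(x)
    sx, sy = float(np.sum(x)), float(np.sum(y))
    sxx, sxy = float(np.sum(x * x)), float(np.sum(x * y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def huber_irls_oracle(x, y, k=1.345, tol=1e-8, max_iter=50):
    """Brute-force Huber IRLS: explicit weighted normal equations,
    scale = 1.4826 * median absolute residual, re-estimated each iteration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope, intercept = ols_closed_form(x, y)
    scale = 0.0
    for _ in range(max_iter):
        r = y - intercept - slope * x
        scale = 1.4826 * float(np.median(np.abs(r)))
        if scale == 0.0:
            break
        w = np.ones_like(r)
        big = np.abs(r) > k * scale
        w[big] = (k * scale) / np.abs(r[big])
        sw = float(np.sum(w))
        swx = float(np.sum(w * x))
        swy = float(np.sum(w * y))
        swxx = float(np.sum(w * x * x))
        swxy = float(np.sum(w * x * y))
        det = sw * swxx - swx * swx
        new_slope = (sw * swxy - swx * swy) / det
        new_intercept = (swy * swxx - swx * swxy) / det
        delta = max(abs(new_slope - slope), abs(new_intercept - intercept))
        slope, intercept = new_slope, new_intercept
        if delta < tol:
            break
    r = y - intercept - slope * x
    scale = 1.4826 * float(np.median(np.abs(r)))
    return slope, intercept, scale


def dynamic_range_dense_scan(model, epsilon_frac=0.01, x_min=0.01,
                             x_max=10_000.0, n_grid=100_000):
    """Dynamic range from a brute-force dense scan with finite-difference
    log-dose slopes (no analytic derivative)."""
    xs = np.logspace(np.log10(x_min), np.log10(x_max), n_grid)
    f = _fpl(model, xs)
    lnx = np.log(xs)
    # centered finite difference of df/d(ln x)
    slope = np.empty_like(xs)
    slope[1:-1] = (f[2:] - f[:-2]) / (lnx[2:] - lnx[:-2])
    slope[0] = (f[1] - f[0]) / (lnx[1] - lnx[0])
    slope[-1] = (f[-1] - f[-2]) / (lnx[-1] - lnx[-2])
    mag = np.abs(slope)
    peak = mag.max()
    if peak == 0:
        return None, None
    mask = mag >= epsilon_frac * peak
    i = int(np.argmax(mag))
    lo = i
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = i
    while hi < n_grid - 1 and mask[hi + 1]:
        hi += 1
    return float(xs[lo]), float(xs[hi])


def _fpl(model, x):
    """Independent evaluation of the dose-response curve (plain formula,
    clipped exponent instead of expit)."""
    L = np.log(np.asarray(x, float) + 1.0)
    g = model.b * L**model.p1 + model.e * L**model.p2
    g = np.clip(g, -700, 700)
    return model.c + (model.d - model.c) / (1.0 + np.exp(g))
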