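"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths of the package: the line fit is a
zooming grid search over the sum of squared errors, and the ANCOVA F
statistics are assembled from residual sums of squares of explicitly
constructed design matrices.
"""

import numpy as np


def brute_force_line(x, y, iterations=10, grid=81, margin=8):
    """OLS oracle: zooming grid search over (slope, intercept) SSE.

    The SSE valley is diagonal in (slope, intercept), so each zoom keeps a
    generous margin around the incumbent to avoid cutting off the joint
    optimum.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    s_lo, s_hi = -10.0, 10.0
    b_lo, b_hi = -10.0, 10.0
    best = (0.0, 0.0)
    for _ in range(iterations):
        slopes = np.linspace(s_lo, s_hi, grid)
        intercepts = np.linspace(b_lo, b_hi, grid)
        sse = (
            (y[None, None, :]
             - slopes[:, None, None] * x[None, None, :]
             - intercepts[None, :, None]) ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (slopes[i], intercepts[j])
        ds, db = slopes[1] - slopes[0], intercepts[1] - intercepts[0]
        s_lo, s_hi = best[0] - margin * ds, best[0] + margin * ds
        b_lo, b_hi = best[1] - margin * db, best[1] + margin * db
    return best


def _sse(design, y):
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def nested_sse_f_tests(x1, y1, x2, y2):
    """F statistics for slope and intercept equality from nested-model SSEs."""
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(len(x1)), np.ones(len(x2))])
    ones = np.ones_like(x)
    full = np.column_stack([ones, g, x, g * x])
    common = np.column_stack([ones, g, x])
    single = np.column_stack([ones, x])
    n = len(x)
    sse_full, sse_common, sse_single = _sse(full, y), _sse(common, y), _sse(single, y)
    f_slope = (sse_common - sse_full) / (sse_full / (n - 4))
    f_int = (sse_single - sse_common) / (sse_common / (n - 3))
    return f_slope, f_int
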