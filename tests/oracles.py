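"""Independent brute-force oracles used by the test suite.

Parametric grid sampling of the retained foot/shank surface patches with a
known spacing: the nearest-sample distance to a query point overestimates the
true point-to-surface distance by at most half the grid diagonal, so it bounds
the closed-form implementation from above with quantifiable slack.  These
samplers are written directly from the surface definitions and share no code
with the closed-form distance functions they check.
"""

import numpy as np


def _grid(a: float, b: float, spacing: float) -> np.ndarray:
    n = max(int(np.ceil((b - a) / spacing)) + 1, 2)
    return np.linspace(a, b, n)


def foot_oracle_grid(shape, spacing: float) -> np.ndarray:
    """Grid sample of heel wall (with calcaneus bulge), side walls and sole."""
    r, l, h, d = shape.r, shape.l, shape.h, shape.d
    ytoe = l - r
    z0 = -0.4 * h
    out = []

    zs = _grid(-h, 0.0, spacing)
    az = _grid(-np.pi / 2, np.pi / 2, spacing / (r + d))
    for z in zs:
        rad = r + (d * (z - z0) / (0 - z0) if (d > 0 and z > z0) else 0.0)
        out.append(
            np.column_stack([rad * np.sin(az), -rad * np.cos(az), np.full(len(az), z)])
        )

    ys = _grid(0.0, ytoe, spacing)
    yy, zz = np.meshgrid(ys, zs)
    for sgn in (-1.0, 1.0):
        out.append(np.column_stack([np.full(yy.size, sgn * r), yy.ravel(), zz.ravel()]))

    xs = _grid(-r, r, spacing)
    xx, yy = np.meshgrid(xs, ys)
    out.append(np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, -h)]))
    xx, yy = np.meshgrid(xs, _grid(-r, 0.0, spacing))
    keep = np.hypot(xx, yy) <= r
    out.append(np.column_stack([xx[keep], yy[keep], np.full(int(keep.sum()), -h)]))
    return np.vstack(out)


def shank_oracle_grid(shape, spacing: float) -> np.ndarray:
    """Grid sample of the rear half of the tapered cylinder wall."""
    rmax = max(shape.r1, shape.r2)
    zs = _grid(0.0, shape.s, spacing)
    az = _grid(-np.pi / 2, np.pi / 2, spacing / rmax)
    out = []
    for z in zs:
        rad = shape.r1 + (shape.r2 - shape.r1) * z / shape.s
        out.append(
            np.column_stack([rad * np.sin(az), -rad * np.cos(az), np.full(len(az), z)])
        )
    return np.vstack(out)
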