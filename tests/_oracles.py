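"""Independent numerical oracles shared by the test suite.

These deliberately avoid the package's Monte-Carlo machinery: the
normalizing integral of the step-selection density is computed by an
exhaustive sum over grid cells, with the cell containing the step origin
(where the planar kernel has an integrable 1/length singularity)
integrated by adaptive quadrature and the rest subdivided.
"""

import numpy as np
from scipy import integrate

from memstep.kernels import crw_density


def exhaustive_kw_normalizer(landscape, start, heading_in, rho_ns, kappa,
                             dt_hours, weight_grid, subdivide=3):
    """Brute-force integral(k * W) over the landscape grid.

    ``weight_grid`` holds W per cell (W is piecewise constant on cells);
    k is integrated within each cell by an ss x ss midpoint rule, except
    the cell containing ``start``, which uses dblquad.
    """
    start = np.asarray(start, dtype=float)
    a = landscape.cell_size
    x0, y0 = landscape.origin
    n_rows, n_cols = landscape.n_rows, landscape.n_cols
    row0, col0 = landscape.cell_index([start])
    row0, col0 = int(row0[0]), int(col0[0])

    ss = subdivide
    offs = (np.arange(ss) + 0.5) / ss * a
    total = 0.0
    for r in range(n_rows):
        ys = y0 + r * a + offs
        for c in range(n_cols):
            W = weight_grid[r, c]
            if W == 0.0:
                continue
            if r == row0 and c == col0:
                def f(y, x):
                    d = np.array([x, y]) - start
                    length = float(np.hypot(*d))
                    turn = float(np.arctan2(d[1], d[0])) - heading_in
                    return float(crw_density(length, turn, rho_ns, kappa,
                                             dt_hours))
                val, _ = integrate.dblquad(
                    f, x0 + c * a, x0 + (c + 1) * a,
                    y0 + r * a, y0 + (r + 1) * a, epsabs=1e-10, epsrel=1e-8)
                total += W * val
                continue
            xs = x0 + c * a + offs
            X, Y = np.meshgrid(xs, ys)
            d = np.stack([X - start[0], Y - start[1]], axis=-1)
            lens = np.hypot(d[..., 0], d[..., 1])
            turns = np.arctan2(d[..., 1], d[..., 0]) - heading_in
            k = crw_density(lens, turns, rho_ns, kappa, dt_hours)
            total += W * k.sum() * (a / ss) ** 2
    return float(total)
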