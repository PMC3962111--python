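"""Independent loop-based CP ANN reference used as a training oracle.

Deliberately written as plain Python triple loops over neurons and weight
components, with no shared code with the production trainer beyond the
published update rule, so the two can be compared bit-for-bit.
"""

from __future__ import annotations

import numpy as np


def naive_train(config, X, Y):
    """Returns (kohonen W, output O, winner sequence as 0-based tuples)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    nx, ny = config.nx, config.ny
    p, r = X.shape[1], Y.shape[1]
    rng = np.random.default_rng(config.seed)
    W = rng.random((nx, ny, p))
    O = rng.random((nx, ny, r))
    n = len(X)
    total = config.epochs * n
    r_max = max(nx, ny) / 2.0
    winners = []
    t = 0
    for _epoch in range(config.epochs):
        for i in range(n):
            x, y = X[i], Y[i]
            best = None
            best_d = None
            for a in range(nx):
                for b in range(ny):
                    s = 0.0
                    for k in range(p):
                        diff = W[a, b, k] - x[k]
                        s += diff * diff
                    if best_d is None or s < best_d:
                        best_d = s
                        best = (a, b)
            winners.append(best)
            if total > 1:
                eta = config.eta_max + (config.eta_min - config.eta_max) * (t / (total - 1))
            else:
                eta = config.eta_max
            radius = r_max * (1.0 - t / total)
            for a in range(nx):
                for b in range(ny):
                    da, db = abs(a - best[0]), abs(b - best[1])
                    if config.topology == "toroidal":
                        da = min(da, nx - da)
                        db = min(db, ny - db)
                    d = max(da, db) if config.grid_metric == "chebyshev" else da + db
                    if d <= radius:
                        if config.neighborhood == "triangular":
                            h = 1.0 - d / (radius + 1.0)
                        else:
                            h = np.exp(-((d / (radius + 1.0)) ** 2))
                        f = eta * h
                        for k in range(p):
                            W[a, b, k] += f * (x[k] - W[a, b, k])
                        for k in range(r):
                            O[a, b, k] += f * (y[k] - O[a, b, k])
            t += 1
    return W, O, winners
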