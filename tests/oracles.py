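"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: kinetic
models are integrated with a fixed-step 4th-order Runge-Kutta scheme,
hinge-model selection is checked against exhaustive enumeration, TV
denoising against a slack-variable QP, and the voxelwise GLM against
explicit normal equations.
"""

from __future__ import annotations

import itertools

import numpy as np


def _rk4(deriv, y0, t0, t1, n_steps):
    y = np.array(y0, dtype=float)
    t = t0
    h = (t1 - t0) / n_steps
    for _ in range(n_steps):
        k1 = deriv(t, y)
        k2 = deriv(t + h / 2, y + h / 2 * k1)
        k3 = deriv(t + h / 2, y + h / 2 * k2)
        k4 = deriv(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


def buxton_ode(cbf, att_ms, proto, pld, n_steps=2000):
    """Single-compartment delivery-decay ODE integrated piecewise by RK4."""
    delta = att_ms / 1000.0
    tau = proto.label_dur
    t_end = tau + pld
    if t_end <= delta:
        return 0.0
    f = cbf / (6000.0 * proto.lambda_part)
    a = 2.0 * proto.label_eff * f * np.exp(-delta / proto.t1_blood)
    r1b = 1.0 / proto.t1_blood

    def inflow(t, y):
        return np.array([a - r1b * y[0]])

    def decay(t, y):
        return np.array([-r1b * y[0]])

    t_mid = min(delta + tau, t_end)
    y = _rk4(inflow, [0.0], delta, t_mid, n_steps)
    if t_end > t_mid:
        y = _rk4(decay, y, t_mid, t_end, n_steps)
    return float(y[0])


def spa_ode(cbf, att_ms, kw, proto, pld, r1t=None, n_steps=2000):
    """Two-compartment delivery/exchange/relaxation ODE via RK4.

    Returns (capillary, tissue) label fractions at readout.
    """
    delta = att_ms / 1000.0
    tau = proto.label_dur
    t_end = tau + pld
    if t_end <= delta:
        return 0.0, 0.0
    f = cbf / (6000.0 * proto.lambda_part)
    a = 2.0 * proto.label_eff * f * np.exp(-delta / proto.t1_blood)
    r1b = 1.0 / proto.t1_blood
    r1t = 1.0 / proto.t1_tissue if r1t is None else r1t
    k = kw / 60.0

    def inflow(t, y):
        return np.array([a - (r1b + k) * y[0], k * y[0] - r1t * y[1]])

    def decay(t, y):
        return np.array([-(r1b + k) * y[0], k * y[0] - r1t * y[1]])

    t_mid = min(delta + tau, t_end)
    y = _rk4(inflow, [0.0, 0.0], delta, t_mid, n_steps)
    if t_end > t_mid:
        y = _rk4(decay, y, t_mid, t_end, n_steps)
    return float(y[0]), float(y[1])


def exhaustive_hinge_gcv(age, y, knots, penalty=3.0, max_knots=2, with_linear=True):
    """Minimum GCV over all hinge models with at most ``max_knots`` knots.

    Enumerates every combination of knot subset, per-knot direction choice
    ({+}, {-}, or both), and optional linear age term; each model is fit by
    OLS and scored with the same GCV formula the package uses.
    """
    n = len(y)

    def gcv(cols):
        x = np.column_stack([np.ones(n)] + cols)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            return np.inf
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ beta) ** 2).sum())
        m = x.shape[1]
        c = m + penalty * (m - 1) / 2.0
        if c >= n:
            return np.inf
        return (rss / n) / (1.0 - c / n) ** 2

    best = gcv([])
    dir_choices = [(+1,), (-1,), (+1, -1)]
    for r in range(0, max_knots + 1):
        for ks in itertools.combinations(knots, r):
            for dirs in itertools.product(dir_choices, repeat=r):
                for lin in ([False, True] if with_linear else [False]):
                    cols = []
                    if lin:
                        cols.append(age.astype(float))
                    for knot, dd in zip(ks, dirs):
                        for direction in dd:
                            cols.append(np.maximum(0.0, direction * (age - knot)))
                    best = min(best, gcv(cols))
    return best


def tv_qp_1d(f, weight):
    """1-D TV denoising solved as a slack-variable QP with SLSQP."""
    from scipy.optimize import minimize

    n = len(f)
    d = np.diff(np.eye(n), axis=0)

    def obj(z):
        u, t = z[:n], z[n:]
        return 0.5 * ((u - f) ** 2).sum() + weight * t.sum()

    cons = [
        {"type": "ineq", "fun": lambda z: z[n:] - d @ z[:n]},
        {"type": "ineq", "fun": lambda z: z[n:] + d @ z[:n]},
    ]
    z0 = np.concatenate([f, np.abs(d @ f) + 0.1])
    res = minimize(
        obj, z0, method="SLSQP", constraints=cons, options={"maxiter": 2000, "ftol": 1e-16}
    )
    return res.x[:n]


def ols_t_oracle(x, y, contrast):
    """T statistic from explicit normal equations."""
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    s2 = resid @ resid / df
    var = contrast @ np.linalg.inv(xtx) @ contrast * s2
    return (contrast @ beta) / np.sqrt(var)


def flood_fill_sizes(binary, connectivity=6):
    """Connected-component sizes by explicit BFS flood fill."""
    offsets = []
    for d in range(3):
        for s in (-1, 1):
            off = [0, 0, 0]
            off[d] = s
            offsets.append(tuple(off))
    if connectivity >= 18:
        raise NotImplementedError
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    coords = np.argwhere(binary)
    binset = set(map(tuple, coords))
    for start in map(tuple, coords):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            cur = queue.pop()
            size += 1
            for off in offsets:
                nxt = tuple(np.add(cur, off))
                if nxt in binset and not seen[nxt]:
                    seen[nxt] = True
                    queue.append(nxt)
        sizes.append(size)
    return sorted(sizes)
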