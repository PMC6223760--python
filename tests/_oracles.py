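"""Independent brute-force oracles used by the test suite.

These deliberately avoid the closed-form paths under test: rigid point
matching is solved by direct numerical minimization over rotation-vector
and translation parameters, and pivot calibration by direct minimization
of the residual sum, so both can cross-check the SVD / stacked-linear
solutions.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


def brute_force_rigid_fit(P: np.ndarray, Q: np.ndarray, n_starts: int = 4):
    """Minimize sum ||R(rotvec) p + t - q||^2 directly.

    Multi-start Levenberg-Marquardt over the 6 rigid parameters; returns
    (R, t, fre) of the best local minimum found.
    """

    def residuals(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return (P @ R.T + x[3:] - Q).ravel()

    rng = np.random.default_rng(12345)
    best = None
    starts = [np.zeros(3)] + [
        rng.uniform(-np.pi, np.pi, 3) * rng.uniform(0.2, 1.0) for _ in range(n_starts)
    ]
    for rv0 in starts:
        x0 = np.concatenate([rv0, Q.mean(axis=0) - P.mean(axis=0)])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    t = best.x[3:]
    fre = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, fre


def brute_force_pivot(rotations: np.ndarray, translations: np.ndarray):
    """Minimize sum ||R_i tip + t_i - pivot||^2 over (tip, pivot)."""

    def residuals(x):
        tip, pivot = x[:3], x[3:]
        return (rotations @ tip + translations - pivot).ravel()

    sol = least_squares(
        residuals, np.zeros(6), method="lm", xtol=1e-15, ftol=1e-15
    )
    tip, pivot = sol.x[:3], sol.x[3:]
    res = np.linalg.norm(rotations @ tip + translations - pivot, axis=1)
    return tip, pivot, float(np.sqrt(np.mean(res**2)))
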