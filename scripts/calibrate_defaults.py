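#!/usr/bin/env python
"""Reproduce the frozen default simulator calibration.

Finds the intercept and exposure coefficient of each structural equation by
stratum-wise Brent root finding on a large simulated confounder/exposure
draw, targeting the published marginal prevalences: exposure 0.389 overall,
M1 0.184/0.306, M2 0.315/0.406 and Y 0.027/0.083 within the unexposed /
exposed strata.  The resulting numbers are hard-coded in
``famstress.synthetic`` (``_DEFAULT_ALPHA_*``).

Usage: python scripts/calibrate_defaults.py [--n 2000000] [--seed 12345]
"""

from __future__ import annotations

import argparse

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from famstress.preprocessing import CONFOUNDERS
from famstress.synthetic import _DEFAULT_ALPHA_X, _DEFAULT_CONF_PREV


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=2_000_000)
    parser.add_argument("--seed", type=int, default=12345)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    n = args.n
    c = np.column_stack(
        [(rng.random(n) < _DEFAULT_CONF_PREV[k]) for k in CONFOUNDERS]
    ).astype(float)

    bx = np.array([_DEFAULT_ALPHA_X.conf[k] for k in CONFOUNDERS])
    lp_x = c @ bx
    ax = brentq(lambda a: expit(a + lp_x).mean() - 0.389, -10, 10, xtol=1e-8)
    print(f"alpha_x intercept: {ax:.4f}")
    x = (rng.random(n) < expit(ax + lp_x)).astype(float)

    def calibrate(conf_coef: float, targets: tuple[float, float], upstream: np.ndarray):
        base = c @ np.full(len(CONFOUNDERS), conf_coef) + upstream
        unexp, exp_ = x == 0, x == 1
        a = brentq(lambda a_: expit(a_ + base[unexp]).mean() - targets[0], -15, 10, xtol=1e-8)
        b = brentq(lambda b_: expit(a + b_ + base[exp_]).mean() - targets[1], -10, 10, xtol=1e-8)
        return a, b, base

    a1, b1, base1 = calibrate(0.25, (0.184, 0.306), np.zeros(n))
    print(f"alpha_m1 intercept: {a1:.4f}  x: {b1:.4f}")
    m1 = (rng.random(n) < expit(a1 + b1 * x + base1)).astype(float)

    a2, b2, base2 = calibrate(0.20, (0.315, 0.406), 0.5 * m1)
    print(f"alpha_m2 intercept: {a2:.4f}  x: {b2:.4f}")
    m2 = (rng.random(n) < expit(a2 + b2 * x + base2)).astype(float)

    ay, by, _ = calibrate(0.30, (0.027, 0.083), 0.8 * m1 + 0.7 * m2)
    print(f"alpha_y intercept: {ay:.4f}  x: {by:.4f}")


if __name__ == "__main__":
    main()
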