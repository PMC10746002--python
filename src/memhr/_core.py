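"""Jit-compiled numerical core.

All long-horizon work (trajectory integration, Lyapunov spectra, Benettin
cross-checks) runs through the compiled routines here.  Parameters travel as
a flat float64 vector ``p = (a, b, c, d, k, alpha, beta, A1, f1, A2, f2)`` so
the kernels stay monomorphic.

The kernels are generic in the right-hand side: ``dp45``, ``lyap_qr`` and
``benettin_le1`` accept jitted callbacks, so the exact same integrator code
paths can be exercised on closed-form oracle systems in the test suite.

``dp45`` is an adaptive Dormand-Prince 5(4) pair (the ODE45 contract) with
cubic-Hermite dense output on a uniform sample grid.  The Lyapunov kernels
use fixed-step RK4 on the state+tangent system with QR (modified
Gram-Schmidt) reorthonormalization, the classic Benettin setup.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi

# status codes for dp45
OK = 0
NONFINITE = 1
STEP_UNDERFLOW = 2


@njit(cache=True)
def rhs(t, y, p):
    """Vector field of the memristive HR neuron under two-tone AC drive."""
    a, b, c, d, k, alpha, beta, A1, f1, A2, f2 = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
    )
    x, yv, phi = y[0], y[1], y[2]
    W = alpha + beta * phi * phi
    I = A1 * np.sin(TWO_PI * f1 * t) + A2 * np.sin(TWO_PI * f2 * t)
    out = np.empty(3)
    out[0] = yv + a * x * x - b * x * x * x + k * W * x + I
    out[1] = c - d * x * x - yv
    out[2] = x - phi
    return out


@njit(cache=True)
def jac(t, y, p):
    """State-space Jacobian of the vector field (drive terms drop out)."""
    a, b, d, k, beta = p[0], p[1], p[3], p[4], p[6]
    alpha = p[5]
    x, phi = y[0], y[2]
    J = np.zeros((3, 3))
    J[0, 0] = 2.0 * a * x - 3.0 * b * x * x + k * (alpha + beta * phi * phi)
    J[0, 1] = 1.0
    J[0, 2] = 2.0 * k * beta * phi * x
    J[1, 0] = -2.0 * d * x
    J[1, 1] = -1.0
    J[2, 0] = 1.0
    J[2, 2] = -1.0
    return J


@njit
def dp45(f, p, y0, t0, t1, rtol, atol, max_step, sample_dt):
    """Adaptive Dormand-Prince 5(4) with dense output on a uniform grid.

    ``f(t, y, p)`` is a jitted right-hand side of any dimension.  Returns
    (t_samples, y_samples, status, t_fail).  Sampling uses cubic Hermite
    interpolation on each accepted step (interpolation error is far below
    the step-control tolerance at the default settings).
    """
    ndim = y0.shape[0]
    n_out = int(np.floor((t1 - t0) / sample_dt + 1e-9)) + 1
    ts = np.empty(n_out)
    ys = np.empty((n_out, ndim))
    for i in range(n_out):
        ts[i] = t0 + i * sample_dt
    ts[n_out - 1] = min(ts[n_out - 1], t1)

    t = t0
    y = y0.copy()
    fv = f(t, y, p)
    ys[0] = y
    i_out = 1

    h = min(1e-3, max_step)
    safety, minfac, maxfac = 0.9, 0.2, 5.0

    while t < t1 - 1e-12:
        if h > max_step:
            h = max_step
        if t + h > t1:
            h = t1 - t
        if h < 1e-13:
            return ts[:i_out], ys[:i_out], STEP_UNDERFLOW, t

        k1 = fv
        k2 = f(t + 0.2 * h, y + h * (0.2 * k1), p)
        k3 = f(t + 0.3 * h, y + h * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2), p)
        k4 = f(t + 0.8 * h, y + h * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2
                                     + 32.0 / 9.0 * k3), p)
        k5 = f(t + 8.0 / 9.0 * h,
               y + h * (19372.0 / 6561.0 * k1 - 25360.0 / 2187.0 * k2
                        + 64448.0 / 6561.0 * k3 - 212.0 / 729.0 * k4), p)
        k6 = f(t + h,
               y + h * (9017.0 / 3168.0 * k1 - 355.0 / 33.0 * k2
                        + 46732.0 / 5247.0 * k3 + 49.0 / 176.0 * k4
                        - 5103.0 / 18656.0 * k5), p)
        y5 = y + h * (35.0 / 384.0 * k1 + 500.0 / 1113.0 * k3
                      + 125.0 / 192.0 * k4 - 2187.0 / 6784.0 * k5
                      + 11.0 / 84.0 * k6)
        k7 = f(t + h, y5, p)
        # embedded 4th-order error estimate
        e = h * ((35.0 / 384.0 - 5179.0 / 57600.0) * k1
                 + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3
                 + (125.0 / 192.0 - 393.0 / 640.0) * k4
                 + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5
                 + (11.0 / 84.0 - 187.0 / 2100.0) * k6
                 + (-1.0 / 40.0) * k7)

        errn = 0.0
        ok = True
        for j in range(ndim):
            if not np.isfinite(y5[j]):
                ok = False
                break
            sc = atol + rtol * max(abs(y[j]), abs(y5[j]))
            r = e[j] / sc
            errn += r * r
        if not ok:
            return ts[:i_out], ys[:i_out], NONFINITE, t
        errn = np.sqrt(errn / ndim)

        if errn <= 1.0:
            # dense output over (t, t+h]
            while i_out < n_out and ts[i_out] <= t + h + 1e-12:
                th = (ts[i_out] - t) / h
                h00 = (1.0 + 2.0 * th) * (1.0 - th) * (1.0 - th)
                h10 = th * (1.0 - th) * (1.0 - th)
                h01 = th * th * (3.0 - 2.0 * th)
                h11 = th * th * (th - 1.0)
                for j in range(ndim):
                    ys[i_out, j] = (h00 * y[j] + h10 * h * k1[j]
                                    + h01 * y5[j] + h11 * h * k7[j])
                i_out += 1
            t = t + h
            y = y5
            fv = k7  # FSAL
            fac = safety * errn ** -0.2 if errn > 1e-10 else maxfac
        else:
            fac = safety * errn ** -0.2
        if fac < minfac:
            fac = minfac
        elif fac > maxfac:
            fac = maxfac
        h = h * fac

    if i_out < n_out:
        ys[n_out - 1] = y
        i_out = n_out
    return ts, ys, OK, t1


@njit
def _rk4_step(f, t, y, h, p):
    k1 = f(t, y, p)
    k2 = f(t + 0.5 * h, y + 0.5 * h * k1, p)
    k3 = f(t + 0.5 * h, y + 0.5 * h * k2, p)
    k4 = f(t + h, y + h * k3, p)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit
def rk4_transient(f, p, y0, t0, t_len, dt):
    """Advance the state by t_len with fixed-step RK4 (no output)."""
    n = max(1, int(np.ceil(t_len / dt)))
    h = t_len / n
    t = t0
    y = y0.copy()
    for _ in range(n):
        y = _rk4_step(f, t, y, h, p)
        t += h
    return y


@njit
def _rk4_step_aug(f, fjac, t, s, V, h, p):
    """One RK4 step of the augmented (state, tangent-frame) system."""
    n = s.shape[0]
    k1s = f(t, s, p)
    k1v = fjac(t, s, p) @ V
    s2 = s + 0.5 * h * k1s
    k2s = f(t + 0.5 * h, s2, p)
    k2v = fjac(t + 0.5 * h, s2, p) @ (V + 0.5 * h * k1v)
    s3 = s + 0.5 * h * k2s
    k3s = f(t + 0.5 * h, s3, p)
    k3v = fjac(t + 0.5 * h, s3, p) @ (V + 0.5 * h * k2v)
    s4 = s + h * k3s
    k4s = f(t + h, s4, p)
    k4v = fjac(t + h, s4, p) @ (V + h * k3v)
    s_new = s + (h / 6.0) * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
    V_new = V + (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    return s_new, V_new


@njit
def lyap_qr(f, fjac, p, y0, t_transient, t_horizon, renorm_dt, dt, V0):
    """Full Lyapunov spectrum by tangent-space integration with QR renorm.

    ``f(t, y, p)`` and ``fjac(t, y, p)`` are jitted callbacks (any state
    dimension).  Returns (exponents in integration order, trace of running
    estimates, trace times).
    """
    n = y0.shape[0]
    y = rk4_transient(f, p, y0, 0.0, t_transient, dt) if t_transient > 0 \
        else y0.copy()
    t = t_transient
    V = V0.copy()

    n_renorm = max(1, int(np.round(t_horizon / renorm_dt)))
    cum = np.zeros(n)
    trace = np.empty((n_renorm, n))
    t_trace = np.empty(n_renorm)
    n_sub = max(1, int(np.ceil(renorm_dt / dt)))
    h = renorm_dt / n_sub

    for i in range(n_renorm):
        for _ in range(n_sub):
            y, V = _rk4_step_aug(f, fjac, t, y, V, h, p)
            t += h
        # modified Gram-Schmidt on the tangent columns
        for col in range(n):
            for prev in range(col):
                dot = 0.0
                for row in range(n):
                    dot += V[row, col] * V[row, prev]
                for row in range(n):
                    V[row, col] -= dot * V[row, prev]
            nrm = 0.0
            for row in range(n):
                nrm += V[row, col] ** 2
            nrm = np.sqrt(nrm)
            if nrm < 1e-300 or not np.isfinite(nrm):
                trace[i:] = np.nan
                return np.full(n, np.nan), trace, t_trace
            cum[col] += np.log(nrm)
            for row in range(n):
                V[row, col] /= nrm
        elapsed = (i + 1) * renorm_dt
        t_trace[i] = t_transient + elapsed
        for col in range(n):
            trace[i, col] = cum[col] / elapsed
    return cum / t_horizon, trace, t_trace


@njit
def benettin_le1(f, p, y0, t_transient, t_horizon, renorm_dt, dt, d0):
    """Leading Lyapunov exponent from two nearby trajectories (cross-check)."""
    n = y0.shape[0]
    y = rk4_transient(f, p, y0, 0.0, t_transient, dt) if t_transient > 0 \
        else y0.copy()
    t = t_transient
    z = y.copy()
    z[0] += d0

    n_renorm = max(1, int(np.round(t_horizon / renorm_dt)))
    n_sub = max(1, int(np.ceil(renorm_dt / dt)))
    h = renorm_dt / n_sub
    cum = 0.0
    for _ in range(n_renorm):
        tt = t
        for _ in range(n_sub):
            y = _rk4_step(f, tt, y, h, p)
            z = _rk4_step(f, tt, z, h, p)
            tt += h
        t = tt
        dist = 0.0
        for j in range(n):
            dist += (y[j] - z[j]) ** 2
        dist = np.sqrt(dist)
        if dist < 1e-300 or not np.isfinite(dist):
            return np.nan
        cum += np.log(dist / d0)
        for j in range(n):
            z[j] = y[j] + (z[j] - y[j]) * (d0 / dist)
    return cum / (n_renorm * renorm_dt)
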