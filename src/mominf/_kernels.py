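"""Compiled numerical kernels (numba).

Everything on the hot path of inference lives here: the Gillespie direct
method for the feedback loop, an adaptive Dormand-Prince integrator for the
six closure ODE systems, the weighted moment-mismatch objective (scalar and
population-batched for vectorised differential evolution) and the adaptive
Metropolis chain.  The pure-Python modules wrap these with validated,
documented interfaces.

Closure state layouts (theta = (rho_u, b, d, sigma_b, sigma_u); e1, e2, e3
are the first three raw moments of the geometric burst law):

- ``lna``  (5): [p_on, phi_n, V_gg, V_gn, V_nn] - rate equations plus the
  linear-noise covariance (Lyapunov) equation with burst-augmented diffusion.
- ``3ma``  (9): all raw joint moments <y^i n^j>, 1 <= i+j <= 3, of the
  (gene, protein) species pair treated as ordinary mass-action species
  (the binary-gene identity y^2 = y is *not* used, as in standard moment-
  closure software); the order-4 moments <y^3 n>, <y^2 n^2>, <y n^3> are
  closed by zero fourth joint cumulants.
- ``dm``   (9): same state and equations, order-4 moments closed by the
  derivative-matching products with binomial-coefficient exponents.
- ``cg``   (7): [p_on, c1, c2, c3, z1, z2, z3] with c_k = <y n^k> and
  z_k = <(1-y) n^k>; the fourth conditional moment is closed by a zero
  fourth conditional cumulant (conditional Gaussian at fourth order).
- ``cdm``  (7): same layout extended to third conditional moments; the
  fourth conditional moment is closed by univariate derivative matching
  E[n^4|g] = E[n|g]^4 E[n^3|g]^4 / E[n^2|g]^6.
- ``lma``  (7): [p_on, c1, c2, c3, z1, z2, z3] for the mapped linear (bursty
  telegraph) system whose ON->OFF switching rate sigma_b * E[n|ON] is updated
  self-consistently from the state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# closure ids
CID = {"lna": 0, "3ma": 1, "dm": 2, "cdm": 3, "cg": 4, "lma": 5}
_DIMS = np.array([5, 9, 9, 7, 7, 7], dtype=np.int64)

_SQRT_PI = np.sqrt(np.pi)
PENALTY = 1.0e12

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
])
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array([
    5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
    -92097 / 339200, 187 / 2100, 1 / 40,
])

_RTOL = 1.0e-8
_ATOL = 1.0e-10
_MAX_STEPS = 200_000


@njit(cache=True)
def _closure_dim(cid):
    return _DIMS[cid]


@njit(cache=True)
def _rhs(cid, y, r, d, sb, su, e1, e2, e3, dy):
    """Time derivative of the closure state ``y`` into ``dy``."""
    if cid == 0:  # LNA
        g = y[0]
        n = y[1]
        vgg = y[2]
        vgn = y[3]
        vnn = y[4]
        dy[0] = su * (1.0 - g) - sb * g * n
        dy[1] = r * e1 * g - d * n - sb * g * n
        j00 = -su - sb * n
        j01 = -sb * g
        j10 = r * e1 - sb * n
        j11 = -d - sb * g
        fb = sb * g * n
        fu = su * (1.0 - g)
        dy[2] = 2.0 * (j00 * vgg + j01 * vgn) + fb + fu
        dy[3] = j10 * vgg + (j00 + j11) * vgn + j01 * vnn + fb
        dy[4] = 2.0 * (j10 * vgn + j11 * vnn) + r * g * e2 + d * n + fb
    elif cid == 1 or cid == 2:  # 3MA / DM on the full two-species hierarchy
        M10 = y[0]
        M01 = y[1]
        M20 = y[2]
        M11 = y[3]
        M02 = y[4]
        M30 = y[5]
        M21 = y[6]
        M12 = y[7]
        M03 = y[8]
        if cid == 1:
            # zero fourth joint cumulants, expressed in raw moments
            Q13 = (6.0 * M01 ** 3 * M10 - 6.0 * M01 ** 2 * M11
                   - 6.0 * M01 * M02 * M10 + 3.0 * M01 * M12
                   + 3.0 * M02 * M11 + M03 * M10)
            Q22 = (6.0 * M01 ** 2 * M10 ** 2 - 2.0 * M01 ** 2 * M20
                   - 8.0 * M01 * M10 * M11 + 2.0 * M01 * M21
                   - 2.0 * M02 * M10 ** 2 + M02 * M20
                   + 2.0 * M10 * M12 + 2.0 * M11 ** 2)
            Q31 = (6.0 * M01 * M10 ** 3 - 6.0 * M01 * M10 * M20 + M01 * M30
                   - 6.0 * M10 ** 2 * M11 + 3.0 * M10 * M21 + 3.0 * M11 * M20)
        else:
            # derivative-matching products (lognormal-consistent exponents)
            if (M01 < 1.0e-10 or M11 < 1.0e-10 or M02 < 1.0e-10
                    or M20 < 1.0e-10 or M10 < 1.0e-10):
                Q13 = 0.0
                Q22 = 0.0
                Q31 = 0.0
            else:
                Q31 = (M10 / M20) ** 3 * M30 * M01 * (M21 / M11) ** 3
                Q22 = (M10 * M01 * M21 * M12 / (M11 * M11)) ** 2 / (M20 * M02)
                Q13 = (M01 / M02) ** 3 * M03 * M10 * (M12 / M11) ** 3
        dy[0] = su * (1.0 - M10) - sb * M11
        dy[1] = r * e1 * M10 - d * M01 - sb * M11
        dy[2] = sb * (M11 - 2.0 * M21) + su * (M10 - 2.0 * M20 + 1.0)
        dy[3] = (r * e1 * M20 - d * M11 + sb * (M11 - M12 - M21)
                 + su * (M01 - M11))
        dy[4] = (r * (e2 * M10 + 2.0 * e1 * M11) + d * (M01 - 2.0 * M02)
                 + sb * (M11 - 2.0 * M12))
        dy[5] = (sb * (3.0 * M21 - M11 - 3.0 * Q31)
                 + su * (2.0 * M10 - 3.0 * M30 + 1.0))
        dy[6] = (r * e1 * M30 - d * M21
                 + sb * (M12 + 2.0 * M21 - M11 - 2.0 * Q22 - Q31)
                 + su * (M01 + M11 - 2.0 * M21))
        dy[7] = (r * (e2 * M20 + 2.0 * e1 * M21) + d * (M11 - 2.0 * M12)
                 + sb * (2.0 * M12 + M21 - M11 - Q13 - 2.0 * Q22)
                 + su * (M02 - M12))
        dy[8] = (r * (e3 * M10 + 3.0 * e2 * M11 + 3.0 * e1 * M12)
                 + d * (3.0 * M02 - M01 - 3.0 * M03)
                 + sb * (3.0 * M12 - M11 - 3.0 * Q13))
    elif cid == 3 or cid == 4:  # CDM / CG (conditional closures, order 3)
        g = y[0]
        c1 = y[1]
        c2 = y[2]
        c3 = y[3]
        z1 = y[4]
        z2 = y[5]
        z3 = y[6]
        if cid == 3:
            # conditional derivative matching for E[n^4 | ON]:
            # E[n^4] = E[n]^4 E[n^3]^4 / E[n^2]^6 (lognormal-consistent)
            if c1 < 1.0e-8 or c2 < 1.0e-12 or g < 1.0e-12:
                q4 = 0.0
            else:
                q4 = c1 ** 4 * c3 ** 4 / (c2 ** 6 * g)
        else:
            # zero fourth conditional cumulant (conditional Gaussian)
            if g < 1.0e-12:
                q4 = 0.0
            else:
                n1 = c1 / g
                n2 = c2 / g
                n3 = c3 / g
                mu2c = n2 - n1 * n1
                mu3c = n3 - 3.0 * n1 * n2 + 2.0 * n1 ** 3
                e4 = (3.0 * mu2c * mu2c + 4.0 * n1 * mu3c
                      + 6.0 * n1 * n1 * mu2c + n1 ** 4)
                q4 = g * e4
        dy[0] = su * (1.0 - g) - sb * c1
        dy[1] = r * e1 * g - d * c1 - sb * c2 + su * z1
        dy[2] = (r * (2.0 * e1 * c1 + e2 * g) + d * (c1 - 2.0 * c2)
                 - sb * c3 + su * z2)
        dy[3] = (r * (3.0 * e1 * c2 + 3.0 * e2 * c1 + e3 * g)
                 + d * (3.0 * c2 - c1 - 3.0 * c3) - sb * q4 + su * z3)
        dy[4] = -d * z1 + sb * (c2 - c1) - su * z1
        dy[5] = d * (z1 - 2.0 * z2) + sb * (c3 - 2.0 * c2 + c1) - su * z2
        dy[6] = (d * (3.0 * z2 - z1 - 3.0 * z3)
                 + sb * (q4 - 3.0 * c3 + 3.0 * c2 - c1) - su * z3)
    else:  # LMA: mapped bursty telegraph system
        g = y[0]
        c1 = y[1]
        c2 = y[2]
        c3 = y[3]
        z1 = y[4]
        z2 = y[5]
        z3 = y[6]
        gg = g if g > 1.0e-12 else 1.0e-12
        s = sb * c1 / gg  # effective switching rate sigma_b * E[n | ON]
        dy[0] = su * (1.0 - g) - s * g
        dy[1] = r * e1 * g - d * c1 - s * c1 + su * z1
        dy[2] = r * (2.0 * e1 * c1 + e2 * g) + d * (c1 - 2.0 * c2) - s * c2 + su * z2
        dy[3] = (r * (3.0 * e1 * c2 + 3.0 * e2 * c1 + e3 * g)
                 + d * (3.0 * c2 - c1 - 3.0 * c3) - s * c3 + su * z3)
        dy[4] = -d * z1 + s * c1 - su * z1
        dy[5] = d * (z1 - 2.0 * z2) + s * c2 - su * z2
        dy[6] = d * (3.0 * z2 - z1 - 3.0 * z3) + s * c3 - su * z3


@njit(cache=True)
def _raw_output(cid, y, out):
    """Raw protein moments (m1, m2, m3) implied by closure state ``y``."""
    if cid == 0:
        m1 = y[1]
        m2 = y[4] + m1 * m1
        m3 = 3.0 * m1 * m2 - 2.0 * m1 ** 3  # central third identically zero
    elif cid == 1 or cid == 2:
        m1 = y[1]
        m2 = y[4]
        m3 = y[8]
    elif cid == 3 or cid == 4:
        m1 = y[1] + y[4]
        m2 = y[2] + y[5]
        m3 = y[3] + y[6]
    else:
        m1 = y[1] + y[4]
        m2 = y[2] + y[5]
        m3 = y[3] + y[6]
    out[0] = m1
    out[1] = m2
    out[2] = m3


@njit(cache=True)
def integrate_closure(cid, r, d, sb, su, e1, e2, e3, times, out_raw):
    """Adaptive DP45 integration of the closure from the (ON, n=0) state.

    ``out_raw`` (3, L) receives raw moments at the grid times.  Returns True
    on success; False on step-count exhaustion or non-finite state (the
    caller treats the evaluation as an infinite-likelihood penalty).
    """
    dim = _closure_dim(cid)
    y = np.zeros(dim)
    y[0] = 1.0  # all mass on gene ON, zero proteins
    if cid == 1 or cid == 2:
        y[2] = 1.0  # <y^2> = <y^3> = 1 at t=0
        y[5] = 1.0
    k = np.empty((7, dim))
    ytmp = np.empty(dim)
    y5 = np.empty(dim)
    y4 = np.empty(dim)
    tmp3 = np.empty(3)

    t = 0.0
    h = 1.0e-4
    nsteps = 0
    _rhs(cid, y, r, d, sb, su, e1, e2, e3, k[0])
    have_k0 = True
    for li in range(times.shape[0]):
        t_target = times[li]
        while t < t_target - 1.0e-12:
            if nsteps > _MAX_STEPS:
                return False
            if h > t_target - t:
                h = t_target - t
            if not have_k0:
                _rhs(cid, y, r, d, sb, su, e1, e2, e3, k[0])
                have_k0 = True
            # stages 2..7
            for s in range(1, 6):
                for j in range(dim):
                    acc = 0.0
                    for q in range(s):
                        acc += _A[s, q] * k[q, j]
                    ytmp[j] = y[j] + h * acc
                _rhs(cid, ytmp, r, d, sb, su, e1, e2, e3, k[s])
            for j in range(dim):
                acc = 0.0
                for q in range(6):
                    acc += _B5[q] * k[q, j]
                y5[j] = y[j] + h * acc
            _rhs(cid, y5, r, d, sb, su, e1, e2, e3, k[6])
            for j in range(dim):
                acc = 0.0
                for q in range(7):
                    acc += _B4[q] * k[q, j]
                y4[j] = y[j] + h * acc
            # error norm
            err = 0.0
            ok = True
            for j in range(dim):
                if not np.isfinite(y5[j]):
                    ok = False
                    break
                sc = _ATOL + _RTOL * max(abs(y[j]), abs(y5[j]))
                e = (y5[j] - y4[j]) / sc
                err += e * e
            nsteps += 1
            if not ok:
                return False
            err = np.sqrt(err / dim)
            if err <= 1.0:
                t = t + h
                for j in range(dim):
                    y[j] = y5[j]
                for j in range(dim):
                    k[0, j] = k[6, j]  # FSAL
                have_k0 = True
                if err < 1.0e-30:
                    fac = 5.0
                else:
                    fac = min(5.0, max(0.2, 0.9 * err ** (-0.2)))
                h = h * fac
            else:
                h = h * max(0.1, 0.9 * err ** (-0.2))
                have_k0 = True  # k0 unchanged, still valid
                if h < 1.0e-14:
                    return False
        _raw_output(cid, y, tmp3)
        out_raw[0, li] = tmp3[0]
        out_raw[1, li] = tmp3[1]
        out_raw[2, li] = tmp3[2]
    return True


@njit(cache=True)
def burst_moments(b):
    e1 = b
    e2 = 2.0 * b * b + b
    e3 = 6.0 * b ** 3 + 6.0 * b * b + b
    return e1, e2, e3


@njit(cache=True)
def _lognormal_log_params(mean, sd, scale_flag):
    """(mu, sigma) of ln rho_u; scale_flag 0 = arithmetic, 1 = log."""
    if scale_flag == 1:
        return np.log(mean), sd
    if sd <= 0.0:
        return np.log(mean), 0.0
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


@njit(cache=True)
def closure_raw(cid, theta, times, out_raw):
    """Homogeneous closure prediction; theta = (rho_u, b, d, sb, su)."""
    e1, e2, e3 = burst_moments(theta[1])
    return integrate_closure(
        cid, theta[0], theta[2], theta[3], theta[4], e1, e2, e3, times, out_raw
    )


@njit(cache=True)
def closure_raw_het(cid, theta6, scale_flag, gh_x, gh_w, times, out_raw):
    """Lognormal-rho_u mixture prediction via Gauss-Hermite quadrature.

    theta6 = (mean_rho_u, sd_rho_u, b, d, sigma_b, sigma_u).  Population raw
    moments are quadrature-weighted averages of the conditional (fixed rho_u)
    closure moments: the law of total expectation applied to E[n^k].
    """
    mu, sig = _lognormal_log_params(theta6[0], theta6[1], scale_flag)
    e1, e2, e3 = burst_moments(theta6[2])
    d = theta6[3]
    sb = theta6[4]
    su = theta6[5]
    L = times.shape[0]
    for q in range(3):
        for l in range(L):
            out_raw[q, l] = 0.0
    if sig == 0.0:
        return integrate_closure(
            cid, theta6[0], d, sb, su, e1, e2, e3, times, out_raw
        )
    node = np.empty((3, L))
    for i in range(gh_x.shape[0]):
        rho = np.exp(mu + np.sqrt(2.0) * sig * gh_x[i])
        wt = gh_w[i] / _SQRT_PI
        ok = integrate_closure(cid, rho, d, sb, su, e1, e2, e3, times, node)
        if not ok:
            return False
        for q in range(3):
            for l in range(L):
                out_raw[q, l] += wt * node[q, l]
    return True


@njit(cache=True)
def raw_to_central(raw, central):
    """In-place conversion of (3, L) raw moments to central moments."""
    for l in range(raw.shape[1]):
        m1 = raw[0, l]
        m2 = raw[1, l]
        m3 = raw[2, l]
        central[0, l] = m1
        central[1, l] = m2 - m1 * m1
        central[2, l] = m3 - 3.0 * m1 * m2 + 2.0 * m1 ** 3


@njit(cache=True)
def chi2(cid, theta, het, scale_flag, gh_x, gh_w, times, data, w):
    """Weighted moment mismatch sum_k sum_l (mu_hat - mu_tilde)^2 / sigma_k^2.

    ``data`` and ``w`` are (3, L); orders not used carry zero weight.  Flagged
    closure evaluations (blow-up, negative predicted variance) return the
    large PENALTY value.
    """
    L = times.shape[0]
    raw = np.empty((3, L))
    if het == 1:
        ok = closure_raw_het(cid, theta, scale_flag, gh_x, gh_w, times, raw)
    else:
        ok = closure_raw(cid, theta, times, raw)
    if not ok:
        return PENALTY
    cen = np.empty((3, L))
    raw_to_central(raw, cen)
    total = 0.0
    for l in range(L):
        if cen[1, l] < -1.0e-6 * (1.0 + abs(raw[1, l])):
            return PENALTY  # negative predicted variance: flagged
    for q in range(3):
        for l in range(L):
            if w[q, l] > 0.0:
                diff = data[q, l] - cen[q, l]
                total += diff * diff * w[q, l]
    if not np.isfinite(total):
        return PENALTY
    return total


@njit(cache=True)
def chi2_batch(cid, log_thetas, het, scale_flag, gh_x, gh_w, times, data, w):
    """Vectorised objective for differential evolution (log-parameter rows)."""
    P = log_thetas.shape[0]
    out = np.empty(P)
    for p in range(P):
        theta = np.exp(log_thetas[p])
        out[p] = chi2(cid, theta, het, scale_flag, gh_x, gh_w, times, data, w)
    return out


# ---------------------------------------------------------------------------
# Stochastic simulation (Gillespie direct method, bursty production)


@njit(cache=True)
def ssa_cells(seeds, rho, b, d, sb, su, times):
    """Simulate one trajectory per cell, sampling protein counts at ``times``.

    ``seeds``: per-cell RNG seeds; ``rho``: per-cell burst-firing rates
    (identical entries for homogeneous populations).  Initial condition:
    gene ON, zero proteins.
    """
    N = seeds.shape[0]
    L = times.shape[0]
    counts = np.zeros((N, L), dtype=np.int64)
    q = b / (1.0 + b)
    lnq = np.log(q)
    for i in range(N):
        np.random.seed(seeds[i])
        r = rho[i]
        t = 0.0
        g = 1
        n = 0
        idx = 0
        while idx < L:
            a1 = r if g == 1 else 0.0
            a2 = sb * n if g == 1 else 0.0
            a3 = su if g == 0 else 0.0
            a4 = d * n
            a0 = a1 + a2 + a3 + a4
            if a0 <= 0.0:
                while idx < L:
                    counts[i, idx] = n
                    idx += 1
                break
            tau = -np.log(1.0 - np.random.random()) / a0
            t_next = t + tau
            while idx < L and times[idx] <= t_next:
                counts[i, idx] = n
                idx += 1
            if idx >= L:
                break
            t = t_next
            u = np.random.random() * a0
            if u < a1:
                # bursty production: geometric burst on {0, 1, ...}
                m = int(np.floor(np.log(1.0 - np.random.random()) / lnq))
                n += m
            elif u < a1 + a2:
                g = 0
                n -= 1
            elif u < a1 + a2 + a3:
                g = 1
            else:
                n -= 1
    return counts


# ---------------------------------------------------------------------------
# Adaptive Metropolis sampler (Haario-style, log-parameter space)


@njit(cache=True)
def _chol_jitter(a):
    """Cholesky with escalating diagonal jitter for near-singular matrices."""
    dim = a.shape[0]
    jitter = 0.0
    scale = 0.0
    for i in range(dim):
        if a[i, i] > scale:
            scale = a[i, i]
    if scale <= 0.0:
        scale = 1.0
    for _ in range(10):
        L = np.zeros((dim, dim))
        ok = True
        for i in range(dim):
            for j in range(i + 1):
                s = a[i, j]
                if i == j:
                    s += jitter
                for m in range(j):
                    s -= L[i, m] * L[j, m]
                if i == j:
                    if s <= 0.0:
                        ok = False
                        break
                    L[i, i] = np.sqrt(s)
                else:
                    L[i, j] = s / L[j, j]
            if not ok:
                break
        if ok:
            return L
        jitter = scale * 1.0e-10 if jitter == 0.0 else jitter * 100.0
    return np.eye(dim) * np.sqrt(scale)


@njit(cache=True)
def am_chain(cid, het, scale_flag, gh_x, gh_w, times, data, w,
             log_lo, log_hi, x0, n_iter, seed):
    """One adaptive Metropolis chain over ln(theta).

    Log-posterior = -chi2/2 within the uniform log-space prior box, -inf
    outside.  The proposal is N(0, lambda^2 * (2.38^2/d) * Sigma) where
    Sigma is re-estimated every 500 iterations from the most recent half of
    the chain and the scalar lambda is tuned towards a 25% acceptance rate
    with a diminishing adaptation schedule (vanishing adaptation keeps the
    ergodic limit correct).
    """
    np.random.seed(seed)
    dim = x0.shape[0]
    samples = np.empty((n_iter, dim))
    logp = np.empty(n_iter)
    x = x0.copy()
    lp = -0.5 * chi2(cid, np.exp(x), het, scale_flag, gh_x, gh_w, times, data, w)

    warm = 500
    lam = 1.0
    base = 0.02 / np.sqrt(dim)
    chol = np.eye(dim) * base
    accepted = 0
    recent_acc = 0.0
    z = np.empty(dim)
    xp = np.empty(dim)
    mean = np.empty(dim)
    covm = np.empty((dim, dim))
    for it in range(n_iter):
        for j in range(dim):
            z[j] = np.random.standard_normal()
        inside = True
        for j in range(dim):
            step = 0.0
            for m in range(j + 1):
                step += chol[j, m] * z[m]
            xp[j] = x[j] + lam * step
            if xp[j] < log_lo[j] or xp[j] > log_hi[j]:
                inside = False
        acc = False
        if inside:
            lpp = -0.5 * chi2(
                cid, np.exp(xp), het, scale_flag, gh_x, gh_w, times, data, w
            )
            if lpp - lp > np.log(1.0 - np.random.random()):
                for j in range(dim):
                    x[j] = xp[j]
                lp = lpp
                accepted += 1
                acc = True
        samples[it] = x
        logp[it] = lp
        # scalar scale adaptation towards 25% acceptance (diminishing)
        gamma = 1.0 / np.sqrt(it + 10.0)
        lam *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.25))
        if lam < 1.0e-3:
            lam = 1.0e-3
        elif lam > 1.0e3:
            lam = 1.0e3
        # covariance re-estimation from the most recent half of the chain
        if it >= warm and (it + 1) % 500 == 0:
            lo = (it + 1) // 2
            n = it + 1 - lo
            for j in range(dim):
                s = 0.0
                for q in range(lo, it + 1):
                    s += samples[q, j]
                mean[j] = s / n
            for j in range(dim):
                for m in range(j + 1):
                    s = 0.0
                    for q in range(lo, it + 1):
                        s += (samples[q, j] - mean[j]) * (samples[q, m] - mean[m])
                    covm[j, m] = s / (n - 1)
                    covm[m, j] = covm[j, m]
            sd = 2.38 * 2.38 / dim
            a = covm * sd
            for j in range(dim):
                a[j, j] += 1.0e-12 + 1.0e-8 * a[j, j]
            chol = _chol_jitter(a)
    return samples, logp, accepted
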