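"""Numba Gibbs kernels for the homogeneous and heterogeneous models.

Single-threaded, seeded through numba's internal RNG, with incremental
residual maintenance (adjust-on-update) giving O(n * m) work per cycle.
Residuals are rebuilt from scratch every ``_REFRESH`` cycles to cap float
drift.  Status codes: 0 ok, 1 variance ceiling exceeded (divergence).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_REFRESH = 1000


@njit(cache=True)
def _sample_variance_nb(ss, k, ceiling):
    """sigma2 | rest under a flat prior on (0, ceiling]:
    density prop. to sigma2^(-k/2) exp(-ss / (2 sigma2))."""
    if k >= 3 and ss > 0.0:
        for _ in range(100):
            v = ss / np.random.chisquare(k - 2)
            if v <= ceiling:
                return v
        return ceiling
    lo = ceiling * 1e-14
    ngrid = 512
    llo = np.log(lo)
    lhi = np.log(ceiling)
    xs = np.empty(ngrid)
    logp = np.empty(ngrid)
    for t in range(ngrid):
        lx = llo + (lhi - llo) * (t + 0.5) / ngrid
        x = np.exp(lx)
        xs[t] = x
        logp[t] = -0.5 * k * np.log(x) - ss / (2.0 * x) + lx
    mx = logp.max()
    total = 0.0
    cdf = np.empty(ngrid)
    for t in range(ngrid):
        total += np.exp(logp[t] - mx)
        cdf[t] = total
    u = np.random.random() * total
    for t in range(ngrid):
        if cdf[t] >= u:
            return xs[t]
    return xs[ngrid - 1]


@njit(cache=True)
def _wdot_col(W, col, w, e):
    """sum_n w[n] * W[n, col] * e[n]."""
    acc = 0.0
    for n in range(W.shape[0]):
        acc += w[n] * W[n, col] * e[n]
    return acc


@njit(cache=True)
def _axpy_col(W, col, coef, e):
    for n in range(W.shape[0]):
        e[n] += coef * W[n, col]


@njit(cache=True)
def _deviance(n1, n2, w1, w2, e1, e2, s2e1, s2e2, logdet_d1, logdet_d2):
    ss1 = 0.0
    for n in range(n1):
        ss1 += w1[n] * e1[n] * e1[n]
    ss2 = 0.0
    for n in range(n2):
        ss2 += w2[n] * e2[n] * e2[n]
    two_pi = 2.0 * np.pi
    return (n1 * np.log(two_pi * s2e1) + logdet_d1 + ss1 / s2e1
            + n2 * np.log(two_pi * s2e2) + logdet_d2 + ss2 / s2e2)


@njit(cache=True)
def run_hom(W1, W2, y1, y2, w1, w2,
            n_cycles, burn_in, store_every, seed,
            r1_init, r2_init, s2a1_init, s2a2_init,
            ceiling1, ceiling2):
    """Gibbs sampler for a_i = r_i * s0 + a*_i (one variance channel).

    Returns (status, bad_cycle, stored cycle numbers, out dict arrays...,
    ghat1, ghat2, u_mean, s2e_mean).
    """
    np.random.seed(seed)
    n1, n2 = W1.shape[0], W2.shape[0]
    m = W1.shape[1]

    sw1 = np.sum(w1)
    sw2 = np.sum(w2)
    logdet_d1 = -np.sum(np.log(w1))
    logdet_d2 = -np.sum(np.log(w2))
    wcss1 = np.empty(m)
    wcss2 = np.empty(m)
    for k in range(m):
        acc1 = 0.0
        for n in range(n1):
            acc1 += w1[n] * W1[n, k] * W1[n, k]
        wcss1[k] = acc1
        acc2 = 0.0
        for n in range(n2):
            acc2 += w2[n] * W2[n, k] * W2[n, k]
        wcss2[k] = acc2

    u1 = 0.0
    u2 = 0.0
    acc = 0.0
    for n in range(n1):
        acc += w1[n] * y1[n]
    u1 = acc / sw1
    acc = 0.0
    for n in range(n2):
        acc += w2[n] * y2[n]
    u2 = acc / sw2

    s0 = np.zeros(m)
    a1s = np.zeros(m)
    a2s = np.zeros(m)
    r1 = r1_init
    r2 = r2_init
    s2a1 = s2a1_init
    s2a2 = s2a2_init
    s2e1 = 0.0
    s2e2 = 0.0
    acc = 0.0
    for n in range(n1):
        acc += w1[n] * (y1[n] - u1) ** 2
    s2e1 = 0.5 * acc / n1
    acc = 0.0
    for n in range(n2):
        acc += w2[n] * (y2[n] - u2) ** 2
    s2e2 = 0.5 * acc / n2

    e1 = np.empty(n1)
    e2 = np.empty(n2)
    for n in range(n1):
        e1[n] = y1[n] - u1
    for n in range(n2):
        e2[n] = y2[n] - u2

    n_store = n_cycles // store_every
    cyc_out = np.empty(n_store, dtype=np.int64)
    u_out = np.empty((n_store, 2))
    r_out = np.empty((n_store, 2))
    s2a_out = np.empty((n_store, 2))
    s2e_out = np.empty((n_store, 2))
    dev_out = np.empty(n_store)
    var_a_out = np.empty((n_store, 1, 2))
    cov_a_out = np.empty((n_store, 1))

    ghat1 = np.zeros(n1)
    ghat2 = np.zeros(n2)
    u_mean = np.zeros(2)
    s2e_mean = np.zeros(2)
    n_acc = 0

    x1 = np.empty(n1)
    x2 = np.empty(n2)

    status = 0
    bad_cycle = -1
    idx = 0
    for cycle in range(1, n_cycles + 1):
        # overall means
        acc = 0.0
        for n in range(n1):
            acc += w1[n] * (e1[n] + u1)
        mu = acc / sw1
        u1_new = mu + np.random.normal() * np.sqrt(s2e1 / sw1)
        shift = u1 - u1_new
        for n in range(n1):
            e1[n] += shift
        u1 = u1_new
        acc = 0.0
        for n in range(n2):
            acc += w2[n] * (e2[n] + u2)
        mu = acc / sw2
        u2_new = mu + np.random.normal() * np.sqrt(s2e2 / sw2)
        shift = u2 - u2_new
        for n in range(n2):
            e2[n] += shift
        u2 = u2_new

        # SNP loop: shared latent entry then residual effects
        for k in range(m):
            dot1 = _wdot_col(W1, k, w1, e1)
            dot2 = _wdot_col(W2, k, w2, e2)

            old = s0[k]
            prec = 1.0 + r1 * r1 * wcss1[k] / s2e1 + r2 * r2 * wcss2[k] / s2e2
            rhs = (r1 * (dot1 + r1 * wcss1[k] * old) / s2e1
                   + r2 * (dot2 + r2 * wcss2[k] * old) / s2e2)
            new = rhs / prec + np.random.normal() / np.sqrt(prec)
            s0[k] = new
            delta = new - old
            if delta != 0.0:
                _axpy_col(W1, k, -r1 * delta, e1)
                _axpy_col(W2, k, -r2 * delta, e2)
                dot1 -= r1 * wcss1[k] * delta
                dot2 -= r2 * wcss2[k] * delta

            old = a1s[k]
            prec = 1.0 / s2a1 + wcss1[k] / s2e1
            rhs = (dot1 + wcss1[k] * old) / s2e1
            new = rhs / prec + np.random.normal() / np.sqrt(prec)
            a1s[k] = new
            delta = new - old
            if delta != 0.0:
                _axpy_col(W1, k, -delta, e1)

            old = a2s[k]
            prec = 1.0 / s2a2 + wcss2[k] / s2e2
            rhs = (dot2 + wcss2[k] * old) / s2e2
            new = rhs / prec + np.random.normal() / np.sqrt(prec)
            a2s[k] = new
            delta = new - old
            if delta != 0.0:
                _axpy_col(W2, k, -delta, e2)

        # population scalars (flat prior)
        for n in range(n1):
            acc = 0.0
            for k in range(m):
                acc += W1[n, k] * s0[k]
            x1[n] = acc
        xwx = 0.0
        xwe = 0.0
        for n in range(n1):
            xwx += w1[n] * x1[n] * x1[n]
            xwe += w1[n] * x1[n] * (e1[n] + r1 * x1[n])
        if xwx > 0.0:
            prec = xwx / s2e1
            new = xwe / s2e1 / prec + np.random.normal() / np.sqrt(prec)
            delta = new - r1
            r1 = new
            for n in range(n1):
                e1[n] -= x1[n] * delta
        for n in range(n2):
            acc = 0.0
            for k in range(m):
                acc += W2[n, k] * s0[k]
            x2[n] = acc
        xwx = 0.0
        xwe = 0.0
        for n in range(n2):
            xwx += w2[n] * x2[n] * x2[n]
            xwe += w2[n] * x2[n] * (e2[n] + r2 * x2[n])
        if xwx > 0.0:
            prec = xwx / s2e2
            new = xwe / s2e2 / prec + np.random.normal() / np.sqrt(prec)
            delta = new - r2
            r2 = new
            for n in range(n2):
                e2[n] -= x2[n] * delta

        # group-rescaling move (r1, r2, s0) -> (t r1, t r2, s0 / t):
        # likelihood-invariant; t^2 ~ sum(s0^2) / chisq(m - 2) exactly
        if m > 4:
            ss = 0.0
            for k in range(m):
                ss += s0[k] * s0[k]
            t = np.sqrt(ss / np.random.chisquare(m - 2))
            for k in range(m):
                s0[k] /= t
            r1 *= t
            r2 *= t

        # variances
        ss = 0.0
        for k in range(m):
            ss += a1s[k] * a1s[k]
        s2a1 = _sample_variance_nb(ss, m, ceiling1)
        ss = 0.0
        for k in range(m):
            ss += a2s[k] * a2s[k]
        s2a2 = _sample_variance_nb(ss, m, ceiling2)
        ss = 0.0
        for n in range(n1):
            ss += w1[n] * e1[n] * e1[n]
        s2e1 = _sample_variance_nb(ss, n1, ceiling1)
        ss = 0.0
        for n in range(n2):
            ss += w2[n] * e2[n] * e2[n]
        s2e2 = _sample_variance_nb(ss, n2, ceiling2)

        if (s2e1 >= ceiling1 or s2e2 >= ceiling2 or s2a1 >= ceiling1
                or s2a2 >= ceiling2 or r1 * r1 >= ceiling1
                or r2 * r2 >= ceiling2):
            status = 1
            bad_cycle = cycle
            break

        dev = _deviance(n1, n2, w1, w2, e1, e2, s2e1, s2e2,
                        logdet_d1, logdet_d2)

        if cycle % store_every == 0:
            cyc_out[idx] = cycle
            u_out[idx, 0] = u1
            u_out[idx, 1] = u2
            r_out[idx, 0] = r1
            r_out[idx, 1] = r2
            s2a_out[idx, 0] = s2a1
            s2a_out[idx, 1] = s2a2
            s2e_out[idx, 0] = s2e1
            s2e_out[idx, 1] = s2e2
            dev_out[idx] = dev
            var_a_out[idx, 0, 0] = r1 * r1 + s2a1
            var_a_out[idx, 0, 1] = r2 * r2 + s2a2
            cov_a_out[idx, 0] = r1 * r2
            idx += 1

        if cycle > burn_in:
            for n in range(n1):
                ghat1[n] += y1[n] - u1 - e1[n]
            for n in range(n2):
                ghat2[n] += y2[n] - u2 - e2[n]
            u_mean[0] += u1
            u_mean[1] += u2
            s2e_mean[0] += s2e1
            s2e_mean[1] += s2e2
            n_acc += 1

        if cycle % _REFRESH == 0:
            # rebuild residuals from state to cap incremental float drift
            for n in range(n1):
                acc = 0.0
                for k in range(m):
                    acc += W1[n, k] * (r1 * s0[k] + a1s[k])
                e1[n] = y1[n] - u1 - acc
            for n in range(n2):
                acc = 0.0
                for k in range(m):
                    acc += W2[n, k] * (r2 * s0[k] + a2s[k])
                e2[n] = y2[n] - u2 - acc

    if n_acc > 0:
        for n in range(n1):
            ghat1[n] /= n_acc
        for n in range(n2):
            ghat2[n] /= n_acc
        u_mean /= n_acc
        s2e_mean /= n_acc

    return (status, bad_cycle, idx, cyc_out, u_out, r_out, s2a_out, s2e_out,
            dev_out, var_a_out, cov_a_out, ghat1, ghat2, u_mean, s2e_mean)


@njit(cache=True)
def run_het(W1, W2, y1, y2, w1, w2, rstart, rend,
            n_cycles, burn_in, store_every, seed,
            r1_init, r2_init, s2a1_init, s2a2_init,
            ceiling1, ceiling2):
    """Gibbs sampler for a_ij = r_i s0 + r_ij s1 + a*_ij.

    ``rstart``/``rend`` are the regions' inclusive marker-index bounds.
    Storage layout mirrors run_hom, with per-region scalars and derived
    per-region var/cov draws added.
    """
    np.random.seed(seed)
    n1, n2 = W1.shape[0], W2.shape[0]
    m = W1.shape[1]
    ngroup = rstart.shape[0]

    sw1 = np.sum(w1)
    sw2 = np.sum(w2)
    logdet_d1 = -np.sum(np.log(w1))
    logdet_d2 = -np.sum(np.log(w2))
    wcss1 = np.empty(m)
    wcss2 = np.empty(m)
    for k in range(m):
        acc1 = 0.0
        for n in range(n1):
            acc1 += w1[n] * W1[n, k] * W1[n, k]
        wcss1[k] = acc1
        acc2 = 0.0
        for n in range(n2):
            acc2 += w2[n] * W2[n, k] * W2[n, k]
        wcss2[k] = acc2

    acc = 0.0
    for n in range(n1):
        acc += w1[n] * y1[n]
    u1 = acc / sw1
    acc = 0.0
    for n in range(n2):
        acc += w2[n] * y2[n]
    u2 = acc / sw2

    s0 = np.zeros(m)
    s1v = np.zeros(m)
    a1s = np.zeros(m)
    a2s = np.zeros(m)
    r1 = r1_init
    r2 = r2_init
    rj = np.zeros((ngroup, 2))
    for j in range(ngroup):
        rj[j, 0] = 0.1 * r1_init
        rj[j, 1] = 0.1 * r2_init
    s2r1 = max(0.01 * r1_init * r1_init, 1e-10)
    s2r2 = max(0.01 * r2_init * r2_init, 1e-10)
    s2a1 = s2a1_init
    s2a2 = s2a2_init
    acc = 0.0
    for n in range(n1):
        acc += w1[n] * (y1[n] - u1) ** 2
    s2e1 = 0.5 * acc / n1
    acc = 0.0
    for n in range(n2):
        acc += w2[n] * (y2[n] - u2) ** 2
    s2e2 = 0.5 * acc / n2

    e1 = np.empty(n1)
    e2 = np.empty(n2)
    for n in range(n1):
        e1[n] = y1[n] - u1
    for n in range(n2):
        e2[n] = y2[n] - u2

    n_store = n_cycles // store_every
    cyc_out = np.empty(n_store, dtype=np.int64)
    u_out = np.empty((n_store, 2))
    r_out = np.empty((n_store, 2))
    rj_out = np.empty((n_store, ngroup, 2))
    s2r_out = np.empty((n_store, 2))
    s2a_out = np.empty((n_store, 2))
    s2e_out = np.empty((n_store, 2))
    dev_out = np.empty(n_store)
    var_a_out = np.empty((n_store, ngroup, 2))
    cov_a_out = np.empty((n_store, ngroup))

    ghat1 = np.zeros(n1)
    ghat2 = np.zeros(n2)
    u_mean = np.zeros(2)
    s2e_mean = np.zeros(2)
    n_acc = 0

    x1 = np.empty(n1)
    x2 = np.empty(n2)

    status = 0
    bad_cycle = -1
    idx = 0
    for cycle in range(1, n_cycles + 1):
        acc = 0.0
        for n in range(n1):
            acc += w1[n] * (e1[n] + u1)
        mu = acc / sw1
        u1_new = mu + np.random.normal() * np.sqrt(s2e1 / sw1)
        shift = u1 - u1_new
        for n in range(n1):
            e1[n] += shift
        u1 = u1_new
        acc = 0.0
        for n in range(n2):
            acc += w2[n] * (e2[n] + u2)
        mu = acc / sw2
        u2_new = mu + np.random.normal() * np.sqrt(s2e2 / sw2)
        shift = u2 - u2_new
        for n in range(n2):
            e2[n] += shift
        u2 = u2_new

        for j in range(ngroup):
            r1j = rj[j, 0]
            r2j = rj[j, 1]
            for k in range(rstart[j], rend[j] + 1):
                dot1 = _wdot_col(W1, k, w1, e1)
                dot2 = _wdot_col(W2, k, w2, e2)

                # shared genome channel
                old = s0[k]
                prec = (1.0 + r1 * r1 * wcss1[k] / s2e1
                        + r2 * r2 * wcss2[k] / s2e2)
                rhs = (r1 * (dot1 + r1 * wcss1[k] * old) / s2e1
                       + r2 * (dot2 + r2 * wcss2[k] * old) / s2e2)
                new = rhs / prec + np.random.normal() / np.sqrt(prec)
                s0[k] = new
                delta = new - old
                if delta != 0.0:
                    _axpy_col(W1, k, -r1 * delta, e1)
                    _axpy_col(W2, k, -r2 * delta, e2)
                    dot1 -= r1 * wcss1[k] * delta
                    dot2 -= r2 * wcss2[k] * delta

                # region channel
                old = s1v[k]
                prec = (1.0 + r1j * r1j * wcss1[k] / s2e1
                        + r2j * r2j * wcss2[k] / s2e2)
                rhs = (r1j * (dot1 + r1j * wcss1[k] * old) / s2e1
                       + r2j * (dot2 + r2j * wcss2[k] * old) / s2e2)
                new = rhs / prec + np.random.normal() / np.sqrt(prec)
                s1v[k] = new
                delta = new - old
                if delta != 0.0:
                    _axpy_col(W1, k, -r1j * delta, e1)
                    _axpy_col(W2, k, -r2j * delta, e2)
                    dot1 -= r1j * wcss1[k] * delta
                    dot2 -= r2j * wcss2[k] * delta

                # residual SNP effects
                old = a1s[k]
                prec = 1.0 / s2a1 + wcss1[k] / s2e1
                rhs = (dot1 + wcss1[k] * old) / s2e1
                new = rhs / prec + np.random.normal() / np.sqrt(prec)
                a1s[k] = new
                delta = new - old
                if delta != 0.0:
                    _axpy_col(W1, k, -delta, e1)

                old = a2s[k]
                prec = 1.0 / s2a2 + wcss2[k] / s2e2
                rhs = (dot2 + wcss2[k] * old) / s2e2
                new = rhs / prec + np.random.normal() / np.sqrt(prec)
                a2s[k] = new
                delta = new - old
                if delta != 0.0:
                    _axpy_col(W2, k, -delta, e2)

        # global scalars (flat prior)
        for n in range(n1):
            acc = 0.0
            for k in range(m):
                acc += W1[n, k] * s0[k]
            x1[n] = acc
        xwx = 0.0
        xwe = 0.0
        for n in range(n1):
            xwx += w1[n] * x1[n] * x1[n]
            xwe += w1[n] * x1[n] * (e1[n] + r1 * x1[n])
        if xwx > 0.0:
            prec = xwx / s2e1
            new = xwe / s2e1 / prec + np.random.normal() / np.sqrt(prec)
            delta = new - r1
            r1 = new
            for n in range(n1):
                e1[n] -= x1[n] * delta
        for n in range(n2):
            acc = 0.0
            for k in range(m):
                acc += W2[n, k] * s0[k]
            x2[n] = acc
        xwx = 0.0
        xwe = 0.0
        for n in range(n2):
            xwx += w2[n] * x2[n] * x2[n]
            xwe += w2[n] * x2[n] * (e2[n] + r2 * x2[n])
        if xwx > 0.0:
            prec = xwx / s2e2
            new = xwe / s2e2 / prec + np.random.normal() / np.sqrt(prec)
            delta = new - r2
            r2 = new
            for n in range(n2):
                e2[n] -= x2[n] * delta

        # region scalars, N(0, sigma2_r_i) prior
        for j in range(ngroup):
            for n in range(n1):
                acc = 0.0
                for k in range(rstart[j], rend[j] + 1):
                    acc += W1[n, k] * s1v[k]
                x1[n] = acc
            xwx = 0.0
            xwe = 0.0
            for n in range(n1):
                xwx += w1[n] * x1[n] * x1[n]
                xwe += w1[n] * x1[n] * (e1[n] + rj[j, 0] * x1[n])
            prec = 1.0 / s2r1 + xwx / s2e1
            new = xwe / s2e1 / prec + np.random.normal() / np.sqrt(prec)
            delta = new - rj[j, 0]
            rj[j, 0] = new
            for n in range(n1):
                e1[n] -= x1[n] * delta

            for n in range(n2):
                acc = 0.0
                for k in range(rstart[j], rend[j] + 1):
                    acc += W2[n, k] * s1v[k]
                x2[n] = acc
            xwx = 0.0
            xwe = 0.0
            for n in range(n2):
                xwx += w2[n] * x2[n] * x2[n]
                xwe += w2[n] * x2[n] * (e2[n] + rj[j, 1] * x2[n])
            prec = 1.0 / s2r2 + xwx / s2e2
            new = xwe / s2e2 / prec + np.random.normal() / np.sqrt(prec)
            delta = new - rj[j, 1]
            rj[j, 1] = new
            for n in range(n2):
                e2[n] -= x2[n] * delta

        # group-rescaling moves, likelihood-invariant:
        # (r1, r2, s0) -> (t r1, t r2, s0 / t) with t^2 ~ sum s0^2 / chisq(m-2)
        if m > 4:
            ss = 0.0
            for k in range(m):
                ss += s0[k] * s0[k]
            t = np.sqrt(ss / np.random.chisquare(m - 2))
            for k in range(m):
                s0[k] /= t
            r1 *= t
            r2 *= t
        # (r_ij, sigma2_r_i, s1) -> (t r_ij, t^2 sigma2_r_i, s1 / t) with
        # t^2 ~ sum s1^2 / chisq(m - 4)
        if m > 6:
            ss = 0.0
            for k in range(m):
                ss += s1v[k] * s1v[k]
            t = np.sqrt(ss / np.random.chisquare(m - 4))
            for k in range(m):
                s1v[k] /= t
            for j in range(ngroup):
                rj[j, 0] *= t
                rj[j, 1] *= t
            s2r1 *= t * t
            s2r2 *= t * t

        # variances
        ss = 0.0
        for j in range(ngroup):
            ss += rj[j, 0] * rj[j, 0]
        s2r1 = _sample_variance_nb(ss, ngroup, ceiling1)
        ss = 0.0
        for j in range(ngroup):
            ss += rj[j, 1] * rj[j, 1]
        s2r2 = _sample_variance_nb(ss, ngroup, ceiling2)
        ss = 0.0
        for k in range(m):
            ss += a1s[k] * a1s[k]
        s2a1 = _sample_variance_nb(ss, m, ceiling1)
        ss = 0.0
        for k in range(m):
            ss += a2s[k] * a2s[k]
        s2a2 = _sample_variance_nb(ss, m, ceiling2)
        ss = 0.0
        for n in range(n1):
            ss += w1[n] * e1[n] * e1[n]
        s2e1 = _sample_variance_nb(ss, n1, ceiling1)
        ss = 0.0
        for n in range(n2):
            ss += w2[n] * e2[n] * e2[n]
        s2e2 = _sample_variance_nb(ss, n2, ceiling2)

        if (s2e1 >= ceiling1 or s2e2 >= ceiling2 or s2a1 >= ceiling1
                or s2a2 >= ceiling2 or r1 * r1 >= ceiling1
                or r2 * r2 >= ceiling2 or s2r1 >= ceiling1
                or s2r2 >= ceiling2):
            status = 1
            bad_cycle = cycle
            break

        dev = _deviance(n1, n2, w1, w2, e1, e2, s2e1, s2e2,
                        logdet_d1, logdet_d2)

        if cycle % store_every == 0:
            cyc_out[idx] = cycle
            u_out[idx, 0] = u1
            u_out[idx, 1] = u2
            r_out[idx, 0] = r1
            r_out[idx, 1] = r2
            s2r_out[idx, 0] = s2r1
            s2r_out[idx, 1] = s2r2
            s2a_out[idx, 0] = s2a1
            s2a_out[idx, 1] = s2a2
            s2e_out[idx, 0] = s2e1
            s2e_out[idx, 1] = s2e2
            dev_out[idx] = dev
            for j in range(ngroup):
                rj_out[idx, j, 0] = rj[j, 0]
                rj_out[idx, j, 1] = rj[j, 1]
                var_a_out[idx, j, 0] = r1 * r1 + rj[j, 0] * rj[j, 0] + s2a1
                var_a_out[idx, j, 1] = r2 * r2 + rj[j, 1] * rj[j, 1] + s2a2
                cov_a_out[idx, j] = r1 * r2 + rj[j, 0] * rj[j, 1]
            idx += 1

        if cycle > burn_in:
            for n in range(n1):
                ghat1[n] += y1[n] - u1 - e1[n]
            for n in range(n2):
                ghat2[n] += y2[n] - u2 - e2[n]
            u_mean[0] += u1
            u_mean[1] += u2
            s2e_mean[0] += s2e1
            s2e_mean[1] += s2e2
            n_acc += 1

        if cycle % _REFRESH == 0:
            for n in range(n1):
                acc = 0.0
                for j in range(ngroup):
                    for k in range(rstart[j], rend[j] + 1):
                        acc += W1[n, k] * (r1 * s0[k] + rj[j, 0] * s1v[k]
                                           + a1s[k])
                e1[n] = y1[n] - u1 - acc
            for n in range(n2):
                acc = 0.0
                for j in range(ngroup):
                    for k in range(rstart[j], rend[j] + 1):
                        acc += W2[n, k] * (r2 * s0[k] + rj[j, 1] * s1v[k]
                                           + a2s[k])
                e2[n] = y2[n] - u2 - acc

    if n_acc > 0:
        for n in range(n1):
            ghat1[n] /= n_acc
        for n in range(n2):
            ghat2[n] /= n_acc
        u_mean /= n_acc
        s2e_mean /= n_acc

    return (status, bad_cycle, idx, cyc_out, u_out, r_out, rj_out, s2r_out,
            s2a_out, s2e_out, dev_out, var_a_out, cov_a_out,
            ghat1, ghat2, u_mean, s2e_mean)
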