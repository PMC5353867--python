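"""Full conditional distributions of the hierarchical model, in plain
NumPy, plus a slow reference Gibbs sampler built from them.

The production samplers (numba kernels in :mod:`.kernels`) implement the
same conditionals with incremental residual updates; this module trades
speed for readability and is what the unit tests exercise against an
independent Metropolis oracle on toy problems.  See docs/derivations.md
for the algebra.

Notation (population i in {1, 2}, marker k, region j):

    y_i = u_i + W_i a_i + e_i,  e_in ~ N(0, d_in * sigma2_e_i)
    a_i  = r_i s0 + a*_i                      (homogeneous)
    a_ij = r_i s0 + r_ij s1 + a*_ij           (heterogeneous)

Priors: s0, s1 ~ N(0, I); a*_i ~ N(0, I sigma2_a*_i); r_i flat;
r_ij ~ N(0, sigma2_r_i); all variances flat on (0, ceiling].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cond_mean",
    "cond_regression_scalar",
    "cond_latent_entry",
    "sample_variance_flat",
    "reference_gibbs_hom",
]


def cond_mean(y_resid_plus_u: np.ndarray, w: np.ndarray, sigma2_e: float) -> tuple:
    """Conditional N(mean, var) of an overall mean u given everything else.

    ``y_resid_plus_u`` is y - W a (the residual with u added back);
    ``w`` = 1/d are the record precisions up to sigma2_e.
    """
    sw = np.sum(w)
    mean = np.sum(w * y_resid_plus_u) / sw
    return mean, sigma2_e / sw


def cond_regression_scalar(
    x: np.ndarray, e_plus: np.ndarray, w: np.ndarray, sigma2_e: float,
    prior_prec: float = 0.0,
) -> tuple:
    """Conditional N(mean, var) of a scalar coefficient b in e = x b + noise.

    ``e_plus`` is the residual with b's contribution added back
    (y - everything else).  With ``prior_prec`` = 0 the prior is flat; for
    the region scalars r_ij pass 1/sigma2_r_i.
    """
    xwx = np.sum(w * x * x)
    xwe = np.sum(w * x * e_plus)
    prec = prior_prec + xwx / sigma2_e
    if prec <= 0.0:
        raise ValueError("degenerate conditional: zero precision with flat prior")
    return xwe / sigma2_e / prec, 1.0 / prec


def cond_latent_entry(
    cols: tuple, scalars: tuple, e_plus: tuple, weights: tuple,
    sigma2_e: tuple, prior_prec: float = 1.0,
) -> tuple:
    """Conditional N(mean, var) of one entry of a shared latent vector
    (s0_k or s1_k), which both populations' likelihoods see through their
    scaling scalars.

    ``cols``: the two panels' centered genotype columns for marker k;
    ``scalars``: (r_1, r_2) or (r_1j, r_2j); ``e_plus``: residuals with
    this entry's contribution added back.
    """
    prec = prior_prec
    rhs = 0.0
    for x, r, ep, w, s2 in zip(cols, scalars, e_plus, weights, sigma2_e):
        prec += r * r * np.sum(w * x * x) / s2
        rhs += r * np.sum(w * x * ep) / s2
    return rhs / prec, 1.0 / prec


def sample_variance_flat(ss: float, k: int, ceiling: float, rng) -> float:
    """Draw sigma2 from p(sigma2) prop. to sigma2^(-k/2) exp(-ss/(2 sigma2))
    on (0, ceiling] — the conditional under a flat (bounded-uniform) prior
    with k Gaussian terms carrying sum of squares ``ss``.

    For k >= 3 this is ss / chisq(k - 2) (rejection against the ceiling);
    smaller k falls back to grid inversion of the truncated density.
    """
    if ss < 0:
        raise ValueError("negative sum of squares")
    if k >= 3 and ss > 0:
        for _ in range(100):
            v = ss / rng.chisquare(k - 2)
            if v <= ceiling:
                return float(v)
        return float(ceiling)
    # low-information case: inverse-CDF on a log-spaced grid
    lo = ceiling * 1e-14
    grid = np.exp(np.linspace(np.log(lo), np.log(ceiling), 512))
    logp = -0.5 * k * np.log(grid) - ss / (2.0 * grid) + np.log(grid)
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    u = rng.random() * cdf[-1]
    return float(grid[np.searchsorted(cdf, u)])


def reference_gibbs_hom(
    W1, W2, y1, y2, d1, d2, n_cycles, rng, ceiling=None, r_init=(0.1, 0.1),
):
    """Slow, recompute-everything Gibbs sampler for the homogeneous model.

    Residuals are rebuilt from scratch at every step (no incremental
    bookkeeping), so this is an implementation-independent cross-check of
    the production kernel at toy scale.  Returns a dict of traces.
    """
    W = (np.asarray(W1, float), np.asarray(W2, float))
    y = (np.asarray(y1, float), np.asarray(y2, float))
    w = (1.0 / np.asarray(d1, float), 1.0 / np.asarray(d2, float))
    m = W[0].shape[1]
    if ceiling is None:
        ceiling = 1e6 * max(np.var(y[0]), np.var(y[1]))

    u = np.array([np.average(y[0], weights=w[0]), np.average(y[1], weights=w[1])])
    s0 = np.zeros(m)
    a_star = np.zeros((m, 2))
    r = np.array(r_init, dtype=float)
    s2a = np.array([np.var(y[0]), np.var(y[1])]) / (2.0 * m)
    s2a = np.maximum(s2a, 1e-12)
    s2e = np.array([0.5 * np.var(y[0]), 0.5 * np.var(y[1])])

    def effects():
        return r[np.newaxis, :] * s0[:, np.newaxis] + a_star

    traces = {k: [] for k in ("u", "r", "sigma2_astar", "sigma2_e",
                              "var_a", "cov_a", "deviance")}
    for _ in range(n_cycles):
        a = effects()
        for i in range(2):
            resid_plus_u = y[i] - W[i] @ a[:, i]
            mean, var = cond_mean(resid_plus_u, w[i], s2e[i])
            u[i] = mean + rng.standard_normal() * np.sqrt(var)

        for k in range(m):
            a = effects()
            e = [y[i] - u[i] - W[i] @ a[:, i] for i in range(2)]
            cols = (W[0][:, k], W[1][:, k])
            e_plus = tuple(e[i] + r[i] * cols[i] * s0[k] for i in range(2))
            mean, var = cond_latent_entry(cols, tuple(r), e_plus, w, tuple(s2e))
            s0[k] = mean + rng.standard_normal() * np.sqrt(var)
            for i in range(2):
                a = effects()
                ei = y[i] - u[i] - W[i] @ a[:, i]
                mean, var = cond_regression_scalar(
                    cols[i], ei + cols[i] * a_star[k, i], w[i], s2e[i],
                    prior_prec=1.0 / s2a[i],
                )
                a_star[k, i] = mean + rng.standard_normal() * np.sqrt(var)

        for i in range(2):
            x = W[i] @ s0
            e = y[i] - u[i] - W[i] @ effects()[:, i]
            mean, var = cond_regression_scalar(x, e + x * r[i], w[i], s2e[i])
            r[i] = mean + rng.standard_normal() * np.sqrt(var)

        for i in range(2):
            s2a[i] = sample_variance_flat(
                float(np.sum(a_star[:, i] ** 2)), m, ceiling, rng
            )
        dev = 0.0
        for i in range(2):
            e = y[i] - u[i] - W[i] @ effects()[:, i]
            s2e[i] = sample_variance_flat(
                float(np.sum(w[i] * e * e)), len(e), ceiling, rng
            )
            dev += (len(e) * np.log(2.0 * np.pi * s2e[i])
                    - np.sum(np.log(w[i])) + np.sum(w[i] * e * e) / s2e[i])

        traces["u"].append(u.copy())
        traces["r"].append(r.copy())
        traces["sigma2_astar"].append(s2a.copy())
        traces["sigma2_e"].append(s2e.copy())
        traces["var_a"].append(r**2 + s2a)
        traces["cov_a"].append(r[0] * r[1])
        traces["deviance"].append(dev)
    return {k: np.asarray(v) for k, v in traces.items()}
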