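"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: the Gabor
response oracle rasterises filter and grating on a fine pixel grid and
integrates; the posterior oracle evaluates the generative model's
likelihood with direct scipy calls and explicit loops on tiny problems.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def raster_gabor_response(
    x0, y0, lam, theta_deg, phi_deg, delta, stim_theta_deg, stim_phase_deg,
    stim_period, contrast, u_dc, u_ac,
):
    """Pixel-grid quadrature of the Gabor/grating inner product, calibrated
    the same way as the analytic path: truncation at 4*delta, grid step
    min(lambda, lambda_s)/40, amplitude calibration from a dense phase scan
    at the preferred orientation/period and full contrast."""

    def raw_inner(s_theta, s_phase, s_period, c):
        step = min(lam, s_period) / 40.0
        half = 4.0 * delta
        g = np.arange(-half, half + 0.5 * step, step)
        X, Y = np.meshgrid(x0 + g, y0 + g, indexing="ij")
        env = np.exp(-(((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * delta**2)))
        th = np.deg2rad(theta_deg)
        carrier = np.cos(
            2.0 * np.pi * (np.sin(th) * (X - x0) - np.cos(th) * (Y - y0)) / lam
            - np.deg2rad(phi_deg)
        )
        vt = np.deg2rad(s_theta)
        grating = c * np.cos(
            2.0 * np.pi * (np.sin(vt) * X - np.cos(vt) * Y) / s_period
            - np.deg2rad(s_phase)
        )
        return float((env * carrier * grating).sum() * step * step)

    phases = np.arange(0.0, 360.0, 3.0)
    cal = np.array([raw_inner(theta_deg, p, lam, 1.0) for p in phases])
    amplitude = 0.5 * (cal.max() - cal.min())
    raw = raw_inner(stim_theta_deg, stim_phase_deg, stim_period, contrast)
    return u_dc + u_ac * raw / amplitude


def dense_posterior(rates, grid_means, grid_labels, sigma, u_th, kappa, prefactor, n_classes):
    """Brute-force class posterior for one rate vector (tiny problems only).

    Explicit product over neurons of the zero-rate point mass or the
    change-of-variables density, then a normalised sum per class.
    """
    rates = np.asarray(rates, dtype=float)
    lik = np.zeros(len(grid_means))
    for s, g in enumerate(np.asarray(grid_means, dtype=float)):
        p = 1.0
        for n, r in enumerate(rates):
            if r == 0.0:
                p *= stats.norm.cdf(u_th, loc=g[n], scale=sigma)
            else:
                u = u_th + (r / prefactor) ** (1.0 / kappa)
                drdu = prefactor * kappa * max(u - u_th, 0.0) ** (kappa - 1.0)
                if kappa == 1.0:
                    drdu = prefactor
                p *= stats.norm.pdf(u, loc=g[n], scale=sigma) / drdu
        lik[s] = p
    post = np.zeros(n_classes)
    for k in range(n_classes):
        post[k] = lik[np.asarray(grid_labels) == k].sum()
    total = post.sum()
    if total == 0:
        return np.full(n_classes, 1.0 / n_classes)
    return post / total


def ilc_posterior_direct(rates, grid_means, grid_labels, grid_orients, sigma, u_th,
                         kappa, prefactor, n_classes, sigma_theta):
    """Direct summation of the stimulus-jitter marginalisation."""
    # posterior over encoded grid stimuli
    lik = np.zeros(len(grid_means))
    for s, g in enumerate(np.asarray(grid_means, dtype=float)):
        p = 1.0
        for n, r in enumerate(np.asarray(rates, dtype=float)):
            if r == 0.0:
                p *= stats.norm.cdf(u_th, loc=g[n], scale=sigma)
            else:
                u = u_th + (r / prefactor) ** (1.0 / kappa)
                drdu = prefactor if kappa == 1.0 else prefactor * kappa * (u - u_th) ** (kappa - 1.0)
                p *= stats.norm.pdf(u, loc=g[n], scale=sigma) / drdu
        lik[s] = p
    p_enc = lik / lik.sum()
    orients = np.asarray(grid_orients, dtype=float)
    p_true = np.zeros(len(orients))
    for i, big_theta in enumerate(orients):
        acc = 0.0
        for j, th in enumerate(orients):
            d = th - big_theta
            kern = sum(
                np.exp(-0.5 * ((d + m * 180.0) / sigma_theta) ** 2) for m in range(-3, 4)
            )
            acc += p_enc[j] * kern
        p_true[i] = acc
    p_true /= p_true.sum()
    post = np.array([p_true[np.asarray(grid_labels) == k].sum() for k in range(n_classes)])
    return post / post.sum()
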