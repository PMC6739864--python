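"""Linear and optimal Bayesian decoders, and decoding performance measures.

The linear decoder is a multinomial logistic regression trained by
Barzilai-Borwein gradient descent on the (weakly L2-regularised) softmax
cross-entropy.  The optimal decoder inverts the generative model of the
responses: for each candidate (orientation, nuisance) grid stimulus the
likelihood of the observed rate vector mixes a point mass at zero rate
(the subthreshold probability) with the change-of-variables density of the
Gaussian membrane potential through the firing-rate nonlinearity; the class
posterior marginalises the nuisance grid.  All accumulation is in the log
domain.

Performance measures: fraction correct (FC), probabilistic fraction correct
(PFC, the geometric mean of the posterior mass on the true class), and a
Monte-Carlo mutual-information estimate I = H(class) + <log p(true | r)>
in bits.  ``predicted_linear_fc`` is the sparseness-scaled total-information
prediction (FC_opt - chance) * sparseness + chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, logsumexp

from .responses import FRNL, ResponseMatrix

__all__ = [
    "TrainOptions",
    "LinearDecoder",
    "train_linear_decoder",
    "decode_linear",
    "GenerativeModel",
    "optimal_posterior",
    "ilc_posterior",
    "PerformanceReport",
    "performance",
    "predicted_linear_fc",
]

_LOG_FLOOR = np.log(1e-300)


# ---------------------------------------------------------------------------
# linear decoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainOptions:
    max_iter: int = 400
    tol: float = 1e-8  # relative objective-change stopping tolerance
    l2: float = 1e-8  # weak ridge on weights (fixes the softmax gauge)
    standardize: bool = True


@dataclass
class LinearDecoder:
    """Trained multinomial logistic decoder.

    ``weights`` is K x (N+1); the last column is the bias.  Features are
    standardised with the stored train-set mean/scale before the linear map.
    """

    weights: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_iter: int = 0
    final_objective: float = np.nan
    converged: bool = True

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1] - 1


def _softmax_rows(z):
    z = z - z.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    return z


def _objective_grad(X, Y, W, b, l2):
    """Mean cross-entropy + 0.5*l2*||W||^2 and its gradient."""
    m = X.shape[0]
    Z = X @ W.T + b
    Z -= Z.max(axis=1, keepdims=True)
    logZ = logsumexp(Z, axis=1)
    obj = float(-(Z[np.arange(m), Y] - logZ).mean() + 0.5 * l2 * (W**2).sum())
    P = np.exp(Z - logZ[:, None])
    P[np.arange(m), Y] -= 1.0
    P /= m
    gW = P.T @ X + l2 * W
    gb = P.sum(axis=0)
    return obj, gW.astype(W.dtype, copy=False), gb.astype(b.dtype, copy=False)


def train_linear_decoder(
    train: ResponseMatrix | np.ndarray,
    n_classes: int | None = None,
    labels=None,
    opts: TrainOptions = TrainOptions(),
) -> LinearDecoder:
    """Fit the multinomial logistic decoder by Barzilai-Borwein descent.

    The objective is convex; BB steps use the spectral step length
    (dw.dg)/(dg.dg), safeguarded into [1e-8, 1e8], starting from a
    1/L-like step for the standardised design.  Non-convergence within
    ``opts.max_iter`` is flagged in the metadata, not raised.
    """
    if isinstance(train, ResponseMatrix):
        X, y = train.values, train.labels
    else:
        X, y = np.asarray(train), np.asarray(labels)
    y = np.asarray(y, dtype=int)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    counts = np.bincount(y, minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError("every class needs at least one training row")

    dtype = X.dtype if X.dtype in (np.float32, np.float64) else np.float64
    X = np.asarray(X, dtype=dtype)
    if opts.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0).astype(dtype)
        Xs = (X - mu) / sd
    else:
        mu = np.zeros(X.shape[1], dtype=dtype)
        sd = np.ones(X.shape[1], dtype=dtype)
        Xs = X

    K, D = n_classes, X.shape[1]
    W = np.zeros((K, D), dtype=dtype)
    b = np.zeros(K, dtype=dtype)
    obj, gW, gb = _objective_grad(Xs, y, W, b, opts.l2)
    step = 4.0 / max(D, 1)  # ~1/L for standardised features (Hessian <= X'X/(2m))
    n_iter = 0
    converged = False
    for n_iter in range(1, opts.max_iter + 1):
        W_new = W - step * gW
        b_new = b - step * gb
        obj_new, gW_new, gb_new = _objective_grad(Xs, y, W_new, b_new, opts.l2)
        dW, db = W_new - W, b_new - b
        dgW, dgb = gW_new - gW, gb_new - gb
        denom = float((dgW * dgW).sum() + (dgb * dgb).sum())
        numer = float((dW * dgW).sum() + (db * dgb).sum())
        step = numer / denom if denom > 0 and numer > 0 else step
        step = float(np.clip(step, 1e-8, 1e8))
        rel = abs(obj - obj_new) / max(1.0, abs(obj))
        W, b, gW, gb = W_new, b_new, gW_new, gb_new
        if rel < opts.tol and n_iter > 2:
            obj = obj_new
            converged = True
            break
        obj = obj_new
    weights = np.concatenate([W, b[:, None]], axis=1)
    return LinearDecoder(
        weights=weights,
        feature_mean=mu,
        feature_scale=sd,
        n_iter=n_iter,
        final_objective=obj,
        converged=converged,
    )


def decode_linear(dec: LinearDecoder, test: ResponseMatrix | np.ndarray):
    """Softmax class probabilities and hard labels (argmax, lowest-index ties).

    Returns ``(probabilities, labels)`` with probability rows summing to 1.
    """
    X = test.values if isinstance(test, ResponseMatrix) else np.asarray(test)
    if X.shape[1] != dec.n_features:
        raise ValueError(
            f"feature count mismatch: decoder expects {dec.n_features}, got {X.shape[1]}"
        )
    Xs = (X - dec.feature_mean) / dec.feature_scale
    Z = Xs @ dec.weights[:, :-1].T + dec.weights[:, -1]
    P = _softmax_rows(np.asarray(Z, dtype=np.float64))
    return P, P.argmax(axis=1)


# ---------------------------------------------------------------------------
# optimal Bayesian decoder
# ---------------------------------------------------------------------------

@dataclass
class GenerativeModel:
    """Everything the ideal observer knows about the response process.

    grid_means: (S, N) noise-free mean potentials on the latent stimulus grid
        (all within-class orientation bins x nuisance grid points).
    grid_labels: (S,) class index of each grid stimulus.
    sigma: membrane-potential noise SD (scalar or per-cell).
    frnl: the firing-rate nonlinearity in force.
    grid_orientations: optional (S,) orientation (deg) of each grid stimulus,
        needed for the information-limiting-correlation variant.
    log_prior: optional (S,) log prior over grid stimuli (default uniform).
    """

    grid_means: np.ndarray
    grid_labels: np.ndarray
    sigma: float | np.ndarray
    frnl: FRNL
    grid_orientations: np.ndarray | None = None
    log_prior: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return int(np.max(self.grid_labels)) + 1 if len(self.grid_labels) else 0


def _stimulus_log_likelihood(rates, model: GenerativeModel, batch=2048):
    """log p(r_m | grid stimulus s) up to per-row constants; (M, S)."""
    if np.any(np.asarray(model.frnl.exponent) < 1.0):
        raise ValueError("optimal decoder requires kappa >= 1")
    R = rates.values if isinstance(rates, ResponseMatrix) else np.asarray(rates)
    R = np.asarray(R, dtype=np.float64)
    G = np.asarray(model.grid_means, dtype=np.float64)  # (S, N)
    sig = np.broadcast_to(np.asarray(model.sigma, dtype=np.float64), (G.shape[1],))
    uth = np.broadcast_to(np.asarray(model.frnl.threshold, dtype=np.float64), (G.shape[1],))
    kap = np.broadcast_to(np.asarray(model.frnl.exponent, dtype=np.float64), (G.shape[1],))
    phi = np.broadcast_to(np.asarray(model.frnl.prefactor, dtype=np.float64), (G.shape[1],))

    # subthreshold point mass: log P(u < u_th | s) per (s, n)
    L0 = log_ndtr((uth[None, :] - G) / sig[None, :])  # (S, N)
    Gw = G / sig[None, :] ** 2
    Gsq = (G**2) / sig[None, :] ** 2

    M = R.shape[0]
    out = np.empty((M, G.shape[0]), dtype=np.float64)
    for lo in range(0, M, batch):
        hi = min(lo + batch, M)
        r = R[lo:hi]
        Z = (r > 0).astype(np.float64)
        # invert the FRNL on the positive entries
        with np.errstate(divide="ignore"):
            u = uth[None, :] + (r / phi[None, :]) ** (1.0 / kap[None, :])
        u = np.where(Z > 0, u, 0.0)
        # sum over positive n of -(u - G)^2 / (2 sigma^2), row constants dropped
        quad = (u * Z) @ Gw.T - 0.5 * (Z @ Gsq.T)
        out[lo:hi] = quad + (1.0 - Z) @ L0.T
    return out


def _class_log_posterior(loglik, model: GenerativeModel):
    lp = loglik if model.log_prior is None else loglik + model.log_prior[None, :]
    K = model.n_classes
    cols = [np.flatnonzero(model.grid_labels == k) for k in range(K)]
    logpost = np.column_stack([logsumexp(lp[:, c], axis=1) for c in cols])
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return logpost


def optimal_posterior(rates, model: GenerativeModel) -> np.ndarray:
    """Posterior over the K classes for each rate-vector row; rows sum to 1.

    With zero neurons (empty grid_means second axis) the prior is returned.
    """
    R = rates.values if isinstance(rates, ResponseMatrix) else np.atleast_2d(rates)
    if model.grid_means.shape[1] == 0 or R.shape[1] == 0:
        K = model.n_classes
        lp = np.zeros((R.shape[0], len(model.grid_labels)))
        return np.exp(_class_log_posterior(lp, model))
    loglik = _stimulus_log_likelihood(R, model)
    return np.exp(_class_log_posterior(loglik, model))


def _wrapped_normal_kernel(theta, sigma_theta, period=180.0, n_wraps=3):
    """kernel[i, j] ∝ wrapped-normal density of theta_i given center theta_j."""
    d = theta[:, None] - theta[None, :]
    k = np.zeros_like(d)
    for m in range(-n_wraps, n_wraps + 1):
        k += np.exp(-0.5 * ((d + m * period) / sigma_theta) ** 2)
    return k


def ilc_posterior(rates, model: GenerativeModel, sigma_theta: float) -> np.ndarray:
    """Posterior over the *true* orientation class under stimulus-jitter ILC.

    The encoded orientation is modelled as a (wrapped) normal draw of width
    ``sigma_theta`` around the true orientation; the posterior over encoded
    grid stimuli is mixed through that kernel and re-aggregated into classes.
    Reduces to :func:`optimal_posterior` as sigma_theta -> 0.
    """
    if sigma_theta < 0:
        raise ValueError("sigma_theta must be non-negative")
    if model.grid_orientations is None:
        raise ValueError("model.grid_orientations required for the ILC posterior")
    if sigma_theta == 0.0:
        return optimal_posterior(rates, model)
    R = rates.values if isinstance(rates, ResponseMatrix) else np.atleast_2d(rates)
    loglik = _stimulus_log_likelihood(R, model)
    lp = loglik if model.log_prior is None else loglik + model.log_prior[None, :]
    lp -= logsumexp(lp, axis=1, keepdims=True)
    p_stim = np.exp(lp)  # (M, S) posterior over encoded grid stimuli

    theta = np.asarray(model.grid_orientations, dtype=np.float64)
    kern = _wrapped_normal_kernel(theta, float(sigma_theta))
    # p(True grid point) ∝ sum_s p(s | r) * p(theta_s | Theta)
    p_true = p_stim @ kern
    p_true /= p_true.sum(axis=1, keepdims=True)

    K = model.n_classes
    post = np.zeros((p_true.shape[0], K))
    for k in range(K):
        post[:, k] = p_true[:, model.grid_labels == k].sum(axis=1)
    post /= post.sum(axis=1, keepdims=True)
    return post


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceReport:
    fraction_correct: float
    pfc: float | None = None  # probabilistic fraction correct
    mutual_information_bits: float | None = None
    n_trials: int = 0
    n_floored: int = 0  # rows where the true-class posterior hit the log floor
    circular_error_deg: float | None = None  # mean circular class-center error


def _circular_class_error(hard, labels, n_classes, period):
    step = period / n_classes
    d = np.abs(hard - labels) * step
    return float(np.mean(np.minimum(d, period - d)))


def performance(
    predictions, labels, n_classes: int | None = None, class_period_deg: float | None = None
) -> PerformanceReport:
    """Score hard labels (1-D) or posteriors (2-D, rows summing to 1).

    For posteriors: FC uses the argmax (lowest-index ties), PFC is the
    geometric mean of the true-class posterior (log floored at 1e-300 and
    the flooring counted), and the mutual-information estimate is
    log2 K + mean log2 p(true | r) bits — the Monte-Carlo identity that
    makes log PFC an estimate of the negative conditional entropy.
    With ``class_period_deg`` (180 for orientation classes) the mean
    circular distance between decoded and true class centers is added.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("need at least one trial")
    preds = np.asarray(predictions)
    if preds.ndim == 1:
        fc = float(np.mean(preds == labels))
        circ = None
        if class_period_deg is not None:
            K = n_classes if n_classes is not None else int(max(preds.max(), labels.max())) + 1
            circ = _circular_class_error(preds, labels, K, class_period_deg)
        return PerformanceReport(fc, n_trials=labels.size, circular_error_deg=circ)
    K = preds.shape[1] if n_classes is None else n_classes
    hard = preds.argmax(axis=1)
    fc = float(np.mean(hard == labels))
    p_true = preds[np.arange(len(labels)), labels]
    logs = np.log(np.maximum(p_true, 0.0), where=p_true > 0, out=np.full(len(labels), _LOG_FLOOR))
    floored = int(np.sum(logs <= _LOG_FLOOR))
    logs = np.maximum(logs, _LOG_FLOOR)
    mean_log = float(logs.mean())
    pfc = float(np.exp(mean_log))
    mi = float(np.log2(K) + mean_log / np.log(2.0))
    circ = (
        _circular_class_error(hard, labels, K, class_period_deg)
        if class_period_deg is not None
        else None
    )
    return PerformanceReport(fc, pfc, mi, labels.size, floored, circ)


def predicted_linear_fc(fc_opt, sparseness, chance):
    """Sparseness-scaled prediction (FC_opt - chance) * sparseness + chance."""
    fc_opt = np.asarray(fc_opt, dtype=float)
    sp = np.asarray(sparseness, dtype=float)
    return (fc_opt - chance) * sp + chance
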