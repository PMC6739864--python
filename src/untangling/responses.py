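"""Stochastic membrane potentials, the firing-rate nonlinearity, sparseness.

Membrane potentials are the noise-free filter responses plus zero-mean
Gaussian noise, sampled i.i.d. per 20 ms time bin (each stimulus row of a
response matrix is one such snapshot).  Optional uniform correlations
Sigma_ij = rho * sigma_i * sigma_j are realised with a shared latent factor.

Firing rates follow the threshold-power-law nonlinearity
r(u) = Phi * max(u - u_th, 0)^kappa; sparseness is the fraction of
exactly-zero rate entries across all (stimulus, neuron) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .util import as_rng

__all__ = [
    "NoiseModel",
    "FRNL",
    "ResponseMatrix",
    "sample_membrane_potentials",
    "apply_frnl",
    "sparseness",
    "activity_sparseness",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian membrane-potential noise.

    sigma: noise SD in mV, a scalar or per-cell array.
    rho:   uniform off-diagonal correlation in [0, 1).
    bin_width_ms: nominal width of the i.i.d. sampling bin (bookkeeping only;
        every response-matrix row is one bin).
    """

    sigma: float | np.ndarray = 3.0
    rho: float = 0.0
    bin_width_ms: float = 20.0

    def __post_init__(self):
        sig = np.asarray(self.sigma, dtype=float)
        if np.any(sig < 0):
            raise ValueError("sigma must be non-negative")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1) for a PSD covariance")


@dataclass(frozen=True)
class FRNL:
    """Threshold-power-law firing-rate nonlinearity r = Phi*(u - u_th)_+^kappa.

    Fields may be scalars or per-cell arrays (heterogeneous populations).
    """

    threshold: float | np.ndarray  # mV
    exponent: float | np.ndarray = 1.0  # kappa, dimensionless >= 1
    prefactor: float | np.ndarray = 16.7  # Phi, Hz/mV^kappa

    def __post_init__(self):
        if np.any(np.asarray(self.exponent, dtype=float) < 1.0):
            raise ValueError("exponent kappa must be >= 1")
        if np.any(np.asarray(self.prefactor, dtype=float) <= 0.0):
            raise ValueError("prefactor Phi must be positive")


@dataclass
class ResponseMatrix:
    """Population responses with per-row stimulus bookkeeping.

    values: (M, N) array — mV for membrane potentials, Hz for firing rates.
    labels: (M,) int class indices in 0..K-1.
    stimuli: DataFrame (M rows) with the stimulus parameters of each row.
    """

    values: np.ndarray
    labels: np.ndarray
    stimuli: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (stimuli x neurons)")
        if len(self.labels) != len(self.values):
            raise ValueError("labels length must match number of rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def save(self, path_prefix: str):
        """Persist as <prefix>.npy plus a <prefix>.json sidecar."""
        np.save(str(path_prefix) + ".npy", self.values)
        side = {"labels": self.labels.tolist()}
        if self.stimuli is not None:
            side["stimuli"] = self.stimuli.to_dict(orient="list")
        with open(str(path_prefix) + ".json", "w") as fh:
            json.dump(side, fh)

    @classmethod
    def load(cls, path_prefix: str) -> "ResponseMatrix":
        values = np.load(str(path_prefix) + ".npy")
        with open(str(path_prefix) + ".json") as fh:
            side = json.load(fh)
        stim = pd.DataFrame(side["stimuli"]) if "stimuli" in side else None
        return cls(values, np.asarray(side["labels"]), stim)

    def to_csv(self, path):
        """CSV export for small fixtures (stimuli + label + response columns)."""
        df = self.stimuli.copy() if self.stimuli is not None else pd.DataFrame(index=range(self.n_rows))
        df["label"] = self.labels
        for j in range(self.n_cells):
            df[f"cell{j}"] = self.values[:, j]
        df.to_csv(path, index=False)


def sample_membrane_potentials(
    means: np.ndarray, noise: NoiseModel, rng, labels=None, stimuli=None, dtype=None
) -> ResponseMatrix:
    """Add one i.i.d. Gaussian noise draw per row of ``means``.

    With rho > 0 the draw is from the uniform-correlation multivariate
    normal Sigma_ij = rho*sigma_i*sigma_j (i != j), realised as
    sqrt(rho)*shared + sqrt(1-rho)*private.
    """
    means = np.asarray(means)
    rng = as_rng(rng)
    if dtype is None:
        dtype = means.dtype
    sig = np.asarray(noise.sigma, dtype=dtype)
    z = rng.standard_normal(means.shape).astype(dtype, copy=False)
    if noise.rho > 0.0:
        shared = rng.standard_normal((means.shape[0], 1)).astype(dtype, copy=False)
        z = np.sqrt(1.0 - noise.rho) * z + np.sqrt(noise.rho) * shared
    u = means + sig * z
    if labels is None:
        labels = np.zeros(means.shape[0], dtype=int)
    return ResponseMatrix(u.astype(dtype, copy=False), labels, stimuli)


def apply_frnl(u, frnl: FRNL):
    """Elementwise firing rate Phi * max(u - u_th, 0)^kappa (Hz).

    Accepts a raw array or a ResponseMatrix (returning a new ResponseMatrix).
    """
    if isinstance(u, ResponseMatrix):
        return ResponseMatrix(apply_frnl(u.values, frnl), u.labels, u.stimuli)
    u = np.asarray(u)
    drive = np.maximum(u - np.asarray(frnl.threshold, dtype=u.dtype), 0.0)
    kappa = np.asarray(frnl.exponent, dtype=u.dtype)
    if np.all(kappa == 1.0):
        out = drive
    else:
        out = drive**kappa
    return np.asarray(frnl.prefactor, dtype=u.dtype) * out


def sparseness(rates) -> float:
    """Fraction of exactly-zero entries across all (stimulus, neuron) pairs."""
    values = rates.values if isinstance(rates, ResponseMatrix) else np.asarray(rates)
    if values.size == 0:
        raise ValueError("empty response matrix")
    if np.any(values < 0):
        raise ValueError("firing rates must be non-negative")
    return float(np.mean(values == 0.0))


def activity_sparseness(rates) -> float:
    """Population (Treves-Rolls) activity sparseness, averaged over stimuli.

    Per stimulus, a = (mean r)^2 / (mean r^2); sparseness = (1 - a)/(1 - 1/N).
    A fully silent population contributes 0 (no activity to be sparse about).
    Unlike the zero fraction this measure also counts weakly-driven cells as
    inactive, which is what makes it track linear decodability on the rising
    flank of a threshold sweep.
    """
    values = rates.values if isinstance(rates, ResponseMatrix) else np.asarray(rates)
    if values.size == 0:
        raise ValueError("empty response matrix")
    if np.any(values < 0):
        raise ValueError("firing rates must be non-negative")
    v = np.asarray(values, dtype=np.float64)
    m1 = v.mean(axis=1)
    m2 = (v**2).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(m2 > 0, m1**2 / np.maximum(m2, 1e-300), 1.0)
    n = v.shape[1]
    if n < 2:
        raise ValueError("activity sparseness needs at least 2 neurons")
    return float(np.mean((1.0 - a) / (1.0 - 1.0 / n)))
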