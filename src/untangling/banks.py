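"""Stimulus banks: labelled grids over orientation and nuisance parameters.

The decoded variable (orientation by default) is partitioned into K classes;
within each class M_theta grid bins represent within-class uncertainty.
Each variable nuisance parameter contributes a grid dimension; non-uniform
priors (lognormal spatial period, beta contrast) are laid out with the
distorted-grid (inverse-CDF) construction so that grid nodes carry equal
probability mass.  Train and test banks share the stimulus grid and differ
only in the membrane-potential noise (M_rep vs M_rep_test independent
repetitions per grid node).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .filters import PopulationSpec, mean_response_matrix
from .responses import NoiseModel, ResponseMatrix, sample_membrane_potentials
from .util import as_rng

__all__ = ["Nuisance", "BankSpec", "stimulus_grid", "build_bank", "PERIOD_LOGNORM", "CONTRAST_BETA"]

#: reference nuisance distributions (natural-statistics fits)
PERIOD_LOGNORM = dict(mu=0.95, sigma=0.55)
CONTRAST_BETA = dict(a=2.4, b=3.6)


@dataclass(frozen=True)
class Nuisance:
    """Mode of one nuisance parameter: fixed at a value, or variable over a
    grid of ``bins`` nodes drawn from its prior by inverse-CDF."""

    variable: bool
    value: float = 0.0  # used when fixed
    bins: int = 1  # grid size when variable

    @staticmethod
    def fixed(value: float) -> "Nuisance":
        return Nuisance(False, value=value)

    @staticmethod
    def var(bins: int) -> "Nuisance":
        return Nuisance(True, bins=bins)


@dataclass(frozen=True)
class BankSpec:
    """Stimulus-bank layout.

    Defaults reproduce the reference phase-nuisance set: K=10 orientation
    classes x M_theta=10 within-class bins x M_phi=50 phases x M_rep=20
    noise repetitions = 10^5 training rows, with the spatial period fixed at
    3 deg and the contrast at 0.5; the test bank uses M_rep_test=50.
    """

    n_classes: int = 10
    m_theta: int = 10
    m_rep: int = 20
    m_rep_test: int = 50
    phase: Nuisance = Nuisance.var(50)
    spatial_period: Nuisance = Nuisance.fixed(3.0)
    contrast: Nuisance = Nuisance.fixed(0.5)
    period_mu: float = PERIOD_LOGNORM["mu"]
    period_sigma: float = PERIOD_LOGNORM["sigma"]
    contrast_a: float = CONTRAST_BETA["a"]
    contrast_b: float = CONTRAST_BETA["b"]
    target: str = "orientation"  # decoded variable
    m_orientation: int = 8  # orientation nuisance bins when target != orientation

    def __post_init__(self):
        if self.n_classes < 2 or self.m_theta < 1:
            raise ValueError("need K >= 2 classes and M_theta >= 1")
        if self.period_sigma <= 0 or self.contrast_a <= 0 or self.contrast_b <= 0:
            raise ValueError("degenerate nuisance distribution parameters")

    @property
    def n_train(self) -> int:
        return len(stimulus_grid(self)) * self.m_rep

    @property
    def n_test(self) -> int:
        return len(stimulus_grid(self)) * self.m_rep_test


def _centered(n: int) -> np.ndarray:
    return (np.arange(n) + 0.5) / n


def _period_dist(spec: BankSpec):
    return stats.lognorm(s=spec.period_sigma, scale=np.exp(spec.period_mu))


def _contrast_dist(spec: BankSpec):
    return stats.beta(spec.contrast_a, spec.contrast_b)


def _nuisance_grid(nuis: Nuisance, dist=None, circular_span=None):
    if not nuis.variable:
        return np.array([nuis.value])
    q = _centered(nuis.bins)
    if circular_span is not None:  # uniform circular parameter
        return circular_span * q
    return dist.ppf(q)


def _target_grid(spec: BankSpec):
    """Values and labels of the decoded parameter: K equal-probability-mass
    classes, m_theta within-class bins per class (class = quantile bin)."""
    n = spec.n_classes * spec.m_theta
    q = _centered(n)
    labels = np.repeat(np.arange(spec.n_classes), spec.m_theta)
    if spec.target == "orientation":
        return 180.0 * q, labels
    if spec.target == "spatial_period":
        return _period_dist(spec).ppf(q), labels
    if spec.target == "contrast":
        return _contrast_dist(spec).ppf(q), labels
    raise ValueError(f"unknown decode target {spec.target!r}")


def stimulus_grid(spec: BankSpec) -> pd.DataFrame:
    """The deterministic labelled stimulus grid (one row per grid node).

    Columns: orientation, phase, spatial_period, contrast, label.
    """
    tvals, tlabels = _target_grid(spec)

    if spec.target == "orientation":
        orient = (tvals, tlabels)
        phase = (_nuisance_grid(spec.phase, circular_span=360.0), None)
        period = (_nuisance_grid(spec.spatial_period, _period_dist(spec)), None)
        contrast = (_nuisance_grid(spec.contrast, _contrast_dist(spec)), None)
    else:
        # decoding a nuisance feature: orientation becomes a uniform nuisance
        orient = (_nuisance_grid(Nuisance.var(spec.m_orientation), circular_span=180.0), None)
        phase = (_nuisance_grid(spec.phase, circular_span=360.0), None)
        if spec.target == "spatial_period":
            period = (tvals, tlabels)
            contrast = (_nuisance_grid(spec.contrast, _contrast_dist(spec)), None)
        else:
            period = (_nuisance_grid(spec.spatial_period, _period_dist(spec)), None)
            contrast = (tvals, tlabels)

    cols = {"orientation": orient, "phase": phase, "spatial_period": period, "contrast": contrast}
    names = list(cols)
    arrays = [cols[k][0] for k in names]
    mesh = np.meshgrid(*arrays, indexing="ij")
    df = pd.DataFrame({k: m.ravel() for k, m in zip(names, mesh)})
    for k in names:
        if cols[k][1] is not None:
            lbl_mesh = np.meshgrid(
                *[cols[j][1] if j == k else np.zeros(len(cols[j][0]), dtype=int) for j in names],
                indexing="ij",
            )
            df["label"] = sum(lbl_mesh).ravel()
    return df


def build_bank(
    spec: BankSpec,
    pop: PopulationSpec,
    noise: NoiseModel,
    rng,
    dtype=np.float64,
    ilc_sigma_theta: float | None = None,
):
    """Generate the (train, test) membrane-potential banks.

    Returns ``(train, test, grid, grid_means)`` where train/test are
    :class:`ResponseMatrix` of membrane potentials with independent noise
    and grid_means is the (S, N) noise-free mean matrix of the grid — the
    quantity the ideal observer needs.

    With ``ilc_sigma_theta`` set, each repetition's encoded orientation is
    jittered with a wrapped normal of that width around the grid value
    (information-limiting correlations as stimulus jitter); grid_means stays
    un-jittered, matching the labels.
    """
    rng = as_rng(rng)
    grid = stimulus_grid(spec)
    means = mean_response_matrix(pop, grid, dtype=dtype)
    out = []
    for m_rep in (spec.m_rep, spec.m_rep_test):
        reps = pd.concat([grid] * m_rep, ignore_index=True)
        labels = np.tile(grid["label"].to_numpy(int), m_rep)
        if ilc_sigma_theta:
            jitter = reps.copy()
            jitter["orientation"] = np.mod(
                jitter["orientation"].to_numpy()
                + rng.normal(0.0, ilc_sigma_theta, size=len(jitter)),
                180.0,
            )
            rep_means = mean_response_matrix(pop, jitter, dtype=dtype)
            reps = jitter  # record the encoded (jittered) orientations
        else:
            rep_means = np.tile(means, (m_rep, 1))
        out.append(sample_membrane_potentials(rep_means, noise, rng, labels, reps, dtype=dtype))
    train, test = out
    return train, test, grid, means
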