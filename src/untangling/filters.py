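"""Grating stimuli, receptive-field filters, and their noise-free responses.

The encoding population consists of model neurons whose mean membrane
potential to a full-field sine grating is the linear response of a
receptive-field filter, affinely calibrated so that ``u_dc`` is the
phase-averaged baseline and ``u_ac`` the modulation amplitude at the
preferred orientation and spatial period at 100% contrast.

Three receptive-field families are supported:

* ``"V1"`` -- circular Gabor filters (simple cells).  The response to an
  infinite grating has a closed form: with filter wave vector k_f and
  stimulus wave vector k_s (magnitudes 2*pi/lambda and 2*pi/lambda_s,
  directions set by the preferred and stimulus orientations), the Gaussian
  envelope of width delta turns the product of the two carrier waves into
  two terms attenuated by exp(-delta^2 |k_f -+ k_s|^2 / 2):

      u = u_dc + c * u_ac * [ cos(psi + phi - phi_s) * E_minus
                            + cos(psi - phi - phi_s) * E_plus ]

  where psi = k_s . (x, y) is the location phase of the stimulus at the
  filter center, phi the filter phase, phi_s the stimulus phase.  For equal
  periods E_-+ = exp[-(2 pi delta / lambda)^2 (1 -+ cos(theta - vartheta))].
  The counter-rotating (E_plus) term is below 1e-7 of u_ac at the default
  delta = 2 deg, lambda = 3 deg.  The unequal-period form is the same
  Gaussian integral evaluated with the two wave vectors at their own
  magnitudes; it is validated against a pixel-grid quadrature oracle in the
  test suite.

* ``"retina"`` -- pixel-like point samplers: the grating value at the filter
  center, with a per-neuron gain calibrated so the noise-free response
  variance over a reference stimulus ensemble matches the corresponding V1
  neuron.

* ``"LGN"`` -- difference-of-Gaussians (center-surround) filters, modelled
  as the difference of two unmodulated Gaussian envelopes (center SD
  1.5 deg, surround SD 4 deg, balanced), calibrated like the retina model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np
import pandas as pd

from .util import TWO_PI, as_rng, rad, wrap_orientation, wrap_phase

__all__ = [
    "Stimulus",
    "GaborFilter",
    "PopulationSpec",
    "mean_response",
    "mean_response_matrix",
    "make_population",
]

#: default center-surround envelope SDs (degrees of visual angle)
LGN_CENTER_SD = 1.5
LGN_SURROUND_SD = 4.0


@dataclass(frozen=True)
class Stimulus:
    """A static full-field sine grating.

    Angles are stored in their principal ranges (orientation in [0, 180),
    phase in [0, 360)); contrast is clipped to [0, 1].
    """

    orientation: float  # deg
    phase: float  # deg
    spatial_period: float  # deg of visual angle
    contrast: float  # dimensionless

    def __post_init__(self):
        if not self.spatial_period > 0:
            raise ValueError("spatial_period must be positive")
        # a grating at orientation v+180 with phase p is the same grating as
        # (v, -p): folding into [0, 180) must negate the phase
        o = float(np.mod(self.orientation, 360.0))
        p = float(self.phase)
        if o >= 180.0:
            o -= 180.0
            p = -p
        object.__setattr__(self, "orientation", o)
        object.__setattr__(self, "phase", float(wrap_phase(p)))
        object.__setattr__(self, "contrast", float(np.clip(self.contrast, 0.0, 1.0)))


@dataclass(frozen=True)
class GaborFilter:
    """A circular Gabor receptive field (six geometric parameters)."""

    x: float  # deg, center abscissa
    y: float  # deg, center ordinate
    spatial_period: float  # deg, carrier period lambda
    preferred_orientation: float  # deg in [0, 180)
    filter_phase: float  # deg in [0, 360), phase offset relative to center
    envelope_width: float  # deg, Gaussian envelope SD delta

    def __post_init__(self):
        if not self.spatial_period > 0:
            raise ValueError("spatial_period must be positive")
        if not self.envelope_width > 0:
            raise ValueError("envelope_width must be positive")
        object.__setattr__(
            self, "preferred_orientation", float(wrap_orientation(self.preferred_orientation))
        )
        object.__setattr__(self, "filter_phase", float(wrap_phase(self.filter_phase)))

    @property
    def location_phase_coeff(self):
        """The location phase psi is 2*pi*(sin v * x - cos v * y)/lambda_s for
        stimulus orientation v; this helper returns (x, y) for convenience."""
        return (self.x, self.y)


@dataclass
class PopulationSpec:
    """A calibrated ensemble of receptive-field filters.

    Per-cell geometry is stored as arrays of length ``n``.  For the retina
    and LGN variants ``gain`` holds the per-neuron affine calibration factor
    that equates the noise-free response variance (over the reference
    stimulus ensemble used at construction) with the matched V1 neuron.
    """

    kind: str  # "V1" | "retina" | "LGN"
    x: np.ndarray
    y: np.ndarray
    spatial_period: np.ndarray  # carrier period per cell (V1)
    preferred_orientation: np.ndarray
    filter_phase: np.ndarray
    envelope_width: np.ndarray
    u_dc: float  # mV
    u_ac: float  # mV
    gain: np.ndarray | None = None  # retina / LGN calibration
    center_sd: float = LGN_CENTER_SD
    surround_sd: float = LGN_SURROUND_SD

    @property
    def n(self) -> int:
        return len(self.x)

    def filters(self):
        """Materialise the per-cell :class:`GaborFilter` objects (V1 only)."""
        return [
            GaborFilter(
                self.x[i],
                self.y[i],
                self.spatial_period[i],
                self.preferred_orientation[i],
                self.filter_phase[i],
                self.envelope_width[i],
            )
            for i in range(self.n)
        ]

    # -- plain-text round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "N": self.n,
            "uDC": self.u_dc,
            "uAC": self.u_ac,
            "lambda": self.spatial_period.tolist(),
            "delta": self.envelope_width.tolist(),
            "theta": self.preferred_orientation.tolist(),
            "phi": self.filter_phase.tolist(),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
        }
        if self.gain is not None:
            d["gain"] = self.gain.tolist()
        if self.kind == "LGN":
            d["center_sd"] = self.center_sd
            d["surround_sd"] = self.surround_sd
        return d

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(
            kind=d["kind"],
            x=arr("x"),
            y=arr("y"),
            spatial_period=arr("lambda"),
            preferred_orientation=arr("theta"),
            filter_phase=arr("phi"),
            envelope_width=arr("delta"),
            u_dc=float(d["uDC"]),
            u_ac=float(d["uAC"]),
            gain=arr("gain") if "gain" in d else None,
            center_sd=float(d.get("center_sd", LGN_CENTER_SD)),
            surround_sd=float(d.get("surround_sd", LGN_SURROUND_SD)),
        )

    @classmethod
    def from_json(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# noise-free mean responses
# ---------------------------------------------------------------------------

def _stimulus_arrays(stimuli):
    """Accept a Stimulus, a DataFrame with the four stimulus columns, or a
    tuple of arrays; return broadcastable 1-D arrays."""
    if isinstance(stimuli, Stimulus):
        return (
            np.atleast_1d(stimuli.orientation),
            np.atleast_1d(stimuli.phase),
            np.atleast_1d(stimuli.spatial_period),
            np.atleast_1d(stimuli.contrast),
        )
    if isinstance(stimuli, pd.DataFrame):
        return (
            stimuli["orientation"].to_numpy(float),
            stimuli["phase"].to_numpy(float),
            stimuli["spatial_period"].to_numpy(float),
            stimuli["contrast"].to_numpy(float),
        )
    th, ph, lam, c = stimuli
    return (np.atleast_1d(th), np.atleast_1d(ph), np.atleast_1d(lam), np.atleast_1d(c))


def _check_stimuli(lam_s):
    if np.any(lam_s <= 0):
        raise ValueError("stimulus spatial period must be positive")


def _gabor_means(pop, th, ph, lam_s, c, dtype=np.float64):
    """Closed-form Gabor response for an (S stimuli) x (N cells) block."""
    vt = rad(th)[:, None]  # stimulus orientation
    ps = rad(ph)[:, None]  # stimulus phase
    ks = (TWO_PI / lam_s)[:, None]
    kf = (TWO_PI / pop.spatial_period)[None, :]
    theta = rad(pop.preferred_orientation)[None, :]
    phi = rad(pop.filter_phase)[None, :]
    delta = pop.envelope_width[None, :]

    psi = ks * (np.sin(vt) * pop.x[None, :] - np.cos(vt) * pop.y[None, :])
    cosd = np.cos(theta - vt)
    half_d2 = 0.5 * delta**2
    e_minus = np.exp(-half_d2 * (kf**2 + ks**2 - 2.0 * kf * ks * cosd))
    e_plus = np.exp(-half_d2 * (kf**2 + ks**2 + 2.0 * kf * ks * cosd))
    ac = np.cos(psi + phi - ps) * e_minus + np.cos(psi - phi - ps) * e_plus
    out = pop.u_dc + c[:, None] * pop.u_ac * ac
    return out.astype(dtype, copy=False)


def _point_sample(pop, th, ph, lam_s, c):
    """Grating value at each filter center (common to retina and LGN)."""
    vt = rad(th)[:, None]
    ps = rad(ph)[:, None]
    ks = (TWO_PI / lam_s)[:, None]
    psi = ks * (np.sin(vt) * pop.x[None, :] - np.cos(vt) * pop.y[None, :])
    return c[:, None] * np.cos(psi - ps), ks


def _retina_means(pop, th, ph, lam_s, c, dtype=np.float64):
    raw, _ = _point_sample(pop, th, ph, lam_s, c)
    gain = pop.gain if pop.gain is not None else np.full(pop.n, pop.u_ac)
    out = pop.u_dc + gain[None, :] * raw
    return out.astype(dtype, copy=False)


def _lgn_means(pop, th, ph, lam_s, c, dtype=np.float64):
    raw, ks = _point_sample(pop, th, ph, lam_s, c)
    dog = np.exp(-0.5 * (ks * pop.center_sd) ** 2) - np.exp(-0.5 * (ks * pop.surround_sd) ** 2)
    gain = pop.gain if pop.gain is not None else np.full(pop.n, pop.u_ac)
    out = pop.u_dc + gain[None, :] * (dog * raw)
    return out.astype(dtype, copy=False)


_KIND_DISPATCH = {"V1": _gabor_means, "retina": _retina_means, "LGN": _lgn_means}


def mean_response_matrix(pop: PopulationSpec, stimuli, dtype=np.float64) -> np.ndarray:
    """Noise-free mean membrane potentials, shape (n_stimuli, n_cells), mV."""
    th, ph, lam_s, c = _stimulus_arrays(stimuli)
    _check_stimuli(lam_s)
    try:
        fn = _KIND_DISPATCH[pop.kind]
    except KeyError:
        raise ValueError(f"unknown population kind {pop.kind!r}") from None
    return fn(pop, th, ph, lam_s, np.clip(c, 0.0, 1.0), dtype=dtype)


def mean_response(filt: GaborFilter, stim: Stimulus, u_dc: float, u_ac: float) -> float:
    """Mean membrane potential (mV) of a single Gabor cell to one grating."""
    pop = PopulationSpec(
        kind="V1",
        x=np.array([filt.x]),
        y=np.array([filt.y]),
        spatial_period=np.array([filt.spatial_period]),
        preferred_orientation=np.array([filt.preferred_orientation]),
        filter_phase=np.array([filt.filter_phase]),
        envelope_width=np.array([filt.envelope_width]),
        u_dc=u_dc,
        u_ac=u_ac,
    )
    return float(mean_response_matrix(pop, stim)[0, 0])


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------

def _reference_ensemble(n_orient=40, n_phase=24, spatial_period=3.0, contrast=1.0):
    """The stimulus ensemble over which retina/LGN gains are calibrated:
    a full (orientation x phase) grid at the default period, full contrast."""
    th = 180.0 * (np.arange(n_orient) + 0.5) / n_orient
    ph = 360.0 * (np.arange(n_phase) + 0.5) / n_phase
    T, P = np.meshgrid(th, ph, indexing="ij")
    lam = np.full(T.size, spatial_period)
    c = np.full(T.size, contrast)
    return (T.ravel(), P.ravel(), lam, c)


def make_population(
    n: int,
    kind: str = "V1",
    rng=None,
    radius: float = 90.0,
    spatial_period: float = 3.0,
    envelope_width: float = 2.0,
    u_dc: float = -60.0,
    u_ac: float = 12.0,
    spatial_periods: np.ndarray | None = None,
) -> PopulationSpec:
    """Build a calibrated encoder population.

    Preferred orientations evenly cover [0, 180) as theta_n = 180*(n-1)/N;
    filter phases evenly cover [0, 360) in a randomly permuted assignment;
    centers are uniform over a disk of radius ``radius`` (90 deg for the
    full-field model, 1.5 deg for the hypercolumn variant).

    ``spatial_periods`` optionally gives per-cell carrier periods (used for
    the period-diverse population of the nuisance-decoding experiment).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind not in _KIND_DISPATCH:
        raise ValueError(f"unknown population kind {kind!r}")
    rng = as_rng(rng)
    r = radius * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0.0, TWO_PI, size=n)
    x, y = r * np.cos(ang), r * np.sin(ang)
    theta = 180.0 * np.arange(n) / n
    phi = rng.permutation(360.0 * np.arange(n) / n)
    if spatial_periods is None:
        lam = np.full(n, float(spatial_period))
    else:
        lam = np.asarray(spatial_periods, dtype=float)
        if lam.shape != (n,) or np.any(lam <= 0):
            raise ValueError("spatial_periods must be n positive values")
    pop = PopulationSpec(
        kind="V1",
        x=x,
        y=y,
        spatial_period=lam,
        preferred_orientation=theta,
        filter_phase=phi,
        envelope_width=np.full(n, float(envelope_width)),
        u_dc=u_dc,
        u_ac=u_ac,
    )
    if kind == "V1":
        return pop

    # retina / LGN: same geometry, gains calibrated to the V1 variance target
    ref = _reference_ensemble(spatial_period=float(spatial_period))
    v1_var = mean_response_matrix(pop, ref).var(axis=0)
    probe = replace(pop, kind=kind, gain=np.ones(n))
    raw_var = mean_response_matrix(probe, ref).var(axis=0)
    if np.any(raw_var <= 0):
        raise ValueError("degenerate calibration ensemble for kind %r" % kind)
    probe.gain = np.sqrt(v1_var / raw_var)
    return probe
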