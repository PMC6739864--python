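"""Synthetic intracellular recordings and miniature population fixtures.

``synth_trace`` emulates a whole-cell recording of a simple cell driven by a
drifting grating: the generator potential is a 2 Hz sinusoid of amplitude
u_ac around u_dc plus Gaussian noise held constant within 20 ms bins, spikes
are an inhomogeneous Poisson process with rate Phi*(u - u_th)_+^kappa, and a
stereotyped spike waveform (fast rise, exponential decay, brief
after-hyperpolarisation) is added at each spike time.  Ground truth (the
spike-free generator potential and the true spike times) is stored in the
trace and is read downstream only by tests.

``fixture_population`` builds a seconds-scale end-to-end decoding fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np

from .banks import BankSpec, Nuisance, build_bank
from .filters import make_population
from .responses import NoiseModel
from .util import as_rng

__all__ = ["CellParams", "VoltageTrace", "synth_trace", "fixture_population", "spike_waveform"]

GRATING_HZ = 2.0  # temporal frequency of the drifting grating
TRIAL_SECONDS = 3.0  # stimulus presentation per trial
NOISE_BIN_SECONDS = 0.020


@dataclass(frozen=True)
class CellParams:
    """Ground-truth response parameters of one model cell."""

    u_dc: float  # mV
    u_ac: float  # mV
    sigma: float  # mV
    u_th: float  # mV
    kappa: float = 1.0
    prefactor: float = 16.7  # Hz/mV^kappa

    def __post_init__(self):
        if self.u_ac <= 0 or self.sigma < 0:
            raise ValueError("need u_ac > 0 and sigma >= 0")

    @property
    def normalized_threshold(self) -> float:
        return (self.u_th - self.u_dc) / self.u_ac

    @property
    def noise_to_signal(self) -> float:
        return self.sigma / self.u_ac


@dataclass
class VoltageTrace:
    """A synthetic voltage recording with ground truth attached."""

    samples: np.ndarray  # mV
    sampling_rate: float  # Hz
    trial_starts: np.ndarray  # s, start of each stimulus trial
    trial_seconds: float
    true_spike_times: np.ndarray  # s
    true_generator: np.ndarray  # mV, spike-free ground truth
    params: CellParams | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def save(self, path_prefix: str):
        np.save(str(path_prefix) + ".npy", np.stack([self.samples, self.true_generator]))
        side = {
            "sampling_rate": self.sampling_rate,
            "trial_starts": self.trial_starts.tolist(),
            "trial_seconds": self.trial_seconds,
            "true_spike_times": self.true_spike_times.tolist(),
        }
        if self.params is not None:
            side["params"] = self.params.__dict__
        with open(str(path_prefix) + ".json", "w") as fh:
            json.dump(side, fh)

    @classmethod
    def load(cls, path_prefix: str) -> "VoltageTrace":
        arr = np.load(str(path_prefix) + ".npy")
        with open(str(path_prefix) + ".json") as fh:
            side = json.load(fh)
        params = CellParams(**side["params"]) if "params" in side else None
        return cls(
            arr[0],
            side["sampling_rate"],
            np.asarray(side["trial_starts"]),
            side["trial_seconds"],
            np.asarray(side["true_spike_times"]),
            arr[1],
            params,
        )


def spike_waveform(sampling_rate: float, peak_mv: float = 60.0) -> np.ndarray:
    """Stereotyped action-potential shape: 0.3 ms rise, ~1 ms exponential
    decay, and a small after-hyperpolarisation, ~4 ms total."""
    dt = 1.0 / sampling_rate
    t_rise, tau_decay, t_total = 3e-4, 8e-4, 4e-3
    t = np.arange(0.0, t_total, dt)
    w = np.where(
        t < t_rise,
        peak_mv * (t / t_rise),
        peak_mv * np.exp(-(t - t_rise) / tau_decay),
    )
    ahp = -0.08 * peak_mv * np.exp(-((t - 1.8e-3) / 8e-4) ** 2)
    return w + ahp


def synth_trace(
    params: CellParams,
    n_trials: int = 10,
    sampling_rate: float = 10_000.0,
    rng=None,
    phase_jitter_deg: float = 10.0,
    gray_seconds: float = 0.0,
    include_gray: bool = False,
) -> VoltageTrace:
    """Generate a synthetic drifting-grating voltage trace.

    Each 3 s trial carries 6 cycles of 2 Hz sinusoidal modulation with a
    small per-trial phase jitter (SD ``phase_jitter_deg`` of cycle phase).
    ``include_gray`` prepends 3 s of unmodulated baseline per trial.
    """
    rng = as_rng(rng)
    if sampling_rate < 5000.0:
        raise ValueError("sampling_rate must resolve spike shapes (>= 5 kHz)")
    dt = 1.0 / sampling_rate
    n_per_trial = int(round(TRIAL_SECONDS * sampling_rate))
    gray = int(round((gray_seconds or TRIAL_SECONDS) * sampling_rate)) if include_gray else 0
    block = gray + n_per_trial
    total = block * n_trials
    gen = np.empty(total)
    trial_starts = np.empty(n_trials)

    bin_len = int(round(NOISE_BIN_SECONDS * sampling_rate))
    t_trial = np.arange(n_per_trial) * dt
    for i in range(n_trials):
        jitter = np.deg2rad(rng.normal(0.0, phase_jitter_deg))
        mod = params.u_dc + params.u_ac * np.sin(2.0 * np.pi * GRATING_HZ * t_trial + jitter)
        lo = i * block
        if gray:
            n_bins_gray = -(-gray // bin_len)
            gnoise = np.repeat(rng.normal(0.0, params.sigma, n_bins_gray), bin_len)[:gray]
            gen[lo : lo + gray] = params.u_dc + gnoise
        n_bins = -(-n_per_trial // bin_len)
        noise = np.repeat(rng.normal(0.0, params.sigma, n_bins), bin_len)[:n_per_trial]
        gen[lo + gray : lo + block] = mod + noise
        trial_starts[i] = (lo + gray) * dt

    # inhomogeneous Poisson spiking from the generator potential
    rate = params.prefactor * np.maximum(gen - params.u_th, 0.0) ** params.kappa
    spikes_mask = rng.uniform(size=total) < rate * dt
    spike_idx = np.flatnonzero(spikes_mask)
    # enforce a 2 ms absolute refractory period
    keep = []
    last = -np.inf
    refr = int(round(2e-3 * sampling_rate))
    for idx in spike_idx:
        if idx - last >= refr:
            keep.append(idx)
            last = idx
    spike_idx = np.asarray(keep, dtype=int)

    samples = gen.copy()
    wf = spike_waveform(sampling_rate)
    for idx in spike_idx:
        hi = min(idx + len(wf), total)
        samples[idx:hi] += wf[: hi - idx]

    return VoltageTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        trial_starts=trial_starts,
        trial_seconds=TRIAL_SECONDS,
        true_spike_times=spike_idx * dt,
        true_generator=gen,
        params=params,
    )


def fixture_population(n_small: int = 8, n_classes: int = 3, rng=None):
    """A miniature end-to-end decoding fixture (population + banks).

    Returns ``(pop, spec, noise, train, test, grid, grid_means)`` — enough
    to exercise every pipeline stage in well under a second.
    """
    rng = as_rng(rng)
    pop = make_population(n_small, "V1", rng)
    spec = BankSpec(
        n_classes=n_classes,
        m_theta=2,
        m_rep=4,
        m_rep_test=6,
        phase=Nuisance.var(6),
    )
    noise = NoiseModel(sigma=3.0)
    train, test, grid, grid_means = build_bank(spec, pop, noise, rng)
    return pop, spec, noise, train, test, grid, grid_means
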