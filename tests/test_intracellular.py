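"""Recording-analysis pipeline: spike removal, parameter recovery, FRNL
estimation, and the optimality permutation test."""

import numpy as np
import pytest

from untangling.experiments import RobustRegime
from untangling.intracellular import (
    RECORDED_CELLS,
    estimate_frnl,
    extract_cell_params,
    normalise_cells,
    optimality_test,
    remove_spikes,
)
from untangling.synth import CellParams, synth_trace


@pytest.fixture(scope="module")
def default_trace():
    p = CellParams(u_dc=-50.0, u_ac=10.0, sigma=2.5, u_th=-45.0)
    return p, synth_trace(p, n_trials=10, rng=np.random.default_rng(3))


def _match_rate(detected, truth, tol=1e-3):
    if len(detected) == 0:
        return 0.0, 0.0
    hits = np.mean([np.min(np.abs(detected - t)) < tol for t in truth])
    fps = np.mean([np.min(np.abs(truth - d)) > tol for d in detected])
    return hits, fps


def test_spike_detection_rates(default_trace):
    p, tr = default_trace
    gen, st = remove_spikes(tr)
    hits, fps = _match_rate(np.asarray(st), tr.true_spike_times)
    assert hits >= 0.99
    assert fps <= 0.01


def test_spike_free_trace_unchanged(rng):
    p = CellParams(u_dc=-60.0, u_ac=5.0, sigma=1.0, u_th=-40.0)
    tr = synth_trace(p, n_trials=3, rng=rng)
    gen, st = remove_spikes(tr)
    assert len(st) == 0
    assert np.array_equal(gen, tr.samples)


def test_generator_recovery_rms(default_trace):
    p, tr = default_trace
    gen, _ = remove_spikes(tr)
    mask = np.ones(len(gen), bool)
    fs = tr.sampling_rate
    for t in tr.true_spike_times:
        i = int(t * fs)
        mask[max(i - int(5e-4 * fs), 0) : i + int(5e-3 * fs)] = False
    rms = np.sqrt(np.mean((gen[mask] - tr.true_generator[mask]) ** 2))
    assert rms <= 0.5


def test_cycle_overlay_parameter_recovery():
    truth = CellParams(u_dc=-60.0, u_ac=12.0, sigma=3.0, u_th=-56.0)
    tr = synth_trace(truth, n_trials=10, rng=np.random.default_rng(8))
    gen, st = remove_spikes(tr)
    est, per_trial = extract_cell_params(gen, tr)
    assert est.u_dc == pytest.approx(truth.u_dc, abs=0.5)
    assert est.u_ac == pytest.approx(truth.u_ac, abs=0.8)
    assert est.sigma == pytest.approx(truth.sigma, abs=0.4)
    assert len(per_trial) == 10


def test_noiseless_trace_recovers_zero_sigma(rng):
    truth = CellParams(u_dc=-55.0, u_ac=8.0, sigma=0.0, u_th=-20.0)
    tr = synth_trace(truth, n_trials=4, rng=rng, phase_jitter_deg=0.0)
    est, _ = extract_cell_params(tr.samples, tr)
    assert est.sigma < 0.05


def test_amplitude_estimators_agree(default_trace):
    p, tr = default_trace
    gen, _ = remove_spikes(tr)
    sin_est, _ = extract_cell_params(gen, tr, amplitude_method="sinusoid")
    ptp_est, _ = extract_cell_params(gen, tr, amplitude_method="peak_trough")
    assert sin_est.u_ac == pytest.approx(ptp_est.u_ac, rel=0.05)


def test_frnl_threshold_recovery(default_trace):
    p, tr = default_trace
    gen, st = remove_spikes(tr)
    est = estimate_frnl(gen, st, tr.sampling_rate)
    assert est.threshold == pytest.approx(p.u_th, abs=1.0)
    # rates in bins clearly below threshold vanish up to Poisson noise
    below = est.bin_centers < p.u_th - 2.0
    assert est.rate[below].max(initial=0.0) < 5.0
    # linear-truth data: kappa=1 fit at least as good as kappa=2
    assert est.power_law_fits[1.0]["sse"] <= est.power_law_fits[2.0]["sse"]


def test_frnl_histogram_mass_conservation(default_trace):
    p, tr = default_trace
    gen, st = remove_spikes(tr)
    est = estimate_frnl(gen, st, tr.sampling_rate)
    n_win = len(gen) // int(0.020 * tr.sampling_rate)
    assert est.occupancy.sum() == pytest.approx(n_win * 0.020)
    assert est.spike_counts.sum() == len(st)


def test_frnl_requires_spikes():
    with pytest.raises(ValueError):
        estimate_frnl(np.full(10_000, -60.0), np.array([]), 10_000.0)


def test_end_to_end_recovery_grid():
    """Recovery across a 3x3 grid of (sigma, u_th) ground truths."""
    for sigma in (2.0, 2.5, 3.0):
        for uth in (-46.0, -45.0, -44.0):
            truth = CellParams(u_dc=-50.0, u_ac=10.0, sigma=sigma, u_th=uth)
            seed = 50_000 + int(sigma * 10) * 10 + int(uth + 50.0)
            tr = synth_trace(truth, n_trials=10, rng=np.random.default_rng(seed))
            gen, st = remove_spikes(tr)
            est, _ = extract_cell_params(gen, tr)
            frnl = estimate_frnl(gen, st, tr.sampling_rate)
            assert est.u_dc == pytest.approx(-50.0, abs=0.5)
            assert est.u_ac == pytest.approx(10.0, abs=0.8)
            assert est.sigma == pytest.approx(sigma, abs=0.4)
            assert frnl.threshold == pytest.approx(uth, abs=1.0)


def test_printed_cells_normalisation():
    cells = normalise_cells(RECORDED_CELLS)
    nts = [c.normalized_threshold for c in cells]
    xis = [c.noise_to_signal for c in cells]
    assert np.allclose(nts, [0.266, 0.418, 0.536, 0.230], atol=5e-3)
    assert np.allclose(xis, [0.238, 0.311, 0.533, 0.410], atol=5e-3)
    assert all(nt > 0 for nt in nts)


def test_optimality_test_trivial_regimes(rng):
    whole_plane = RobustRegime(
        "RU", 0.9, np.array([1.0]), np.array([0.0, 1.0]),
        lo=np.array([-100.0, -100.0]), hi=np.array([100.0, 100.0]),
    )
    inside, p, meta = optimality_test(RECORDED_CELLS, whole_plane, n_shuffles=200, rng=rng)
    assert inside == 4
    assert p == 1.0
    nowhere = RobustRegime(
        "RU", 0.9, np.array([1.0]), np.array([0.0, 1.0]),
        lo=np.array([np.nan, np.nan]), hi=np.array([np.nan, np.nan]),
    )
    inside, p, meta = optimality_test(RECORDED_CELLS, nowhere, n_shuffles=200, rng=rng)
    assert inside == 0
    assert p == 1.0  # every shuffle ties the observed zero


def test_optimality_test_detects_cotuning(rng):
    """A band hugging the observed points is hit by all cells but rarely by
    independent permutations."""
    cells = RECORDED_CELLS
    xis = np.array([c.noise_to_signal for c in cells])
    nts = np.array([c.normalized_threshold for c in cells])
    order = np.argsort(xis)
    band = RobustRegime(
        "RU", 0.9, np.array([1.0]), xis[order], lo=nts[order] - 0.05, hi=nts[order] + 0.05
    )
    inside, p, meta = optimality_test(cells, band, n_shuffles=500, rng=rng)
    assert inside == 4
    assert p < 0.1
    inside2, p2, _ = optimality_test(cells, band, n_shuffles=500, rng=rng, mode="threshold_only")
    assert inside2 == 4
    with pytest.raises(ValueError):
        optimality_test(cells, band, n_shuffles=10, rng=rng, mode="bogus")


def test_shuffle_warning_metadata(rng):
    whole_plane = RobustRegime(
        "RU", 0.9, np.array([1.0]), np.array([0.0, 1.0]),
        lo=np.array([-100.0, -100.0]), hi=np.array([100.0, 100.0]),
    )
    _, _, meta = optimality_test(RECORDED_CELLS, whole_plane, n_shuffles=50, rng=rng)
    assert "warning" in meta
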