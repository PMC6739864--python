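"""Sweeps, scans, regimes and the heterogeneous-population experiment.

These use deliberately small populations and banks: the claims under test
(scale invariance, monotone degradation, interval mechanics) are robust to
problem size, and the quantitative reproduction lives in the acceptance
suite.
"""

import numpy as np
import pytest

from untangling import (
    BankSpec,
    Nuisance,
    NoiseModel,
    decode_nuisance,
    default_threshold_grid,
    heterogeneous_experiment,
    make_population,
    parameter_scan,
    robust_regime,
    threshold_sweep,
)
from untangling.experiments import RobustRegime


SMALL_SPEC = BankSpec(n_classes=4, m_theta=3, m_rep=3, m_rep_test=5, phase=Nuisance.var(8))


def test_sweep_far_above_mp_range_is_chance(rng):
    pop = make_population(20, "V1", rng)
    sweep = threshold_sweep(
        pop, SMALL_SPEC, NoiseModel(sigma=2.0), [-20.0, -10.0], rng, which="both",
        opt_eval_rows=200,
    )
    assert np.all(sweep.sparseness == 1.0)
    assert np.all(np.abs(sweep.linear_fc - 0.25) < 0.1)
    assert np.all(np.abs(sweep.optimal_fc - 0.25) < 0.1)


def test_sweep_metadata_and_refinement(rng):
    pop = make_population(24, "V1", rng)
    sweep = threshold_sweep(
        pop, SMALL_SPEC, NoiseModel(sigma=2.0), np.arange(-64.0, -51.9, 4.0), rng,
        which="linear", refine_step=2.0,
    )
    # refinement adds points around the coarse peak
    assert len(sweep.thresholds) > 4
    assert sweep.optimal_threshold in sweep.thresholds
    assert sweep.linear_fc.max() == sweep.linear_fc[list(sweep.thresholds).index(sweep.optimal_threshold)]
    df = sweep.to_frame()
    assert {"threshold_mV", "linear_fc", "sparseness"} <= set(df.columns)


def test_joint_scaling_leaves_normalized_optimum(rng):
    """Scaling sigma and uAC together is a pure change of units: with a
    grid scaled the same way, the normalised optimum is identical."""
    spec = BankSpec(n_classes=4, m_theta=3, m_rep=4, m_rep_test=8, phase=Nuisance.var(10))
    nts = np.arange(-0.5, 1.01, 0.25)
    outs = []
    for scale in (1.0, 2.0):
        rng_run = np.random.default_rng(99)
        pop = make_population(60, "V1", rng_run, u_ac=12.0 * scale)
        sweep = threshold_sweep(
            pop, spec, NoiseModel(sigma=3.0 * scale), -60.0 + nts * 12.0 * scale,
            rng_run, which="linear",
        )
        outs.append(sweep.normalized_optimum)
    assert outs[0] == pytest.approx(outs[1], abs=0.26)


def test_parameter_scan_table_shape(rng):
    spec = BankSpec(n_classes=4, m_theta=2, m_rep=2, m_rep_test=4, phase=Nuisance.var(6))
    df = parameter_scan("sigma", [2.0, 4.0], rng, n=30, spec=spec, threshold_step=3.0)
    assert list(df["parameter"]) == ["sigma", "sigma"]
    assert df["noise_to_signal"].tolist() == [2.0 / 12.0, 4.0 / 12.0]
    assert np.all(df["peak_fc"] > 0.25)
    with pytest.raises(ValueError):
        parameter_scan("bogus", [1], rng)


def test_robust_regime_contains_and_empty(rng):
    regime = RobustRegime(
        "RU", 0.9, np.array([1.0]), np.array([0.2, 0.4]),
        lo=np.array([0.0, 0.1]), hi=np.array([0.5, 0.6]),
    )
    assert regime.contains(0.3, 0.3)
    assert not regime.contains(0.3, 0.58)
    empty = RobustRegime(
        "RU", 0.9, np.array([1.0]), np.array([0.2]), lo=np.array([np.nan]), hi=np.array([np.nan])
    )
    assert not empty.contains(0.2, 0.0)


def test_robust_regime_small_model_mechanics(rng):
    """RU band bounded; infomax band unbounded below (total information can
    only fall as the threshold rises)."""
    spec = BankSpec(n_classes=4, m_theta=2, m_rep=3, m_rep_test=5, phase=Nuisance.var(8))
    nts = np.arange(-0.5, 1.01, 0.25)
    ru = robust_regime([0.25], rng, "RU", kappas=(1.0, 2.0), spec=spec, n=40,
                       normalized_thresholds=nts)
    assert np.isfinite(ru.lo[0]) and np.isfinite(ru.hi[0])
    im = robust_regime([0.25], rng, "infomax", kappas=(1.0, 2.0), spec=spec, n=40,
                       normalized_thresholds=nts, opt_eval_rows=300)
    assert im.lo[0] == -np.inf
    with pytest.raises(ValueError):
        robust_regime([0.25], rng, "bogus")


def test_decode_nuisance_classes_and_performance(rng):
    spec = BankSpec(n_classes=3, m_theta=3, m_rep=3, m_rep_test=6, phase=Nuisance.var(6),
                    contrast=Nuisance.var(3), target="spatial_period")
    sweep = decode_nuisance(
        "spatial_period", rng, n=60, spec=spec,
        thresholds=np.arange(-66.0, -47.9, 3.0),
    )
    chance = 1.0 / 3.0
    # decodable above chance at the best threshold (binomial significance),
    # with the peak in the interior of the sweep, not at the edges
    se = np.sqrt(chance * (1 - chance) / sweep.n_test)
    assert sweep.linear_fc.max() > chance + 4 * se
    assert sweep.thresholds[np.argmax(sweep.linear_fc)] not in (
        sweep.thresholds[0], sweep.thresholds[-1],
    )
    assert sweep.linear_fc.max() > sweep.linear_fc[0]
    assert sweep.linear_fc.max() > sweep.linear_fc[-1]
    with pytest.raises(ValueError):
        decode_nuisance("orientation", rng)


def test_heterogeneous_perturbation_degrades_performance(rng):
    df = heterogeneous_experiment(
        rng,
        kappas=(1.0, 1.5),
        sigmas=(2.5, 3.5),
        n_per_combo=8,
        perturbation_radii=(0.0, 4.0, 12.0),
        n_perturbations=2,
        spec=BankSpec(n_classes=4, m_theta=2, m_rep=3, m_rep_test=6, phase=Nuisance.var(8)),
        n_scan=32,
        scan_step=2.0,
    )
    ref = df.loc[df["distance"] == 0.0, "fraction_correct"].iloc[0]
    far = df.loc[df["distance"] == 12.0, "fraction_correct"].mean()
    assert far < ref
    # quadratic fit has non-positive curvature
    coef = np.polyfit(df["distance"], df["fraction_correct"], 2)
    assert coef[0] <= 1e-4


def test_generalization_across_stimulus_statistics(rng):
    """A decoder trained on the reference spatial-period distribution and
    evaluated on a shifted one performs best at (or near) the threshold
    that is optimal for the reference statistics: the optimum generalises."""
    from dataclasses import replace

    from untangling import make_population

    pop = make_population(120, "V1", np.random.default_rng(21))
    spec = BankSpec(n_classes=4, m_theta=3, m_rep=4, m_rep_test=10,
                    phase=Nuisance.var(10), spatial_period=Nuisance.var(6))
    shifted = replace(spec, period_mu=1.25)
    thresholds = np.arange(-66.0, -47.9, 3.0)
    matched = threshold_sweep(pop, spec, NoiseModel(sigma=3.0), thresholds,
                              np.random.default_rng(22), which="linear")
    cross = threshold_sweep(pop, spec, NoiseModel(sigma=3.0), thresholds,
                            np.random.default_rng(22), which="linear", test_spec=shifted)
    ref_opt = matched.optimal_threshold
    fc_at_ref = cross.linear_fc[list(cross.thresholds).index(ref_opt)]
    se = np.sqrt(0.25 / cross.n_test)
    assert fc_at_ref >= cross.linear_fc.max() - 2 * se - 0.02


def test_hypercolumn_population_keeps_interior_optimum(rng):
    """Receptive fields packed into a 3 deg circle (one retinotopic
    location) still show an interior linear-decoding optimum under phase
    nuisance, above the membrane-potential (lowest-threshold) level."""
    from untangling import make_population

    pop = make_population(150, "V1", np.random.default_rng(31), radius=1.5)
    spec = BankSpec(m_theta=3, m_rep=4, m_rep_test=8, phase=Nuisance.var(16))
    sweep = threshold_sweep(pop, spec, NoiseModel(sigma=3.0),
                            np.arange(-75.0, -45.9, 3.0), np.random.default_rng(32),
                            which="linear")
    i = int(np.argmax(sweep.linear_fc))
    assert 0 < i < len(sweep.thresholds) - 1
    assert sweep.linear_fc[i] > sweep.linear_fc[0] + 0.1
    assert -60.0 <= sweep.optimal_threshold <= -52.0


def test_decoder_weights_track_preferred_orientation(rng):
    """At a rectifying threshold the trained weights carry orientation
    structure: cells whose preferred orientation is near a class's center
    receive larger weights for that class than cells far from it."""
    from untangling import FRNL, apply_frnl, make_population, train_linear_decoder
    from untangling.banks import build_bank
    from untangling.util import circ_orientation_distance

    pop = make_population(200, "V1", np.random.default_rng(41))
    spec = BankSpec(m_theta=4, m_rep=6, m_rep_test=2, phase=Nuisance.var(20))
    train, _, _, _ = build_bank(spec, pop, NoiseModel(sigma=3.0),
                                np.random.default_rng(42), dtype=np.float32)
    frnl = FRNL(-56.0)
    dec = train_linear_decoder(apply_frnl(train.values, frnl), 10, train.labels)
    K = 10
    centers = (np.arange(K) + 0.5) * 180.0 / K
    W = dec.weights[:, :-1]
    dist = np.stack([
        circ_orientation_distance(pop.preferred_orientation, c) for c in centers
    ])  # (K, N)
    r = np.corrcoef(W.ravel(), dist.ravel())[0, 1]
    assert r < -0.1  # nearer preferred orientation -> larger weight
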