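"""Pipeline drivers: threshold sweeps, parameter scans, robust regimes,
nuisance-feature decoding and the heterogeneous-population experiment.

A *threshold sweep* regenerates firing rates from one fixed set of
membrane-potential draws at every firing-threshold grid point, retrains the
linear decoder, and records linear fraction correct, the optimal (Bayesian)
decoder's performance, response sparseness, and the sparseness-scaled
prediction of linear performance.  The optimal threshold is the argmax of
linear FC on the grid (optionally refined on a finer local grid).

A *robust regime* is, per noise-to-signal ratio sigma/u_ac, the set of
normalised thresholds (u_th - u_dc)/u_ac that retain at least a criterion
fraction (default 90%) of peak performance for every FRNL exponent kappa in
the scanned range — peak linear FC for the representational-untangling
criterion, maximal total information (mutual-information estimate of the
ideal observer) for the infomax criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .banks import BankSpec, build_bank, stimulus_grid
from .decoders import (
    GenerativeModel,
    TrainOptions,
    decode_linear,
    optimal_posterior,
    performance,
    predicted_linear_fc,
    train_linear_decoder,
)
from .filters import PopulationSpec, make_population, mean_response_matrix
from .responses import FRNL, NoiseModel, ResponseMatrix, activity_sparseness, apply_frnl, sparseness
from .util import as_rng

__all__ = [
    "SweepResult",
    "RobustRegime",
    "default_threshold_grid",
    "threshold_sweep",
    "parameter_scan",
    "robust_regime",
    "decode_nuisance",
    "heterogeneous_experiment",
]


@dataclass
class SweepResult:
    """Per-threshold decoding performance along a firing-threshold sweep."""

    thresholds: np.ndarray  # mV
    linear_fc: np.ndarray
    sparseness: np.ndarray  # zero-rate fraction
    activity_sparseness: np.ndarray | None = None  # Treves-Rolls measure
    optimal_fc: np.ndarray | None = None
    optimal_mi_bits: np.ndarray | None = None
    optimal_pfc: np.ndarray | None = None
    predicted_fc: np.ndarray | None = None  # (FC_opt-chance)*activity_sparseness+chance
    predicted_fc_zero: np.ndarray | None = None  # same with the zero-rate fraction
    chance: float = 0.1
    u_dc: float = np.nan
    u_ac: float = np.nan
    sigma: float = np.nan
    n_test: int = 0

    @property
    def optimal_threshold(self) -> float:
        """Threshold attaining the max of linear FC on the grid (mV)."""
        return float(self.thresholds[int(np.argmax(self.linear_fc))])

    @property
    def normalized_optimum(self) -> float:
        return (self.optimal_threshold - self.u_dc) / self.u_ac

    @property
    def noise_to_signal(self) -> float:
        return self.sigma / self.u_ac

    def to_frame(self) -> pd.DataFrame:
        d = {"threshold_mV": self.thresholds, "linear_fc": self.linear_fc, "sparseness": self.sparseness}
        for k in ("activity_sparseness", "optimal_fc", "optimal_mi_bits", "optimal_pfc",
                  "predicted_fc", "predicted_fc_zero"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return pd.DataFrame(d)


def default_threshold_grid(u_dc=-60.0, u_ac=12.0, sigma=3.0, contrast=0.5, step=1.0):
    """A grid spanning the membrane-potential distribution with margin:
    [u_dc - c*u_ac - 3*sigma, u_dc + c*u_ac + 3*sigma] at ``step`` mV."""
    lo = u_dc - contrast * u_ac - 3.0 * sigma
    hi = u_dc + contrast * u_ac + 3.0 * sigma
    return np.arange(lo, hi + 0.5 * step, step)


def _subsample(n_total, n_keep, rng):
    if n_keep is None or n_keep >= n_total:
        return slice(None)
    return rng.choice(n_total, size=n_keep, replace=False)


def threshold_sweep(
    pop: PopulationSpec,
    spec: BankSpec,
    noise: NoiseModel,
    thresholds,
    rng,
    kappa: float = 1.0,
    prefactor: float = 16.7,
    which: str = "both",
    opt_eval_rows: int | None = 2000,
    train_opts: TrainOptions = TrainOptions(),
    dtype=np.float32,
    refine_step: float | None = None,
    test_spec: BankSpec | None = None,
) -> SweepResult:
    """Sweep the FRNL threshold, retraining/re-evaluating decoders per point.

    The same membrane-potential draws are reused across thresholds, so the
    lowest grid point (below the whole potential distribution) reproduces
    membrane-potential decoding exactly.  ``opt_eval_rows`` caps the number
    of test rows scored by the ideal observer.  With ``refine_step`` the
    grid is refined around the coarse linear-FC peak.  ``test_spec``
    substitutes a different bank layout for evaluation (decoders stay
    trained on ``spec``) — the stimulus-statistics generalisation
    experiment, where test nuisance distributions are shifted.
    """
    if which not in ("linear", "optimal", "both"):
        raise ValueError("which must be linear | optimal | both")
    rng = as_rng(rng)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    train, test, grid, grid_means = build_bank(spec, pop, noise, rng, dtype=dtype)
    if test_spec is not None:
        _, test, _, _ = build_bank(test_spec, pop, noise, rng, dtype=dtype)
    K = spec.n_classes
    chance = 1.0 / K
    if train.values.min() >= thresholds.max():
        pass  # grid entirely below the MP range is fine (pure MP decoding)

    sub = _subsample(test.n_rows, opt_eval_rows, rng)
    test_opt_values = test.values[sub]
    test_opt_labels = test.labels[sub]

    def eval_point(uth):
        frnl = FRNL(uth, kappa, prefactor)
        r_tr = apply_frnl(train.values, frnl)
        r_te = apply_frnl(test.values, frnl)
        sp = sparseness(r_te)
        sp_act = activity_sparseness(r_te)
        fc_lin = np.nan
        if which in ("linear", "both"):
            dec = train_linear_decoder(r_tr, K, train.labels, opts=train_opts)
            _, hard = decode_linear(dec, r_te)
            fc_lin = performance(hard, test.labels).fraction_correct
        fc_opt = mi = pfc = np.nan
        if which in ("optimal", "both"):
            model = GenerativeModel(grid_means, grid["label"].to_numpy(int), noise.sigma, frnl)
            post = optimal_posterior(apply_frnl(test_opt_values, frnl), model)
            rep = performance(post, test_opt_labels, n_classes=K)
            fc_opt, mi, pfc = rep.fraction_correct, rep.mutual_information_bits, rep.pfc
        return fc_lin, fc_opt, mi, pfc, sp, sp_act

    rows = {uth: eval_point(uth) for uth in thresholds}

    if refine_step is not None and which in ("linear", "both") and len(thresholds) > 2:
        coarse_fc = np.array([rows[t][0] for t in thresholds])
        i = int(np.argmax(coarse_fc))
        lo = thresholds[max(i - 1, 0)]
        hi = thresholds[min(i + 1, len(thresholds) - 1)]
        for uth in np.arange(lo, hi + 0.5 * refine_step, refine_step):
            uth = float(round(uth, 9))
            if uth not in rows:
                rows[uth] = eval_point(uth)

    ths = np.array(sorted(rows))
    cols = np.array([rows[t] for t in ths], dtype=float)
    has_opt = which in ("optimal", "both")
    fc_opt = cols[:, 1] if has_opt else None
    return SweepResult(
        thresholds=ths,
        linear_fc=cols[:, 0],
        sparseness=cols[:, 4],
        activity_sparseness=cols[:, 5],
        optimal_fc=fc_opt,
        optimal_mi_bits=cols[:, 2] if has_opt else None,
        optimal_pfc=cols[:, 3] if has_opt else None,
        predicted_fc=predicted_linear_fc(fc_opt, cols[:, 5], chance) if has_opt else None,
        predicted_fc_zero=predicted_linear_fc(fc_opt, cols[:, 4], chance) if has_opt else None,
        chance=chance,
        u_dc=pop.u_dc,
        u_ac=pop.u_ac,
        sigma=float(np.mean(noise.sigma)),
        n_test=test.n_rows,
    )


# ---------------------------------------------------------------------------
# parameter scans
# ---------------------------------------------------------------------------

def parameter_scan(
    parameter: str,
    values,
    rng,
    n: int = 150,
    spec: BankSpec | None = None,
    u_dc: float = -60.0,
    u_ac: float = 12.0,
    sigma: float = 3.0,
    kappa: float = 1.0,
    rho: float = 0.0,
    threshold_step: float = 1.0,
    **sweep_kwargs,
) -> pd.DataFrame:
    """One threshold sweep per value of ``parameter`` in
    {"uAC", "sigma", "N", "K", "rho", "kappa"}; returns a tidy table of
    (parameter, value, noise_to_signal, normalized_optimum, peak_fc)."""
    if parameter not in {"uAC", "sigma", "N", "K", "rho", "kappa"}:
        raise ValueError(f"unknown scan parameter {parameter!r}")
    rng = as_rng(rng)
    spec = spec or BankSpec()
    records = []
    for v in values:
        p = dict(n=n, u_dc=u_dc, u_ac=u_ac, sigma=sigma, kappa=kappa, rho=rho)
        sp = spec
        if parameter == "uAC":
            p["u_ac"] = v
        elif parameter == "sigma":
            p["sigma"] = v
        elif parameter == "N":
            p["n"] = int(v)
        elif parameter == "K":
            sp = replace(spec, n_classes=int(v))
        elif parameter == "rho":
            p["rho"] = v
        elif parameter == "kappa":
            p["kappa"] = v
        pop = make_population(p["n"], "V1", rng, u_dc=p["u_dc"], u_ac=p["u_ac"])
        noise = NoiseModel(sigma=p["sigma"], rho=p["rho"])
        fixed_c = sp.contrast.value if not sp.contrast.variable else 0.5
        grid_th = default_threshold_grid(p["u_dc"], p["u_ac"], p["sigma"], fixed_c, threshold_step)
        sweep = threshold_sweep(
            pop, sp, noise, grid_th, rng, kappa=p["kappa"], which="linear", **sweep_kwargs
        )
        records.append(
            dict(
                parameter=parameter,
                value=v,
                noise_to_signal=p["sigma"] / p["u_ac"],
                normalized_optimum=sweep.normalized_optimum,
                peak_fc=float(sweep.linear_fc.max()),
            )
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# robust regimes
# ---------------------------------------------------------------------------

@dataclass
class RobustRegime:
    """Per noise-to-signal ratio, the interval of normalised thresholds that
    keeps >= ``criterion`` of peak performance for every scanned kappa.

    ``lo``/``hi`` are arrays aligned with ``noise_to_signal``; an unbounded
    lower edge (infomax) is -inf, an empty intersection is (nan, nan).
    """

    criterion_kind: str  # "RU" | "infomax"
    criterion: float
    kappas: np.ndarray
    noise_to_signal: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def contains(self, xi, normalized_threshold) -> bool:
        """Membership with linear interpolation of the band edges in xi."""
        xi = float(xi)
        order = np.argsort(self.noise_to_signal)
        xs = self.noise_to_signal[order]
        lo = np.interp(xi, xs, self.lo[order])
        hi = np.interp(xi, xs, self.hi[order])
        if np.isnan(lo) or np.isnan(hi):
            return False
        return bool(lo <= normalized_threshold <= hi)


def robust_regime(
    noise_to_signal_values,
    rng,
    criterion_kind: str = "RU",
    criterion: float = 0.9,
    kappas=(1.0, 1.25, 1.5, 1.75, 2.0),
    normalized_thresholds=None,
    n: int = 120,
    u_dc: float = -60.0,
    u_ac: float = 12.0,
    spec: BankSpec | None = None,
    grid_unbounded_below: bool = True,
    combine: str = "union",
    **sweep_kwargs,
) -> RobustRegime:
    """Compute the robust-performance band over a noise-to-signal grid.

    For each sigma/u_ac value and each kappa a threshold sweep is run; the
    per-kappa admissible set is where the performance measure (linear FC
    for "RU", the ideal observer's mutual-information estimate for
    "infomax") reaches ``criterion`` x its per-curve maximum.  A measured
    cell's exponent is unknown within the scanned range, so the default
    band is the *union* of the per-kappa sets (a threshold is admissible if
    it is near-optimal for some realistic exponent); ``combine =
    "intersection"`` gives the stricter every-exponent band.  For the
    infomax criterion an admissible lowest grid point marks a regime
    unbounded below (total information can only decrease with threshold).
    """
    if criterion_kind not in ("RU", "infomax"):
        raise ValueError("criterion_kind must be 'RU' or 'infomax'")
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    rng = as_rng(rng)
    spec = spec or BankSpec()
    if normalized_thresholds is None:
        normalized_thresholds = np.arange(-0.5, 1.01, 1.0 / 6.0)
    normalized_thresholds = np.asarray(normalized_thresholds, dtype=float)
    which = "linear" if criterion_kind == "RU" else "optimal"

    lo_out, hi_out = [], []
    for xi in noise_to_signal_values:
        sigma = xi * u_ac
        thresholds = u_dc + normalized_thresholds * u_ac
        admissible = np.full(len(thresholds), combine == "intersection")
        pop = make_population(n, "V1", rng, u_dc=u_dc, u_ac=u_ac)
        noise = NoiseModel(sigma=sigma)
        for kappa in kappas:
            sweep = threshold_sweep(
                pop, spec, noise, thresholds, rng, kappa=kappa, which=which, **sweep_kwargs
            )
            curve = sweep.linear_fc if criterion_kind == "RU" else sweep.optimal_mi_bits
            per_kappa = curve >= criterion * np.nanmax(curve)
            if combine == "intersection":
                admissible &= per_kappa
            else:
                admissible |= per_kappa
        idx = np.flatnonzero(admissible)
        if len(idx) == 0:
            lo_out.append(np.nan)
            hi_out.append(np.nan)
            continue
        lo = normalized_thresholds[idx[0]]
        hi = normalized_thresholds[idx[-1]]
        if criterion_kind == "infomax" and grid_unbounded_below and idx[0] == 0:
            lo = -np.inf
        lo_out.append(lo)
        hi_out.append(hi)
    return RobustRegime(
        criterion_kind=criterion_kind,
        criterion=criterion,
        kappas=np.asarray(kappas, dtype=float),
        noise_to_signal=np.asarray(noise_to_signal_values, dtype=float),
        lo=np.asarray(lo_out),
        hi=np.asarray(hi_out),
    )


# ---------------------------------------------------------------------------
# nuisance-feature decoding
# ---------------------------------------------------------------------------

def decode_nuisance(
    target: str,
    rng,
    n: int = 150,
    spec: BankSpec | None = None,
    sigma: float = 3.0,
    thresholds=None,
    u_dc: float = -60.0,
    u_ac: float = 12.0,
    **sweep_kwargs,
) -> SweepResult:
    """Decode spatial period or contrast with every other parameter variable.

    The encoder filters sample their carrier periods from the stimulus
    period distribution, so the population spans the decoded range; classes
    are equal-probability-mass bins of the target prior.
    """
    if target not in ("spatial_period", "contrast"):
        raise ValueError("target must be 'spatial_period' or 'contrast'")
    from .banks import Nuisance
    from scipy import stats as _st

    rng = as_rng(rng)
    base = spec or BankSpec(n_classes=4, m_theta=4, m_rep=4, m_rep_test=8,
                            phase=Nuisance.var(10), m_orientation=8)
    sp = replace(base, target=target)
    # encoder carrier periods sample the stimulus period distribution
    periods = _st.lognorm(s=sp.period_sigma, scale=np.exp(sp.period_mu)).ppf(
        (np.arange(n) + 0.5) / n
    )
    pop = make_population(n, "V1", rng, u_dc=u_dc, u_ac=u_ac,
                          spatial_periods=rng.permutation(periods))
    noise = NoiseModel(sigma=sigma)
    if thresholds is None:
        thresholds = default_threshold_grid(u_dc, u_ac, sigma, 0.5, 2.0)
    return threshold_sweep(pop, sp, noise, thresholds, rng, **sweep_kwargs)


# ---------------------------------------------------------------------------
# heterogeneous population
# ---------------------------------------------------------------------------

def heterogeneous_experiment(
    rng,
    kappas=(1.0, 1.2, 1.4, 1.6, 1.8),
    sigmas=(2.0, 2.5, 3.0, 3.5, 4.0),
    n_per_combo: int = 20,
    perturbation_radii=(0.0, 2.0, 4.0, 8.0, 16.0),
    n_perturbations: int = 4,
    spec: BankSpec | None = None,
    u_dc: float = -60.0,
    u_ac: float = 12.0,
    n_scan: int = 60,
    scan_step: float = 1.0,
    **sweep_kwargs,
) -> pd.DataFrame:
    """Locally-optimal thresholds in a heterogeneous population, perturbed.

    Each (kappa, sigma) combination receives ``n_per_combo`` cells whose
    threshold is the optimum found by a homogeneous-population sweep with
    those parameters.  Thresholds are then jointly perturbed by random
    vectors of given Euclidean norms and the linear decoder retrained;
    returns a table of (distance, fraction_correct) with the unperturbed
    reference at distance 0.
    """
    rng = as_rng(rng)
    from .banks import Nuisance

    spec = spec or BankSpec(m_theta=4, phase=Nuisance.var(12), m_rep=4, m_rep_test=8)

    opt_threshold = {}
    for kappa in kappas:
        for sig in sigmas:
            pop = make_population(n_scan, "V1", rng, u_dc=u_dc, u_ac=u_ac)
            grid_th = default_threshold_grid(u_dc, u_ac, sig, 0.5, scan_step)
            sweep = threshold_sweep(
                pop, spec, NoiseModel(sigma=sig), grid_th, rng, kappa=kappa,
                which="linear", **sweep_kwargs,
            )
            opt_threshold[(kappa, sig)] = sweep.optimal_threshold

    combos = [(k, s) for k in kappas for s in sigmas]
    n_total = len(combos) * n_per_combo
    kap_vec = np.repeat([c[0] for c in combos], n_per_combo)
    sig_vec = np.repeat([c[1] for c in combos], n_per_combo)
    uth_vec = np.repeat([opt_threshold[c] for c in combos], n_per_combo)

    pop = make_population(n_total, "V1", rng, u_dc=u_dc, u_ac=u_ac)
    noise = NoiseModel(sigma=sig_vec)
    train, test, grid, _ = build_bank(spec, pop, noise, rng, dtype=np.float32)
    K = spec.n_classes

    def fc_at(uth):
        frnl = FRNL(uth, kap_vec, 16.7)
        dec = train_linear_decoder(apply_frnl(train.values, frnl), K, train.labels)
        _, hard = decode_linear(dec, apply_frnl(test.values, frnl))
        return performance(hard, test.labels).fraction_correct

    records = [dict(distance=0.0, fraction_correct=fc_at(uth_vec), perturbation=0)]
    for radius in perturbation_radii:
        if radius == 0.0:
            continue
        for j in range(n_perturbations):
            d = rng.standard_normal(n_total)
            d *= radius / np.linalg.norm(d)
            records.append(
                dict(distance=radius, fraction_correct=fc_at(uth_vec + d), perturbation=j + 1)
            )
    return pd.DataFrame(records)
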