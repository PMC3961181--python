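"""Canned synthetic-testbed experiments.

These functions assemble the package's modules into the study-level
experiments: the homotopic-connection manipulation, the random SC
perturbation curves, the window-length analysis, and SAR coupling
recovery.  They are used both by the test suite and by the reproduction
script, with the problem size (number of regions, seeds, samples) as
explicit arguments.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .core import connection_masks
from .dynamics import ModelSpec, sar_fc, sar_sample
from .evaluation import predictive_power
from .manipulation import add_homotopic, perturb_sc, shuffle_homotopic
from .pipeline import ExperimentConfig, optimize_coupling, simulate_bold_run
from .synthetic import SyntheticConfig, make_empirical_like_fc, make_sc
from .temporal import window_length_curve

__all__ = [
    "sar_monte_carlo_deviation",
    "recover_coupling",
    "homotopic_effect",
    "perturbation_curves",
    "window_length_experiment",
]

K_TRUE_DEFAULT = 0.6  # generative SAR coupling of the synthetic testbed
T_SESSION_DEFAULT = 240  # samples at TR = 2 s -> an 8-minute session


def sar_monte_carlo_deviation(n_regions: int = 20, n_draws: int = 200_000,
                              k: float = K_TRUE_DEFAULT, seed: int = 0) -> float:
    """Max abs deviation between analytic SAR FC and Monte-Carlo sample FC."""
    sc = make_sc(SyntheticConfig(n_regions=n_regions, seed=seed))
    analytic = sar_fc(sc, k).values
    draws = sar_sample(sc, k, n_draws, seed=seed + 1)
    sample = np.corrcoef(draws)
    return float(np.abs(analytic - sample).max())


def recover_coupling(k_true: float = K_TRUE_DEFAULT, n_regions: int = 40,
                     t_samples: int = 10_000, grid_step: float = 0.05,
                     seed: int = 0) -> tuple[float, float]:
    """Generate SAR 'empirical' FC at k_true and re-estimate k on a grid.

    Returns (recovered k, grid step).
    """
    sc = make_sc(SyntheticConfig(n_regions=n_regions, seed=seed))
    emp_fc, _ = make_empirical_like_fc(sc, k_true, t_samples, noise_sd=0.0, seed=seed + 1)
    grid = np.round(np.arange(grid_step, 1.0, grid_step), 10)
    best, _table = optimize_coupling("sar", sc, emp_fc, grid=grid)
    return best, grid_step


def _optimized_sar_r(sc, emp_fc, mask, grid) -> float:
    best, _ = optimize_coupling("sar", sc, emp_fc, grid=grid)
    return predictive_power(sar_fc(sc, best), emp_fc, mask)


def homotopic_effect(n_regions: int = 60, n_seeds: int = 20,
                     t_samples: int = T_SESSION_DEFAULT,
                     k_true: float = K_TRUE_DEFAULT,
                     noise_sd: float = 0.05, base_seed: int = 0) -> dict[str, float]:
    """The homotopic-connection manipulation on the synthetic testbed.

    Ground truth SC contains homotopic links (weight 0.5); the observed SC
    is the same connectome with homotopic weights fully degraded (as
    tractography would underestimate callosal fibers).  "Empirical" FC is
    generated from the ground truth.  Reported (averaged over seeds):
    interhemispheric and indirect predictive power of the SAR model with
    the observed SC, after add_homotopic(0.5), and after additionally
    shuffling the homotopic matching.  Connection classes are always
    derived from the observed (pre-edit) SC.
    """
    grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
    acc = {key: [] for key in ("r_inter_obs", "r_inter_add", "r_indirect_obs",
                               "r_indirect_add", "r_all_add", "r_all_shuffle")}
    for s in range(n_seeds):
        seed = base_seed + s
        truth = make_sc(SyntheticConfig(n_regions=n_regions, homotopic_weight=0.5,
                                        homotopic_degradation=0.0, seed=seed))
        observed = make_sc(SyntheticConfig(n_regions=n_regions, homotopic_weight=0.5,
                                           homotopic_degradation=1.0, seed=seed))
        emp_fc, _ = make_empirical_like_fc(truth, k_true, t_samples,
                                           noise_sd=noise_sd, seed=seed + 10_000)
        masks = connection_masks(observed)
        added = add_homotopic(observed, 0.5).sc
        shuffled = shuffle_homotopic(added, seed=seed + 20_000).sc

        acc["r_inter_obs"].append(
            _optimized_sar_r(observed, emp_fc, masks["interhemispheric"], grid))
        acc["r_inter_add"].append(
            _optimized_sar_r(added, emp_fc, masks["interhemispheric"], grid))
        acc["r_indirect_obs"].append(
            _optimized_sar_r(observed, emp_fc, masks["indirect"], grid))
        acc["r_indirect_add"].append(
            _optimized_sar_r(added, emp_fc, masks["indirect"], grid))
        acc["r_all_add"].append(
            _optimized_sar_r(added, emp_fc, masks["all"], grid))
        acc["r_all_shuffle"].append(
            _optimized_sar_r(shuffled, emp_fc, masks["all"], grid))
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["inter_gain"] = out["r_inter_add"] - out["r_inter_obs"]
    out["indirect_gain"] = out["r_indirect_add"] - out["r_indirect_obs"]
    out["shuffle_deficit"] = out["r_all_add"] - out["r_all_shuffle"]
    out["n_seeds"] = n_seeds
    return out


def perturbation_curves(n_regions: int = 60, n_seeds: int = 50,
                        fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
                        t_samples: int = T_SESSION_DEFAULT,
                        k_true: float = K_TRUE_DEFAULT,
                        noise_sd: float = 0.05, base_seed: int = 0) -> dict[str, list[float]]:
    """Mean SAR predictive power vs fraction of randomly manipulated edges.

    For each seed, 'empirical' FC is generated from the intact connectome;
    the SAR coupling is optimized once on the intact SC, then held fixed
    while a fraction of connections is removed / added / permuted.
    Returns the seed-averaged curve per mode.
    """
    grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
    modes = ("remove", "add", "permute")
    curves = {m: np.zeros(len(fractions)) for m in modes}
    for s in range(n_seeds):
        seed = base_seed + s
        sc = make_sc(SyntheticConfig(n_regions=n_regions, homotopic_weight=0.5,
                                     seed=seed))
        emp_fc, _ = make_empirical_like_fc(sc, k_true, t_samples,
                                           noise_sd=noise_sd, seed=seed + 10_000)
        mask_all = connection_masks(sc)["all"]
        k_opt, _ = optimize_coupling("sar", sc, emp_fc, grid=grid)
        for mode in modes:
            for fi, frac in enumerate(fractions):
                edited = perturb_sc(sc, mode, frac, seed=seed + 30_000 + fi).sc
                curves[mode][fi] += predictive_power(
                    sar_fc(edited, k_opt), emp_fc, mask_all)
    out = {m: (curves[m] / n_seeds).tolist() for m in modes}
    out["fractions"] = list(fractions)
    return out


def window_length_experiment(n_regions: int = 60, n_seeds: int = 10,
                             lengths: Optional[Sequence[float]] = None,
                             duration: float = 480.0,
                             k_true: float = K_TRUE_DEFAULT,
                             noise_sd: float = 0.1,
                             base_seed: int = 0,
                             cfg: Optional[ExperimentConfig] = None) -> dict:
    """Window-length curves for the SAR (flat) and rate-model predictors.

    Stationary synthetic empirical BOLD is generated from the SAR model;
    the rate model is simulated for the same duration, passed through the
    hemodynamic stage, and scored with all-pairs windowed predictive power
    at every window length.  The SAR predictor's curve is its whole-session
    predictive power (exactly flat).  Returns the seed-averaged curves.
    """
    lengths = list(lengths) if lengths is not None else [20.0 * i for i in range(1, 22)]
    cfg = cfg or ExperimentConfig(apply_gsr=False, noise_sd=1.0)
    t_samples = int(round(duration / cfg.tr))
    rate_curve = np.zeros(len(lengths))
    sar_vals = []
    opt_grid = (0.3, 0.5, 0.7, 0.9)
    model = ModelSpec(model_id="rate")
    for s in range(n_seeds):
        seed = base_seed + s
        sc = make_sc(SyntheticConfig(n_regions=n_regions, homotopic_weight=0.5,
                                     seed=seed))
        emp_fc, emp_bold = make_empirical_like_fc(
            sc, k_true, t_samples, noise_sd=noise_sd, seed=seed + 10_000, tr=cfg.tr)
        masks = connection_masks(sc)
        grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
        k_sar, _ = optimize_coupling("sar", sc, emp_fc, grid=grid)
        sar_flat = window_length_curve(sar_fc(sc, k_sar), emp_bold, lengths,
                                       masks["all"])
        sar_vals.append(sar_flat[0]["mean"])
        # rate model: coarse coupling optimization on a short run, then one
        # full-duration run per seed
        seed_cfg = dataclasses.replace(cfg, seed=seed)
        k_rate, _ = optimize_coupling(model, sc, emp_fc, grid=opt_grid, cfg=seed_cfg)
        bold = simulate_bold_run(model, sc, k_rate, seed_cfg, duration,
                                 seed=seed + 40_000)
        curve = window_length_curve(bold, emp_bold, lengths, masks["all"])
        rate_curve += np.array([c["mean"] for c in curve])
    return {
        "lengths": lengths,
        "rate_mean": (rate_curve / n_seeds).tolist(),
        "sar_flat": float(np.mean(sar_vals)),
        "n_seeds": n_seeds,
    }
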