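"""Calibration and recovery benchmarks run on synthetic study conditions.

Each function regenerates its inputs from scratch under a caller-supplied
seed, runs the corresponding analysis end to end, and returns the summary
quantities (recovery medians, selection rates, sensitivities, losses).
They serve both as acceptance checks and as worked examples of how the
pipeline behaves under known ground truth.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import dynamics as dyn
from . import maxent, qc, rsa
from .geometry import lda_module_loss, pca_embed
from .graphs import build_modular_graph, random_walk, transition_matrix
from .synthetic import SynthConfig, gen_ied_recording, gen_neural, ied_sensitivity

__all__ = [
    "beta_recovery",
    "rsa_noise_calibration",
    "rsa_planted_recovery",
    "cv_distance_bias",
    "module_loss_by_beta",
    "convergence_benchmark",
    "ied_benchmark",
]


def beta_recovery(
    betas: tuple[float, ...] = (0.05, 0.2, 1.0),
    n_trials: int = 1000,
    n_seeds: int = 20,
    noise_sd: float = 0.0625,  # |r1| / 4
    r0: float = 0.75,
    r1: float = -0.25,
    seed: int = 0,
) -> dict:
    """Parameter-recovery simulation for the discount parameter.

    Residuals are generated directly from the learner's linear reaction-time
    model (r0 + r1 * a(t) + noise) on fresh walks, then refitted; reports
    the median recovered beta and median relative error per true value.
    """
    A = transition_matrix(build_modular_graph())
    medians, rel_errors = [], []
    for bt in betas:
        fits = []
        for k in range(n_seeds):
            rng = np.random.default_rng(seed * 100_003 + k * 1009 + int(bt * 1e4))
            x = random_walk(A, n_trials, rng)
            a = maxent.anticipation(x, bt)
            a[0] = 0.1
            resid = r0 + r1 * a + rng.normal(0, noise_sd, n_trials)
            fit = maxent.fit_beta(x, resid - resid.mean())
            fits.append(fit.beta if fit.status == "interior" else np.nan)
        med = float(np.nanmedian(fits))
        medians.append(med)
        rel_errors.append(abs(med - bt) / bt)
    return {
        "betas_true": list(betas),
        "medians": medians,
        "relative_errors": rel_errors,
        "monotone": bool(np.all(np.diff(medians) > 0)),
    }


def _templates(beta: float = 1.0):
    A = transition_matrix(build_modular_graph())
    latent = rsa.latent_template(maxent.analytic_estimate(A, beta))
    exact = rsa.latent_template(A)
    return latent, exact


def rsa_noise_calibration(
    n_channels: int = 200,
    n_trials: int = 300,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Selection rate on channels of pure noise (false-positive calibration).

    With a 95-of-100 null criterion the expected per-channel rate is close
    to, but below, 5%.
    """
    latent, exact = _templates()
    cfg = SynthConfig(
        n_trials=n_trials, n_channels=n_channels, snr=1.0, fs=60.0, seed=seed
    )
    epochs = rsa.truncate_epochs(gen_neural(cfg, latent, ()), "stimulus")
    sel = rsa.contact_selection(epochs, latent, exact, n_perm=n_perm, seed=seed + 1)
    n_sel = int(np.sum(sel["selected_latent"]))
    exceed_rate = float(np.mean(sel["null_exceed_count"] >= int(np.ceil(0.95 * n_perm))))
    return {
        "n_channels": n_channels,
        "selection_rate": n_sel / n_channels,
        "null_exceed_rate": exceed_rate,
    }


def rsa_planted_recovery(
    n_seeds: int = 20,
    snr: float = 2.0,
    n_trials: int = 1000,
    n_channels: int = 20,
    structured: tuple[int, ...] = (2, 5, 9),
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Recovery of channels carrying the latent-space template at fixed SNR."""
    latent, exact = _templates()
    hits = total = 0
    false_pos = noise_total = 0
    exact_support = 0
    for k in range(n_seeds):
        cfg = SynthConfig(
            n_trials=n_trials, n_channels=n_channels, snr=snr, fs=60.0,
            seed=seed * 7919 + k,
        )
        epochs = rsa.truncate_epochs(gen_neural(cfg, latent, structured), "stimulus")
        sel = rsa.contact_selection(
            epochs, latent, exact, n_perm=n_perm, seed=seed * 104_729 + k
        )
        selected = set(np.nonzero(sel["selected_latent"])[0].tolist())
        hits += len(selected & set(structured))
        total += len(structured)
        false_pos += len(selected - set(structured))
        noise_total += n_channels - len(structured)
        exact_support += selected == set(structured)
    return {
        "n_seeds": n_seeds,
        "sensitivity": hits / total,
        "false_positive_rate": false_pos / noise_total,
        "exact_support_count": exact_support,
    }


def cv_distance_bias(n_sims: int = 200, n_trials_per_cond: int = 10, n_feat: int = 15, seed: int = 0) -> dict:
    """Bias of the cross-validated squared distance for identical conditions."""
    rng = np.random.default_rng(seed)
    labels = np.r_[np.zeros(n_trials_per_cond, int), np.ones(n_trials_per_cond, int)]
    vals = [
        rsa._cv_rdm_direct(rng.standard_normal((2 * n_trials_per_cond, n_feat)), labels, 2)[0, 1]
        for _ in range(n_sims)
    ]
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(n_sims))
    return {"mean": mean, "se": se, "within_3se_of_zero": bool(abs(mean) < 3 * se)}


def module_loss_by_beta(betas: tuple[float, ...] = (0.01, 0.05, 0.1, 1.0, 2.0, 10.0)) -> dict:
    """LDA module loss of the PCA-embedded analytic estimate across beta."""
    g = build_modular_graph()
    A = transition_matrix(g)
    losses = {}
    for b in betas:
        emb = pca_embed(maxent.analytic_estimate(A, b))
        losses[b] = lda_module_loss(emb, g.module_labels)
    return {"losses": losses}


def convergence_benchmark(n_walks: int = 20, n_trials: int = 1000, seed: int = 0) -> dict:
    """Finite-vs-infinite estimate agreement over learning."""
    g = build_modular_graph()
    hi = dyn.convergence_curve(g, 1.0, n_trials=n_trials, n_walks=n_walks, seed=seed)
    lo = dyn.convergence_curve(g, 0.1, n_trials=n_trials, n_walks=n_walks, seed=seed)
    return {
        "final_corr_beta1": float(hi[-1]),
        "corr_at_200_beta1": float(hi[199]),
        "corr_at_200_beta01": float(lo[199]),
        "beta1_dominates_at_200": bool(hi[199] > lo[199]),
    }


def ied_benchmark(
    n_channels: int = 20,
    duration: float = 120.0,
    n_spikes: int = 30,
    snr: float = 5.0,
    seed: int = 0,
) -> dict:
    """Planted-spike detection benchmark: sensitivity and false events."""
    signals, times = gen_ied_recording(n_channels, duration, n_spikes, snr, seed=seed)
    events = qc.detect_ieds(signals, 512.0)
    passed = [ev for ev in events if ev.passed_spatial_filter]
    from .synthetic import SPIKE_DURATION

    centre = times + SPIKE_DURATION / 2
    false_events = sum(
        1 for ev in passed if len(times) == 0 or np.min(np.abs(centre - ev.time)) > 0.1
    )
    minutes = duration / 60.0
    return {
        "sensitivity": ied_sensitivity(events, times),
        "false_event_rate_per_min_per_channel": false_events / minutes / n_channels,
        "n_passed_events": len(passed),
    }
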