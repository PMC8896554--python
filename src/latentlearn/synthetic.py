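"""Synthetic behavior, evoked epochs, and continuous recordings.

Generators reproduce the statistical structure the analysis modules assume,
so the whole pipeline can be exercised and calibrated without any recorded
data: (i) reaction times produced by a temporally discounted learner
observing a random walk (r(t) = r0 + r1*a(t) + recency effect + noise);
(ii) multichannel evoked epochs whose condition-mean geometry embeds a
chosen similarity template at a controlled signal-to-noise ratio; and
(iii) continuous multichannel traces with planted epileptiform discharges.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bhv
from .graphs import GraphSpec, build_lattice_graph, build_modular_graph, random_walk, transition_matrix
from .maxent import anticipation
from .rsa import MIN_EPOCH_SECONDS, DissimilarityMatrix, EpochArray

__all__ = ["SynthConfig", "gen_behavior", "gen_neural", "gen_ied_recording", "ied_sensitivity"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the task design: 1000 trials of a walk on a 10-node
    graph, a baseline reaction time r0 of 0.75 s (clinical cohorts respond
    around 0.7 s), a negative anticipation slope r1 (well-predicted stimuli
    are answered faster), residual noise about a quarter of |r1|, a small
    recency benefit, and 97% response accuracy.
    """

    graph_kind: str = "modular"
    beta_true: float = 0.2
    r0: float = 0.75  # s, reaction time at zero anticipation
    r1: float = -0.25  # s per unit anticipation; negative = faster when expected
    noise_sd: float = 0.06  # s
    recency_gamma: float = 0.05  # s per log-trial of recency
    rt_noise: str = "gaussian"  # or "lognormal"
    accuracy: float = 0.97
    n_trials: int = 1000
    n_channels: int = 20
    fs: float = 100.0  # Hz, epoch sampling rate
    snr: float = 2.0  # condition-mean pattern norm / expected noise norm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 100:
            raise ValueError("n_trials must be >= 100")
        if self.snr <= 0 or self.noise_sd <= 0:
            raise ValueError("snr and noise_sd must be positive")

    def graph(self) -> GraphSpec:
        if self.graph_kind == "modular":
            return build_modular_graph()
        if self.graph_kind == "lattice":
            return build_lattice_graph()
        raise ValueError("graph_kind must be 'modular' or 'lattice'")


def gen_behavior(c: SynthConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Random walk plus reaction times from a discounted learner.

    rt(t) = r0 + r1 * a(t) + gamma * recency(t) + noise, where a(t) is the
    anticipation of a learner with the configured beta (trial 1, which has
    no anticipation, uses the uniform prediction 1/n).  Correctness is
    Bernoulli with the configured accuracy.  The returned table carries the
    generating anticipation in column ``a_true`` for recovery tests.
    """
    rng = np.random.default_rng(c.seed)
    g = c.graph()
    A = transition_matrix(g)
    x = random_walk(A, c.n_trials, rng)
    a = anticipation(x, c.beta_true, g.n_nodes)
    a[0] = 1.0 / g.n_nodes
    recency = bhv.recency_covariate(x)
    if c.rt_noise == "gaussian":
        eps = rng.normal(0.0, c.noise_sd, c.n_trials)
    elif c.rt_noise == "lognormal":
        sigma = np.sqrt(np.log1p(c.noise_sd**2))  # matches the gaussian variance
        eps = rng.lognormal(-0.5 * sigma**2, sigma, c.n_trials) - 1.0
    else:
        raise ValueError("rt_noise must be 'gaussian' or 'lognormal'")
    rt = np.maximum(c.r0 + c.r1 * a + c.recency_gamma * recency + eps, 0.051)
    trial = np.arange(1, c.n_trials + 1)
    table = pd.DataFrame(
        {
            "trial": trial,
            "node": x,
            "rt": rt,
            "correct": rng.random(c.n_trials) < c.accuracy,
            "stage": bhv.stage_of_trial(trial),
            "finger": (x % 5).astype(int).astype(str),
            "hand_transition": np.r_[0, (np.diff(x // 5) != 0).astype(int)],
            "recency": recency,
            "a_true": a,
        }
    )
    table.attrs["config"] = c
    return x, table


def _template_patterns(
    template: DissimilarityMatrix, n_feat: int, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-node mean patterns in R^n_feat whose distances match a template.

    Similarity templates are affinely flipped into dissimilarities, embedded
    with classical MDS (dimension min(9, n_feat)), rescaled so the mean
    pattern norm equals ``scale``, and rotated into the feature space by a
    random orthonormal mixing so every feature carries signal.
    """
    D = template.values.copy()
    if template.polarity == "similarity":
        off = D[~np.eye(D.shape[0], dtype=bool)]
        D = off.max() - D
    np.fill_diagonal(D, 0.0)
    dims = min(D.shape[0] - 1, n_feat)
    if dims < 2:
        raise ValueError("feature budget too small to embed the template geometry")
    # Embed so that *squared* pattern distances are an affine image of the
    # template dissimilarities — the cross-validated RDM estimates squared
    # distances, so the structured-channel RDM is then linear in the
    # template.  Templates need not be Euclidean; the Lingoes additive
    # constant (uniform shift of squared off-diagonal dissimilarities,
    # which lifts every double-centred eigenvalue and leaves Pearson
    # correlations untouched) makes the embedding exact when the feature
    # budget allows n-1 dimensions.
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    evals, evecs = np.linalg.eigh(B)
    lift = max(0.0, -evals.min())
    evals = evals + lift
    order = np.argsort(evals)[::-1][:dims]
    Y = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    norms = np.linalg.norm(Y, axis=1)
    Y = Y * (scale / norms.mean())
    Q, _ = np.linalg.qr(rng.standard_normal((n_feat, dims)))
    return Y @ Q.T


def gen_neural(
    c: SynthConfig,
    template: DissimilarityMatrix,
    structured_channels: set[int] | list[int] = (),
) -> EpochArray:
    """Multichannel epochs whose structured channels embed a template.

    Each structured channel carries node-specific mean time-courses over
    the first 200 ms of every trial (the part guaranteed to survive
    stimulus-aligned truncation) whose pairwise Euclidean geometry matches
    the template; all other samples, and all remaining channels, are unit
    white noise.  ``snr`` is the ratio of the average condition-mean
    pattern norm to the expected noise vector norm over those samples.
    Trial lengths follow the simulated reaction times.
    """
    rng = np.random.default_rng(c.seed)
    x, table = gen_behavior(c)
    rts = table["rt"].to_numpy()
    n_times = int(np.ceil(rts.max() * c.fs))
    L0 = int(round(MIN_EPOCH_SECONDS * c.fs))
    if template.values.shape[0] != c.graph().n_nodes:
        raise ValueError("template size must match the number of nodes")
    data = rng.standard_normal((c.n_channels, n_times, c.n_trials))
    scale = c.snr * np.sqrt(L0)  # noise is unit variance per sample
    for ch in sorted(set(structured_channels)):
        M = _template_patterns(template, L0, scale, rng)  # n_nodes x L0
        data[ch, :L0, :] += M[x].T
    return EpochArray(
        data=data, fs=c.fs, labels=x, rts=rts, alignment=None, n_nodes=c.graph().n_nodes
    )


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


SPIKE_DURATION = 0.070  # s, biphasic discharge template length


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic 70-ms discharge, windowed.

    One and a half cycles across the 70 ms (~21 Hz) keep the transient's
    energy inside the detector's 10-60 Hz band.
    """
    t = np.arange(int(SPIKE_DURATION * fs)) / fs
    wave = np.sin(2 * np.pi * 1.5 * t / SPIKE_DURATION)
    return wave * np.hanning(len(t))


def gen_ied_recording(
    n_channels: int = 20,
    duration: float = 120.0,
    n_spikes: int = 30,
    snr: float = 5.0,
    seed: int = 0,
    fs: float = 512.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous signals with synchronous multi-channel planted discharges.

    The background of each channel mixes pink noise with an ongoing
    beta-band rhythm (as in real intracranial recordings, whose band-limited
    envelope is far tighter than that of pure noise — the adaptive detector
    threshold relies on this).  Each discharge is injected at the same time
    on a random subset of at least four channels with peak amplitude
    ``snr`` times the background standard deviation.  Spike times are drawn
    with a 0.5-s margin and at least 0.3 s apart (collisions re-drawn).

    Returns (signals [channels x samples], spike_times [s]).
    """
    if duration < 10.0:
        raise ValueError("duration must be >= 10 s")
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    signals = np.empty((n_channels, n))
    for ch in range(n_channels):
        rhythm = np.sin(2 * np.pi * 18.0 * t + rng.uniform(0, 2 * np.pi))
        rhythm *= 1.0 + 0.1 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        mix = 0.8 * rhythm + 0.6 * _pink_noise(n, rng)
        signals[ch] = mix / mix.std()
    # re-draw spike times until all pairwise gaps exceed the refractory margin
    times = np.empty(0)
    for _ in range(1000):
        need = n_spikes - len(times)
        if need <= 0:
            break
        cand = rng.uniform(0.5, duration - 0.5, need)
        merged = np.sort(np.r_[times, cand])
        ok = np.r_[True, np.diff(merged) > 0.3]
        times = merged[ok]
    if len(times) < n_spikes:
        raise RuntimeError("could not place all spikes without collisions")
    times = np.sort(times[:n_spikes])
    template = _spike_template(fs) * snr
    for t0 in times:
        k = rng.integers(4, n_channels + 1) if n_channels > 4 else 4
        chans = rng.choice(n_channels, size=min(k, n_channels), replace=False)
        start = int(t0 * fs)
        stop = min(start + len(template), n)
        for ch in chans:
            signals[ch, start:stop] += template[: stop - start]
    return signals, times


def ied_sensitivity(events, truth_times: np.ndarray, tol: float = 0.1) -> float:
    """Fraction of planted spikes matched by a spatial-filter-passing event."""
    passed = np.array([ev.time for ev in events if ev.passed_spatial_filter])
    truth_times = np.asarray(truth_times)
    if len(truth_times) == 0:
        return float("nan")
    if len(passed) == 0:
        return 0.0
    hits = [np.min(np.abs(passed - (t + SPIKE_DURATION / 2))) <= tol for t in truth_times]
    return float(np.mean(hits))
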