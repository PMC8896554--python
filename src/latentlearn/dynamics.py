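"""Time-resolved analyses of latent-space formation.

Covers (i) sliding-window recomputation of RDM/template correlations and of
the discount parameter beta, normalised to their full-data values, and
(ii) simulated convergence of the finite-time latent-space estimate A_hat(t)
toward the infinite-time closed form as a walk unfolds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import maxent
from .graphs import GraphSpec, random_walk, transition_matrix
from .rsa import DissimilarityMatrix, EpochArray, cv_euclidean_rdm, template_corr

__all__ = [
    "WindowSpec",
    "sliding_windows",
    "windowed_template_corr",
    "windowed_beta",
    "convergence_curve",
]


@dataclass
class WindowSpec:
    """Sliding trial windows (1-based, inclusive start indices)."""

    n_trials: int
    width: int = 500
    step: int = 100
    starts: np.ndarray = None

    def __post_init__(self) -> None:
        if self.width > self.n_trials:
            raise ValueError("window width exceeds the number of trials")
        if self.starts is None:
            self.starts = np.arange(1, self.n_trials - self.width + 2, self.step)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def bounds(self) -> list[tuple[int, int]]:
        """(start, end) 1-based inclusive bounds of each window."""
        return [(int(s), int(s + self.width - 1)) for s in self.starts]


def sliding_windows(n_trials: int, width: int = 500, step: int = 100) -> WindowSpec:
    """Windows of ``width`` trials advancing by ``step`` (1000/500/100 -> 6)."""
    return WindowSpec(n_trials=n_trials, width=width, step=step)


def windowed_template_corr(
    e: EpochArray,
    templates: dict[str, DissimilarityMatrix],
    w: WindowSpec,
    channels: list[int] | None = None,
    trial_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Template correlations recomputed per sliding window and channel.

    The epochs must already be truncated to the full-data common length, so
    correlations are comparable across windows.  ``trial_index`` gives each
    epoch's 1-based trial number (defaults to 1..n_trials); windows restrict
    to the epochs whose trial number falls inside.  Each raw correlation is
    also reported normalised by that channel/template's full-data value.
    A window in which some condition has fewer than two trials yields
    missing values with a warning.

    Returns a tidy frame: window, start, end, channel, template, r, r_norm.
    """
    if channels is None:
        channels = list(range(e.n_channels))
    if trial_index is None:
        trial_index = np.arange(1, e.n_trials + 1)
    trial_index = np.asarray(trial_index)
    full = {
        (ch, name): template_corr(cv_euclidean_rdm(e, channel=ch), tpl)
        for ch in channels
        for name, tpl in templates.items()
    }
    rows = []
    for k, (start, end) in enumerate(w.bounds()):
        idx = np.nonzero((trial_index >= start) & (trial_index <= end))[0]
        for ch in channels:
            for name, tpl in templates.items():
                try:
                    sub = e.subset_trials(idx)
                    r = template_corr(cv_euclidean_rdm(sub, channel=ch), tpl)
                except ValueError:
                    warnings.warn(
                        f"window {k}: condition with <2 trials; value missing"
                    )
                    r = np.nan
                rows.append(
                    {
                        "window": k,
                        "start": start,
                        "end": end,
                        "channel": ch,
                        "template": name,
                        "r": r,
                        "r_norm": r / full[(ch, name)],
                    }
                )
    return pd.DataFrame(rows)


def windowed_beta(
    x: np.ndarray,
    resid: pd.DataFrame,
    w: WindowSpec,
    n_nodes: int = 10,
    min_trials: int = 50,
) -> pd.DataFrame:
    """Refit the discount parameter independently in each sliding window.

    Each window's model sees only that window's slice of the stimulus
    sequence and residuals.  Extreme fits (beta at 0 or diverging) are
    reported as missing beta values, mirroring how extreme participants are
    dropped from downstream statistics.
    """
    x = np.asarray(x)
    trials = resid["trial"].to_numpy(dtype=int)
    rows = []
    for k, (start, end) in enumerate(w.bounds()):
        keep = (trials >= start) & (trials <= end)
        sub = pd.DataFrame(
            {
                "trial": trials[keep] - start + 1,
                "residual": resid["residual"].to_numpy()[keep],
            }
        )
        fit = maxent.TemporalDiscountingModel(
            x[start - 1 : end], sub, n_nodes=n_nodes
        ).fit(min_trials=min_trials)
        rows.append(
            {
                "window": k,
                "start": start,
                "end": end,
                "beta": np.nan if fit.is_extreme else fit.beta,
                "status": fit.status,
                "r0": fit.r0,
                "r1": fit.r1,
                "objective": fit.objective,
            }
        )
    return pd.DataFrame(rows)


def convergence_curve(
    g: GraphSpec,
    beta: float,
    n_trials: int = 1000,
    n_walks: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Mean correlation between finite- and infinite-time latent estimates.

    For each of ``n_walks`` random walks, the discounted-count estimate
    A_hat(t) is tracked trial by trial and its strictly-lower-triangle
    Pearson correlation with the closed-form infinite-time A_hat is
    recorded; curves are averaged over walks.  Entries for t < 3 (too few
    observations for a meaningful estimate) are NaN.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = transition_matrix(g)
    target = maxent.analytic_estimate(A, beta)
    il, jl = np.tril_indices(g.n_nodes, k=-1)
    tv = target[il, jl]
    rng = np.random.default_rng(seed)
    curves = np.full((n_walks, n_trials), np.nan)
    for wk in range(n_walks):
        x = random_walk(A, n_trials, rng)
        counts = maxent.DiscountedCounts(g.n_nodes, beta)
        counts.start(int(x[0]))
        for t in range(1, n_trials):
            counts.observe(int(x[t]))
            if t < 2:
                continue
            est = counts.estimate()[il, jl]
            ec = est - est.mean()
            denom = np.sqrt((ec**2).sum() * ((tv - tv.mean()) ** 2).sum())
            if denom == 0:
                continue
            curves[wk, t] = float(ec @ (tv - tv.mean()) / denom)
    with warnings.catch_warnings():
        # the first two trials are undefined on every walk (all-NaN columns)
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(curves, axis=0)
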