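"""Behavioral trial cleaning, covariates, and reaction-time residualisation.

A behavior table holds one row per trial: the stimulus node shown, the
reaction time in seconds, correctness, and nuisance covariates (response
finger, hand transitions, recency of the current stimulus).  Before the
temporal-discounting model is fitted, trials are cleaned (implausibly fast,
outlying-slow, and incorrect trials removed) and reaction times are
residualised against the nuisance covariates so that what remains reflects
sequence expectations rather than motor demands.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "filter_trials",
    "recency_covariate",
    "residualize_rt",
    "stage_of_trial",
    "REQUIRED_COLUMNS",
    "DEFAULT_COVARIATES",
]

REQUIRED_COLUMNS = ("trial", "node", "rt", "correct")

#: covariates used by default in the single-subject residualisation
DEFAULT_COVARIATES = ("trial", "stage", "finger", "hand_transition", "recency")

MIN_RT = 0.050  # seconds; faster responses cannot follow stimulus perception
RECENCY_CAP = 10  # trials; gaps longer than this are saturated


def stage_of_trial(trial: np.ndarray | pd.Series, block: int = 250) -> np.ndarray:
    """Stage number (1-4 for a 1000-trial session) from 1-based trial index."""
    return np.ceil(np.asarray(trial, dtype=float) / block).astype(int)


def filter_trials(table: pd.DataFrame, sd_mult: float = 2.0) -> pd.DataFrame:
    """Remove implausibly short, outlying-slow, and incorrect trials.

    Retains trials with rt >= 50 ms, rt <= mean + ``sd_mult``·SD, and
    correct == True.  The mean and SD are computed once on the full input
    table (before any exclusion), so the rule does not depend on the order
    in which exclusions are applied.
    """
    if len(table) == 0:
        raise ValueError("behavior table is empty")
    rt = table["rt"].to_numpy(dtype=float)
    mean, sd = rt.mean(), rt.std(ddof=1) if len(rt) > 1 else 0.0
    keep = (rt >= MIN_RT) & (rt <= mean + sd_mult * sd) & table["correct"].astype(bool).to_numpy()
    return table.loc[keep].copy()


def recency_covariate(x: np.ndarray, cap: int = RECENCY_CAP) -> np.ndarray:
    """Log of the (capped) number of trials since the current node last appeared.

    The gap for trial t is t minus the index of the previous occurrence of
    node x_t; first occurrences are treated as a saturated gap of ``cap``.
    Values therefore lie in [0, ln(cap)].
    """
    x = np.asarray(x)
    if len(x) == 0:
        raise ValueError("sequence is empty")
    out = np.empty(len(x), dtype=float)
    last_seen: dict[int, int] = {}
    for t, node in enumerate(x):
        gap = t - last_seen[node] if node in last_seen else cap
        out[t] = np.log(min(gap, cap))
        last_seen[int(node)] = t
    return out


def attach_covariates(table: pd.DataFrame, sequence: np.ndarray | None = None) -> pd.DataFrame:
    """Fill in stage and recency columns where absent.

    ``sequence`` is the full stimulus sequence (all trials, before any
    exclusion); recency must be computed on it, not on a filtered table.
    If omitted, the table's own ``node`` column is used and the table is
    assumed unfiltered.
    """
    out = table.copy()
    if "stage" not in out:
        out["stage"] = stage_of_trial(out["trial"])
    if "recency" not in out:
        seq = out["node"].to_numpy() if sequence is None else np.asarray(sequence)
        rec = recency_covariate(seq)
        # align by 1-based trial index in case the table was filtered
        out["recency"] = rec[out["trial"].to_numpy() - 1]
    return out


def _design_matrix(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = []
    for name in covariates:
        if name not in table:
            continue
        col = table[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            cols.append(pd.get_dummies(col, prefix=name, drop_first=True, dtype=float))
        else:
            cols.append(col.astype(float))
    X = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=table.index)
    return sm.add_constant(X, has_constant="add")


def residualize_rt(
    table: pd.DataFrame, covariates: list[str] | tuple[str, ...] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """OLS residuals of reaction time on nuisance covariates.

    For a single subject the mixed model with per-participant random slopes
    collapses to ordinary least squares; categorical covariates are
    dummy-coded.  Collinear columns are dropped (with a warning) via the
    pseudoinverse fit.  Returns a two-column frame (trial, residual) aligned
    to the retained trials.
    """
    covariates = [c for c in covariates if c in table.columns]
    X = _design_matrix(table, covariates)
    y = table["rt"].astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design; collinear columns effectively dropped")
    fit = sm.OLS(y, X).fit(method="pinv")
    return pd.DataFrame({"trial": table["trial"].to_numpy(), "residual": fit.resid.to_numpy()})
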