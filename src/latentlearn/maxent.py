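"""Temporally discounted estimation of a latent transition graph (maximum
entropy learner) and its fit to reaction-time residuals.

The learner accumulates discounted transition counts: when the sequence
advances to a new node, every past node deposits mass on the transition
(past node -> new node), down-weighted exponentially by how long ago it was
seen.  A single inverse-temperature parameter beta sets the steepness of the
discount: large beta reduces to exact transition counting, beta -> 0 smears
associations across the whole history.  In the infinite-data limit the
learner's estimate of a row-stochastic transition matrix A has the closed
form

    A_hat = (1 - e^-beta) * A * (I - e^-beta * A)^-1,

a geometric mixture of all powers of A.  The learner's anticipation of the
observed transition at trial t, a(t) = A_hat_{x_{t-1}, x_t}(t-1), predicts
reaction time through the linear model r_hat(t) = r0 + r1 * a(t); beta is
estimated by minimising the root-mean-square error of that prediction on a
participant's reaction-time residuals (log grid search followed by gradient
descent).

The public surface follows the Model/Results convention:
``TemporalDiscountingModel(sequence, residuals).fit()`` returns a
``TemporalDiscountingResults`` carrying beta, r0, r1, the RMSE curve over
the search grid, and diagnostics; the lower-level functions
(``analytic_estimate``, ``update_counts``, ``finite_estimate``,
``anticipation``, ``fit_rt_linear``, ``fit_beta``) remain importable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # jit-compiled inner loop; the numpy path below is the reference
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "analytic_estimate",
    "DiscountedCounts",
    "update_counts",
    "finite_estimate",
    "anticipation",
    "fit_rt_linear",
    "fit_beta",
    "TemporalDiscountingModel",
    "TemporalDiscountingResults",
    "BETA_GRID",
]

#: default beta search grid: 100 logarithmically spaced points on [1e-4, 10]
BETA_GRID = np.logspace(-4, 1, 100)

BETA_MAX = 1000.0  # beyond this the search is flagged as diverging to infinity
BETA_MIN = 1e-6  # below this the search is flagged as collapsing to zero


def analytic_estimate(A: np.ndarray, beta: float) -> np.ndarray:
    """Infinite-time latent-space estimate (1-e^-beta) A (I - e^-beta A)^-1.

    For beta -> infinity this converges to A itself (exact counting); for
    beta -> 0 it converges to the uniform matrix 1/n (all transitions deemed
    equally likely).  Rows sum to 1 for any beta > 0.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = np.asarray(A, dtype=float)
    eta = np.exp(-beta)
    n = A.shape[0]
    M = np.eye(n) - eta * A
    # I - eta*A is strictly diagonally dominant for eta < 1 and stochastic A
    return (1.0 - eta) * A @ np.linalg.inv(M)


@dataclass
class DiscountedCounts:
    """Discounted transition-count matrix n_tilde with incremental updates.

    Maintains the recursion form of the update: a presence vector p over
    nodes holding the discounted weight of every past position, so a full
    update is O(n) rather than O(t).  ``observe`` both deposits the update
    for a new node and advances the history.
    """

    n_nodes: int
    beta: float
    n_tilde: np.ndarray = field(init=False)
    _presence: np.ndarray = field(init=False)
    _weight_sum: float = field(init=False, default=0.0)
    _row_sums: np.ndarray = field(init=False)
    t: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.n_tilde = np.zeros((self.n_nodes, self.n_nodes))
        self._presence = np.zeros(self.n_nodes)
        self._row_sums = np.zeros(self.n_nodes)

    def start(self, first_node: int) -> None:
        """Register the first node of the history without any transition."""
        decay = np.exp(-self.beta)
        self._presence *= decay
        self._presence[first_node] += 1.0
        self._weight_sum = self._weight_sum * decay + 1.0
        self.t += 1

    def observe(self, next_node: int) -> None:
        """Deposit the discounted update for the transition into next_node.

        Every past position t - dt contributes e^(-beta*dt)/Z to
        n_tilde[x_{t-dt}, next_node], Z normalising so exactly unit mass is
        added per observed transition; then next_node joins the history.
        """
        if not 0 <= next_node < self.n_nodes:
            raise ValueError("next_node out of range")
        if self.t == 0:
            raise ValueError("history is empty; call start() first")
        w = self._presence / self._weight_sum
        self.n_tilde[:, next_node] += w
        self._row_sums += w
        self.start(next_node)

    def estimate(self) -> np.ndarray:
        """Row-normalised finite-time estimate; zero-mass rows are uniform."""
        return finite_estimate(self.n_tilde)

    def predict(self, i: int, j: int) -> float:
        """Estimated probability of transition i -> j (O(1))."""
        rs = self._row_sums[i]
        return self.n_tilde[i, j] / rs if rs > 0 else 1.0 / self.n_nodes


def update_counts(
    n_tilde: np.ndarray, history: np.ndarray, next_node: int, beta: float
) -> np.ndarray:
    """One literal discounted-count update (reference form, O(t)).

    Given history x_1..x_t and the newly observed ``next_node``, adds
    e^(-beta*dt)/Z to entry (x_{t-dt}, next_node) for dt = 0..t-1, with
    Z = sum of the weights, so total added mass is 1.  Returns a new matrix.
    """
    history = np.asarray(history)
    t = len(history)
    if t == 0:
        raise ValueError("history is empty")
    n = n_tilde.shape[0]
    if not 0 <= next_node < n:
        raise ValueError("next_node out of range")
    weights = np.exp(-beta * np.arange(t))  # dt = 0 is the most recent node
    weights /= weights.sum()
    out = n_tilde.astype(float).copy()
    for dt, w in enumerate(weights):
        out[history[t - 1 - dt], next_node] += w
    return out


def finite_estimate(n_tilde: np.ndarray) -> np.ndarray:
    """Row-normalise a count matrix; rows with zero mass become uniform."""
    n_tilde = np.asarray(n_tilde, dtype=float)
    n = n_tilde.shape[0]
    rs = n_tilde.sum(axis=1, keepdims=True)
    out = np.where(rs > 0, n_tilde / np.where(rs > 0, rs, 1.0), 1.0 / n)
    return out


def _anticipation_multi(x: np.ndarray, betas: np.ndarray, n_nodes: int) -> np.ndarray:
    """Anticipation series for several betas in one sweep of the sequence.

    Vectorised over betas so that the 100-point grid search costs a single
    pass over the sequence.  Returns an (n_betas, T) array; column 0 is NaN.
    """
    x = np.asarray(x, dtype=int)
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    T = len(x)
    B = len(betas)
    decay = np.exp(-betas)
    counts = np.zeros((B, n_nodes, n_nodes))
    row_sums = np.zeros((B, n_nodes))
    presence = np.zeros((B, n_nodes))
    presence[:, x[0]] = 1.0
    weight_sum = np.ones(B)
    a = np.full((B, T), np.nan)
    uniform = 1.0 / n_nodes
    for t in range(1, T):
        i, j = x[t - 1], x[t]
        rs = row_sums[:, i]
        a[:, t] = np.where(rs > 0, counts[:, i, j] / np.where(rs > 0, rs, 1.0), uniform)
        w = presence / weight_sum[:, None]
        counts[:, :, j] += w
        row_sums += w
        presence *= decay[:, None]
        presence[:, j] += 1.0
        weight_sum = weight_sum * decay + 1.0
    return a


def _anticipation_loop(x: np.ndarray, beta: float, n_nodes: int) -> np.ndarray:
    """Scalar inner loop for a single beta (jit-compiled when available)."""
    T = x.shape[0]
    decay = np.exp(-beta)
    counts = np.zeros((n_nodes, n_nodes))
    row_sums = np.zeros(n_nodes)
    presence = np.zeros(n_nodes)
    presence[x[0]] = 1.0
    weight_sum = 1.0
    a = np.full(T, np.nan)
    uniform = 1.0 / n_nodes
    for t in range(1, T):
        i = x[t - 1]
        j = x[t]
        rs = row_sums[i]
        a[t] = counts[i, j] / rs if rs > 0 else uniform
        for m in range(n_nodes):
            w = presence[m] / weight_sum
            counts[m, j] += w
            row_sums[m] += w
            presence[m] *= decay
        presence[j] += 1.0
        weight_sum = weight_sum * decay + 1.0
    return a


if _HAVE_NUMBA:
    _anticipation_loop = njit(cache=True)(_anticipation_loop)


def anticipation(x: np.ndarray, beta: float, n_nodes: int = 10) -> np.ndarray:
    """Anticipation series a(t) = A_hat_{x_{t-1}, x_t}(t-1) for t = 2..T.

    Returns an array of length T whose first entry is NaN (no anticipation
    exists for the first trial).  The estimate at trial t incorporates all
    transitions up to and including the one into x_{t-1}; before any
    transition has been seen the prediction is uniform (1/n).
    """
    x = np.asarray(x, dtype=np.int64)
    if len(x) < 2:
        raise ValueError("sequence must have length >= 2")
    return _anticipation_loop(x, float(beta), n_nodes)


def fit_rt_linear(a: np.ndarray, resid: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of residual RT on anticipation: r = r0 + r1*a.

    Returns (r0, r1, rmse).  A constant anticipation series cannot identify
    a slope; r1 is then set to 0 with r0 = mean(resid), and a warning is
    issued.
    """
    a = np.asarray(a, dtype=float)
    resid = np.asarray(resid, dtype=float)
    if len(a) != len(resid):
        raise ValueError("series must be aligned")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0.0:
        warnings.warn("constant anticipation series; slope not identifiable")
        r0 = float(resid.mean())
        return r0, 0.0, float(np.sqrt(np.mean((resid - r0) ** 2)))
    # closed-form 2x2 normal equations
    am, rm = a.mean(), resid.mean()
    r1 = float(np.sum((a - am) * (resid - rm)) / np.sum((a - am) ** 2))
    r0 = float(rm - r1 * am)
    rmse = float(np.sqrt(np.mean((resid - r0 - r1 * a) ** 2)))
    return r0, r1, rmse


class TemporalDiscountingModel:
    """Fit the temporal-discounting learner to reaction-time residuals.

    Parameters
    ----------
    sequence : (T,) int array
        The full stimulus node sequence, including trials later excluded
        from the regression — the learner's internal counts are driven by
        everything the participant saw.
    residuals : DataFrame with columns (trial, residual), or (T,) array
        Reaction-time residuals for the retained trials.  1-based trial
        indices locate each residual within ``sequence``; a plain array is
        taken to cover all T trials.
    n_nodes : number of distinct stimuli (default 10).
    grid : beta values evaluated in the initial search (default 100
        log-spaced points on [1e-4, 10]).
    transition_matrix : optional true transition matrix, enabling
        ``results.latent_estimate(mode="infinite")``.
    """

    def __init__(
        self,
        sequence: np.ndarray,
        residuals: pd.DataFrame | np.ndarray,
        n_nodes: int = 10,
        grid: np.ndarray = BETA_GRID,
        transition_matrix: np.ndarray | None = None,
    ) -> None:
        self.sequence = np.asarray(sequence, dtype=int)
        self.n_nodes = n_nodes
        self.grid = np.asarray(grid, dtype=float)
        self.transition_matrix = transition_matrix
        T = len(self.sequence)
        if isinstance(residuals, pd.DataFrame):
            trials = residuals["trial"].to_numpy(dtype=int)
            values = residuals["residual"].to_numpy(dtype=float)
        else:
            values = np.asarray(residuals, dtype=float)
            trials = np.arange(1, len(values) + 1)
        ok = trials >= 2  # the first trial has no anticipation
        self.trials = trials[ok]
        self.resid = values[ok]
        if np.any(self.trials > T):
            raise ValueError("residual trial index beyond sequence length")
        self.nobs = len(self.resid)

    def _objective(self, beta: float) -> tuple[float, float, float]:
        """(rmse, r0, r1) at a given beta."""
        a = anticipation(self.sequence, beta, self.n_nodes)[self.trials - 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r0, r1, rmse = fit_rt_linear(a, self.resid)
        return rmse, r0, r1

    def fit(self, min_trials: int = 50, gtol: float = 1e-6) -> "TemporalDiscountingResults":
        """Grid search over beta followed by gradient descent in log(beta).

        The descent uses a central finite-difference gradient (step 1e-4 in
        log beta) with backtracking halving line search, and stops when the
        absolute gradient falls below ``gtol``, or when beta collapses to 0
        or diverges past 1000 (recorded as extreme statuses).
        """
        if self.nobs < min_trials:
            raise ValueError(f"only {self.nobs} usable trials; need >= {min_trials}")
        a_grid = _anticipation_multi(self.sequence, self.grid, self.n_nodes)[:, self.trials - 1]
        am = a_grid.mean(axis=1, keepdims=True)
        rm = self.resid.mean()
        var_a = np.sum((a_grid - am) ** 2, axis=1)
        cov = np.sum((a_grid - am) * (self.resid - rm), axis=1)
        r1s = np.where(var_a > 0, cov / np.where(var_a > 0, var_a, 1.0), 0.0)
        r0s = rm - r1s * am[:, 0]
        pred = r0s[:, None] + r1s[:, None] * a_grid
        grid_rmse = np.sqrt(np.mean((self.resid - pred) ** 2, axis=1))
        k0 = int(np.argmin(grid_rmse))
        log_b = float(np.log(self.grid[k0]))
        f = float(grid_rmse[k0])
        h = 1e-4
        status = "interior"
        for _ in range(500):
            g = (self._objective(np.exp(log_b + h))[0] - self._objective(np.exp(log_b - h))[0]) / (
                2 * h
            )
            if abs(g) < gtol:
                break
            step = -g
            improved = False
            alpha = 1.0
            for _ in range(50):
                cand = log_b + alpha * step
                fc = self._objective(np.exp(cand))[0]
                if fc < f:
                    log_b, f = cand, fc
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                break
            if np.exp(log_b) > BETA_MAX:
                status = "infinite"
                break
            if np.exp(log_b) < BETA_MIN:
                status = "zero"
                break
        if status == "interior":
            beta = float(np.exp(log_b))
            rmse, r0, r1 = self._objective(beta)
        elif status == "infinite":
            beta = np.inf
            rmse, r0, r1 = self._objective(BETA_MAX)
        else:
            beta = 0.0
            rmse, r0, r1 = self._objective(BETA_MIN)
        return TemporalDiscountingResults(
            model=self,
            beta=beta,
            r0=r0,
            r1=r1,
            objective=rmse,
            status=status,
            grid_betas=self.grid.copy(),
            grid_objective=grid_rmse,
        )


@dataclass
class TemporalDiscountingResults:
    """Fitted parameters and diagnostics of the temporal-discounting model.

    ``beta`` is numeric only for interior fits; extreme searches carry
    beta = 0 or inf together with status "zero"/"infinite" and should be
    treated as missing in downstream statistics.
    """

    model: TemporalDiscountingModel
    beta: float
    r0: float
    r1: float
    objective: float  # root-mean-square error, seconds
    status: str  # interior | zero | infinite
    grid_betas: np.ndarray
    grid_objective: np.ndarray

    @property
    def is_extreme(self) -> bool:
        return self.status != "interior"

    def _beta_eval(self) -> float:
        return {"zero": BETA_MIN, "infinite": BETA_MAX}.get(self.status, self.beta)

    def anticipation(self) -> np.ndarray:
        """Anticipation series over the full sequence at the fitted beta."""
        return anticipation(self.model.sequence, self._beta_eval(), self.model.n_nodes)

    def predict(self) -> np.ndarray:
        """Predicted residual reaction times r0 + r1*a(t) on retained trials."""
        a = self.anticipation()[self.model.trials - 1]
        return self.r0 + self.r1 * a

    def latent_estimate(self, mode: str = "infinite") -> np.ndarray:
        """Estimated latent space at the fitted beta.

        mode="infinite": closed-form estimate from the true transition
        matrix (requires the model to have been given one).
        mode="finite": row-normalised discounted counts accumulated over
        the actually observed sequence.
        """
        if mode == "infinite":
            if self.model.transition_matrix is None:
                raise ValueError("model was constructed without a transition matrix")
            return analytic_estimate(self.model.transition_matrix, self._beta_eval())
        if mode == "finite":
            c = DiscountedCounts(self.model.n_nodes, self._beta_eval())
            x = self.model.sequence
            c.start(int(x[0]))
            for node in x[1:]:
                c.observe(int(node))
            return c.estimate()
        raise ValueError("mode must be 'infinite' or 'finite'")

    def summary(self) -> str:
        lines = [
            "Temporal discounting model (maximum entropy learner)",
            "=" * 56,
            f"{'n usable trials':<28}{self.model.nobs:>12d}",
            f"{'status':<28}{self.status:>12s}",
            f"{'beta (discount steepness)':<28}{self.beta:>12.4g}",
            f"{'r0 (intercept, s)':<28}{self.r0:>12.4f}",
            f"{'r1 (anticipation slope, s)':<28}{self.r1:>12.4f}",
            f"{'RMSE (s)':<28}{self.objective:>12.4f}",
            "=" * 56,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta": None if self.is_extreme else float(self.beta),
            "status": self.status,
            "r0": float(self.r0),
            "r1": float(self.r1),
            "objective": float(self.objective),
            "grid_betas": self.grid_betas.tolist(),
            "grid_objective": self.grid_objective.tolist(),
        }


def fit_beta(
    x: np.ndarray,
    resid: pd.DataFrame | np.ndarray,
    n_nodes: int = 10,
    grid: np.ndarray = BETA_GRID,
    min_trials: int = 50,
) -> TemporalDiscountingResults:
    """Convenience wrapper: fit the temporal-discounting model in one call."""
    return TemporalDiscountingModel(x, resid, n_nodes=n_nodes, grid=grid).fit(
        min_trials=min_trials
    )
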