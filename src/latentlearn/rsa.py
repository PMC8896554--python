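"""Representational similarity analysis of evoked activity.

Per recording channel, trials are truncated to a common length, a
10 x 10 cross-validated Euclidean dissimilarity matrix (RDM) between the
condition-evoked patterns is computed, and the RDM's lower triangle is
correlated with candidate templates: the behaviourally estimated latent
space A_hat, the exact latent space A, and the visual (screen-distance)
space.  Channels are selected when their latent-space correlation beats a
circular-shift permutation null (which preserves the autocorrelation of the
recording) and exceeds the correlation with the exact latent space.

Cross-validation makes the expected squared distance between two conditions
with identical generating patterns zero, so individual RDM entries may be
negative; entries are per-sample (normalised by the trial vector length).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import stats

__all__ = [
    "EpochArray",
    "DissimilarityMatrix",
    "NullDistribution",
    "UndefinedCorrelationError",
    "truncate_epochs",
    "cv_euclidean_rdm",
    "template_corr",
    "circular_shift_null",
    "select_contacts",
    "contact_selection",
    "visual_template",
    "latent_template",
    "MIN_EPOCH_SECONDS",
]

MIN_EPOCH_SECONDS = 0.200  # floor on the common trial length


class UndefinedCorrelationError(ValueError):
    """Raised when a template correlation is undefined (zero variance)."""


@dataclass
class DissimilarityMatrix:
    """Condition-pair matrix with an explicit similarity/dissimilarity polarity.

    ``polarity`` records whether large values mean *far apart*
    ("dissimilarity", e.g. a neural RDM) or *strongly connected*
    ("similarity", e.g. the latent-space estimate A_hat); correlations
    against similarity templates are sign-flipped so that positive always
    means "geometry matches".
    """

    values: np.ndarray
    polarity: str = "dissimilarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.polarity not in ("dissimilarity", "similarity"):
            raise ValueError("polarity must be 'dissimilarity' or 'similarity'")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries (the 45 unordered pairs for n=10)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


@dataclass
class NullDistribution:
    correlations: np.ndarray
    seed: int | None = None

    def exceed_count(self, observed: float) -> int:
        """Number of null correlations the observed value strictly exceeds."""
        return int(np.sum(observed > self.correlations))


@dataclass
class EpochArray:
    """Epoched multichannel recordings: channels x time x trials.

    ``rts`` gives each trial's reaction time (seconds); samples beyond
    floor(rt * fs) are padding.  ``alignment`` is None until the epochs
    have been truncated to a common length.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    rts: np.ndarray
    alignment: str | None = None
    n_nodes: int = 10

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.rts = np.asarray(self.rts, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x time x trials")
        if self.data.shape[2] != len(self.labels) or len(self.labels) != len(self.rts):
            raise ValueError("labels/rts must match the trial axis")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def subset_trials(self, idx: np.ndarray) -> "EpochArray":
        return replace(
            self, data=self.data[:, :, idx], labels=self.labels[idx], rts=self.rts[idx]
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            # track_times=False keeps re-runs with identical data byte-identical
            f.create_dataset("data", data=self.data, track_times=False)
            f.create_dataset("labels", data=self.labels, track_times=False)
            f.create_dataset("rts", data=self.rts, track_times=False)
            f.attrs["fs"] = self.fs
            f.attrs["alignment"] = self.alignment if self.alignment else "none"
            f.attrs["n_nodes"] = self.n_nodes

    @classmethod
    def from_hdf5(cls, path) -> "EpochArray":
        with h5py.File(path, "r") as f:
            alignment = f.attrs.get("alignment", "none")
            if isinstance(alignment, bytes):
                alignment = alignment.decode()
            return cls(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                labels=f["labels"][()],
                rts=f["rts"][()],
                alignment=None if alignment == "none" else alignment,
                n_nodes=int(f.attrs.get("n_nodes", 10)),
            )


def truncate_epochs(e: EpochArray, alignment: str = "stimulus") -> EpochArray:
    """Truncate all trials to a common length set by the fastest response.

    The common length is L = floor(min(rt) * fs) samples, floored at 200 ms;
    trials shorter than L are discarded.  Alignment decides which samples
    survive: "stimulus" keeps the first L (the end of trials is cut),
    "response" keeps the last L before the response, and "middle" keeps the
    first ceil(L/2) and last floor(L/2) samples (the centre is cut).
    """
    if alignment not in ("stimulus", "middle", "response"):
        raise ValueError("alignment must be stimulus, middle, or response")
    if e.n_trials == 0:
        raise ValueError("no trials")
    lengths = np.minimum(np.floor(e.rts * e.fs).astype(int), e.n_times)
    L = max(int(lengths.min()), int(round(MIN_EPOCH_SECONDS * e.fs)))
    keep = lengths >= L
    if not np.any(keep):
        raise ValueError("all trials shorter than the minimum epoch length")
    idx = np.nonzero(keep)[0]
    out = np.empty((e.n_channels, L, len(idx)))
    head = -(-L // 2)  # ceil(L/2)
    tail = L - head
    for col, k in enumerate(idx):
        n_t = lengths[k]
        if alignment == "stimulus":
            out[:, :, col] = e.data[:, :L, k]
        elif alignment == "response":
            out[:, :, col] = e.data[:, n_t - L : n_t, k]
        else:  # middle: drop the centre of the trial
            out[:, :head, col] = e.data[:, :head, k]
            out[:, head:, col] = e.data[:, n_t - tail : n_t, k]
    return EpochArray(
        data=out,
        fs=e.fs,
        labels=e.labels[idx],
        rts=e.rts[idx],
        alignment=alignment,
        n_nodes=e.n_nodes,
    )


def _condition_indices(labels: np.ndarray, n_cond: int) -> list[np.ndarray]:
    idx = [np.nonzero(labels == c)[0] for c in range(n_cond)]
    for c, ix in enumerate(idx):
        if len(ix) < 2:
            raise ValueError(f"condition {c} has fewer than 2 trials")
    return idx


def _cv_rdm_direct(X: np.ndarray, labels: np.ndarray, n_cond: int) -> np.ndarray:
    """Reference leave-one-out cross-validated squared-distance RDM.

    X is trials x features.  For a condition pair (a, b), folds pair the
    k-th trial of each condition (the shorter condition's index cycling);
    each fold's estimate is the inner product of the held-out-trial
    difference with the training-mean difference.  Entries are divided by
    the feature count so they are per-sample.
    """
    idx = _condition_indices(labels, n_cond)
    n_feat = X.shape[1]
    sums = [X[ix].sum(axis=0) for ix in idx]
    D = np.zeros((n_cond, n_cond))
    for a in range(n_cond):
        for b in range(a):
            ia, ib = idx[a], idx[b]
            na, nb = len(ia), len(ib)
            K = max(na, nb)
            acc = 0.0
            for k in range(K):
                ta, tb = ia[k % na], ib[k % nb]
                mu_a = (sums[a] - X[ta]) / (na - 1)
                mu_b = (sums[b] - X[tb]) / (nb - 1)
                acc += float((mu_a - mu_b) @ (X[ta] - X[tb]))
            D[a, b] = D[b, a] = acc / K / n_feat
    return D


def _rdm_from_gram(
    G: np.ndarray, cond_idx: list[np.ndarray], n_feat: int
) -> np.ndarray:
    """Same estimator as :func:`_cv_rdm_direct`, from a trial Gram matrix.

    All inner products in the cross-validated distance are entries or
    row-sums of G = X X^T, so a permutation of which trials belong to which
    condition (as in the circular-shift null) can be re-evaluated without
    touching the raw data.
    """
    n_cond = len(cond_idx)
    diag = np.diag(G)
    # R[:, c] = sum of G columns belonging to condition c
    R = np.stack([G[:, ix].sum(axis=1) for ix in cond_idx], axis=1)
    D = np.zeros((n_cond, n_cond))
    for a in range(n_cond):
        for b in range(a):
            ia, ib = cond_idx[a], cond_idx[b]
            na, nb = len(ia), len(ib)
            K = max(na, nb)
            ta = ia[np.arange(K) % na]
            tb = ib[np.arange(K) % nb]
            mu_a_xa = (R[ta, a] - diag[ta]) / (na - 1)
            mu_a_xb = (R[tb, a] - G[ta, tb]) / (na - 1)
            mu_b_xa = (R[ta, b] - G[tb, ta]) / (nb - 1)
            mu_b_xb = (R[tb, b] - diag[tb]) / (nb - 1)
            D[a, b] = D[b, a] = float(
                np.mean(mu_a_xa - mu_a_xb - mu_b_xa + mu_b_xb)
            ) / n_feat
    return D


def _trial_matrix(e: EpochArray, channel: int | None) -> np.ndarray:
    """Trials x features view of an epoch array (one channel or all)."""
    if e.alignment is None:
        raise ValueError("epochs must be truncated to a fixed length first")
    data = e.data if channel is None else e.data[channel : channel + 1]
    return data.reshape(-1, e.n_trials).T


def cv_euclidean_rdm(e: EpochArray, channel: int | None = None) -> DissimilarityMatrix:
    """Leave-one-out cross-validated Euclidean RDM of evoked activity.

    ``channel=None`` concatenates all channels into one feature vector
    (used for the combined selected-contact geometry); otherwise a single
    channel's time samples are the features.
    """
    X = _trial_matrix(e, channel)
    D = _cv_rdm_direct(X, e.labels, e.n_nodes)
    return DissimilarityMatrix(values=D, polarity="dissimilarity")


def template_corr(d: DissimilarityMatrix, template: DissimilarityMatrix) -> float:
    """Pearson correlation of lower triangles, sign-flipped for similarity.

    A neural RDM is a dissimilarity; templates like A_hat are similarities,
    so their correlation is multiplied by -1 — positive output always means
    the neural geometry matches the template's.
    """
    x = d.lower_triangle()
    y = template.lower_triangle()
    if len(x) != len(y):
        raise ValueError("matrix sizes do not match")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return -r if template.polarity == "similarity" else r


def _shifted_condition_indices(
    labels: np.ndarray, n_cond: int, shift: int
) -> list[np.ndarray]:
    """Data-trial indices per condition after a circular shift of the data.

    Reordering the data to (s+1..T, 1..s) while labels keep their original
    order means the trial at position p carries data from trial (p+s) mod T;
    condition c's data indices are therefore (idx_c + s) mod T, kept in
    position order so that leave-one-out fold pairing matches a literal
    rotation of the data array.
    """
    T = len(labels)
    return [(ix + shift) % T for ix in _condition_indices(labels, n_cond)]


def circular_shift_null(
    e: EpochArray,
    templates: dict[str, DissimilarityMatrix],
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    channel: int | None = None,
) -> dict[str, NullDistribution]:
    """Null template correlations from circular shifts of the trial order.

    Each permutation draws a split point s uniformly from [1, T-1], rotates
    the neural data trials to (s+1..T, 1..s) while the stimulus labels stay
    in the original order, recomputes the RDM and the template correlations.
    The rotation preserves the autocorrelation structure of the recording;
    s = 0 and s = T are excluded so every null differs from the observed
    ordering.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = _trial_matrix(e, channel)
    G = X @ X.T
    n_feat = X.shape[1]
    T = e.n_trials
    shifts = rng.integers(1, T, size=n_perm)
    out = {name: np.empty(n_perm) for name in templates}
    for p, s in enumerate(shifts):
        idx = _shifted_condition_indices(e.labels, e.n_nodes, int(s))
        D = DissimilarityMatrix(_rdm_from_gram(G, idx, n_feat))
        for name, tpl in templates.items():
            out[name][p] = template_corr(D, tpl)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return {name: NullDistribution(vals, seed=seed_val) for name, vals in out.items()}


def select_contacts(
    r_latent: np.ndarray,
    r_exact: np.ndarray,
    nulls_latent: list[NullDistribution],
    r_visual: np.ndarray | None = None,
    nulls_visual: list[NullDistribution] | None = None,
    frac: float = 0.95,
) -> dict[str, np.ndarray]:
    """Flag channels whose geometry matches the estimated latent space.

    A channel is selected for the latent space when (1) its latent-template
    correlation exceeds at least ``frac`` of the null correlations and
    (2) it exceeds the channel's correlation with the *exact* latent space.
    Visual-space selection applies criterion (1) only.
    """
    r_latent = np.asarray(r_latent, dtype=float)
    r_exact = np.asarray(r_exact, dtype=float)
    n_perm = len(nulls_latent[0].correlations)
    need = int(np.ceil(frac * n_perm))
    exceed = np.array([nd.exceed_count(r) for nd, r in zip(nulls_latent, r_latent)])
    selected_latent = (exceed >= need) & (r_latent > r_exact)
    out = {
        "r_latent": r_latent,
        "r_exact": r_exact,
        "null_exceed_count": exceed,
        "selected_latent": selected_latent,
    }
    if r_visual is not None and nulls_visual is not None:
        r_visual = np.asarray(r_visual, dtype=float)
        exceed_v = np.array(
            [nd.exceed_count(r) for nd, r in zip(nulls_visual, r_visual)]
        )
        out["r_visual"] = r_visual
        out["null_exceed_count_visual"] = exceed_v
        out["selected_visual"] = exceed_v >= need
    return out


def contact_selection(
    e: EpochArray,
    latent: DissimilarityMatrix,
    exact: DissimilarityMatrix,
    visual: DissimilarityMatrix | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Run the full per-channel selection: RDMs, nulls, and criteria."""
    rng = np.random.default_rng(seed)
    templates = {"latent": latent}
    if visual is not None:
        templates["visual"] = visual
    r_latent, r_exact, r_visual = [], [], []
    nulls_latent, nulls_visual = [], []
    for ch in range(e.n_channels):
        d = cv_euclidean_rdm(e, channel=ch)
        r_latent.append(template_corr(d, latent))
        r_exact.append(template_corr(d, exact))
        nulls = circular_shift_null(e, templates, n_perm=n_perm, seed=rng, channel=ch)
        nulls_latent.append(nulls["latent"])
        if visual is not None:
            r_visual.append(template_corr(d, visual))
            nulls_visual.append(nulls["visual"])
    return select_contacts(
        np.array(r_latent),
        np.array(r_exact),
        nulls_latent,
        r_visual=np.array(r_visual) if visual is not None else None,
        nulls_visual=nulls_visual if visual is not None else None,
    )


def visual_template(
    positions: np.ndarray | None = None,
    node_to_stimulus: np.ndarray | None = None,
    n_nodes: int = 10,
) -> DissimilarityMatrix:
    """Screen-distance template between the squares highlighting each node.

    ``positions`` are per-stimulus screen coordinates (default: a row of
    ten unit-spaced squares); ``node_to_stimulus`` is the random assignment
    of stimuli to graph nodes (default: identity), so the visual geometry
    need not align with the latent one.
    """
    if positions is None:
        positions = np.stack([np.arange(n_nodes, dtype=float), np.zeros(n_nodes)], axis=1)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] != n_nodes:
        raise ValueError("one coordinate per node required")
    perm = (
        np.arange(n_nodes)
        if node_to_stimulus is None
        else np.asarray(node_to_stimulus, dtype=int)
    )
    pos = positions[perm]
    diff = pos[:, None, :] - pos[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    return DissimilarityMatrix(values=D, polarity="dissimilarity")


def latent_template(A_hat: np.ndarray) -> DissimilarityMatrix:
    """Wrap an estimated latent space as a similarity-polarity template."""
    return DissimilarityMatrix(values=np.asarray(A_hat, dtype=float), polarity="similarity")
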