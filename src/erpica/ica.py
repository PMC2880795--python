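"""Infomax ICA on averaged event-related potentials, and the projector
algebra built on the fitted decomposition.

Model
-----
A multi-channel ERP matrix ``P`` (channels x time) is treated as a
linear, instantaneous mixture of temporally independent sources,
``P = A S``.  An unmixing matrix ``U`` is estimated so that ``S = U P``
has maximally independent rows; the columns of the mixing matrix
``U^-1`` are the component scalp topographies.  For component *i* the
matrix ``F_i = U^-1 U_zi`` (``U_zi`` = ``U`` with all rows but *i*
zeroed) is a channel-space spatial filter: it is idempotent, filters of
distinct components annihilate each other, and the filters sum to the
identity on the subspace the decomposition spans, so
``P = sum_i F_i P`` exactly.

``U`` is estimated with the Bell-Sejnowski Infomax rule: natural
gradient ascent on the joint entropy of logistic-transformed source
estimates, which is the maximum-likelihood estimator for super-Gaussian
sources.  Data are pre-whitened by PCA; when the input is rank
deficient (averaged-referenced data always is, by one dimension) a
square ICA is fitted inside the retained subspace and the topographies
mapped back to channel space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

__all__ = [
    "InfomaxICA",
    "MixingModel",
    "StabilityReport",
    "fit_infomax",
    "spatial_filter",
    "component_timecourse",
    "project_component",
    "explained_power_fraction",
    "split_half_stability",
    "match_topographies",
]


@dataclass
class MixingModel:
    """A fitted linear decomposition of channel-space data.

    U : (K, C) unmixing matrix; row i extracts source i from channel data.
    U_inv : (C, K) mixing matrix; column i is the topography of component i.
    Components are ordered by descending explained power on the fitting
    data, and signs are fixed so the largest-|weight| electrode of each
    topography is positive.
    """

    U: np.ndarray
    U_inv: np.ndarray
    channel_order: tuple[str, ...]
    component_names: tuple[str, ...] = ()
    n_iter: int = 0
    converged: bool = True
    seed: int | None = None
    explained_power: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.U_inv = np.asarray(self.U_inv, dtype=float)
        if self.U.shape[::-1] != self.U_inv.shape:
            raise ValueError("U and U_inv have inconsistent shapes")
        if not self.component_names:
            self.component_names = tuple(f"IC{i + 1}" for i in range(self.n_components))

    @property
    def n_components(self) -> int:
        return self.U.shape[0]

    @property
    def n_channels(self) -> int:
        return self.U.shape[1]

    @property
    def topographies(self) -> np.ndarray:
        return self.U_inv

    def _check_index(self, i: int) -> None:
        if not (0 <= i < self.n_components):
            raise IndexError(f"component index {i} out of range 0..{self.n_components - 1}")

    def _check_data(self, P: np.ndarray) -> np.ndarray:
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[0] != self.n_channels:
            raise ValueError(f"expected a {self.n_channels} x T matrix in model channel order, got {P.shape}")
        return P

    def spatial_filter(self, i: int) -> np.ndarray:
        """F_i = U^-1 U_zi, the rank-1 projector extracting component i."""
        self._check_index(i)
        return np.outer(self.U_inv[:, i], self.U[i, :])

    def timecourse(self, i: int, P: np.ndarray) -> np.ndarray:
        """S_i = (U P)_i, the activation of component i."""
        self._check_index(i)
        return self.U[i, :] @ self._check_data(P)

    def project(self, i: int, P: np.ndarray) -> np.ndarray:
        """P_i = F_i P, the scalp contribution of component i."""
        self._check_index(i)
        P = self._check_data(P)
        return np.outer(self.U_inv[:, i], self.U[i, :] @ P)

    def dominant_channel(self, i: int) -> str:
        """Electrode with the largest absolute topography weight."""
        self._check_index(i)
        return self.channel_order[int(np.argmax(np.abs(self.U_inv[:, i])))]

    def to_dict(self) -> dict:
        return {
            "channel_order": list(self.channel_order),
            "U": self.U.tolist(),
            "U_inv": self.U_inv.tolist(),
            "component_names": list(self.component_names),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixingModel":
        return cls(
            U=np.array(d["U"], dtype=float),
            U_inv=np.array(d["U_inv"], dtype=float),
            channel_order=tuple(d["channel_order"]),
            component_names=tuple(d.get("component_names", ())),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", True)),
            seed=d.get("seed"),
        )


class InfomaxICA(BaseEstimator):
    """Infomax independent component analysis.

    Natural-gradient Bell-Sejnowski rule with the logistic nonlinearity,
    appropriate for super-Gaussian sources such as averaged ERP
    deflections.  Data are centered and PCA-whitened; updates run over
    shuffled mini-batches with the learning rate annealed whenever the
    direction of the weight update turns by more than
    ``anneal_angle_deg``.

    Follows the scikit-learn estimator contract: ``fit`` expects
    ``X`` of shape (n_samples, n_channels) — time points are samples —
    and ``transform`` returns source activations (n_samples,
    n_components).

    Parameters
    ----------
    n_components : int, "rank", or None
        None fits a square model and raises on rank-deficient input,
        advising dimension reduction.  "rank" reduces to the numerical
        rank automatically; an int selects the leading PCA dimensions.
    learning_rate : float
        Initial step size of the natural-gradient updates.
    tol : float
        Stop when the per-pass weight-change norm (relative to ||W||)
        falls below this.
    """

    def __init__(
        self,
        n_components: int | str | None = None,
        max_iter: int = 1024,
        tol: float = 1e-7,
        learning_rate: float = 1e-3,
        anneal_angle_deg: float = 60.0,
        anneal_factor: float = 0.9,
        batch_size: int | None = None,
        random_state: int | None = None,
    ) -> None:
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.learning_rate = learning_rate
        self.anneal_angle_deg = anneal_angle_deg
        self.anneal_factor = anneal_factor
        self.batch_size = batch_size
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "InfomaxICA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_channels)")
        n_samples, n_ch = X.shape
        if n_samples < n_ch:
            raise ValueError("need at least as many time samples as channels")

        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_

        # PCA whitening; rank from relative singular-value threshold
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10)) if s[0] > 0 else 0
        if rank == 0:
            raise ValueError("input data are identically zero")
        if self.n_components is None:
            if rank < n_ch:
                raise ValueError(
                    f"data matrix is rank deficient (rank {rank} < {n_ch} channels); "
                    "reduce dimension first, e.g. n_components='rank'"
                )
            k = n_ch
        elif self.n_components == "rank":
            k = rank
        else:
            k = int(self.n_components)
            if not (1 <= k <= rank):
                raise ValueError(f"n_components={k} outside 1..rank={rank}")
        # rows of `whiten` map centered channel data to unit-variance PCs
        whiten = Vt[:k] * (np.sqrt(n_samples) / s[:k])[:, None]
        Z = Xc @ whiten.T  # (n_samples, k), identity covariance

        W, n_iter, converged = self._infomax_loop(Z.T)

        U = W @ whiten  # (k, n_ch): channels -> sources
        U_inv = np.linalg.pinv(U)

        # order by descending explained power of each rank-1 back-projection
        S = U @ Xc.T
        power = (np.linalg.norm(U_inv, axis=0) ** 2) * np.sum(S**2, axis=1)
        order = np.argsort(-power)
        U, U_inv, power = U[order], U_inv[:, order], power[order]
        # sign convention: largest-|weight| electrode of each topography positive
        flip = np.where(U_inv[np.argmax(np.abs(U_inv), axis=0), np.arange(k)] < 0, -1.0, 1.0)
        U *= flip[:, None]
        U_inv *= flip[None, :]

        self.components_ = U
        self.mixing_ = U_inv
        self.explained_power_ = power
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def _infomax_loop(self, Z: np.ndarray) -> tuple[np.ndarray, int, bool]:
        """Mini-batch natural-gradient ascent; Z is (k, T) whitened."""
        k, T = Z.shape
        rng = np.random.default_rng(self.random_state)
        # random orthogonal start so distinct seeds explore distinct bases
        Q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        W = Q
        lr = self.learning_rate
        block = self.batch_size or max(8, min(512, int(np.ceil(5 * np.log(T)))))
        I = np.eye(k)
        delta_prev = None
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            W_old = W.copy()
            perm = rng.permutation(T)
            for start in range(0, T - block + 1, block):
                Yb = W @ Z[:, perm[start:start + block]]
                g = 1.0 / (1.0 + np.exp(-Yb))
                W = W + lr * ((I + (1.0 - 2.0 * g) @ Yb.T / Yb.shape[1]) @ W)
                if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                    # diverged: halve the rate and restart from orthogonal
                    lr *= 0.5
                    Q, _ = np.linalg.qr(rng.standard_normal((k, k)))
                    W = Q
                    delta_prev = None
                    break
            delta = (W - W_old).ravel()
            change = np.linalg.norm(delta) / max(np.linalg.norm(W), 1e-30)
            if delta_prev is not None:
                denom = np.linalg.norm(delta) * np.linalg.norm(delta_prev)
                if denom > 0:
                    cosang = np.clip(delta @ delta_prev / denom, -1.0, 1.0)
                    if np.degrees(np.arccos(cosang)) > self.anneal_angle_deg:
                        lr *= self.anneal_factor
            delta_prev = delta
            if change < self.tol:
                converged = True
                break
        return W, n_iter, converged

    # -- sklearn surface --------------------------------------------------

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, S: np.ndarray) -> np.ndarray:
        return S @ self.mixing_.T + self.mean_

    def to_mixing_model(self, channel_order: tuple[str, ...], component_names: tuple[str, ...] = ()) -> MixingModel:
        return MixingModel(
            U=self.components_.copy(),
            U_inv=self.mixing_.copy(),
            channel_order=tuple(channel_order),
            component_names=tuple(component_names),
            n_iter=self.n_iter_,
            converged=self.converged_,
            seed=self.random_state,
            explained_power=self.explained_power_.copy(),
        )


# ---------------------------------------------------------------------------
# module-level operations on channels x time matrices
# ---------------------------------------------------------------------------

def fit_infomax(
    P: np.ndarray,
    max_iter: int = 1024,
    tol: float = 1e-7,
    seed: int | None = None,
    n_components: int | str | None = None,
    channel_order: tuple[str, ...] | None = None,
    **kwargs,
) -> MixingModel:
    """Fit Infomax ICA to a channels x time ERP matrix."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("P must be channels x time")
    if channel_order is None:
        channel_order = tuple(f"ch{i}" for i in range(P.shape[0]))
    est = InfomaxICA(
        n_components=n_components, max_iter=max_iter, tol=tol, random_state=seed, **kwargs
    ).fit(P.T)
    return est.to_mixing_model(channel_order)


def spatial_filter(model: MixingModel, i: int) -> np.ndarray:
    return model.spatial_filter(i)


def component_timecourse(model: MixingModel, i: int, P: np.ndarray) -> np.ndarray:
    return model.timecourse(i, P)


def project_component(model: MixingModel, i: int, P: np.ndarray) -> np.ndarray:
    return model.project(i, P)


def explained_power_fraction(model: MixingModel, indices, P: np.ndarray) -> float:
    """Power of the summed back-projection of `indices`, as a fraction of
    the total power of P (sum of squares over channels and time)."""
    P = model._check_data(P)
    total = float(np.sum(P**2))
    if total == 0.0:
        raise ValueError("P carries zero power")
    indices = sorted(set(indices))
    if not indices:
        return 0.0
    recon = np.zeros_like(P)
    for i in indices:
        recon += model.project(i, P)
    return float(np.sum(recon**2) / total)


# ---------------------------------------------------------------------------
# topography matching and split-half stability
# ---------------------------------------------------------------------------

def _abs_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between every column pair of A and B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.linalg.norm(Ac, axis=0)
    nb = np.linalg.norm(Bc, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return np.abs((Ac / na).T @ (Bc / nb))


def match_topographies(A: np.ndarray, B: np.ndarray, method: str = "greedy") -> list[tuple[int, int, float]]:
    """Pair columns of two topography matrices by |correlation|.

    'greedy' repeatedly takes the best remaining pair; 'hungarian'
    maximizes the summed |correlation| globally.  Returns
    (index in A, index in B, |corr|) triples, one per matched pair.
    """
    C = _abs_corr_matrix(A, B)
    pairs: list[tuple[int, int, float]] = []
    if method == "hungarian":
        rows, cols = linear_sum_assignment(-C)
        pairs = [(int(r), int(c), float(C[r, c])) for r, c in zip(rows, cols)]
    elif method == "greedy":
        C = C.copy()
        n = min(C.shape)
        for _ in range(n):
            r, c = np.unravel_index(np.argmax(C), C.shape)
            pairs.append((int(r), int(c), float(C[r, c])))
            C[r, :] = -1.0
            C[:, c] = -1.0
    else:
        raise ValueError("method must be 'greedy' or 'hungarian'")
    pairs.sort(key=lambda p: p[0])
    return pairs


@dataclass
class StabilityReport:
    """Split-half reproducibility of the decomposition."""

    matched_pairs: list  # (component in half A, component in half B, |corr|)
    mean_abs_correlation: float
    split_seed: int
    halves: tuple = field(default=(), repr=False)  # subject-id tuples


def _grand_average_matrix(dataset, subject_ids, conditions) -> np.ndarray:
    """Mean over subjects of the condition-concatenated ERP matrices."""
    mats = []
    for sid in subject_ids:
        mats.append(np.hstack([dataset.get(sid, c).data for c in conditions]))
    return np.mean(np.stack(mats), axis=0)


def split_half_stability(
    dataset,
    ica_params: dict | None = None,
    seed: int = 0,
    halves: tuple | None = None,
) -> StabilityReport:
    """Fit ICA on the grand averages of two random subject halves and
    match components across halves by |topography correlation|.

    Subjects are split after sorting ids, so the report is invariant to
    the order subjects appear in the dataset.  Pass ``halves`` to
    override the split (e.g. the duplicate-halves control).
    """
    ica_params = dict(ica_params or {})
    ica_params.setdefault("n_components", "rank")
    ica_params.setdefault("seed", 0)
    conditions = sorted(dataset.conditions)  # fixed order: invariant to subject order
    if halves is None:
        ids = sorted(dataset.subject_ids)
        if len(ids) < 4:
            raise ValueError("need at least 4 subjects for a split-half analysis")
        perm = np.random.default_rng(seed).permutation(len(ids))
        half = len(ids) // 2
        halves = (
            tuple(ids[i] for i in sorted(perm[:half])),
            tuple(ids[i] for i in sorted(perm[half:])),
        )
    models = []
    for ids_half in halves:
        G = _grand_average_matrix(dataset, ids_half, conditions)
        models.append(fit_infomax(G, **ica_params))
    pairs = match_topographies(models[0].topographies, models[1].topographies, method="greedy")
    mean_corr = float(np.mean([p[2] for p in pairs])) if pairs else float("nan")
    return StabilityReport(
        matched_pairs=pairs,
        mean_abs_correlation=mean_corr,
        split_seed=seed,
        halves=halves,
    )
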