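"""Classical i-vector speaker embeddings.

The total-variability model writes an utterance's GMM mean supervector as

    M = m + T w,        w ~ N(0, I)

where m is the UBM mean supervector, T is the (C*F) x R total-variability
matrix and w the latent factor whose MAP point estimate is the i-vector.
Given zeroth/first-order Baum-Welch statistics (N_c, F_c) accumulated under
a diagonal-covariance UBM, the posterior of w is Gaussian with

    L      = I + T' Sigma^-1 N T          (precision)
    E[w]   = L^-1 T' Sigma^-1 Fc~         (the i-vector)

with N the diagonal expansion of the per-component counts and Fc~ the stacked
centered first-order statistics. T is trained by EM over a collection of
utterance statistics; each M-step solves an independent RxR system per
mixture component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from voxscreen.errors import ArgumentError, DegenerateUtteranceError
from voxscreen.features import FrameFeatures
from voxscreen.types import SpeakerEmbedding

DEFAULT_COMPONENTS = 256
DEFAULT_RANK = 256
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class UBM:
    """Diagonal-covariance GMM universal background model."""

    weights: np.ndarray  # (C,)
    means: np.ndarray  # (C, F)
    variances: np.ndarray  # (C, F), diagonal
    log_likelihoods: list = field(default_factory=list)  # per-EM-iteration totals

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ArgumentError("UBM weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ArgumentError("UBM variances must be positive")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def supervector(self) -> np.ndarray:
        """m = concat(mu_1 .. mu_C), length C*F."""
        return self.means.ravel()

    def log_prob(self, x: np.ndarray) -> np.ndarray:
        """Per-frame, per-component weighted log densities, (T, C)."""
        x = np.atleast_2d(x)
        const = -0.5 * (self.dim * _LOG2PI + np.log(self.variances).sum(axis=1))
        # (T, C) mahalanobis for diagonal covariances
        maha = (
            np.square(x).dot((1.0 / self.variances).T)
            - 2.0 * x.dot((self.means / self.variances).T)
            + np.square(self.means / np.sqrt(self.variances)).sum(axis=1)
        )
        return np.log(self.weights) + const - 0.5 * maha

    def responsibilities(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        lp = self.log_prob(x)
        tot = logsumexp(lp, axis=1)
        return np.exp(lp - tot[:, None]), float(tot.sum())


@dataclass
class BaumWelchStats:
    """Zeroth- and centered first-order sufficient statistics of one utterance."""

    n: np.ndarray  # (C,) soft counts
    f: np.ndarray  # (C, F) responsibility-weighted centered sums
    utt_id: str = ""

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        self.f = np.atleast_2d(np.asarray(self.f, dtype=np.float64))
        if np.any(self.n < -1e-9):
            raise ArgumentError("zeroth-order stats must be non-negative")

    @property
    def total_frames(self) -> float:
        return float(self.n.sum())


@dataclass
class TotalVariabilityModel:
    """Low-rank total-variability matrix tied to its UBM."""

    T: np.ndarray  # (C*F, R)
    ubm: UBM

    def __post_init__(self) -> None:
        self.T = np.atleast_2d(np.asarray(self.T, dtype=np.float64))
        if not np.all(np.isfinite(self.T)):
            raise ArgumentError("T contains non-finite values")
        if self.T.shape[0] != self.ubm.n_components * self.ubm.dim:
            raise ArgumentError("T row count must be C*F")
        if self.rank < 1:
            raise ArgumentError("rank must be >= 1")

    @property
    def rank(self) -> int:
        return self.T.shape[1]


def train_ubm(
    features: list[FrameFeatures] | list[np.ndarray],
    n_components: int = DEFAULT_COMPONENTS,
    iters: int = 10,
    seed: int = 0,
    variance_floor_frac: float = 1e-4,
) -> UBM:
    """EM training of the diagonal GMM from a seeded k-means initialization.

    The per-iteration total log-likelihood trajectory is recorded on the
    returned model and is non-decreasing (EM guarantee). Variances are floored
    at ``variance_floor_frac`` of the global per-dimension variance.
    """
    mats = [f.data if isinstance(f, FrameFeatures) else np.atleast_2d(f) for f in features]
    if not mats:
        raise ArgumentError("no features supplied")
    x = np.vstack(mats)
    if x.shape[0] < 10 * n_components:
        raise ArgumentError(
            f"need >= {10 * n_components} frames to train {n_components} components, got {x.shape[0]}"
        )
    floor = np.maximum(variance_floor_frac * x.var(axis=0), 1e-12)

    km = KMeans(n_clusters=n_components, n_init=3, random_state=seed).fit(x)
    means = km.cluster_centers_.copy()
    counts = np.bincount(km.labels_, minlength=n_components).astype(np.float64)
    weights = np.maximum(counts, 1.0)
    weights /= weights.sum()
    variances = np.empty_like(means)
    for c in range(n_components):
        pts = x[km.labels_ == c]
        variances[c] = pts.var(axis=0) if len(pts) > 1 else x.var(axis=0)
    variances = np.maximum(variances, floor)

    ubm = UBM(weights=weights, means=means, variances=variances)
    for _ in range(iters):
        gamma, ll = ubm.responsibilities(x)
        ubm.log_likelihoods.append(ll)
        nk = gamma.sum(axis=0)
        safe = np.maximum(nk, 1e-10)[:, None]
        means = gamma.T.dot(x) / safe
        variances = gamma.T.dot(np.square(x)) / safe - np.square(means)
        variances = np.maximum(variances, floor)
        weights = np.maximum(nk, 1e-10)
        weights /= weights.sum()
        hist = ubm.log_likelihoods
        ubm = UBM(weights=weights, means=means, variances=variances, log_likelihoods=hist)
    _, ll = ubm.responsibilities(x)
    ubm.log_likelihoods.append(ll)
    return ubm


def accumulate_stats(ubm: UBM, features: FrameFeatures | np.ndarray) -> BaumWelchStats:
    """Baum-Welch statistics of one utterance under the UBM.

    N_c = sum_t gamma_t(c); F_c = sum_t gamma_t(c) (x_t - mu_c).
    """
    x = features.data if isinstance(features, FrameFeatures) else np.atleast_2d(features)
    if x.shape[1] != ubm.dim:
        raise ArgumentError(f"feature dim {x.shape[1]} != UBM dim {ubm.dim}")
    gamma, _ = ubm.responsibilities(x)
    n = gamma.sum(axis=0)
    f = gamma.T.dot(x) - n[:, None] * ubm.means
    utt_id = features.utt_id if isinstance(features, FrameFeatures) else ""
    return BaumWelchStats(n=n, f=f, utt_id=utt_id)


def _posterior(model: TotalVariabilityModel, stats: BaumWelchStats) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, precision L) of w given one utterance's statistics."""
    C, F = model.ubm.n_components, model.ubm.dim
    R = model.rank
    Tm = model.T.reshape(C, F, R)
    inv_var = 1.0 / model.ubm.variances  # (C, F)
    L = np.eye(R)
    b = np.zeros(R)
    for c in range(C):
        Tc_w = Tm[c] * inv_var[c][:, None]  # Sigma_c^-1 T_c
        L += stats.n[c] * Tm[c].T.dot(Tc_w)
        b += Tc_w.T.dot(stats.f[c])
    mean = np.linalg.solve(L, b)
    return mean, L


def train_total_variability(
    stats: list[BaumWelchStats],
    rank: int = DEFAULT_RANK,
    iters: int = 5,
    seed: int = 0,
    ubm: UBM | None = None,
) -> TotalVariabilityModel:
    """EM estimation of the total-variability matrix T.

    E-step: per-utterance Gaussian posterior of w. M-step: per-component
    weighted least squares over the accumulated moments. Initialization is
    random Gaussian scaled by the average feature standard deviation.
    """
    if not stats:
        raise ArgumentError("empty statistics collection")
    if ubm is None:
        raise ArgumentError("a UBM must be provided")
    C, F = ubm.n_components, ubm.dim
    rng = np.random.default_rng(seed)
    scale = float(np.sqrt(ubm.variances.mean()))
    T0 = rng.normal(0.0, 0.1 * scale, size=(C * F, rank))
    model = TotalVariabilityModel(T=T0, ubm=ubm)
    for _ in range(iters):
        # accumulators: per component, A_c = sum_u N_uc E[w w'], B_c = sum_u F_uc x E[w]'
        A = np.zeros((C, rank, rank))
        B = np.zeros((C, F, rank))
        for st in stats:
            mean, L = _posterior(model, st)
            cov = np.linalg.inv(L)
            second = cov + np.outer(mean, mean)
            A += st.n[:, None, None] * second[None, :, :]
            B += st.f[:, :, None] * mean[None, None, :]
        Tnew = np.empty((C, F, rank))
        for c in range(C):
            Tnew[c] = np.linalg.solve(A[c] + 1e-8 * np.eye(rank), B[c].T).T
        model = TotalVariabilityModel(T=Tnew.reshape(C * F, rank), ubm=ubm)
    return model


def tv_auxiliary(model: TotalVariabilityModel, stats: list[BaumWelchStats]) -> float:
    """Expected complete-data log-likelihood terms that depend on T.

    Used to verify EM monotonicity: sum_u E[w]' T' Sigma^-1 F_u
    - 0.5 sum_u tr(Sigma^-1 N_u T E[ww'] T').
    """
    C, F = model.ubm.n_components, model.ubm.dim
    Tm = model.T.reshape(C, F, model.rank)
    inv_var = 1.0 / model.ubm.variances
    total = 0.0
    for st in stats:
        mean, L = _posterior(model, st)
        second = np.linalg.inv(L) + np.outer(mean, mean)
        for c in range(C):
            Tc_w = Tm[c] * inv_var[c][:, None]
            total += mean.dot(Tc_w.T.dot(st.f[c]))
            total -= 0.5 * st.n[c] * np.trace(Tm[c].T.dot(Tc_w).dot(second))
    return float(total)


def extract_ivector(
    model: TotalVariabilityModel,
    stats: BaumWelchStats,
    subject_id: str = "",
    task_id: int | None = None,
    feature_kind: str = "mfcc",
    length_norm: bool = False,
) -> SpeakerEmbedding:
    """MAP point estimate of the latent factor w (the i-vector)."""
    if stats.total_frames <= 0:
        raise DegenerateUtteranceError("zero total occupancy; cannot extract i-vector")
    mean, _ = _posterior(model, stats)
    if length_norm:
        norm = np.linalg.norm(mean)
        if norm > 0:
            mean = mean / norm
    from voxscreen.types import embedding_tag

    return SpeakerEmbedding(
        vector=mean, subject_id=subject_id, task_id=task_id, tag=embedding_tag("ivector", feature_kind)
    )


def save_ivector_model(path: str | Path, model: TotalVariabilityModel, fingerprint: str = "") -> None:
    np.savez_compressed(
        path,
        T=model.T,
        weights=model.ubm.weights,
        means=model.ubm.means,
        variances=model.ubm.variances,
        fingerprint=np.array(fingerprint),
    )


def load_ivector_model(path: str | Path) -> TotalVariabilityModel:
    with np.load(path, allow_pickle=False) as z:
        ubm = UBM(weights=z["weights"], means=z["means"], variances=z["variances"])
        return TotalVariabilityModel(T=z["T"], ubm=ubm)
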