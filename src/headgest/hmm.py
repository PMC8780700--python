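"""Gaussian-emission hidden Markov model classifier for head gestures.

A functional reach is modelled as a sequence of stages: a four-state HMM
with multivariate-Gaussian emissions is trained on segments labelled valid,
using k-means clustering to initialize the per-state emission densities and
Baum-Welch (EM) to estimate the transition matrix ``A``, the initial
distribution ``pi`` and (by default) the emissions.  Segments are described
by one of three feature vectors: reference-relative position (P), velocity
(V), or both (PV).

Classification of a new segment uses the joint statistic
``psi = [l_s, n_s]`` — the segment log-likelihood under the trained model
together with the segment length, whose influence is absorbed this way
rather than by length-normalizing ``l_s``.  A bivariate normal null for
``psi`` is fitted on the valid training segments; a segment is accepted
when the squared Mahalanobis distance of its ``psi`` falls inside the
chi-square(2 df) quantile at the chosen confidence level.  The negated
distance serves as a continuous score for ROC sweeps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2
from sklearn.cluster import KMeans

from .segmentation import Segment

__all__ = [
    "FEATURE_KINDS",
    "GaussianHmm",
    "PsiNull",
    "HmmClassifier",
    "extract_features",
    "init_emissions_kmeans",
    "baum_welch",
    "log_likelihood",
    "sample_hmm",
    "fit_psi_null",
    "mahalanobis_score",
    "classify_segment",
    "train_hmm_classifier",
]

FEATURE_KINDS = {"P": 2, "V": 2, "PV": 4}

N_STATES = 4
COV_FLOOR = 1e-4  # diagonal floor on emission covariances (feature units^2)
MAX_ITER = 200
TOL = 1e-4
KMEANS_RESTARTS = 10

# every baum_welch call appends its log-likelihood history here; tests use it
# to audit EM monotonicity across all training runs they trigger
TRAINING_HISTORY_LOG: list[np.ndarray] = []


def extract_features(
    segment: Segment,
    kind: str,
    reference_xy: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Observation matrix (n_s x dim) for a segment.

    P rows are reference-relative positions ``(x - x_h0, y - y_h0)`` in px,
    V rows are velocities ``(vx, vy)`` in px/s, PV concatenates both.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}; expected one of {sorted(FEATURE_KINDS)}")
    if segment.n_s == 0 or len(segment.x) == 0:
        raise ValueError("empty segment")
    rx, ry = reference_xy
    pos = np.column_stack([segment.x - rx, segment.y - ry])
    vel = np.column_stack([segment.vx, segment.vy])
    if kind == "P":
        return pos
    if kind == "V":
        return vel
    return np.hstack([pos, vel])


@dataclass
class GaussianHmm:
    """HMM with per-state multivariate Gaussian emissions.

    ``transmat`` rows sum to one; zero entries encode the topology (zeros
    are preserved by Baum-Welch re-estimation).
    """

    startprob: np.ndarray          # (K,)
    transmat: np.ndarray           # (K, K)
    means: np.ndarray              # (K, d)
    covars: np.ndarray             # (K, d, d)
    feature_kind: str = "PV"

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, float)
        self.transmat = np.asarray(self.transmat, float)
        self.means = np.asarray(self.means, float)
        self.covars = np.asarray(self.covars, float)
        K = len(self.startprob)
        if self.transmat.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.transmat < 0) or not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")
        for c in self.covars:
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError("emission covariances must be symmetric")
            np.linalg.cholesky(c)  # raises if not positive definite

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_dict(self) -> dict:
        return {
            "feature_kind": self.feature_kind,
            "pi": self.startprob.tolist(),
            "A": self.transmat.tolist(),
            "emissions": [
                {"mean": m.tolist(), "cov": c.tolist()}
                for m, c in zip(self.means, self.covars)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHmm":
        return cls(
            startprob=np.array(d["pi"], float),
            transmat=np.array(d["A"], float),
            means=np.array([e["mean"] for e in d["emissions"]], float),
            covars=np.array([e["cov"] for e in d["emissions"]], float),
            feature_kind=d.get("feature_kind", "PV"),
        )


# ---------------------------------------------------------------------------
# Likelihood computation


def _log_gaussian(obs: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(obs; mean, cov) for each row of obs, via Cholesky."""
    d = obs.shape[1]
    L = np.linalg.cholesky(cov)
    diff = obs - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _log_obs_matrix(model: GaussianHmm, obs: np.ndarray) -> np.ndarray:
    """(T, K) matrix of per-state emission log-densities."""
    return np.column_stack(
        [_log_gaussian(obs, model.means[k], model.covars[k]) for k in range(model.n_states)]
    )


def log_likelihood(model: GaussianHmm, obs: np.ndarray) -> float:
    """Segment log-likelihood l_s = log P(obs | model), log-space forward pass."""
    obs = np.asarray(obs, float)
    if obs.ndim != 2 or obs.shape[1] != model.n_features:
        raise ValueError(
            f"observation dimension {obs.shape} does not match model ({model.n_features} features)"
        )
    if len(obs) == 0:
        raise ValueError("empty observation sequence")
    logB = _log_obs_matrix(model, obs)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.startprob)
        logA = np.log(model.transmat)
    la = logpi + logB[0]
    for tt in range(1, len(obs)):
        la = logsumexp(la[:, None] + logA, axis=0) + logB[tt]
    return float(logsumexp(la))


def sample_hmm(model: GaussianHmm, length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one observation sequence of the given length from the model."""
    K = model.n_states
    states = np.empty(length, int)
    states[0] = rng.choice(K, p=model.startprob)
    for tt in range(1, length):
        states[tt] = rng.choice(K, p=model.transmat[states[tt - 1]])
    out = np.empty((length, model.n_features))
    for tt, s in enumerate(states):
        out[tt] = rng.multivariate_normal(model.means[s], model.covars[s])
    return out


# ---------------------------------------------------------------------------
# Initialization


def _left_right_transitions(K: int) -> tuple[np.ndarray, np.ndarray]:
    A = np.zeros((K, K))
    for i in range(K - 1):
        A[i, i] = 0.8
        A[i, i + 1] = 0.2
    A[K - 1, K - 1] = 1.0
    pi = np.full(K, 0.05 / max(K - 1, 1))
    pi[0] = 0.95
    if K == 1:
        pi = np.array([1.0])
    return A, pi


def _ergodic_transitions(K: int) -> tuple[np.ndarray, np.ndarray]:
    A = np.full((K, K), 0.2 / max(K - 1, 1)) + np.eye(K) * (0.8 - 0.2 / max(K - 1, 1))
    if K == 1:
        A = np.array([[1.0]])
    A /= A.sum(axis=1, keepdims=True)
    return A, np.full(K, 1.0 / K)


def init_emissions_kmeans(
    sequences: Sequence[np.ndarray],
    n_states: int = N_STATES,
    seed: int = 0,
    topology: str = "left_right",
    n_init: int = KMEANS_RESTARTS,
    feature_kind: str = "PV",
    cov_floor: float = COV_FLOOR,
) -> GaussianHmm:
    """Initial HMM from k-means clustering of the pooled observations.

    Each cluster's sample mean and covariance seed one state's emission
    density.  States are ordered by the clusters' mean relative
    time-of-occurrence within their segments, so a left-to-right topology
    starts at the earliest movement stage.
    """
    seqs = [np.asarray(s, float) for s in sequences]
    pooled = np.vstack(seqs)
    d = pooled.shape[1]
    if len(pooled) < n_states * d:
        raise ValueError("too few pooled observations to initialize emissions")
    if len(np.unique(pooled, axis=0)) < n_states:
        raise ValueError("fewer distinct observation points than clusters")
    km = KMeans(n_clusters=n_states, n_init=n_init, random_state=seed)
    labels = km.fit_predict(pooled)

    rel_time = np.concatenate(
        [np.linspace(0.0, 1.0, len(s)) if len(s) > 1 else np.array([0.5]) for s in seqs]
    )
    order = np.argsort(
        [rel_time[labels == k].mean() if np.any(labels == k) else 1.0 for k in range(n_states)],
        kind="stable",
    )

    means = np.empty((n_states, d))
    covars = np.empty((n_states, d, d))
    for new_k, k in enumerate(order):
        pts = pooled[labels == k]
        means[new_k] = pts.mean(axis=0)
        cov = np.cov(pts.T, bias=True).reshape(d, d) if len(pts) > 1 else np.zeros((d, d))
        covars[new_k] = _floor_cov(cov, cov_floor)

    if topology == "left_right":
        A, pi = _left_right_transitions(n_states)
    elif topology == "ergodic":
        A, pi = _ergodic_transitions(n_states)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return GaussianHmm(startprob=pi, transmat=A, means=means, covars=covars, feature_kind=feature_kind)


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    """Repair a covariance to be positive definite with eigenvalues >= floor."""
    cov = 0.5 * (cov + cov.T)
    evals = np.linalg.eigvalsh(cov)
    if evals.min() < floor:
        cov = cov + (floor - min(evals.min(), 0.0)) * np.eye(cov.shape[0])
        evals = np.linalg.eigvalsh(cov)
        if evals.min() < floor * (1 - 1e-9):
            cov = cov + (floor - evals.min()) * np.eye(cov.shape[0])
    return cov


# ---------------------------------------------------------------------------
# Baum-Welch (EM)


def _scaled_forward_backward(pi, A, logB, mask):
    """Scaled forward/backward over right-padded sequences.

    ``logB`` is (N, T, K) emission log-densities, ``mask`` (N, T) marks real
    (non-padding) samples.  Uses the classic per-step scaling c_t instead of
    log-space recursions, with the per-sample max of logB factored out so
    emission densities never underflow.  Returns scaled alpha/beta, the
    scale factors, the rescaled emission matrix, per-sequence
    log-likelihoods and the posterior state probabilities gamma
    (zero at padded positions).
    """
    N, T, K = logB.shape
    m = logB.max(axis=2)
    Bt = np.exp(logB - m[:, :, None])
    Bt[~mask] = 1.0
    m = np.where(mask, m, 0.0)

    ahat = np.empty((N, T, K))
    c = np.ones((N, T))
    a0 = pi[None, :] * Bt[:, 0]
    c[:, 0] = a0.sum(axis=1)
    ahat[:, 0] = a0 / c[:, 0, None]
    for tt in range(1, T):
        a = (ahat[:, tt - 1] @ A) * Bt[:, tt]
        ct = a.sum(axis=1)
        valid = mask[:, tt]
        safe = np.where(ct > 0, ct, 1.0)
        c[:, tt] = np.where(valid, safe, 1.0)
        ahat[:, tt] = np.where(valid[:, None], a / safe[:, None], ahat[:, tt - 1])
    ll = (np.log(c) * mask).sum(axis=1) + (m * mask).sum(axis=1)

    bhat = np.empty((N, T, K))
    bhat[:, T - 1] = 1.0
    for tt in range(T - 2, -1, -1):
        nxt = (Bt[:, tt + 1] * bhat[:, tt + 1]) @ A.T
        bt = nxt / c[:, tt + 1, None]
        valid_next = mask[:, tt + 1]
        bhat[:, tt] = np.where(valid_next[:, None], bt, bhat[:, tt + 1])

    gamma = ahat * bhat
    gamma[~mask] = 0.0
    norm = gamma.sum(axis=2, keepdims=True)
    np.divide(gamma, norm, out=gamma, where=norm > 0)
    return ahat, bhat, c, Bt, ll, gamma


def baum_welch(
    sequences: Sequence[np.ndarray],
    init: GaussianHmm,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    update_emissions: bool = True,
    cov_floor: float = COV_FLOOR,
) -> tuple[GaussianHmm, np.ndarray]:
    """Fit the HMM by EM over multiple observation sequences.

    Zero entries of the initial transition matrix are structural (a
    left-to-right topology stays left-to-right).  With
    ``update_emissions=False`` the k-means emissions are frozen and only
    ``A`` and ``pi`` are re-estimated.  Returns the fitted model and the
    history of total log-likelihood per EM iteration, which is
    non-decreasing up to the covariance-floor regularization.
    """
    seqs = [np.asarray(s, float) for s in sequences]
    if not seqs or any(len(s) < 1 for s in seqs):
        raise ValueError("need at least one non-empty observation sequence")
    K, d = init.n_states, init.n_features

    pi = init.startprob.copy()
    A = init.transmat.copy()
    means = init.means.copy()
    covars = init.covars.copy()

    # right-pad to a common length; the mask keeps padding out of the E-step
    N = len(seqs)
    lengths = np.array([len(s) for s in seqs])
    T = int(lengths.max())
    obs = np.zeros((N, T, d))
    mask = np.zeros((N, T), bool)
    for i, s in enumerate(seqs):
        obs[i, : len(s)] = s
        mask[i, : len(s)] = True
    flat = obs.reshape(N * T, d)

    history = []
    prev_ll = -np.inf
    model = GaussianHmm(pi, A, means, covars, feature_kind=init.feature_kind)
    for _ in range(max_iter):
        logB = np.stack(
            [_log_gaussian(flat, means[k], covars[k]).reshape(N, T) for k in range(K)],
            axis=2,
        )
        ahat, bhat, c, Bt, ll, gamma = _scaled_forward_backward(pi, A, logB, mask)
        total_ll = float(ll.sum())
        pi_acc = gamma[:, 0].sum(axis=0)
        if T > 1:
            w = (Bt[:, 1:] * bhat[:, 1:] / c[:, 1:, None]) * mask[:, 1:, None]
            xi_acc = A * np.einsum("nti,ntj->ij", ahat[:, :-1], w)
        else:
            xi_acc = np.zeros((K, K))
        g2 = gamma.reshape(N * T, K)
        gw = g2.sum(axis=0)
        gx = g2.T @ flat
        gxx = np.einsum("nk,nd,ne->kde", g2, flat, flat)
        if not (
            np.isfinite(total_ll)
            and np.all(np.isfinite(pi_acc))
            and np.all(np.isfinite(xi_acc))
            and np.all(np.isfinite(gx))
        ):
            # numerical collapse (near-singular emission after responsibility
            # starvation); keep the last valid model
            warnings.warn("Baum-Welch stopped early: non-finite E-step statistics")
            break
        history.append(total_ll)
        if total_ll - prev_ll < tol and len(history) > 1:
            break
        prev_ll = total_ll

        # M-step
        pi = pi_acc / N
        pi = pi / pi.sum()
        rows = xi_acc.sum(axis=1)
        newA = A.copy()
        nz = rows > 0
        newA[nz] = xi_acc[nz] / rows[nz, None]
        A = newA
        if update_emissions:
            for k in range(K):
                if gw[k] <= 1e-6:
                    continue  # dead state: keep previous parameters
                mu = gx[k] / gw[k]
                cov = gxx[k] / gw[k] - np.outer(mu, mu)
                if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(cov))):
                    continue
                floored = _floor_cov(cov, cov_floor)
                if not np.allclose(floored, cov, atol=1e-12):
                    warnings.warn("emission covariance floored to remain positive definite")
                means[k] = mu
                covars[k] = floored
        model = GaussianHmm(pi, A, means.copy(), covars.copy(), feature_kind=init.feature_kind)
    history_arr = np.asarray(history)
    TRAINING_HISTORY_LOG.append(history_arr)
    return model, history_arr


# ---------------------------------------------------------------------------
# psi statistic and Mahalanobis classification


@dataclass
class PsiNull:
    """Normal null of psi = [l_s, n_s] over valid training segments."""

    mu: np.ndarray       # (2,)
    sigma: np.ndarray    # (2, 2)
    confidence: float = 0.95

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        np.linalg.cholesky(self.sigma)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "confidence": self.confidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PsiNull":
        return cls(
            mu=np.array(d["mu"], float),
            sigma=np.array(d["sigma"], float),
            confidence=float(d.get("confidence", 0.95)),
        )


def fit_psi_null(
    psis: np.ndarray | Sequence[Sequence[float]],
    confidence: float = 0.95,
    ridge: float = 1e-6,
) -> PsiNull:
    """Sample mean/covariance of psi over valid segments (>= 3 required).

    A singular covariance (e.g. identical psi values) is regularized by a
    diagonal ridge, with a warning.
    """
    psis = np.asarray(psis, float)
    if psis.ndim != 2 or psis.shape[1] != 2:
        raise ValueError("psis must be an (n, 2) array of [l_s, n_s] rows")
    finite = np.all(np.isfinite(psis), axis=1)
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} non-finite psi rows before fitting the null")
        psis = psis[finite]
    if len(psis) < 3:
        raise ValueError("need at least 3 valid segments to fit the psi null")
    mu = psis.mean(axis=0)
    sigma = np.cov(psis.T, ddof=1)
    evals = np.linalg.eigvalsh(sigma)
    if evals.min() < ridge:
        warnings.warn("singular psi covariance; applying diagonal ridge")
        sigma = sigma + (ridge - min(evals.min(), 0.0) + ridge) * np.eye(2)
    return PsiNull(mu=mu, sigma=sigma, confidence=confidence)


def mahalanobis_score(psi: Sequence[float] | np.ndarray, null: PsiNull) -> float:
    """Mahalanobis distance d = sqrt((psi-mu)^T Sigma^-1 (psi-mu))."""
    diff = np.asarray(psi, float) - null.mu
    sol = np.linalg.solve(null.sigma, diff)
    return float(np.sqrt(diff @ sol))


@dataclass
class HmmClassifier:
    """Trained HMM plus psi null; scores segments with -Mahalanobis distance."""

    model: GaussianHmm
    null: PsiNull
    reference_xy: tuple[float, float] = (0.0, 0.0)

    def psi(self, segment: Segment) -> np.ndarray:
        obs = extract_features(segment, self.model.feature_kind, self.reference_xy)
        return np.array([log_likelihood(self.model, obs), segment.n_s])

    def score(self, segment: Segment) -> float:
        score, _ = classify_segment(segment, self.model, self.null, self.reference_xy)
        return score

    def to_json(self, path: str | Path) -> None:
        d = self.model.to_dict()
        d["psi_null"] = self.null.to_dict()
        d["reference_xy"] = list(self.reference_xy)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            model=GaussianHmm.from_dict(d),
            null=PsiNull.from_dict(d["psi_null"]),
            reference_xy=tuple(d.get("reference_xy", (0.0, 0.0))),
        )


def classify_segment(
    segment: Segment,
    model: GaussianHmm,
    null: PsiNull,
    reference_xy: tuple[float, float] = (0.0, 0.0),
    confidence: float | None = None,
) -> tuple[float, bool]:
    """Score and classify one segment.

    The score is ``-d`` (negated Mahalanobis distance of psi), so larger
    means more reach-like and ROC sweeps run in the same direction for all
    classifiers.  The decision accepts the segment when ``d**2`` is inside
    the chi-square quantile (2 df) at the null's confidence level.  Segments
    too short to score (fewer samples than model states) are rejected.
    """
    conf = null.confidence if confidence is None else confidence
    if segment.n_s < model.n_states:
        warnings.warn(f"segment with n_s={segment.n_s} below scoreable minimum; classified invalid")
        return -np.inf, False
    obs = extract_features(segment, model.feature_kind, reference_xy)
    ls = log_likelihood(model, obs)
    d = mahalanobis_score([ls, segment.n_s], null)
    return -d, bool(d**2 <= chi2.ppf(conf, df=2))


def train_hmm_classifier(
    valid_segments: Sequence[Segment],
    feature_kind: str = "PV",
    reference_xy: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    n_states: int = N_STATES,
    topology: str = "left_right",
    confidence: float = 0.95,
    update_emissions: bool = True,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> tuple[HmmClassifier, np.ndarray]:
    """Full training path: features -> k-means init -> Baum-Welch -> psi null.

    Returns the classifier and the Baum-Welch log-likelihood history.
    """
    feats = [extract_features(s, feature_kind, reference_xy) for s in valid_segments]
    init = init_emissions_kmeans(
        feats, n_states=n_states, seed=seed, topology=topology, feature_kind=feature_kind
    )
    model, history = baum_welch(
        feats, init, max_iter=max_iter, tol=tol, update_emissions=update_emissions
    )
    psis = np.array([[log_likelihood(model, f), len(f)] for f in feats])
    null = fit_psi_null(psis, confidence=confidence)
    return HmmClassifier(model=model, null=null, reference_xy=reference_xy), history
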