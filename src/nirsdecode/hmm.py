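"""Dual left-to-right Gaussian-mixture HMM classifier.

One HMM is trained per class (active pinching, rest) on the class's training
observations; a test observation is labeled by comparing the forward-algorithm
log-likelihoods under the two models (ties resolve to rest, matching the
strict inequality of the decision rule).  Left-to-right structure: the chain
starts in the leftmost state and each state transitions only to itself or its
direct right neighbor.  Emissions are mixtures of N_m full-covariance
Gaussians per state.

Because initialization (k-means emission clusters, random transitions) is
stochastic, training is restarted ``n_restarts`` times per class and every
candidate pair is scored on the training trials with the weighted training
accuracy

    kappa = sum_{correct trials} |D(i)| / sum_{all trials} |D(i)|,

where D(i) = LL_active(i) - LL_rest(i); the kappa-maximizing pair is kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .features import Observation

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Topology:
    n_states: int
    n_mixtures: int

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_mixtures < 1:
            raise ValueError("states and mixtures must be >= 1")


def default_grid() -> list[Topology]:
    """The 10 investigated topologies: N_s in 1..5 crossed with N_m in {1, 2}."""
    return [Topology(ns, nm) for ns in range(1, 6) for nm in (1, 2)]


@dataclass(frozen=True)
class EMConfig:
    max_iter: int = 100
    tol: float = 1e-6           # relative log-likelihood improvement
    cov_floor: float = 1e-6     # eigenvalue floor of covariance matrices


@dataclass
class GaussianMixtureHMM:
    """Parameters of one trained (or initialized) model."""

    topology: Topology
    startprob: np.ndarray        # (S,), fixed to (1, 0, ..., 0)
    transmat: np.ndarray         # (S, S), row-stochastic, left-to-right
    weights: np.ndarray          # (S, M) mixture weights
    means: np.ndarray            # (S, M, d)
    covars: np.ndarray           # (S, M, d, d)
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def ndim(self) -> int:
        return self.means.shape[-1]

    def validate(self) -> None:
        S = self.topology.n_states
        if not np.allclose(self.startprob, np.eye(S)[0]):
            raise ValueError("start distribution must be the leftmost state")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be row-stochastic")
        allowed = np.eye(S, dtype=bool) | np.eye(S, k=1, dtype=bool)
        if np.any(self.transmat[~allowed] != 0):
            raise ValueError("transitions restricted to self and right neighbor")
        if abs(self.transmat[-1, -1] - 1.0) > 1e-12:
            raise ValueError("last state must self-loop with probability 1")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ValueError("mixture weights must sum to 1 per state")
        for s in range(S):
            for m in range(self.topology.n_mixtures):
                cov = self.covars[s, m]
                if not np.allclose(cov, cov.T):
                    raise ValueError("covariances must be symmetric")
                if np.linalg.eigvalsh(cov).min() <= 0:
                    raise ValueError("covariances must be positive definite")


@dataclass
class DualClassifier:
    """Selected active/rest model pair with its selection score."""

    hmm_active: GaussianMixtureHMM
    hmm_rest: GaussianMixtureHMM
    kappa: float
    topology: Topology


# --------------------------------------------------------------------------
# numerics
# --------------------------------------------------------------------------

def _as_array(observations) -> np.ndarray:
    """Stack observations (list of Observation or (T, d) arrays) to (n, T, d)."""
    if isinstance(observations, Observation):
        return observations.data[None]
    if isinstance(observations, np.ndarray):
        if observations.ndim == 2:
            return observations[None]
        return observations
    rows = [o.data if isinstance(o, Observation) else np.asarray(o)
            for o in observations]
    return np.stack(rows)


def _component_logpdf(X: np.ndarray, hmm: GaussianMixtureHMM) -> np.ndarray:
    """Log N(x; mu_sm, Sigma_sm) for all samples: (n, T, S, M)."""
    n, T, d = X.shape
    S, M = hmm.weights.shape
    flat = X.reshape(-1, d)
    out = np.empty((n * T, S, M))
    for s in range(S):
        for m in range(M):
            chol = np.linalg.cholesky(hmm.covars[s, m])
            diff = flat - hmm.means[s, m]
            sol = solve_triangular(chol, diff.T, lower=True)
            maha = np.sum(sol * sol, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, s, m] = -0.5 * (d * _LOG_2PI + logdet + maha)
    return out.reshape(n, T, S, M)


def _emission_logprob(X: np.ndarray, hmm: GaussianMixtureHMM
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mixture emission log-probs (n, T, S) and component log-pdfs."""
    comp = _component_logpdf(X, hmm)
    with np.errstate(divide="ignore"):
        log_w = np.log(hmm.weights)
    logB = logsumexp(comp + log_w[None, None], axis=3)
    return logB, comp


def _log_transmat(hmm: GaussianMixtureHMM) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(hmm.transmat)


def _forward(logB: np.ndarray, logA: np.ndarray, log_pi: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Batched log-domain forward pass; returns (logP (n,), log_alpha)."""
    n, T, S = logB.shape
    log_alpha = np.empty((n, T, S))
    log_alpha[:, 0] = log_pi[None] + logB[:, 0]
    for t in range(1, T):
        log_alpha[:, t] = (logsumexp(log_alpha[:, t - 1, :, None]
                                     + logA[None], axis=1) + logB[:, t])
    return logsumexp(log_alpha[:, -1], axis=1), log_alpha


def _backward(logB: np.ndarray, logA: np.ndarray) -> np.ndarray:
    n, T, S = logB.shape
    log_beta = np.zeros((n, T, S))
    for t in range(T - 2, -1, -1):
        log_beta[:, t] = logsumexp(
            logA[None] + (logB[:, t + 1] + log_beta[:, t + 1])[:, None, :],
            axis=2)
    return log_beta


def log_likelihood(hmm: GaussianMixtureHMM, observation) -> float:
    """Forward-algorithm log P(O | HMM) for a single (T, d) observation."""
    X = _as_array(observation)
    if X.shape[-1] != hmm.ndim:
        raise ValueError(f"observation dimension {X.shape[-1]} does not match "
                         f"model dimension {hmm.ndim}")
    logB, _ = _emission_logprob(X, hmm)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.startprob)
    logP, _ = _forward(logB, _log_transmat(hmm), log_pi)
    return float(logP[0]) if logP.size == 1 else logP


def _floor_covariance(cov: np.ndarray, floor: float) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < floor:
        vals = np.maximum(vals, floor)
        cov = (vecs * vals) @ vecs.T
    return cov


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def init_hmm(observations, topology: Topology,
             seed: int | np.random.Generator = 0) -> GaussianMixtureHMM:
    """Initialize emissions from k-means clusters, transitions randomly.

    All observation rows are pooled and clustered with k-means
    (k = N_s * N_m, 5 restarts); clusters are assigned to (state, mixture)
    slots in order of their temporal centroid (mean within-sequence time
    index of their members), so early-responding clusters initialize left
    states.  Allowed transition entries are drawn uniformly and
    row-normalized; the start distribution is fixed to the leftmost state.
    """
    rng = np.random.default_rng(seed)
    X = _as_array(observations)
    n, T, d = X.shape
    S, M = topology.n_states, topology.n_mixtures
    k = S * M
    if n * T < k:
        raise ValueError(f"need at least {k} observation rows, got {n * T}")
    flat = X.reshape(-1, d)
    t_index = np.tile(np.arange(T), n)

    if k == 1:
        labels = np.zeros(flat.shape[0], dtype=int)
        centers = flat.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=5,
                    random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(flat)
        centers = km.cluster_centers_
    centroids_t = np.array([t_index[labels == c].mean() if np.any(labels == c)
                            else np.inf for c in range(k)])
    order = np.argsort(centroids_t, kind="stable")

    weights = np.empty((S, M))
    means = np.empty((S, M, d))
    covars = np.empty((S, M, d, d))
    for s in range(S):
        slot_clusters = order[s * M:(s + 1) * M]
        sizes = np.array([(labels == c).sum() for c in slot_clusters],
                         dtype=float)
        sizes = sizes / sizes.sum() if sizes.sum() > 0 else np.full(M, 1.0 / M)
        for m, c in enumerate(slot_clusters):
            members = flat[labels == c]
            weights[s, m] = sizes[m]
            means[s, m] = centers[c]
            if members.shape[0] > d:
                cov = np.cov(members, rowvar=False)
            else:
                cov = np.cov(flat, rowvar=False)
            cov = np.atleast_2d(cov)
            covars[s, m] = _floor_covariance(cov, 1e-6)

    transmat = np.zeros((S, S))
    for s in range(S - 1):
        draw = rng.uniform(size=2)
        transmat[s, s], transmat[s, s + 1] = draw / draw.sum()
    transmat[S - 1, S - 1] = 1.0
    startprob = np.eye(S)[0]
    hmm = GaussianMixtureHMM(topology=topology, startprob=startprob,
                             transmat=transmat, weights=weights, means=means,
                             covars=covars)
    hmm.validate()
    return hmm


# --------------------------------------------------------------------------
# Baum-Welch
# --------------------------------------------------------------------------

def train_hmm(observations, initial: GaussianMixtureHMM,
              em_config: EMConfig | None = None) -> GaussianMixtureHMM:
    """Expectation-maximization respecting the left-to-right mask.

    The total training log-likelihood is non-decreasing across the recorded
    iterations; if covariance flooring ever produces a decrease, the previous
    parameters are restored and training stops there.  Returns a new model
    (the initializer is not modified) with the LL history and a convergence
    flag.
    """
    cfg = em_config or EMConfig()
    X = _as_array(observations)
    if X.shape[-1] != initial.ndim:
        raise ValueError("observation dimension does not match the model")
    n, T, d = X.shape
    S, M = initial.weights.shape

    hmm = GaussianMixtureHMM(
        topology=initial.topology, startprob=initial.startprob.copy(),
        transmat=initial.transmat.copy(), weights=initial.weights.copy(),
        means=initial.means.copy(), covars=initial.covars.copy())
    allowed = np.eye(S, dtype=bool) | np.eye(S, k=1, dtype=bool)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.startprob)

    history: list[float] = []
    converged = False
    floored = False
    prev = None
    for _ in range(cfg.max_iter):
        logB, comp = _emission_logprob(X, hmm)
        logA = _log_transmat(hmm)
        logP, log_alpha = _forward(logB, logA, log_pi)
        ll = float(logP.sum())
        if prev is not None and ll < history[-1] - 1e-10:
            # flooring broke the EM guarantee; keep the last good parameters
            hmm.transmat, hmm.weights, hmm.means, hmm.covars = prev
            converged = True
            break
        history.append(ll)
        if len(history) > 1:
            gain = history[-1] - history[-2]
            if gain <= cfg.tol * abs(history[-2]):
                converged = True
                break
        prev = (hmm.transmat.copy(), hmm.weights.copy(),
                hmm.means.copy(), hmm.covars.copy())

        log_beta = _backward(logB, logA)
        log_gamma = log_alpha + log_beta - logP[:, None, None]
        gamma = np.exp(log_gamma)

        if S > 1:
            log_xi = (log_alpha[:, :-1, :, None] + logA[None, None]
                      + (logB[:, 1:] + log_beta[:, 1:])[:, :, None, :]
                      - logP[:, None, None, None])
            xi_sum = np.exp(log_xi).sum(axis=(0, 1))
            new_A = np.zeros_like(hmm.transmat)
            row_tot = xi_sum.sum(axis=1)
            for s in range(S):
                if row_tot[s] > 1e-300:
                    new_A[s] = np.where(allowed[s], xi_sum[s] / row_tot[s], 0.0)
                else:
                    new_A[s] = hmm.transmat[s]
            new_A[S - 1] = 0.0
            new_A[S - 1, S - 1] = 1.0
            hmm.transmat = new_A

        # component responsibilities
        with np.errstate(divide="ignore"):
            log_w = np.log(hmm.weights)
        log_r = (log_gamma[..., None] + log_w[None, None] + comp
                 - logB[..., None])
        r = np.exp(log_r)                       # (n, T, S, M)
        denom = r.sum(axis=(0, 1))              # (S, M)
        flat = X.reshape(-1, d)
        r_flat = r.reshape(-1, S, M)
        for s in range(S):
            state_tot = denom[s].sum()
            if state_tot <= 1e-300:
                continue
            hmm.weights[s] = denom[s] / state_tot
            for m in range(M):
                if denom[s, m] <= 1e-300:
                    continue
                w = r_flat[:, s, m]
                mu = (w @ flat) / denom[s, m]
                diff = flat - mu
                cov = (diff.T * w) @ diff / denom[s, m]
                before = cov.copy()
                cov = _floor_covariance(cov, cfg.cov_floor)
                if not np.allclose(before, cov):
                    floored = True
                hmm.means[s, m] = mu
                hmm.covars[s, m] = cov
    if floored:
        warnings.warn("covariance eigenvalues floored during EM")
    hmm.log_likelihoods = history
    hmm.converged = converged
    hmm.validate()
    return hmm


# --------------------------------------------------------------------------
# model selection and classification
# --------------------------------------------------------------------------

def kappa_score(d_values: np.ndarray, labels: list[str]) -> float:
    """Weighted training accuracy of the sign rule on LL differences.

    A trial is correct when sign(D) matches its label under the strict rule
    (active iff D > 0, so D = 0 counts as rest and is incorrect for active
    trials).  If every |D| is zero, kappa is defined as 0 with a warning.
    """
    d = np.asarray(d_values, dtype=float)
    total = np.abs(d).sum()
    if total == 0:
        warnings.warn("all log-likelihood differences are zero; kappa := 0")
        return 0.0
    predicted = np.where(d > 0, "active", "rest")
    correct = predicted == np.asarray(labels)
    return float(np.abs(d[correct]).sum() / total)


def select_model_pair(candidates_active: list[GaussianMixtureHMM],
                      candidates_rest: list[GaussianMixtureHMM],
                      train_observations: list[Observation]) -> DualClassifier:
    """Choose the kappa-maximizing (active, rest) candidate pair.

    Log-likelihoods of every training observation under every candidate are
    computed once; all len(a) x len(r) pairings are then scored.
    """
    X = _as_array(train_observations)
    labels = [o.label for o in train_observations]
    ll_a = np.vstack([log_likelihood(h, X) for h in candidates_active])
    ll_r = np.vstack([log_likelihood(h, X) for h in candidates_rest])
    best = None
    for ia in range(ll_a.shape[0]):
        for ir in range(ll_r.shape[0]):
            k = kappa_score(ll_a[ia] - ll_r[ir], labels)
            if best is None or k > best[0]:
                best = (k, ia, ir)
    k, ia, ir = best
    return DualClassifier(hmm_active=candidates_active[ia],
                          hmm_rest=candidates_rest[ir], kappa=k,
                          topology=candidates_active[ia].topology)


def train_dual_classifier(train_observations: list[Observation],
                          topology: Topology, n_restarts: int = 10,
                          seed: int | np.random.SeedSequence = 0,
                          em_config: EMConfig | None = None) -> DualClassifier:
    """Restarted per-class training followed by kappa pair selection."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(2 * n_restarts)
    by_class = {"active": [o for o in train_observations if o.label == "active"],
                "rest": [o for o in train_observations if o.label == "rest"]}
    candidates = {}
    for ci, label in enumerate(("active", "rest")):
        obs = by_class[label]
        if not obs:
            raise ValueError(f"no training observations for class {label!r}")
        cands = []
        for r in range(n_restarts):
            rng = np.random.default_rng(children[ci * n_restarts + r])
            initial = init_hmm(obs, topology, rng)
            cands.append(train_hmm(obs, initial, em_config))
        candidates[label] = cands
    return select_model_pair(candidates["active"], candidates["rest"],
                             train_observations)


def classify(classifier: DualClassifier, observation) -> str:
    """'active' iff LL under the active model strictly exceeds the rest LL."""
    ll_a = log_likelihood(classifier.hmm_active, observation)
    ll_r = log_likelihood(classifier.hmm_rest, observation)
    return "active" if ll_a > ll_r else "rest"


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def hmm_to_dict(hmm: GaussianMixtureHMM) -> dict:
    return {
        "n_states": hmm.topology.n_states,
        "n_mixtures": hmm.topology.n_mixtures,
        "startprob": hmm.startprob.tolist(),
        "transmat": hmm.transmat.tolist(),
        "weights": hmm.weights.tolist(),
        "means": hmm.means.tolist(),
        "covars": hmm.covars.tolist(),
        "log_likelihoods": list(hmm.log_likelihoods),
        "converged": bool(hmm.converged),
    }


def hmm_from_dict(d: dict) -> GaussianMixtureHMM:
    hmm = GaussianMixtureHMM(
        topology=Topology(d["n_states"], d["n_mixtures"]),
        startprob=np.asarray(d["startprob"]),
        transmat=np.asarray(d["transmat"]),
        weights=np.asarray(d["weights"]),
        means=np.asarray(d["means"]),
        covars=np.asarray(d["covars"]),
        log_likelihoods=list(d["log_likelihoods"]),
        converged=bool(d["converged"]),
    )
    hmm.validate()
    return hmm


def save_classifier(clf: DualClassifier, path) -> None:
    payload = {"kappa": clf.kappa,
               "active": hmm_to_dict(clf.hmm_active),
               "rest": hmm_to_dict(clf.hmm_rest)}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_classifier(path) -> DualClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    active = hmm_from_dict(payload["active"])
    return DualClassifier(hmm_active=active,
                          hmm_rest=hmm_from_dict(payload["rest"]),
                          kappa=float(payload["kappa"]),
                          topology=active.topology)
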