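"""Core blind source separation machinery.

PCA whitening, Infomax ICA with natural-gradient updates, multi-run
stability scoring (ICASSO-style cluster quality index Iq), and the
permutation/sign matching utilities needed to compare decompositions.

Orientation convention: a data matrix ``X`` is samples x features.  For
spatial ICA the rows are observations (time points or subjects) treated as
mixtures of ``k`` spatial sources, so PCA reduces the *sample* dimension:
``reduced = reducing @ (X - mean)`` has shape ``k x features`` with
whitened rows, and the model is ``X ~ A @ S`` with loadings
``A`` (samples x k) and sources ``S`` (k x features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.special import expit


@dataclass
class Whitening:
    """PCA projection onto the top-k variance axes with unit output variance.

    ``reducing`` maps the sample dimension down (k x samples);
    ``dewhitening`` is its right inverse (samples x k), so
    ``reducing @ dewhitening == I_k``.  ``mean_vector`` holds the removed
    per-row means; ``eigenvalues`` the retained variances (nonincreasing);
    ``all_eigenvalues`` the full spectrum for variance-fraction queries.
    """

    reducing: np.ndarray
    dewhitening: np.ndarray
    eigenvalues: np.ndarray
    mean_vector: np.ndarray
    all_eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.reducing.shape[0]

    @property
    def retained_variance_fraction(self) -> float:
        total = float(np.sum(self.all_eigenvalues))
        if total <= 0:
            return 1.0
        return float(np.sum(self.eigenvalues)) / total

    def project(self, X: np.ndarray) -> np.ndarray:
        """Whiten new data laid out like the fitting data."""
        return self.reducing @ (X - self.mean_vector[:, None])

    def reconstruct(self, reduced: np.ndarray) -> np.ndarray:
        return self.dewhitening @ reduced + self.mean_vector[:, None]


def pca_reduce(X: np.ndarray, k: int) -> tuple[Whitening, np.ndarray]:
    """Reduce the sample (row) dimension of ``X`` to ``k`` whitened axes.

    Parameters
    ----------
    X : ndarray, samples x features
    k : number of axes to keep; must not exceed the effective rank.

    Returns
    -------
    (Whitening, reduced) where ``reduced`` is k x features with zero-mean,
    unit-variance, mutually uncorrelated rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n_samples, n_features = X.shape
    if not 1 <= k <= min(n_samples, n_features):
        raise ValueError(f"k={k} outside 1..min(dims)={min(n_samples, n_features)}")

    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    # Row covariance; eigh is exact and cheap because samples << features
    # in every use here.
    C = (Xc @ Xc.T) / n_features
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    rank = int(np.sum(evals > max(n_samples, n_features) * np.finfo(float).eps * max(evals.max(), 1e-300)))
    if k > rank:
        raise ValueError(f"k={k} exceeds effective rank {rank} of the data")

    lam = evals[:k]
    E = evecs[:, :k]
    reducing = (E / np.sqrt(lam)).T          # k x samples
    dewhitening = E * np.sqrt(lam)           # samples x k
    reduced = reducing @ Xc
    wh = Whitening(
        reducing=reducing,
        dewhitening=dewhitening,
        eigenvalues=lam.copy(),
        mean_vector=mean,
        all_eigenvalues=evals.copy(),
    )
    return wh, reduced


@dataclass
class InfomaxParams:
    """Tunables for the natural-gradient Infomax iteration.

    Defaults follow common group-ICA practice: modest fixed step with
    multiplicative annealing when the update direction oscillates.
    """

    learning_rate: float = 0.1
    anneal: float = 0.9
    anneal_angle_deg: float = 60.0
    max_iter: int = 512
    tol: float = 1e-6
    diverge_norm: float = 1e8


@dataclass
class IcaResult:
    """One ICA decomposition.

    ``W @ whitened == sources`` exactly.  ``loadings`` are the dewhitened
    mixing columns (samples x k) when a Whitening was supplied, otherwise
    the whitened-space mixing (k x k).  Components are ordered by explained
    variance in the original data space and sign-fixed so each source's
    largest-magnitude element is positive.
    """

    unmixing: np.ndarray
    sources: np.ndarray
    loadings: np.ndarray
    converged: bool
    n_iterations: int
    entropy_trace: np.ndarray

    @property
    def k(self) -> int:
        return self.unmixing.shape[0]


class _InfomaxState:
    """Stepwise Infomax engine shared by :func:`infomax` and parallel ICA.

    Full-batch natural-gradient updates with the logistic nonlinearity:
    ``dW = lr * (I + (1 - 2*sigmoid(U)) @ U.T / n) @ W``.  Deterministic
    given the initial weights, so two interleaved engines evolve exactly
    as two standalone runs unless something external modifies ``W``.
    """

    def __init__(self, k: int, params: InfomaxParams, rng: np.random.Generator):
        self.k = k
        self.params = params
        self.lr = params.learning_rate
        # small random rotation-ish init; identity plus noise keeps the
        # early iterations well-conditioned
        self.W = np.eye(k) + 0.05 * rng.standard_normal((k, k))
        self.converged = False
        self.n_iter = 0
        self.last_change = np.inf
        self.entropy_trace: list[float] = []
        self._prev_dW: np.ndarray | None = None

    def step(self, Z: np.ndarray) -> float:
        """One full-batch update; returns the weight-change norm."""
        p = self.params
        n = Z.shape[1]
        U = self.W @ Z
        Y = expit(U)
        gram = (1.0 - 2.0 * Y) @ U.T / n
        dW = self.lr * (np.eye(self.k) + gram) @ self.W
        W_new = self.W + dW

        if not np.all(np.isfinite(W_new)) or np.linalg.norm(W_new) > p.diverge_norm:
            raise FloatingPointError(
                "Infomax diverged (weight norm blow-up); reduce the learning rate"
            )

        # entropy of the logistic-transformed output, up to an additive
        # constant: log|det W| + mean log y(1-y)
        sign, logdet = np.linalg.slogdet(W_new)
        with np.errstate(divide="ignore"):
            h = logdet + float(np.mean(np.sum(np.log(np.clip(Y * (1 - Y), 1e-300, None)), axis=0)))
        self.entropy_trace.append(h)

        # anneal when successive update directions disagree strongly
        if self._prev_dW is not None:
            num = float(np.sum(dW * self._prev_dW))
            den = float(np.linalg.norm(dW) * np.linalg.norm(self._prev_dW))
            if den > 0:
                cos = max(-1.0, min(1.0, num / den))
                if np.degrees(np.arccos(cos)) > p.anneal_angle_deg:
                    self.lr *= p.anneal
        self._prev_dW = dW

        change = float(np.max(np.abs(dW)))
        self.last_change = change
        self.W = W_new
        self.n_iter += 1
        if change < p.tol:
            self.converged = True
        return change

    def run(self, Z: np.ndarray) -> None:
        while not self.converged and self.n_iter < self.params.max_iter:
            self.step(Z)


def _finalize(
    W: np.ndarray,
    Z: np.ndarray,
    whitening: Whitening | None,
    converged: bool,
    n_iter: int,
    entropy_trace: list[float],
) -> IcaResult:
    """Scale sources to unit variance, order by explained variance, fix signs."""
    S = W @ Z
    sd = S.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("degenerate source with zero variance")
    W = W / sd[:, None]
    S = S / sd[:, None]

    M = np.linalg.inv(W)                       # whitened-space mixing, k x k
    A = whitening.dewhitening @ M if whitening is not None else M

    # explained variance of component i in data space: ||A[:,i]||^2 * var(S_i)
    # and var(S_i) == 1 after scaling
    ev = np.sum(A**2, axis=0)
    order = np.argsort(ev)[::-1]
    W, S, A = W[order], S[order], A[:, order]

    signs = np.sign(S[np.arange(S.shape[0]), np.argmax(np.abs(S), axis=1)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    S = S * signs[:, None]
    A = A * signs[None, :]

    return IcaResult(
        unmixing=W,
        sources=S,
        loadings=A,
        converged=converged,
        n_iterations=n_iter,
        entropy_trace=np.asarray(entropy_trace),
    )


def infomax(
    whitened: np.ndarray,
    params: InfomaxParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    whitening: Whitening | None = None,
) -> IcaResult:
    """Infomax ICA on whitened data (k x n).

    The seed controls only the weight initialisation; updates are
    full-batch and hence deterministic, so equal seeds give bitwise-equal
    results.
    """
    Z = np.asarray(whitened, dtype=float)
    if Z.ndim != 2:
        raise ValueError("whitened data must be 2-D (k x n)")
    params = params or InfomaxParams()
    rng = np.random.default_rng(seed)
    state = _InfomaxState(Z.shape[0], params, rng)
    state.run(Z)
    return _finalize(state.W, Z, whitening, state.converged, state.n_iter, state.entropy_trace)


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of a square matrix.

    Zero iff ``P`` is a scaled permutation; the raw row+column sum lies in
    ``[0, 2k(k-1)]`` and is scaled to ``[0, 1]``.
    """
    P = np.abs(np.asarray(P, dtype=float))
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    k = P.shape[0]
    row_max = P.max(axis=1)
    col_max = P.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("P has an all-zero row or column")
    row_term = float(np.sum(P.sum(axis=1) / row_max - 1.0))
    col_term = float(np.sum(P.sum(axis=0) / col_max - 1.0))
    return (row_term + col_term) / (2.0 * k * (k - 1.0)) if k > 1 else 0.0


def match_components(
    S_est: np.ndarray, S_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimally pair estimated with true components by absolute correlation.

    Returns ``(permutation, signs, abs_corrs)`` such that
    ``signs[i] * S_est[permutation[i]]`` is the best match for
    ``S_true[i]``, with the assignment maximising total |r|.
    """
    S_est = np.asarray(S_est, dtype=float)
    S_true = np.asarray(S_true, dtype=float)
    if S_est.shape[0] != S_true.shape[0]:
        raise ValueError("component counts differ")
    if np.any(S_est.std(axis=1) == 0) or np.any(S_true.std(axis=1) == 0):
        raise ValueError("zero-variance component")
    k = S_est.shape[0]
    R = np.corrcoef(S_true, S_est)[:k, k:]      # true_i x est_j
    rows, cols = linear_sum_assignment(-np.abs(R))
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    signed = R[np.arange(k), perm]
    signs = np.where(signed >= 0, 1.0, -1.0)
    return perm, signs, np.abs(signed)


@dataclass
class StabilityResult:
    """Multi-run stability summary.

    ``iq_per_component`` is the cluster quality index: mean within-cluster
    similarity minus mean similarity to components outside the cluster,
    in [-1, 1].  ``consensus_sources`` holds the centrotype of each
    cluster (the member with the largest within-cluster similarity sum).
    """

    iq_per_component: np.ndarray
    run_results: list[IcaResult]
    consensus_assignment: np.ndarray
    consensus_sources: np.ndarray = field(default=None)  # type: ignore[assignment]


def icasso(
    X: np.ndarray,
    k: int,
    n_runs: int = 5,
    seeds: list[int] | None = None,
    params: InfomaxParams | None = None,
) -> StabilityResult:
    """Run Infomax ``n_runs`` times and score component stability.

    Pools all runs' sources, clusters them by absolute correlation with
    average linkage into ``k`` clusters, and reports Iq per cluster.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")

    wh, Z = pca_reduce(np.asarray(X, dtype=float), k)
    runs = [infomax(Z, params=params, seed=s, whitening=wh) for s in seeds]

    pooled = np.vstack([r.sources for r in runs])
    sim = np.abs(np.corrcoef(pooled))
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    # condensed distance for average-linkage agglomeration
    iu = np.triu_indices_from(dist, k=1)
    labels = fcluster(linkage(dist[iu], method="average"), t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise RuntimeError(f"could not form {k} clusters from pooled components")

    iq = np.empty(k)
    centro_rows = np.empty(k, dtype=int)
    for c in range(1, k + 1):
        inside = np.where(labels == c)[0]
        outside = np.where(labels != c)[0]
        Sin = sim[np.ix_(inside, inside)]
        intra = float(Sin.mean())
        extra = float(sim[np.ix_(inside, outside)].mean()) if outside.size else 0.0
        iq[c - 1] = intra - extra
        centro_rows[c - 1] = inside[np.argmax(Sin.sum(axis=1))]

    order = np.argsort(iq)[::-1]
    return StabilityResult(
        iq_per_component=iq[order],
        run_results=runs,
        consensus_assignment=labels,
        consensus_sources=pooled[centro_rows[order]],
    )
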