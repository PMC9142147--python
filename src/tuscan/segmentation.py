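"""Two-state HMM segmentation of binned coverage.

The genome (per strand) is modelled as a two-state hidden Markov chain over
200 bp bins with Poisson-log-normal emissions: in state s the bin count is
Poisson(lambda) with log(lambda) ~ Normal(mu_s, sigma_s^2). This marginal is
heavy-tailed, which absorbs the burstiness of nascent-RNA coverage that a
plain Poisson HMM would over-segment. State 1 ("transcribed") is the state
with the larger marginal mean exp(mu + sigma^2/2).

Fitting is Baum-Welch (EM); the emission M-step has no closed form and is
solved numerically. Decoding is Viterbi by default; maximal runs of the
transcribed state become segments, which are then filtered on RPK (fragment
midpoints per kilobase, computed without pseudo-counts) and their borders
sharpened by a least-squares step-function fit at base-pair resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .intervals import GenomicInterval
from .tracks import CoverageTrack

__all__ = [
    "HmmModel",
    "Segment",
    "plnorm_pmf",
    "plnorm_logpmf",
    "fit_hmm",
    "decode",
    "viterbi_path",
    "forward_backward",
    "refine_boundary",
]


# ------------------------------------------------------- emission marginal


def plnorm_logpmf(k, mu: float, sigma: float, nodes: int = 64) -> np.ndarray:
    """log pmf of the Poisson-log-normal marginal via adaptive Gauss-Hermite
    quadrature.

    pmf(k) = integral Pois(k; e^x) N(x; mu, sigma^2) dx. The quadrature grid
    is centred on the mode of the integrand (found by Newton iteration) and
    scaled to its curvature, so ``nodes`` points give near-machine accuracy
    across counts and sigma; a fixed grid at (mu, sigma) loses accuracy as
    soon as k pulls the posterior far from the prior. Vectorized over ``k``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    scalar = np.isscalar(k) or np.ndim(k) == 0
    k = np.atleast_1d(np.asarray(k))
    if not np.issubdtype(k.dtype, np.integer):
        kk = np.asarray(k, dtype=float)
        if not np.all(kk == np.floor(kk)):
            raise ValueError("counts must be non-negative integers")
        k = kk.astype(np.int64)
    if np.any(k < 0):
        raise ValueError("counts must be non-negative integers")
    t, w = np.polynomial.hermite.hermgauss(nodes)
    kf = k.astype(float)
    inv_s2 = 1.0 / sigma**2
    # mode of g(x) = k x - e^x - (x - mu)^2 / (2 sigma^2) by Newton iteration
    xhat = np.where(kf > 0, np.log(np.maximum(kf, 1e-12)), mu)
    for _ in range(40):
        ex = np.exp(xhat)
        grad = kf - ex - (xhat - mu) * inv_s2
        hess = -ex - inv_s2
        step = grad / hess
        xhat = xhat - step
        if np.max(np.abs(step)) < 1e-12:
            break
    tau = 1.0 / np.sqrt(np.exp(xhat) + inv_s2)  # (n_k,)
    x = xhat[:, None] + np.sqrt(2.0) * tau[:, None] * t[None, :]
    g = (
        kf[:, None] * x
        - np.exp(x)
        - (x - mu) ** 2 * (0.5 * inv_s2)
    )
    lp = (
        logsumexp(np.log(w)[None, :] + t[None, :] ** 2 + g, axis=-1)
        + np.log(np.sqrt(2.0) * tau)
        - 0.5 * np.log(2.0 * np.pi * sigma**2)
        - gammaln(k + 1)
    )
    return float(lp[0]) if scalar else lp


def plnorm_pmf(k, mu: float, sigma: float, nodes: int = 64):
    """Poisson-log-normal pmf (see :func:`plnorm_logpmf`)."""
    return np.exp(plnorm_logpmf(k, mu, sigma, nodes))


# ------------------------------------------------------- model containers


@dataclass
class HmmModel:
    """Two-state HMM with Poisson-log-normal emissions.

    State 0 is "untranscribed", state 1 "transcribed"; after fitting the
    states are ordered so state 1 has the larger emission mean.
    """

    initial_probs: np.ndarray
    transition: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    quadrature_nodes: int = 64
    degenerate: bool = False
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if abs(self.initial_probs.sum() - 1) > 1e-9:
            raise ValueError("initial_probs must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")

    def emission_means(self) -> np.ndarray:
        return np.exp(self.mu + 0.5 * self.sigma**2)

    def order_states(self) -> "HmmModel":
        """Reorder so state 1 has the larger emission mean."""
        order = np.argsort(self.emission_means())
        return HmmModel(
            initial_probs=self.initial_probs[order],
            transition=self.transition[np.ix_(order, order)],
            mu=self.mu[order],
            sigma=self.sigma[order],
            quadrature_nodes=self.quadrature_nodes,
            degenerate=self.degenerate,
            log_likelihood=self.log_likelihood,
        )

    def to_json(self, path) -> None:
        doc = {
            "initial_probs": self.initial_probs.tolist(),
            "transition": self.transition.tolist(),
            "emissions": [
                {"mu": float(m), "sigma": float(s)}
                for m, s in zip(self.mu, self.sigma)
            ],
            "quadrature_nodes": self.quadrature_nodes,
            "degenerate": self.degenerate,
            "log_likelihood": self.log_likelihood,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HmmModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            initial_probs=np.array(doc["initial_probs"]),
            transition=np.array(doc["transition"]),
            mu=np.array([e["mu"] for e in doc["emissions"]]),
            sigma=np.array([e["sigma"] for e in doc["emissions"]]),
            quadrature_nodes=doc.get("quadrature_nodes", 64),
            degenerate=doc.get("degenerate", False),
            log_likelihood=doc.get("log_likelihood", float("nan")),
        )


@dataclass
class Segment:
    """A decoded transcribed interval."""

    interval: GenomicInterval
    mean_coverage: float
    posterior_mean: float
    rpk: float = float("nan")


# ------------------------------------------------------- fwd/bwd machinery


def _log_emissions(counts: np.ndarray, model: HmmModel) -> np.ndarray:
    """(T, 2) log emission matrix, computed once per unique count value."""
    uniq, inv = np.unique(counts, return_inverse=True)
    le = np.empty((len(uniq), 2))
    for s in range(2):
        le[:, s] = plnorm_logpmf(uniq, model.mu[s], model.sigma[s], model.quadrature_nodes)
    return le[inv]


def forward_backward(counts: np.ndarray, model: HmmModel):
    """Scaled forward-backward.

    Returns (gamma, xi_sum, loglik): gamma is (T, 2) posterior state
    probabilities summing to 1 at every bin; xi_sum is the (2, 2) matrix of
    expected transition counts.
    """
    logB = _log_emissions(np.asarray(counts), model)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    shift = logB.max(axis=1)
    T = len(B)
    A = model.transition
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a = model.initial_probs * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi_sum, loglik


def viterbi_path(counts: np.ndarray, model: HmmModel) -> np.ndarray:
    """Most probable state path (0/1 per bin), log-space."""
    logB = _log_emissions(np.asarray(counts), model)
    logA = np.log(model.transition + 1e-300)
    T = len(logB)
    delta = np.log(model.initial_probs + 1e-300) + logB[0]
    back = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + logB[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ------------------------------------------------------- EM fitting


def _kmeans_init(counts: np.ndarray, nodes: int) -> HmmModel:
    """Seed emission means with k-means (k=2) on log counts; sigma = 0.5,
    self-transition 0.99. Reproducible and scale-free."""
    from sklearn.cluster import KMeans

    x = np.log(np.asarray(counts, dtype=float) + 1.0).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(x)
    mu = np.sort(km.cluster_centers_.ravel())
    if mu[1] - mu[0] < 1e-6:
        mu = np.array([mu[0] - 0.25, mu[0] + 0.25])
    return HmmModel(
        initial_probs=np.array([0.5, 0.5]),
        transition=np.array([[0.99, 0.01], [0.01, 0.99]]),
        mu=mu,
        sigma=np.array([0.5, 0.5]),
        quadrature_nodes=nodes,
    )


def _mstep_emission(
    uniq: np.ndarray, weights: np.ndarray, mu0: float, sigma0: float, nodes: int
) -> tuple[float, float]:
    """Maximize the weighted PLN log-likelihood over (mu, sigma).

    Generalized-EM guard: fall back to the incoming parameters when the
    optimizer fails to improve, so the EM objective never decreases.
    """

    def neg(x):
        m, ls = x
        s = np.exp(ls)
        return -float(weights @ plnorm_logpmf(uniq, m, s, nodes))

    x0 = np.array([mu0, np.log(sigma0)])
    res = minimize(
        neg,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200},
    )
    if res.fun <= neg(x0):
        return float(res.x[0]), float(np.exp(np.clip(res.x[1], np.log(1e-3), np.log(10))))
    return mu0, sigma0


def fit_hmm(
    track_or_counts,
    init: HmmModel | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    nodes: int = 64,
) -> HmmModel:
    """Baum-Welch fit of the two-state PLN HMM.

    Accepts a :class:`~tuscan.tracks.CoverageTrack` (all chromosome/strand
    vectors concatenated; augmented counts) or a plain count vector. The
    log-likelihood is non-decreasing across iterations; fitting stops when
    its change drops below ``tol`` or after ``max_iter`` iterations.
    """
    if isinstance(track_or_counts, CoverageTrack):
        counts = np.concatenate(
            [track_or_counts.counts(c, s) for c in track_or_counts.chroms for s in "+-"]
        )
    else:
        counts = np.asarray(track_or_counts)
    if counts.size == 0:
        raise ValueError("empty coverage")
    model = init if init is not None else _kmeans_init(counts, nodes)
    if len(np.unique(counts)) == 1:
        warnings.warn("all-constant coverage: emission states are degenerate")
        model = HmmModel(
            initial_probs=model.initial_probs,
            transition=model.transition,
            mu=model.mu,
            sigma=model.sigma,
            quadrature_nodes=model.quadrature_nodes,
            degenerate=True,
        )
        return model.order_states()

    uniq, inv = np.unique(counts, return_inverse=True)
    prev_ll = -np.inf
    lls = []
    for _ in range(max_iter):
        gamma, xi_sum, ll = forward_backward(counts, model)
        lls.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
        A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        pi = gamma[0] / gamma[0].sum()
        mu = model.mu.copy()
        sigma = model.sigma.copy()
        for s in range(2):
            w = np.bincount(inv, weights=gamma[:, s], minlength=len(uniq))
            mu[s], sigma[s] = _mstep_emission(
                uniq, w, mu[s], sigma[s], model.quadrature_nodes
            )
        model = HmmModel(
            initial_probs=pi,
            transition=A,
            mu=mu,
            sigma=sigma,
            quadrature_nodes=model.quadrature_nodes,
        )
    model.log_likelihood = prev_ll
    return model.order_states()


# ------------------------------------------------------- decoding


def decode(
    track: CoverageTrack,
    model: HmmModel,
    min_rpk: float = 26.5,
    method: str = "viterbi",
) -> list[Segment]:
    """Decode a coverage track into transcribed segments.

    Maximal runs of the transcribed state become segments; segments with
    fragment-midpoint RPK (pseudo-count-free) below ``min_rpk`` are dropped.
    ``method`` is ``viterbi`` (default) or ``posterior`` (state 1 when its
    posterior exceeds 0.5).
    """
    segments: list[Segment] = []
    for chrom in track.chroms:
        L = track.genome[chrom]
        for strand in "+-":
            counts = track.counts(chrom, strand)
            if method == "viterbi":
                path = viterbi_path(counts, model)
                gamma, _, _ = forward_backward(counts, model)
            elif method == "posterior":
                gamma, _, _ = forward_backward(counts, model)
                path = (gamma[:, 1] > 0.5).astype(np.int8)
            else:
                raise ValueError(f"unknown decode method {method!r}")
            raw = track.raw(chrom, strand)
            for lo, hi in _runs(path):
                start = lo * track.bin_size
                end = min(hi * track.bin_size, L)
                n_mid = int(raw[lo:hi].sum())
                rpk = n_mid / ((end - start) / 1000.0)
                if rpk < min_rpk:
                    continue
                iv = GenomicInterval(chrom, start, end, strand, score=round(rpk, 3))
                segments.append(
                    Segment(
                        interval=iv,
                        mean_coverage=float(raw[lo:hi].mean()),
                        posterior_mean=float(gamma[lo:hi, 1].mean()),
                        rpk=rpk,
                    )
                )
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.strand))
    return segments


def _runs(path: np.ndarray):
    """Maximal runs of state 1 as (lo, hi) bin slices."""
    d = np.diff(np.concatenate(([0], path.astype(np.int8), [0])))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends))


# ------------------------------------------------------- boundary refinement


def refine_boundary(
    coverage: np.ndarray,
    initial_boundary: int,
    window_bins: int = 4,
    bin_size: int = 200,
    origin: int = 0,
) -> int:
    """Sharpen a segment border by fitting a two-level step function.

    ``coverage`` holds per-bp (or per-bin with ``bin_size=1``) values
    starting at genomic position ``origin``. Candidate changepoints c span
    the ``window_bins`` bins centred on ``initial_boundary``; the SSE of the
    best (left-mean, right-mean) step split at c is minimized, ties broken
    toward the initial boundary.
    """
    half = window_bins * bin_size // 2
    lo = initial_boundary - half
    hi = initial_boundary + half
    if lo < origin or hi > origin + len(coverage):
        warnings.warn("refinement window clipped to available coverage")
        lo = max(lo, origin)
        hi = min(hi, origin + len(coverage))
    w = np.asarray(coverage[lo - origin : hi - origin], dtype=float)
    n = len(w)
    if n < 2:
        return initial_boundary
    csum = np.concatenate(([0.0], np.cumsum(w)))
    csq = np.concatenate(([0.0], np.cumsum(w * w)))
    # candidate split index i in [1, n-1]: left w[:i], right w[i:]
    i = np.arange(1, n)
    left_n = i.astype(float)
    right_n = (n - i).astype(float)
    left_sum = csum[i]
    right_sum = csum[n] - csum[i]
    sse = (
        csq[i] - left_sum**2 / left_n + (csq[n] - csq[i]) - right_sum**2 / right_n
    )
    best = sse.min()
    cand = i[np.isclose(sse, best, rtol=0, atol=1e-9)]
    pos = cand + lo
    # ties toward the initial boundary, then lower coordinate
    order = np.lexsort((pos, np.abs(pos - initial_boundary)))
    return int(pos[order[0]])
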