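"""Transfer FDR: composite LDA scoring, mixture model, posteriors, q-values.

Transfers already identified by MS/MS in the acceptor run (type 2) and
their m/z-shifted decoys (type -2) provide labelled training data for a
Fisher linear discriminant; its weights turn the per-transfer scores into a
single composite score s = sum_i w_i b_i.  The composite scores of the
remaining transfers (type 1) and their decoys (type -1) are modelled as a
two-component mixture f(s) = pi_true f_true(s) + pi_false f_false(s) fitted
by expectation-maximization, the false component anchored on the decoy
score distribution when decoys are available.  The posterior probability of
a correct transfer is

    p(s) = pi_true f_true(s) / (pi_false f_false(s) + pi_true f_true(s))

and the global FDR above a score threshold t is the average local FDR
FDR(t) = sum_{s_i >= t} (1 - p(s_i)) / #{s_i >= t}, monotonized into
q-values.
"""
from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.linalg import solve

log = logging.getLogger(__name__)

_SD_FLOOR = 1e-3


class FdrModelError(ValueError):
    """A model required for transfer FDR could not be trained."""


@dataclasses.dataclass
class LdaModel:
    """Fisher discriminant separating true-like (type 2) from decoy (type -2)."""

    weights: np.ndarray
    intercept: float

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.size:
            raise ValueError(
                f"expected {self.weights.size} score dimensions, got {X.shape[1]}"
            )
        return X @ self.weights + self.intercept


def train_lda(
    type2_scores: np.ndarray,
    typem2_scores: np.ndarray,
    min_class: int = 20,
    ridge: float = 1e-6,
) -> LdaModel:
    """Closed-form Fisher LDA: w proportional to pooled-Sigma^-1 (mu2 - mu-2).

    The pooled covariance gets a ridge proportional to its trace so that
    collinear score columns still yield finite weights.  Orientation is
    fixed so the mean type-2 composite exceeds the mean type -2 composite.
    """
    X2 = np.atleast_2d(np.asarray(type2_scores, dtype=float))
    Xm = np.atleast_2d(np.asarray(typem2_scores, dtype=float))
    if X2.shape[0] < min_class or Xm.shape[0] < min_class:
        raise FdrModelError(
            f"need >= {min_class} examples per class to train the transfer "
            f"discriminant (got {X2.shape[0]} target-like, {Xm.shape[0]} decoy); "
            "disable transfer FDR or add runs"
        )
    mu2 = X2.mean(axis=0)
    mum = Xm.mean(axis=0)
    n2, nm = X2.shape[0], Xm.shape[0]
    S2 = np.cov(X2, rowvar=False, ddof=1)
    Sm = np.cov(Xm, rowvar=False, ddof=1)
    Sw = ((n2 - 1) * np.atleast_2d(S2) + (nm - 1) * np.atleast_2d(Sm)) / (n2 + nm - 2)
    d = Sw.shape[0]
    Sw = Sw + (ridge * max(np.trace(Sw), 1.0) / d) * np.eye(d)
    w = solve(Sw, mu2 - mum, assume_a="pos")
    intercept = float(-0.5 * w @ (mu2 + mum))
    model = LdaModel(weights=w, intercept=intercept)
    if model.score(X2).mean() < model.score(Xm).mean():
        model = LdaModel(weights=-w, intercept=-intercept)
    return model


def composite_scores(model: LdaModel, scores: np.ndarray) -> np.ndarray:
    """Composite score s = sum_i w_i b_i (+ intercept) per candidate."""
    return model.score(scores)


def _norm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))


def _logsumexp2(cols: list[np.ndarray]) -> np.ndarray:
    M = np.stack(cols, axis=0)
    mx = M.max(axis=0)
    return mx + np.log(np.exp(M - mx).sum(axis=0))


@dataclasses.dataclass
class MixtureFit:
    """Two-population mixture of transfer composite scores.

    The *true* population (correct transfers) enters the posterior
    numerator and may itself be a small Gaussian mixture (skewed score
    distributions); the *false* population models incorrect transfers and
    is anchored on decoy scores when available.
    """

    pi_true: float
    pi_false: float
    true_weights: np.ndarray  # sum to 1 over the true sub-components
    true_means: np.ndarray
    true_sds: np.ndarray
    mu_false: float
    sd_false: float
    converged: bool
    n_iter: int
    loglik_path: np.ndarray
    anchored: bool
    kde_null: object | None = None  # optional gaussian_kde over decoy scores

    @property
    def mu_true(self) -> float:
        """Weighted mean of the true population."""
        return float(np.dot(self.true_weights, self.true_means))

    @property
    def sd_true(self) -> float:
        """Weighted within+between sd of the true population."""
        m = self.mu_true
        var = np.dot(self.true_weights,
                     self.true_sds ** 2 + (self.true_means - m) ** 2)
        return float(math.sqrt(max(var, 0.0)))

    def logpdf_true(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        cols = [math.log(max(w, 1e-300)) + _norm_logpdf(s, mu, sd)
                for w, mu, sd in zip(self.true_weights, self.true_means,
                                     self.true_sds)]
        return _logsumexp2(cols)

    def logpdf_false(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.kde_null is not None:
            with np.errstate(divide="ignore"):
                return np.log(np.maximum(self.kde_null(s), 1e-300))
        return _norm_logpdf(s, self.mu_false, self.sd_false)


def fit_mixture(
    scores: np.ndarray,
    decoy_scores: np.ndarray | None = None,
    min_scores: int = 100,
    max_iter: int = 1000,
    tol: float = 1e-8,
    kde_null: bool = False,
    n_true_components: int = 1,
) -> MixtureFit:
    """Fit the score mixture by EM.

    With decoys (>= 20), the false component is pinned to the decoy score
    distribution (Gaussian moments, or a kernel density with ``kde_null``)
    and EM estimates the priors and the true population, itself modelled
    as a mixture of ``n_true_components`` Gaussians (useful for skewed
    true-score distributions).  Without decoys a free two-Gaussian EM is
    run (one Gaussian per population) from a deterministic median-split
    initialization.  The likelihood is non-decreasing across iterations;
    non-convergence returns the best fit with ``converged=False``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < min_scores:
        raise FdrModelError(
            f"need >= {min_scores} transfer scores to fit the mixture, got {s.size}"
        )
    if np.ptp(s) == 0:
        raise FdrModelError("degenerate fit: all transfer scores identical")

    anchored = decoy_scores is not None and np.asarray(decoy_scores).size >= 20
    kde = None
    K = max(int(n_true_components), 1) if anchored else 1

    def _moments(x: np.ndarray, fallback_mu: float):
        if x.size == 0:
            return fallback_mu, 1.0
        mu = float(x.mean())
        sd = max(float(x.std(ddof=1)) if x.size > 1 else 1.0, _SD_FLOOR)
        return mu, sd

    if anchored:
        dec = np.asarray(decoy_scores, dtype=float)
        mu_f = float(dec.mean())
        sd_f = max(float(dec.std(ddof=1)) if dec.size > 1 else 0.0, _SD_FLOOR)
        if kde_null and np.ptp(dec) > 0:
            from scipy.stats import gaussian_kde

            kde = gaussian_kde(dec)
        upper = np.sort(s[s > np.median(s)])
        if upper.size == 0:
            upper = np.sort(s)
        # deterministic init: split the upper half into K equal slices
        chunks = np.array_split(upper, K)
        mus, sds = zip(*[_moments(c, float(s.mean()) + 1.0) for c in chunks])
        w_true = np.full(K, 0.5 / K)
        mu_t = np.asarray(mus)
        sd_t = np.asarray(sds)
        pi_f = 0.5
    else:
        med = float(np.median(s))
        lower, upper = s[s <= med], s[s > med]
        mu_f, sd_f = _moments(lower, med - 1.0)
        mu_u, sd_u = _moments(upper, med + 1.0)
        w_true = np.array([upper.size / s.size if upper.size else 0.5])
        mu_t = np.array([mu_u])
        sd_t = np.array([sd_u])
        pi_f = 1.0 - w_true[0]

    def _log_false() -> np.ndarray:
        if kde is not None:
            with np.errstate(divide="ignore"):
                return np.log(np.maximum(kde(s), 1e-300))
        return _norm_logpdf(s, mu_f, sd_f)

    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cols = [math.log(max(w, 1e-300)) + _norm_logpdf(s, mu, sd)
                for w, mu, sd in zip(w_true, mu_t, sd_t)]
        cols.append(math.log(max(pi_f, 1e-300)) + _log_false())
        M = np.stack(cols, axis=0)
        mx = M.max(axis=0)
        denom = mx + np.log(np.exp(M - mx).sum(axis=0))
        R = np.exp(M - denom)  # responsibilities: K true rows + 1 false row
        ll = float(denom.sum())
        logliks.append(ll)

        nk = R.sum(axis=1)
        w_new = np.clip(nk / s.size, 1e-8, 1.0)
        w_new /= w_new.sum()
        pi_f = float(w_new[-1])
        w_true = w_new[:-1]
        for k in range(K):
            if nk[k] > 1e-12:
                mu_t[k] = float((R[k] * s).sum() / nk[k])
                sd_t[k] = max(
                    math.sqrt(max((R[k] * (s - mu_t[k]) ** 2).sum() / nk[k], 0.0)),
                    _SD_FLOOR)
        if not anchored and nk[-1] > 1e-12:
            mu_f = float((R[-1] * s).sum() / nk[-1])
            sd_f = max(math.sqrt(max((R[-1] * (s - mu_f) ** 2).sum() / nk[-1], 0.0)),
                       _SD_FLOOR)
        if len(logliks) > 1:
            prev = logliks[-2]
            if abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
    if not converged:
        log.warning("mixture EM did not converge in %d iterations", it)

    pi_t = float(w_true.sum())
    if anchored:
        # identifiability guard: on data fully explained by the decoy null
        # the likelihood is flat in the priors; collapse the true population
        # unless the mixture beats the null-only model by its BIC cost.
        ll_null = float(_log_false().sum())
        n_params = 3 * K  # weight, mean, sd per true sub-component
        if 2.0 * (logliks[-1] - ll_null) < n_params * math.log(s.size):
            log.warning("mixture indistinguishable from the decoy null; "
                        "collapsing the true-transfer prior to ~0")
            pi_t = 1e-6
            w_true = w_true * (pi_t / max(w_true.sum(), 1e-300))
    fit = MixtureFit(
        pi_true=pi_t, pi_false=1.0 - pi_t,
        true_weights=w_true / max(pi_t, 1e-300), true_means=mu_t.copy(),
        true_sds=sd_t.copy(), mu_false=mu_f, sd_false=sd_f,
        converged=converged, n_iter=it, loglik_path=np.asarray(logliks),
        anchored=anchored, kde_null=kde,
    )
    if not anchored and fit.mu_true < fit.mu_false:
        # relabel so the high-score component is the true one
        fit = dataclasses.replace(
            fit, pi_true=fit.pi_false, pi_false=fit.pi_true,
            true_weights=np.array([1.0]), true_means=np.array([fit.mu_false]),
            true_sds=np.array([fit.sd_false]), mu_false=fit.true_means[0],
            sd_false=fit.true_sds[0],
        )
    return fit


def posteriors(fit: MixtureFit, scores: np.ndarray) -> np.ndarray:
    """Posterior probability of a correct transfer for each score."""
    s = np.asarray(scores, dtype=float)
    a = math.log(max(fit.pi_true, 1e-300)) + fit.logpdf_true(s)
    b = math.log(max(fit.pi_false, 1e-300)) + fit.logpdf_false(s)
    mx = np.maximum(a, b)
    p = np.exp(a - mx) / (np.exp(a - mx) + np.exp(b - mx))
    return np.clip(p, 0.0, 1.0)


def qvalues(scores: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Monotone global FDR estimate per entry from posterior probabilities.

    Entries are ranked by score (descending); the running mean of the local
    FDR 1 - p gives FDR-hat at each threshold, monotonized by a cumulative
    minimum from the lowest score up so that q is non-increasing in the
    threshold.  Returned in the input order.
    """
    s = np.asarray(scores, dtype=float)
    p = np.asarray(post, dtype=float)
    order = np.argsort(-s, kind="stable")
    fdr = np.cumsum(1.0 - p[order]) / np.arange(1, s.size + 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q
    return out


def accept_at_level(
    scores: np.ndarray,
    post: np.ndarray,
    keys: list,
    alpha: float,
) -> set:
    """Collapse entries by ``keys`` (max-posterior representative), compute
    q-values at the collapsed level and return the accepted key set."""
    best: dict[object, int] = {}
    for idx, k in enumerate(keys):
        if k not in best or post[idx] > post[best[k]] or (
            post[idx] == post[best[k]] and scores[idx] > scores[best[k]]
        ):
            best[k] = idx
    reps = sorted(best.items(), key=lambda kv: str(kv[0]))
    rep_idx = np.array([i for _, i in reps], dtype=int)
    if rep_idx.size == 0:
        return set()
    q = qvalues(np.asarray(scores)[rep_idx], np.asarray(post)[rep_idx])
    return {reps[j][0] for j in range(rep_idx.size) if q[j] <= alpha}
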