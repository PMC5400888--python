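"""EM mixture clustering, cross-validated model selection, partition metrics.

The mixture treats features as conditionally independent given the
component ("diagonal" model), with a distributional form per feature
kind:

* count features (n-gram, lexicon-term and message counts) follow a
  Poisson with a per-component smoothed rate — the rate estimate is
  shrunk toward the global mean rate by a pseudocount, which keeps
  held-out likelihoods finite when a component never saw a term;
* continuous features (the style ratios) follow a Gaussian whose
  variance is floored at a fraction of the feature's global variance.

Hard labels are the argmax of the posterior (ties to the lowest index).

The number of components is chosen by a forward search on mean held-out
log-likelihood under k-fold cross-validation: K grows from 1 while the
CV log-likelihood improves, and the search returns the last improving K.

Partition agreement between two labelings is computed by pair counting:
with a = pairs co-clustered in both, b = co-clustered in the reference
only, c = co-clustered in the prediction only, d = in neither,
Rand = (a+d)/(a+b+c+d), Jaccard = a/(a+b+c), FM = a/sqrt((a+b)(a+c)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp
from sklearn.model_selection import KFold

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


def _split_blocks(X: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(count block, continuous block, is_count mask). Plain arrays are
    treated as all-continuous."""
    if isinstance(X, FeatureMatrix):
        mask = X.is_count
        V = X.values.astype(float)
        return V[:, mask], V[:, ~mask], mask
    V = np.atleast_2d(np.asarray(X, dtype=float))
    mask = np.zeros(V.shape[1], dtype=bool)
    return V[:, :0], V, mask


@dataclass
class MixtureModel:
    """A fitted mixture: weights plus per-feature component parameters.

    ``rates`` holds the smoothed Poisson rates of the count features,
    ``means``/``variances`` the Gaussian parameters of the continuous
    features; ``is_count`` records which original column went where.
    """

    K: int
    weights: np.ndarray  # (K,)
    rates: np.ndarray  # (K, d_count), > 0
    means: np.ndarray  # (K, d_cont)
    variances: np.ndarray  # (K, d_cont), floored
    is_count: np.ndarray  # (d,) bool over original columns
    log_likelihood: float
    feature_names: list[str] | None = None
    n_iter: int = 0

    def _weighted_log_prob(
        self, C: np.ndarray, G: np.ndarray, lgC: np.ndarray | None = None
    ) -> np.ndarray:
        n = max(C.shape[0], G.shape[0])
        wlp = np.broadcast_to(np.log(self.weights), (n, self.K)).copy()
        if C.shape[1]:
            if lgC is None:  # constant in the parameters; hoisted by EM loops
                lgC = gammaln(C + 1).sum(axis=1)
            wlp += C @ np.log(self.rates).T - self.rates.sum(axis=1) - lgC[:, None]
        if G.shape[1]:
            inv = 1.0 / self.variances
            quad = (
                (G**2) @ inv.T
                - 2.0 * G @ (self.means * inv).T
                + np.sum(self.means**2 * inv, axis=1)
            )
            wlp += -0.5 * (
                G.shape[1] * _LOG2PI + np.sum(np.log(self.variances), axis=1) + quad
            )
        return wlp

    def weighted_log_prob(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        C, G, _ = _split_blocks(X)
        return self._weighted_log_prob(C, G)

    def score_samples(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        """Per-unit mixture log-likelihood."""
        return logsumexp(self.weighted_log_prob(X), axis=1)


@dataclass
class ClusterAssignment:
    """Posterior membership matrix and hard labels for a set of units."""

    unit_ids: list[str]
    posterior: np.ndarray  # (n, K), rows sum to 1
    labels: np.ndarray  # (n,), argmax of posterior, ties to lowest index


def _seed_centers(Z: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """D^2-weighted (k-means++ style) choice of K seed rows."""
    n = Z.shape[0]
    centers = [int(rng.integers(n))]
    if K > 1:
        d2 = np.sum((Z - Z[centers[0]]) ** 2, axis=1)
        for _ in range(K - 1):
            total = d2.sum()
            if total <= 0:
                centers.append(int(rng.integers(n)))
                continue
            j = int(rng.choice(n, p=d2 / total))
            centers.append(j)
            d2 = np.minimum(d2, np.sum((Z - Z[j]) ** 2, axis=1))
    return np.asarray(centers)


def _em_single(
    C: np.ndarray,
    G: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    rate_smoothing: float,
    var_floor: np.ndarray,
    lgC: np.ndarray | None = None,
) -> tuple[MixtureModel, float]:
    n = max(C.shape[0], G.shape[0])
    gmean = np.maximum(C.mean(axis=0), 1e-4) if C.shape[1] else np.zeros(0)
    if lgC is None:
        lgC = gammaln(C + 1).sum(axis=1) if C.shape[1] else np.zeros(n)

    centers = _seed_centers(np.hstack([np.log1p(C), G]), K, rng)
    rates = (C[centers] + rate_smoothing * gmean) / (1.0 + rate_smoothing)
    means = G[centers] + rng.normal(scale=1e-3, size=(K, G.shape[1]))
    variances = np.tile(np.maximum(G.var(axis=0), var_floor), (K, 1))
    weights = np.full(K, 1.0 / K)

    def rate_penalty(r: np.ndarray) -> float:
        # Gamma-prior term matching the smoothed M-step; the EM ascent
        # guarantee applies to ll + this penalty, not to ll alone.
        if not C.shape[1] or rate_smoothing == 0.0:
            return 0.0
        return float(rate_smoothing * (gmean * np.log(r) - r).sum())

    model = MixtureModel(K, weights, rates, means, variances, np.zeros(0, bool), -np.inf)
    prev_ll = -np.inf
    prev_obj = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        wlp = model._weighted_log_prob(C, G, lgC)
        norm = logsumexp(wlp, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood in EM")
        # MAP-EM guarantees a non-decreasing penalized objective; small
        # violations can only come from variance flooring or FP noise.
        # Reviving an empty component intentionally restarts the ascent.
        obj = ll + rate_penalty(model.rates)
        if obj < prev_obj - 1e-6 * max(1.0, abs(prev_obj)):
            raise AssertionError(
                f"EM objective decreased: {prev_obj} -> {obj} at iter {n_iter}"
            )
        prev_obj = obj
        resp = np.exp(wlp - norm[:, None])
        if ll - prev_ll < tol * max(1.0, abs(ll)) and n_iter > 1:
            prev_ll = ll
            break
        prev_ll = ll

        nk = resp.sum(axis=0)
        for k in np.flatnonzero(nk < 1e-10):  # revive empty components
            j = int(rng.integers(n))
            resp[:, k] = 0.0
            resp[j, k] = 1.0
            prev_obj = -np.inf
        nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        if C.shape[1]:
            rates = (resp.T @ C + rate_smoothing * gmean) / (
                nk[:, None] + rate_smoothing
            )
        if G.shape[1]:
            means = (resp.T @ G) / nk[:, None]
            ex2 = (resp.T @ (G**2)) / nk[:, None]
            variances = np.maximum(ex2 - means**2, var_floor)
        model = MixtureModel(K, weights, rates, means, variances, np.zeros(0, bool), ll)
    model.log_likelihood = prev_ll
    model.n_iter = n_iter
    return model, prev_ll


def fit_em(
    X: FeatureMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    n_init: int = 5,
    rate_smoothing: float = 5.0,
    var_floor: float = 1e-6,
    var_floor_frac: float = 0.1,
) -> tuple[MixtureModel, ClusterAssignment]:
    """Fit a K-component mixture by EM, best of ``n_init`` restarts.

    Count columns get Poisson components (rates shrunk toward the global
    mean by ``rate_smoothing`` pseudocounts); continuous columns get
    Gaussians with variances floored at
    ``max(var_floor, var_floor_frac * global variance)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    C, G, mask = _split_blocks(X)
    n = max(C.shape[0], G.shape[0])
    if n < K:
        raise ValueError(f"cannot fit {K} components to {n} units")
    rng = np.random.default_rng(seed)
    floor = np.maximum(var_floor, var_floor_frac * G.var(axis=0)) if G.shape[1] else np.zeros(0)
    lgC = gammaln(C + 1).sum(axis=1) if C.shape[1] else np.zeros(n)

    best: MixtureModel | None = None
    for _ in range(max(1, n_init)):
        model, ll = _em_single(C, G, K, rng, tol, max_iter, rate_smoothing, floor, lgC)
        if best is None or ll > best.log_likelihood:
            best = model
    best.is_count = mask
    best.feature_names = X.feature_names if isinstance(X, FeatureMatrix) else None

    wlp = best._weighted_log_prob(C, G, lgC)
    post = np.exp(wlp - logsumexp(wlp, axis=1)[:, None])
    labels = np.argmax(post, axis=1)  # argmax ties break to the lowest index
    ids = (
        list(X.unit_ids) if isinstance(X, FeatureMatrix) else [str(i) for i in range(n)]
    )
    return best, ClusterAssignment(ids, post, labels)


def select_k(
    X: FeatureMatrix | np.ndarray,
    k_max: int = 6,
    folds: int = 10,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-5,
    max_iter: int = 200,
    rate_smoothing: float = 5.0,
    var_floor: float = 1e-6,
    var_floor_frac: float = 0.1,
) -> tuple[int, dict[int, float]]:
    """Choose the component count by cross-validated forward search.

    For K = 1, 2, ... the mean per-unit held-out log-likelihood over
    ``folds`` folds is computed; the search stops at the first K that
    fails to improve on K-1 and returns the previous K. Returns the
    selected K and the per-K CV log-likelihood table.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    C, G, _ = _split_blocks(X)
    n = max(C.shape[0], G.shape[0])
    folds = min(folds, n)
    # The floor is computed once on the full data so every fold and every
    # K is scored against the same density family.
    floor = np.maximum(var_floor, var_floor_frac * G.var(axis=0)) if G.shape[1] else np.zeros(0)
    lgC = gammaln(C + 1).sum(axis=1) if C.shape[1] else np.zeros(n)
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    splits = list(kf.split(np.arange(n)))

    cv_table: dict[int, float] = {}
    best_k = 1
    prev_score = -np.inf
    for K in range(1, k_max + 1):
        total_ll = 0.0
        for train_idx, test_idx in splits:
            if len(train_idx) < K:
                total_ll = -np.inf
                break
            best_model, best_ll = None, -np.inf
            for _ in range(max(1, n_init)):
                model, ll = _em_single(
                    C[train_idx], G[train_idx], K, rng, tol, max_iter,
                    rate_smoothing, floor, lgC[train_idx],
                )
                if ll > best_ll:
                    best_model, best_ll = model, ll
            total_ll += float(
                logsumexp(
                    best_model._weighted_log_prob(
                        C[test_idx], G[test_idx], lgC[test_idx]
                    ),
                    axis=1,
                ).sum()
            )
        score = total_ll / n
        cv_table[K] = score
        if score > prev_score:
            best_k = K
            prev_score = score
        else:
            break
    return best_k, cv_table


@dataclass(frozen=True)
class PartitionMetrics:
    """Pair-counting agreement between two partitions, each in [0, 1]."""

    rand: float
    jaccard: float
    fm: float


def _pair_counts(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int, int]:
    """(a, b, c, d) pair counts via the contingency table."""
    n = len(pred)
    _, pi = np.unique(pred, return_inverse=True)
    _, ri = np.unique(ref, return_inverse=True)
    cont = np.zeros((pi.max() + 1, ri.max() + 1), dtype=np.int64)
    np.add.at(cont, (pi, ri), 1)

    def comb2(x):
        return int((x * (x - 1) // 2).sum())

    total = n * (n - 1) // 2
    a = comb2(cont)
    same_pred = comb2(cont.sum(axis=1))
    same_ref = comb2(cont.sum(axis=0))
    b = same_ref - a  # co-clustered in reference only
    c = same_pred - a  # co-clustered in prediction only
    d = total - a - b - c
    return a, b, c, d


def partition_metrics(pred_labels, ref_labels) -> PartitionMetrics:
    """Rand, Jaccard and Fowlkes-Mallows indices between two labelings."""
    pred = np.asarray(pred_labels)
    ref = np.asarray(ref_labels)
    if pred.shape != ref.shape:
        raise ValueError("label vectors must have equal length")
    if len(pred) < 2:
        raise ValueError("need at least 2 units")
    a, b, c, d = _pair_counts(pred, ref)
    total = a + b + c + d
    rand = (a + d) / total
    jaccard = a / (a + b + c) if (a + b + c) else 0.0
    fm = a / np.sqrt((a + b) * (a + c)) if a else 0.0
    return PartitionMetrics(rand=float(rand), jaccard=float(jaccard), fm=float(fm))


def two_sample_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t test (two-sided).

    Degenerate case: both samples constant with equal means gives
    (t, p) = (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must have size >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def cluster_t_tests(
    X: FeatureMatrix | np.ndarray, assignment: ClusterAssignment, model: MixtureModel
) -> dict[tuple[int, int], tuple[float, float]]:
    """Pairwise Welch t tests between clusters.

    The per-member statistic is the posterior-weighted component-summary
    score: s_i = posterior_i . rowmean(component parameters). Returns
    {(i, j): (t, p)} for every unordered cluster pair with >= 2 members
    on each side.
    """
    summary = np.hstack([model.rates, model.means]).mean(axis=1)
    scores = assignment.posterior @ summary
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(model.K):
        for j in range(i + 1, model.K):
            si = scores[assignment.labels == i]
            sj = scores[assignment.labels == j]
            if len(si) >= 2 and len(sj) >= 2:
                out[(i, j)] = two_sample_t(si, sj)
    return out
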