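"""Deterministic Bayesian fine-mapping of a z-score panel.

The locus model is multivariate normal on the z-score scale,

.. math::

    Z \\sim N(R\\beta, R),

where ``R`` is the null correlation of the factor z-scores and the sparse
effect vector β is non-zero on a configuration γ drawn from an independent
Bernoulli prior (default inclusion probability 1/p), with non-zero entries
i.i.d. mean-zero normal with variance φ² (a single value or a grid with
mixture weights).  For a configuration S this yields the closed-form Bayes
factor

.. math::

    \\log BF(S) = -\\tfrac12 \\log\\det(I + \\varphi^2 R_{SS})
                 + \\tfrac12 z_S'(R_{SS} + \\varphi^{-2} I)^{-1} z_S ,

the ratio of the two zero-mean Gaussian densities of Z with covariances
``R + φ² R_{·S} R_{S·}`` and ``R``.

The adaptive search evaluates the null and all single-factor models exactly,
admits candidate factors whose single-factor posterior odds against the null
model exceed ``10^{-λ}``, grows model size by expanding retained models with
candidates, and stops when a size level contributes less than ``10^{-λ}`` of
the cumulative explored weight.  Posterior mass of the
never-evaluated remainder of the model space is approximated
combinatorially with elementary-symmetric-polynomial dynamic programmes in
log space: an unexplored model factorizes into its candidate part — scored
by its exact explored weight where available, by the product of
single-factor Bayes factors otherwise — times the product of its
non-candidate (noise) factors' single-factor weights.  Scoring the
candidate part exactly matters: strong correlated factors violate the
product approximation by orders of magnitude, and anchoring them at their
explored weights is what makes the result insensitive to the exploration
threshold λ.  Factors
are finally aggregated into signal clusters by a greedy complete-linkage
rule on squared correlation.

Everything is deterministic: identical inputs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.linalg import LinAlgError
from scipy.special import logsumexp

from .fbat_score import ZPanel

LN10 = math.log(10.0)
NEG_INF = -math.inf

DEFAULT_LAMBDA = 2.0
DEFAULT_K_MAX = 5
DEFAULT_CLUSTER_R2 = 0.25
DEFAULT_PIP_FLOOR = 0.01
DEFAULT_RETENTION_WINDOW = 4.0
DEFAULT_LD_ADMIT_R2 = 0.25
DEFAULT_PHI2_GRID = (0.04, 0.16, 0.64)
BF_RIDGE = 1e-8


def log10sumexp(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return NEG_INF
    return float(logsumexp(arr * LN10)) / LN10


def log10add(a: float, b: float) -> float:
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    return float(np.logaddexp(a * LN10, b * LN10)) / LN10


def log10diffexp(a: float, b: float) -> float:
    """log10(10^a - 10^b); -inf when the difference underflows to <= 0."""
    if b == NEG_INF:
        return a
    if b >= a:
        return NEG_INF
    x = 10.0 ** (b - a)
    if x >= 1.0:  # difference lost to rounding
        return NEG_INF
    return a + math.log1p(-x) / LN10


@dataclass
class PriorSpec:
    """Configuration prior: per-factor inclusion probabilities and the
    effect-size variance (single value or grid with mixture weights)."""

    pi: np.ndarray
    phi2: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_PHI2_GRID)
    )
    phi2_weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.phi2 = np.atleast_1d(np.asarray(self.phi2, dtype=float))
        if self.phi2_weights is None:
            self.phi2_weights = np.full(self.phi2.size, 1.0 / self.phi2.size)
        self.phi2_weights = np.asarray(self.phi2_weights, dtype=float)
        if np.any(self.pi <= 0.0) or np.any(self.pi >= 1.0):
            raise ValueError("prior inclusion probabilities must lie in (0, 1)")
        if np.any(self.phi2 <= 0.0):
            raise ValueError("effect variance must be positive")
        if self.phi2_weights.shape != self.phi2.shape:
            raise ValueError("phi2 grid and weights must have the same length")
        if abs(self.phi2_weights.sum() - 1.0) > 1e-8:
            raise ValueError("phi2 grid weights must sum to 1")
        self._log10_odds = np.log10(self.pi) - np.log10(1.0 - self.pi)
        self._log10_null = float(np.sum(np.log10(1.0 - self.pi)))

    @classmethod
    def default(
        cls,
        n_factors: int,
        phi2: float | Sequence[float] = DEFAULT_PHI2_GRID,
        phi2_weights: Sequence[float] | None = None,
    ) -> "PriorSpec":
        """Default prior: inclusion probability 1/p for each of p factors."""
        pi = np.full(n_factors, 1.0 / n_factors)
        return cls(pi, np.atleast_1d(np.asarray(phi2, float)),
                   None if phi2_weights is None else np.asarray(phi2_weights, float))

    @property
    def n_factors(self) -> int:
        return self.pi.size


@dataclass
class ModelRecord:
    """One causal configuration γ with its Bayes factor and posterior weight."""

    factor_index_set: tuple[int, ...]
    log10_bf: float
    log10_prior: float

    @property
    def log10_weight(self) -> float:
        return self.log10_bf + self.log10_prior


@dataclass
class Cluster:
    members: list[int]
    cluster_pip: float
    min_r2: float


@dataclass
class FineMapResult:
    """Per-factor PIPs, signal clusters and the explored model space."""

    factor_names: list[str]
    pips: np.ndarray
    log10_nc: float
    clusters: list[Cluster]
    models: list[ModelRecord]
    settings: dict
    #: per-size log10 approximated mass of the unexplored model space
    #: (None when the posterior was normalized over an explicit enumeration)
    log10_unexplored: Optional[list[float]] = None

    @property
    def cluster_assignment(self) -> np.ndarray:
        """Cluster index per factor (-1 for unclustered)."""
        out = np.full(len(self.factor_names), -1, dtype=int)
        for cid, cl in enumerate(self.clusters):
            out[cl.members] = cid
        return out


def _log10_bf_batch_grid(
    idx: np.ndarray, z: np.ndarray, R: np.ndarray, phi2: np.ndarray
) -> np.ndarray:
    """Per-grid-component log10 Bayes factors, shape (G, m).

    ``idx`` is an (m, k) integer array of factor indices; the closed form is
    evaluated with batched linear algebra for each effect variance in the
    grid.
    """
    m, k = idx.shape
    if k == 0:
        return np.zeros((phi2.size, m))
    Zs = z[idx]  # (m, k)
    Rss = R[idx[:, :, None], idx[:, None, :]]  # (m, k, k)
    eye = np.eye(k)
    parts = np.empty((phi2.size, m))
    for g, p2 in enumerate(phi2):
        A = Rss + eye / p2
        try:
            sol = np.linalg.solve(A, Zs[..., None])[..., 0]
        except LinAlgError:  # pragma: no cover - A is PD for PSD R
            import warnings

            warnings.warn("near-singular R submatrix; adding ridge")
            sol = np.linalg.solve(A + BF_RIDGE * eye, Zs[..., None])[..., 0]
        quad = np.einsum("mk,mk->m", Zs, sol)
        _, logdet = np.linalg.slogdet(eye + p2 * Rss)
        parts[g] = 0.5 * (quad - logdet) / LN10
    return parts


def _log10_bf_batch(
    idx: np.ndarray, z: np.ndarray, R: np.ndarray,
    phi2: np.ndarray, weights: np.ndarray,
) -> np.ndarray:
    """log10 Bayes factors for a batch of same-size subsets, combining the
    φ² grid with its mixture weights by log-sum-exp."""
    parts = _log10_bf_batch_grid(idx, z, R, phi2)
    return (
        logsumexp(parts * LN10 + np.log(weights)[:, None], axis=0) / LN10
    )


def _log10_bf_core(
    z_S: np.ndarray, R_SS: np.ndarray, phi2: np.ndarray, weights: np.ndarray
) -> float:
    if z_S.size == 0:
        return 0.0
    k = len(z_S)
    return float(
        _log10_bf_batch(
            np.arange(k)[None, :], z_S, R_SS, phi2, weights
        )[0]
    )


def log10_bf(
    subset: Iterable[int], zpanel: ZPanel, prior: PriorSpec
) -> float:
    """log10 Bayes factor of configuration ``subset`` against the null model."""
    S = sorted(set(int(i) for i in subset))
    z_S = zpanel.z[S]
    R_SS = zpanel.R[np.ix_(S, S)]
    return _log10_bf_core(z_S, R_SS, prior.phi2, prior.phi2_weights)


def model_log10_prior(subset: Iterable[int], prior: PriorSpec) -> float:
    """Independent-Bernoulli configuration prior, in log10."""
    S = set(int(i) for i in subset)
    return prior._log10_null + float(
        sum(prior._log10_odds[i] for i in S)
    )


def log10_esp(log10_phi: np.ndarray, k_max: int) -> np.ndarray:
    """Elementary symmetric sums e_0..e_{k_max} of 10**log10_phi, in log10.

    O(p·k) dynamic programme entirely in log space; exact for non-negative
    terms (which per-factor weights always are).
    """
    e = np.full(k_max + 1, NEG_INF)
    e[0] = 0.0
    for x in log10_phi:
        upper = min(k_max, len(log10_phi))
        for k in range(upper, 0, -1):
            e[k] = log10add(e[k], e[k - 1] + x)
    return e


def unexplored_mass(
    k: int,
    log10_phi: np.ndarray,
    explored: Iterable[frozenset],
    log10_null_prior: float,
) -> float:
    """log10 total approximated weight of all *unexplored* size-k models.

    Each never-evaluated model M is approximated by the product of its
    members' single-factor weights φ_i = BF({i})·π_i/(1−π_i); the total over
    all size-k subsets is the k-th elementary symmetric sum, from which the
    (identically approximated) weights of the exactly evaluated size-k
    subsets are subtracted.
    """
    p = len(log10_phi)
    if k > p or k < 1:
        return NEG_INF
    total = log10_esp(log10_phi, k)[k]
    explored_terms = [
        float(sum(log10_phi[i] for i in S)) for S in explored if len(S) == k
    ]
    remaining = log10diffexp(total, log10sumexp(explored_terms))
    return remaining + log10_null_prior


def build_clusters(
    pips: np.ndarray,
    R: np.ndarray,
    cluster_r2: float = DEFAULT_CLUSTER_R2,
    pip_floor: float = DEFAULT_PIP_FLOOR,
) -> list[Cluster]:
    """Greedy complete-linkage signal clusters in decreasing PIP order.

    Seeds are the highest-PIP unassigned factors with PIP >= ``pip_floor``;
    an unassigned factor joins a cluster only if its squared correlation with
    *every* current member is >= ``cluster_r2``.  Ties broken by panel order.
    """
    p = len(pips)
    order = np.argsort(-pips, kind="stable")
    assigned = np.zeros(p, dtype=bool)
    clusters: list[Cluster] = []
    for seed in order:
        if assigned[seed] or pips[seed] < pip_floor:
            continue
        members = [int(seed)]
        assigned[seed] = True
        for cand in order:
            if assigned[cand]:
                continue
            if all(R[cand, m] ** 2 >= cluster_r2 for m in members):
                members.append(int(cand))
                assigned[cand] = True
        if len(members) > 1:
            min_r2 = min(
                R[a, b] ** 2
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )
        else:
            min_r2 = 1.0
        clusters.append(
            Cluster(
                members=sorted(members),
                cluster_pip=float(np.sum(pips[members])),
                min_r2=float(min_r2),
            )
        )
    return clusters


def _pips_from_space(
    records: dict[frozenset, ModelRecord],
    p: int,
    log10_nc: float,
    log10_phi: np.ndarray | None = None,
    log10_null_prior: float = 0.0,
    k_max: int = 0,
) -> np.ndarray:
    """PIPs from exact explored weights plus (optionally) the combinatorial
    approximation of unexplored models containing each factor."""
    exact = np.full(p, NEG_INF)
    for S, rec in records.items():
        for i in S:
            exact[i] = log10add(exact[i], rec.log10_weight)

    numer = exact.copy()
    if log10_phi is not None and k_max >= 1:
        # single pass: per-factor, per-size log10 sum of the product
        # approximation over *explored* subsets containing the factor
        explored_i = np.full((p, k_max + 1), NEG_INF)
        for S in records:
            k = len(S)
            if k == 0 or k > k_max:
                continue
            w_approx = float(sum(log10_phi[j] for j in S)) + log10_null_prior
            for i in S:
                explored_i[i, k] = log10add(explored_i[i, k], w_approx)
        for i in range(p):
            others = np.delete(log10_phi, i)
            e_other = log10_esp(others, k_max - 1)
            for k in range(1, k_max + 1):
                if k - 1 > len(others):
                    continue
                total_i = log10_phi[i] + e_other[k - 1] + log10_null_prior
                approx = log10diffexp(total_i, explored_i[i, k])
                numer[i] = log10add(numer[i], approx)

    pips = 10.0 ** (numer - log10_nc)
    if np.any(pips > 1.0 + 1e-9):
        raise AssertionError("PIP exceeded 1 beyond tolerance")
    return np.clip(pips, 0.0, 1.0)


def _approximate_unexplored_component(
    W_C: np.ndarray,
    prodC: np.ndarray,
    W_Ci: np.ndarray,
    prodCi: np.ndarray,
    log10_phi: np.ndarray,
    candidates: list[int],
    noise: list[int],
    p: int,
    k_max: int,
    cap_rel: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-phi2-component combinatorial approximation.

    An unexplored model M splits into its candidate part D = M intersect C
    and its noise part M minus C.  D is scored by its exact relative weight
    when it was evaluated and by the product of single-factor weights
    otherwise; every noise factor contributes its single-factor weight
    multiplicatively (exact when noise factors are uncorrelated with the
    rest, since Bayes factors of independent blocks multiply at fixed
    effect variance).  All weights are relative to the null model; per-size
    totals come from elementary-symmetric-sum DPs.

    ``W_C``/``prodC`` are per-size log10 sums of exact relative weights and
    of single-factor products over the *explored* candidate subsets;
    ``W_Ci``/``prodCi`` are the same restricted to subsets containing each
    factor.  Returns per-size log10 unexplored mass (relative) and
    per-factor log10 approximated inclusion weight (relative).
    """
    phi_C = log10_phi[candidates] if candidates else np.empty(0)
    phi_N = log10_phi[noise] if noise else np.empty(0)
    K = k_max

    eC = log10_esp(phi_C, K)
    eN = log10_esp(phi_N, K)
    P_C = np.full(K + 1, NEG_INF)
    for j in range(1, K + 1):
        # candidate subsets left unexplored by the stopping rule or the
        # retention window: the plain product over correlated candidates can
        # vastly overestimate their weight, but the truncation itself
        # certifies that the forfeited mass is below the exploration
        # threshold -- so the estimator is capped by that certificate
        P_C[j] = min(log10diffexp(eC[j], prodC[j]), cap_rel)
    # total candidate-part mass per size (exact where explored, product
    # approximation for the pruned remainder); A[0] = null reference
    A = np.array([0.0] + [log10add(W_C[j], P_C[j]) for j in range(1, K + 1)])

    unexplored = np.full(K, NEG_INF)
    for k in range(1, K + 1):
        terms = []
        for j in range(0, k + 1):
            m = k - j
            if j == 0:
                if m >= 2:  # noise-only; all singletons were evaluated
                    terms.append(eN[m])
            else:
                if m >= 1:
                    terms.append(W_C[j] + eN[m])
                terms.append(P_C[j] + eN[m])
        unexplored[k - 1] = log10sumexp(terms)

    approx_rel = np.full(p, NEG_INF)
    noise_pos = {i: a for a, i in enumerate(noise)}
    for i in noise:
        e_wo = log10_esp(np.delete(phi_N, noise_pos[i]), K - 1)
        terms = []
        for j in range(0, K + 1):
            for m in range(0, K):
                size = j + m + 1
                if size < 2 or size > K:
                    continue
                terms.append(A[j] + e_wo[m])
        approx_rel[i] = log10_phi[i] + log10sumexp(terms)
    cand_pos = {i: a for a, i in enumerate(candidates)}
    for i in candidates:
        e_woC = log10_esp(np.delete(phi_C, cand_pos[i]), K - 1)
        terms = []
        for j in range(1, K + 1):
            P_Ci_j = min(
                log10diffexp(log10_phi[i] + e_woC[j - 1], prodCi[i, j]),
                P_C[j],
            )
            for m in range(0, K - j + 1):
                if m >= 1:
                    terms.append(W_Ci[i, j] + eN[m])
                terms.append(P_Ci_j + eN[m])
        approx_rel[i] = log10sumexp(terms)
    return unexplored, approx_rel


def _grouped_log10sum(keys: np.ndarray, vals: np.ndarray):
    """log10-sum ``vals`` grouped by integer ``keys``.

    ``vals`` may be (n,) or (G, n); returns (unique_keys, sums) with sums of
    matching trailing shape.
    """
    order = np.argsort(keys, kind="stable")
    ks = keys[order]
    bounds = np.nonzero(np.r_[True, ks[1:] != ks[:-1]])[0]
    v = np.take(vals, order, axis=-1) * LN10
    sums = np.logaddexp.reduceat(v, bounds, axis=-1) / LN10
    return ks[bounds], sums


def _approximate_unexplored(
    batches: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    prior: PriorSpec,
    candidates: list[int],
    p: int,
    k_max: int,
    explored_total: float,
    lambda_: float,
) -> tuple[float, list[float], np.ndarray]:
    """Grid-resolved approximation of the never-evaluated model space.

    The effect-variance grid is mixed at the *model* level in exact
    evaluation, so the approximation is run once per grid component -- with
    component-specific single-factor weights and exact component-specific
    explored weights -- and the components are then combined with the
    mixture weights.  ``batches`` holds the evaluated configurations as
    (index array (m, k), per-component log10 BFs (G, m), prior log10-odds
    sums (m,)) tuples; the first batch must be the singletons in factor
    order.  Returns the log10 normalizing constant, per-size log10
    unexplored masses (absolute scale), and per-factor log10 approximated
    inclusion weight relative to the null model.
    """
    w0 = prior._log10_null  # null model weight (BF = 1)
    G = prior.phi2.size
    K = k_max
    logw_g = np.log10(prior.phi2_weights)
    phi_g = batches[0][1] + prior._log10_odds[None, :]  # (G, p)
    cand_mask = np.zeros(p, dtype=bool)
    cand_mask[list(candidates)] = True
    noise = [i for i in range(p) if not cand_mask[i]]
    cap_rel = (explored_total - w0) - lambda_

    W_C = np.full((G, K + 1), NEG_INF)
    prodC = np.full((G, K + 1), NEG_INF)
    ent_key: list[np.ndarray] = []
    ent_rel: list[np.ndarray] = []
    ent_prod: list[np.ndarray] = []
    for idx, parts, odds_sum in batches:
        m, k = idx.shape
        if k == 0 or k > K:
            continue
        sub = cand_mask[idx].all(axis=1)
        if not sub.any():
            continue
        rel = parts[:, sub] + odds_sum[None, sub]  # (G, s)
        prod = phi_g[:, idx[sub]].sum(axis=2)  # (G, s)
        for g in range(G):
            W_C[g, k] = log10add(W_C[g, k], log10sumexp(rel[g]))
            prodC[g, k] = log10add(prodC[g, k], log10sumexp(prod[g]))
        ent_key.append(idx[sub].ravel() * (K + 1) + k)
        ent_rel.append(np.repeat(rel, k, axis=1))
        ent_prod.append(np.repeat(prod, k, axis=1))

    W_Ci = np.full((G, p, K + 1), NEG_INF)
    prodCi = np.full((G, p, K + 1), NEG_INF)
    if ent_key:
        keys = np.concatenate(ent_key)
        uk, rsum = _grouped_log10sum(keys, np.concatenate(ent_rel, axis=1))
        _, psum = _grouped_log10sum(keys, np.concatenate(ent_prod, axis=1))
        fi, fj = uk // (K + 1), uk % (K + 1)
        W_Ci[:, fi, fj] = rsum
        prodCi[:, fi, fj] = psum

    unexp_g = np.full((G, K), NEG_INF)
    approx_g = np.full((G, p), NEG_INF)
    for g in range(G):
        unexp_g[g], approx_g[g] = _approximate_unexplored_component(
            W_C[g], prodC[g], W_Ci[g], prodCi[g], phi_g[g],
            list(candidates), noise, p, K, cap_rel,
        )
    unexplored = [
        log10sumexp(logw_g + unexp_g[:, k]) + w0 for k in range(K)
    ]
    approx_rel = np.array(
        [log10sumexp(logw_g + approx_g[:, i]) for i in range(p)]
    )
    log10_nc = log10sumexp([explored_total] + unexplored)
    return log10_nc, unexplored, approx_rel


def adaptive_dap(
    zpanel: ZPanel,
    prior: PriorSpec | None = None,
    lambda_: float = DEFAULT_LAMBDA,
    k_max: int = DEFAULT_K_MAX,
    cluster_r2: float = DEFAULT_CLUSTER_R2,
    pip_floor: float = DEFAULT_PIP_FLOOR,
    retention_window: float = DEFAULT_RETENTION_WINDOW,
    ld_admit_r2: float = DEFAULT_LD_ADMIT_R2,
) -> FineMapResult:
    """Adaptive deterministic search over causal configurations.

    ``lambda_`` sets the exploration threshold ``10^{-lambda}`` for both
    candidate admission (on single-factor posterior odds against the null
    model) and the level stopping rule; larger values explore more models.
    ``k_max`` caps the model size, ``retention_window`` the log10 distance
    from the best model within which models are expanded further, and
    ``ld_admit_r2`` additionally admits factors in LD with an
    odds-admitted candidate.
    """
    if lambda_ <= 0.0:
        raise ValueError("lambda must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    zpanel.validate()
    p = zpanel.n_factors
    if prior is None:
        prior = PriorSpec.default(p)
    if prior.n_factors != p:
        raise ValueError("prior dimension does not match the panel")

    records: dict[frozenset, ModelRecord] = {}
    batches: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    records[frozenset()] = ModelRecord((), 0.0, prior._log10_null)

    def evaluate_batch(subsets: list[frozenset]) -> np.ndarray:
        """Exact evaluation of same-size configurations, batched; keeps the
        per-component Bayes factors for the unexplored-space machinery.
        Returns the mixture log10 weights of the batch."""
        idx = np.array([sorted(S) for S in subsets], dtype=int)
        parts = _log10_bf_batch_grid(idx, zpanel.z, zpanel.R, prior.phi2)
        bfs = (
            logsumexp(
                parts * LN10 + np.log(prior.phi2_weights)[:, None], axis=0
            )
            / LN10
        )
        odds_sum = prior._log10_odds[idx].sum(axis=1)
        priors = prior._log10_null + odds_sum
        for col, (S, row) in enumerate(zip(subsets, idx)):
            records[S] = ModelRecord(
                factor_index_set=tuple(int(i) for i in row),
                log10_bf=float(bfs[col]),
                log10_prior=float(priors[col]),
            )
        batches.append((idx, parts, odds_sum))
        return bfs + priors

    single_weights = evaluate_batch([frozenset((i,)) for i in range(p)])
    log10_phi = single_weights - prior._log10_null

    # Candidate admission: factor i joins the search when the posterior odds
    # of its single-factor model against the null model,
    # phi_i = BF_i * pi_i / (1 - pi_i), exceed 10^{-lambda}, together with
    # every factor in non-trivial LD (r^2 >= ld_admit_r2) with such a
    # factor.  Factors outside the candidate set are left to the
    # combinatorial approximation, which is safe for them by construction:
    # their own weight is suppressed below the exploration threshold, and
    # being (nearly) uncorrelated with every admitted factor, their
    # single-factor Bayes factors multiply almost exactly.  This is what
    # keeps the result insensitive to the choice of lambda.  (A rule based
    # on *normalized* marginal inclusion is unstable here: a strong proxy
    # can fall below any normalized cutoff when an even stronger signal
    # dominates the locus, and the product approximation of the unexplored
    # {signal, proxy} model then vastly overestimates its weight.)
    base = [i for i in range(p) if log10_phi[i] > -lambda_]
    in_ld = np.zeros(p, dtype=bool)
    for i in base:
        in_ld |= zpanel.R[i] ** 2 >= ld_admit_r2
    candidates = sorted(set(base) | set(np.nonzero(in_ld)[0].tolist()))

    cumulative = log10sumexp(
        [prior._log10_null] + list(single_weights)
    )
    for k in range(2, k_max + 1):
        if not candidates:
            break
        best = max(r.log10_weight for r in records.values())
        cand_set = frozenset(candidates)
        parents = [
            S
            for S, r in records.items()
            if len(S) == k - 1
            and S <= cand_set
            and r.log10_weight >= best - retention_window
        ]
        new_models = sorted(
            {S | {i} for S in parents for i in candidates if i not in S}
            - records.keys(),
            key=sorted,
        )
        if not new_models:
            break
        level_weights = evaluate_batch(new_models)
        level_weight = log10sumexp(level_weights)
        cumulative = log10add(cumulative, level_weight)
        if level_weight < cumulative - lambda_:
            break

    explored_total = log10sumexp(r.log10_weight for r in records.values())
    log10_nc, unexplored, approx_rel = _approximate_unexplored(
        batches, prior, candidates, p, k_max, explored_total, lambda_
    )

    # exact per-factor inclusion over the explored space, grouped
    flat_i = np.concatenate(
        [b[0].ravel() for b in batches if b[0].shape[1] >= 1]
    )
    logw_grid = np.log(prior.phi2_weights)[:, None]
    flat_w = np.concatenate(
        [
            np.repeat(
                logsumexp(b[1] * LN10 + logw_grid, axis=0) / LN10
                + prior._log10_null
                + b[2],
                b[0].shape[1],
            )
            for b in batches
            if b[0].shape[1] >= 1
        ]
    )
    exact = np.full(p, NEG_INF)
    uk, sums = _grouped_log10sum(flat_i, flat_w)
    exact[uk] = sums

    w0 = prior._log10_null
    numer = np.array(
        [log10add(exact[i], approx_rel[i] + w0) for i in range(p)]
    )
    pips = 10.0 ** (numer - log10_nc)
    if np.any(pips > 1.0 + 1e-9):
        raise AssertionError("PIP exceeded 1 beyond tolerance")
    pips = np.clip(pips, 0.0, 1.0)
    clusters = build_clusters(pips, zpanel.R, cluster_r2, pip_floor)
    models = sorted(
        records.values(), key=lambda r: (-r.log10_weight, r.factor_index_set)
    )
    return FineMapResult(
        factor_names=list(zpanel.names),
        pips=pips,
        log10_nc=log10_nc,
        clusters=clusters,
        models=models,
        log10_unexplored=unexplored,
        settings={
            "method": "adaptive",
            "lambda": lambda_,
            "k_max": k_max,
            "cluster_r2": cluster_r2,
            "pip_floor": pip_floor,
            "retention_window": retention_window,
            "ld_admit_r2": ld_admit_r2,
            "phi2": list(map(float, prior.phi2)),
            "phi2_weights": list(map(float, prior.phi2_weights)),
        },
    )


def finemap_frames(result: FineMapResult):
    """Per-factor, cluster and ranked-model tables as DataFrames."""
    import pandas as pd

    assign = result.cluster_assignment
    factor_df = pd.DataFrame(
        {
            "factor_id": result.factor_names,
            "pip": result.pips,
            "cluster_id": [int(c) if c >= 0 else -1 for c in assign],
        }
    )
    cluster_df = pd.DataFrame(
        [
            {
                "cluster_id": cid,
                "cluster_pip": cl.cluster_pip,
                "n_members": len(cl.members),
                "min_within_r2": cl.min_r2,
                "members": ",".join(result.factor_names[m] for m in cl.members),
            }
            for cid, cl in enumerate(result.clusters)
        ]
    )
    model_df = pd.DataFrame(
        [
            {
                "rank": rank,
                "configuration": (
                    ",".join(result.factor_names[i] for i in rec.factor_index_set)
                    or "<null>"
                ),
                "size": len(rec.factor_index_set),
                "log10_bf": rec.log10_bf,
                "log10_prior": rec.log10_prior,
                "log10_weight": rec.log10_weight,
                "posterior": 10.0 ** (rec.log10_weight - result.log10_nc),
            }
            for rank, rec in enumerate(result.models, start=1)
        ]
    )
    return factor_df, cluster_df, model_df


def write_finemap_result(
    result: FineMapResult,
    prefix: str,
    metadata: dict | None = None,
    max_models: int = 1000,
) -> list[str]:
    """Write ``<prefix>.factors.tsv``, ``<prefix>.clusters.tsv`` and
    ``<prefix>.models.tsv`` with an embedded metadata header."""
    meta = dict(metadata or {})
    meta.setdefault("log10_nc", f"{result.log10_nc:.6f}")
    for key, val in result.settings.items():
        meta.setdefault(f"setting_{key}", val)
    factor_df, cluster_df, model_df = finemap_frames(result)
    paths = []
    for suffix, df in (
        ("factors", factor_df),
        ("clusters", cluster_df),
        ("models", model_df.head(max_models)),
    ):
        path = f"{prefix}.{suffix}.tsv"
        with open(path, "w") as fh:
            for key, val in meta.items():
                fh.write(f"# {key}: {val}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        paths.append(path)
    return paths


def load_prior_table(
    path, names: Sequence[str], default_pi: float | None = None
) -> np.ndarray:
    """Per-factor prior inclusion probabilities from a two-column TSV
    (factor_id, pi); factors absent from the table get ``default_pi``
    (default: the reciprocal of the number of factors)."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", comment="#")
    cols = list(table.columns[:2])
    mapping = dict(zip(table[cols[0]].astype(str), table[cols[1]].astype(float)))
    if default_pi is None:
        default_pi = 1.0 / len(names)
    pi = np.array([mapping.get(str(n), default_pi) for n in names])
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("prior probabilities must lie strictly in (0, 1)")
    return pi
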