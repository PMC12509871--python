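"""Exact Bayesian enumeration of all causal configurations up to a size cap.

This is the brute-force counterpart of the adaptive search: every subset of
factors of size <= K is evaluated with the same Bayes-factor and prior code
(single source of truth in :mod:`famfine.dapg`), and the posterior is
normalized exactly over that restricted model space.  It serves both as a
CAVIAR-style comparator (exhaustive computation with a small maximum number
of causal variants, typically 2) and as the oracle against which the
adaptive approximation is checked.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .dapg import (
    DEFAULT_CLUSTER_R2,
    DEFAULT_PIP_FLOOR,
    FineMapResult,
    ModelRecord,
    PriorSpec,
    build_clusters,
    log10_bf,
    log10sumexp,
    model_log10_prior,
    _pips_from_space,
)
from .fbat_score import ZPanel

MODEL_COUNT_GUARD = 2_000_000


def exhaustive_posterior(
    zpanel: ZPanel,
    prior: PriorSpec | None = None,
    K: int = 2,
    cluster_r2: float = DEFAULT_CLUSTER_R2,
    pip_floor: float = DEFAULT_PIP_FLOOR,
) -> FineMapResult:
    """Exact posterior over all configurations of size <= K.

    Enumeration is lexicographic for reproducibility.  Raises ``ValueError``
    when the model count exceeds the enumeration guard (2e6): use a smaller
    K or a smaller panel.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    zpanel.validate()
    p = zpanel.n_factors
    if prior is None:
        prior = PriorSpec.default(p)
    if prior.n_factors != p:
        raise ValueError("prior dimension does not match the panel")
    K = min(K, p)

    n_models = sum(math.comb(p, k) for k in range(K + 1))
    if n_models > MODEL_COUNT_GUARD:
        raise ValueError(
            f"{n_models} models exceed the enumeration guard "
            f"({MODEL_COUNT_GUARD}); reduce K or the panel size"
        )

    records: dict[frozenset, ModelRecord] = {}
    for k in range(K + 1):
        for combo in itertools.combinations(range(p), k):
            S = frozenset(combo)
            records[S] = ModelRecord(
                factor_index_set=combo,
                log10_bf=log10_bf(S, zpanel, prior),
                log10_prior=model_log10_prior(S, prior),
            )

    log10_nc = log10sumexp(r.log10_weight for r in records.values())
    pips = _pips_from_space(records, p, log10_nc)
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
        settings={
            "method": "exhaustive",
            "K": K,
            "cluster_r2": cluster_r2,
            "pip_floor": pip_floor,
            "phi2": list(map(float, prior.phi2)),
            "phi2_weights": list(map(float, prior.phi2_weights)),
        },
    )
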