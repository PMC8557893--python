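"""Bayesian microbial source attribution via a collapsed Gibbs sampler.

Each individual (sequence) in a sink community is assigned to one of the
candidate source communities or to an Unknown source.  Known sources
have fixed Dirichlet-smoothed taxon profiles,

    P(t | v) = (m_vt + α_src) / (m_v· + α_src·T),

while the Unknown source's profile is learned from the mass currently
assigned to it under a heavy flat smoothing (β pseudo-counts per taxon),

    P(t | unknown) = (u_t + β) / (u· + β·T),

which keeps it close to uniform: it wins only for taxa no known source
explains, rather than absorbing sampling noise.  The full conditional
for assigning an individual of taxon t to source v is

    P(z_i = v | ·) ∝ P(t | v) · (n_v^{−i} + α_sink)

where n_v is the number of sink individuals currently assigned to v.
Mixing proportions are posterior means of n_v / N over post-burn-in
sweeps, averaged over independent restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"

DEFAULT_PARAMS = {
    "alpha_source": 0.001,  # per-taxon smoothing of known source profiles
    "alpha_sink": 0.1,      # prior pseudo-count on mixing assignments
    "beta_unknown": 10.0,   # per-taxon flat smoothing of the unknown source
    "n_burnin": 50,
    "n_draws": 100,
    "n_restarts": 4,
    "rarefaction_depth": 1000,
}


@dataclass(frozen=True)
class SourceProfile:
    source_id: str
    counts: np.ndarray  # aligned to the shared taxon order

    def __post_init__(self):
        c = np.asarray(self.counts)
        if (c < 0).any() or c.sum() <= 0:
            raise ValueError(f"source {self.source_id!r} must have non-negative counts, total > 0")


@dataclass(frozen=True)
class SourceEstimate:
    sink_id: str
    proportions: dict[str, float]
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)


@njit(cache=True)
def _gibbs_kernel(taxon_of, P, n_sweeps, n_burnin, alpha_sink, beta_unknown, seed):
    np.random.seed(seed)
    N = taxon_of.shape[0]
    T, V = P.shape  # taxa × known sources
    K = V + 1
    z = np.empty(N, np.int64)
    n = np.zeros(K, np.float64)
    u = np.zeros(T, np.float64)
    for i in range(N):
        v = np.random.randint(0, K)
        z[i] = v
        n[v] += 1.0
        if v == V:
            u[taxon_of[i]] += 1.0
    n_rec = n_sweeps - n_burnin
    draws = np.zeros((n_rec, K), np.float64)
    probs = np.empty(K, np.float64)
    for sweep in range(n_sweeps):
        for i in range(N):
            t = taxon_of[i]
            v = z[i]
            n[v] -= 1.0
            if v == V:
                u[t] -= 1.0
            tot = 0.0
            for k in range(V):
                probs[k] = P[t, k] * (n[k] + alpha_sink)
                tot += probs[k]
            p_unk = (u[t] + beta_unknown) / (n[V] + beta_unknown * T)
            probs[V] = p_unk * (n[V] + alpha_sink)
            tot += probs[V]
            r = np.random.random() * tot
            acc = 0.0
            v2 = K - 1
            for k in range(K):
                acc += probs[k]
                if r < acc:
                    v2 = k
                    break
            z[i] = v2
            n[v2] += 1.0
            if v2 == V:
                u[t] += 1.0
        if sweep >= n_burnin:
            for k in range(K):
                draws[sweep - n_burnin, k] = n[k] / N
    return draws


def estimate_source_proportions(
    sink: np.ndarray | pd.Series,
    sources: list[SourceProfile],
    sink_id: str = "sink",
    params: dict | None = None,
    seed: int | None = None,
) -> SourceEstimate:
    """Estimate the mixing proportions of a sink over sources + Unknown.

    ``sink`` and every source must be aligned to the same taxon order
    (align on the union, filling zeros).  Sink taxa absent from every
    source are legal — they drive the Unknown estimate.  The sink is
    rarefied to ``rarefaction_depth`` (without replacement) to bound the
    per-individual sampler's cost.  Deterministic for a given seed.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    sink = np.asarray(sink, dtype=np.int64)
    if sink.sum() <= 0:
        raise ValueError("empty sink")
    if not sources:
        raise ValueError("need at least one source")
    for s in sources:
        if len(s.counts) != len(sink):
            raise ValueError(f"source {s.source_id!r} not aligned with sink")
    rng = np.random.default_rng(seed)
    depth = p["rarefaction_depth"]
    if depth and sink.sum() > depth:
        sink = rng.multivariate_hypergeometric(sink, depth)
    taxon_of = np.repeat(np.arange(len(sink)), sink).astype(np.int64)
    T = len(sink)
    V = len(sources)
    P = np.empty((T, V), dtype=np.float64)
    for v, s in enumerate(sources):
        m = np.asarray(s.counts, dtype=np.float64)
        P[:, v] = (m + p["alpha_source"]) / (m.sum() + p["alpha_source"] * T)
    all_draws = []
    for r in range(p["n_restarts"]):
        kernel_seed = int(rng.integers(2**31))
        draws = _gibbs_kernel(
            taxon_of,
            P,
            p["n_burnin"] + p["n_draws"],
            p["n_burnin"],
            p["alpha_sink"],
            p["beta_unknown"],
            kernel_seed,
        )
        all_draws.append(draws)
    restart_means = np.array([d.mean(axis=0) for d in all_draws])
    spread = restart_means.max(axis=0) - restart_means.min(axis=0)
    if (spread > 0.05).any():
        logger.warning(
            "sink %s: restart-to-restart spread exceeds 0.05 (max %.3f); "
            "consider more sweeps", sink_id, spread.max(),
        )
    pooled = np.vstack(all_draws)
    mean = pooled.mean(axis=0)
    lo = np.percentile(pooled, 2.5, axis=0)
    hi = np.percentile(pooled, 97.5, axis=0)
    names = [s.source_id for s in sources] + [UNKNOWN]
    return SourceEstimate(
        sink_id=sink_id,
        proportions={name: float(mean[k]) for k, name in enumerate(names)},
        intervals={name: (float(lo[k]), float(hi[k])) for k, name in enumerate(names)},
    )


def collapse_sources(
    estimates: list[SourceEstimate], mapping: dict[str, str]
) -> pd.DataFrame:
    """Sum member-source proportions into classes (starter/environment/unknown).

    ``mapping`` maps every source_id to its class; the Unknown source maps
    to class ``"unknown"`` automatically unless overridden.
    """
    rows = {}
    for est in estimates:
        row: dict[str, float] = {}
        for source_id, prop in est.proportions.items():
            if source_id == UNKNOWN:
                cls = mapping.get(UNKNOWN, "unknown")
            elif source_id in mapping:
                cls = mapping[source_id]
            else:
                raise ValueError(f"source {source_id!r} missing from class mapping")
            row[cls] = row.get(cls, 0.0) + prop
        rows[est.sink_id] = row
    return pd.DataFrame(rows).T.fillna(0.0)


def align_sources(
    sink: pd.Series, source_series: dict[str, pd.Series]
) -> tuple[np.ndarray, list[SourceProfile], list[str]]:
    """Align a sink and sources on the union of their taxa (zeros filled)."""
    union = sorted(
        set(sink.index).union(*[set(s.index) for s in source_series.values()])
    )
    sink_arr = sink.reindex(union, fill_value=0).to_numpy(dtype=np.int64)
    profiles = [
        SourceProfile(name, s.reindex(union, fill_value=0).to_numpy(dtype=np.int64))
        for name, s in source_series.items()
    ]
    return sink_arr, profiles, union
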