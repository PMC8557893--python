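"""Jaccard dissimilarity partitioning (turnover vs nestedness) and PERMANOVA.

The incidence-based family splits total pairwise Jaccard dissimilarity
β_jac into an additive turnover component β_jtu (species replacement)
and a nestedness-resultant component β_jne (species gain/loss):

    β_jac = (b + c) / (a + b + c)
    β_jtu = 2·min(b, c) / (a + 2·min(b, c))
    β_jne = β_jac − β_jtu

with a = shared taxa, b/c = taxa unique to either sample.  The fraction
of each component attributable to a grouping (e.g. sampling time) is
quantified by one-way PERMANOVA on the component distance matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .data_model import CountTable


@dataclass(frozen=True)
class PairComponents:
    a: int  # shared
    b: int  # unique to first
    c: int  # unique to second


@dataclass(frozen=True)
class PartitionResult:
    beta_jac: float
    beta_jtu: float
    beta_jne: float


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def pair_components(x: set, y: set) -> PairComponents:
    """Incidence components (a, b, c) for two presence sets."""
    if not x and not y:
        raise ValueError("both presence sets are empty")
    return PairComponents(len(x & y), len(x - y), len(y - x))


def partition_jaccard(x: set, y: set) -> PartitionResult:
    """Partition pairwise Jaccard dissimilarity into turnover + nestedness."""
    comp = pair_components(x, y)
    a, b, c = comp.a, comp.b, comp.c
    m = min(b, c)
    beta_jac = (b + c) / (a + b + c)
    beta_jtu = (2 * m / (a + 2 * m)) if m > 0 else 0.0
    return PartitionResult(beta_jac, beta_jtu, beta_jac - beta_jtu)


def partition_matrices(
    table: CountTable,
) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """Pairwise (β_jac, β_jtu, β_jne) matrices for every sample pair."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    pres = table.presence().to_numpy()
    ids = table.sample_ids
    n = len(ids)
    jac = np.zeros((n, n))
    jtu = np.zeros((n, n))
    jne = np.zeros((n, n))
    sets = [set(np.flatnonzero(pres[i])) for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        try:
            res = partition_jaccard(sets[i], sets[j])
        except ValueError as exc:
            raise ValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
        jac[i, j] = jac[j, i] = res.beta_jac
        jtu[i, j] = jtu[j, i] = res.beta_jtu
        jne[i, j] = jne[j, i] = res.beta_jne
    return (
        DistanceMatrix(jac, ids=ids),
        DistanceMatrix(jtu, ids=ids),
        DistanceMatrix(jne, ids=ids),
    )


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(pseudo-F, R²) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0 or df_within == 0:
        f = math.inf if ss_among > 0 else 0.0
    else:
        f = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F on a distance matrix).

    p = (1 + #{permuted F ≥ observed F}) / (1 + n_permutations) under
    random label permutation; with ``exhaustive=True`` every permutation
    of the labels is enumerated instead (feasible for small n) and
    p = #{F ≥ observed} / n! including the identity.
    """
    labels = np.asarray(list(labels))
    if len(labels) != dist.shape[0]:
        raise ValueError("labels length must match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs, r2 = _permanova_stats(d2, codes, len(uniq))
    # non-Euclidean dissimilarities (e.g. the nestedness component) can make
    # SS_among marginally negative; report within the declared ranges while
    # the permutation test keeps comparing raw statistics
    f_rep = max(f_obs, 0.0)
    r2_rep = float(min(max(r2, 0.0), 1.0))
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(len(codes))):
            f_p, _ = _permanova_stats(d2, codes[list(perm)], len(uniq))
            count += f_p >= f_obs or math.isclose(f_p, f_obs, rel_tol=1e-12)
            total += 1
        return PermanovaResult(f_rep, r2_rep, count / total, total)
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        f_p, _ = _permanova_stats(d2, rng.permutation(codes), len(uniq))
        if f_p >= f_obs or math.isclose(f_p, f_obs, rel_tol=1e-12):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(f_rep, r2_rep, p, n_permutations)


def partition_time_variance(
    table: CountTable,
    time_labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """PERMANOVA of each partition component matrix against sampling time.

    Returns a row per component (jac, jtu, jne) with pseudo-F, R², and p;
    R² operationalises "the share of the component's variation related to
    sampling time".
    """
    jac, jtu, jne = partition_matrices(table)
    rows = {}
    for name, dm in (("jac", jac), ("jtu", jtu), ("jne", jne)):
        if np.allclose(dm.data, 0):
            rows[name] = {"pseudo_F": 0.0, "r_squared": 0.0, "p_value": 1.0}
            continue
        res = permanova(dm, time_labels, n_permutations=n_permutations, seed=seed)
        rows[name] = {
            "pseudo_F": res.pseudo_f,
            "r_squared": res.r_squared,
            "p_value": res.p_value,
        }
    return pd.DataFrame(rows).T
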