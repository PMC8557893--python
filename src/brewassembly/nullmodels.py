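"""Phylogenetic and taxonomic null models for community-assembly inference.

For each pair of communities sampled at the same time point, the beta
mean nearest taxon distance (βMNTD) is compared against a null
distribution obtained by shuffling taxon labels across all tree tips,
giving the z-score βNTI.  |βNTI| > 2 indicates deterministic selection
(βNTI > 2 variable selection, βNTI < −2 homogeneous selection).  For
phylogenetically insignificant pairs (|βNTI| < 2), the Raup-Crick index
on Bray-Curtis dissimilarity (RC_bray) disentangles the stochastic
processes: RC_bray > 0.95 dispersal limitation, RC_bray < −0.95
homogenizing dispersal, |RC_bray| < 0.95 ecological drift.  Boundary
values fall to the stochastic/drift side (strict inequalities).

βMNTD is abundance-weighted by default:

    βMNTD(x, y) = ½ [ Σ_{i∈x} f_i · min_{j∈y} D(i,j)
                    + Σ_{j∈y} f_j · min_{i∈x} D(j,i) ]

with f the within-sample relative abundances and D patristic distance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .data_model import CountTable

logger = logging.getLogger(__name__)

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
    "undetermined",
)


@dataclass(frozen=True)
class AssemblyScore:
    pair: tuple[str, str]
    bmntd_obs: float
    null_mean: float
    null_sd: float
    bnti: float  # NaN when the null is degenerate
    rc_bray: float | None
    process: str


@dataclass(frozen=True)
class PoolStats:
    """Occurrence frequencies and mean relative abundances of a source pool."""

    taxon_ids: list[str]
    occurrence_freq: np.ndarray
    mean_rel_abund: np.ndarray

    @classmethod
    def from_table(cls, table: CountTable) -> "PoolStats":
        pres = table.presence().to_numpy()
        freq = pres.mean(axis=0)
        rel = table.relative().to_numpy().mean(axis=0)
        return cls(table.taxon_ids, freq, rel)


def patristic_matrix(tree: TreeNode, taxon_ids: list[str]) -> np.ndarray:
    """Patristic (branch-length) distance matrix aligned to ``taxon_ids``."""
    dm = tree.tip_tip_distances()
    missing = sorted(set(taxon_ids) - set(dm.ids))
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    idx = [dm.ids.index(t) for t in taxon_ids]
    return np.asarray(dm.data)[np.ix_(idx, idx)]


def _weights(counts: np.ndarray, weighted: bool) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    if weighted:
        return counts / total
    w = (counts > 0).astype(float)
    return w / w.sum()


def beta_mntd(
    x: np.ndarray, y: np.ndarray, dist: np.ndarray, weighted: bool = True
) -> float:
    """βMNTD between two aligned abundance vectors.

    ``dist`` is the patristic matrix aligned to the same taxon order.  A
    taxon present in both samples has nearest-neighbour distance 0.
    """
    fx, fy = _weights(x, weighted), _weights(y, weighted)
    ix, iy = np.flatnonzero(fx), np.flatnonzero(fy)
    min_xy = dist[np.ix_(ix, iy)].min(axis=1)
    min_yx = dist[np.ix_(iy, ix)].min(axis=1)
    return float(0.5 * (fx[ix] @ min_xy + fy[iy] @ min_yx))


def _bmntd_all_pairs(F: np.ndarray, present: list[np.ndarray], dist: np.ndarray) -> np.ndarray:
    """βMNTD for every sample pair from weight matrix F (samples × taxa).

    Uses the taxon-to-community minimum-distance matrix M so each null
    replicate costs one pass over the distance matrix, not one per pair.
    """
    n = F.shape[0]
    M = np.empty((dist.shape[0], n))
    for s, idx in enumerate(present):
        M[:, s] = dist[:, idx].min(axis=1)
    A = F @ M  # A[i, j] = Σ_t F[i,t]·min-dist(t → community j)
    B = 0.5 * (A + A.T)
    np.fill_diagonal(B, 0.0)
    return B


def bmntd_matrix(table: CountTable, dist: np.ndarray, weighted: bool = True) -> np.ndarray:
    """Observed βMNTD matrix for all sample pairs of a table."""
    counts = table.data.to_numpy(dtype=float)
    F = np.vstack([_weights(row, weighted) for row in counts])
    present = [np.flatnonzero(row) for row in counts]
    return _bmntd_all_pairs(F, present, dist)


def beta_nti_matrix(
    table: CountTable,
    dist: np.ndarray,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> dict[str, np.ndarray]:
    """βNTI for all sample pairs against a shared tip-shuffling null.

    Each null replicate permutes taxon labels across all tips (one
    permutation applied to the whole patristic matrix, scoring every
    pair), holding both community compositions fixed.  The z-score uses
    the sample (n−1) standard deviation of the null draws; degenerate
    nulls (sd = 0) yield NaN βNTI.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = table.data.to_numpy(dtype=float)
    F = np.vstack([_weights(row, weighted) for row in counts])
    present = [np.flatnonzero(row) for row in counts]
    obs = _bmntd_all_pairs(F, present, dist)
    rng = np.random.default_rng(seed)
    t = dist.shape[0]
    nulls = np.empty((n_null, obs.shape[0], obs.shape[0]))
    for k in range(n_null):
        perm = rng.permutation(t)
        dp = dist[np.ix_(perm, perm)]
        nulls[k] = _bmntd_all_pairs(F, present, dp)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - mean) / sd
    bnti[sd == 0] = np.nan
    np.fill_diagonal(bnti, 0.0)
    return {"obs": obs, "null_mean": mean, "null_sd": sd, "bnti": bnti}


def beta_nti(
    x: np.ndarray,
    y: np.ndarray,
    dist: np.ndarray,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> tuple[float, float, float]:
    """(βNTI, null mean, null sd) for one pair of aligned abundance vectors."""
    df = pd.DataFrame([np.asarray(x), np.asarray(y)], index=["x", "y"]).astype(np.int64)
    res = beta_nti_matrix(CountTable(df), dist, n_null=n_null, seed=seed, weighted=weighted)
    return float(res["bnti"][0, 1]), float(res["null_mean"][0, 1]), float(res["null_sd"][0, 1])


def _bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum() / (a + b).sum())


def _null_communities(
    rng: np.random.Generator,
    n_null: int,
    richness: int,
    total: int,
    freq: np.ndarray,
    abund: np.ndarray,
) -> np.ndarray:
    """(n_null × taxa) null count matrix preserving richness and total.

    Taxon identity is drawn without replacement with probability
    proportional to pool occurrence frequency (Gumbel-top-k, equivalent
    to sequential weighted draws); each drawn taxon receives one
    individual and the remaining individuals are assigned multinomially
    with probability proportional to pool mean relative abundance.
    """
    t = len(freq)
    candidates = np.flatnonzero(freq > 0)
    if richness > len(candidates):
        raise ValueError("sample richness exceeds number of pool taxa")
    logw = np.full(t, -np.inf)
    logw[candidates] = np.log(freq[candidates])
    gumbel = rng.gumbel(size=(n_null, t))
    keys = logw[None, :] + gumbel
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_null, t), dtype=np.int64)
    rows = np.repeat(np.arange(n_null), richness)
    out[rows, chosen.ravel()] = 1
    extra = total - richness
    if extra > 0:
        for k in range(n_null):
            w = abund[chosen[k]]
            if w.sum() <= 0:
                w = np.ones_like(w)
            w = w / w.sum()
            out[k, chosen[k]] += rng.multinomial(extra, w)
    return out


def rc_bray(
    x: np.ndarray,
    y: np.ndarray,
    pool: PoolStats,
    n_null: int = 999,
    seed: int | None = None,
) -> float:
    """Raup-Crick index on Bray-Curtis dissimilarity, in [−1, 1].

    Null communities preserve each sample's observed richness and total
    count; RC = 2·[(#{null < obs} + ½·#{null = obs}) / n_null] − 1.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    for name, v in (("x", x), ("y", y)):
        if v.sum() <= 0:
            raise ValueError(f"sample {name} is empty")
        absent = np.flatnonzero((v > 0) & (pool.occurrence_freq <= 0))
        if absent.size:
            missing = [pool.taxon_ids[i] for i in absent]
            raise ValueError(f"pool missing taxa present in the pair: {missing}")
    obs = _bray_curtis(x.astype(float), y.astype(float))
    rng = np.random.default_rng(seed)
    nx = _null_communities(
        rng, n_null, int((x > 0).sum()), int(x.sum()), pool.occurrence_freq, pool.mean_rel_abund
    )
    ny = _null_communities(
        rng, n_null, int((y > 0).sum()), int(y.sum()), pool.occurrence_freq, pool.mean_rel_abund
    )
    fx, fy = nx.astype(float), ny.astype(float)
    bc = np.abs(fx - fy).sum(axis=1) / (fx + fy).sum(axis=1)
    eps = 1e-12
    less = int((bc < obs - eps).sum())
    eq = int((np.abs(bc - obs) <= eps).sum())
    return float(2.0 * ((less + 0.5 * eq) / n_null) - 1.0)


def classify_process(bnti: float, rc: float | None = None) -> str:
    """Map (βNTI, RC_bray) to the five assembly processes.

    Strict thresholds: βNTI > 2 variable selection, βNTI < −2 homogeneous
    selection; otherwise RC_bray is required (RC > 0.95 dispersal
    limitation, RC < −0.95 homogenizing dispersal, else drift).  Boundary
    ties resolve to the stochastic/drift side.  A NaN βNTI (degenerate
    null) is undetermined.
    """
    if bnti is None or np.isnan(bnti):
        return "undetermined"
    if bnti > 2:
        return "variable_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rc is None or np.isnan(rc):
        raise ValueError("RC_bray required when |bnti| < 2")
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def score_pairs(
    table: CountTable,
    dist: np.ndarray,
    pool: PoolStats,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> list[AssemblyScore]:
    """βNTI + (conditional) RC_bray + process label for every sample pair.

    RC_bray is computed only for phylogenetically insignificant pairs
    (|βNTI| < 2), against the given pool.
    """
    ids = table.sample_ids
    rng = np.random.default_rng(seed)
    res = beta_nti_matrix(table, dist, n_null=n_null, seed=int(rng.integers(2**31)), weighted=weighted)
    scores = []
    counts = table.data.to_numpy()
    for i, j in itertools.combinations(range(len(ids)), 2):
        bnti = res["bnti"][i, j]
        rc = None
        if not np.isnan(bnti) and abs(bnti) < 2:
            rc = rc_bray(counts[i], counts[j], pool, n_null=n_null, seed=int(rng.integers(2**31)))
        scores.append(
            AssemblyScore(
                pair=(ids[i], ids[j]),
                bmntd_obs=float(res["obs"][i, j]),
                null_mean=float(res["null_mean"][i, j]),
                null_sd=float(res["null_sd"][i, j]),
                bnti=float(bnti),
                rc_bray=rc,
                process=classify_process(bnti, rc),
            )
        )
    return scores


def assembly_within_groups(
    table: CountTable,
    tree: TreeNode | np.ndarray,
    frame: pd.DataFrame,
    group_keys: tuple[str, ...] = ("group", "stage", "time_point"),
    pool_keys: tuple[str, ...] = ("group", "stage"),
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> list[AssemblyScore]:
    """Score every within-group sample pair (never across time points).

    ``group_keys`` define the pairing scope (default: same group, stage
    and sampling time — replicate batches only).  RC_bray is computed
    only for phylogenetically insignificant pairs (|βNTI| < 2), with the
    null pool built from all samples sharing ``pool_keys``.  Groups of a
    single sample are skipped with a warning.
    """
    dist = tree if isinstance(tree, np.ndarray) else patristic_matrix(tree, table.taxon_ids)
    frame = frame.loc[[s for s in table.sample_ids if s in frame.index]]
    rng = np.random.default_rng(seed)
    pools: dict = {}
    for key, sub in frame.groupby(list(pool_keys), sort=True):
        pools[key] = PoolStats.from_table(table.select_samples(sub.index))
    scores: list[AssemblyScore] = []
    for key, sub in frame.groupby(list(group_keys), sort=True):
        ids = list(sub.index)
        if len(ids) < 2:
            logger.warning("group %s has a single sample; skipped", key)
            continue
        pool_key = tuple(sub.iloc[0][k] for k in pool_keys)
        if len(pool_keys) == 1:
            pool_key = pool_key[0]
        scores.extend(
            score_pairs(
                table.select_samples(ids),
                dist,
                pools[pool_key],
                n_null=n_null,
                seed=int(rng.integers(2**31)),
                weighted=weighted,
            )
        )
    return scores


def summarize_assembly(scores: list[AssemblyScore]) -> pd.DataFrame:
    """Process tally and median βNTI over a list of pair scores."""
    df = pd.DataFrame(
        {
            "bnti": [s.bnti for s in scores],
            "process": [s.process for s in scores],
        }
    )
    tally = df["process"].value_counts().reindex(PROCESS_LABELS, fill_value=0)
    out = tally.to_frame("n_pairs")
    out.loc["__median_bnti__", "n_pairs"] = float(np.nanmedian(df["bnti"])) if len(df) else np.nan
    return out


def regress_bnti_on_factor(
    scores: list[AssemblyScore],
    frame: pd.DataFrame,
    factor: str,
    log_transform: bool = False,
    predictor: str = "mean",
):
    """OLS of pairwise βNTI on a physicochemical factor.

    The pair-level predictor is the mean of the factor across the two
    samples (or the absolute difference with ``predictor="absdiff"``),
    optionally log-transformed.  Returns a RegressionFit.
    """
    import statsmodels.api as sm

    xs, ys = [], []
    for s in scores:
        if np.isnan(s.bnti):
            continue
        try:
            v1 = float(frame.loc[s.pair[0], factor])
            v2 = float(frame.loc[s.pair[1], factor])
        except KeyError:
            continue
        if np.isnan(v1) or np.isnan(v2):
            continue
        val = (v1 + v2) / 2 if predictor == "mean" else abs(v1 - v2)
        if log_transform:
            if val <= 0:
                continue
            val = np.log(val)
        xs.append(val)
        ys.append(s.bnti)
    if len(xs) < 4:
        raise ValueError(f"fewer than 4 usable pairs for factor {factor!r}")
    x = np.asarray(xs)
    if np.allclose(x, x[0]):
        raise ValueError(f"constant predictor for factor {factor!r}")
    model = sm.OLS(np.asarray(ys), sm.add_constant(x)).fit()
    return RegressionFit(
        factor=factor,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
    )


@dataclass(frozen=True)
class RegressionFit:
    factor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def scores_to_frame(scores: list[AssemblyScore]) -> pd.DataFrame:
    """Flatten AssemblyScore records into a DataFrame for TSV export."""
    return pd.DataFrame(
        {
            "sample_1": [s.pair[0] for s in scores],
            "sample_2": [s.pair[1] for s in scores],
            "bmntd_obs": [s.bmntd_obs for s in scores],
            "null_mean": [s.null_mean for s in scores],
            "null_sd": [s.null_sd for s in scores],
            "bnti": [s.bnti for s in scores],
            "rc_bray": [s.rc_bray for s in scores],
            "process": [s.process for s in scores],
        }
    )
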