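"""Alpha and beta diversity, rarefaction curves, diversity–factor correlation.

Alpha indices follow the QIIME-lineage conventions: Shannon entropy in
bits (log base 2), Pielou's evenness H/log2(S), observed richness, and
Faith's phylogenetic diversity including the stem path to the root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import spearmanr
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from .data_model import CountTable, FACTOR_COLUMNS

logger = logging.getLogger(__name__)

ALPHA_INDICES = ("shannon", "pielou", "observed", "faith_pd")


@dataclass(frozen=True)
class AlphaDiversity:
    sample_id: str
    shannon: float
    pielou: float | None
    observed: int
    faith_pd: float | None = None


def shannon_index(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy −Σ p_i log p_i over non-zero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(
    counts: np.ndarray,
    taxon_ids: list[str],
    tree: TreeNode,
    include_root: bool = True,
) -> float:
    """Faith's PD: total branch length of the minimal subtree spanning the
    observed tips.

    With ``include_root`` (default) the stem path from the spanning
    subtree up to the tree root is counted, so a single-tip community has
    PD equal to its root-to-tip distance.
    """
    counts = np.asarray(counts)
    present = [t for t, c in zip(taxon_ids, counts) if c > 0]
    if not present:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(set(present) - tip_names)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    present_set = set(present)
    total = 0.0
    # postorder pass: a branch is counted when its subtree holds ≥1 observed
    # tip; under the crown convention the branch is skipped when it holds all
    # of them (the paths above the crown ancestor contribute nothing).
    n_obs: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            k = 1 if node.name in present_set else 0
        else:
            k = sum(n_obs[id(ch)] for ch in node.children)
        n_obs[id(node)] = k
        if node.parent is None:
            continue
        if k >= 1 and (include_root or k < len(present_set)):
            total += node.length or 0.0
    return float(total)


def alpha_diversity(
    counts: np.ndarray,
    taxon_ids: list[str],
    sample_id: str = "",
    tree: TreeNode | None = None,
    base: float = 2.0,
    include_root: bool = True,
) -> AlphaDiversity:
    """Compute the four alpha indices for one sample.

    Pielou's evenness is undefined for fewer than two observed taxa and
    reported as ``None``.  ``faith_pd`` is ``None`` when no tree is given.
    """
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total count")
    observed = int((counts > 0).sum())
    h = shannon_index(counts, base=base)
    pielou = h / (np.log(observed) / np.log(base)) if observed >= 2 else None
    pd_val = faith_pd(counts, taxon_ids, tree, include_root) if tree is not None else None
    return AlphaDiversity(sample_id, h, pielou, observed, pd_val)


def alpha_diversity_table(
    table: CountTable,
    tree: TreeNode | None = None,
    base: float = 2.0,
    include_root: bool = True,
) -> pd.DataFrame:
    """Alpha indices for every sample, as a DataFrame indexed by sample."""
    rows = []
    for s in table.sample_ids:
        a = alpha_diversity(
            table.data.loc[s].to_numpy(), table.taxon_ids, s, tree, base, include_root
        )
        rows.append(
            {"shannon": a.shannon, "pielou": a.pielou, "observed": a.observed, "faith_pd": a.faith_pd}
        )
    return pd.DataFrame(rows, index=table.sample_ids)


def alpha_rarefaction_curve(
    table: CountTable,
    depths: list[int],
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean observed richness per (sample, depth) over repeated rarefactions.

    Depths exceeding a sample's total are skipped (recorded as NaN).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=table.sample_ids, columns=depths, dtype=float)
    for s in table.sample_ids:
        row = table.data.loc[s].to_numpy()
        total = row.sum()
        for d in depths:
            if d > total:
                logger.info("depth %d exceeds total %d for sample %s; skipped", d, total, s)
                continue
            obs = [
                int((rng.multivariate_hypergeometric(row, d) > 0).sum()) for _ in range(reps)
            ]
            out.loc[s, d] = float(np.mean(obs))
    return out


def dissimilarity_matrix(
    table: CountTable, metric: str = "bray_curtis", use_relative: bool = False
) -> DistanceMatrix:
    """Pairwise Jaccard (presence/absence) or Bray-Curtis dissimilarity.

    Bray-Curtis operates on counts by default; with equal row sums (after
    rarefaction) counts and relative abundances give identical values.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    if (totals == 0).any():
        raise ValueError(f"empty samples: {totals.index[totals == 0].tolist()}")
    if metric == "jaccard":
        x = table.presence().to_numpy()
        condensed = pdist(x, metric="jaccard")
    elif metric == "bray_curtis":
        x = table.relative().to_numpy() if use_relative else table.data.to_numpy().astype(float)
        condensed = pdist(x, metric="braycurtis")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def correlate_diversity_factors(
    alpha: pd.DataFrame,
    frame: pd.DataFrame,
    factors: tuple[str, ...] = FACTOR_COLUMNS,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of each alpha index with each factor.

    Benjamini–Hochberg adjustment is applied across the whole table.
    Constant factors (or too few paired observations) yield missing
    coefficients with a reason.
    """
    records = []
    for index_name in alpha.columns:
        for factor in factors:
            if factor not in frame.columns:
                continue
            pair = pd.concat(
                [alpha[index_name], pd.to_numeric(frame[factor], errors="coerce")], axis=1
            ).dropna()
            if len(pair) < min_n:
                records.append((index_name, factor, np.nan, np.nan, f"n={len(pair)}<{min_n}"))
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if y.nunique() < 2 or x.nunique() < 2:
                records.append((index_name, factor, np.nan, np.nan, "constant input"))
                continue
            rho, p = spearmanr(x, y)
            records.append((index_name, factor, float(rho), float(p), ""))
    df = pd.DataFrame(
        records, columns=["index", "factor", "rho", "p_value", "note"]
    )
    mask = df["p_value"].notna()
    df["p_adjusted"] = np.nan
    if mask.any():
        df.loc[mask, "p_adjusted"] = multipletests(df.loc[mask, "p_value"], method="fdr_bh")[1]
    return df
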