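"""Synthetic communities with known ground truth.

Generates phylogenies, regional species pools with phylogenetically
conserved environmental optima, communities assembled under each of the
five ecological processes, and a two-stage (aerobic saccharification →
anaerobic fermentation) succession scenario with starter and environment
source pools — so every pipeline stage has a recovery test against
recorded truth, with no sequencing data required.

Scale defaults mirror the emulated study design: 2 groups × 3 batches,
5 saccharification time points (hours) + 6 fermentation time points
(days) = 66 samples, taxon pools of ~128, sequencing depth 2,000.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
from dendropy.simulate import treesim
from skbio import TreeNode

from .data_model import CountTable
from .sourcetracker import SourceProfile

SACC_TIMES_H = (0, 6, 12, 18, 24)
FERM_TIMES_D = (0, 3, 6, 9, 12, 15)


@dataclass(frozen=True)
class RegionalPool:
    taxon_ids: list[str]
    occurrence_freq: np.ndarray  # in (0, 1]
    mean_rel_abund: np.ndarray   # simplex weights
    trait: np.ndarray            # environmental optimum per taxon, arbitrary units


@dataclass
class ScenarioTruth:
    """Ground truth sufficient to score every downstream stage."""

    process: dict[str, str] = field(default_factory=dict)       # community → generating process
    mixing: dict[str, dict[str, float]] = field(default_factory=dict)  # sink → class → proportion
    lineage_modes: dict[str, str] = field(default_factory=dict)  # lineage → replacement | loss


def _dendropy_newick(tree) -> str:
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length <= 0:
            edge.length = 1e-8
    tree.seed_node.edge.length = None  # a root edge is a simulation artifact
    return tree.as_string(schema="newick", suppress_rooting=True)


def simulate_tree(n_taxa: int, model: str = "birth_death", seed: int | None = None) -> TreeNode:
    """Simulate a rooted phylogeny with tips ``T0001…``.

    ``birth_death`` (rate 1.0 / 0.5) gives non-ultrametric depths;
    ``coalescent`` (Kingman, pop size 1) is ultrametric; ``radiation``
    mimics the clumpy structure of marker-gene ASV trees — two deep
    lineages, each an ancient radiation of tight clades (~4 tips each,
    short within-clade branches), like families of closely related
    sequence variants.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(seed)
    if model == "birth_death":
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.5, num_extant_tips=n_taxa, rng=rng
        )
    elif model == "coalescent":
        tns = dendropy.TaxonNamespace([f"tmp{i}" for i in range(n_taxa)])
        tree = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1, rng=rng)
    elif model == "radiation":
        return _radiation_tree(n_taxa, seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i:04d}"
    return TreeNode.read(io.StringIO(_dendropy_newick(tree)))


def _radiation_tree(
    n_taxa: int,
    seed: int | None,
    clade_size: int = 4,
    n_lineages: int = 2,
    spoke_length: float = 1.5,
    lineage_stem: float = 1.0,
    within_scale: float = 0.02,
    spoke_jitter: float = 0.1,
) -> TreeNode:
    """Deep-lineage radiation: tight clades on long, near-equal spokes."""
    rng = random.Random(seed)
    nrng = np.random.default_rng(None if seed is None else seed + 1)
    sizes = []
    remaining = n_taxa
    while remaining > 0:
        s = min(clade_size, remaining)
        sizes.append(s)
        remaining -= s
    lineages: list[list[str]] = [[] for _ in range(n_lineages)]
    for i, s in enumerate(sizes):
        lineages[i % n_lineages].append(s)  # type: ignore[arg-type]
    k = 0
    lineage_parts = []
    for clade_sizes in lineages:
        parts = []
        for s in clade_sizes:
            if s == 1:
                k += 1
                sub_nwk = f"T{k:04d}:{within_scale:.6f}"
            else:
                st = treesim.birth_death_tree(
                    birth_rate=1.0, death_rate=0.0, num_extant_tips=s, rng=rng
                )
                for leaf in st.leaf_node_iter():
                    k += 1
                    leaf.taxon.label = f"T{k:04d}"
                for e in st.preorder_edge_iter():
                    if e.length is None or e.length <= 0:
                        e.length = 1e-8
                    e.length *= within_scale
                sub_nwk = (
                    st.as_string(schema="newick", suppress_rooting=True).strip().rstrip(";")
                )
            stem = spoke_length * (1 + spoke_jitter * (nrng.random() - 0.5))
            parts.append(f"({sub_nwk}):{stem:.6f}" if s == 1 else f"{sub_nwk}:{stem:.6f}")
        lineage_parts.append("(" + ",".join(parts) + f"):{lineage_stem:.6f}")
    return TreeNode.read(io.StringIO("(" + ",".join(lineage_parts) + ");"))


def _brownian_traits(tree: TreeNode, rate: float, rng: np.random.Generator) -> dict[str, float]:
    trait = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = trait[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(rate * (node.length or 0.0))) if rate > 0 else 0.0
        trait[id(node)] = parent_val + step
    return {tip.name: trait[id(tip)] for tip in tree.tips()}


def simulate_pool(
    tree: TreeNode,
    trait_signal: float = 1.0,
    abund_lognormal_sigma: float = 1.5,
    seed: int | None = None,
) -> RegionalPool:
    """Regional pool over a tree's tips.

    Traits evolve by Brownian motion (variance ``trait_signal`` per unit
    branch length), so close relatives get similar optima.  Mean relative
    abundances are lognormal; occurrence frequencies decrease with
    abundance rank (common taxa are also the prevalent ones).
    """
    rng = np.random.default_rng(seed)
    taxa = sorted(t.name for t in tree.tips())
    traits_map = _brownian_traits(tree, trait_signal, rng)
    trait = np.array([traits_map[t] for t in taxa])
    abund = rng.lognormal(0.0, abund_lognormal_sigma, size=len(taxa))
    abund = abund / abund.sum()
    order = np.argsort(-abund)  # rank 0 = most abundant
    freq = np.empty(len(taxa))
    freq[order] = np.linspace(0.95, 0.15, len(taxa))
    return RegionalPool(taxa, freq, abund, trait)


def _weighted_subset(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """k indices without replacement, P ∝ weights (Gumbel-top-k)."""
    with np.errstate(divide="ignore"):
        keys = np.where(weights > 0, np.log(weights), -np.inf) + rng.gumbel(size=len(weights))
    if (weights > 0).sum() < k:
        raise ValueError("fewer positive-weight taxa than requested richness")
    return np.argpartition(-keys, k - 1)[:k]


def simulate_assembly(
    pool: RegionalPool,
    tree: TreeNode,
    process: str,
    n_communities: int = 20,
    richness: int = 16,
    depth: int = 2000,
    env_optima: np.ndarray | None = None,
    sigma_frac: float | None = None,
    seed: int | None = None,
) -> tuple[CountTable, ScenarioTruth]:
    """Communities assembled under one generating ecological process.

    * ``homogeneous_selection`` — community membership is drawn with a
      Gaussian trait weight exp(−(trait−opt)²/2σ²) around one shared
      optimum (at the trait distribution's upper decile, where conserved
      clades live); abundances follow the pool.  By default σ adapts to
      the realized trait distribution so the niche holds about twice the
      community richness in candidate taxa (pass ``sigma_frac`` for a
      fixed σ as a fraction of the trait range instead).
    * ``variable_selection`` — the same filter with per-community optima
      alternating between the two trait extremes (or ``env_optima``).
    * ``drift`` — taxa drawn by pool occurrence frequency, abundances by
      pool mean relative abundance, independently per community.
    * ``dispersal_limitation`` — each community is confined to its own
      uniformly random sub-pool and its abundances drift independently
      (Dirichlet), so isolated communities diverge beyond the pool's
      frequency-and-abundance expectation.
    * ``homogenizing_dispersal`` — all communities are multinomial
      resamples of one fixed mother community (uneven mother abundances,
      so rare members flicker in and out of detection).

    Counts are multinomial at ``depth``.
    """
    if richness > len(pool.taxon_ids):
        raise ValueError("richness exceeds pool size")
    if depth < 10 * richness:
        raise ValueError("depth must be at least 10 × richness")
    rng = np.random.default_rng(seed)
    t_range = pool.trait.max() - pool.trait.min()
    names = [f"C{k + 1:03d}" for k in range(n_communities)]
    counts = np.zeros((n_communities, len(pool.taxon_ids)), dtype=np.int64)

    def niche_sigma(opt: float) -> float:
        if sigma_frac is not None:
            return max(sigma_frac * t_range, 1e-9)
        gaps = np.sort(np.abs(pool.trait - opt))
        w = min(2 * richness, len(gaps) - 1)
        return max(gaps[w] / 2, 1e-9)

    def gaussian_community(opt: float) -> np.ndarray:
        # selection acts on the trait alone; realized abundances of the
        # selected members follow the pool's abundance structure
        sigma = niche_sigma(opt)
        filt = np.exp(-((pool.trait - opt) ** 2) / (2 * sigma**2))
        idx = _weighted_subset(rng, filt, richness)
        p = np.zeros(len(filt))
        p[idx] = np.maximum(pool.mean_rel_abund[idx], 1e-300)
        return rng.multinomial(depth, p / p.sum())

    if process == "homogeneous_selection":
        opt = (
            float(np.quantile(pool.trait, 0.9))
            if env_optima is None
            else float(np.asarray(env_optima).ravel()[0])
        )
        for k in range(n_communities):
            counts[k] = gaussian_community(opt)
    elif process == "variable_selection":
        if env_optima is None:
            extremes = np.quantile(pool.trait, [0.05, 0.95])
            env_optima = extremes[np.arange(n_communities) % 2]
        for k in range(n_communities):
            counts[k] = gaussian_community(float(env_optima[k]))
    elif process == "drift":
        for k in range(n_communities):
            idx = _weighted_subset(rng, pool.occurrence_freq, richness)
            p = np.zeros(len(pool.taxon_ids))
            p[idx] = pool.mean_rel_abund[idx]
            counts[k] = rng.multinomial(depth, p / p.sum())
    elif process == "dispersal_limitation":
        # isolation does not impoverish the communities: double richness so
        # the pool-based null expects substantial sharing that the isolated
        # communities fail to show
        r = min(2 * richness, len(pool.taxon_ids))
        for k in range(n_communities):
            idx = rng.choice(len(pool.taxon_ids), size=r, replace=False)
            p = np.zeros(len(pool.taxon_ids))
            p[idx] = rng.dirichlet(np.full(r, 0.8))
            counts[k] = rng.multinomial(depth, p)
    elif process == "homogenizing_dispersal":
        # strongly uneven mother so rare members flicker across resamples
        r = min(2 * richness, len(pool.taxon_ids))
        idx = _weighted_subset(rng, pool.occurrence_freq, r)
        mother = np.zeros(len(pool.taxon_ids))
        mother[idx] = rng.lognormal(0.0, 2.0, size=r)
        mother = mother / mother.sum()
        for k in range(n_communities):
            counts[k] = rng.multinomial(depth, mother)
    else:
        raise ValueError(f"unknown process {process!r}")

    table = CountTable(pd.DataFrame(counts, index=names, columns=pool.taxon_ids))
    truth = ScenarioTruth(process={name: process for name in names})
    return table, truth


#: canonical conditions for assembly-process recovery studies
RECOVERY_CONDITIONS = {
    "n_taxa": 128,
    "tree_model": "radiation",
    "trait_signal": 1.0,
    "abund_lognormal_sigma": 0.25,
    "n_communities": 20,
    "richness": 16,
    "depth": 2000,
}


def simulate_assembly_suite(
    seed: int | None = None,
    processes: tuple[str, ...] = (
        "homogeneous_selection",
        "variable_selection",
        "drift",
        "dispersal_limitation",
        "homogenizing_dispersal",
    ),
    **overrides,
) -> tuple[TreeNode, RegionalPool, dict[str, tuple[CountTable, ScenarioTruth]]]:
    """One regional pool plus one community table per generating process.

    Conditions default to :data:`RECOVERY_CONDITIONS`; the pool's flat-ish
    abundance distribution keeps the abundance-weighted βMNTD signal from
    being dominated by a few taxa, so the phylogenetic structure under
    test is what drives the z-scores.
    """
    cond = dict(RECOVERY_CONDITIONS)
    cond.update(overrides)
    rng = np.random.default_rng(seed)
    tree = simulate_tree(cond["n_taxa"], cond["tree_model"], seed=int(rng.integers(2**31)))
    pool = simulate_pool(
        tree,
        trait_signal=cond["trait_signal"],
        abund_lognormal_sigma=cond["abund_lognormal_sigma"],
        seed=int(rng.integers(2**31)),
    )
    tables = {}
    for process in processes:
        tables[process] = simulate_assembly(
            pool,
            tree,
            process,
            n_communities=cond["n_communities"],
            richness=cond["richness"],
            depth=cond["depth"],
            seed=int(rng.integers(2**31)),
        )
    return tree, pool, tables


def simulate_sink_mixture(
    sources: list[SourceProfile],
    mixing: np.ndarray,
    depth: int = 2000,
    seed: int | None = None,
) -> np.ndarray:
    """Multinomial sink drawn from Σ_v mixing_v · normalized profile_v."""
    mixing = np.asarray(mixing, dtype=float)
    if len(mixing) != len(sources):
        raise ValueError("mixing length must match number of sources")
    if (mixing < 0).any() or abs(mixing.sum() - 1.0) > 1e-9:
        raise ValueError("mixing vector must be a simplex")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = np.zeros(len(sources[0].counts))
    for w, s in zip(mixing, sources):
        c = np.asarray(s.counts, dtype=float)
        p += w * (c / c.sum())
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, p / p.sum())


@dataclass
class TwoStageScenario:
    """Output bundle of :func:`simulate_two_stage_succession`."""

    lineages: dict[str, CountTable]          # "bacteria" (replacement), "fungi" (loss)
    frame: pd.DataFrame                      # sample metadata incl. factors
    sources: dict[str, dict[str, SourceProfile]]  # lineage → source_id → profile
    trees: dict[str, TreeNode]
    truth: ScenarioTruth


def _factor_trajectories(stage: str, frac: float, rng: np.random.Generator) -> dict[str, float]:
    """Monotone-with-noise physicochemical curves shaped like the study's.

    ``frac`` is the within-stage progress in [0, 1].  Units: moisture %,
    temperature °C, reducing sugar and ethanol g/100 g, acidity titration
    units (mmol NaOH per g), pH unitless.
    """
    def noisy(v, sd):
        return max(float(v + rng.normal(0, sd)), 1e-3)

    if stage == "SAC":
        return {
            "moisture": noisy(50 + 6 * frac, 0.5),
            "temperature": noisy(25 + 13 * frac, 0.6),
            "reducing_sugar": noisy(2 + 13 * frac, 0.5),
            "acidity": noisy(0.3 + 0.5 * frac, 0.03),
            "pH": noisy(6.2 - 1.0 * frac, 0.05),
            "ethanol": noisy(0.05 + 0.4 * frac, 0.02),
        }
    return {
        "moisture": noisy(58 + 4 * frac, 0.5),
        "temperature": noisy(20 + 12 * frac * np.exp(-2 * (frac - 0.4) ** 2), 0.6),
        "reducing_sugar": noisy(12 - 10 * frac, 0.4),
        "acidity": noisy(1.5 + 2.0 * frac, 0.08),
        "pH": noisy(4.5 - 1.1 * frac, 0.05),
        "ethanol": noisy(0.5 + 13.5 * frac, 0.4),
    }


def simulate_two_stage_succession(
    n_batches: int = 3,
    groups: tuple[str, str] = ("PS", "TS"),
    sacc_times: tuple[int, ...] = SACC_TIMES_H,
    ferm_times: tuple[int, ...] = FERM_TIMES_D,
    n_starter_taxa: int = 32,
    n_env_taxa: int = 64,
    depth: int = 2000,
    replacement_fraction: float = 0.85,
    loss_fraction: float = 0.6,
    env_mass_sac: float = 0.08,
    env_mass_fer_final: float = 0.9,
    batch_noise_sigma: float = 0.3,
    seed: int | None = None,
) -> TwoStageScenario:
    """Two-stage succession with starter and environment source pools.

    Two lineages are generated over one sample design: a
    replacement-mode lineage ("bacteria") in which starter taxa are
    progressively substituted by environment taxa during fermentation at
    roughly constant richness, and a loss-mode lineage ("fungi") in which
    starter taxa are deleted without substitution (richness shrinks,
    nested subsets) while a handful of environment taxa come to dominate.
    Saccharification samples are drawn chiefly from the group's starter
    pool with a small environmental admixture.  True per-sample source
    mass fractions and per-lineage modes are recorded in ScenarioTruth.
    """
    rng = np.random.default_rng(seed)
    truth = ScenarioTruth(lineage_modes={"bacteria": "replacement", "fungi": "loss"})
    lineages: dict[str, CountTable] = {}
    all_sources: dict[str, dict[str, SourceProfile]] = {}
    trees: dict[str, TreeNode] = {}
    frame_rows: dict[str, dict] = {}

    for lineage, mode in (("bacteria", "replacement"), ("fungi", "loss")):
        n_total = 2 * n_starter_taxa + n_env_taxa
        tree = simulate_tree(n_total, "birth_death", seed=int(rng.integers(2**31)))
        # assign tips to pools with auditable prefixes (P/T starters, E environment)
        tips = sorted(t.name for t in tree.tips())
        perm = rng.permutation(n_total)
        pool_of: dict[str, str] = {}
        new_names = {}
        counters = {"P": 0, "T": 0, "E": 0}
        for pos, tip_idx in enumerate(perm):
            prefix = "P" if pos < n_starter_taxa else ("T" if pos < 2 * n_starter_taxa else "E")
            counters[prefix] += 1
            new_names[tips[tip_idx]] = f"{prefix}{counters[prefix]:04d}_{lineage[0]}"
        for tip in tree.tips():
            tip.name = new_names[tip.name]
        taxa = sorted(t.name for t in tree.tips())
        trees[lineage] = tree
        tax_index = {t: i for i, t in enumerate(taxa)}

        def profile(prefix: str, sigma: float = 1.2) -> np.ndarray:
            w = np.zeros(len(taxa))
            members = [t for t in taxa if t.startswith(prefix)]
            vals = rng.lognormal(0, sigma, size=len(members))
            for t, v in zip(members, vals):
                w[tax_index[t]] = v
            return w / w.sum()

        starter_profiles = {g: profile(g[0]) for g in groups}  # P…, T…
        env_profile = profile("E")
        # per-group tolerance ranking of starter taxa (which survive longest)
        starter_order = {
            g: [i for i in np.argsort(-starter_profiles[g] + rng.normal(0, 1e-9, len(taxa)))
                if starter_profiles[g][i] > 0]
            for g in groups
        }
        env_order = [i for i in np.argsort(-env_profile) if env_profile[i] > 0]

        counts_rows = {}
        for g in groups:
            for b in range(1, n_batches + 1):
                batch_jitter = rng.lognormal(0, batch_noise_sigma, size=len(taxa))
                for stage, times, unit in (("SAC", sacc_times, "h"), ("FER", ferm_times, "d")):
                    for ti, tp in enumerate(times):
                        frac = ti / max(len(times) - 1, 1)
                        sid = f"{g[0]}{stage}{tp}{unit}{b}"
                        if stage == "SAC":
                            surv = starter_order[g]
                            env_mass = env_mass_sac
                            env_taxa = env_order[:4]
                        elif mode == "replacement":
                            n_start = len(starter_order[g])
                            keep = max(int(round(n_start * (1 - replacement_fraction * frac))), 2)
                            surv = starter_order[g][:keep]
                            n_new = min(n_start - keep + 4, len(env_order))
                            env_taxa = env_order[: max(n_new, 4)]
                            env_mass = 0.3 + (env_mass_fer_final - 0.3) * frac
                        else:  # loss mode
                            n_start = len(starter_order[g])
                            keep = max(int(round(n_start * (1 - loss_fraction * frac))), 2)
                            surv = starter_order[g][:keep]
                            env_taxa = env_order[:3]
                            env_mass = 0.3 + (env_mass_fer_final - 0.3) * frac
                        w = np.zeros(len(taxa))
                        sp = starter_profiles[g].copy()
                        sp_mask = np.zeros(len(taxa), dtype=bool)
                        sp_mask[surv] = True
                        sp[~sp_mask] = 0.0
                        ep = env_profile.copy()
                        ep_mask = np.zeros(len(taxa), dtype=bool)
                        ep_mask[env_taxa] = True
                        ep[~ep_mask] = 0.0
                        w = (1 - env_mass) * sp / sp.sum() + env_mass * ep / ep.sum()
                        w = w * batch_jitter
                        w = w / w.sum()
                        counts_rows[sid] = rng.multinomial(depth, w)
                        env_true = float(
                            w[[i for i in range(len(taxa)) if taxa[i].startswith("E")]].sum()
                        )
                        truth.mixing[f"{lineage}:{sid}"] = {
                            "starter": 1 - env_true,
                            "environment": env_true,
                            "unknown": 0.0,
                        }
                        if sid not in frame_rows:
                            frame_rows[sid] = {
                                "group": g,
                                "stage": stage,
                                "time_point": tp,
                                "batch": b,
                                **_factor_trajectories(stage, frac, rng),
                            }
        lineages[lineage] = CountTable(
            pd.DataFrame.from_dict(counts_rows, orient="index", columns=taxa).astype(np.int64)
        )
        # sequenced source communities: starters and the environment pool
        all_sources[lineage] = {
            f"starter_{g}": SourceProfile(
                f"starter_{g}", rng.multinomial(depth * 3, starter_profiles[g])
            )
            for g in groups
        }
        all_sources[lineage]["environment"] = SourceProfile(
            "environment", rng.multinomial(depth * 3, env_profile)
        )

    frame = pd.DataFrame.from_dict(frame_rows, orient="index")
    frame.index.name = "sample_id"
    return TwoStageScenario(lineages, frame, all_sources, trees, truth)
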