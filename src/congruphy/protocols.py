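"""Desk-scale study protocols: the scaled-down experiments the package runs
to demonstrate the phenomena end to end without any external data.

Problem sizes here are deliberate scientific choices documented in
docs/methods.md: large enough for the effects to be measurable, small enough
that the whole battery runs on a laptop.  Every function takes a master
``seed`` and is bit-reproducible.
"""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
from scipy import stats

from .characters import MORPHOLOGY, combine_partitions
from .experiments import (
    records_to_dataframe,
    run_site_resampling,
    run_taxon_addition,
    summarize_and_fit,
)
from .metrics import (
    normalized_rf,
    quartet_divergence,
    quartet_status_counts,
    shared_partitions,
    shared_quartet_proportion,
)
from .parsimony import (
    export_hypothetical_ancestors,
    fitch_length,
    mp_search,
)
from .reference import (
    fitch_length_bruteforce,
    quartet_counts_bruteforce,
    random_binary_tree,
)
from .simulate import SimulationConfig, build_synthetic_dataset
from .trees import parse_tree, prune
from .characters import CharacterMatrix


def _sub_seed(master: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(master)] + [int(p) for p in path])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Worked 5-taxon example (hand-checkable)
# ---------------------------------------------------------------------------


def toy_metrics() -> dict:
    """The worked 5-taxon pair: T1=((A,B),C,(D,E)) vs T2=((A,C),B,(D,E))."""
    t1 = parse_tree("((A,B),C,(D,E));")
    t2 = parse_tree("((A,C),B,(D,E));")
    c = quartet_status_counts(t1, t2)
    rf = normalized_rf(t1, t2)
    return {
        "Q": c.Q,
        "s": c.s,
        "d": c.d,
        "quartet_divergence": quartet_divergence(c),
        "shared_quartet_proportion": shared_quartet_proportion(c),
        "rf_raw": rf.raw,
        "shared_partitions": shared_partitions(t1, t2),
    }


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------


def quartet_oracle_agreement(seed: int, n_pairs: int = 200, max_n: int = 12) -> float:
    """Fraction of random tree pairs where the vectorized quartet counts
    equal brute-force enumeration (expected: 1.0)."""
    rng = random.Random(_sub_seed(seed, 11))
    hits = 0
    for _ in range(n_pairs):
        n = rng.randint(5, max_n)
        labels = [f"t{i}" for i in range(n)]
        t1 = random_binary_tree(labels, rng)
        t2 = random_binary_tree(labels, rng)
        c = quartet_status_counts(t1, t2)
        hits += (c.Q, c.s, c.d, c.r1, c.r2, c.u) == quartet_counts_bruteforce(t1, t2)
    return hits / n_pairs


def _random_column_matrix(
    labels: list[str], n_cols: int, rng: random.Random
) -> CharacterMatrix:
    from .characters import MISSING

    cells = []
    for _ in labels:
        row = []
        for _ in range(n_cols):
            r = rng.random()
            if r < 0.1:
                row.append(MISSING)
            elif r < 0.2:
                row.append(frozenset(rng.sample("012", 2)))
            else:
                row.append(frozenset(rng.choice("012")))
        cells.append(row)
    return CharacterMatrix(list(labels), cells, [MORPHOLOGY] * n_cols)


def fitch_oracle_agreement(seed: int, n_instances: int = 150) -> float:
    """Fraction of random (tree <= 7 leaves, <= 3-state character) instances
    where the bitmask Fitch pass equals exhaustive labeling minimization."""
    rng = random.Random(_sub_seed(seed, 12))
    hits = 0
    for _ in range(n_instances):
        n = rng.randint(4, 7)
        labels = [f"t{i}" for i in range(n)]
        tree = random_binary_tree(labels, rng)
        m = _random_column_matrix(labels, 1, rng)
        fast = int(fitch_length(tree, m)[0][0])
        hits += fast == fitch_length_bruteforce(tree, m, 0)
    return hits / n_instances


def search_oracle_agreement(seed: int, n_instances: int = 4) -> float:
    """Fraction of small matrices where the heuristic search attains the
    exhaustive optimum score."""
    rng = random.Random(_sub_seed(seed, 13))
    hits = 0
    for i in range(n_instances):
        n = 7 if i < n_instances - 1 else 8
        labels = [f"t{i}" for i in range(n)]
        m = _random_column_matrix(labels, 12, rng)
        exact = mp_search(m, method="exhaustive", seed=_sub_seed(seed, 13, i))
        heur = mp_search(
            m, method="heuristic", replicates=5, swap="spr",
            seed=_sub_seed(seed, 13, i, 1),
        )
        hits += abs(exact.score - heur.score) < 1e-9
    return hits / n_instances


# ---------------------------------------------------------------------------
# Site-resampling recovery (the Fig 5-style experiment, scaled down)
# ---------------------------------------------------------------------------

SITE_LEVELS = (0.02, 0.05, 0.1, 0.2, 0.5, 0.9)


def site_resampling_recovery(
    seed: int, n_datasets: int = 3, reps: int = 10
) -> dict:
    """Scaled-down molecular resampling experiment with both morphology arms.

    Datasets: 20 core extant taxa, 150 morphology characters, 1,200 DNA sites
    + 30 indels (saturating molecular partition, conservative morphology).
    Returns per-level mean quartet divergence per arm, Spearman trend of the
    shared-quartet proportion over levels, and the per-level morphology
    advantage count.
    """
    dfs = []
    for k in range(n_datasets):
        cfg = SimulationConfig(
            n_extant=20, n_core=20, n_fossil=0, n_morph_chars=150,
            n_dna_sites=1200, n_indels=30, seed=_sub_seed(seed, 31, k),
        )
        ds = build_synthetic_dataset(cfg)
        recs = run_site_resampling(
            ds.matrix, ds.reference_tree, list(SITE_LEVELS),
            reps_per_condition=reps, seed=_sub_seed(seed, 32, k),
        )
        dfs.append(records_to_dataframe(recs))
    df = pd.concat(dfs, ignore_index=True)
    div = df.groupby(["fraction", "with_morphology"])["quartet_divergence"].mean().unstack()
    sq = df.groupby(["fraction", "with_morphology"])["shared_quartet_proportion"].mean().unstack()
    rho_with = float(stats.spearmanr(sq.index, sq[True]).statistic)
    rho_without = float(stats.spearmanr(sq.index, sq[False]).statistic)
    advantage_levels = int((div[True] <= div[False]).sum())
    return {
        "levels": list(div.index),
        "divergence_with_morphology": div[True].tolist(),
        "divergence_without_morphology": div[False].tolist(),
        "spearman_with_morphology": rho_with,
        "spearman_without_morphology": rho_without,
        "n_levels": len(div),
        "morphology_advantage_levels": advantage_levels,
    }


# ---------------------------------------------------------------------------
# Taxon-addition recovery (the Fig 6/7-style experiment, scaled down)
# ---------------------------------------------------------------------------


def taxon_addition_recovery(
    seed: int, n_datasets: int = 8, reps: int = 3
) -> dict:
    """Scaled-down incremental taxon addition, morphology only.

    Datasets: 21 extant (15 core + 6 unstable), 12 fossils, 150 morphology
    characters.  Fossils and hypothetical ancestors are added to the full
    extant base; extra extant taxa are added to the core base.  Records are
    pooled across datasets and an OLS slope of quartet divergence on the
    number of added taxa is fitted per pool.
    """
    pools: dict[str, list] = {"fossil": [], "ancestor": [], "extant": []}
    for k in range(n_datasets):
        cfg = SimulationConfig(
            n_extant=21, n_core=15, n_fossil=12, n_morph_chars=150,
            n_dna_sites=0, n_indels=0, seed=_sub_seed(seed, 41, k),
        )
        ds = build_synthetic_dataset(cfg)
        morph = ds.matrix.select_columns(ds.matrix.columns_with_tags(MORPHOLOGY))
        ancestors = export_hypothetical_ancestors(
            ds.reference_tree, morph.select_taxa(ds.core_taxa), "acctran"
        )
        merged = combine_partitions([morph]).add_rows(ancestors)
        extant_base = sorted(ds.extant_taxa)
        jobs = [
            ("fossil", extant_base, ds.fossil_taxa),
            ("ancestor", extant_base, ancestors.taxa[1:]),  # non-root nodes
            ("extant", ds.core_taxa, sorted(set(ds.extant_taxa) - set(ds.core_taxa))),
        ]
        for name, base, pool in jobs:
            counts = [c for c in (0, 3, 6, 9, 12) if c <= len(pool)]
            recs = run_taxon_addition(
                merged, ds.reference_tree, base, pool, counts,
                reps_per_count=reps, seed=_sub_seed(seed, 42, k),
                experiment=f"add_{name}", pool_label=name,
            )
            pools[name].extend(recs)
    out: dict = {}
    for name, recs in pools.items():
        fit = summarize_and_fit(recs, "n_added", "quartet_divergence")
        out[f"{name}_slope"] = fit.slope
        out[f"{name}_p"] = fit.p_slope
        out[f"{name}_level_means"] = fit.level_means["mean"].tolist()
    return out


# ---------------------------------------------------------------------------
# End-to-end combined-data recovery
# ---------------------------------------------------------------------------


def end_to_end_recovery(seed: int) -> dict:
    """Combined morphology+DNA MP analysis of a full synthetic study.

    41 core + 19 other extant + 20 fossils, 219 morphology characters and
    4,000 DNA sites; the consensus pruned to the core is compared with the
    reference restricted to the core.
    """
    cfg = SimulationConfig(
        n_extant=60, n_core=41, n_fossil=20, n_morph_chars=219,
        n_dna_sites=4000, n_indels=0, seed=_sub_seed(seed, 51),
    )
    ds = build_synthetic_dataset(cfg)
    result = mp_search(ds.matrix, replicates=2, seed=_sub_seed(seed, 52))
    common = sorted(set(result.consensus.leaf_labels) & set(ds.reference_tree.leaf_labels))
    test = prune(result.consensus, common)
    ref = prune(ds.reference_tree, common)
    c = quartet_status_counts(test, ref)
    return {
        "n_common_taxa": len(common),
        "shared_quartet_proportion": shared_quartet_proportion(c),
        "quartet_divergence": quartet_divergence(c),
        "shared_partitions": shared_partitions(test, ref),
        "mp_score": result.score,
    }
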