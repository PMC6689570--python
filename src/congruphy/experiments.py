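"""Resampling experiments: molecular site resampling (with/without
morphology) and incremental taxon addition (fossils, hypothetical ancestors,
extant taxa), each replicate scored against a reference tree.

Every replicate runs an MP search, takes the strict consensus of the
retained co-optimal trees, prunes consensus and reference to their common
taxa, and records all four congruence metrics.  Per-replicate seeds are
derived from the master seed with a counter-based scheme
(``numpy.random.SeedSequence``), so any level/arm/replicate can be rerun
independently and the whole experiment is bit-reproducible from
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .characters import DNA, INDEL, MORPHOLOGY, CharacterMatrix, subsample_sites
from .metrics import (
    MetricError,
    QuartetStatusCounts,
    normalized_rf,
    quartet_divergence,
    quartet_status_counts,
    shared_partitions,
    shared_quartet_proportion,
)
from .parsimony import mp_search
from .trees import PhyloTree, prune, split_blocks, write_tree


class ExperimentError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class ExperimentRecord:
    """One analysis replicate and its congruence against the reference."""

    experiment: str
    condition: dict
    replicate: int
    seed: int
    consensus_newick: str
    n_common_taxa: int
    quartets: QuartetStatusCounts
    quartet_divergence: float
    shared_quartet_proportion: float | None
    rf_raw: int
    rf_normalized: float | None
    shared_partitions: int
    mp_score: float


@dataclass
class TrendFit:
    """OLS fit of a metric on a condition variable, plus per-level summaries."""

    slope: float
    intercept: float
    r2_adjusted: float
    p_slope: float
    level_means: pd.DataFrame  # columns: x, mean, sd, n

    def plotting_payload(self) -> dict:
        """Mean +/- 1 SD polygons per level, as plain lists."""
        lm = self.level_means
        return {
            "x": lm["x"].tolist(),
            "mean": lm["mean"].tolist(),
            "lower": (lm["mean"] - lm["sd"]).tolist(),
            "upper": (lm["mean"] + lm["sd"]).tolist(),
        }


def _derive_seed(master: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(master)] + [int(p) for p in path])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _score_replicate(
    experiment: str,
    condition: dict,
    replicate: int,
    seed: int,
    matrix: CharacterMatrix,
    taxa: Sequence[str],
    reference: PhyloTree,
    search_kwargs: dict,
) -> ExperimentRecord:
    result = mp_search(matrix, taxa=list(taxa), seed=seed, **search_kwargs)
    consensus = result.consensus
    common = sorted(set(consensus.leaf_labels) & set(reference.leaf_labels))
    if len(common) < 4:
        raise ExperimentError(
            f"reference and test tree share only {len(common)} taxa"
        )
    test = prune(consensus, common)
    ref = prune(reference, common)
    c = quartet_status_counts(test, ref)
    try:
        sq = shared_quartet_proportion(c)
    except MetricError:
        sq = None
    try:
        rf = normalized_rf(test, ref)
        rf_raw, rf_norm = rf.raw, rf.normalized
    except MetricError:  # star consensus: raw RF still defined
        rf_raw, rf_norm = len(split_blocks(test) ^ split_blocks(ref)), None
    return ExperimentRecord(
        experiment=experiment,
        condition=dict(condition),
        replicate=replicate,
        seed=seed,
        consensus_newick=write_tree(consensus, lengths=False),
        n_common_taxa=len(common),
        quartets=c,
        quartet_divergence=quartet_divergence(c),
        shared_quartet_proportion=sq,
        rf_raw=rf_raw,
        rf_normalized=rf_norm,
        shared_partitions=shared_partitions(test, ref),
        mp_score=result.score,
    )


def run_site_resampling(
    m: CharacterMatrix,
    reference: PhyloTree,
    levels: Sequence[float],
    reps_per_condition: int = 25,
    seed: int = 0,
    taxa: Sequence[str] | None = None,
    arms: tuple[bool, ...] = (True, False),
    search_kwargs: dict | None = None,
) -> list[ExperimentRecord]:
    """Molecular site-resampling experiment, with/without morphology arms.

    For every sampling level (fraction of DNA+indel columns), arm and
    replicate: subsample sites without replacement, optionally append the
    full (unsubsampled) morphology partition, run an MP search on the extant
    taxa, take the strict consensus, prune to taxa shared with the reference,
    and record all congruence metrics.  The study protocol is 11 levels
    (2%–90%) x 25 replicates x 2 arms = 550 records.

    ``taxa`` defaults to the taxa with at least one observed molecular cell
    (the extant sample).
    """
    if not levels or any(not (0 < f <= 1) for f in levels):
        raise ExperimentError("levels must be fractions in (0, 1]")
    search_kwargs = dict(search_kwargs or {})
    search_kwargs.setdefault("replicates", 3)
    mol_cols = m.columns_with_tags((DNA, INDEL))
    if not mol_cols:
        raise ExperimentError("matrix has no dna/indel columns")
    if taxa is None:
        taxa = [
            t
            for i, t in enumerate(m.taxa)
            if any(isinstance(m.cells[i][j], frozenset) for j in mol_cols)
        ]
    morph = m.select_columns(m.columns_with_tags(MORPHOLOGY)).select_taxa(taxa)
    molecular = m.select_columns(mol_cols).select_taxa(taxa)

    records: list[ExperimentRecord] = []
    for li, level in enumerate(levels):
        for rep in range(reps_per_condition):
            # the two arms are paired: same site draw, +/- morphology
            draw_seed = _derive_seed(seed, 1, li, rep)
            base_sub = subsample_sites(
                molecular, (DNA, INDEL), level, np.random.default_rng(draw_seed)
            )
            for ai, with_morph in enumerate(arms):
                rseed = _derive_seed(seed, 1, li, rep, ai)
                sub = _cbind(base_sub, morph) if with_morph else base_sub
                rec = _score_replicate(
                    "site_resampling",
                    {"fraction": level, "with_morphology": with_morph},
                    rep,
                    rseed,
                    sub,
                    taxa,
                    reference,
                    search_kwargs,
                )
                records.append(rec)
    return records


def _cbind(a: CharacterMatrix, b: CharacterMatrix) -> CharacterMatrix:
    from .characters import combine_partitions

    return combine_partitions([a, b])


def run_taxon_addition(
    m: CharacterMatrix,
    reference: PhyloTree,
    base: Sequence[str],
    pool: Sequence[str],
    counts: Sequence[int],
    reps_per_count: int = 25,
    seed: int = 0,
    search_kwargs: dict | None = None,
    experiment: str = "taxon_addition",
    pool_label: str = "pool",
) -> list[ExperimentRecord]:
    """Incremental taxon-addition experiment (fossils | ancestors | extant).

    For each N in ``counts`` and each replicate, N pool members are drawn
    without replacement, a morphology-only MP search is run on base + drawn,
    and the strict consensus is scored against the reference after pruning to
    common taxa.  Supports both study designs: the 60-extant base with
    fossils/ancestors added (25 replicates per N), and the 41-core base with
    up to 18 added taxa (18 replicates per N).
    """
    base, pool = list(base), list(pool)
    overlap = set(base) & set(pool)
    if overlap:
        raise ExperimentError(f"pool overlaps base: {sorted(overlap)}")
    if any(n > len(pool) or n < 0 for n in counts):
        raise ExperimentError("counts must be within [0, len(pool)]")
    search_kwargs = dict(search_kwargs or {})
    search_kwargs.setdefault("replicates", 3)
    morph = m.select_columns(m.columns_with_tags(MORPHOLOGY))

    records: list[ExperimentRecord] = []
    for ni, n_add in enumerate(counts):
        for rep in range(reps_per_count):
            rseed = _derive_seed(seed, 2, ni, rep)
            rng = np.random.default_rng(rseed)
            drawn = (
                sorted(rng.choice(pool, size=n_add, replace=False).tolist())
                if n_add
                else []
            )
            taxa = base + drawn
            rec = _score_replicate(
                experiment,
                {"n_added": n_add, "pool": pool_label, "drawn": drawn},
                rep,
                rseed,
                morph.select_taxa(taxa),
                taxa,
                reference,
                search_kwargs,
            )
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def records_to_dataframe(records: Iterable[ExperimentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "experiment": r.experiment,
            "replicate": r.replicate,
            "seed": r.seed,
            "n_common_taxa": r.n_common_taxa,
            "quartet_divergence": r.quartet_divergence,
            "shared_quartet_proportion": r.shared_quartet_proportion,
            "rf_raw": r.rf_raw,
            "rf_normalized": r.rf_normalized,
            "shared_partitions": r.shared_partitions,
            "mp_score": r.mp_score,
            "consensus_newick": r.consensus_newick,
        }
        for k, v in r.condition.items():
            if k != "drawn":
                row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_and_fit(
    records: Sequence[ExperimentRecord], x: str, y: str
) -> TrendFit:
    """Per-level mean/SD of metric ``y`` plus an OLS fit of y on condition
    variable ``x`` (adjusted R-squared and slope p-value), the linear-model
    summary used for the taxon-addition trends."""
    import statsmodels.api as sm

    df = records_to_dataframe(records)
    if x not in df.columns:
        raise ExperimentError(f"unknown condition variable {x!r}")
    if y not in df.columns:
        raise ExperimentError(f"unknown metric {y!r}")
    sub = df[[x, y]].dropna()
    if sub[x].nunique() < 2:
        raise ExperimentError("need at least 2 distinct x values for a fit")
    xv = sub[x].astype(float).to_numpy()
    yv = sub[y].astype(float).to_numpy()
    model = sm.OLS(yv, sm.add_constant(xv)).fit()
    level_means = (
        sub.groupby(x)[y]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .rename(columns={x: "x"})
    )
    level_means["sd"] = level_means["sd"].fillna(0.0)
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2_adjusted=float(model.rsquared_adj),
        p_slope=float(model.pvalues[1]),
        level_means=level_means,
    )


def paired_arm_test(
    records: Sequence[ExperimentRecord],
    y: str = "shared_quartet_proportion",
    test: str = "wilcoxon",
) -> dict:
    """Paired comparison of the with- vs without-morphology arms.

    Pairs per (level, replicate); ``test`` is 'ttest' or 'wilcoxon'.  Returns
    the statistic, p-value and per-arm means.
    """
    from scipy import stats

    df = records_to_dataframe(records)
    piv = df.pivot_table(
        index=["fraction", "replicate"], columns="with_morphology", values=y
    ).dropna()
    with_arm = piv[True].to_numpy()
    without_arm = piv[False].to_numpy()
    if test == "ttest":
        res = stats.ttest_rel(with_arm, without_arm)
    elif test == "wilcoxon":
        diffs = with_arm - without_arm
        if np.allclose(diffs, 0):
            return {"statistic": 0.0, "p_value": 1.0,
                    "mean_with": float(with_arm.mean()),
                    "mean_without": float(without_arm.mean())}
        res = stats.wilcoxon(with_arm, without_arm)
    else:
        raise ExperimentError(f"unknown test {test!r}")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_with": float(with_arm.mean()),
        "mean_without": float(without_arm.mean()),
    }
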