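"""FF/FP/PP pattern calls, stress-sharing clusters, trajectories, co-expression.

A paralog pair is **FF** under a condition when both genes are differentially
expressed (padj < 0.05 and |log2FC| > 1, strict), **FP** when exactly one is,
and **PP** when neither is; a missing DE record means "not DE". Pairs are
grouped into seven stress-sharing clusters by the set of stresses in which
they show the focal pattern (all four; the two abiotic Dr+Cd; the two biotic
Bc+Pr; or one specific stress) with every other Venn region collected in an
explicit "other" cluster. Across the three time points of a stress the pair's
pattern rank (PP=0, FP=1, FF=2) traces a trajectory: enhancing (PP→…→FF),
decreasing (FF→…→PP), stable, or mixed. Co-expressed pairs are those whose
within-pair Pearson correlation across treated samples exceeds 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import STRESSES, DERecord, ExpressionMatrix, ParalogPair

__all__ = [
    "PATTERN_RANK",
    "DEIndex",
    "call_de",
    "classify_pair",
    "classify_pairs",
    "assign_cluster",
    "classify_trajectory",
    "trajectory_table",
    "coexpressed_fraction",
    "pattern_counts",
]

logger = logging.getLogger(__name__)

PATTERN_RANK: dict[str, int] = {"PP": 0, "FP": 1, "FF": 2}

_CLUSTER_MAP = {
    frozenset(STRESSES): "all_four",
    frozenset({"Dr", "Cd"}): "abiotic_shared",
    frozenset({"Bc", "Pr"}): "biotic_shared",
    frozenset({"Dr"}): "Dr_specific",
    frozenset({"Cd"}): "Cd_specific",
    frozenset({"Bc"}): "Bc_specific",
    frozenset({"Pr"}): "Pr_specific",
}


class DEIndex:
    """Lookup of DE records by (gene, stress, time_index); missing means not DE."""

    def __init__(self, records: Iterable[DERecord]):
        self._by_key: dict[tuple[str, str, int], DERecord] = {
            (r.gene, r.stress, r.time_index): r for r in records
        }

    def get(self, gene: str, stress: str, time_index: int) -> Optional[DERecord]:
        return self._by_key.get((gene, stress, time_index))

    def conditions(self) -> list[tuple[str, int]]:
        return sorted({(s, t) for (_, s, t) in self._by_key})


def call_de(record: Optional[DERecord], alpha: float = 0.05, lfc: float = 1.0) -> bool:
    """True iff the gene is expressed, padj < alpha and |log2FC| > lfc (strict)."""
    if record is None:
        return False
    return bool(record.expressed and record.padj < alpha and abs(record.log2fc) > lfc)


def classify_pair(
    pair: ParalogPair,
    condition: tuple[str, int],
    de_index: DEIndex,
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> str:
    """FF / FP / PP pattern of one pair under one (stress, time) condition."""
    stress, t = condition
    de_a = call_de(de_index.get(pair.gene_a, stress, t), alpha, lfc)
    de_b = call_de(de_index.get(pair.gene_b, stress, t), alpha, lfc)
    if de_a and de_b:
        return "FF"
    if de_a or de_b:
        return "FP"
    return "PP"


def classify_pairs(
    pairs: Sequence[ParalogPair],
    de_records: Iterable[DERecord],
    alpha: float = 0.05,
    lfc: float = 1.0,
    conditions: Optional[Sequence[tuple[str, int]]] = None,
) -> pd.DataFrame:
    """Long-format pattern table: one row per pair x condition with the FF/FP/PP call."""
    index = de_records if isinstance(de_records, DEIndex) else DEIndex(de_records)
    if conditions is None:
        conditions = index.conditions()
    rows = []
    for pair in pairs:
        for cond in conditions:
            rows.append(
                {
                    "pair_id": pair.pair_id,
                    "stress": cond[0],
                    "time_index": cond[1],
                    "pattern": classify_pair(pair, cond, index, alpha, lfc),
                }
            )
    return pd.DataFrame(rows, columns=["pair_id", "stress", "time_index", "pattern"])


def assign_cluster(pair_id: str, membership: set[str] | frozenset[str]) -> str:
    """Map a pair's per-stress focal-pattern membership to one of the 7 named
    stress-sharing clusters, or "other" for unnamed Venn regions."""
    membership = frozenset(membership)
    if not membership:
        raise ValueError(f"pair {pair_id}: empty membership, pair should not be clustered")
    unknown = membership - set(STRESSES)
    if unknown:
        raise ValueError(f"pair {pair_id}: unknown stress code(s) {sorted(unknown)}")
    return _CLUSTER_MAP.get(membership, "other")


def classify_trajectory(ranks: Sequence[int]) -> str:
    """Trajectory over time of the pattern rank (PP=0, FP=1, FF=2):
    enhancing, decreasing, stable or mixed."""
    if len(ranks) != 3:
        raise ValueError("trajectory classification expects 3 time points")
    if any(r not in (0, 1, 2) for r in ranks):
        raise ValueError(f"ranks {tuple(ranks)} outside {{0, 1, 2}}")
    r1, r2, r3 = ranks
    if r1 == r2 == r3:
        return "stable"
    if r1 <= r2 <= r3 and r3 == 2 and r1 < 2:
        return "enhancing"
    if r1 >= r2 >= r3 and r1 == 2 and r3 < 2:
        return "decreasing"
    return "mixed"


def trajectory_table(pattern_calls: pd.DataFrame) -> pd.DataFrame:
    """Per pair x stress trajectory labels from a long-format pattern table."""
    rows = []
    for (pair_id, stress), grp in pattern_calls.groupby(["pair_id", "stress"], sort=False):
        grp = grp.sort_values("time_index")
        ranks = [PATTERN_RANK[p] for p in grp["pattern"]]
        if len(ranks) != 3:
            continue
        rows.append({"pair_id": pair_id, "stress": stress,
                     "trajectory": classify_trajectory(ranks)})
    return pd.DataFrame(rows, columns=["pair_id", "stress", "trajectory"])


def coexpressed_fraction(
    pairs: Sequence[ParalogPair],
    expression: ExpressionMatrix,
    subset: Optional[Iterable[str]] = None,
    stress: Optional[str] = None,
    r_threshold: float = 0.5,
) -> float:
    """Fraction of pairs with within-pair Pearson r > ``r_threshold`` across
    treated samples (optionally of one stress), on log expression.

    Pairs with undefined r (zero variance) are excluded from numerator and
    denominator; their count is logged.
    """
    if subset is not None:
        subset = set(subset)
        pairs = [p for p in pairs if p.pair_id in subset]
    if not pairs:
        raise ValueError("empty pair subset")
    samples = expression.treated_samples(stress=stress)
    if len(samples) < 3:
        raise ValueError("need >= 3 treated samples for a defined correlation")
    logvals = expression.log_values(samples)
    n_undefined = 0
    n_co = 0
    n_def = 0
    for pair in pairs:
        x = logvals.loc[pair.gene_a].to_numpy()
        y = logvals.loc[pair.gene_b].to_numpy()
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            n_undefined += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        n_def += 1
        if r > r_threshold:
            n_co += 1
    if n_undefined:
        logger.info("coexpressed_fraction: %d pair(s) with undefined r excluded", n_undefined)
    if n_def == 0:
        raise ValueError("no pair with a defined correlation")
    return n_co / n_def


def pattern_counts(pattern_calls: pd.DataFrame) -> pd.DataFrame:
    """FF/FP/PP counts per (stress, time_index); rows sum to the number of pairs."""
    table = (
        pattern_calls.pivot_table(
            index=["stress", "time_index"], columns="pattern", values="pair_id",
            aggfunc="count", fill_value=0,
        )
        .reindex(columns=["FF", "FP", "PP"], fill_value=0)
    )
    table.columns.name = None
    return table.reset_index()
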