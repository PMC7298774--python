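"""Model/Results interface tying the analysis stages together.

:class:`ParalogDivergenceModel` is constructed from the three data inputs
(paralog pairs, DE table, expression matrix, optionally a TF list) or from a
:class:`~paradiverge.simulate.SimulationConfig`, and ``fit()`` runs the full
analysis: NG86 divergence per pair, FF/FP/PP pattern calls, stress-sharing
clusters and trajectories, within-pair correlation and rescaled r′, the
r′-vs-Ks regression per pattern class, the randomized-pair permutation tests
of the class Ka/Ks statistics, and the thresholded co-expression network.
The returned :class:`ParalogDivergenceResults` carries every table plus a
``summary()`` text report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import divergence as dv
from . import network as net
from . import patterns as pt
from . import permutation as perm
from . import stats as st
from .io_formats import (
    STRESSES,
    DERecord,
    ExpressionMatrix,
    ParalogPair,
    TFList,
    read_de_tsv,
    read_expression_tsv,
    read_pair_fasta,
    read_tf_list,
)
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset

__all__ = ["AnalysisSettings", "ParalogDivergenceModel", "ParalogDivergenceResults"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisSettings:
    """Thresholds and options of the analysis.

    ``analysis_time_index`` selects the single time point per stress used for
    the FF/FP/PP pattern call (the last of the three by default, where the
    stress response is fully developed); trajectories always use all three.
    """

    alpha: float = 0.05
    lfc: float = 1.0
    coexpr_r: float = 0.5
    power: int = 10
    node_r_min: float = 0.5
    edge_w_min: float = 0.3
    rescale_mode: str = "printed"  # or "fisher"
    statistic: str = "median"  # or "mean"
    n_reps: int = 10_000
    analysis_time_index: int = 3
    # recorded for provenance only; module detection is out of scope
    min_module_size: int = 30
    merge_cut_height: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc < 0:
            raise ValueError("lfc must be >= 0")
        if self.rescale_mode not in {"printed", "fisher"}:
            raise ValueError("rescale_mode must be 'printed' or 'fisher'")
        if self.statistic not in {"median", "mean"}:
            raise ValueError("statistic must be 'median' or 'mean'")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class ParalogDivergenceResults:
    """Fitted results; see each attribute's table schema in the writer docstrings."""

    settings: AnalysisSettings
    n_pairs: int
    divergence: pd.DataFrame  # per pair: S, N, Sd, Nd, Ka, Ks, Ka_Ks, selection
    patterns: pd.DataFrame  # long: pair_id, stress, time_index, pattern
    pattern_counts: pd.DataFrame
    clusters: pd.DataFrame  # pair_id, focal (FF/FP), cluster
    trajectories: pd.DataFrame  # pair_id, stress, trajectory
    correlations: Optional[pd.DataFrame]  # pair_id, r, r_prime, n_samples
    coexpressed: dict  # (class, stress) -> fraction
    regressions: dict  # class -> RegressionResult or skip reason
    permutations: dict  # (class, stress) -> PermutationResult or skip reason
    ks_summary: Optional[st.KsDensitySummary]
    network: Optional[dict]  # graph, counts, ranking, dep_tf_edges
    notes: list[str] = field(default_factory=list)

    def class_pairs(self, focal: str) -> list[str]:
        """Pair IDs showing the focal pattern in >=1 stress at the analysis time point."""
        t = self.settings.analysis_time_index
        sub = self.patterns[(self.patterns["time_index"] == t) & (self.patterns["pattern"] == focal)]
        return sorted(sub["pair_id"].unique())

    def summary(self) -> str:
        lines = [
            "Paralog expression/sequence divergence analysis",
            "=" * 48,
            f"pairs analysed: {self.n_pairs}",
            "",
            "Pattern counts (per stress, analysis time point):",
        ]
        t = self.settings.analysis_time_index
        counts = self.pattern_counts[self.pattern_counts["time_index"] == t]
        lines.append(counts.to_string(index=False))
        if not self.clusters.empty:
            lines.append("")
            lines.append("Stress-sharing clusters:")
            tab = self.clusters.groupby(["focal", "cluster"]).size().rename("pairs")
            lines.append(tab.to_string())
        if not self.trajectories.empty:
            lines.append("")
            lines.append("Trajectories (per stress):")
            tab = (
                self.trajectories.groupby(["stress", "trajectory"]).size().rename("pairs")
            )
            lines.append(tab.to_string())
        if self.coexpressed:
            lines.append("")
            lines.append("Co-expressed fractions (within-pair r > "
                         f"{self.settings.coexpr_r}):")
            for (cls, stress), frac in sorted(self.coexpressed.items()):
                lines.append(f"  {cls} under {stress}: {frac:.3f}")
        lines.append("")
        lines.append("r' vs Ks regressions:")
        for cls, reg in self.regressions.items():
            if isinstance(reg, st.RegressionResult):
                lines.append(
                    f"  {cls}: slope={reg.slope:.4f}  p={reg.p_slope:.3g}  "
                    f"r^2={reg.r_squared:.3f}  n={reg.n}"
                )
            else:
                lines.append(f"  {cls}: skipped ({reg})")
        lines.append("")
        reps = next(
            (r.n_reps for r in self.permutations.values()
             if isinstance(r, perm.PermutationResult)),
            self.settings.n_reps,
        )
        lines.append(f"Permutation tests ({self.settings.statistic} Ka/Ks vs randomized pairs, "
                     f"{reps} reps):")
        for (cls, stress), res in sorted(self.permutations.items()):
            if isinstance(res, perm.PermutationResult):
                lines.append(
                    f"  {cls} under {stress}: observed={res.observed:.4f}  "
                    f"tail={res.tail}  p={res.empirical_p:.3g}"
                )
            else:
                lines.append(f"  {cls} under {stress}: skipped ({res})")
        if self.ks_summary is not None:
            lines.append("")
            lines.append(
                f"Ks distribution: modal bin midpoint {self.ks_summary.modal_bin_midpoint:.2f}, "
                f"P(Ks > 1) = {self.ks_summary.fraction_above_1:.3f} (n={self.ks_summary.n})"
            )
        if self.network is not None:
            c = self.network["counts"]
            lines.append("")
            lines.append(
                f"Co-expression network: {c['nodes_after']}/{c['nodes_before']} nodes, "
                f"{c['edges_after']}/{c['edges_before']} edges after thresholding"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


class ParalogDivergenceModel:
    """The full paralog-pair analysis as a fit-once model object."""

    def __init__(
        self,
        pairs: Sequence[ParalogPair],
        de_records: Iterable[DERecord],
        expression: Optional[ExpressionMatrix] = None,
        tf_list: Optional[TFList] = None,
        tf_families: Optional[Mapping[str, str]] = None,
        settings: Optional[AnalysisSettings] = None,
    ):
        if not pairs:
            raise ValueError("need at least one paralog pair")
        self.pairs = list(pairs)
        self.de_records = list(de_records)
        self.expression = expression
        self.tf_list = tf_list
        self.tf_families = dict(tf_families or {})
        self.settings = settings or AnalysisSettings()
        self._de_index = pt.DEIndex(self.de_records)

    # ------------------------------------------------------------------
    @classmethod
    def from_files(
        cls,
        pairs_fasta,
        de_tsv,
        expression_tsv=None,
        tf_list_path=None,
        settings: Optional[AnalysisSettings] = None,
    ) -> "ParalogDivergenceModel":
        return cls(
            pairs=read_pair_fasta(pairs_fasta),
            de_records=read_de_tsv(de_tsv),
            expression=read_expression_tsv(expression_tsv) if expression_tsv else None,
            tf_list=read_tf_list(tf_list_path) if tf_list_path else None,
            settings=settings,
        )

    @classmethod
    def from_simulation(
        cls,
        config: SimulationConfig,
        settings: Optional[AnalysisSettings] = None,
    ) -> "ParalogDivergenceModel":
        dataset = simulate_dataset(config)
        model = cls(
            pairs=dataset.pairs,
            de_records=dataset.de_records,
            expression=dataset.expression,
            settings=settings,
        )
        model.dataset_: SyntheticDataset = dataset
        return model

    # ------------------------------------------------------------------
    def _divergence_table(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            est = dv.compute_ka_ks(pair)
            rows.append(
                {
                    "pair_id": est.pair_id,
                    "S": est.s_sites,
                    "N": est.n_sites,
                    "Sd": est.s_diffs,
                    "Nd": est.n_diffs,
                    "ka": np.nan if est.ka is None else est.ka,
                    "ks": np.nan if est.ks is None else est.ks,
                    "ka_ks": np.nan if est.ka_ks is None else est.ka_ks,
                    "selection": est.selection,
                }
            )
        return pd.DataFrame(rows).set_index("pair_id", drop=False)

    def _correlation_table(self) -> Optional[pd.DataFrame]:
        if self.expression is None:
            return None
        samples = self.expression.treated_samples()
        logvals = self.expression.log_values(samples)
        rows = []
        for pair in self.pairs:
            x = logvals.loc[pair.gene_a].to_numpy()
            y = logvals.loc[pair.gene_b].to_numpy()
            r = st.pearson_r(x, y)
            if np.isfinite(r) and -1.0 < r < 1.0:
                rp = st.rescale_r(r, self.settings.rescale_mode)
            else:
                rp = np.nan
            rows.append(
                {"pair_id": pair.pair_id, "r": r, "r_prime": rp, "n_samples": len(samples)}
            )
        return pd.DataFrame(rows).set_index("pair_id", drop=False)

    def fit(self, seed: Optional[int] = None, n_reps: Optional[int] = None) -> ParalogDivergenceResults:
        """Run every stage and return the results object.

        ``seed`` drives the permutation-null resampling; ``n_reps`` overrides
        the settings default (10,000).
        """
        s = self.settings
        n_reps = n_reps or s.n_reps
        rng = np.random.default_rng(seed)
        notes: list[str] = []

        divergence = self._divergence_table()
        n_undef = int(divergence["ka_ks"].isna().sum())
        if n_undef:
            notes.append(f"{n_undef} pair(s) with undefined Ka/Ks excluded from ratio statistics")

        patterns = pt.classify_pairs(self.pairs, self._de_index, alpha=s.alpha, lfc=s.lfc)
        counts = pt.pattern_counts(patterns)
        trajectories = pt.trajectory_table(patterns)

        # stress-sharing clusters for the FF and FP classes at the analysis time
        t = s.analysis_time_index
        cluster_rows = []
        at_t = patterns[patterns["time_index"] == t]
        for focal in ("FF", "FP"):
            member = at_t[at_t["pattern"] == focal].groupby("pair_id")["stress"].agg(set)
            for pair_id, stresses in member.items():
                cluster_rows.append(
                    {"pair_id": pair_id, "focal": focal,
                     "cluster": pt.assign_cluster(pair_id, stresses)}
                )
        clusters = pd.DataFrame(cluster_rows, columns=["pair_id", "focal", "cluster"])

        correlations = self._correlation_table()

        # class membership: focal pattern in >=1 stress at the analysis time
        class_ids: dict[str, list[str]] = {}
        for focal in ("FF", "FP"):
            sub = at_t[at_t["pattern"] == focal]
            class_ids[focal] = sorted(sub["pair_id"].unique())

        coexpressed: dict[tuple[str, str], float] = {}
        if self.expression is not None:
            stresses_present = sorted(at_t["stress"].unique())
            for focal in ("FF", "FP"):
                for stress in stresses_present:
                    ids = at_t[(at_t["pattern"] == focal) & (at_t["stress"] == stress)]["pair_id"]
                    if len(ids) == 0:
                        continue
                    coexpressed[(focal, stress)] = pt.coexpressed_fraction(
                        self.pairs, self.expression, subset=set(ids), stress=stress,
                        r_threshold=s.coexpr_r,
                    )

        regressions: dict[str, object] = {}
        if correlations is not None:
            for focal in ("FF", "FP"):
                ids = class_ids[focal]
                if len(ids) < 3:
                    regressions[focal] = f"fewer than 3 {focal} pairs"
                    logger.info("regression for %s skipped: %s", focal, regressions[focal])
                    continue
                pts = np.column_stack(
                    [
                        correlations.loc[ids, "r_prime"].to_numpy(dtype=float),
                        divergence.loc[ids, "ks"].to_numpy(dtype=float),
                    ]
                )
                try:
                    regressions[focal] = st.regress_rprime_on_ks(pts)
                except ValueError as exc:
                    regressions[focal] = str(exc)
        else:
            notes.append("no expression matrix: correlation/regression/network stages skipped")

        permutations: dict[tuple[str, str], object] = {}
        pool_ids = [p.pair_id for p in self.pairs]
        stat_name = f"{s.statistic}_ka_ks"
        # directional hypotheses: FF under purifying selection (smaller Ka/Ks
        # than random pairs), FP under relaxed/positive selection (larger)
        tails = {"FF": "less", "FP": "greater"}
        for focal in ("FF", "FP"):
            for stress in sorted(at_t["stress"].unique()):
                ids = list(at_t[(at_t["pattern"] == focal) & (at_t["stress"] == stress)]["pair_id"])
                key = (focal, stress)
                if not ids:
                    permutations[key] = "no pairs in class"
                    continue
                if divergence.loc[ids, "ka_ks"].notna().sum() == 0:
                    permutations[key] = "no defined Ka/Ks in class"
                    continue
                permutations[key] = perm.permutation_test(
                    ids, pool_ids, divergence, statistic=stat_name,
                    n_reps=n_reps, tail=tails[focal], rng=rng,
                )

        ffp_ids = sorted(set(class_ids["FF"]) | set(class_ids["FP"]))
        ks_vals = divergence.loc[ffp_ids, "ks"].dropna() if ffp_ids else pd.Series(dtype=float)
        ks_summary = st.ks_density_summary(ks_vals) if len(ks_vals) else None

        network = None
        if self.expression is not None and self.tf_list is not None:
            network = self._build_network(at_t, trajectories)

        return ParalogDivergenceResults(
            settings=s,
            n_pairs=len(self.pairs),
            divergence=divergence,
            patterns=patterns,
            pattern_counts=counts,
            clusters=clusters,
            trajectories=trajectories,
            correlations=correlations,
            coexpressed=coexpressed,
            regressions=regressions,
            permutations=permutations,
            ks_summary=ks_summary,
            network=network,
            notes=notes,
        )

    def _build_network(self, at_t: pd.DataFrame, trajectories: pd.DataFrame) -> dict:
        s = self.settings
        gene_of = {}
        for pair in self.pairs:
            gene_of[pair.pair_id] = (pair.gene_a, pair.gene_b)
        dep_ids = at_t[at_t["pattern"].isin(["FF", "FP"])]["pair_id"].unique()
        dep_genes = sorted({g for pid in dep_ids for g in gene_of[pid]})
        expr_genes = set(self.expression.genes)
        tf_genes = sorted(g for g in self.tf_list.genes if g in expr_genes)
        genes = [g for g in dep_genes if g in expr_genes] + [g for g in tf_genes if g not in dep_genes]
        if len(genes) < 2:
            return {"graph": None, "counts": None, "ranking": None,
                    "dep_tf_edges": None, "skipped": "fewer than 2 network genes"}
        adjacency = net.build_adjacency(self.expression, genes, power=s.power)
        graph, counts = net.threshold_network(adjacency, node_r_min=s.node_r_min,
                                              edge_w_min=s.edge_w_min)
        # gene-level trajectory labels inherited from the pair
        gene_traj: dict[str, str] = {}
        for row in trajectories.itertuples(index=False):
            if row.trajectory in ("enhancing", "decreasing"):
                for g in gene_of[row.pair_id]:
                    gene_traj[g] = row.trajectory
        annotated = net.annotate_and_count(
            graph, self.tf_list, dep_genes, tf_families=self.tf_families,
            gene_trajectory=gene_traj,
        )
        return {"graph": graph, "counts": counts, **annotated}
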