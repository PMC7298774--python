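"""End-to-end pipeline runner: one config in, eight result files out.

``run_pipeline`` executes simulate (or load) → classify → Ka/Ks → correlate →
permute → network and writes, under the configured output directory:

* ``kaks.tsv`` — per-pair NG86 estimates (undefined values encoded "NA");
* ``patterns.tsv`` — FF/FP/PP call per pair × condition;
* ``clusters.tsv`` — stress-sharing cluster per FF/FP pair;
* ``trajectories.tsv`` — enhancing/decreasing/stable/mixed per pair × stress;
* ``regression.json`` — r′-vs-Ks OLS per pattern class;
* ``permutation.json`` — randomized-pair test per class × stress;
* ``network.tsv`` — retained co-expression edges (if TF list given);
* ``summary.json`` — thresholds, seed, version, counts, skip reasons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .model import AnalysisSettings, ParalogDivergenceModel, ParalogDivergenceResults
from .permutation import PermutationResult
from .simulate import SimulationConfig
from .stats import RegressionResult

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_OUTPUTS = (
    "kaks.tsv", "patterns.tsv", "clusters.tsv", "trajectories.tsv",
    "regression.json", "permutation.json", "network.tsv", "summary.json",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; JSON round-trips without loss."""

    outdir: str = "paradiverge_out"
    seed: int = 0
    n_reps: int = 1000
    simulation: Optional[SimulationConfig] = None
    pairs_fasta: Optional[str] = None
    de_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None
    tf_list: Optional[str] = None
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)

    def __post_init__(self) -> None:
        if self.simulation is None and (self.pairs_fasta is None or self.de_tsv is None):
            raise ValueError("need either a simulation config or pairs_fasta + de_tsv")

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["settings"] = asdict(self.settings)
        if self.simulation is not None:
            doc["simulation"] = asdict(self.simulation)
        Path(path).write_text(json.dumps(doc, indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        if doc.get("settings"):
            doc["settings"] = AnalysisSettings(**doc["settings"])
        if doc.get("simulation"):
            sim = doc["simulation"]
            for key in ("ks_range", "stresses"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            doc["simulation"] = SimulationConfig(**sim)
        return cls(**doc)


def _na(value) -> str:
    return "NA" if value is None or (isinstance(value, float) and not np.isfinite(value)) else f"{value:.6g}"


def _write_kaks(divergence: pd.DataFrame, path: Path) -> None:
    df = divergence
    out = pd.DataFrame(
        {
            "pair_id": df["pair_id"],
            "S": df["S"].map(_na),
            "N": df["N"].map(_na),
            "Sd": df["Sd"].map(_na),
            "Nd": df["Nd"].map(_na),
            "Ka": df["ka"].map(_na),
            "Ks": df["ks"].map(_na),
            "Ka_Ks": df["ka_ks"].map(_na),
            "selection": df["selection"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _regression_doc(results: ParalogDivergenceResults) -> dict:
    doc = {}
    for cls, reg in results.regressions.items():
        if isinstance(reg, RegressionResult):
            doc[cls] = asdict(reg)
        else:
            doc[cls] = {"skipped": str(reg)}
    return doc


def _permutation_doc(results: ParalogDivergenceResults) -> dict:
    doc = {}
    for (cls, stress), res in results.permutations.items():
        key = f"{cls}_{stress}"
        if isinstance(res, PermutationResult):
            doc[key] = {
                "observed": res.observed,
                "empirical_p": res.empirical_p,
                "n_reps": res.n_reps,
                "tail": res.tail,
                "statistic": res.statistic,
                "null_mean": float(np.nanmean(res.null_values)),
                "histogram": res.histogram.to_dict(orient="list"),
            }
        else:
            doc[key] = {"skipped": str(res)}
    return doc


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis per ``config``; returns the summary document."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        logger.info("simulating %d pairs (seed %d)", sim.n_pairs, config.seed)
        model = ParalogDivergenceModel.from_simulation(sim, settings=config.settings)
    else:
        model = ParalogDivergenceModel.from_files(
            config.pairs_fasta, config.de_tsv, config.expression_tsv, config.tf_list,
            settings=config.settings,
        )

    results = model.fit(seed=config.seed, n_reps=config.n_reps)

    _write_kaks(results.divergence, outdir / "kaks.tsv")
    results.patterns.to_csv(outdir / "patterns.tsv", sep="\t", index=False)
    results.clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    results.trajectories.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    (outdir / "regression.json").write_text(json.dumps(_regression_doc(results), indent=2) + "\n")
    (outdir / "permutation.json").write_text(json.dumps(_permutation_doc(results), indent=2) + "\n")

    net_rows = []
    if results.network is not None and results.network.get("graph") is not None:
        graph = results.network["graph"]
        for u, v, d in sorted(graph.edges(data=True)):
            net_rows.append({"gene_a": u, "gene_b": v, "r": f"{d['r']:.6g}",
                             "weight": f"{d['weight']:.6g}"})
    pd.DataFrame(net_rows, columns=["gene_a", "gene_b", "r", "weight"]).to_csv(
        outdir / "network.tsv", sep="\t", index=False
    )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_reps": config.n_reps,
        "n_pairs": results.n_pairs,
        "settings": asdict(config.settings),
        "simulation": asdict(config.simulation) if config.simulation else None,
        "pattern_counts": results.pattern_counts.to_dict(orient="records"),
        "cluster_counts": results.clusters.groupby(["focal", "cluster"]).size().to_dict()
        if not results.clusters.empty else {},
        "coexpressed": {f"{c}_{s}": v for (c, s), v in results.coexpressed.items()},
        "regression": _regression_doc(results),
        "permutation": {
            k: {kk: vv for kk, vv in v.items() if kk != "histogram"}
            for k, v in _permutation_doc(results).items()
        },
        "ks_modal_bin_midpoint": results.ks_summary.modal_bin_midpoint
        if results.ks_summary else None,
        "ks_fraction_above_1": results.ks_summary.fraction_above_1
        if results.ks_summary else None,
        "network_counts": results.network.get("counts") if results.network else None,
        "notes": results.notes,
        "outputs": list(_OUTPUTS),
    }
    # cluster_counts keys are tuples; make them JSON-safe
    summary["cluster_counts"] = {
        f"{f}_{c}": int(n) for (f, c), n in summary["cluster_counts"].items()
    } if summary["cluster_counts"] else {}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    logger.info("pipeline complete: outputs in %s", outdir)
    return summary
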