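"""Synthetic paralog datasets: codon evolution, coupled expression, DE tables.

The generator plants the statistical structure the downstream analysis is
designed to detect, so every stage can be tested end to end without external
data:

* **sequences** — an ancestral CDS of random sense codons is duplicated and
  each copy evolved by iterated single-nucleotide proposals with an
  acceptance-probability ratio ω between nonsynonymous and synonymous
  changes (proposals creating stop codons are rejected). Each lineage stops
  once its realized synonymous substitutions per NG86 synonymous site reach
  half the pairwise target Ks, so the pair diverges symmetrically.
* **expression** — the two genes of a pair share log-scale expression drawn
  from a bivariate normal with correlation ρ = exp(−λ·Ks): expression
  divergence grows with sequence divergence, the structure the r′-vs-Ks
  regression should recover with a negative slope. Values are exponentiated
  to an FPKM-like scale; controls sit at the per-gene baseline.
* **DE tables** — per gene × condition, a call is differentially expressed
  with probability ``de_fraction`` (padj ~ U(0, 0.049),
  |log2FC| = 1 + Exp(mean = effect_mu − 1), random sign) and otherwise
  fails both thresholds (padj ~ U(0.05, 1), |log2FC| ~ U(0, 1)). A
  configurable fraction of pairs per stress is planted with enhancing
  (PP→…→FF) or decreasing (FF→…→PP) rank trajectories across the three
  time points; the planted truth is returned for recovery tests.

The experiment layout mirrors the study design the pipeline targets: four
stresses (drought Dr, cold Cd, *Botrytis* Bc, *Pieris* Pr), three time
points each, with per-condition controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .divergence import CHANGE_CLASS, SENSE_CODONS, SYN_SITES
from .io_formats import STRESSES, DERecord, ExpressionMatrix, ParalogPair

__all__ = [
    "SimulationConfig",
    "EvolvedPair",
    "SyntheticDataset",
    "generate_ancestral_cds",
    "evolve_pair",
    "simulate_expression",
    "simulate_de_table",
    "simulate_dataset",
]

_NTS = "ACGT"

# non-decreasing rank triples ending at FF (enhancing) and their reverses
_ENHANCING_TRIPLES: tuple[tuple[int, int, int], ...] = (
    (0, 0, 2), (0, 1, 2), (0, 2, 2), (1, 1, 2), (1, 2, 2),
)
_DECREASING_TRIPLES: tuple[tuple[int, int, int], ...] = tuple(
    t[::-1] for t in _ENHANCING_TRIPLES
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults describe the baseline condition used throughout: 300 pairs of
    100-codon genes under purifying selection (ω = 0.5) with pairwise Ks
    drawn uniformly on [0.05, 2.0], expression coupling λ = 1, four stresses
    × three time points × three treated replicates plus one control each,
    30% DE calls with mean |log2FC| 2.5 among DE genes.
    """

    n_pairs: int = 300
    codons_per_gene: int = 100
    omega: float = 0.5
    target_ks: float = 0.5
    ks_range: Optional[tuple[float, float]] = (0.05, 2.0)
    coupling_lambda: float = 1.0
    de_fraction: float = 0.3
    effect_mu: float = 2.5
    enhancing_fraction: float = 0.0
    decreasing_fraction: float = 0.0
    n_timepoints: int = 3
    n_replicates: int = 3
    stresses: tuple[str, ...] = STRESSES
    baseline_log_fpkm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.codons_per_gene < 1:
            raise ValueError("codons_per_gene must be >= 1")
        if self.omega < 0:
            raise ValueError("omega must be > 0")
        if self.target_ks < 0:
            raise ValueError("target_ks must be >= 0")
        if self.coupling_lambda < 0:
            raise ValueError("coupling_lambda must be >= 0")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0, 1]")
        if self.effect_mu <= 1.0:
            raise ValueError("effect_mu must exceed 1 (mean |log2FC| of DE genes)")
        if self.enhancing_fraction + self.decreasing_fraction > 1.0:
            raise ValueError("planted trajectory fractions exceed 1")


@dataclass(frozen=True)
class EvolvedPair:
    """An evolved pair plus its ground truth: the ω used and the per-lineage
    tallies of accepted synonymous/nonsynonymous substitutions."""

    pair: ParalogPair
    true_omega: float
    target_ks: float
    syn_subs: tuple[int, int]
    nonsyn_subs: tuple[int, int]


def generate_ancestral_cds(codons: int, rng: np.random.Generator) -> str:
    """Random CDS of uniformly drawn sense codons (no stops), length 3 x codons."""
    if codons < 1:
        raise ValueError("codons must be >= 1")
    idx = rng.integers(0, len(SENSE_CODONS), size=codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _evolve_lineage(
    codons: list[str],
    omega: float,
    target_ks_half: float,
    rng: np.random.Generator,
) -> tuple[list[str], int, int]:
    """Evolve one lineage in place until syn substitutions per NG86 syn site
    reach ``target_ks_half``; returns (codons, syn_count, nonsyn_count)."""
    n_codons = len(codons)
    length = 3 * n_codons
    s_sites = sum(SYN_SITES[c] for c in codons)
    syn = nonsyn = 0
    if target_ks_half <= 0:
        return codons, 0, 0
    # acceptance-probability ratio: for omega < 1 nonsynonymous proposals are
    # thinned to omega; for omega > 1 synonymous proposals are thinned to 1/omega
    p_nonsyn = min(omega, 1.0)
    p_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    max_proposals = 50 * length
    proposals = 0
    while s_sites > 0 and syn / s_sites < target_ks_half:
        if proposals >= max_proposals:
            raise RuntimeError(
                f"target divergence unreachable: {max_proposals} proposals exhausted "
                f"(realized Ks/2 = {syn / s_sites:.3f}, target {target_ks_half:.3f})"
            )
        proposals += 1
        site = int(rng.integers(0, length))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        cur = codon[pos]
        nt = _NTS[int(rng.integers(0, 4))]
        if nt == cur:
            continue
        cls = CHANGE_CLASS[(codon, pos, nt)]
        if cls == "stop":
            continue
        accept_p = p_syn if cls == "syn" else p_nonsyn
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        new_codon = codon[:pos] + nt + codon[pos + 1 :]
        s_sites += SYN_SITES[new_codon] - SYN_SITES[codon]
        codons[ci] = new_codon
        if cls == "syn":
            syn += 1
        else:
            nonsyn += 1
    return codons, syn, nonsyn


def evolve_pair(
    ancestor: str,
    omega: float,
    target_ks: float,
    rng: np.random.Generator,
    pair_id: str = "pair1",
    gene_a: str = "g1a",
    gene_b: str = "g1b",
) -> EvolvedPair:
    """Duplicate ``ancestor`` and evolve both copies independently to a pairwise
    synonymous divergence of ``target_ks`` (half per lineage)."""
    if omega < 0:
        raise ValueError("omega must be > 0")
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    anc = [ancestor[i : i + 3] for i in range(0, len(ancestor), 3)]
    half = target_ks / 2.0
    seq_a, syn_a, nonsyn_a = _evolve_lineage(list(anc), omega, half, rng)
    seq_b, syn_b, nonsyn_b = _evolve_lineage(list(anc), omega, half, rng)
    pair = ParalogPair(
        pair_id=pair_id,
        gene_a=gene_a,
        gene_b=gene_b,
        cds_a="".join(seq_a),
        cds_b="".join(seq_b),
    )
    return EvolvedPair(
        pair=pair,
        true_omega=omega,
        target_ks=target_ks,
        syn_subs=(syn_a, syn_b),
        nonsyn_subs=(nonsyn_a, nonsyn_b),
    )


def _sample_layout(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for stress in config.stresses:
        for t in range(1, config.n_timepoints + 1):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {"sample": f"{stress}_{t}_{rep}", "stress": stress,
                     "time_index": t, "replicate": rep, "is_control": False}
                )
            rows.append(
                {"sample": f"{stress}_{t}_1_ctrl", "stress": stress,
                 "time_index": t, "replicate": 1, "is_control": True}
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_expression(
    pairs: Sequence[ParalogPair],
    ks_per_pair: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """FPKM-like expression with within-pair log-scale correlation exp(−λ·Ks)."""
    if config.coupling_lambda < 0:
        raise ValueError("coupling_lambda must be >= 0")
    if len(ks_per_pair) != len(pairs):
        raise ValueError("need exactly one Ks value per pair")
    meta = _sample_layout(config)
    treated = np.flatnonzero(~meta["is_control"].to_numpy())
    controls = np.flatnonzero(meta["is_control"].to_numpy())
    n_samples = len(meta)
    genes: list[str] = []
    rows: list[np.ndarray] = []
    for pair, ks in zip(pairs, ks_per_pair):
        rho = float(np.exp(-config.coupling_lambda * ks))
        mu_a = config.baseline_log_fpkm + rng.normal(0.0, 1.0)
        mu_b = config.baseline_log_fpkm + rng.normal(0.0, 1.0)
        x = np.empty(n_samples)
        y = np.empty(n_samples)
        z1 = rng.normal(size=treated.size)
        z2 = rng.normal(size=treated.size)
        x[treated] = z1
        y[treated] = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
        x[controls] = rng.normal(size=controls.size)
        y[controls] = rng.normal(size=controls.size)
        genes.extend([pair.gene_a, pair.gene_b])
        rows.append(np.exp(mu_a + x))
        rows.append(np.exp(mu_b + y))
    values = pd.DataFrame(np.vstack(rows), index=genes, columns=meta.index)
    return ExpressionMatrix(values=values, sample_meta=meta)


def _de_record(
    gene: str, stress: str, t: int, is_de: bool, config: SimulationConfig,
    rng: np.random.Generator,
) -> DERecord:
    if is_de:
        padj = rng.uniform(0.0, 0.049)
        lfc = (1.0 + rng.exponential(config.effect_mu - 1.0)) * (1 if rng.random() < 0.5 else -1)
    else:
        padj = rng.uniform(0.05, 1.0)
        lfc = rng.uniform(0.0, 1.0) * (1 if rng.random() < 0.5 else -1)
    return DERecord(gene=gene, stress=stress, time_index=t, log2fc=float(lfc),
                    padj=float(padj), expressed=True)


def simulate_de_table(
    pairs: Sequence[ParalogPair],
    config: SimulationConfig,
    rng: np.random.Generator,
    return_truth: bool = False,
):
    """Per-gene x condition DE calls; optionally also the planted trajectory truth.

    With ``return_truth=True`` returns ``(records, truth)`` where ``truth`` is a
    DataFrame (pair_id, stress, trajectory) listing planted enhancing/decreasing
    pairs and their rank triples.
    """
    if not (0.0 <= config.de_fraction <= 1.0):
        raise ValueError("de_fraction must be in [0, 1]")
    records: list[DERecord] = []
    truth_rows: list[dict] = []
    times = range(1, config.n_timepoints + 1)
    for pair in pairs:
        for stress in config.stresses:
            u = rng.random()
            ranks: Optional[tuple[int, ...]] = None
            label = None
            if config.n_timepoints == 3 and u < config.enhancing_fraction:
                ranks = _ENHANCING_TRIPLES[int(rng.integers(0, len(_ENHANCING_TRIPLES)))]
                label = "enhancing"
            elif config.n_timepoints == 3 and u < config.enhancing_fraction + config.decreasing_fraction:
                ranks = _DECREASING_TRIPLES[int(rng.integers(0, len(_DECREASING_TRIPLES)))]
                label = "decreasing"
            if ranks is not None:
                truth_rows.append(
                    {"pair_id": pair.pair_id, "stress": stress,
                     "trajectory": label, "ranks": ranks}
                )
                for t, rank in zip(times, ranks):
                    # rank = number of DE genes in the pair at this time point
                    if rank == 2:
                        de_a = de_b = True
                    elif rank == 1:
                        de_a = rng.random() < 0.5
                        de_b = not de_a
                    else:
                        de_a = de_b = False
                    records.append(_de_record(pair.gene_a, stress, t, de_a, config, rng))
                    records.append(_de_record(pair.gene_b, stress, t, de_b, config, rng))
            else:
                for t in times:
                    for gene in (pair.gene_a, pair.gene_b):
                        is_de = rng.random() < config.de_fraction
                        records.append(_de_record(gene, stress, t, is_de, config, rng))
    if return_truth:
        truth = pd.DataFrame(truth_rows, columns=["pair_id", "stress", "trajectory", "ranks"])
        return records, truth
    return records


@dataclass
class SyntheticDataset:
    """A complete simulated input set plus its ground truth."""

    config: SimulationConfig
    pairs: list[ParalogPair]
    evolved: list[EvolvedPair]
    true_ks: np.ndarray
    expression: ExpressionMatrix
    de_records: list[DERecord]
    trajectory_truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate sequences, expression and DE table under one config (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    if config.ks_range is not None:
        lo, hi = config.ks_range
        true_ks = rng.uniform(lo, hi, size=config.n_pairs)
    else:
        true_ks = np.full(config.n_pairs, config.target_ks, dtype=float)
    evolved = []
    for i in range(config.n_pairs):
        anc = generate_ancestral_cds(config.codons_per_gene, rng)
        evolved.append(
            evolve_pair(
                anc, config.omega, float(true_ks[i]), rng,
                pair_id=f"P{i+1:05d}", gene_a=f"P{i+1:05d}a", gene_b=f"P{i+1:05d}b",
            )
        )
    pairs = [e.pair for e in evolved]
    expression = simulate_expression(pairs, true_ks, config, rng)
    de_records, truth = simulate_de_table(pairs, config, rng, return_truth=True)
    return SyntheticDataset(
        config=config, pairs=pairs, evolved=evolved, true_ks=true_ks,
        expression=expression, de_records=de_records, trajectory_truth=truth,
    )
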