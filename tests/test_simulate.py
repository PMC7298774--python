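import numpy as np
import pytest
from Bio.Seq import Seq

from paradiverge.divergence import compute_ka_ks
from paradiverge.io_formats import write_de_tsv, write_expression_tsv, write_pair_fasta
from paradiverge.patterns import call_de
from paradiverge.simulate import (
    SimulationConfig,
    evolve_pair,
    generate_ancestral_cds,
    simulate_dataset,
    simulate_de_table,
    simulate_expression,
)


class TestAncestralCds:
    def test_single_codon_is_sense(self, rng):
        for _ in range(50):
            cds = generate_ancestral_cds(1, rng)
            assert str(Seq(cds).translate()) != "*"

    def test_no_stops_in_translation(self, rng):
        for _ in range(1000):
            cds = generate_ancestral_cds(5, rng)
            assert "*" not in str(Seq(cds).translate())

    def test_deterministic_under_fixed_seed(self):
        a = generate_ancestral_cds(100, np.random.default_rng(7))
        b = generate_ancestral_cds(100, np.random.default_rng(7))
        assert a == b

    def test_rejects_nonpositive_count(self, rng):
        with pytest.raises(ValueError):
            generate_ancestral_cds(0, rng)


class TestEvolvePair:
    def test_zero_target_keeps_ancestor(self, rng):
        anc = generate_ancestral_cds(50, rng)
        ep = evolve_pair(anc, 0.5, 0.0, rng)
        assert ep.pair.cds_a == anc and ep.pair.cds_b == anc

    def test_omega_zero_means_no_nonsynonymous_changes(self, rng):
        for _ in range(10):
            anc = generate_ancestral_cds(60, rng)
            ep = evolve_pair(anc, 0.0, 0.4, rng)
            assert ep.nonsyn_subs == (0, 0)
            # every accepted change is synonymous, so the protein is untouched
            # (NG86 pathway averaging may still split composite codon
            # differences between the two lineages into syn+nonsyn steps)
            assert Seq(ep.pair.cds_a).translate() == Seq(anc).translate()
            assert Seq(ep.pair.cds_b).translate() == Seq(anc).translate()

    def test_neutral_rates_agree_with_tallies(self, rng):
        """At omega=1 the per-site nonsynonymous and synonymous rates match
        within 3 Monte-Carlo sigma of their event counts."""
        tS = tN = tSd = tNd = 0.0
        for _ in range(100):
            anc = generate_ancestral_cds(100, rng)
            est = compute_ka_ks(evolve_pair(anc, 1.0, 0.1, rng).pair)
            tS += est.s_sites
            tN += est.n_sites
            tSd += est.s_diffs
            tNd += est.n_diffs
        ratio = (tNd / tN) / (tSd / tS)
        sigma = np.sqrt(1.0 / tSd + 1.0 / tNd)
        assert abs(ratio - 1.0) <= 3.0 * sigma

    def test_saturation_guard_raises(self, rng):
        anc = generate_ancestral_cds(5, rng)
        with pytest.raises(RuntimeError, match="unreachable"):
            evolve_pair(anc, 0.5, 600.0, rng)


class TestSimulateExpression:
    def _pairs(self, n, rng):
        return [evolve_pair(generate_ancestral_cds(10, rng), 1.0, 0.0, rng,
                            pair_id=f"P{i}", gene_a=f"P{i}a", gene_b=f"P{i}b").pair
                for i in range(n)]

    def test_lambda_zero_gives_perfect_coupling(self, rng):
        cfg = SimulationConfig(n_pairs=20, coupling_lambda=0.0, seed=0)
        pairs = self._pairs(20, rng)
        expr = simulate_expression(pairs, np.linspace(0, 2, 20), cfg, rng)
        lv = expr.log_values(expr.treated_samples())
        for p in pairs:
            r = np.corrcoef(lv.loc[p.gene_a], lv.loc[p.gene_b])[0, 1]
            # the +1 pseudocount in the log transform slightly bends the
            # otherwise exactly collinear profiles
            assert r == pytest.approx(1.0, abs=0.05)

    def test_mean_pair_correlation_tracks_exp_decay(self, rng):
        """At Ks=0.5 and lambda=1 the mean within-pair r is near exp(-0.5)."""
        cfg = SimulationConfig(n_pairs=500, coupling_lambda=1.0, seed=0,
                               stresses=("Dr",), n_replicates=4)
        pairs = self._pairs(500, rng)
        expr = simulate_expression(pairs, np.full(500, 0.5), cfg, rng)
        samples = expr.treated_samples()
        assert len(samples) == 12
        lv = expr.log_values(samples)
        rs = [np.corrcoef(lv.loc[p.gene_a], lv.loc[p.gene_b])[0, 1] for p in pairs]
        assert np.mean(rs) == pytest.approx(np.exp(-0.5), abs=0.1)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(coupling_lambda=-1.0)

    def test_ks_count_mismatch_rejected(self, rng):
        cfg = SimulationConfig(n_pairs=3, seed=0)
        pairs = self._pairs(3, rng)
        with pytest.raises(ValueError, match="one Ks value per pair"):
            simulate_expression(pairs, [0.5, 0.5], cfg, rng)


class TestSimulateDeTable:
    def _pairs(self, n, rng):
        return [evolve_pair(generate_ancestral_cds(5, rng), 1.0, 0.0, rng,
                            pair_id=f"P{i}", gene_a=f"P{i}a", gene_b=f"P{i}b").pair
                for i in range(n)]

    def test_de_fraction_zero_passes_nothing(self, rng):
        cfg = SimulationConfig(n_pairs=30, de_fraction=0.0, seed=0)
        records = simulate_de_table(self._pairs(30, rng), cfg, rng)
        assert not any(call_de(r) for r in records)

    def test_de_fraction_one_passes_everything(self, rng):
        cfg = SimulationConfig(n_pairs=30, de_fraction=1.0, effect_mu=2.0, seed=0)
        records = simulate_de_table(self._pairs(30, rng), cfg, rng)
        assert all(call_de(r) for r in records)

    def test_passing_fraction_matches_de_fraction(self, rng):
        """Binomial check: fraction of threshold-passing calls within 3 sigma of 0.3."""
        cfg = SimulationConfig(n_pairs=500, de_fraction=0.3, seed=0, stresses=("Dr",),
                               n_timepoints=3)
        records = simulate_de_table(self._pairs(500, rng), cfg, rng)
        one_cond = [r for r in records if r.condition == ("Dr", 1)]
        assert len(one_cond) == 1000
        frac = np.mean([call_de(r) for r in one_cond])
        assert frac == pytest.approx(0.3, abs=0.05)

    def test_planted_ranks_reflected_in_de_flags(self, rng):
        cfg = SimulationConfig(n_pairs=40, de_fraction=0.1, enhancing_fraction=0.5,
                               decreasing_fraction=0.5, seed=0)
        pairs = self._pairs(40, rng)
        records, truth = simulate_de_table(pairs, cfg, rng, return_truth=True)
        assert len(truth) == 40 * 4  # every pair x stress planted
        by_key = {(r.gene, r.stress, r.time_index): r for r in records}
        gene_of = {p.pair_id: (p.gene_a, p.gene_b) for p in pairs}
        for row in truth.itertuples(index=False):
            ga, gb = gene_of[row.pair_id]
            for t, rank in zip((1, 2, 3), row.ranks):
                n_de = call_de(by_key[(ga, row.stress, t)]) + call_de(by_key[(gb, row.stress, t)])
                assert n_de == rank


class TestDeterminism:
    def test_identical_config_gives_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_pairs=12, codons_per_gene=20, seed=99,
                               enhancing_fraction=0.2)
        for d in ("a", "b"):
            ds = simulate_dataset(cfg)
            out = tmp_path / d
            out.mkdir()
            write_pair_fasta(ds.pairs, out / "pairs.fasta")
            write_expression_tsv(ds.expression, out / "expr.tsv")
            write_de_tsv(ds.de_records, out / "de.tsv")
        for name in ("pairs.fasta", "expr.tsv", "de.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
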