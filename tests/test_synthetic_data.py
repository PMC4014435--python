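import numpy as np
import pytest

from paleogen.divergence import expected_discordance
from paleogen.errors import ValidationError
from paleogen.synthetic_data import (
    DemographyGraph,
    SampleSpec,
    degrade_ancient,
    sample_panel,
    simulate_frequencies,
    simulate_pileup,
    simulate_trio_counts,
)


def graph_from(edges=(), admixtures=(), samples=(), **kw):
    return DemographyGraph.from_dict({
        "root": {"name": "R", **kw},
        "edges": list(edges),
        "admixtures": list(admixtures),
        "samples": list(samples),
    })


class TestDemographyGraph:
    def test_cycle_detection(self):
        with pytest.raises(ValidationError):
            graph_from(edges=[
                {"child": "A", "parent": "B", "F": 0.1},
                {"child": "B", "parent": "A", "F": 0.1},
            ])

    def test_two_parents_rejected_outside_admixture(self):
        with pytest.raises(ValidationError):
            graph_from(edges=[
                {"child": "A", "parent": "R", "F": 0.1},
                {"child": "A", "parent": "R", "F": 0.2},
            ])

    def test_f_bounds(self):
        with pytest.raises(ValidationError):
            graph_from(edges=[{"child": "A", "parent": "R", "F": 1.0}])

    def test_alpha_bounds(self):
        with pytest.raises(ValidationError):
            graph_from(
                edges=[{"child": "A", "parent": "R", "F": 0.1},
                       {"child": "B", "parent": "R", "F": 0.1}],
                admixtures=[{"child": "X", "parents": ["A", "B"], "alpha": 1.5}],
            )

    def test_yaml_roundtrip(self, tmp_path):
        text = """
root: {name: R, freq: [0.1, 0.9]}
edges:
  - {child: A, parent: R, F: 0.1}
samples:
  - {population: A, n: 3, ploidy: 1, class: ancient}
"""
        (tmp_path / "g.yaml").write_text(text)
        graph, config = DemographyGraph.from_yaml(tmp_path / "g.yaml")
        assert graph.root == "R"
        assert graph.root_freq == (0.1, 0.9)
        assert graph.samples == [SampleSpec("A", 3, 1, "ancient")]


class TestSimulateFrequencies:
    def test_zero_drift_copies_root(self):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.0}])
        sim = simulate_frequencies(g, 50, seed=1)
        np.testing.assert_array_equal(sim.freq("A"), sim.freq("R"))

    def test_alpha_one_copies_parent1(self):
        g = graph_from(
            edges=[{"child": "A", "parent": "R", "F": 0.1},
                   {"child": "B", "parent": "R", "F": 0.1}],
            admixtures=[{"child": "X", "parents": ["A", "B"], "alpha": 1.0}],
        )
        sim = simulate_frequencies(g, 50, seed=2)
        np.testing.assert_allclose(sim.freq("X"), sim.freq("A"))

    def test_balding_nichols_moments(self):
        # [DERIVED] mean p, variance F p (1-p) at p=0.3, F=0.1 over 10k sites
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.1}],
                       freq=[0.3, 0.3])
        sim = simulate_frequencies(g, 10_000, seed=3)
        child = sim.freq("A")
        assert child.mean() == pytest.approx(0.30, abs=0.01)
        assert child.var() == pytest.approx(0.1 * 0.3 * 0.7, rel=0.1)

    def test_frequencies_in_unit_interval(self):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.9}])
        sim = simulate_frequencies(g, 2_000, seed=4)
        for node in ("R", "A"):
            f = sim.freq(node)
            assert (f >= 0).all() and (f <= 1).all()

    def test_snp_map_sorted_and_polarized(self):
        g = DemographyGraph.from_dict({
            "root": "R", "genome": {"1": 10**7, "2": 10**7},
            "edges": [{"child": "A", "parent": "R", "F": 0.1}],
        })
        sim = simulate_frequencies(g, 500, seed=5)
        seen = []
        last = None
        for s in sim.snps:
            if s.chromosome != last:
                assert s.chromosome not in seen
                seen.append(s.chromosome)
                last = s.chromosome
                prev = 0
            assert s.position > prev
            prev = s.position
            assert s.ancestral_allele == s.ref_allele

    def test_ts_tv_ratio(self):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.1}])
        sim = simulate_frequencies(g, 20_000, seed=6)
        ts = sum(1 for s in sim.snps if s.is_transition)
        assert ts / len(sim.snps) == pytest.approx(2 / 3, abs=0.02)

    def test_determinism(self):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.1}])
        a = simulate_frequencies(g, 100, seed=7)
        b = simulate_frequencies(g, 100, seed=7)
        assert a.snps == b.snps
        np.testing.assert_array_equal(a.freq("A"), b.freq("A"))


class TestSamplePanel:
    def test_fixed_frequencies(self):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.0}],
                       freq=[0.0, 0.0],
                       samples=[{"population": "A", "n": 4},
                                {"population": "A", "n": 2, "ploidy": 1}])
        sim = simulate_frequencies(g, 30, seed=1)
        panel, _ = sample_panel(sim, graph=g, seed=1)
        assert (panel.genotypes == 0).all()

    def test_p_one(self):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.0}],
                       freq=[1.0, 1.0],
                       samples=[{"population": "A", "n": 2},
                                {"population": "A", "n": 2, "ploidy": 1}])
        sim = simulate_frequencies(g, 30, seed=1)
        panel, _ = sample_panel(sim, graph=g, seed=1)
        assert (panel.genotypes[:2] == 2).all()
        assert (panel.genotypes[2:] == 1).all()

    def test_binomial_mean(self):
        # [DERIVED] 2000 diploids at p=0.5 -> mean alt count 1.0
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.0}],
                       freq=[0.5, 0.5],
                       samples=[{"population": "A", "n": 2000}])
        sim = simulate_frequencies(g, 5, seed=2)
        panel, _ = sample_panel(sim, graph=g, seed=2)
        assert panel.genotypes.mean() == pytest.approx(1.0, abs=0.03)

    def test_truth_recorded(self, two_pop_graph):
        sim = simulate_frequencies(two_pop_graph, 20, seed=3)
        panel, truth = sample_panel(sim, graph=two_pop_graph, seed=3)
        assert set(truth.true_genotypes) == {ind.id for ind in panel.individuals}
        np.testing.assert_array_equal(truth.true_genotypes["A0"],
                                      panel.genotypes[0])


class TestDegradeAncient:
    def _ancient_panel(self, m=200, seed=1, freq=0.5):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.0}],
                       freq=[freq, freq],
                       samples=[{"population": "A", "n": 1, "ploidy": 1,
                                 "class": "ancient"}])
        sim = simulate_frequencies(g, m, seed=seed)
        panel, truth = sample_panel(sim, graph=g, seed=seed)
        return panel, truth

    def test_no_degradation_is_identity(self):
        panel, _ = self._ancient_panel()
        calls = degrade_ancient(panel, "A00".replace("00", "0"), 0.0, 0.0, seed=2)
        for m, snp in enumerate(panel.snps):
            g = panel.genotypes[0, m]
            expected = snp.alt_allele if g == 1 else snp.ref_allele
            assert calls.alleles[m] == expected

    def test_full_damage_flips_every_c(self):
        panel, _ = self._ancient_panel()
        calls = degrade_ancient(panel, "A0", 1.0, 0.0, seed=3)
        for m, snp in enumerate(panel.snps):
            a = calls.alleles[m]
            if snp.allele_pair == frozenset("CT"):
                assert a != "C"
            if snp.allele_pair == frozenset("GA"):
                assert a != "G"

    def test_heavy_missingness_k8_scale(self):
        # ~1k surviving calls from 100k sites at 99% missingness
        panel, _ = self._ancient_panel(m=100_000, seed=4)
        calls = degrade_ancient(panel, "A0", 0.0, 0.99, seed=4)
        surviving = sum(1 for a in calls.alleles if a)
        assert 800 <= surviving <= 1200

    def test_alleles_stay_in_pair(self):
        panel, _ = self._ancient_panel()
        calls = degrade_ancient(panel, "A0", 0.5, 0.2, seed=5)
        for snp, a in zip(panel.snps, calls.alleles):
            assert all(c in snp.allele_pair for c in a)

    def test_rate_bounds(self):
        panel, _ = self._ancient_panel(m=10)
        with pytest.raises(ValidationError):
            degrade_ancient(panel, "A0", 1.5, 0.0, seed=1)
        with pytest.raises(ValidationError):
            degrade_ancient(panel, "A0", 0.0, -0.1, seed=1)


class TestSimulatePileup:
    def _snps_alleles(self, m=100, seed=1):
        g = graph_from(edges=[{"child": "A", "parent": "R", "F": 0.1}])
        sim = simulate_frequencies(g, m, seed=seed)
        return sim.snps, ["C"] * m

    def test_zero_depth(self):
        snps, alleles = self._snps_alleles()
        sites = simulate_pileup(snps, alleles, 0.0, 0.0, seed=1)
        assert all(s.depth == 0 for s in sites)

    def test_error_free_haploid(self):
        snps, alleles = self._snps_alleles()
        sites = simulate_pileup(snps, alleles, 50.0, 0.0, seed=2)
        for s in sites:
            assert all(b == "C" for b, _, _ in s.reads)

    def test_error_rate(self):
        # [DERIVED] binomial proportion of non-truth bases
        snps, alleles = self._snps_alleles(m=2000)
        sites = simulate_pileup(snps, alleles, 50.0, 0.01, seed=3)
        total = wrong = 0
        for s in sites:
            for b, _, _ in s.reads:
                total += 1
                wrong += b != "C"
        assert total > 90_000
        assert wrong / total == pytest.approx(0.01, rel=0.15)

    def test_poisson_depth(self):
        snps, alleles = self._snps_alleles(m=5000)
        sites = simulate_pileup(snps, alleles, 3.0, 0.0, seed=4)
        depths = np.array([s.depth for s in sites])
        assert depths.mean() == pytest.approx(3.0, rel=0.05)
        assert depths.var() == pytest.approx(3.0, rel=0.1)


class TestTrioCounts:
    def test_tau_zero_limit(self):
        c = simulate_trio_counts(0.0, 100_000, seed=1)
        ratio = c.n_discordant / (c.n_concordant + c.n_discordant)
        assert ratio == pytest.approx(2 / 3, abs=0.01)

    def test_deep_divergence(self):
        c = simulate_trio_counts(20.0, 50_000, seed=2)
        assert c.n_discordant / (c.n_concordant + c.n_discordant) < 1e-4

    def test_tau_half_matches_closed_form(self):
        # [DERIVED] R(0.5) = 0.3655 (validated against the closed form)
        c = simulate_trio_counts(0.5, 200_000, seed=3)
        ratio = c.n_discordant / (c.n_concordant + c.n_discordant)
        assert ratio == pytest.approx(0.3655, abs=0.005)

    @pytest.mark.parametrize("tau", [0.0, 0.1, 0.3, 0.5, 1.0, 2.0])
    def test_matches_closed_form_within_3se(self, tau):
        n = 200_000
        c = simulate_trio_counts(tau, n, seed=17)
        ratio = c.n_discordant / (c.n_concordant + c.n_discordant)
        r = expected_discordance(tau)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(ratio - r) <= 3 * se

    def test_ancient_age_invariance(self):
        a = simulate_trio_counts(1.0, 50_000, seed=5, ancient_age=0.0)
        b = simulate_trio_counts(1.0, 50_000, seed=5, ancient_age=0.9)
        np.testing.assert_array_equal(a.block_concordant, b.block_concordant)
        np.testing.assert_array_equal(a.block_discordant, b.block_discordant)

    def test_block_totals(self):
        c = simulate_trio_counts(0.5, 10_000, seed=6, n_blocks=20)
        assert c.block_concordant.sum() + c.block_discordant.sum() == 10_000
        assert c.n_blocks == 20

    def test_negative_tau(self):
        with pytest.raises(ValidationError):
            simulate_trio_counts(-0.1, 100, seed=1)

    def test_determinism_and_exchangeability(self):
        a = simulate_trio_counts(0.5, 20_000, seed=9)
        b = simulate_trio_counts(0.5, 20_000, seed=9)
        assert a.n_discordant == b.n_discordant
        c = simulate_trio_counts(0.5, 20_000, seed=10)
        assert abs(c.n_discordant - a.n_discordant) < 1_000
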