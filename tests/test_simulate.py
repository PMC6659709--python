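import json

import numpy as np
import pytest
from scipy import stats

from mtpopgen import vcf_io
from mtpopgen.core import MISSING
from mtpopgen.diversity import group_pi
from mtpopgen.differentiation import weighted_fst
from mtpopgen.haplonet import collapse_haplotypes, shared_haplotypes
from mtpopgen.simulate import (
    SimConfig,
    SimTruth,
    evaluate_recovery,
    simulate_dataset,
    simulate_unlinked_loci,
)
from mtpopgen.variant_summary import FilterConfig, apply_filters

SMALL = dict(
    reference_length=60_000, n_wild=12, n_dom_a=10, n_dom_b=14,
    sweeps_a=(), sweeps_b=((20_000, 25_000),),
    missing_rate=0.0, het_rate=0.0, high_missing_site_fraction=0.0,
)


class TestDeterminismAndRoundtrip:
    def test_same_seed_byte_identical_vcf(self, tmp_path):
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        simulate_dataset(SimConfig(**SMALL, seed=5)).write_vcf(p1)
        simulate_dataset(SimConfig(**SMALL, seed=5)).write_vcf(p2)
        assert p1.read_bytes() == p2.read_bytes()
        p3 = tmp_path / "c.vcf"
        simulate_dataset(SimConfig(**SMALL, seed=6)).write_vcf(p3)
        assert p1.read_bytes() != p3.read_bytes()

    def test_vcf_roundtrip_with_het_and_missing(self, tmp_path):
        cfg = SimConfig(reference_length=60_000, n_wild=12, n_dom_a=10,
                        n_dom_b=14, sweeps_a=(), sweeps_b=(),
                        missing_rate=0.02, het_rate=0.02, seed=11)
        ds = simulate_dataset(cfg)
        path = tmp_path / "sim.vcf"
        ds.write_vcf(path)
        back = vcf_io.read_vcf(path)
        # heterozygous-coded cells resolve to MISSING under the default
        # policy, matching the in-memory matrix exactly
        assert np.array_equal(back.calls, ds.gm.calls)
        assert back.reference_length == cfg.reference_length
        assert [v.pos for v in back.variants] == [v.pos for v in ds.gm.variants]

    def test_metadata_groups_match_config(self):
        ds = simulate_dataset(SimConfig(**SMALL, seed=1))
        st = ds.samples
        assert len(st.members("wild")) == 12
        assert len(st.members("indica")) == 10
        assert len(st.members("japonica")) == 14

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_wild=1, n_dom_a=0, n_dom_b=0)
        with pytest.raises(ValueError):
            SimConfig(bottleneck_b=0.0)
        with pytest.raises(ValueError):
            SimConfig(sweeps_b=((0, 10**9),))


class TestStatisticalProperties:
    def test_wild_pi_matches_theta(self):
        """E(pi) = theta under the neutral coalescent (scaled-down check)."""
        theta = 0.004
        pis = []
        for seed in range(60):
            cfg = SimConfig(reference_length=30_000, n_wild=16, n_dom_a=0,
                            n_dom_b=0, theta_wild=theta, sweeps_a=(), sweeps_b=(),
                            missing_rate=0.0, het_rate=0.0,
                            high_missing_site_fraction=0.0, seed=seed)
            pis.append(group_pi(simulate_dataset(cfg).gm, _all_wild(cfg), "wild"))
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - theta) < 3 * se

    def test_mutation_count_poisson_given_tree(self):
        """S | tree ~ Poisson(theta/2 * L * T): aggregate z^2 is chi-square."""
        z2 = []
        for seed in range(100):
            cfg = SimConfig(reference_length=30_000, n_wild=10, n_dom_a=0,
                            n_dom_b=0, theta_wild=0.004, sweeps_a=(), sweeps_b=(),
                            missing_rate=0.0, het_rate=0.0,
                            high_missing_site_fraction=0.0, seed=100 + seed)
            ds = simulate_dataset(cfg)
            lam = cfg.theta_wild / 2 * cfg.reference_length * ds.truth.total_tree_length
            z2.append((ds.truth.n_variants - lam) ** 2 / lam)
        stat = np.sum(z2)
        p = 1 - stats.chi2.cdf(stat, df=len(z2))
        assert p > 0.01

    def test_no_divergence_no_differentiation(self):
        vals = []
        for seed in range(20):
            cfg = SimConfig(reference_length=40_000, n_wild=10, n_dom_a=25,
                            n_dom_b=25, split_a=0.0, split_b=0.0,
                            bottleneck_a=1.0, bottleneck_b=1.0,
                            sweeps_a=(), sweeps_b=(), missing_rate=0.0,
                            het_rate=0.0, high_missing_site_fraction=0.0,
                            seed=seed)
            ds = simulate_dataset(cfg)
            vals.append(weighted_fst(ds.gm, ds.samples, "indica", "japonica").fst)
        assert abs(np.mean(vals)) < 0.02

    def test_wild_exceeds_bottlenecked_diversity(self):
        wins = 0
        for seed in range(20):
            cfg = SimConfig(reference_length=60_000, n_wild=14, n_dom_a=0,
                            n_dom_b=20, sweeps_a=(), sweeps_b=(),
                            missing_rate=0.0, het_rate=0.0,
                            high_missing_site_fraction=0.0, seed=seed)
            ds = simulate_dataset(cfg)
            wins += group_pi(ds.gm, ds.samples, "wild") > group_pi(
                ds.gm, ds.samples, "japonica"
            )
        assert wins >= 19  # >= 95% of replicates

    def test_pi_against_msprime_oracle(self):
        """Mean diversity of a bottlenecked lineage agrees with msprime."""
        msprime = pytest.importorskip("msprime")
        theta, L, B, split = 0.004, 30_000, 0.2, 0.4
        mine = []
        for seed in range(60):
            cfg = SimConfig(reference_length=L, n_wild=4, n_dom_a=0, n_dom_b=10,
                            theta_wild=theta, split_b=split, bottleneck_b=B,
                            sweeps_a=(), sweeps_b=(), missing_rate=0.0,
                            het_rate=0.0, high_missing_site_fraction=0.0,
                            seed=seed)
            ds = simulate_dataset(cfg)
            mine.append(group_pi(ds.gm, ds.samples, "japonica"))
        theirs = []
        demography = msprime.Demography()
        demography.add_population(name="wild", initial_size=1)
        demography.add_population(name="dom", initial_size=B)
        demography.add_population_split(time=split, derived=["dom"],
                                        ancestral="wild")
        for seed in range(60):
            ts = msprime.sim_ancestry(
                samples={"wild": 4, "dom": 10}, ploidy=1,
                demography=demography, sequence_length=L,
                random_seed=seed + 1,
            )
            mts = msprime.sim_mutations(ts, rate=theta / 2, random_seed=seed + 1)
            dom = ts.samples(population=1)
            theirs.append(
                mts.diversity(sample_sets=dom, mode="site")
            )
        se = np.sqrt(
            np.var(mine, ddof=1) / len(mine) + np.var(theirs, ddof=1) / len(theirs)
        )
        assert abs(np.mean(mine) - np.mean(theirs)) < 3 * se


class TestHaplotypeSharing:
    def _shared(self, migrants, seed):
        cfg = SimConfig(reference_length=120_000, n_wild=10, n_dom_a=12,
                        n_dom_b=16, sweeps_a=(), sweeps_b=((100_000, 110_000),),
                        migrants=migrants, missing_rate=0.0,
                        het_rate=0.0, high_missing_site_fraction=0.0, seed=seed)
        ds = simulate_dataset(cfg)
        hq = apply_filters(ds.gm, FilterConfig())
        haps = collapse_haplotypes(hq, ds.samples)
        return shared_haplotypes(haps, ds.samples, "indica", "japonica")[0]

    def test_no_migration_no_shared_haplotypes(self):
        assert all(self._shared(0, seed) == 0 for seed in range(8))

    def test_migrant_copy_creates_sharing(self):
        assert all(self._shared(3, seed) >= 1 for seed in range(4))


class TestUnlinkedGenerator:
    def test_sfs_shape_matches_neutral_spectrum(self):
        ds = simulate_unlinked_loci(20, 500_000, 0.01, seed=2)
        counts, n = ds.gm.allele_counts()
        derived = counts[:, 1]
        # singleton fraction ~ (1/1)/H_19
        h = sum(1 / i for i in range(1, 20))
        frac1 = (derived == 1).mean()
        assert frac1 == pytest.approx(1 / h, abs=0.02)

    def test_deterministic(self):
        a = simulate_unlinked_loci(10, 20_000, 0.01, seed=9)
        b = simulate_unlinked_loci(10, 20_000, 0.01, seed=9)
        assert np.array_equal(a.gm.calls, b.gm.calls)


class TestRecoveryScoring:
    def _truth(self, sweeps_b=((10_000, 20_000),), migration=()):
        return SimTruth(
            config={}, seed=0, tmrca=1.0, total_tree_length=5.0, n_variants=100,
            sweeps={"dom_a": [], "dom_b": [list(iv) for iv in sweeps_b]},
            migration_events=list(migration),
            expected_pi_order=["wild", "dom_a", "dom_b"],
        )

    def test_planted_sweep_hit_recorded(self):
        truth = self._truth()
        report = evaluate_recovery(
            truth,
            regions={"dom_b": [(9_500, 19_000)], "dom_a": []},
            pi={"wild": 0.01, "dom_a": 0.005, "dom_b": 0.001},
            shared_haplotypes=0,
        )
        hits = {h["scanned_group"]: h for h in report["sweep_hits"]}
        assert hits["dom_b"]["detected"]
        assert hits["dom_b"]["overlap_bp"] == 9_000
        assert not hits["dom_a"]["detected"]
        assert report["pi_order_ok"]
        assert report["shared_haplotypes_ok"]

    def test_true_negative_recorded(self):
        truth = self._truth()
        report = evaluate_recovery(truth, regions={"dom_a": [(50_000, 51_000)]})
        (hit,) = report["sweep_hits"]
        assert not hit["detected"] and not hit["false_positive"]

    def test_fst_ordering_reported(self):
        report = evaluate_recovery(
            self._truth(), fst={"a_b": 0.5, "a_wild": 0.2}
        )
        assert report["fst_between_lineages_highest"]

    def test_truth_json_roundtrip(self, tmp_path):
        truth = self._truth()
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SimTruth(**json.loads(path.read_text()))
        assert back.sweeps == truth.sweeps


def _all_wild(cfg):
    from mtpopgen.simulate import _sample_names
    from mtpopgen.core import SampleTable

    names, labels = _sample_names(cfg)
    return SampleTable.from_records(zip(names, labels))
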