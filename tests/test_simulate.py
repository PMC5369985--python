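"""Simulator: the generative BAF model, determinism, scenario structure."""

import numpy as np
import pandas as pd
import pytest

from clonedeconv import simulate as sim
from clonedeconv.clonal import expected_baf
from clonedeconv.io import counts_to_frame


class TestTrueBaf:
    def test_heterozygous_diploid_pure_tumor(self):
        assert sim.true_baf_mixture(1.0, 1.0, [], []) == pytest.approx(0.5)

    def test_loh_pure_tumor_is_one(self):
        assert sim.true_baf_mixture(1.0, 1.0, [(1.0, 1, 1)], [(1.0, 1)]) == pytest.approx(1.0)

    def test_half_purity_clonal_ab(self):
        # rho*f*m / (rho*2 + 2(1-rho)) = 0.5/2
        assert sim.true_baf_mixture(0.5, 1.0, [], []) == pytest.approx(0.25)

    def test_matches_single_state_model(self):
        for state, (m, n) in {"B": (1, 1), "BB": (2, 2), "ABB": (2, 3)}.items():
            for rho in (0.3, 0.8):
                for f in (0.4, 1.0):
                    mixed = sim.true_baf_mixture(rho, f, [(f, m, n)], [(f, n)])
                    assert mixed == pytest.approx(expected_baf(state, rho, f))

    def test_aberrant_fraction_cannot_exceed_carriers(self):
        with pytest.raises(ValueError):
            sim.true_baf_mixture(1.0, 0.3, [(0.5, 1, 1)], [(0.5, 1)])


class TestScenarioValidation:
    def test_child_above_parent_rejected(self):
        scen = sim.scenario_like_patient1()
        scen.phi.loc["c3a", "center"] = 0.9  # above its parent c2b (0.65)
        with pytest.raises(ValueError, match="exceeds its parent"):
            scen.validate()

    def test_sibling_sum_above_parent_rejected(self):
        scen = sim.scenario_like_patient1()
        scen.phi.loc["c2a", "center"] = 0.6  # c2a + c2b = 1.25 > phi(c1a)
        with pytest.raises(ValueError, match="pigeonhole"):
            scen.validate()

    def test_root_must_be_fully_clonal(self):
        scen = sim.scenario_like_patient1()
        scen.phi.loc["c1a", "front"] = 0.8
        with pytest.raises(ValueError, match="root"):
            scen.validate()


class TestPatient1Scenario:
    def test_seven_clones_four_biopsies(self):
        scen = sim.scenario_like_patient1()
        assert len(scen.parent) == 7
        assert len(scen.biopsies) == 4
        assert 27 <= sum(scen.mutations_per_clone.values()) <= 156

    def test_second_generation_clone_has_three_daughters(self):
        scen = sim.scenario_like_patient1()
        assert sorted(c for c, p in scen.parent.items() if p == "c2b") == [
            "c3a", "c3b", "c3c",
        ]

    def test_node_private_clones_absent_from_primaries(self):
        scen = sim.scenario_like_patient1()
        primaries = ["front", "center", "back"]
        for clone in ("c3b", "c4a"):
            assert (scen.phi.loc[clone, primaries] == 0).all()
            assert scen.phi.loc[clone, "node"] > 0

    def test_independent_loh_in_two_sibling_lineages(self):
        scen = sim.scenario_like_patient1()
        loh_clones = {e.clone for e in scen.copy_events if e.chrom == "chr10"}
        assert loh_clones == {"c3b", "c3c"}  # disjoint daughters of c2b


class TestSimulateCohort:
    def test_fixed_seed_reproduces_identical_output(self, tmp_path):
        from clonedeconv.pipeline import run_simulation

        scen = sim.scenario_like_patient1(seed=3)
        run_simulation(scen, tmp_path / "a", seed=3)
        run_simulation(scen, tmp_path / "b", seed=3)
        for rel in ("counts_deep.tsv", "counts_wes.tsv", "truth/phi.tsv",
                    "windows/front.windows.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_empirical_baf_converges_to_truth_at_extreme_depth(self):
        """Law of large numbers: alt fraction within 3 binomial SDs of the
        generative BAF at depth 1e5."""
        scen = sim.scenario_like_patient1(seed=5)
        scen.depth_deep = 100_000
        cohort = sim.simulate_cohort(scen)
        df = counts_to_frame(cohort.counts_deep)
        truth = cohort.truth
        merged = df[df["sample"].isin(scen.biopsy_ids)].merge(
            truth.mutations.reset_index()[["mut_id", "chrom", "pos"]],
            on=["chrom", "pos"],
        )
        zs = []
        for r in merged.itertuples():
            p = truth.true_baf.loc[r.mut_id, r.sample]
            depth = r.ref_reads + r.alt_reads
            sd = np.sqrt(max(p * (1 - p), 1e-9) / depth)
            zs.append(abs(r.alt_reads / depth - p) / (sd + 1e-9))
        zs = np.array(zs)
        # per-site tolerance is 3 SDs; over ~600 draws allow the expected
        # handful of 3-sigma exceedances but no gross outlier
        assert (zs <= 3).mean() >= 0.99
        assert zs.max() <= 5.0

    def test_ground_truth_satisfies_pigeonhole_everywhere(self):
        for seed in range(5):
            scen = sim.random_scenario(n_clones=5, seed=seed)
            for p in scen.parent:
                kids = [c for c, q in scen.parent.items() if q == p]
                if kids:
                    assert (
                        scen.phi.loc[kids].sum(axis=0) <= scen.phi.loc[p] + 1e-9
                    ).all()

    def test_mutation_count_in_study_range(self):
        scen = sim.scenario_like_patient1(seed=1)
        cohort = sim.simulate_cohort(scen)
        assert 27 <= len(cohort.truth.mutations) <= 158


class TestRandomScenario:
    def test_requested_clone_count_and_valid_tree(self):
        for k in (3, 5, 7):
            scen = sim.random_scenario(n_clones=k, seed=11)
            assert len(scen.parent) == k
            scen.validate()

    def test_purity_within_study_range(self):
        scen = sim.random_scenario(n_clones=4, seed=2)
        assert all(0.2 <= r <= 0.8 for r in scen.purity.values())

    def test_every_clone_detectable_somewhere(self):
        scen = sim.random_scenario(n_clones=6, seed=3)
        assert (scen.phi.max(axis=1) > 0.15).all()
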