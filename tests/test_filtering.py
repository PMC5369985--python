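"""Somatic filter rules: boundary cases, monotonicity, germline removal."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonedeconv import filtering as flt
from clonedeconv.io import counts_to_frame

from .oracles import literal_discovery, literal_validation


class TestComputeBaf:
    @pytest.mark.parametrize(
        "alt,ref,expected",
        [(3, 57, 0.05), (0, 100, 0.0), (10, 0, 1.0), (1, 3, 0.25)],
    )
    def test_values(self, alt, ref, expected):
        assert flt.compute_baf(alt, ref) == pytest.approx(expected)

    def test_zero_depth_is_undefined_not_zero(self):
        assert math.isnan(flt.compute_baf(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            flt.compute_baf(-1, 10)


class TestDiscovery:
    def test_exact_boundary_called(self):
        # BAF exactly 5% with exactly 3 alt reads, blood clean at 50x
        res = flt.call_discovery({"b1": (3, 60)}, (0, 50))
        assert res.called and res.qualifying == {"b1"}

    def test_high_baf_but_too_few_alt_reads(self):
        assert not flt.call_discovery({"b1": (2, 10)}, (0, 50)).called

    def test_any_blood_alt_read_vetoes(self):
        assert not flt.call_discovery({"b1": (30, 100)}, (1, 200)).called

    def test_shallow_blood_vetoes(self):
        assert not flt.call_discovery({"b1": (30, 100)}, (0, 9)).called

    def test_missing_blood_is_an_error(self):
        with pytest.raises(flt.MissingBloodError):
            flt.call_discovery({"b1": (30, 100)}, None)

    def test_zero_depth_biopsy_is_no_evidence(self):
        res = flt.call_discovery({"b1": (0, 0), "b2": (5, 50)}, (0, 50))
        assert res.called and res.qualifying == {"b2"}


class TestValidation:
    def test_boundary_just_above_three_percent(self):
        assert flt.call_validation({"b1": (10, 333)}, (0, 100)).called  # 10/333 >= 3%

    def test_below_three_percent_not_called(self):
        assert not flt.call_validation({"b1": (10, 400)}, (0, 100)).called  # 2.5%

    def test_blood_baf_cap_is_inclusive(self):
        assert flt.call_validation({"b1": (50, 500)}, (1, 100)).called  # blood exactly 1%
        assert not flt.call_validation({"b1": (50, 500)}, (2, 100)).called

    def test_rescue_grants_presence_below_baf_threshold(self):
        # second biopsy at BAF 0.5% but 5 alt reads: present once called elsewhere
        res = flt.call_validation({"b1": (50, 500), "b2": (5, 1000)}, (0, 100))
        assert res.called
        assert res.qualifying == {"b1"}
        assert res.present_in == {"b1", "b2"}

    def test_rescue_needs_enough_alt_reads(self):
        res = flt.call_validation({"b1": (50, 500), "b2": (4, 1000)}, (0, 100))
        assert res.present_in == {"b1"}


class TestMonotonicity:
    """Adding tumor evidence never un-calls; adding blood evidence never calls."""

    @given(
        alt=st.integers(0, 30),
        depth=st.integers(0, 200),
        blood_alt=st.integers(0, 5),
        blood_depth=st.integers(0, 200),
        extra=st.integers(1, 20),
    )
    def test_more_biopsy_alt_reads_never_uncalls(self, alt, depth, blood_alt, blood_depth, extra):
        alt = min(alt, depth)
        blood_alt = min(blood_alt, blood_depth)
        before = flt.call_discovery({"b": (alt, depth)}, (blood_alt, blood_depth)).called
        after = flt.call_discovery(
            {"b": (alt + extra, depth + extra)}, (blood_alt, blood_depth)
        ).called
        assert after >= before

    @given(
        alt=st.integers(0, 30),
        depth=st.integers(0, 200),
        blood_alt=st.integers(0, 5),
        blood_depth=st.integers(0, 200),
        extra=st.integers(1, 20),
    )
    def test_more_blood_alt_reads_never_calls(self, alt, depth, blood_alt, blood_depth, extra):
        alt = min(alt, depth)
        blood_alt = min(blood_alt, blood_depth)
        before = flt.call_validation({"b": (alt, depth)}, (blood_alt, blood_depth)).called
        after = flt.call_validation(
            {"b": (alt, depth)}, (blood_alt + extra, blood_depth + extra)
        ).called
        assert after <= before


class TestOracleAgreement:
    """Spot agreement with the literal rule transcription (the exhaustive
    sweep lives in the acceptance suite)."""

    @given(
        a1=st.integers(0, 20), d1=st.integers(0, 60),
        a2=st.integers(0, 20), d2=st.integers(0, 60),
        ba=st.integers(0, 10), bd=st.integers(0, 80),
    )
    def test_discovery_matches_literal_rules(self, a1, d1, a2, d2, ba, bd):
        a1, a2, ba = min(a1, d1), min(a2, d2), min(ba, bd)
        biopsies = {"b1": (a1, d1), "b2": (a2, d2)}
        if bd == 0:
            return
        assert flt.call_discovery(biopsies, (ba, bd)).called == literal_discovery(
            biopsies, (ba, bd)
        )

    @given(
        a1=st.integers(0, 20), d1=st.integers(0, 60),
        ba=st.integers(0, 10), bd=st.integers(0, 80),
    )
    def test_validation_matches_literal_rules(self, a1, d1, ba, bd):
        a1, ba = min(a1, d1), min(ba, bd)
        if bd == 0:
            return
        biopsies = {"b1": (a1, d1)}
        assert flt.call_validation(biopsies, (ba, bd)).called == literal_validation(
            biopsies, (ba, bd)
        )


class TestConfirmationRate:
    def test_ratio(self):
        disc = [("chr1", i, "A", "T") for i in range(10)]
        assert flt.confirmation_rate(disc, disc[:8]) == pytest.approx(0.8)

    def test_none_confirmed(self):
        disc = [("chr1", i, "A", "T") for i in range(5)]
        assert flt.confirmation_rate(disc, []) == 0.0

    def test_identical_sets(self):
        disc = [("chr1", 1, "A", "T")]
        assert flt.confirmation_rate(disc, disc) == 1.0

    def test_empty_discovery_undefined(self):
        assert math.isnan(flt.confirmation_rate([], []))

    def test_validated_outside_discovery_rejected(self):
        with pytest.raises(ValueError):
            flt.confirmation_rate([("chr1", 1, "A", "T")], [("chr1", 2, "A", "T")])


class TestOnSimulatedCohort:
    def test_germline_hets_removed_and_clonal_mutations_recovered(self, patient1_cohort):
        """Blood-based exclusion removes >= 99% of germline heterozygous
        sites; every truncal mutation (deep BAF far above threshold) is
        recovered by the validation stage."""
        scenario, sim = patient1_cohort
        cohort = scenario.cohort_table()
        df = counts_to_frame(sim.counts_deep)
        variants = flt.call_sites(df, cohort, "validation")
        called = {(v.chrom, v.pos) for v in variants}
        germline = set(
            zip(sim.truth.mutations.chrom, sim.truth.mutations.pos)
        )  # somatic keys
        g_sites = {
            (c.chrom, c.pos)
            for c in sim.counts_deep
            if (c.chrom, c.pos) not in germline
        }
        leaked = len(g_sites & called)
        assert leaked <= max(1, 0.01 * len(g_sites))
        truncal = sim.truth.mutations.index[sim.truth.mutations.clone == "c1a"]
        truncal_keys = {
            (r.chrom, r.pos) for r in sim.truth.mutations.loc[truncal].itertuples()
        }
        assert truncal_keys <= called

    def test_vectorized_matches_scalar_on_cohort(self, patient1_cohort):
        scenario, sim = patient1_cohort
        cohort = scenario.cohort_table()
        df = counts_to_frame(sim.counts_deep)
        wide_alt, wide_depth, blood = [], [], []
        for _, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
            obs = {
                r.sample: (int(r.alt_reads), int(r.ref_reads + r.alt_reads))
                for r in grp.itertuples()
            }
            wide_alt.append([obs[b][0] for b in cohort.biopsy_ids])
            wide_depth.append([obs[b][1] for b in cohort.biopsy_ids])
            blood.append(obs[cohort.normal_sample])
        blood = np.array(blood)
        vec = flt.call_sites_vectorized(
            np.array(wide_alt), np.array(wide_depth), blood[:, 0], blood[:, 1], "validation"
        )
        scal = [
            flt.call_validation(
                dict(zip(cohort.biopsy_ids, zip(a, d))), tuple(b)
            ).called
            for a, d, b in zip(wide_alt, wide_depth, blood)
        ]
        assert vec.tolist() == scal
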