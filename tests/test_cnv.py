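"""Windowed copy-number: window construction, LogR, variant lookup."""

import math

import numpy as np
import pandas as pd
import pytest

from clonedeconv import cnv


class TestMakeWindows:
    def test_windows_of_fixed_read_count(self):
        pos = {"chr1": list(range(1, 25_001))}
        ws = cnv.make_windows(pos, window_size=10_000)
        assert [w.normal_reads for w in ws] == [10_000, 10_000, 5_000]
        assert ws[0].start == 1 and ws[0].end == 10_000
        assert ws[2].start == 20_001 and ws[2].end == 25_000

    def test_window_size_one_is_one_window_per_read(self):
        ws = cnv.make_windows({"chr1": [5, 9, 12]}, window_size=1)
        assert [(w.start, w.end) for w in ws] == [(5, 5), (9, 9), (12, 12)]

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="not sorted"):
            cnv.make_windows({"chr1": [10, 5, 20]}, window_size=2)

    def test_empty_chromosome_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning, match="no normal reads"):
            assert cnv.make_windows({"chrX": []}) == []

    def test_read_conservation(self):
        rng = np.random.default_rng(0)
        pos = {
            f"chr{i}": np.sort(rng.integers(1, 10**6, size=rng.integers(1, 5000)))
            for i in range(1, 5)
        }
        ws = cnv.make_windows(pos, window_size=700)
        assert sum(w.normal_reads for w in ws) == sum(len(p) for p in pos.values())

    def test_tumor_reads_conserved_when_counted(self):
        rng = np.random.default_rng(1)
        npos = {"chr1": np.sort(rng.integers(1, 10**6, size=20_000))}
        ws = cnv.make_windows(npos, window_size=5_000)
        tpos = {"chr1": rng.integers(1, 10**6, size=30_000)}
        cnv.count_tumor_reads(ws, tpos)
        assert sum(w.tumor_reads for w in ws) == 30_000


class TestComputeLogr:
    def _w(self, chrom, start, end, n, t):
        return cnv.CopyWindow(chrom, start, end, n, t)

    def test_equal_reads_give_zero(self):
        ws = [self._w("chr1", 1, 100, 1000, 1000)]
        logr = cnv.compute_logr(ws, library_size_factor=1.0, center="none")
        assert logr[0] == pytest.approx(0.0)

    def test_doubled_tumor_gives_one(self):
        ws = [self._w("chr1", 1, 100, 1000, 2000)]
        assert cnv.compute_logr(ws, 1.0, center="none")[0] == pytest.approx(1.0)

    def test_clonal_one_copy_loss_gives_minus_one(self):
        ws = [self._w("chr1", 1, 100, 1000, 500)]
        assert cnv.compute_logr(ws, 1.0, center="none")[0] == pytest.approx(-1.0)

    def test_default_library_factor_and_median_centering(self):
        # 3 diploid windows + 1 half-depth window: diploid mode must sit at 0
        ws = [self._w("chr1", 1 + i * 10, 10 + i * 10, 100, t) for i, t in
              enumerate([400, 400, 400, 200])]
        logr = cnv.compute_logr(ws)
        assert logr[:3] == pytest.approx([0.0, 0.0, 0.0])
        assert logr[3] == pytest.approx(-1.0)

    def test_zero_tumor_window_floored_and_flagged(self):
        ws = [self._w("chr1", 1, 10, 100, 0), self._w("chr1", 11, 20, 100, 100)]
        logr = cnv.compute_logr(ws, 1.0, center="none")
        assert math.isfinite(logr[0]) and "zero_tumor_floored" in ws[0].flags


class TestAssignLogr:
    def _windows(self):
        ws = [
            cnv.CopyWindow("chr1", 100, 5000, 10, 10, logr=-0.4),
            cnv.CopyWindow("chr1", 6000, 9000, 10, 10, logr=0.2),
        ]
        return ws

    def test_containment(self):
        out = cnv.assign_logr(pd.DataFrame({"chrom": ["chr1"], "pos": [300]}), self._windows())
        assert out.logr.iloc[0] == pytest.approx(-0.4)
        assert out.logr_flag.iloc[0] == ""

    def test_gap_uses_nearest_window(self):
        out = cnv.assign_logr(
            pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [5100, 5950]}), self._windows()
        )
        assert out.logr.tolist() == pytest.approx([-0.4, 0.2])
        assert set(out.logr_flag) == {"nearest"}

    def test_past_last_window_flagged_nearest(self):
        out = cnv.assign_logr(pd.DataFrame({"chrom": ["chr1"], "pos": [20_000]}), self._windows())
        assert out.logr.iloc[0] == pytest.approx(0.2)
        assert out.logr_flag.iloc[0] == "nearest"

    def test_chromosome_without_windows_is_undefined(self):
        out = cnv.assign_logr(pd.DataFrame({"chrom": ["chr9"], "pos": [5]}), self._windows())
        assert math.isnan(out.logr.iloc[0])
        assert out.logr_flag.iloc[0] == "no_windows"


class TestSubclonalLossLimit:
    def test_segment_logr_matches_closed_form(self):
        """A clone-private one-copy loss at purity rho and clone fraction f
        shifts the segment LogR to log2(1 - rho*f/2) in expectation."""
        from clonedeconv.simulate import CopyEvent, scenario_like_patient1, simulate_cohort

        scen = scenario_like_patient1(seed=7)
        scen.copy_events = [CopyEvent("c2b", "chr5", "loss")]
        scen.tagged_mutations = []
        sim = simulate_cohort(scen)
        b = "center"  # rho=0.6, phi(c2b)=0.65
        rho, f = scen.purity[b], float(scen.phi.loc["c2b", b])
        ws = cnv.windows_from_table(sim.windows[b])
        cnv.compute_logr(ws)
        seg = [w.logr for w in ws if w.chrom == "chr5"]
        expected = math.log2(1 - rho * f / 2)
        sd = (1 / math.log(2)) / math.sqrt(scen.window_size * (1 - rho * f / 2))
        assert np.mean(seg) == pytest.approx(expected, abs=3 * sd / math.sqrt(len(seg)) + 0.01)
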