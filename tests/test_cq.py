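"""CQ semantics, window tagging, scaffold calls and gene assignment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sexscan as sx
from sexscan import cq as cqm
from sexscan.coverage import CoverageTrack


def _track(rpkms, sex, length=10_000):
    n = len(rpkms)
    win = pd.DataFrame({
        "scaffold": "s", "start": np.arange(n) * length,
        "end": (np.arange(n) + 1) * length, "index": np.arange(n),
        "length": length, "partial": False, "count": 0,
        "rpkm": np.asarray(rpkms, float)})
    return CoverageTrack(sex=sex, library_size=1_000_000, windows=win)


def _tagged(cqs, length=10_000, scaffold="s"):
    n = len(cqs)
    df = pd.DataFrame({
        "scaffold": scaffold, "start": np.arange(n) * length,
        "end": (np.arange(n) + 1) * length, "index": np.arange(n),
        "length": length, "partial": False,
        "f_rpkm": 1.0, "m_rpkm": 1.0, "cq": np.asarray(cqs, float)})
    return cqm.tag_regions(df, cqm.Thresholds(), length)


class TestRegionCq:
    def test_zero_denominator_semantics(self):
        f = _track([4.0, 0.0, 1.0], "female")
        m = _track([2.0, 0.0, 0.0], "male")
        cq = cqm.region_cq(f, m)["cq"]
        assert cq.iloc[0] == pytest.approx(2.0)
        assert np.isnan(cq.iloc[1])
        assert np.isposinf(cq.iloc[2])

    def test_mismatched_tilings_raise(self):
        with pytest.raises(ValueError, match="tiling"):
            cqm.region_cq(_track([1.0], "female"), _track([1.0, 1.0], "male"))

    def test_epsilon_mode_keeps_ratio_finite(self):
        f = _track([1.0, 0.0], "female")
        m = _track([0.0, 0.0], "male")
        cq = cqm.region_cq(f, m, epsilon=0.1)["cq"]
        assert np.isfinite(cq).all()
        assert cq.iloc[0] == pytest.approx(1.1 / 0.1)


class TestTagging:
    @pytest.mark.parametrize("cq,tag", [
        (0.03, "Y"),           # Table-3-scale Y window
        (0.2, "neutral"),      # boundary is exclusive
        (2.0, "neutral"),      # "above 2" is strict
        (2.01, "X"),
        (np.inf, "X"),
        (np.nan, "undefined"),
    ])
    def test_threshold_semantics(self, cq, tag):
        assert _tagged([cq])["tag"].iloc[0] == tag

    def test_short_window_left_undefined(self):
        df = pd.DataFrame({
            "scaffold": "s", "start": [0, 10_000], "end": [10_000, 14_000],
            "index": [0, 1], "length": [10_000, 4_000],
            "partial": [False, True], "f_rpkm": 1.0, "m_rpkm": 1.0,
            "cq": [5.0, 5.0]})
        tagged = cqm.tag_regions(df, cqm.Thresholds(), 10_000)
        assert list(tagged["tag"]) == ["X", "undefined"]

    def test_rederiving_tags_is_idempotent(self):
        rng = np.random.default_rng(0)
        cqs = np.concatenate([rng.uniform(0, 3, 50), [np.inf, np.nan]])
        t1 = _tagged(cqs)
        t2 = cqm.tag_regions(t1, cqm.Thresholds(), 10_000)
        assert list(t1["tag"]) == list(t2["tag"])

    @given(y1=st.floats(0.01, 1.9), y2=st.floats(0.01, 1.9))
    @settings(max_examples=30, deadline=None)
    def test_raising_y_max_never_loses_y_windows(self, y1, y2):
        lo, hi = sorted((y1, y2))
        rng = np.random.default_rng(1)
        df = _tagged(rng.uniform(0, 3, 40))
        th_lo = cqm.Thresholds(y_max=lo)
        th_hi = cqm.Thresholds(y_max=hi)
        tags_lo = cqm.tag_regions(df, th_lo, 10_000)["tag"]
        tags_hi = cqm.tag_regions(df, th_hi, 10_000)["tag"]
        assert set(np.nonzero((tags_lo == "Y").to_numpy())[0]) <= \
            set(np.nonzero((tags_hi == "Y").to_numpy())[0])


class TestScaffoldCalls:
    def test_x_scaffold_at_paper_scale(self):
        """A 455-window scaffold with 346 X-tagged windows (76%) is an
        X-candidate under the 40%-of-length rule."""
        cqs = np.full(455, 1.0)
        cqs[:346] = 2.5
        tagged = _tagged(cqs)
        asm = sx.Assembly({"s": "A" * 4_550_000})
        calls = cqm.call_scaffolds(tagged, asm)
        assert calls["call"].iloc[0] == cqm.CALL_X
        assert calls["fraction_x"].iloc[0] == pytest.approx(346 / 455)

    def test_all_neutral_unassigned(self):
        tagged = _tagged(np.full(10, 1.0))
        asm = sx.Assembly({"s": "A" * 100_000})
        calls = cqm.call_scaffolds(tagged, asm)
        assert calls["call"].iloc[0] == cqm.CALL_NONE
        assert calls["fraction_x"].iloc[0] == 0.0
        assert calls["fraction_y"].iloc[0] == 0.0

    def test_exact_tie_warns_unassigned(self):
        tagged = _tagged([3.0, 3.0, 3.0, 3.0, 0.1, 0.1, 0.1, 0.1, 1.0, 1.0])
        asm = sx.Assembly({"s": "A" * 100_000})
        with pytest.warns(UserWarning, match="tie"):
            calls = cqm.call_scaffolds(tagged, asm)
        assert calls["call"].iloc[0] == cqm.CALL_NONE

    def test_average_cq_excludes_nonfinite_and_reports(self):
        tagged = _tagged([1.0, 2.0, np.inf, np.nan])
        asm = sx.Assembly({"s": "A" * 40_000})
        calls = cqm.call_scaffolds(tagged, asm)
        assert calls["average_cq"].iloc[0] == pytest.approx(1.5)
        assert calls["n_windows_excluded"].iloc[0] == 2

    def test_forty_percent_is_inclusive(self):
        tagged = _tagged([0.1, 0.1, 0.1, 0.1, 1, 1, 1, 1, 1, 1])
        asm = sx.Assembly({"s": "A" * 100_000})
        assert cqm.call_scaffolds(tagged, asm)["call"].iloc[0] == cqm.CALL_Y


def _counts(vals):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(vals))],
                         "scaffold": "s", "start": 0, "end": 100,
                         "count": vals})


class TestGeneCq:
    def test_equal_counts_equal_libraries(self):
        out = cqm.gene_cq(_counts([10]), _counts([10]), 10**6, 10**6)
        assert out["gene_cq"].iloc[0] == pytest.approx(1.0)

    def test_y_like_gene(self):
        out = cqm.gene_cq(_counts([5]), _counts([100]), 10**6, 10**6)
        assert out["gene_cq"].iloc[0] == pytest.approx(0.05)
        assert out["gene_cq"].iloc[0] < 0.2

    def test_library_normalization(self):
        out = cqm.gene_cq(_counts([10]), _counts([10]), 2 * 10**6, 10**6)
        assert out["gene_cq"].iloc[0] == pytest.approx(0.5)

    def test_scale_invariance(self):
        a = cqm.gene_cq(_counts([7]), _counts([13]), 10**6, 10**6)
        b = cqm.gene_cq(_counts([21]), _counts([39]), 3 * 10**6, 3 * 10**6)
        assert a["gene_cq"].iloc[0] == pytest.approx(b["gene_cq"].iloc[0])

    def test_zero_library_raises(self):
        with pytest.raises(ValueError):
            cqm.gene_cq(_counts([1]), _counts([1]), 0, 10**6)


class TestContextCq:
    def test_gene_inside_one_window(self):
        tagged = _tagged([0.1, 0.3])
        genes = pd.DataFrame({"gene_id": ["g"], "scaffold": "s",
                              "start": [2_000], "end": [3_000]})
        out = cqm.context_cq(genes, tagged)
        assert out["context_cq"].iloc[0] == pytest.approx(0.1)

    def test_midpoint_on_boundary_goes_right(self):
        tagged = _tagged([0.1, 0.3])
        genes = pd.DataFrame({"gene_id": ["g"], "scaffold": "s",
                              "start": [9_000], "end": [11_000]})
        out = cqm.context_cq(genes, tagged)
        assert out["context_cq"].iloc[0] == pytest.approx(0.3)

    def test_spanning_gene_reports_weighted_mean(self):
        tagged = _tagged([0.1, 0.3])
        genes = pd.DataFrame({"gene_id": ["g"], "scaffold": "s",
                              "start": [6_000], "end": [12_000]})
        out = cqm.context_cq(genes, tagged)
        assert out["context_cq"].iloc[0] == pytest.approx(0.1)  # midpoint 9000
        expected = (0.1 * 4_000 + 0.3 * 2_000) / 6_000
        assert out["context_cq_weighted"].iloc[0] == pytest.approx(expected)


class TestAssignment:
    def _assign(self, gene_cq_value, context_cq_value):
        gcq = _counts([1]).assign(gene_cq=gene_cq_value)
        ctx = pd.DataFrame({"gene_id": ["g0"], "context_cq": [context_cq_value],
                            "context_cq_weighted": [context_cq_value]})
        return cqm.assign_genes(gcq, ctx)["assignment"].iloc[0]

    @pytest.mark.parametrize("g,c,expected", [
        (0.1, 0.05, "Y"),     # Table-3-like g17083
        (0.0, 0.1, "Y"),      # Table-3-like g10424
        (3.0, 1.0, "none"),   # joint criterion: context fails
        (1.0, 0.1, "none"),   # gene CQ fails
        (2.5, np.inf, "X"),
        (np.nan, 0.0, "none"),
    ])
    def test_joint_rule(self, g, c, expected):
        assert self._assign(g, c) == expected


class TestRecoveryOnTinyStudy:
    """Copy-number recovery on the small simulated study (Y and autosomes;
    X calls sit on the strict CQ > 2 boundary and are exercised at scale in
    the acceptance suite)."""

    def test_y_called_autosomes_clean(self, tiny_sim, tiny_tracks):
        rec = cqm.region_cq(tiny_tracks["female"]["track"],
                            tiny_tracks["male"]["track"])
        tagged = cqm.tag_regions(rec, cqm.Thresholds(), 10_000)
        calls = cqm.call_scaffolds(tagged, tiny_sim["assembly"])
        comp = tiny_sim["truth"].scaffold_compartment
        for _, row in calls.iterrows():
            if comp[row["scaffold"]] == "Y":
                assert row["call"] == cqm.CALL_Y
            elif comp[row["scaffold"]] == "autosome":
                assert row["call"] == cqm.CALL_NONE

    def test_compartment_cq_means(self, tiny_sim, tiny_tracks):
        rec = cqm.region_cq(tiny_tracks["female"]["track"],
                            tiny_tracks["male"]["track"])
        comp = rec["scaffold"].map(tiny_sim["truth"].scaffold_compartment)
        cq = rec["cq"].to_numpy()
        fin = np.isfinite(cq)
        auto = cq[fin & (comp == "autosome").to_numpy()]
        x = cq[fin & (comp == "X").to_numpy()]
        y = cq[fin & (comp == "Y").to_numpy()]
        assert 0.85 < auto.mean() < 1.15
        assert 1.7 < x.mean() < 2.3
        assert y.mean() <= 0.1
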