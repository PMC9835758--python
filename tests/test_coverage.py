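"""Window tiling, read placement, RPKM normalization and gene counting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sexscan as sx
from sexscan import _seq
from sexscan import coverage as cov
from tests.conftest import make_readset


class TestTiling:
    @pytest.mark.parametrize("length,expected", [
        (25_000, [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]),
        (10_000, [(0, 10_000)]),
        (9_999, [(0, 9_999)]),
    ])
    def test_examples(self, length, expected):
        asm = sx.Assembly({"s": "A" * length})
        win = cov.tile_windows(asm)
        assert list(zip(win["start"], win["end"])) == expected
        assert win["partial"].iloc[-1] == (length % 10_000 != 0)

    @given(length=st.integers(1, 100_000), w=st.integers(1, 20_000))
    @settings(max_examples=50, deadline=None)
    def test_tiling_partitions_scaffold(self, length, w):
        asm = sx.Assembly({"s": "A" * length})
        win = cov.tile_windows(asm, w)
        assert win["start"].iloc[0] == 0
        assert win["end"].iloc[-1] == length
        assert (win["start"].to_numpy()[1:] == win["end"].to_numpy()[:-1]).all()
        assert int(win["length"].sum()) == length


def _placements(rows):
    return pd.DataFrame(rows, columns=["read_index", "scaffold", "start",
                                       "strand", "status", "length"])


class TestRpkm:
    def test_worked_example(self):
        asm = sx.Assembly({"s": "A" * 10_000})
        win = cov.tile_windows(asm)
        pl = _placements([(i, "s", i, "+", "unique", 100) for i in range(100)])
        track = cov.window_rpkm(pl, win, library_size=1_000_000)
        assert track.windows["rpkm"].iloc[0] == pytest.approx(10.0)

    def test_partial_window_length_normalized(self):
        asm = sx.Assembly({"s": "A" * 5_000})
        win = cov.tile_windows(asm)
        pl = _placements([(i, "s", i, "+", "unique", 100) for i in range(100)])
        track = cov.window_rpkm(pl, win, library_size=1_000_000)
        assert track.windows["rpkm"].iloc[0] == pytest.approx(20.0)

    def test_empty_window_zero(self):
        asm = sx.Assembly({"s": "A" * 20_000})
        win = cov.tile_windows(asm)
        pl = _placements([(0, "s", 1, "+", "unique", 100)])
        track = cov.window_rpkm(pl, win, library_size=10)
        assert track.windows["rpkm"].iloc[1] == 0.0

    def test_scale_invariance(self):
        asm = sx.Assembly({"s": "A" * 10_000})
        win = cov.tile_windows(asm)
        pl = _placements([(i, "s", 50 * i, "+", "unique", 100)
                          for i in range(50)])
        single = cov.window_rpkm(pl, win, library_size=1_000)
        doubled = cov.window_rpkm(pd.concat([pl, pl]), win, library_size=2_000)
        assert np.allclose(single.windows["rpkm"], doubled.windows["rpkm"])

    def test_zero_library_raises(self):
        asm = sx.Assembly({"s": "A" * 10_000})
        with pytest.raises(ValueError):
            cov.window_rpkm(_placements([]), cov.tile_windows(asm), 0)

    def test_count_conservation(self, tiny_tracks):
        for sex in ("female", "male"):
            data = tiny_tracks[sex]
            assert int(data["track"].windows["count"].sum()) == \
                data["library_size"]


class TestPlacement:
    def test_error_free_reads_recover_origin(self, tiny_sim):
        """Truth-id oracle: every unique placement equals the encoded origin."""
        assembly, reads = tiny_sim["assembly"], tiny_sim["male"]
        pl = cov.place_reads(reads, assembly)
        uq = pl[pl["status"] == cov.UNIQUE]
        idx = uq["read_index"].to_numpy()
        assert len(uq) / len(pl) > 0.9
        has_origin = reads.origin_start[idx] >= 0
        uq, idx = uq[has_origin], idx[has_origin]
        assert (uq["scaffold"].to_numpy() == reads.origin_scaffold[idx]).all()
        assert (uq["start"].to_numpy() == reads.origin_start[idx]).all()
        assert (uq["strand"].to_numpy() == reads.origin_strand[idx]).all()

    def test_unique_ambiguous_unmapped(self):
        rng = np.random.default_rng(5)
        block = _seq.decode(rng.integers(0, 4, 300).astype(np.uint8))
        uniq = _seq.decode(rng.integers(0, 4, 400).astype(np.uint8))
        asm = sx.Assembly({"s1": block + uniq + block, "s2": uniq[::-1]})
        reads = make_readset([
            uniq[100:200],                      # single exact locus -> unique
            block[50:150],                      # two identical loci -> ambiguous
            _seq.decode(rng.integers(0, 4, 100).astype(np.uint8)),  # unmapped
        ])
        pl = cov.place_reads(reads, asm)
        assert list(pl["status"]) == [cov.UNIQUE, cov.AMBIGUOUS, cov.UNMAPPED]
        assert pl["start"].iloc[0] == 400

    def test_reverse_complement_read_placed(self):
        rng = np.random.default_rng(6)
        seq = _seq.decode(rng.integers(0, 4, 500).astype(np.uint8))
        asm = sx.Assembly({"s": seq})
        pl = cov.place_reads(make_readset([_seq.revcomp(seq[120:220])]), asm)
        assert pl["status"].iloc[0] == cov.UNIQUE
        assert pl["start"].iloc[0] == 120
        assert pl["strand"].iloc[0] == "-"

    def test_seed_anchored_fallback_on_errors(self):
        rng = np.random.default_rng(7)
        seq = _seq.decode(rng.integers(0, 4, 500).astype(np.uint8))
        asm = sx.Assembly({"s": seq})
        read = list(seq[200:300])
        read[60] = "ACGT"[("ACGT".index(read[60]) + 1) % 4]
        read[80] = "ACGT"[("ACGT".index(read[80]) + 2) % 4]
        pl = cov.place_reads(make_readset(["".join(read)]), asm)
        assert pl["status"].iloc[0] == cov.UNIQUE
        assert pl["start"].iloc[0] == 200

    def test_random_best_policy_resolves_ambiguous(self):
        rng = np.random.default_rng(8)
        block = _seq.decode(rng.integers(0, 4, 200).astype(np.uint8))
        pad = _seq.decode(rng.integers(0, 4, 150).astype(np.uint8))
        asm = sx.Assembly({"s": block + pad + block})
        reads = make_readset([block[10:110]])
        pl = cov.place_reads(reads, asm, policy="random-best",
                             rng=np.random.default_rng(0))
        assert pl["status"].iloc[0] == cov.UNIQUE
        assert int(pl["start"].iloc[0]) in (10, 360)

    def test_empty_assembly_raises(self):
        with pytest.raises(ValueError):
            cov.place_reads(make_readset(["ACGT" * 25]), sx.Assembly({}))


SAM_TEMPLATE = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:s\tLN:1000
r1\t0\ts\t11\t0\t50M\t*\t0\t0\t{seq}\t*
r2\t0\ts\t101\t30\t50M\t*\t0\t0\t{seq}\t*
r3\t16\ts\t201\t60\t50M\t*\t0\t0\t{seq}\t*
r4\t256\ts\t301\t60\t50M\t*\t0\t0\t*\t*
r5\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*
"""


class TestLoadAlignments:
    def test_mapq_filter_and_flags(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(SAM_TEMPLATE.format(seq="A" * 50))
        asm = sx.Assembly({"s": "A" * 1000})
        pl = cov.load_alignments(sam, asm, min_mapq=20)
        # secondary r4 dropped entirely; r1 ambiguous, r2/r3 unique, r5 unmapped
        assert len(pl) == 4
        assert list(pl["status"]) == [cov.AMBIGUOUS, cov.UNIQUE, cov.UNIQUE,
                                      cov.UNMAPPED]
        assert list(pl.loc[pl["status"] == cov.UNIQUE, "start"]) == [100, 200]
        assert pl["strand"].iloc[2] == "-"

    def test_empty_sam(self, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:s\tLN:100\n")
        assert len(cov.load_alignments(sam, sx.Assembly({"s": "A" * 100}))) == 0

    def test_reference_mismatch_raises(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:other\tLN:100\n")
        with pytest.raises(ValueError, match="not in assembly"):
            cov.load_alignments(sam, sx.Assembly({"s": "A" * 100}))


class TestGeneCounts:
    def test_boundary_read_counts_for_both_genes(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"], "scaffold": "s",
                              "start": [0, 500], "end": [500, 1000]})
        pl = _placements([(0, "s", 450, "+", "unique", 100)])
        counts = cov.count_gene_reads(pl, genes)
        assert list(counts["count"]) == [1, 1]

    def test_no_overlap_zero(self):
        genes = pd.DataFrame({"gene_id": ["a"], "scaffold": "s",
                              "start": [500], "end": [600]})
        pl = _placements([(0, "s", 399, "+", "unique", 100),
                          (1, "s", 600, "+", "unique", 100)])
        assert list(cov.count_gene_reads(pl, genes)["count"]) == [0]

    def test_quadratic_oracle(self):
        """Searchsorted counting equals brute-force all-pairs overlap."""
        rng = np.random.default_rng(12)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)], "scaffold": "s",
            "start": rng.integers(0, 9_000, 20)})
        genes["end"] = genes["start"] + rng.integers(200, 2_000, 20)
        pl = _placements([(i, "s", int(p), "+", "unique", 100)
                          for i, p in enumerate(rng.integers(0, 10_000, 300))])
        counts = cov.count_gene_reads(pl, genes)
        for _, g in counts.iterrows():
            brute = sum(1 for _, r in pl.iterrows()
                        if r["start"] < g["end"]
                        and r["start"] + r["length"] > g["start"])
            assert g["count"] == brute

    def test_missing_scaffold_warns_and_skips(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"],
                              "scaffold": ["s", "ghost"],
                              "start": [0, 0], "end": [100, 100]})
        asm = sx.Assembly({"s": "A" * 1000})
        with pytest.warns(UserWarning, match="absent"):
            counts = cov.count_gene_reads(_placements([]), genes, asm)
        assert list(counts["gene_id"]) == ["a"]
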