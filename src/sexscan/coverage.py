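"""Windowed RPKM coverage and per-gene read counts from sexed read sets.

The module turns reads (or externally produced alignments) into the two
inputs chromosome-quotient analysis needs: per-window normalized coverage
(RPKM in non-overlapping 10 kb windows) and raw read counts per gene.

Read placement on desk-scale synthetic data is done by an internal
exact-match placer (seed k-mer index plus full-length verification on both
strands); real alignments from bwa/Bowtie2 can be supplied as BAM/SAM
instead via :func:`load_alignments`. Multi-mapped (ambiguous) reads are
excluded from coverage by default, standing in for alignment against a
repeat-masked genome.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .assembly import Assembly
from .sim import ReadSet

UNIQUE, AMBIGUOUS, UNMAPPED = "unique", "ambiguous", "unmapped"


def tile_windows(assembly: Assembly, window_size: int = 10_000) -> pd.DataFrame:
    """Tile every scaffold with non-overlapping windows of ``window_size`` bp.

    The final window of a scaffold may be partial; it is retained and flagged.
    Returns a DataFrame with columns scaffold, start, end, index, length,
    partial (0-based half-open coordinates).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    rows = []
    for name in assembly.names:
        L = assembly.length(name)
        starts = np.arange(0, L, window_size)
        for i, s in enumerate(starts):
            e = min(int(s) + window_size, L)
            rows.append((name, int(s), e, i, e - int(s), e - int(s) < window_size))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "index",
                                       "length", "partial"])


def _expand_ranges(lo: np.ndarray, count: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten per-query index ranges [lo, lo+count) into (query_idx, flat_idx)."""
    total = int(count.sum())
    qidx = np.repeat(np.arange(len(count)), count)
    within = np.arange(total) - np.repeat(np.cumsum(count) - count, count)
    return qidx, lo[qidx] + within


def place_reads(readset: ReadSet, assembly: Assembly, policy: str = "unique",
                seed_length: int = 25, min_identity: float = 0.95,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place every read on the assembly by exact seed-and-verify matching.

    Each read is searched forward and reverse-complement, case-insensitively
    (the repeat soft mask plays no role here: exclusion of multi-mapped reads
    is the stand-in for masking). A read with exactly one best full-length
    location is ``unique``; more than one best location is ``ambiguous``;
    none is ``unmapped``. Reads carrying simulated errors fall back to the
    best seed-anchored location when at least ``min_identity`` of bases
    match.

    policy ``"unique"`` leaves ambiguous reads flagged (excluded from
    coverage downstream); ``"random-best"`` resolves each ambiguous read to
    one of its best locations with the supplied seeded RNG and reports it as
    unique.

    Returns a DataFrame with columns read_index, scaffold, start, strand,
    status, length.
    """
    if len(assembly) == 0:
        raise ValueError("cannot build an index of an empty assembly")
    if policy not in ("unique", "random-best"):
        raise ValueError(f"unknown placement policy {policy!r}")
    n, rl = readset.library_size, readset.read_length
    empty = pd.DataFrame({"read_index": np.arange(n), "scaffold": "",
                          "start": -1, "strand": "+", "status": UNMAPPED,
                          "length": rl})
    if n == 0:
        return empty.iloc[:0]
    if min(assembly.lengths.values()) < rl:
        raise ValueError("reads longer than the shortest scaffold")
    k = min(seed_length, rl)
    max_mm = int(np.floor((1.0 - min_identity) * rl))

    # concatenated genome with read-length spacers of invalid code 255
    names = assembly.names
    parts, offsets, pos = [], [], 0
    spacer = np.full(rl, 255, np.uint8)
    for name in names:
        offsets.append(pos)
        c = assembly.codes(name)
        parts.extend((c, spacer))
        pos += len(c) + rl
    gcodes = np.concatenate(parts)
    offsets = np.asarray(offsets, np.int64)
    gseeds, gvalid = _seq.kmer_ints_1d(gcodes, k)
    vpos = np.nonzero(gvalid)[0]
    vseeds = gseeds[gvalid]
    order = np.argsort(vseeds, kind="stable")
    svs, spos = vseeds[order], vpos[order]

    fcodes = readset.codes
    rcodes = _seq.revcomp_codes(fcodes)

    def _seed_ints(mat):
        v = np.zeros(n, np.uint64)
        c = mat.astype(np.uint64)
        for j in range(k):
            v = (v << np.uint64(2)) | (c[:, j] & np.uint64(3))
        return v

    cand_r, cand_p, cand_s, cand_mm = [], [], [], []
    for strand_code, mat in ((0, fcodes), (1, rcodes)):
        q = _seed_ints(mat)
        lo = np.searchsorted(svs, q, "left")
        hi = np.searchsorted(svs, q, "right")
        cnt = hi - lo
        qidx, flat = _expand_ranges(lo, cnt)
        gpos = spos[flat]
        # chunked full-length verification
        for a in range(0, len(qidx), 500_000):
            b = min(a + 500_000, len(qidx))
            win = gcodes[gpos[a:b, None] + np.arange(rl)]
            mm = (win != mat[qidx[a:b]]).sum(axis=1)
            cand_mm.append(mm.astype(np.int32))
        cand_r.append(qidx)
        cand_p.append(gpos)
        cand_s.append(np.full(len(qidx), strand_code, np.uint8))

    ridx = np.concatenate(cand_r) if cand_r else np.empty(0, np.int64)
    gpos = np.concatenate(cand_p) if cand_p else np.empty(0, np.int64)
    strand = np.concatenate(cand_s) if cand_s else np.empty(0, np.uint8)
    mm = np.concatenate(cand_mm) if cand_mm else np.empty(0, np.int32)

    status = np.full(n, UNMAPPED, object)
    out_pos = np.full(n, -1, np.int64)
    out_strand = np.full(n, 0, np.uint8)

    keep = mm <= max_mm
    ridx, gpos, strand, mm = ridx[keep], gpos[keep], strand[keep], mm[keep]
    if len(ridx):
        srt = np.lexsort((mm, ridx))
        ridx, gpos, strand, mm = ridx[srt], gpos[srt], strand[srt], mm[srt]
        first = np.ones(len(ridx), bool)
        first[1:] = ridx[1:] != ridx[:-1]
        fidx = np.nonzero(first)[0]
        reads_with = ridx[fidx]
        best_mm = mm[fidx]
        nxt = fidx + 1
        has_tie = (nxt < len(ridx)) & (ridx[np.minimum(nxt, len(ridx) - 1)] == reads_with) \
            & (mm[np.minimum(nxt, len(ridx) - 1)] == best_mm)
        uniq = ~has_tie
        status[reads_with[uniq]] = UNIQUE
        out_pos[reads_with[uniq]] = gpos[fidx[uniq]]
        out_strand[reads_with[uniq]] = strand[fidx[uniq]]
        status[reads_with[has_tie]] = AMBIGUOUS
        if policy == "random-best" and has_tie.any():
            if rng is None:
                rng = np.random.default_rng(0)
            # per ambiguous read, choose uniformly among best-mm candidates
            for f in fidx[has_tie]:
                r, bm = ridx[f], mm[f]
                j = f
                while j < len(ridx) and ridx[j] == r and mm[j] == bm:
                    j += 1
                pick = int(rng.integers(f, j))
                status[r] = UNIQUE
                out_pos[r] = gpos[pick]
                out_strand[r] = strand[pick]

    si = np.searchsorted(offsets, out_pos, "right") - 1
    si = np.clip(si, 0, len(names) - 1)
    local = out_pos - offsets[si]
    # a mapped read must lie fully within its scaffold: fallback matches that
    # would overhang the scaffold end are rejected
    lens = np.asarray([assembly.length(nm) for nm in names], np.int64)
    overhang = (out_pos >= 0) & (local + rl > lens[si])
    status[overhang] = UNMAPPED
    out_pos[overhang] = -1
    local[overhang] = -1
    name_arr = np.asarray(names, object)
    scaffold = np.where(out_pos >= 0, name_arr[si], "")
    return pd.DataFrame({
        "read_index": np.arange(n),
        "scaffold": scaffold,
        "start": np.where(out_pos >= 0, local, -1),
        "strand": np.where(out_strand == 0, "+", "-"),
        "status": status,
        "length": rl,
    })


def load_alignments(path: str | os.PathLike, assembly: Assembly,
                    min_mapq: int = 20) -> pd.DataFrame:
    """Convert a BAM/SAM file into the placement table the pipeline uses.

    Primary mapped records with MAPQ >= ``min_mapq`` become unique
    placements; lower MAPQ becomes ambiguous; unmapped stays unmapped.
    Secondary and supplementary records are dropped. Raises if the file
    references scaffolds absent from the assembly.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        refs = set(fh.references or ())
        missing = refs - set(assembly.names)
        if missing:
            raise ValueError(
                f"alignment references not in assembly: {sorted(missing)[:5]}")
        i = 0
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                rows.append((i, "", -1, "+", UNMAPPED, rec.query_length or 0))
            else:
                st = UNIQUE if rec.mapping_quality >= min_mapq else AMBIGUOUS
                rows.append((i, rec.reference_name, rec.reference_start,
                             "-" if rec.is_reverse else "+", st,
                             rec.query_length or rec.infer_query_length() or 0))
            i += 1
    return pd.DataFrame(rows, columns=["read_index", "scaffold", "start",
                                       "strand", "status", "length"])


def retained(placements: pd.DataFrame) -> pd.DataFrame:
    """Placements retained for coverage: uniquely mapped reads only."""
    return placements[placements["status"] == UNIQUE]


@dataclass
class CoverageTrack:
    """Per-window normalized coverage (RPKM) of one sexed library."""

    sex: str
    library_size: int
    windows: pd.DataFrame  # scaffold, start, end, index, length, partial, count, rpkm


def window_rpkm(placements: pd.DataFrame, windows: pd.DataFrame,
                library_size: int, sex: str = "") -> CoverageTrack:
    """Count retained reads per window (by start coordinate) and normalize.

    RPKM(window) = count / ((window length / 1000) * (library_size / 1e6)).
    ``library_size`` is the number of retained mapped reads and must be > 0.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    kept = retained(placements)
    win = windows.copy().reset_index(drop=True)
    counts = np.zeros(len(win), np.int64)
    for scaffold, grp in kept.groupby("scaffold", sort=False):
        widx = np.nonzero((win["scaffold"] == scaffold).to_numpy())[0]
        if len(widx) == 0:
            continue
        wstart = win.loc[widx, "start"].to_numpy()
        wend = win.loc[widx, "end"].to_numpy()
        starts = grp["start"].to_numpy()
        j = np.searchsorted(wstart, starts, "right") - 1
        ok = (j >= 0) & (starts < wend[np.clip(j, 0, len(widx) - 1)])
        np.add.at(counts, widx[j[ok]], 1)
    win["count"] = counts
    win["rpkm"] = counts / ((win["length"] / 1000.0) * (library_size / 1e6))
    return CoverageTrack(sex=sex, library_size=library_size, windows=win)


def count_gene_reads(placements: pd.DataFrame, genes: pd.DataFrame,
                     assembly: Assembly | None = None) -> pd.DataFrame:
    """Count retained reads overlapping each gene by >= 1 bp.

    A read spanning two genes counts once for each. Genes on scaffolds
    absent from the assembly trigger a warning and are skipped.
    """
    kept = retained(placements)
    gene_rows = genes
    if assembly is not None:
        missing = ~genes["scaffold"].isin(assembly.names)
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} gene(s) on scaffolds absent from the "
                "assembly were skipped", stacklevel=2)
            gene_rows = genes[~missing]
    out = gene_rows.copy().reset_index(drop=True)
    counts = np.zeros(len(out), np.int64)
    by_scaffold = dict(tuple(kept.groupby("scaffold", sort=False)))
    for scaffold, gidx in out.groupby("scaffold", sort=False).groups.items():
        grp = by_scaffold.get(scaffold)
        if grp is None:
            continue
        gidx = np.asarray(list(gidx))
        gstart = out.loc[gidx, "start"].to_numpy()
        gend = out.loc[gidx, "end"].to_numpy()
        for length, sub in grp.groupby("length", sort=False):
            starts = np.sort(sub["start"].to_numpy())
            # overlap >=1 bp: start in (gstart - length, gend)
            lo = np.searchsorted(starts, gstart - length + 1, "left")
            hi = np.searchsorted(starts, gend, "left")
            counts[gidx] += hi - lo
    out["count"] = counts
    return out
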