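"""Male-unique 25-mer detection: Y-linked material at fine scale.

Canonical (strand-collapsed) k-mers are counted in each sexed read library;
k-mers seen at least ``min_male_count`` times in the male library and never
in the female library are located exactly on the assembly, merged into
Y-unique regions (contiguous intervals of >= k bases covered only by
male-derived sequence) and summarized as a density track in 1.8 Mbp
non-overlapping windows along each scaffold — a local spike on a
chromosome-scale scaffold flags Y material misassembled into it.

Counting is in-memory on packed 64-bit k-mer codes (k <= 31).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .assembly import Assembly
from .sim import ReadSet


@dataclass
class KmerTable:
    """Canonical k-mer counts of one read set (sorted packed codes + counts)."""

    k: int
    kmers: np.ndarray   # uint64, sorted, canonical
    counts: np.ndarray  # int64, >= 1

    def __len__(self) -> int:
        return len(self.kmers)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        """Count of a k-mer given as a string (canonicalized first)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        code = np.uint64(_seq.kmer_to_int(_seq.canonical(kmer)))
        i = np.searchsorted(self.kmers, code)
        if i < len(self.kmers) and self.kmers[i] == code:
            return int(self.counts[i])
        return 0

    def to_dict(self) -> dict[str, int]:
        """Decode to a {k-mer string: count} dict (small tables only)."""
        return {_seq.int_to_kmer(int(v), self.k): int(c)
                for v, c in zip(self.kmers, self.counts)}


def _aggregate(chunks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if not chunks:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    allk = np.concatenate(chunks)
    kmers, counts = np.unique(allk, return_counts=True)
    return kmers, counts.astype(np.int64)


def count_kmers(readset: ReadSet, k: int = 25,
                chunk_reads: int = 200_000) -> KmerTable:
    """Count every canonical k-mer window of every read.

    Reads shorter than k contribute nothing; windows containing non-ACGT
    symbols are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 (packed 64-bit codes)")
    rl = readset.read_length
    if readset.library_size == 0 or rl < k:
        return KmerTable(k, np.empty(0, np.uint64), np.empty(0, np.int64))
    parts = []
    for a in range(0, readset.library_size, chunk_reads):
        mat = readset.codes[a : a + chunk_reads]
        if np.any(mat >= 4):
            # rows with ambiguous bases: keep only valid windows
            can = _seq.canonical_ints_2d(np.where(mat < 4, mat, 0), k)
            bad = (mat >= 4).astype(np.int32)
            cs = np.concatenate(
                [np.zeros((mat.shape[0], 1), np.int32), np.cumsum(bad, 1)], 1)
            valid = (cs[:, k:] - cs[:, :-k]) == 0
            km = can[valid]
        else:
            km = _seq.canonical_ints_2d(mat, k).ravel()
        # collapse per chunk to keep the final sort smaller
        u, c = np.unique(km, return_counts=True)
        parts.append(u)
        parts.append(c)
    # merge per-chunk (unique, counts) pairs
    keys = np.concatenate(parts[0::2]) if parts else np.empty(0, np.uint64)
    vals = np.concatenate(parts[1::2]) if parts else np.empty(0, np.int64)
    order = np.argsort(keys, kind="stable")
    keys, vals = keys[order], vals[order]
    if len(keys) == 0:
        return KmerTable(k, keys, vals.astype(np.int64))
    first = np.ones(len(keys), bool)
    first[1:] = keys[1:] != keys[:-1]
    uk = keys[first]
    csum = np.concatenate(([0], np.cumsum(vals)))
    starts = np.nonzero(first)[0]
    ends = np.concatenate((starts[1:], [len(keys)]))
    uc = csum[ends] - csum[starts]
    return KmerTable(k, uk, uc.astype(np.int64))


def count_kmers_sequences(sequences, k: int = 25) -> KmerTable:
    """Canonical k-mer counts over an iterable of sequence strings."""
    chunks = []
    for seq in sequences:
        codes = _seq.encode(seq)
        can, valid = _seq.canonical_ints_1d(codes, k)
        chunks.append(can[valid])
    kmers, counts = _aggregate(chunks)
    return KmerTable(k, kmers, counts)


@dataclass
class UniqueKmerSet:
    """Sorted canonical k-mer codes present only in one library."""

    k: int
    kmers: np.ndarray  # uint64, sorted

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        code = np.uint64(_seq.kmer_to_int(_seq.canonical(kmer)))
        i = np.searchsorted(self.kmers, code)
        return bool(i < len(self.kmers) and self.kmers[i] == code)

    def to_strings(self) -> list[str]:
        return [_seq.int_to_kmer(int(v), self.k) for v in self.kmers]


def male_unique(male: KmerTable, female: KmerTable, min_male_count: int = 2,
                max_female_count: int = 0) -> UniqueKmerSet:
    """K-mers with male count >= ``min_male_count`` and female count <=
    ``max_female_count`` (default: absent from the female library entirely).

    ``min_male_count`` of 2 discards singleton sequencing-error k-mers; 1
    reproduces the literal "uniquely present in male" reading.
    """
    if male.k != female.k:
        raise ValueError(f"k mismatch: male {male.k} vs female {female.k}")
    cand = male.kmers[male.counts >= min_male_count]
    if max_female_count == 0:
        keep = ~np.isin(cand, female.kmers, assume_unique=True)
    elif len(female.kmers) == 0:
        keep = np.ones(len(cand), bool)
    else:
        idx = np.clip(np.searchsorted(female.kmers, cand), 0,
                      len(female.kmers) - 1)
        fc = np.where(female.kmers[idx] == cand, female.counts[idx], 0)
        keep = fc <= max_female_count
    return UniqueKmerSet(male.k, cand[keep])


def locate_kmers(unique: UniqueKmerSet, assembly: Assembly) -> pd.DataFrame:
    """Exact occurrences of the unique k-mers on the assembly (either strand).

    Matching is case-insensitive (soft-masking ignored). A minus-strand
    occurrence is reported at the forward coordinate of its reverse
    complement. Returns a sorted DataFrame with columns scaffold, start.
    """
    rows = []
    for name in assembly.names:
        can, valid = _seq.canonical_ints_1d(assembly.codes(name), unique.k)
        if len(can) == 0:
            continue
        hit = valid & np.isin(can, unique.kmers, assume_unique=False)
        pos = np.nonzero(hit)[0]
        if len(pos):
            rows.append(pd.DataFrame({"scaffold": name, "start": pos}))
    if not rows:
        return pd.DataFrame(columns=["scaffold", "start"]).astype(
            {"scaffold": object, "start": np.int64})
    return pd.concat(rows, ignore_index=True)


def merge_y_regions(hits: pd.DataFrame, k: int = 25,
                    max_gap: int = 0) -> pd.DataFrame:
    """Union overlapping/abutting k-mer hit intervals into Y-unique regions.

    Each hit spans [start, start+k); spans separated by at most ``max_gap``
    are merged (the default 0 merges only overlapping or abutting spans,
    mirroring interval-merge defaults). Every output region is >= k long.
    Returns scaffold, start, end, n_kmers.
    """
    rows = []
    for scaffold, grp in hits.groupby("scaffold", sort=True):
        starts = np.sort(grp["start"].to_numpy())
        if len(starts) == 0:
            continue
        ends = starts + k
        breaks = np.nonzero(starts[1:] > ends[:-1] + max_gap)[0] + 1
        bounds = np.concatenate(([0], breaks, [len(starts)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append((scaffold, int(starts[a]),
                         int(ends[a:b].max()), int(b - a)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_kmers"])


def density_track(regions: pd.DataFrame, assembly: Assembly,
                  bin_size: int = 1_800_000) -> pd.DataFrame:
    """Y-unique region density per non-overlapping ``bin_size`` window.

    n_regions counts each region once, in the bin holding its midpoint;
    n_bases apportions region bases exactly among the bins they overlap, so
    summed n_bases equals summed region lengths.
    """
    rows = []
    per_scaffold = dict(tuple(regions.groupby("scaffold", sort=False)))
    for name in assembly.names:
        L = assembly.length(name)
        nbins = max(1, -(-L // bin_size))
        n_regions = np.zeros(nbins, np.int64)
        n_bases = np.zeros(nbins, np.int64)
        grp = per_scaffold.get(name)
        if grp is not None:
            for _, r in grp.iterrows():
                s, e = int(r["start"]), int(r["end"])
                mid_bin = ((s + e) // 2) // bin_size
                n_regions[mid_bin] += 1
                for b in range(s // bin_size, (e - 1) // bin_size + 1):
                    lo = max(s, b * bin_size)
                    hi = min(e, (b + 1) * bin_size)
                    n_bases[b] += hi - lo
        for b in range(nbins):
            rows.append((name, b * bin_size, min((b + 1) * bin_size, L),
                         int(n_regions[b]), int(n_bases[b])))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "n_regions", "n_bases"])


def plot_density(density: pd.DataFrame, path: str,
                 scaffolds: list[str] | None = None) -> None:
    """Bar plot of Y-unique bases per density bin, one panel per scaffold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = scaffolds or list(dict.fromkeys(density["scaffold"]))
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)),
                             squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        grp = density[density["scaffold"] == name]
        ax.bar(grp["start"] / 1e6, grp["n_bases"],
               width=(grp["end"] - grp["start"]) / 1e6, align="edge")
        ax.set_ylabel("Y-unique bp")
        ax.set_title(name, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
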