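"""Synthetic assemblies, gene models and sexed WGS read sets with known truth.

The generator emulates the copy-number structure that chromosome-quotient (CQ)
analysis assumes: autosomal scaffolds carry two copies in both sexes, X
scaffolds two copies in females and one in males, and Y scaffolds one copy in
males only. Scaffolds are i.i.d. uniform-random sequence interrupted by
soft-masked repeat tracts (diverged copies of small repeat libraries, with an
optional library shared across compartments to model cross-mapping), carry
non-overlapping gene intervals, and may receive injected Y-origin segments to
emulate Y material misassembled into chromosome-scale scaffolds. Read sets are
single-end, fixed-length, sampled uniformly per position with Poisson library
sizes so that expected per-base depth equals ``mean_depth x copy_number``.

Everything is deterministic given the config seed; read ids encode their
origin (scaffold, position, strand) so placement can be checked without any
aligner.
"""
from __future__ import annotations

import os
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .assembly import Assembly

#: Compartment labels.
AUTOSOME, X, Y = "autosome", "X", "Y"

#: copy_number[compartment][sex] under the XX female / XY male model.
COPY_NUMBER = {
    AUTOSOME: {"female": 2, "male": 2},
    X: {"female": 2, "male": 1},
    Y: {"female": 0, "male": 1},
}

_REPEAT_CLASSES = ("LTR", "LINE", "DNA", "Simple_repeat", "Unknown")

#: Window size the downstream CQ analysis uses; scaffolds must hold >= 3 windows.
DEFAULT_WINDOW = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults are the desk-scale study conditions used throughout the test
    suite: ten 100 kb scaffolds per compartment at 20x haploid depth with
    error-free 100 bp single-end reads and 30% interspersed repeats.

    Attributes
    ----------
    n_autosomal_scaffolds, n_x_scaffolds, n_y_scaffolds
        Scaffold counts per compartment.
    scaffold_length_range
        Inclusive (min, max) scaffold length in bp; min must be at least
        three CQ windows and one read length.
    repeat_fraction
        Target fraction of each scaffold covered by soft-masked repeat
        tracts, in [0, 1).
    shared_repeat_fraction
        Fraction of repeat tracts drawn from a library common to all
        compartments (models cross-mapping between compartments).
    n_genes_per_scaffold
        Non-overlapping gene intervals placed per scaffold.
    read_length
        Single-end read length in bp.
    mean_depth
        Expected fold-coverage per haploid copy; per-base depth of a
        scaffold is ``mean_depth * copy_number[compartment][sex]``.
    error_rate
        Per-base substitution probability in [0, 0.05].
    seed
        Master seed; identical configs yield byte-identical outputs.
    y_injections
        Tuple of ``(target_scaffold, segment_length, insertion_offset)``
        Y-origin segments spliced into non-Y scaffolds.
    """

    n_autosomal_scaffolds: int = 10
    n_x_scaffolds: int = 10
    n_y_scaffolds: int = 10
    scaffold_length_range: tuple[int, int] = (100_000, 100_000)
    repeat_fraction: float = 0.3
    shared_repeat_fraction: float = 0.0
    n_genes_per_scaffold: int = 5
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    read_length: int = 100
    mean_depth: float = 20.0
    error_rate: float = 0.0
    seed: int = 1
    y_injections: tuple[tuple[str, int, int], ...] = ()
    repeat_length_range: tuple[int, int] = (300, 3_000)
    repeat_divergence: float = 0.02
    repeat_library_size: int = 8

    def __post_init__(self):
        for name in ("n_autosomal_scaffolds", "n_x_scaffolds", "n_y_scaffolds",
                     "n_genes_per_scaffold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.scaffold_length_range
        if lo > hi:
            raise ValueError("scaffold_length_range min > max")
        if lo < 3 * DEFAULT_WINDOW:
            raise ValueError(
                f"scaffold_length_range min must be >= {3 * DEFAULT_WINDOW} "
                f"(three {DEFAULT_WINDOW} bp analysis windows)")
        if lo < self.read_length:
            raise ValueError("scaffold length below read length")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if not 0 <= self.shared_repeat_fraction <= 1:
            raise ValueError("shared_repeat_fraction must be in [0, 1]")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        object.__setattr__(self, "y_injections",
                           tuple(tuple(i) for i in self.y_injections))


@dataclass
class SimTruth:
    """Ground truth of a simulated study: the acceptance surface for recovery.

    ``genes``, ``repeats`` and ``injections`` are DataFrames with 0-based
    half-open coordinates on the (final, post-injection) assembly.
    """

    scaffold_compartment: dict[str, str]
    genes: pd.DataFrame        # gene_id, scaffold, start, end, strand, compartment
    repeats: pd.DataFrame      # scaffold, start, end, repeat_class
    injections: pd.DataFrame   # scaffold, start, end

    @property
    def gene_compartment(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["compartment"]))

    def copy_number(self, scaffold: str, sex: str) -> int:
        return COPY_NUMBER[self.scaffold_compartment[scaffold]][sex]

    @property
    def injected_y_intervals(self) -> pd.DataFrame:
        return self.injections

    @property
    def repeat_intervals(self) -> pd.DataFrame:
        return self.repeats

    def scaffolds(self, compartment: str) -> list[str]:
        return [s for s, c in self.scaffold_compartment.items() if c == compartment]


@dataclass
class ReadSet:
    """Fixed-length single-end reads of one sexed library.

    Sequences are stored 2-bit encoded as an ``(n, read_length)`` uint8
    matrix; origins (assembly scaffold, 0-based start of the forward-strand
    window, strand) are kept as parallel arrays and encoded in the read ids.
    """

    sex: str
    codes: np.ndarray
    origin_scaffold: np.ndarray   # object array of scaffold names
    origin_start: np.ndarray      # int64
    origin_strand: np.ndarray     # '+' / '-'

    @property
    def library_size(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1] if self.codes.size else 0

    def sequence(self, i: int) -> str:
        return _seq.decode(self.codes[i])

    def read_id(self, i: int) -> str:
        return (f"{self.sex[0]}{i:08d}|{self.origin_scaffold[i]}"
                f"|{self.origin_start[i]}|{self.origin_strand[i]}")

    @property
    def ids(self) -> list[str]:
        return [self.read_id(i) for i in range(self.library_size)]

    def to_fastq(self, path: str | os.PathLike) -> None:
        qual = "I" * self.read_length
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        with open(path, "w") as fh:
            for i in range(self.library_size):
                seq = bytes(lut[self.codes[i]]).decode("ascii")
                fh.write(f"@{self.read_id(i)}\n{seq}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path: str | os.PathLike, sex: str) -> "ReadSet":
        """Load a uniform-length FASTQ library (ids need not encode origins)."""
        import pysam

        seqs, names = [], []
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                seqs.append(entry.sequence)
                names.append(entry.name)
        if not seqs:
            return cls(sex, np.empty((0, 0), np.uint8),
                       np.empty(0, object), np.empty(0, np.int64),
                       np.empty(0, object))
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("read set must have uniform read length")
        codes = _seq.encode("".join(seqs)).reshape(len(seqs), lengths.pop())
        origin_scaffold = np.empty(len(seqs), object)
        origin_scaffold[:] = ""
        strands = np.empty(len(seqs), object)
        strands[:] = "+"
        for i, name in enumerate(names):
            parts = name.split("|")
            if len(parts) == 4:
                origin_scaffold[i] = parts[1]
                strands[i] = parts[3]
        starts = np.array(
            [int(n.split("|")[2]) if len(n.split("|")) == 4 else -1 for n in names],
            np.int64)
        return cls(sex, codes, origin_scaffold, starts, strands)


def _make_repeat_library(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[np.ndarray, str]]:
    lib = []
    lo, hi = cfg.repeat_length_range
    for i in range(cfg.repeat_library_size):
        L = int(rng.integers(lo, hi + 1))
        lib.append((rng.integers(0, 4, L, dtype=np.uint8),
                    _REPEAT_CLASSES[i % len(_REPEAT_CLASSES)]))
    return lib


def _diverge(codes: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    out = codes.copy()
    hit = rng.random(len(out)) < rate
    out[hit] = (out[hit] + rng.integers(1, 4, hit.sum(), dtype=np.uint8)) % 4
    return out


def _place_repeats(codes: np.ndarray, rng: np.random.Generator, cfg: SimConfig,
                   own_lib, shared_lib) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Overwrite non-overlapping tracts with diverged repeat copies.

    Returns the soft-mask boolean track and the tract interval list. Tracts
    are placed by rejection sampling until the masked fraction reaches the
    configured target (within one tract length).
    """
    L = len(codes)
    masked = np.zeros(L, bool)
    tracts: list[tuple[int, int, str]] = []
    target = int(round(cfg.repeat_fraction * L))
    tries = 0
    while masked.sum() < target and tries < 50 * max(1, cfg.repeat_library_size):
        use_shared = rng.random() < cfg.shared_repeat_fraction
        lib = shared_lib if use_shared else own_lib
        elem, cls = lib[int(rng.integers(0, len(lib)))]
        remaining = target - int(masked.sum())
        tlen = max(1, min(len(elem), L, remaining))
        start = int(rng.integers(0, L - tlen + 1))
        if masked[start : start + tlen].any():
            tries += 1
            continue
        codes[start : start + tlen] = _diverge(elem[:tlen], rng, cfg.repeat_divergence)
        masked[start : start + tlen] = True
        tracts.append((start, start + tlen, cls))
        tries = 0
    tracts.sort()
    return masked, tracts


def _place_genes(L: int, n: int, rng: np.random.Generator,
                 cfg: SimConfig) -> list[tuple[int, int, str]]:
    lo, hi = cfg.gene_length_range
    out: list[tuple[int, int, str]] = []
    for _ in range(n):
        for _try in range(200):
            glen = int(rng.integers(lo, hi + 1))
            if glen >= L:
                continue
            start = int(rng.integers(0, L - glen + 1))
            if all(start >= e or start + glen <= s for s, e, _ in out):
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                out.append((start, start + glen, strand))
                break
    out.sort()
    return out


def _to_string(codes: np.ndarray, masked: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    raw = lut[codes].copy()
    raw[masked] += 32  # lowercase
    return bytes(raw).decode("ascii")


def simulate_assembly(config: SimConfig) -> tuple[Assembly, SimTruth]:
    """Generate a multi-compartment assembly and its ground truth.

    Scaffolds are named ``auto_NN`` / ``X_NN`` / ``Y_NN``. Repeat tracts are
    soft-masked in the emitted sequence; any requested Y injections are
    applied before returning, so coordinates in the truth refer to the final
    assembly.
    """
    rng = np.random.default_rng([config.seed, 11])
    shared_lib = _make_repeat_library(rng, config)
    comp_libs = {c: _make_repeat_library(rng, config) for c in (AUTOSOME, X, Y)}

    sequences: dict[str, str] = {}
    scaffold_compartment: dict[str, str] = {}
    gene_rows, repeat_rows = [], []
    gene_counter = 0
    plan = [(AUTOSOME, "auto", config.n_autosomal_scaffolds),
            (X, "X", config.n_x_scaffolds),
            (Y, "Y", config.n_y_scaffolds)]
    lo, hi = config.scaffold_length_range
    for comp, prefix, count in plan:
        for i in range(count):
            name = f"{prefix}_{i + 1:02d}"
            L = int(rng.integers(lo, hi + 1))
            codes = rng.integers(0, 4, L, dtype=np.uint8)
            masked, tracts = _place_repeats(codes, rng, config,
                                            comp_libs[comp], shared_lib)
            for s, e, cls in tracts:
                repeat_rows.append((name, s, e, cls))
            for s, e, strand in _place_genes(L, config.n_genes_per_scaffold,
                                             rng, config):
                gene_counter += 1
                gene_rows.append((f"g{gene_counter:05d}", name, s, e, strand, comp))
            sequences[name] = _to_string(codes, masked)
            scaffold_compartment[name] = comp

    assembly = Assembly(sequences)
    truth = SimTruth(
        scaffold_compartment=scaffold_compartment,
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "scaffold", "start",
                                               "end", "strand", "compartment"]),
        repeats=pd.DataFrame(repeat_rows, columns=["scaffold", "start", "end",
                                                   "repeat_class"]),
        injections=pd.DataFrame(columns=["scaffold", "start", "end"]).astype(
            {"scaffold": object, "start": np.int64, "end": np.int64}),
    )
    if config.y_injections:
        assembly, truth = inject_y_segments(assembly, truth, config)
    return assembly, truth


def inject_y_segments(assembly: Assembly, truth: SimTruth,
                      config: SimConfig) -> tuple[Assembly, SimTruth]:
    """Splice Y-origin segments into non-Y scaffolds, shifting coordinates.

    Each requested ``(target, length, offset)`` inserts freshly generated
    Y-compartment sequence (with its own repeat tracts) at ``offset`` of the
    target scaffold. Gene and repeat coordinates at or beyond the insertion
    point are shifted downstream; the injected interval is recorded in
    ``truth.injections``. Offsets refer to the scaffold before injection.
    """
    if not config.y_injections:
        return assembly, truth
    rng = np.random.default_rng([config.seed, 29])
    y_lib = _make_repeat_library(rng, config)
    shared_lib = _make_repeat_library(rng, config)

    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for target, seg_len, offset in config.y_injections:
        if target not in assembly:
            raise ValueError(f"injection target {target!r} not in assembly")
        if truth.scaffold_compartment.get(target) == Y:
            raise ValueError(f"injection target {target!r} is a Y scaffold")
        if not 0 <= offset <= assembly.length(target):
            raise ValueError(
                f"injection offset {offset} outside scaffold {target!r} bounds")
        per_scaffold.setdefault(target, []).append((int(offset), int(seg_len)))

    sequences = dict(assembly.sequences)
    genes = truth.genes.copy()
    repeats = truth.repeats.copy()
    injection_rows = []
    for target, items in per_scaffold.items():
        items.sort()
        offsets = [o for o, _ in items]
        if len(set(offsets)) != len(offsets):
            raise ValueError(f"overlapping injections requested on {target!r}")
        shift = 0
        pieces, cursor = [], 0
        seq = sequences[target]
        for offset, seg_len in items:
            seg_codes = rng.integers(0, 4, seg_len, dtype=np.uint8)
            seg_mask, seg_tracts = _place_repeats(seg_codes, rng, config,
                                                  y_lib, shared_lib)
            seg = _to_string(seg_codes, seg_mask)
            pieces.append(seq[cursor:offset])
            pieces.append(seg)
            cursor = offset
            final_start = offset + shift
            injection_rows.append((target, final_start, final_start + seg_len))
            for s, e, cls in seg_tracts:
                repeats.loc[len(repeats)] = (target, final_start + s,
                                             final_start + e, cls)
            shift += seg_len
        pieces.append(seq[cursor:])
        sequences[target] = "".join(pieces)

        def _shift_pos(pos: np.ndarray) -> np.ndarray:
            out = pos.astype(np.int64).copy()
            for offset, seg_len in items:
                out[pos >= offset] += seg_len
            return out

        for df in (genes, repeats):
            on_target = (df["scaffold"] == target).to_numpy()
            # only shift entities that predate this injection pass
            pre = on_target & (df.index < (len(truth.genes) if df is genes
                                           else len(truth.repeats)))
            if pre.any():
                df.loc[pre, "start"] = _shift_pos(df.loc[pre, "start"].to_numpy())
                df.loc[pre, "end"] = _shift_pos(df.loc[pre, "end"].to_numpy())

    injections = pd.concat(
        [truth.injections,
         pd.DataFrame(injection_rows, columns=["scaffold", "start", "end"])],
        ignore_index=True)
    repeats = repeats.sort_values(["scaffold", "start"], ignore_index=True)
    return Assembly(sequences), SimTruth(truth.scaffold_compartment, genes,
                                         repeats, injections)


def _sources(assembly: Assembly, truth: SimTruth, scaffold: str, rl: int,
             seed: int) -> list[dict]:
    """True-genome read sources of one assembly scaffold.

    A scaffold without injections is one source. A scaffold carrying
    injected Y segments decomposes into (a) its contiguous pre-injection
    sequence (the autosomal/X molecule the flanks really come from) and (b)
    one Y source per injected segment — in the true genome the Y material is
    not adjacent to its flanks, but the flanks ARE adjacent to each other.
    Every source is padded with ``rl - 1`` bases of deterministic random
    flanking context on both sides: assembly scaffolds are windows into
    continuous chromosomes, so per-base read depth must not taper at their
    ends. ``pieces`` maps source coordinates back to assembly coordinates.
    """
    comp = truth.scaffold_compartment[scaffold]
    inj = truth.injections[truth.injections["scaffold"] == scaffold]
    codes = _seq.encode(assembly.sequences[scaffold])
    sources = []
    if inj.empty:
        sources.append({"codes": codes, "compartment": comp,
                        "pieces": [(0, len(codes), 0)]})
    else:
        host_parts, pieces, cursor, src_pos = [], [], 0, 0
        for _, row in inj.sort_values("start").iterrows():
            s, e = int(row["start"]), int(row["end"])
            if s > cursor:
                host_parts.append(codes[cursor:s])
                pieces.append((src_pos, src_pos + (s - cursor), cursor))
                src_pos += s - cursor
            sources.append({"codes": codes[s:e], "compartment": Y,
                            "pieces": [(0, e - s, s)]})
            cursor = e
        if cursor < len(codes):
            host_parts.append(codes[cursor:])
            pieces.append((src_pos, src_pos + len(codes) - cursor, cursor))
        sources.insert(0, {"codes": np.concatenate(host_parts),
                           "compartment": comp, "pieces": pieces})
    for i, src in enumerate(sources):
        scaffold_key = zlib.crc32(scaffold.encode()) & 0x7FFFFFFF
        pad_rng = np.random.default_rng([seed, 55, scaffold_key, i])
        pad = rl - 1
        src["codes"] = np.concatenate([
            pad_rng.integers(0, 4, pad, dtype=np.uint8), src["codes"],
            pad_rng.integers(0, 4, pad, dtype=np.uint8)])
        src["pad"] = pad
    return sources


def simulate_reads(assembly: Assembly, truth: SimTruth, sex: str,
                   config: SimConfig) -> ReadSet:
    """Sample a sexed single-end read library from the simulated true genome.

    Per read source (see :func:`_sources`) with copy number ``c`` for this
    sex, the read count is Poisson with mean ``mean_depth * c *
    (source_length + read_length - 1) / read_length`` and starts are uniform
    over every position overlapping the source, so per-base depth is
    exactly ``mean_depth * c`` everywhere — including scaffold ends, which
    continue into simulated chromosomal context. Strand is uniform;
    substitution errors are applied at ``error_rate``. Read ids encode the
    origin as assembly coordinates; reads overhanging a source boundary
    (context or a splice junction) carry origin position -1 since they have
    no single assembly locus.
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    rng = np.random.default_rng([config.seed, 101 if sex == "female" else 102])
    rl = config.read_length

    all_sources = {name: _sources(assembly, truth, name, rl, config.seed)
                   for name in assembly.names}
    any_copy = any(COPY_NUMBER[src["compartment"]][sex] > 0
                   for srcs in all_sources.values() for src in srcs)
    if not any_copy:
        raise ValueError(f"every copy number is zero for sex {sex!r}")

    blocks, scaf_names, starts_all, strands_all = [], [], [], []
    for name in assembly.names:
        for src in all_sources[name]:
            copy = COPY_NUMBER[src["compartment"]][sex]
            padded = src["codes"]
            src_len = len(padded) - 2 * src["pad"]
            if copy == 0 or config.mean_depth == 0:
                continue
            mean = config.mean_depth * copy * (src_len + rl - 1) / rl
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            starts = rng.integers(0, src_len + rl - 1, size=n)
            strands = rng.integers(0, 2, size=n)
            mat = padded[starts[:, None] + np.arange(rl)]
            minus = strands == 1
            if minus.any():
                mat[minus] = _seq.revcomp_codes(mat[minus])
            # assembly coordinate of each read, -1 when it overhangs a piece
            src_start = starts.astype(np.int64) - src["pad"]
            asm_start = np.full(n, -1, np.int64)
            for ps, pe, asm_off in src["pieces"]:
                inside = (src_start >= ps) & (src_start + rl <= pe)
                asm_start[inside] = src_start[inside] - ps + asm_off
            blocks.append(mat)
            scaf_names.append(np.full(n, name, object))
            starts_all.append(asm_start)
            strands_all.append(np.where(minus, "-", "+").astype(object))

    if not blocks:
        return ReadSet(sex, np.empty((0, rl), np.uint8), np.empty(0, object),
                       np.empty(0, np.int64), np.empty(0, object))
    codes = np.vstack(blocks)
    if config.error_rate > 0:
        hit = rng.random(codes.shape) < config.error_rate
        shift = rng.integers(1, 4, codes.shape, dtype=np.uint8)
        codes = np.where(hit, (codes + shift) % 4, codes)
    return ReadSet(sex, codes, np.concatenate(scaf_names),
                   np.concatenate(starts_all), np.concatenate(strands_all))


def write_fixture(assembly: Assembly, truth: SimTruth,
                  readsets: list[ReadSet] | tuple[ReadSet, ...],
                  out_dir: str | os.PathLike, force: bool = False) -> dict[str, str]:
    """Emit the simulated study as plain-text files; returns a path manifest.

    Writes a soft-masked FASTA, one Phred+33 FASTQ per read set, a GFF3 of
    gene models, BED files of truth intervals (0-based half-open) and a TSV
    truth table. Refuses to overwrite existing files unless ``force``.
    """
    from . import io as sio

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "assembly": os.path.join(out_dir, "assembly.fasta"),
        "genes": os.path.join(out_dir, "genes.gff3"),
        "truth_scaffolds": os.path.join(out_dir, "truth_scaffolds.tsv"),
        "truth_genes": os.path.join(out_dir, "truth_genes.tsv"),
        "injections": os.path.join(out_dir, "injected_y.bed"),
        "repeats": os.path.join(out_dir, "repeats.bed"),
    }
    for rs in readsets:
        manifest[f"reads_{rs.sex}"] = os.path.join(out_dir, f"reads_{rs.sex}.fastq")
    clashes = [p for p in manifest.values() if os.path.exists(p)]
    if clashes and not force:
        raise FileExistsError(f"refusing to overwrite {clashes[0]} (use force=True)")

    assembly.to_fasta(manifest["assembly"])
    sio.write_gff3_genes(truth.genes, assembly, manifest["genes"])
    rows = [(name, truth.scaffold_compartment[name], assembly.length(name),
             truth.copy_number(name, "female"), truth.copy_number(name, "male"))
            for name in assembly.names]
    pd.DataFrame(rows, columns=["scaffold", "compartment", "length",
                                "copy_female", "copy_male"]).to_csv(
        manifest["truth_scaffolds"], sep="\t", index=False)
    truth.genes.to_csv(manifest["truth_genes"], sep="\t", index=False)
    sio.write_bed(truth.injections.assign(name="injected_Y"),
                  manifest["injections"])
    sio.write_bed(truth.repeats.rename(columns={"repeat_class": "name"}),
                  manifest["repeats"])
    for rs in readsets:
        rs.to_fastq(manifest[f"reads_{rs.sex}"])
    return manifest
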