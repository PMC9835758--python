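"""End-to-end orchestration: simulate -> coverage -> CQ -> k-mers -> repeats.

One :class:`RunConfig` (YAML-serializable) drives a reproducible run that
writes every stage product as a plain-text table plus a machine-readable
JSON summary. Runs are idempotent: the summary records a hash of the
config, and an unchanged rerun over the same output directory skips
recomputation and returns the stored summary.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coverage as cov
from . import cq as cqmod
from . import io as sio
from . import repeats as rep
from . import ykmer
from .assembly import Assembly
from .sim import ReadSet, SimConfig, simulate_assembly, simulate_reads, write_fixture

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All parameters of one pipeline run.

    Either ``sim`` is set (synthetic study) or ``assembly``/``reads_*`` (or
    ``bam_*``) point at existing inputs. Round-trips losslessly through
    YAML.
    """

    out_dir: str = "sexscan_run"
    sim: SimConfig | None = None
    assembly: str | None = None
    reads_female: str | None = None
    reads_male: str | None = None
    bam_female: str | None = None
    bam_male: str | None = None
    genes: str | None = None
    rmout: str | None = None
    window: int = 10_000
    x_min: float = 2.0
    y_max: float = 0.2
    min_fraction: float = 0.40
    k: int = 25
    min_male_count: int = 2
    bin_size: int = 1_800_000
    min_mapq: int = 20
    placement_policy: str = "unique"
    seed: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            d["sim"]["y_injections"] = [list(t) for t in self.sim.y_injections]
            d["sim"]["scaffold_length_range"] = list(self.sim.scaffold_length_range)
            d["sim"]["gene_length_range"] = list(self.sim.gene_length_range)
            d["sim"]["repeat_length_range"] = list(self.sim.repeat_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        simd = d.get("sim")
        if simd is not None:
            simd = dict(simd)
            for key in ("scaffold_length_range", "gene_length_range",
                        "repeat_length_range"):
                if key in simd:
                    simd[key] = tuple(simd[key])
            simd["y_injections"] = tuple(
                tuple(t) for t in simd.get("y_injections", ()))
            d["sim"] = SimConfig(**simd)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path: str) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    @property
    def thresholds(self) -> cqmod.Thresholds:
        return cqmod.Thresholds(x_min=self.x_min, y_max=self.y_max,
                                scaffold_min_fraction=self.min_fraction)


@dataclass
class RunSummary:
    """Machine-readable digest of a run; every number is recomputable from
    the stage tables on disk. Deliberately carries no wall-clock field so
    that identical configs produce byte-identical summaries."""

    config_hash: str
    tool_version: str
    scaffold_calls: dict[str, str] = field(default_factory=dict)
    n_windows: dict[str, int] = field(default_factory=dict)
    gene_assignments: dict[str, int] = field(default_factory=dict)
    y_unique_regions: int = 0
    y_unique_bases: int = 0
    repeat_fractions: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "RunSummary":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_error(stage: str, exc: Exception, out_dir: str) -> Exception:
    marker = os.path.join(out_dir, f"FAILED.{stage}")
    with open(marker, "w") as fh:
        fh.write(f"{type(exc).__name__}: {exc}\n")
    return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")


def run_pipeline(config: RunConfig, force: bool = False) -> RunSummary:
    """Execute every stage in dependency order and write all products.

    An unchanged rerun (same config hash, summary present) skips all stages
    and returns the stored summary. Failures raise a stage-named error and
    leave a FAILED marker beside any partial outputs.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    summary_path = os.path.join(out, "summary.json")
    if not force and os.path.exists(summary_path):
        prev = RunSummary.from_json(summary_path)
        if prev.config_hash == config.config_hash:
            return prev

    # --- inputs / simulation -------------------------------------------------
    try:
        if config.sim is not None:
            assembly, truth = simulate_assembly(config.sim)
            reads_f = simulate_reads(assembly, truth, "female", config.sim)
            reads_m = simulate_reads(assembly, truth, "male", config.sim)
            genes = truth.genes
            write_fixture(assembly, truth, [reads_f, reads_m],
                          os.path.join(out, "sim"), force=True)
        else:
            if not config.assembly:
                raise ValueError("config needs either sim or an assembly path")
            assembly = Assembly.from_fasta(config.assembly)
            genes = (sio.read_gff3_genes(config.genes)
                     if config.genes else pd.DataFrame(
                         columns=["gene_id", "scaffold", "start", "end", "strand"]))
            reads_f = (ReadSet.from_fastq(config.reads_female, "female")
                       if config.reads_female else None)
            reads_m = (ReadSet.from_fastq(config.reads_male, "male")
                       if config.reads_male else None)
    except Exception as exc:
        raise _stage_error("inputs", exc, out) from exc

    # --- coverage ------------------------------------------------------------
    try:
        windows = cov.tile_windows(assembly, config.window)
        placements, tracks, gene_counts = {}, {}, {}
        for sex, reads, bam in (("female", reads_f, config.bam_female),
                                ("male", reads_m, config.bam_male)):
            if bam:
                pl = cov.load_alignments(bam, assembly, config.min_mapq)
            elif reads is not None:
                pl = cov.place_reads(
                    reads, assembly, policy=config.placement_policy,
                    rng=np.random.default_rng([config.seed, 7]))
            else:
                raise ValueError(f"no reads or alignments for sex {sex!r}")
            lib = int((pl["status"] == cov.UNIQUE).sum())
            placements[sex] = pl
            tracks[sex] = cov.window_rpkm(pl, windows, lib, sex=sex)
            gene_counts[sex] = cov.count_gene_reads(pl, genes, assembly)
            sio.write_bedgraph(tracks[sex].windows, "rpkm",
                               os.path.join(out, f"coverage_{sex}.bedgraph"))
        pd.concat([gene_counts["female"].assign(sex="female"),
                   gene_counts["male"].assign(sex="male")]).to_csv(
            os.path.join(out, "gene_counts.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("coverage", exc, out) from exc

    # --- CQ ------------------------------------------------------------------
    try:
        thresholds = config.thresholds
        records = cqmod.region_cq(tracks["female"], tracks["male"])
        tagged = cqmod.tag_regions(records, thresholds, config.window)
        tagged.to_csv(os.path.join(out, "windows_cq.tsv"), sep="\t",
                      index=False)
        calls = cqmod.call_scaffolds(tagged, assembly, thresholds)
        calls.to_csv(os.path.join(out, "scaffold_calls.tsv"), sep="\t",
                     index=False)
        if len(genes):
            gcq = cqmod.gene_cq(gene_counts["female"], gene_counts["male"],
                                tracks["female"].library_size,
                                tracks["male"].library_size)
            ctx = cqmod.context_cq(genes, tagged)
            assignments = cqmod.assign_genes(gcq, ctx, thresholds)
        else:
            assignments = pd.DataFrame(columns=["gene_id", "assignment"])
        assignments.to_csv(os.path.join(out, "gene_assignments.tsv"),
                           sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("cq", exc, out) from exc

    # --- Y k-mers ------------------------------------------------------------
    try:
        if reads_f is not None and reads_m is not None:
            kf = ykmer.count_kmers(reads_f, config.k)
            km = ykmer.count_kmers(reads_m, config.k)
            unique = ykmer.male_unique(km, kf, config.min_male_count)
            hits = ykmer.locate_kmers(unique, assembly)
            regions = ykmer.merge_y_regions(hits, config.k)
            density = ykmer.density_track(regions, assembly, config.bin_size)
        else:
            regions = pd.DataFrame(columns=["scaffold", "start", "end",
                                            "n_kmers"])
            density = ykmer.density_track(regions, assembly, config.bin_size)
        sio.write_bed(regions.assign(name="Y_unique"),
                      os.path.join(out, "y_unique_regions.bed"))
        density.to_csv(os.path.join(out, "y_density.tsv"), sep="\t",
                       index=False)
    except Exception as exc:
        raise _stage_error("ykmer", exc, out) from exc

    # --- repeats -------------------------------------------------------------
    try:
        rsum = rep.masked_fraction(assembly, calls)
        rsum.to_csv(os.path.join(out, "repeat_summary.tsv"), sep="\t",
                    index=False)
        if config.rmout:
            rep.class_fractions(config.rmout, calls, assembly).to_csv(
                os.path.join(out, "repeat_classes.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("repeats", exc, out) from exc

    summary = RunSummary(
        config_hash=config.config_hash,
        tool_version=__version__,
        scaffold_calls=dict(zip(calls["scaffold"], calls["call"])),
        n_windows={t: int((tagged["tag"] == t).sum())
                   for t in (cqmod.TAG_X, cqmod.TAG_Y, cqmod.TAG_NEUTRAL,
                             cqmod.TAG_UNDEFINED)},
        gene_assignments=(assignments["assignment"].value_counts().to_dict()
                          if len(assignments) else {}),
        y_unique_regions=int(len(regions)),
        y_unique_bases=int((regions["end"] - regions["start"]).sum())
        if len(regions) else 0,
        repeat_fractions={r["compartment"]: float(r["masked_fraction"])
                          for _, r in rsum.iterrows()},
    )
    summary.to_json(summary_path)
    config.to_yaml(os.path.join(out, "config.yaml"))
    return summary


def validate_targets(regions: pd.DataFrame, assembly: Assembly,
                     amplicon_range: tuple[int, int] = (400, 800),
                     max_per_region: int = 5) -> pd.DataFrame:
    """Export candidate intervals from Y regions suitable for primer design.

    For each region, tiles candidate amplicons within the requested length
    range, reports GC and soft-masked fractions plus the distance to the
    region edge, and keeps the ``max_per_region`` least-masked candidates
    (primer design itself is out of scope).
    """
    lo, hi = amplicon_range
    rows = []
    for _, r in regions.iterrows():
        scaffold, s, e = r["scaffold"], int(r["start"]), int(r["end"])
        if e - s < lo:
            continue
        amp = min(hi, e - s)
        seq = assembly.sequences[scaffold]
        cands = []
        for a in range(s, e - amp + 1, max(1, amp // 2)):
            sub = seq[a : a + amp]
            up = sub.upper()
            gc = (up.count("G") + up.count("C")) / len(sub)
            masked = sum(1 for c in sub if c.islower()) / len(sub)
            cands.append((scaffold, a, a + amp, amp, gc, masked,
                          min(a - s, e - (a + amp))))
        cands.sort(key=lambda t: (t[5], abs(t[4] - 0.5)))
        rows.extend(cands[:max_per_region])
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "length",
                                       "gc_fraction", "masked_fraction",
                                       "edge_distance"])
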