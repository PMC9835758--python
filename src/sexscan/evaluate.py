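"""Truth-recovery evaluation of simulated studies.

Runs the full analysis (simulate -> place -> RPKM -> CQ -> calls -> genes ->
k-mers) on synthetic studies with known truth and measures how well each
stage recovers the simulated compartments: per-compartment window-CQ means,
scaffold-call recovery, gene-assignment recovery, and male-unique k-mer
soundness/sensitivity against an injected Y segment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import coverage as cov
from . import cq as cqm
from . import ykmer
from .sim import SimConfig, simulate_assembly, simulate_reads

#: minimum male-library read support for a gene to enter recovery statistics
GENE_SUPPORT_MIN = 50


def run_cq_study(seed: int, shared_repeat_fraction: float = 0.0,
                 config: SimConfig | None = None) -> dict:
    """Simulate the standard CQ study and run the analysis end to end.

    The standard study is ten 100 kb scaffolds per compartment at 20x
    haploid depth with error-free reads (the SimConfig defaults).
    """
    if config is None:
        config = SimConfig(seed=seed,
                           shared_repeat_fraction=shared_repeat_fraction)
    assembly, truth = simulate_assembly(config)
    windows = cov.tile_windows(assembly)
    tracks, counts, libs, placements = {}, {}, {}, {}
    for sex in ("female", "male"):
        reads = simulate_reads(assembly, truth, sex, config)
        pl = cov.place_reads(reads, assembly)
        lib = int((pl["status"] == cov.UNIQUE).sum())
        placements[sex] = (reads, pl)
        libs[sex] = lib
        tracks[sex] = cov.window_rpkm(pl, windows, lib, sex=sex)
        counts[sex] = cov.count_gene_reads(pl, truth.genes, assembly)
    records = cqm.region_cq(tracks["female"], tracks["male"])
    tagged = cqm.tag_regions(records, cqm.Thresholds(), 10_000)
    calls = cqm.call_scaffolds(tagged, assembly)
    gcq = cqm.gene_cq(counts["female"], counts["male"], libs["female"],
                      libs["male"])
    ctx = cqm.context_cq(truth.genes, tagged)
    assignments = cqm.assign_genes(gcq, ctx)
    return {"config": config, "assembly": assembly, "truth": truth,
            "tagged": tagged, "calls": calls, "assignments": assignments,
            "gene_counts": counts, "libs": libs, "placements": placements}


def cq_means(study: dict) -> dict[str, float]:
    """Mean defined (finite) window CQ per truth compartment."""
    tagged, truth = study["tagged"], study["truth"]
    comp = tagged["scaffold"].map(truth.scaffold_compartment)
    cq = tagged["cq"].to_numpy()
    out = {}
    for c in ("autosome", "X", "Y"):
        sel = np.isfinite(cq) & (comp == c).to_numpy()
        out[c] = float(cq[sel].mean()) if sel.any() else float("nan")
        out[f"n_{c}"] = int(sel.sum())
    return out


def scaffold_recovery(study: dict) -> dict:
    """Fraction of truth X/Y scaffolds called correctly; autosomal miscalls."""
    calls, truth = study["calls"], study["truth"]
    comp = calls["scaffold"].map(truth.scaffold_compartment)
    call = calls["call"]
    x_sel, y_sel = comp == "X", comp == "Y"
    auto_sel = comp == "autosome"
    x_ok = int((call[x_sel] == cqm.CALL_X).sum())
    y_ok = int((call[y_sel] == cqm.CALL_Y).sum())
    miscalled = int((call[auto_sel] != cqm.CALL_NONE).sum())
    n_xy = int(x_sel.sum() + y_sel.sum())
    return {
        "x_correct": x_ok, "x_total": int(x_sel.sum()),
        "y_correct": y_ok, "y_total": int(y_sel.sum()),
        "auto_miscalled": miscalled, "auto_total": int(auto_sel.sum()),
        "xy_recovery_pct": 100.0 * (x_ok + y_ok) / n_xy if n_xy else 100.0,
    }


def gene_recovery(study: dict, support_min: int = GENE_SUPPORT_MIN) -> dict:
    """Gene-assignment recovery among well-supported genes.

    Support is measured in the male library, which covers every compartment
    (a female-side support filter would exclude all truth-Y genes, whose
    female coverage is zero by construction).
    """
    truth = study["truth"]
    asg = study["assignments"].merge(truth.genes[["gene_id", "compartment"]],
                                     on="gene_id")
    support = (study["gene_counts"]["male"].set_index("gene_id")["count"]
               .reindex(asg["gene_id"]).to_numpy())
    asg = asg[support >= support_min]
    xy = asg[asg["compartment"].isin(["X", "Y"])]
    correct = int((xy["assignment"] == xy["compartment"]).sum())
    auto = asg[asg["compartment"] == "autosome"]
    return {
        "xy_eligible": int(len(xy)), "xy_correct": correct,
        "xy_recovery_pct": 100.0 * correct / len(xy) if len(xy) else 100.0,
        "auto_eligible": int(len(auto)),
        "auto_miscalled": int((auto["assignment"] != cqm.ASSIGN_NONE).sum()),
    }


def run_kmer_study(seed: int, host_length: int = 3_700_000,
                   segment_length: int = 50_000,
                   offset: int = 2_100_000) -> dict:
    """Y-in-autosome misassembly screen: one injected segment, full k-mer scan.

    Simulates one chromosome-scale autosomal scaffold carrying one injected
    Y segment, counts canonical 25-mers in both sexed libraries, and
    measures: soundness (fraction of located male-unique k-mer hits whose
    25 bp span overlaps truth Y material), sensitivity (fraction of injected
    bases covered by merged Y-unique regions) and whether the 1.8 Mb density
    bin containing the injection ranks first on the scaffold.
    """
    config = SimConfig(
        n_autosomal_scaffolds=1, n_x_scaffolds=0, n_y_scaffolds=0,
        scaffold_length_range=(host_length, host_length), seed=seed,
        y_injections=(("auto_01", segment_length, offset),))
    assembly, truth = simulate_assembly(config)
    k = 25
    kf = ykmer.count_kmers(simulate_reads(assembly, truth, "female", config), k)
    km = ykmer.count_kmers(simulate_reads(assembly, truth, "male", config), k)
    unique = ykmer.male_unique(km, kf)
    hits = ykmer.locate_kmers(unique, assembly)
    regions = ykmer.merge_y_regions(hits, k)
    density = ykmer.density_track(regions, assembly)

    inj = truth.injections.iloc[0]
    overlap = ((hits["start"] + k > inj["start"])
               & (hits["start"] < inj["end"])).to_numpy()
    contained = ((hits["start"] >= inj["start"])
                 & (hits["start"] + k <= inj["end"])).to_numpy()
    covered = 0
    for _, r in regions[regions["scaffold"] == inj["scaffold"]].iterrows():
        covered += max(0, min(r["end"], inj["end"]) - max(r["start"],
                                                          inj["start"]))
    host = density[density["scaffold"] == inj["scaffold"]]
    rank_order = host.sort_values("n_bases", ascending=False)
    inj_bin_start = (int(inj["start"]) // 1_800_000) * 1_800_000
    rank = int(np.nonzero((rank_order["start"] == inj_bin_start)
                          .to_numpy())[0][0]) + 1
    return {
        "n_unique_kmers": int(len(unique)),
        "n_hits": int(len(hits)),
        "n_regions": int(len(regions)),
        "soundness_pct": 100.0 * overlap.mean() if len(hits) else 100.0,
        "soundness_contained_pct": (100.0 * contained.mean()
                                    if len(hits) else 100.0),
        "sensitivity_pct": 100.0 * covered / (int(inj["end"])
                                              - int(inj["start"])),
        "injection_bin_rank": rank,
        "n_bins": int(len(host)),
        "density": density,
    }
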