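"""Chromosome-quotient (CQ) computation, window tagging and X/Y calling.

The chromosome quotient of a region or gene is the ratio of female to male
normalized sequencing coverage. Under the XX/XY copy-number model it is ~1
on autosomes (2:2 copies), ~2 on the X (2:1) and ~0 on the Y (0:1). Windows
with CQ strictly above 2 are tagged X, strictly below 0.2 tagged Y;
scaffolds with at least 40% of their length in X- (or Y-) tagged windows
become X- (Y-) candidates; genes are assigned X or Y only when both the
gene CQ and the CQ of the surrounding 10 kb context window pass the same
threshold.

Zero male coverage is handled without pseudocounts: CQ is +inf when only
the female library covers a window (an X signature at any threshold) and
undefined (NaN) when neither library does. An epsilon-pseudocount mode is
available for noisy real data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import Assembly
from .coverage import CoverageTrack

TAG_X, TAG_Y, TAG_NEUTRAL, TAG_UNDEFINED = "X", "Y", "neutral", "undefined"
CALL_X, CALL_Y, CALL_NONE = "X-candidate", "Y-candidate", "unassigned"


@dataclass(frozen=True)
class Thresholds:
    """CQ classification thresholds.

    ``x_min`` and ``y_max`` are exclusive bounds ("above 2" / "below 0.2");
    ``scaffold_min_fraction`` ("at least 40% of their length") is inclusive.
    Windows shorter than ``min_window_fraction`` of the nominal window size
    are left untagged.
    """

    x_min: float = 2.0
    y_max: float = 0.2
    scaffold_min_fraction: float = 0.40
    min_window_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.y_max < self.x_min:
            raise ValueError("need 0 < y_max < x_min")


def _cq_values(f: np.ndarray, m: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Female/male ratio with explicit zero-denominator semantics."""
    if epsilon > 0:
        return (f + epsilon) / (m + epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        cq = np.where(m > 0, f / np.where(m > 0, m, 1.0),
                      np.where(f > 0, np.inf, np.nan))
    return cq


def region_cq(female: CoverageTrack, male: CoverageTrack,
              epsilon: float = 0.0) -> pd.DataFrame:
    """Per-window CQ from one female and one male coverage track.

    Both tracks must share the same window tiling. Returns the window table
    with f_rpkm, m_rpkm and cq columns (tags not yet applied).
    """
    fw, mw = female.windows, male.windows
    key = ["scaffold", "start", "end"]
    if len(fw) != len(mw) or not fw[key].reset_index(drop=True).equals(
            mw[key].reset_index(drop=True)):
        raise ValueError("female and male coverage tracks have different tilings")
    out = fw[key + ["index", "length", "partial"]].copy().reset_index(drop=True)
    out["f_rpkm"] = fw["rpkm"].to_numpy()
    out["m_rpkm"] = mw["rpkm"].to_numpy()
    out["cq"] = _cq_values(out["f_rpkm"].to_numpy(), out["m_rpkm"].to_numpy(),
                           epsilon)
    return out


def tag_regions(records: pd.DataFrame, thresholds: Thresholds = Thresholds(),
                window_size: int | None = None) -> pd.DataFrame:
    """Tag each window X (cq > x_min, including +inf), Y (cq < y_max) or neutral.

    Windows with undefined CQ, or shorter than ``min_window_fraction`` of
    the nominal window size, are tagged undefined.
    """
    out = records.copy()
    cq = out["cq"].to_numpy()
    if window_size is None:
        window_size = int(out["length"].max()) if len(out) else 0
    tag = np.full(len(out), TAG_NEUTRAL, object)
    tag[cq > thresholds.x_min] = TAG_X
    tag[cq < thresholds.y_max] = TAG_Y
    tag[np.isnan(cq)] = TAG_UNDEFINED
    if window_size:
        short = out["length"].to_numpy() < thresholds.min_window_fraction * window_size
        tag[short] = TAG_UNDEFINED
    out["tag"] = tag
    return out


def call_scaffolds(tagged: pd.DataFrame, assembly: Assembly,
                   thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Aggregate window tags into per-scaffold X/Y candidate calls.

    fraction_x (fraction_y) is the total length of X- (Y-) tagged windows
    divided by the full scaffold length (undefined windows included in the
    denominator). A scaffold is an X-candidate when fraction_x >=
    ``scaffold_min_fraction`` (likewise Y); if both qualify the larger
    fraction wins and an exact tie is left unassigned with a warning.
    average_cq is the mean of finite window CQs (the number of excluded
    infinite/undefined windows is reported).
    """
    rows = []
    grouped = dict(tuple(tagged.groupby("scaffold", sort=False)))
    for name in assembly.names:
        L = assembly.length(name)
        grp = grouped.get(name)
        if grp is None:
            rows.append((name, L, 0.0, 0.0, np.nan, 0, 0, CALL_NONE))
            continue
        len_x = int(grp.loc[grp["tag"] == TAG_X, "length"].sum())
        len_y = int(grp.loc[grp["tag"] == TAG_Y, "length"].sum())
        fraction_x, fraction_y = len_x / L, len_y / L
        cq = grp["cq"].to_numpy()
        finite = np.isfinite(cq)
        average_cq = float(np.mean(cq[finite])) if finite.any() else np.nan
        n_excluded = int((~finite).sum())
        call = CALL_NONE
        qx = fraction_x >= thresholds.scaffold_min_fraction
        qy = fraction_y >= thresholds.scaffold_min_fraction
        if qx and qy:
            if fraction_x == fraction_y:
                warnings.warn(f"scaffold {name}: X and Y fractions tie at "
                              f"{fraction_x:.3f}; leaving unassigned", stacklevel=2)
            else:
                call = CALL_X if fraction_x > fraction_y else CALL_Y
        elif qx:
            call = CALL_X
        elif qy:
            call = CALL_Y
        rows.append((name, L, fraction_x, fraction_y, average_cq,
                     n_excluded, len(grp), call))
    return pd.DataFrame(rows, columns=["scaffold", "length", "fraction_x",
                                       "fraction_y", "average_cq",
                                       "n_windows_excluded", "n_windows", "call"])


def gene_cq(gene_counts_female: pd.DataFrame, gene_counts_male: pd.DataFrame,
            library_size_female: int, library_size_male: int,
            epsilon: float = 0.0) -> pd.DataFrame:
    """Library-size-normalized female/male ratio per gene.

    gene_cq = (female count / female library size) /
              (male count / male library size)
    with the same zero-denominator semantics as region CQ.
    """
    if library_size_female <= 0 or library_size_male <= 0:
        raise ValueError("library sizes must be > 0")
    key = ["gene_id", "scaffold", "start", "end"]
    merged = gene_counts_female[key + ["count"]].merge(
        gene_counts_male[key + ["count"]], on=key, suffixes=("_f", "_m"))
    f = merged["count_f"].to_numpy() / library_size_female
    m = merged["count_m"].to_numpy() / library_size_male
    merged["gene_cq"] = _cq_values(f, m, epsilon)
    return merged


def context_cq(genes: pd.DataFrame, tagged: pd.DataFrame) -> pd.DataFrame:
    """CQ of the window containing each gene's midpoint, plus a weighted mean.

    A midpoint landing exactly on a window boundary belongs to the later
    window (half-open convention). For genes spanning several windows a
    length-weighted mean of the finite window CQs is also reported.
    """
    out = genes.copy().reset_index(drop=True)
    ctx = np.full(len(out), np.nan)
    wmean = np.full(len(out), np.nan)
    ctx_tag = np.full(len(out), TAG_UNDEFINED, object)
    grouped = dict(tuple(tagged.groupby("scaffold", sort=False)))
    for i, g in out.iterrows():
        grp = grouped.get(g["scaffold"])
        if grp is None:
            continue
        wstart = grp["start"].to_numpy()
        wend = grp["end"].to_numpy()
        mid = (int(g["start"]) + int(g["end"])) // 2
        j = np.searchsorted(wstart, mid, "right") - 1
        if 0 <= j < len(grp) and mid < wend[j]:
            ctx[i] = grp["cq"].to_numpy()[j]
            ctx_tag[i] = grp["tag"].to_numpy()[j]
        ov = np.minimum(wend, int(g["end"])) - np.maximum(wstart, int(g["start"]))
        sel = ov > 0
        cqv = grp["cq"].to_numpy()[sel]
        w = ov[sel].astype(float)
        fin = np.isfinite(cqv)
        if fin.any():
            wmean[i] = float(np.average(cqv[fin], weights=w[fin]))
    out["context_cq"] = ctx
    out["context_tag"] = ctx_tag
    out["context_cq_weighted"] = wmean
    return out


ASSIGN_X, ASSIGN_Y, ASSIGN_NONE = "X", "Y", "none"


def assign_genes(gene_cqs: pd.DataFrame, context_cqs: pd.DataFrame,
                 thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Joint gene + context criterion: X iff both CQs > x_min, Y iff both < y_max."""
    key = ["gene_id"]
    merged = gene_cqs.merge(
        context_cqs[key + ["context_cq", "context_cq_weighted"]], on=key)
    g = merged["gene_cq"].to_numpy()
    c = merged["context_cq"].to_numpy()
    assignment = np.full(len(merged), ASSIGN_NONE, object)
    assignment[(g > thresholds.x_min) & (c > thresholds.x_min)] = ASSIGN_X
    assignment[(g < thresholds.y_max) & (c < thresholds.y_max)] = ASSIGN_Y
    merged["assignment"] = assignment
    return merged
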