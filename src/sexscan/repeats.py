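"""Repeat-content summaries per called compartment (autosome / X / Y).

Works from an existing soft-masked assembly (lowercase = repeat-annotated)
and, optionally, a RepeatMasker-style ``.out`` annotation table; it does not
run any repeat annotation itself. "Known bases" are non-N bases; all
fractions are over known bases.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .assembly import Assembly
from .cq import CALL_X, CALL_Y

_CLASS_MAP = {
    "LTR": "LTR", "LINE": "LINE", "SINE": "SINE", "DNA": "DNA",
    "Simple_repeat": "Simple_repeat", "Unknown": "Unknown",
    "Low_complexity": "Simple_repeat",
}


def _compartment_of(call: str) -> str:
    if call == CALL_X:
        return "X"
    if call == CALL_Y:
        return "Y"
    return "autosome"


def compartments_from_calls(calls) -> dict[str, str]:
    """Scaffold -> compartment map from a scaffold-call table or dict.

    Unassigned scaffolds are grouped with the autosomes, mirroring how a
    genome-wide repeat comparison treats everything without a sex-linked
    signal.
    """
    if isinstance(calls, dict):
        return dict(calls)
    return {r["scaffold"]: _compartment_of(r["call"])
            for _, r in calls.iterrows()}


def masked_fraction(assembly: Assembly, calls) -> pd.DataFrame:
    """Soft-masked fraction of known (non-N) bases per compartment.

    ``calls`` is a scaffold-call DataFrame from
    :func:`sexscan.cq.call_scaffolds` or a scaffold -> compartment dict.
    Returns one row per compartment plus an "all" row; warns when the
    assembly carries no lowercase bases at all (likely unmasked input).
    """
    comp_of = compartments_from_calls(calls)
    acc: dict[str, np.ndarray] = {}
    for name in assembly.names:
        seq = assembly.sequences[name]
        raw = np.frombuffer(seq.encode("ascii"), np.uint8)
        masked = int(((raw >= 97) & (raw <= 122) & (raw != ord("n"))).sum())
        lower_n = int((raw == ord("n")).sum())
        unknown = int((raw == ord("N")).sum()) + lower_n
        comp = comp_of.get(name, "autosome")
        a = acc.setdefault(comp, np.zeros(3, np.int64))
        a += (len(seq), len(seq) - unknown, masked)
    rows = []
    total = np.zeros(3, np.int64)
    for comp in ("autosome", "X", "Y"):
        if comp not in acc:
            continue
        t, known, m = acc[comp]
        total += acc[comp]
        rows.append((comp, int(t), int(known), int(m),
                     m / known if known else np.nan))
    t, known, m = total
    rows.append(("all", int(t), int(known), int(m),
                 m / known if known else np.nan))
    if m == 0:
        warnings.warn("assembly contains no soft-masked (lowercase) bases; "
                      "was it repeat-masked?", stacklevel=2)
    return pd.DataFrame(rows, columns=["compartment", "total_bases",
                                       "known_bases", "masked_bases",
                                       "masked_fraction"])


def read_repeatmasker_out(path: str) -> pd.DataFrame:
    """Parse a RepeatMasker ``.out`` table (whitespace-delimited, 3-line header).

    Returns scaffold, start, end (converted to 0-based half-open),
    repeat_name, repeat_class.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            if lineno < 3 or not line.strip():
                continue
            f = line.split()
            if len(f) < 11:
                raise ValueError(f"malformed .out line {lineno + 1}: {line!r}")
            scaffold, begin, end = f[4], int(f[5]), int(f[6])
            cls = f[10].split("/")[0]
            rows.append((scaffold, begin - 1, end, f[9],
                         _CLASS_MAP.get(cls, cls)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "repeat_name", "repeat_class"])


def _flatten_length(intervals: np.ndarray) -> int:
    """Total covered length of possibly overlapping (start, end) intervals."""
    if len(intervals) == 0:
        return 0
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    iv = intervals[order]
    total, cur_s, cur_e = 0, int(iv[0, 0]), int(iv[0, 1])
    for s, e in iv[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = int(s), int(e)
        else:
            cur_e = max(cur_e, int(e))
    return total + (cur_e - cur_s)


def class_fractions(annotation: pd.DataFrame | str, calls,
                    assembly: Assembly) -> pd.DataFrame:
    """Per-compartment fraction of known bases in each repeat class.

    ``annotation`` is a parsed table from :func:`read_repeatmasker_out` (or
    a path to a ``.out`` file). Overlapping annotations of one class are
    flattened before summing, so double-annotated bases count once per
    class. Raises when coordinates fall outside the scaffold bounds.
    """
    if isinstance(annotation, str):
        annotation = read_repeatmasker_out(annotation)
    comp_of = compartments_from_calls(calls)
    known = {}
    for name in assembly.names:
        seq = assembly.sequences[name]
        comp = comp_of.get(name, "autosome")
        known[comp] = known.get(comp, 0) + len(seq) - seq.upper().count("N")
    for _, r in annotation.iterrows():
        if r["scaffold"] not in assembly:
            raise ValueError(f"annotation references unknown scaffold "
                             f"{r['scaffold']!r}")
        if not 0 <= r["start"] < r["end"] <= assembly.length(r["scaffold"]):
            raise ValueError(
                f"annotation interval {r['scaffold']}:{r['start']}-{r['end']} "
                "outside scaffold bounds")
    ann = annotation.copy()
    ann["compartment"] = [comp_of.get(s, "autosome") for s in ann["scaffold"]]
    rows = []
    for (comp, cls), grp in ann.groupby(["compartment", "repeat_class"]):
        bases = 0
        for _, sub in grp.groupby("scaffold"):
            bases += _flatten_length(sub[["start", "end"]].to_numpy())
        rows.append((comp, cls, bases,
                     bases / known[comp] if known.get(comp) else np.nan))
    return pd.DataFrame(rows, columns=["compartment", "repeat_class",
                                       "bases", "fraction"])
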