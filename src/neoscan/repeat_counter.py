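"""Concatemer repeat counting in long reads by greedy periodic tiling.

Given one junction-inclusive period unit (for a faithful rolling-circle
product: the single-repeat cDNA plus the junction nucleotide, e.g. 120 bp for
a 119-nt template), each read is tiled with approximate occurrences of the
unit. Tiling anchors at the best-scoring occurrence anywhere in the read, then
extends stepwise in both directions; a segment counts as a full unit when its
edit distance to the unit is at most ``max_edit_frac * len(unit)``. Matched
partial units at the read ends are reported as a fraction, never rounded up.
The orientation (read vs. reverse complement) with more accepted units wins.

Edit distances and occurrence locations come from edlib (infix and
prefix-anchored semiglobal alignment), keeping the procedure linear-time in
read length for multi-kilobase reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import edlib

from ._seq import revcomp


@dataclass
class RepeatCountResult:
    """Per-read repeat count with identity and terminal-partial diagnostics."""

    read_id: str
    n_units: int
    orientation: str  # "forward" | "reverse"
    mean_identity: float
    terminal_partial_fraction: float
    unit_boundaries: list[int] = field(default_factory=list)
    n_resync: int = 0  # tiling restarts after a rejected segment


def _edlib_locs(res) -> tuple[int, list[tuple[int, int]]]:
    return res["editDistance"], res.get("locations") or []


def _tile(read: str, unit: str, thr: int):
    """Greedy bidirectional tiling; returns (units, partial_len, n_resync).

    ``units`` is a list of (start, end, dist) for accepted full units;
    ``partial_len`` sums matched partial-unit bases at the two read ends.
    """
    P = len(unit)
    dist, locs = _edlib_locs(edlib.align(unit, read, mode="HW", task="locations"))
    if dist < 0 or dist > thr or not locs:
        return [], 0, 0
    s, e = locs[0]
    units = [(s, e + 1, dist)]
    n_resync = 0

    # extend rightward
    pos = e + 1
    while len(read) - pos >= P - thr:
        window = read[pos : pos + P + thr]
        d, lc = _edlib_locs(edlib.align(unit, window, mode="SHW", task="locations"))
        if 0 <= d <= thr and lc:
            end = pos + lc[0][1] + 1
            units.append((pos, end, d))
            pos = end
            continue
        # resynchronize: look for the next unit within ~two periods
        d2, lc2 = _edlib_locs(
            edlib.align(unit, read[pos : pos + 2 * P + thr], mode="HW",
                        task="locations")
        )
        if 0 <= d2 <= thr and lc2 and lc2[0][0] > 0:
            n_resync += 1
            units.append((pos + lc2[0][0], pos + lc2[0][1] + 1, d2))
            pos = pos + lc2[0][1] + 1
        else:
            break

    # extend leftward from the anchor
    runit = unit[::-1]
    lpos = units[0][0]
    while lpos >= P - thr:
        window = read[max(0, lpos - P - thr) : lpos]
        d, lc = _edlib_locs(
            edlib.align(runit, window[::-1], mode="SHW", task="locations")
        )
        if 0 <= d <= thr and lc:
            start = lpos - (lc[0][1] + 1)
            units.insert(0, (start, lpos, d))
            lpos = start
        else:
            break

    # matched partial units at the read termini
    partial = 0
    head = read[: units[0][0]]
    if len(head) >= 5:
        d, _ = _edlib_locs(edlib.align(head[::-1], runit, mode="SHW"))
        if 0 <= d <= math.ceil(thr * len(head) / P):
            partial += len(head)
    tail = read[units[-1][1] :]
    if len(tail) >= 5:
        d, _ = _edlib_locs(edlib.align(tail, unit, mode="SHW"))
        if 0 <= d <= math.ceil(thr * len(tail) / P):
            partial += len(tail)
    return units, partial, n_resync


def count_repeats(
    read_seq: str,
    unit: str,
    max_edit_frac: float = 0.15,
    read_id: str = "read",
) -> RepeatCountResult:
    """Count full concatemer repeat units in one read.

    ``unit`` must be one junction-inclusive period (>= 20 nt);
    ``max_edit_frac`` is the per-unit edit-distance budget as a fraction of
    the unit length (default 0.15, suited to long noisy reads; use ~0.05 for
    accurate short reads and 0 for exact tiling).
    """
    if len(unit) < 20:
        raise ValueError(f"unit must be >= 20 nt (got {len(unit)})")
    if not 0 <= max_edit_frac <= 0.3:
        raise ValueError("max_edit_frac must be in [0, 0.3]")
    read_seq = read_seq.upper()
    unit = unit.upper()
    P = len(unit)
    thr = int(max_edit_frac * P)
    fwd = _tile(read_seq, unit, thr)
    rev = _tile(revcomp(read_seq), unit, thr)
    if len(rev[0]) > len(fwd[0]):
        units, partial, n_resync = rev
        orientation = "reverse"
    else:
        units, partial, n_resync = fwd
        orientation = "forward"
    if not units:
        return RepeatCountResult(
            read_id=read_id,
            n_units=0,
            orientation=orientation,
            mean_identity=0.0,
            terminal_partial_fraction=0.0,
            unit_boundaries=[],
        )
    total_dist = sum(u[2] for u in units)
    boundaries = [u[0] for u in units] + [units[-1][1]]
    return RepeatCountResult(
        read_id=read_id,
        n_units=len(units),
        orientation=orientation,
        mean_identity=1.0 - total_dist / (len(units) * P),
        terminal_partial_fraction=min(partial / P, (P - 1) / P),
        unit_boundaries=boundaries,
        n_resync=n_resync,
    )


def count_repeats_readset(reads, unit: str, max_edit_frac: float = 0.15):
    """Apply :func:`count_repeats` over reads (ReadSet / records / pairs)."""
    from .junction_caller import _iter_named_seqs

    return [
        count_repeats(seq, unit, max_edit_frac, read_id=rid)
        for rid, seq in _iter_named_seqs(reads)
    ]


def repeat_histogram(
    results: list[RepeatCountResult],
    normalize: str = "counts",
) -> pd.Series:
    """Repeat-length histogram over reads with >= 1 accepted unit.

    ``normalize``: "counts" (raw), "cpm" (count * 1e6 / total reads in the
    sample, zero-unit reads included in the denominator), or "log10cpm"
    (log10 of CPM, no pseudocount -- empty bins are simply absent).
    """
    if not results:
        raise ValueError("no repeat-count results")
    if normalize not in ("counts", "cpm", "log10cpm"):
        raise ValueError("normalize must be counts, cpm or log10cpm")
    total = len(results)
    counts = pd.Series(
        [r.n_units for r in results if r.n_units >= 1], dtype=int
    ).value_counts().sort_index()
    counts.index.name = "n_units"
    if normalize == "counts":
        return counts
    cpm = counts * 1e6 / total
    if normalize == "cpm":
        return cpm
    import numpy as np

    return pd.Series(np.log10(cpm.to_numpy()), index=cpm.index)


def repeat_length_matrix(
    samples: dict[str, list[RepeatCountResult]],
    normalize: str = "log10cpm",
    max_units: int | None = None,
) -> pd.DataFrame:
    """Samples x repeat-length table (heat-map input, default log10 CPM)."""
    rows = {}
    for name, results in samples.items():
        rows[name] = repeat_histogram(results, normalize=normalize)
    df = pd.DataFrame(rows).T
    df = df.reindex(sorted(df.columns), axis=1)
    if max_units is not None:
        df = df.loc[:, [c for c in df.columns if c <= max_units]]
    df.index.name = "sample"
    return df
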