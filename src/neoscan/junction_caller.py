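"""Junction discovery from soft-clipped alignments to a single-repeat reference.

Reads that extend across a repeat-repeat junction cannot align end-to-end to a
single-repeat cDNA reference: the portion beyond the junction is soft-clipped
(CIGAR 'S'). Remapping those 3' clips back onto the unit reveals the jump
target -- for a faithful rolling-circle product, one inserted junction
nucleotide followed by the cDNA 5' start. This module extracts clip segments,
remaps them into junction calls, scores junction fidelity, counts
junction-spanning reads per strand (with CPM normalization), and calls modal
cDNA end coordinates from alignments.

A built-in fallback aligner (leftmost-longest exact match, remainder
soft-clipped) keeps simulations self-contained; real data can be supplied as
SAM/BAM produced by any external aligner.
"""

from __future__ import annotations

import difflib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio.SeqRecord import SeqRecord

from ._seq import count_overlapping, hamming, revcomp
from .locus_sim import CDNA_SENSE, NCRNA_SENSE, LocusModel, ReadSet


@dataclass
class ClipSegment:
    """A soft-clipped read terminus, reference-oriented.

    ``side`` is relative to the cDNA-sense reference: "3prime" clips hang off
    the right (downstream) end of the aligned portion, which for
    junction-spanning reads is the repeat end. ``anchor_end`` is the reference
    coordinate where the aligned portion ends (start for 5' clips, end for 3').
    """

    read_id: str
    side: str  # "5prime" | "3prime"
    clip_seq: str
    anchor_end: int
    strand: str  # cDNA-sense | ncRNA-sense


@dataclass
class JunctionCall:
    """An inferred repeat-repeat junction aggregated over supporting clips."""

    junction_ref_pos: int
    remap_offset: int
    inserted_nt: str
    expected: bool
    support: int
    strand: str
    ambiguous: bool = False


@dataclass
class RemapResult:
    """Junction calls plus clips that could not be remapped (data, not errors)."""

    calls: list[JunctionCall] = field(default_factory=list)
    unmapped: list[ClipSegment] = field(default_factory=list)


@dataclass
class JunctionSpanningCounts:
    """Per-strand junction-context occurrence counts and CPM."""

    cdna_sense: int
    ncrna_sense: int
    total_reads: int
    k_flank: int

    @property
    def cpm_cdna_sense(self) -> float:
        return self.cdna_sense * 1e6 / self.total_reads

    @property
    def cpm_ncrna_sense(self) -> float:
        return self.ncrna_sense * 1e6 / self.total_reads


@dataclass
class CdnaEnds:
    """Modal cDNA 5'/3' coordinates; ties broken toward smaller coordinates."""

    start: int
    end: int
    span: int
    start_counts: dict[int, int]
    end_counts: dict[int, int]
    tied_starts: list[int]
    tied_ends: list[int]


# ---------------------------------------------------------------------------
# fallback aligner
# ---------------------------------------------------------------------------

def make_header(ref_name: str, ref_len: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": ref_name, "LN": ref_len}],
        }
    )


def _longest_match(read: str, ref: str) -> tuple[int, int, int]:
    m = difflib.SequenceMatcher(None, read, ref, autojunk=False)
    blk = m.find_longest_match(0, len(read), 0, len(ref))
    return blk.a, blk.b, blk.size


def align_reads(
    reads,
    reference: str,
    ref_name: str = "unit",
    min_seed: int = 15,
) -> list[pysam.AlignedSegment]:
    """Leftmost-longest exact-match aligner with remainder soft-clipped.

    Each read (SeqRecord, (id, seq) pair, or ReadSet) is aligned to
    ``reference`` in the orientation giving the longer exact match; anything
    outside the match becomes a soft clip. Reads whose best match is shorter
    than ``min_seed`` are emitted as unmapped records.
    """
    header = make_header(ref_name, len(reference))
    out: list[pysam.AlignedSegment] = []
    for rid, seq in _iter_named_seqs(reads):
        fwd = _longest_match(seq, reference)
        rc = revcomp(seq)
        rev = _longest_match(rc, reference)
        if rev[2] > fwd[2]:
            a_off, r_off, size = rev
            oriented, is_rev = rc, True
        else:
            a_off, r_off, size = fwd
            oriented, is_rev = seq, False
        a = pysam.AlignedSegment(header)
        a.query_name = rid
        a.query_sequence = oriented
        if size < min_seed:
            a.flag = 4
            out.append(a)
            continue
        a.flag = 16 if is_rev else 0
        a.reference_id = 0
        a.reference_start = r_off
        a.mapping_quality = 60
        cigar = []
        if a_off:
            cigar.append((4, a_off))
        cigar.append((0, size))
        tail = len(oriented) - a_off - size
        if tail:
            cigar.append((4, tail))
        a.cigartuples = cigar
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# input plumbing
# ---------------------------------------------------------------------------

def _iter_named_seqs(reads):
    """Yield (id, sequence) in original read orientation from flexible inputs."""
    if isinstance(reads, ReadSet):
        reads = reads.reads
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        fmt = "fastq" if str(reads).endswith(("fastq", "fq")) else "fasta"
        reads = list(SeqIO.parse(str(reads), fmt))
    for i, r in enumerate(reads):
        if isinstance(r, SeqRecord):
            yield r.id, str(r.seq).upper()
        elif isinstance(r, pysam.AlignedSegment):
            seq = r.query_sequence or ""
            yield r.query_name, revcomp(seq) if r.is_reverse else seq
        elif isinstance(r, str):
            yield f"read_{i}", r.upper()
        else:
            rid, seq = r
            yield rid, seq.upper()


def _iter_alignments(alignments):
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_softclips(
    alignments,
    min_clip: int = 10,
    reference_name: str | None = None,
) -> list[ClipSegment]:
    """Extract soft-clipped termini of length >= ``min_clip`` from alignments.

    ``alignments`` may be an iterable of pysam records or a SAM/BAM path. If
    ``reference_name`` is given, records mapped to any other reference raise
    a ValueError (reference/locus mismatch). Unclipped or unmapped reads
    contribute nothing.
    """
    if min_clip < 1:
        raise ValueError("min_clip must be >= 1")
    segments: list[ClipSegment] = []
    for a in _iter_alignments(alignments):
        if a.is_unmapped or not a.cigartuples:
            continue
        if reference_name is not None and a.reference_name != reference_name:
            raise ValueError(
                f"alignment reference {a.reference_name!r} does not match "
                f"locus reference {reference_name!r}"
            )
        strand = NCRNA_SENSE if a.is_reverse else CDNA_SENSE
        seq = a.query_sequence or ""
        first_op, first_len = a.cigartuples[0]
        if first_op == 4 and first_len >= min_clip:
            segments.append(
                ClipSegment(
                    read_id=a.query_name,
                    side="5prime",
                    clip_seq=seq[:first_len],
                    anchor_end=a.reference_start,
                    strand=strand,
                )
            )
        last_op, last_len = a.cigartuples[-1]
        if last_op == 4 and last_len >= min_clip:
            segments.append(
                ClipSegment(
                    read_id=a.query_name,
                    side="3prime",
                    clip_seq=seq[len(seq) - last_len :],
                    anchor_end=a.reference_end,
                    strand=strand,
                )
            )
    return segments


def remap_clips(
    clips: list[ClipSegment],
    locus: LocusModel,
    max_mismatch: int = 0,
    max_insert: int = 3,
    probe_len: int = 20,
) -> RemapResult:
    """Remap 3' soft clips onto the single-repeat cDNA to call junctions.

    Each clip is modelled as 0..``max_insert`` inserted junction bases followed
    by sequence re-entering the unit at some offset. All candidate
    (mismatches, insertion, offset) placements of a ``probe_len`` prefix are
    scored; the call takes the fewest mismatches, then the shortest insertion,
    then the offset closest to the cDNA 5' start (ambiguity flagged).
    Identical (junction position, remap offset, inserted bases, strand) triples
    are aggregated with summed support; unmappable clips are returned
    separately as data.
    """
    if not clips:
        raise ValueError("clip list must be nonempty")
    unit = locus.unit
    T = len(unit)
    agg: dict[tuple, dict] = {}
    unmapped: list[ClipSegment] = []
    for clip in clips:
        if clip.side != "3prime":
            continue
        candidates: list[tuple[int, int, int]] = []
        for ins in range(0, max_insert + 1):
            probe = clip.clip_seq[ins : ins + probe_len]
            if len(probe) < 6:
                break
            for off in range(0, T - len(probe) + 1):
                mm = hamming(probe, unit[off : off + len(probe)])
                if mm <= max_mismatch:
                    candidates.append((mm, ins, off))
        if not candidates:
            unmapped.append(clip)
            continue
        best_mm = min(c[0] for c in candidates)
        pool = [c for c in candidates if c[0] == best_mm]
        best_ins = min(c[1] for c in pool)
        pool = [c for c in pool if c[1] == best_ins]
        off = min(c[2] for c in pool)
        key = (clip.anchor_end, off, clip.clip_seq[:best_ins], clip.strand)
        entry = agg.setdefault(key, {"support": 0, "ambiguous": False})
        entry["support"] += 1
        entry["ambiguous"] |= len(pool) > 1
    calls = [
        JunctionCall(
            junction_ref_pos=pos,
            remap_offset=off,
            inserted_nt=ins,
            expected=(
                off == 0 and ins == locus.junction_nt and pos == T
            ),
            support=v["support"],
            strand=strand,
            ambiguous=v["ambiguous"],
        )
        for (pos, off, ins, strand), v in sorted(agg.items())
    ]
    return RemapResult(calls=calls, unmapped=unmapped)


def junction_fidelity(calls: list[JunctionCall]) -> float:
    """Support-weighted fraction of junction calls matching the expected jump."""
    total = sum(c.support for c in calls)
    if total <= 0:
        raise ValueError("junction fidelity requires nonzero total support")
    return sum(c.support for c in calls if c.expected) / total


def called_period(calls: list[JunctionCall]) -> int:
    """Modal inter-repeat period implied by junction calls.

    Each call implies a distance between successive repeat starts of
    ``junction_ref_pos - remap_offset + len(inserted_nt)``; the support-
    weighted mode is returned (ties toward the smaller period).
    """
    if not calls:
        raise ValueError("no junction calls")
    weights: Counter = Counter()
    for c in calls:
        weights[c.junction_ref_pos - c.remap_offset + len(c.inserted_nt)] += (
            c.support
        )
    return min(p for p, w in weights.items() if w == max(weights.values()))


def count_junction_spanning(
    reads_or_alignments,
    locus: LocusModel,
    k_flank: int = 10,
    mismatches: int = 0,
) -> JunctionSpanningCounts:
    """Count junction-context occurrences per strand, CPM-normalized.

    A junction occurrence is an exact (or <= ``mismatches``) match to the
    context ``unit[-k_flank:] + junction_nt + unit[:k_flank]``; matches to its
    reverse complement are counted on the ncRNA-sense strand.
    """
    if k_flank < 5:
        raise ValueError("k_flank must be >= 5")
    ctx = locus.junction_context(k_flank)
    rc_ctx = revcomp(ctx)
    fwd = rev = 0
    total = 0
    for _, seq in _iter_named_seqs(reads_or_alignments):
        total += 1
        if mismatches == 0:
            fwd += count_overlapping(seq, ctx)
            rev += count_overlapping(seq, rc_ctx)
        else:
            for i in range(len(seq) - len(ctx) + 1):
                win = seq[i : i + len(ctx)]
                if hamming(win, ctx) <= mismatches:
                    fwd += 1
                elif hamming(win, rc_ctx) <= mismatches:
                    rev += 1
    if total == 0:
        raise ValueError("no reads supplied")
    return JunctionSpanningCounts(
        cdna_sense=fwd, ncrna_sense=rev, total_reads=total, k_flank=k_flank
    )


def call_cdna_ends(alignments) -> CdnaEnds:
    """Modal alignment start/end coordinates (clip-aware) and their span.

    Soft clips never extend the called ends: the clipped junction side anchors
    at the end of the aligned portion. Ties break toward the smaller
    coordinate; all tied modes are retained in the diagnostics fields.
    """
    starts: Counter = Counter()
    ends: Counter = Counter()
    for a in _iter_alignments(alignments):
        if a.is_unmapped:
            continue
        starts[a.reference_start] += 1
        ends[a.reference_end] += 1
    if not starts:
        raise ValueError("no aligned records")

    def modal(c: Counter) -> tuple[int, list[int]]:
        top = max(c.values())
        tied = sorted(k for k, v in c.items() if v == top)
        return tied[0], tied

    start, tied_starts = modal(starts)
    end, tied_ends = modal(ends)
    return CdnaEnds(
        start=start,
        end=end,
        span=end - start,
        start_counts=dict(starts),
        end_counts=dict(ends),
        tied_starts=tied_starts,
        tied_ends=tied_ends,
    )
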