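"""Simulation of DRT2-like loci and rolling-circle reverse transcription (RCRT).

A DRT2-like locus is a non-coding RNA (ncRNA) carrying a reverse-transcription
template region flanked by two copies of a short jump motif (by default ACA).
The reverse transcriptase reads the template RNA 3'->5'; when it reaches the
motif at the synthesis-terminal (RNA 5') edge of the template (ACA-1), the
nascent cDNA 3' end (5'-TGT-3') re-anneals to the homologous motif just beyond
the RNA 3' edge of the template inside stem-loop SL2 (ACA-2). Continued
synthesis then copies one extra base -- the junction nucleotide -- before
re-entering the template, so an n-repeat concatemer has length
``n*T + (n-1)`` for template length ``T`` and a repeat period of ``T + 1``.

This module builds such loci (optionally designing a stop-codon-free circular
reading frame, a ribosome binding site plus start codon, and a sigma70-style
promoter laid across the repeat junction), synthesizes first-strand and duplex
concatemer molecules, emits neo mRNA-like transcripts, and simulates short- and
long-platform sequencing reads with a complete ground-truth table.

Coordinates are 0-based half-open throughout. Strands are named "cDNA-sense"
(the first-strand cDNA / neo mRNA orientation) and "ncRNA-sense".
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import DNA, STOP_CODONS, complement, revcomp

TRUTH_COLUMNS = [
    "read_id",
    "molecule_id",
    "true_n_repeats",
    "strand",
    "start_offset",
    "error_rate",
    "seed",
]

CDNA_SENSE = "cDNA-sense"
NCRNA_SENSE = "ncRNA-sense"

_NONSTOP_CODONS = [
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in STOP_CODONS
]

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"
SD_HEXAMER = "AGGAGG"


class LocusDesignError(ValueError):
    """Raised when locus constraints are unsatisfiable; names the constraint."""


class StrandStateError(ValueError):
    """Raised on first-strand/duplex state violations."""


@dataclass
class LocusModel:
    """A DRT2-like locus: ncRNA, template region, jump motifs, annotations.

    ``designed_frame``, ``rbs_interval`` and ``start_offset`` refer to the
    cDNA-sense period unit (template length + 1 nt, junction-inclusive).
    """

    locus_id: str
    ncrna_seq: str
    template_interval: tuple[int, int]
    aca1_interval: tuple[int, int]
    aca2_interval: tuple[int, int]
    stem_loops: list[tuple[str, int, int]] = field(default_factory=list)
    junction_nt: str = "A"
    designed_frame: int | None = None
    rbs_interval: tuple[int, int] | None = None
    start_offset: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- derived sequences -------------------------------------------------
    @property
    def template(self) -> str:
        """Template region in ncRNA sense, 5'->3'."""
        s, e = self.template_interval
        return self.ncrna_seq[s:e]

    @property
    def template_length(self) -> int:
        s, e = self.template_interval
        return e - s

    @property
    def unit(self) -> str:
        """Single-repeat cDNA (cDNA sense, 5'->3'); length = template length."""
        return revcomp(self.template)

    @property
    def period(self) -> int:
        """Repeat period in bp: template length + 1 (the junction nucleotide)."""
        return self.template_length + 1

    @property
    def period_unit(self) -> str:
        """One junction-inclusive period in cDNA sense: unit + junction_nt."""
        return self.unit + self.junction_nt

    def junction_context(self, k_flank: int) -> str:
        """cDNA-sense k-mer context across the junction:
        last ``k_flank`` nt of the unit + junction nt + first ``k_flank`` nt."""
        if k_flank > self.template_length:
            raise ValueError(
                "junction context requires k_flank <= template length"
            )
        u = self.unit
        return u[-k_flank:] + self.junction_nt + u[:k_flank]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        ts, te = self.template_interval
        if not (0 <= ts < te <= len(self.ncrna_seq)):
            raise LocusDesignError("template_interval must lie within the ncRNA")
        if te - ts < 30:
            raise LocusDesignError(
                f"template length must be >= 30 nt (got {te - ts})"
            )
        a1s, a1e = self.aca1_interval
        a2s, a2e = self.aca2_interval
        if a1e - a1s != 3 or a2e - a2s != 3:
            raise LocusDesignError("jump motifs must be 3 nt")
        if self.ncrna_seq[a1s:a1e] != self.ncrna_seq[a2s:a2e]:
            raise LocusDesignError(
                "ACA-1 and ACA-2 sequences must be identical (jump homology)"
            )
        if a2s < te and a2e > ts:
            raise LocusDesignError("ACA-2 must not overlap the template region")
        if len(self.junction_nt) != 1 or self.junction_nt not in DNA:
            raise LocusDesignError("junction_nt must be a single A/C/G/T base")
        if self.designed_frame is not None:
            if self.designed_frame not in (0, 1, 2):
                raise LocusDesignError("designed_frame must be 0, 1 or 2")
            p = self.period
            if p % 3 != 0:
                raise LocusDesignError(
                    "designed frame requires period (template length + 1) "
                    f"divisible by 3 (period {p})"
                )
            if _circular_frame_stops(self.period_unit, self.designed_frame):
                raise LocusDesignError(
                    f"circular frame {self.designed_frame} of the period unit "
                    "contains a stop codon"
                )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stem_loops"] = [list(sl) for sl in self.stem_loops]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LocusModel":
        d = dict(d)
        d["template_interval"] = tuple(d["template_interval"])
        d["aca1_interval"] = tuple(d["aca1_interval"])
        d["aca2_interval"] = tuple(d["aca2_interval"])
        d["stem_loops"] = [tuple(sl) for sl in d["stem_loops"]]
        if d.get("rbs_interval") is not None:
            d["rbs_interval"] = tuple(d["rbs_interval"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LocusModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ConcatemerMolecule:
    """A first-strand or duplex concatemeric cDNA.

    ``seq`` is always stored in first-strand (cDNA-sense) coordinates;
    the duplex second strand is its reverse complement.
    """

    molecule_id: str
    locus_id: str
    seq: str
    n_repeats: int
    junction_offsets: list[int]
    strand_state: str  # "first_strand" | "duplex"
    period: int
    regular: bool = True  # False for aberrant-jump (SL2-mutant-like) products

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.strand_state not in ("first_strand", "duplex"):
            raise ValueError("strand_state must be first_strand or duplex")
        if len(self.junction_offsets) != self.n_repeats - 1:
            raise ValueError("junction count must equal n_repeats - 1")
        if self.regular:
            for a, b in zip(self.junction_offsets, self.junction_offsets[1:]):
                if b - a != self.period:
                    raise ValueError(
                        "successive junction offsets must differ by the period"
                    )

    @property
    def second_strand(self) -> str:
        if self.strand_state != "duplex":
            raise StrandStateError(
                "second strand only exists for duplex molecules"
            )
        return revcomp(self.seq)


@dataclass
class ReadSet:
    """Simulated reads plus a complete ground-truth table."""

    reads: list[SeqRecord]
    truth: pd.DataFrame
    platform: str  # "short" | "long"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids must be unique")
        if set(ids) != set(self.truth["read_id"]):
            raise ValueError("truth table must cover every read exactly once")


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

def _circular_frame_stops(unit: str, frame: int) -> bool:
    """True if circular frame ``frame`` of ``unit`` (len % 3 == 0) hits a stop."""
    doubled = unit + unit
    return any(
        doubled[i : i + 3] in STOP_CODONS
        for i in range(frame, frame + len(unit), 3)
    )


def _place_promoter(P: int, frame: int | None) -> dict[int, str]:
    """Choose junction-spanning -35/-10 placements on the circular period.

    Avoids planting a stop codon into the designed frame: TTGACA carries TGA at
    offset 1 and TATAAT carries TAA at offset 2, so those offsets must fall
    outside the designed frame's codon phase.
    """
    for p10 in range(3, 9):
        for spacer in (17, 16, 18, 15, 19):
            p35 = (p10 - 6 - spacer) % P
            if p35 <= p10:  # must wrap around the junction
                continue
            if frame is not None:
                if (p10 + 2 - frame) % 3 == 0:
                    continue
                if (p35 + 1 - frame) % 3 == 0:
                    continue
            placement: dict[int, str] = {}
            for i, b in enumerate(MINUS35):
                placement[(p35 + i) % P] = b
            for i, b in enumerate(MINUS10):
                placement[(p10 + i) % P] = b
            return placement
    raise LocusDesignError(
        "no junction-spanning promoter placement is compatible with the "
        "requested designed frame"
    )


def _design_period_unit(
    T: int,
    frame: int | None,
    with_rbs_start: bool,
    with_promoter: bool,
    jump_motif: str,
    rng: np.random.Generator,
    max_attempts: int = 2000,
) -> tuple[str, int | None, tuple[int, int] | None]:
    """Sample a period unit (unit + junction nt) satisfying all constraints.

    Returns (period_unit, start_offset, rbs_interval).
    """
    P = T + 1
    protected: dict[int, str] = {}
    # cDNA 3' terminus templated by the jump motif (ACA -> TGT)
    tgt = revcomp(jump_motif)
    for i, b in enumerate(tgt):
        protected[T - 3 + i] = b
    if with_promoter:
        if P < 60:
            raise LocusDesignError(
                "junction promoter design requires a period >= 60 nt"
            )
        for pos, b in _place_promoter(P, frame).items():
            if pos in protected and protected[pos] != b:
                raise LocusDesignError(
                    "promoter placement collides with the jump motif"
                )
            protected[pos] = b

    start_offset: int | None = None
    rbs_interval: tuple[int, int] | None = None
    if with_rbs_start:
        if frame is None:
            raise LocusDesignError(
                "RBS/start placement requires a designed stop-free frame"
            )
        for s in range(frame + 30, P - 6, 3):
            span = set(range(s, s + 3)) | set(range(s - 13, s - 7))
            if span & set(protected):
                continue
            start_offset = s
            rbs_interval = (s - 13, s - 7)
            for i, b in enumerate("ATG"):
                protected[s + i] = b
            for i, b in enumerate(SD_HEXAMER):
                protected[s - 13 + i] = b
            break
        if start_offset is None:
            raise LocusDesignError(
                "no RBS + start codon placement avoids the other motifs"
            )

    if frame is not None and P % 3 != 0:
        raise LocusDesignError(
            "designed stop-free frame requires period (template length + 1) "
            f"divisible by 3 (period {P})"
        )

    for _ in range(max_attempts):
        seq = list(rng.choice(list(DNA), size=P))
        for pos, b in protected.items():
            seq[pos] = b
        if frame is None:
            return "".join(seq), start_offset, rbs_interval
        ok = True
        for _ in range(60):  # repair rounds
            dirty = False
            for c0 in range(frame, frame + P, 3):
                codon_pos = [c0 % P, (c0 + 1) % P, (c0 + 2) % P]
                codon = "".join(seq[p] for p in codon_pos)
                if codon in STOP_CODONS:
                    if any(p in protected for p in codon_pos):
                        ok = False
                        break
                    repl = _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
                    for p, b in zip(codon_pos, repl):
                        seq[p] = b
                    dirty = True
            if not ok or not dirty:
                break
        if not ok:
            continue
        unit = "".join(seq)
        if _circular_frame_stops(unit, frame):
            continue
        # every other frame must carry at least one stop
        if any(
            not _circular_frame_stops(unit, g) for g in (0, 1, 2) if g != frame
        ):
            continue
        return unit, start_offset, rbs_interval
    raise LocusDesignError(
        "could not satisfy the requested locus constraints "
        f"within {max_attempts} attempts"
    )


def _annotate_stem_loops(
    ts: int, te: int, ncrna_len: int
) -> list[tuple[str, int, int]]:
    """Nominal SL1-SL8 annotations (labels, not structure predictions)."""
    T = te - ts
    sls: list[tuple[str, int, int]] = []
    if ts >= 25:
        sls.append(("SL1", 5, 25))
    # SL2: basal stem bordering the template 3' edge; ACA-2 in its 3' arm
    sls.append(("SL2", max(ts, te - 8), min(ncrna_len, te + 12)))
    width = min(18, T // 5)
    if width >= 6:
        for label, center in (
            ("SL3", ts + T // 5),
            ("SL4", ts + T // 2),
            ("SL5", ts + (4 * T) // 5),
        ):
            s = max(ts, center - width // 2)
            e = min(te - 9, s + width)
            if e - s >= 6:
                sls.append((label, s, e))
    pos = te + 14
    for label in ("SL6", "SL7", "SL8"):
        if pos + 20 <= ncrna_len:
            sls.append((label, pos, pos + 20))
        pos += 30
    return sls


def build_locus(
    template: str | int,
    *,
    designed_frame: int | None = None,
    with_rbs_start: bool | None = None,
    with_promoter: bool | None = None,
    jump_motif: str = "ACA",
    junction_nt: str | None = None,
    leader_len: int = 35,
    scaffold_len: int = 123,
    locus_id: str | None = None,
    seed: int = 0,
) -> LocusModel:
    """Build a DRT2-like locus from a template sequence or a template length.

    When a length is given, the template is designed de novo; requesting
    ``designed_frame`` guarantees that circular frame of the period unit is
    stop-free while every other frame carries at least one stop, and (by
    default) plants a Shine-Dalgarno RBS + ATG start in that frame and a
    sigma70 -35/-10 promoter across the repeat junction. When a template
    sequence is supplied (ncRNA sense, 5'->3'), constraints are verified
    rather than designed.

    Reproducible from ``seed``; raises :class:`LocusDesignError` naming the
    violated constraint when the request is unsatisfiable.
    """
    rng = np.random.default_rng(seed)
    if len(jump_motif) != 3 or any(b not in DNA for b in jump_motif):
        raise LocusDesignError("jump motif must be 3 nt of A/C/G/T")
    if with_rbs_start is None:
        with_rbs_start = designed_frame is not None
    if with_promoter is None:
        with_promoter = designed_frame is not None

    start_offset: int | None = None
    rbs_interval: tuple[int, int] | None = None

    if isinstance(template, int):
        T = template
        if T < 30:
            raise LocusDesignError(
                f"template length must be >= 30 nt (got {T})"
            )
        period_unit, start_offset, rbs_interval = _design_period_unit(
            T, designed_frame, with_rbs_start, with_promoter, jump_motif, rng
        )
        unit, jnt = period_unit[:T], period_unit[T]
        if junction_nt is not None and junction_nt != jnt:
            # honor an explicit junction base if it keeps the design valid
            cand = unit + junction_nt
            if designed_frame is not None and _circular_frame_stops(
                cand, designed_frame
            ):
                raise LocusDesignError(
                    "requested junction_nt creates a stop in the designed frame"
                )
            jnt = junction_nt
        template_seq = revcomp(unit)
    else:
        template_seq = template.upper()
        T = len(template_seq)
        if T < 30:
            raise LocusDesignError(
                f"template length must be >= 30 nt (got {T})"
            )
        if any(b not in DNA for b in template_seq):
            raise LocusDesignError("template must be A/C/G/T only")
        unit = revcomp(template_seq)
        candidates = [junction_nt] if junction_nt else list(DNA)
        jnt = None
        for c in candidates:
            if designed_frame is not None and _circular_frame_stops(
                unit + c, designed_frame
            ):
                continue
            jnt = c
            break
        if jnt is None:
            raise LocusDesignError(
                "no junction nucleotide keeps the designed frame stop-free "
                "for the supplied template"
            )
        jump_motif = template_seq[:3]

    leader = "".join(rng.choice(list(DNA), size=leader_len))
    scaffold = "".join(rng.choice(list(DNA), size=scaffold_len))
    ts = leader_len
    te = ts + T
    # junction-templating base at te, then ACA-2 (copy of ACA-1) inside SL2
    ncrna = leader + template_seq + complement(jnt) + template_seq[:3] + scaffold
    return LocusModel(
        locus_id=locus_id or f"locus_{seed}",
        ncrna_seq=ncrna,
        template_interval=(ts, te),
        aca1_interval=(ts, ts + 3),
        aca2_interval=(te + 1, te + 4),
        stem_loops=_annotate_stem_loops(ts, te, len(ncrna)),
        junction_nt=jnt,
        designed_frame=designed_frame,
        rbs_interval=rbs_interval,
        start_offset=start_offset,
    )


# ---------------------------------------------------------------------------
# molecule synthesis
# ---------------------------------------------------------------------------

def synthesize_concatemer(
    locus: LocusModel,
    n_repeats: int,
    seed: int = 0,
    aberrant_jump_prob: float = 0.0,
    molecule_id: str | None = None,
) -> ConcatemerMolecule:
    """Synthesize a first-strand concatemeric cDNA by template jumping.

    Each faithful jump appends the junction nucleotide and a full repeat
    (period = template length + 1). ``aberrant_jump_prob`` emulates an
    SL2-mutant-like loss of jump fidelity: with that probability a jump
    inserts 0-2 random bases and lands at a random offset within the unit.
    """
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1 (got {n_repeats})")
    rng = np.random.default_rng(seed)
    unit = locus.unit
    parts = [unit]
    offsets: list[int] = []
    length = len(unit)
    regular = True
    for _ in range(n_repeats - 1):
        offsets.append(length)
        if aberrant_jump_prob > 0 and rng.random() < aberrant_jump_prob:
            regular = False
            ins = "".join(rng.choice(list(DNA), size=rng.integers(0, 3)))
            landing = int(rng.integers(1, len(unit)))
            piece = ins + unit[landing:]
        else:
            piece = locus.junction_nt + unit
        parts.append(piece)
        length += len(piece)
    return ConcatemerMolecule(
        molecule_id=molecule_id or f"{locus.locus_id}_x{n_repeats}_s{seed}",
        locus_id=locus.locus_id,
        seq="".join(parts),
        n_repeats=n_repeats,
        junction_offsets=offsets,
        strand_state="first_strand",
        period=locus.period,
        regular=regular,
    )


def make_second_strand(molecule: ConcatemerMolecule) -> ConcatemerMolecule:
    """Phage-induced second-strand synthesis: first_strand -> duplex.

    Junction offsets stay on the first-strand coordinate system; the second
    strand is available as :attr:`ConcatemerMolecule.second_strand`.
    """
    if molecule.strand_state != "first_strand":
        raise StrandStateError("molecule is already duplex")
    return dataclasses.replace(molecule, strand_state="duplex")


def transcribe_neo_mrna(
    molecule: ConcatemerMolecule,
    promoter_offset: int,
    length_distribution,
    seed: int = 0,
    n_transcripts: int = 10,
    rna: bool = False,
) -> list[str]:
    """Emit heterogeneously sized neo mRNA-like transcripts from a duplex.

    Transcripts are substrings of the first-strand (cDNA-sense) sequence
    starting at ``promoter_offset`` (the TSS). ``length_distribution`` may be
    an int (fixed length), a ``(lo, hi)`` tuple (uniform inclusive), or a
    callable taking a numpy Generator and returning a length. Transcription
    requires the phage-induced duplex state.
    """
    if molecule.strand_state != "duplex":
        raise StrandStateError(
            "neo mRNA transcription requires a duplex molecule "
            "(phage-uninduced first-strand cDNA is not transcribed)"
        )
    if not 0 <= promoter_offset < len(molecule.seq):
        raise ValueError("promoter_offset outside the molecule")
    rng = np.random.default_rng(seed)
    if isinstance(length_distribution, int):
        draw = lambda: length_distribution  # noqa: E731
    elif isinstance(length_distribution, tuple):
        lo, hi = length_distribution
        draw = lambda: int(rng.integers(lo, hi + 1))  # noqa: E731
    elif callable(length_distribution):
        draw = lambda: int(length_distribution(rng))  # noqa: E731
    else:
        raise TypeError("length_distribution must be int, (lo, hi) or callable")
    out = []
    for _ in range(n_transcripts):
        L = max(1, draw())
        t = molecule.seq[promoter_offset : promoter_offset + L]
        out.append(t.replace("T", "U") if rna else t)
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base error model, substitutions:insertions:deletions = 2:1:1."""
    if rate == 0:
        return seq
    out: list[str] = []
    r = rng.random(len(seq))
    for base, x in zip(seq, r):
        if x < rate * 0.5:
            choices = [b for b in DNA if b != base]
            out.append(choices[int(rng.integers(3))])
        elif x < rate * 0.75:
            out.append(base)
            out.append(DNA[int(rng.integers(4))])
        elif x < rate:
            pass  # deletion
        else:
            out.append(base)
    return "".join(out)


def simulate_reads(
    molecules: list[ConcatemerMolecule],
    platform: str,
    n_reads: int,
    read_len: int | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Simulate sequencing reads from concatemer molecules with ground truth.

    Long-platform reads cover whole molecules end-to-end; short-platform reads
    are fixed-length substrings at uniform start offsets (clipped to molecule
    bounds). Reads from first-strand molecules are always cDNA-sense (a
    single-stranded molecule exposes only one strand); duplex molecules are
    read from either strand with equal probability.
    """
    if not molecules:
        raise ValueError("molecule list must be nonempty")
    if not 0 <= error_rate <= 0.3:
        raise ValueError(f"error_rate must be in [0, 0.3] (got {error_rate})")
    if platform not in ("short", "long"):
        raise ValueError("platform must be 'short' or 'long'")
    if platform == "short" and read_len is None:
        raise ValueError("short platform requires read_len")
    rng = np.random.default_rng(seed)
    qual = 40 if error_rate == 0 else max(
        2, min(40, round(-10 * math.log10(error_rate)))
    )
    reads: list[SeqRecord] = []
    rows: list[dict] = []
    for i in range(n_reads):
        mol = molecules[int(rng.integers(len(molecules)))]
        if platform == "long":
            start = 0
            frag = mol.seq
        else:
            start = int(rng.integers(0, max(1, len(mol.seq) - read_len + 1)))
            frag = mol.seq[start : start + read_len]
        if mol.strand_state == "duplex" and rng.random() < 0.5:
            strand = NCRNA_SENSE
            frag = revcomp(frag)
        else:
            strand = CDNA_SENSE
        frag = _mutate(frag, error_rate, rng)
        rid = f"{platform}_{i:06d}"
        rec = SeqRecord(Seq(frag), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [qual] * len(frag)
        reads.append(rec)
        rows.append(
            {
                "read_id": rid,
                "molecule_id": mol.molecule_id,
                "true_n_repeats": mol.n_repeats,
                "strand": strand,
                "start_offset": start,
                "error_rate": error_rate,
                "seed": seed,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return ReadSet(reads=reads, truth=truth, platform=platform)
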