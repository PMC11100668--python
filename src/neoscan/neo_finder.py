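"""Detection of never-ending ORFs (neo) in rolling-circle repeat units.

A concatemer whose junction-inclusive period is a multiple of 3 can carry a
reading frame with no stop codon in any repeat -- a stop-codon-less, "never
ending" ORF whose translation yields a repetitive protein (Neo). This module
scans circularized period units for stop-free frames, locates start codons
with Shine-Dalgarno ribosome-binding-site support, finds sigma70-style
-35/-10 promoters laid across the repeat junction, applies the
Crick-Brenner-style frame rule for insertion lengths, translates the
concatenated ORF (bacterial genetic code, table 11), and combines all checks
into an automated accept/reject verdict for homologous loci.

All scans treat the unit as circular by operating on doubled sequences with
hits canonicalized to offsets in ``[0, period)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from ._seq import DNA, STOP_CODONS, hamming, revcomp

SD_HEXAMER = "AGGAGG"
MINUS35 = "TTGACA"
MINUS10 = "TATAAT"

REJECTION_REASONS = (
    "no_jump_homology",
    "period_not_multiple_of_3",
    "no_stop_free_frame",
    "no_start",
    "no_rbs",
)


@dataclass
class StartSite:
    """An in-frame start codon with its best upstream Shine-Dalgarno match."""

    start_offset: int
    start_codon: str
    rbs_score: int  # matches to AGGAGG, 0..6
    rbs_offset: int  # circular offset of the scored hexamer window
    spacer: int  # nt between hexamer end and start codon


@dataclass
class PromoterHit:
    """A -35/-10 promoter pair; offsets canonical in [0, period)."""

    minus35_offset: int
    spacer: int
    minus10_offset: int
    mismatches: int


@dataclass
class NeoGeneModel:
    """A detected neo gene on one junction-inclusive repeat unit."""

    locus_id: str
    period: int
    stop_free_frames: set[int]
    chosen_frame: int | None
    start_offset: int | None
    start_codon: str | None
    rbs_score: int | None
    rbs_offset: int | None
    promoter_hits: list[PromoterHit] = field(default_factory=list)
    repeat_aa: str = ""


@dataclass
class HomologVerdict:
    """Accept/reject outcome of the automated neo detection pipeline."""

    locus_id: str
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)
    model: NeoGeneModel | None = None

    def __post_init__(self) -> None:
        if self.accepted != (not self.rejection_reasons):
            raise ValueError("accepted must equal 'no rejection reasons'")


# ---------------------------------------------------------------------------
# frame scans
# ---------------------------------------------------------------------------

def circular_stop_scan(unit: str) -> set[int]:
    """Frames of the circularized ``unit`` that stay stop-free through repeats.

    For a unit length divisible by 3, frame ``f`` is stop-free iff reading one
    period from offset ``f`` on the doubled unit yields no stop codon. For
    other lengths the reading phase drifts by ``len % 3`` each repeat, so a
    persistent frame exists only if *no* circular position starts a stop codon
    (then every frame survives, returned as {0, 1, 2}); otherwise the set is
    empty.
    """
    unit = unit.upper()
    L = len(unit)
    if L < 3:
        raise ValueError("unit must be at least one codon long")
    doubled = unit + unit
    if L % 3 == 0:
        return {
            f
            for f in (0, 1, 2)
            if all(
                doubled[i : i + 3] not in STOP_CODONS
                for i in range(f, f + L, 3)
            )
        }
    if all(doubled[i : i + 3] not in STOP_CODONS for i in range(L)):
        return {0, 1, 2}
    return set()


def insertion_frame_effect(period: int, insertion_len: int) -> str:
    """Crick-Brenner frame rule for an insertion into the repeat unit.

    The concatenated reading frame is ``"preserved"`` iff the expanded period
    remains a multiple of 3 -- for a period that is already a multiple of 3,
    iff the insertion length is one too; otherwise ``"broken"``.
    """
    if period < 3:
        raise ValueError("period must be >= 3")
    if insertion_len < 0:
        raise ValueError("insertion length must be >= 0")
    return "preserved" if (period + insertion_len) % 3 == 0 else "broken"


# ---------------------------------------------------------------------------
# start codon / RBS
# ---------------------------------------------------------------------------

def _circ(seq: str, start: int, length: int) -> str:
    L = len(seq)
    start %= L
    s = (seq + seq + seq)[start : start + length]
    return s


def start_candidates(
    unit: str,
    frame: int,
    start_codons: tuple[str, ...] = ("ATG", "GTG"),
    spacer_range: tuple[int, int] = (5, 13),
) -> list[StartSite]:
    """All in-frame start codons on the circular unit with their RBS scores.

    Each candidate is scored by the best match count to the Shine-Dalgarno
    hexamer AGGAGG over a circular upstream window whose spacer (hexamer end
    to codon start) spans ``spacer_range`` inclusive.
    """
    unit = unit.upper()
    L = len(unit)
    if L % 3 == 0:
        offsets = range(frame % 3, L, 3)
    else:  # drifting phase: every circular offset is eventually in frame
        offsets = range(L)
    lo, hi = spacer_range
    sites = []
    for o in offsets:
        codon = _circ(unit, o, 3)
        if codon not in start_codons:
            continue
        best = (-1, 0, 0)
        for spacer in range(lo, hi + 1):
            w = (o - spacer - 6) % L
            score = 6 - hamming(_circ(unit, w, 6), SD_HEXAMER)
            if score > best[0]:
                best = (score, w, spacer)
        sites.append(
            StartSite(
                start_offset=o,
                start_codon=codon,
                rbs_score=best[0],
                rbs_offset=best[1],
                spacer=best[2],
            )
        )
    return sites


def find_start_rbs(
    unit: str,
    frame: int,
    start_codons: tuple[str, ...] = ("ATG", "GTG"),
    spacer_range: tuple[int, int] = (5, 13),
) -> StartSite | None:
    """Best start codon in ``frame``: maximal RBS score, then 5'-most offset."""
    sites = start_candidates(unit, frame, start_codons, spacer_range)
    if not sites:
        return None
    return max(sites, key=lambda s: (s.rbs_score, -s.start_offset))


# ---------------------------------------------------------------------------
# junction promoter
# ---------------------------------------------------------------------------

def scan_junction_promoter(
    unit: str,
    max_mismatches: int = 2,
    spacer_range: tuple[int, int] = (15, 19),
) -> list[PromoterHit]:
    """Find -35/-10 promoter pairs that span the repeat junction.

    The unit (one junction-inclusive period, cDNA sense) is doubled and
    scanned for TTGACA / TATAAT matches with at most ``max_mismatches`` each
    and a spacer in ``spacer_range``; only pairs whose footprint crosses the
    junction between the two copies are reported, with the -35 offset
    canonical in ``[0, period)``. A linear single-unit scan can by
    construction never produce a junction-spanning hit.
    """
    unit = unit.upper()
    L = len(unit)
    if L < 60:
        raise ValueError("promoter scan requires a unit of >= 60 nt")
    doubled = unit + unit
    hits = []
    lo, hi = spacer_range
    for p35 in range(0, L):  # canonical -35 positions only
        mm35 = hamming(doubled[p35 : p35 + 6], MINUS35)
        if mm35 > max_mismatches:
            continue
        for spacer in range(lo, hi + 1):
            p10 = p35 + 6 + spacer
            if p10 + 6 > 2 * L:
                continue
            mm10 = hamming(doubled[p10 : p10 + 6], MINUS10)
            if mm10 > max_mismatches:
                continue
            if p35 < L < p10 + 6:  # footprint spans the junction
                hits.append(
                    PromoterHit(
                        minus35_offset=p35,
                        spacer=spacer,
                        minus10_offset=p10 % L,
                        mismatches=mm35 + mm10,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def emit_neo_protein(
    unit: str, frame: int, start_offset: int, n_repeats: int
) -> str:
    """Translate the n-repeat concatemer from ``start_offset`` (table 11).

    ``unit`` is one junction-inclusive period with length a multiple of 3 and
    ``frame`` stop-free; encountering a stop codon signals inconsistent
    inputs and raises ValueError. Trailing bases short of a codon are dropped.
    """
    unit = unit.upper()
    L = len(unit)
    if L % 3 != 0:
        raise ValueError("unit length must be a multiple of 3")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not 0 <= start_offset < L * n_repeats:
        raise ValueError("start_offset outside the concatemer")
    if start_offset % 3 != frame % 3:
        raise ValueError("start_offset is not in the requested frame")
    concat = unit * n_repeats
    coding = concat[start_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate(table=11))
    if "*" in aa:
        raise ValueError(
            "stop codon encountered during neo translation "
            "(frame/start inconsistent with a stop-free unit)"
        )
    return aa


# ---------------------------------------------------------------------------
# homolog pipeline
# ---------------------------------------------------------------------------

def scan_homolog(
    template_seq: str,
    aca1: tuple[int, int],
    aca2_candidate_seq: str,
    junction_nt: str | None = None,
    rbs_threshold: int = 4,
    start_codons: tuple[str, ...] = ("ATG", "GTG"),
    promoter_max_mismatches: int = 2,
    locus_id: str = "homolog",
) -> HomologVerdict:
    """Automated neo detection for one candidate locus.

    Checks, in order: (1) jump homology -- the template motif at ``aca1``
    equals the candidate ACA-2 sequence; (2) period = template length + 1 is
    a multiple of 3; (3) the circularized period unit has a stop-free frame;
    (4) that frame contains a start codon; (5) its RBS score reaches
    ``rbs_threshold``. All failing reasons are reported; on acceptance the
    returned model includes junction-spanning promoter hits and the
    single-repeat Neo peptide.

    The junction nucleotide is unknowable from the template alone; if
    ``junction_nt`` is None each base is tried (A, C, G, T) and the first
    giving a stop-free frame is kept.
    """
    template_seq = template_seq.upper()
    T = len(template_seq)
    if T < 30:
        raise ValueError(f"template length must be >= 30 nt (got {T})")
    a1s, a1e = aca1
    if not (0 <= a1s < a1e <= T) or a1e - a1s != 3:
        raise ValueError("aca1 must be a 3-nt interval within the template")
    reasons: list[str] = []
    if template_seq[a1s:a1e] != aca2_candidate_seq.upper():
        reasons.append("no_jump_homology")
    period = T + 1
    if period % 3 != 0:
        reasons.append("period_not_multiple_of_3")
    unit = revcomp(template_seq)

    jnt_options = [junction_nt.upper()] if junction_nt else list(DNA)
    best_jnt = jnt_options[0]
    frames: set[int] = set()
    for j in jnt_options:
        f = circular_stop_scan(unit + j)
        if f:
            best_jnt, frames = j, f
            break
    period_unit = unit + best_jnt

    chosen_frame: int | None = None
    site: StartSite | None = None
    if not frames:
        reasons.append("no_stop_free_frame")
    else:
        scored = []
        for f in sorted(frames):
            s = find_start_rbs(period_unit, f, start_codons=start_codons)
            if s is not None:
                scored.append((s.rbs_score, -s.start_offset, f, s))
        if not scored:
            reasons.append("no_start")
        else:
            _, _, chosen_frame, site = max(scored)
            if site.rbs_score < rbs_threshold:
                reasons.append("no_rbs")

    promoter_hits = (
        scan_junction_promoter(period_unit, promoter_max_mismatches)
        if period >= 60
        else []
    )

    accepted = not reasons
    model = None
    if accepted:
        assert site is not None and chosen_frame is not None
        repeat_aa = emit_neo_protein(
            period_unit, chosen_frame, site.start_offset, 2
        )[: period // 3]
        model = NeoGeneModel(
            locus_id=locus_id,
            period=period,
            stop_free_frames=frames,
            chosen_frame=chosen_frame,
            start_offset=site.start_offset,
            start_codon=site.start_codon,
            rbs_score=site.rbs_score,
            rbs_offset=site.rbs_offset,
            promoter_hits=promoter_hits,
            repeat_aa=repeat_aa,
        )
    return HomologVerdict(
        locus_id=locus_id,
        accepted=accepted,
        rejection_reasons=reasons,
        model=model,
    )
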