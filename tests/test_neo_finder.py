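"""Stop-free frame scans, start/RBS, junction promoters, homolog verdicts."""

import numpy as np
import pytest

from neoscan import (
    build_locus,
    circular_stop_scan,
    emit_neo_protein,
    find_start_rbs,
    insertion_frame_effect,
    scan_homolog,
    scan_junction_promoter,
    start_candidates,
)
from neoscan._seq import STOP_CODONS, hamming

RNG = np.random.default_rng(2024)


def brute_force_stop_free_frames(unit, n_repeats=10):
    """Oracle: scan an n-repeat concatemer for stops in each frame."""
    concat = unit * n_repeats
    out = set()
    for f in (0, 1, 2):
        codons = [
            concat[i : i + 3] for i in range(f, len(concat) - 2, 3)
        ]
        if not any(c in STOP_CODONS for c in codons):
            out.add(f)
    return out


def naive_promoter_scan(unit, max_mm=2, spacers=range(15, 20)):
    """Oracle: quadratic two-hexamer scan on the doubled unit."""
    L = len(unit)
    doubled = unit + unit
    hits = set()
    for p35 in range(2 * L - 6):
        if hamming(doubled[p35 : p35 + 6], "TTGACA") > max_mm:
            continue
        for sp in spacers:
            p10 = p35 + 6 + sp
            if p10 + 6 > 2 * L:
                continue
            if hamming(doubled[p10 : p10 + 6], "TATAAT") > max_mm:
                continue
            if p35 < L < p10 + 6:
                hits.add((p35, sp, p10 % L))
    return hits


class TestCircularStopScan:
    def test_poly_gct_all_frames_stop_free(self):
        assert circular_stop_scan("GCTGCTGCTGCT") == {0, 1, 2}

    def test_designed_unit_has_one_frame(self, kpn_locus):
        assert len(circular_stop_scan(kpn_locus.period_unit)) == 1

    def test_planted_stop_excludes_frame(self):
        unit = "ATGTAAGCA"  # TAA at codon position 3 of frame 0
        frames = circular_stop_scan(unit)
        assert 0 not in frames
        assert frames == brute_force_stop_free_frames(unit)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            circular_stop_scan("AC")

    @pytest.mark.parametrize("length_mod3", [0, 1, 2])
    def test_matches_brute_force_oracle(self, length_mod3):
        for _ in range(120):
            L = int(RNG.integers(30, 151))
            L -= (L - length_mod3) % 3
            unit = "".join(RNG.choice(list("ACGT"), size=L))
            assert circular_stop_scan(unit) == brute_force_stop_free_frames(
                unit
            ), unit


class TestFindStartRbs:
    def test_planted_rbs_and_start(self, kpn_locus):
        site = find_start_rbs(kpn_locus.period_unit, kpn_locus.designed_frame)
        assert site is not None
        assert site.start_offset == kpn_locus.start_offset
        assert site.start_codon == "ATG"
        assert site.rbs_score == 6

    def test_exhaustive_window_oracle(self, kpn_locus):
        unit = kpn_locus.period_unit
        site = find_start_rbs(unit, 0)
        L = len(unit)
        tripled = unit * 3
        best = -1
        for sp in range(5, 14):
            w = (site.start_offset - sp - 6) % L
            best = max(best, 6 - hamming(tripled[w : w + 6], "AGGAGG"))
        assert site.rbs_score == best

    def test_no_start_returns_none(self):
        unit = "GGC" * 20  # no ATG/GTG in frame 0 (all GGC codons)
        assert find_start_rbs(unit, 0) is None

    def test_concatemer_yields_one_candidate_per_repeat(self, kpn_locus):
        unit = kpn_locus.period_unit
        for n in (2, 3):
            cands = start_candidates(unit * n, kpn_locus.designed_frame)
            top = [c for c in cands if c.rbs_score == 6]
            assert len(top) == n * len(
                [c for c in start_candidates(unit, kpn_locus.designed_frame)
                 if c.rbs_score == 6]
            )

    def test_gtg_start_supported(self):
        # AGGAGG, 7-nt spacer, then GTG at offset 43 (frame 1)
        unit = "GCA" * 10 + "AGGAGG" + "GCAGCAG" + "GTG" + "GCA" * 20 + "GC"
        assert len(unit) % 3 == 0
        sites = start_candidates(unit, 1)
        gtg = [s for s in sites if s.start_offset == 43]
        assert gtg and gtg[0].start_codon == "GTG" and gtg[0].rbs_score == 6


class TestJunctionPromoter:
    def _planted_unit(self, across_junction=True):
        unit = list("GC" * 60)  # motif-free background
        if across_junction:
            # -35 ends 12 nt before the junction, -10 starts 5 nt after it
            for i, b in enumerate("TTGACA"):
                unit[102 + i] = b
            for i, b in enumerate("TATAAT"):
                unit[5 + i] = b  # spacer = 120 - 108 + 5 = 17
        else:
            for i, b in enumerate("TTGACA"):
                unit[20 + i] = b
            for i, b in enumerate("TATAAT"):
                unit[43 + i] = b
        return "".join(unit)

    def test_planted_junction_promoter_found(self):
        unit = self._planted_unit(True)
        hits = scan_junction_promoter(unit, max_mismatches=0)
        assert len(hits) == 1
        (h,) = hits
        assert (h.minus35_offset, h.spacer, h.minus10_offset) == (102, 17, 5)
        assert h.mismatches == 0

    def test_intra_period_promoter_not_junction_spanning(self):
        unit = self._planted_unit(False)
        assert scan_junction_promoter(unit, max_mismatches=0) == []

    def test_matches_naive_oracle(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            unit = "".join(rng.choice(list("ACGT"), size=120))
            got = {
                (h.minus35_offset, h.spacer, h.minus10_offset)
                for h in scan_junction_promoter(unit, max_mismatches=2)
            }
            assert got == naive_promoter_scan(unit, max_mm=2)

    def test_random_units_rarely_hit_at_zero_mismatch(self):
        total = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            unit = "".join(rng.choice(list("ACGT"), size=120))
            total += len(scan_junction_promoter(unit, max_mismatches=0))
        assert total == 0

    def test_short_unit_rejected(self):
        with pytest.raises(ValueError):
            scan_junction_promoter("ACGT" * 10)

    def test_designed_locus_carries_planted_promoter(self, kpn_locus):
        hits = scan_junction_promoter(kpn_locus.period_unit, max_mismatches=0)
        assert len(hits) >= 1


class TestInsertionFrameEffect:
    @pytest.mark.parametrize(
        "ins,effect",
        [(0, "preserved"), (1, "broken"), (2, "broken"), (3, "preserved"),
         (4, "broken"), (5, "broken"), (6, "preserved"), (7, "broken"),
         (8, "broken"), (9, "preserved")],
    )
    def test_rule_on_120bp_period(self, ins, effect):
        assert insertion_frame_effect(120, ins) == effect

    def test_negative_insertion_rejected(self):
        with pytest.raises(ValueError):
            insertion_frame_effect(120, -1)

    def test_agrees_with_stop_scan_on_inserted_units(self, kpn_locus):
        """Inserting GCx3k (stop-free filler) keeps a stop-free frame iff the
        insertion length is a multiple of 3."""
        unit = kpn_locus.period_unit
        s = kpn_locus.start_offset
        for L in range(0, 10):
            filler = ("GCCGCCGCC" * 2)[:L]
            mutated = unit[:s] + filler + unit[s:]
            has_frame = bool(circular_stop_scan(mutated))
            expect = insertion_frame_effect(120, L) == "preserved"
            # out-of-frame insertions may by chance avoid stops only if every
            # rotation is stop-free, which a designed unit never is
            assert has_frame == expect, (L, circular_stop_scan(mutated))


class TestEmitNeoProtein:
    def test_three_identical_repeats(self, kpn_locus):
        unit = kpn_locus.period_unit
        aa = emit_neo_protein(unit, 0, kpn_locus.start_offset, 3)
        per = 40
        first = aa[:per]
        # windows at 40-aa stride are identical until the trailing partial
        assert aa[per : 2 * per] == first
        assert len(aa) == (3 * 120 - kpn_locus.start_offset) // 3

    def test_prefix_property(self, kpn_locus):
        unit = kpn_locus.period_unit
        one = emit_neo_protein(unit, 0, kpn_locus.start_offset, 1)
        two = emit_neo_protein(unit, 0, kpn_locus.start_offset, 2)
        assert two.startswith(one)

    def test_planted_stop_raises(self):
        unit = "ATGTAAGCAGCA"  # TAA in frame 0
        with pytest.raises(ValueError, match="stop"):
            emit_neo_protein(unit, 0, 0, 2)

    def test_non_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            emit_neo_protein("ACGTACGTAC", 0, 0, 2)


class TestScanHomolog:
    def test_designed_locus_accepted(self, kpn_locus):
        v = scan_homolog(
            kpn_locus.template, (0, 3), kpn_locus.template[0:3],
            junction_nt=kpn_locus.junction_nt, locus_id="kpn_like",
        )
        assert v.accepted
        assert v.rejection_reasons == []
        assert len(v.model.repeat_aa) == 40
        assert v.model.period == 120
        assert v.model.rbs_score >= 4
        assert len(v.model.promoter_hits) >= 1

    def test_period_not_multiple_of_3(self):
        locus = build_locus(118, seed=21)
        v = scan_homolog(locus.template, (0, 3), locus.template[0:3])
        assert not v.accepted
        assert "period_not_multiple_of_3" in v.rejection_reasons
        assert (118 + 1) % 3 == 2  # arithmetic oracle

    def test_all_frames_stopped(self):
        # every circular frame carries a stop: template whose cDNA unit is
        # TAA-rich in all phases
        unit = ("TAA" + "TAAT") * 6  # 42 nt, stops in every rotation
        unit = unit[: 41]  # period 42 with junction base
        from neoscan import revcomp

        template = revcomp(unit)
        v = scan_homolog(template, (0, 3), template[0:3], junction_nt="T")
        assert "no_stop_free_frame" in v.rejection_reasons
        assert not v.accepted

    def test_jump_homology_failure(self, kpn_locus):
        v = scan_homolog(kpn_locus.template, (0, 3), "GGG",
                         junction_nt=kpn_locus.junction_nt)
        assert "no_jump_homology" in v.rejection_reasons

    def test_short_template_rejected(self):
        with pytest.raises(ValueError, match=">= 30"):
            scan_homolog("ACA" + "G" * 20, (0, 3), "ACA")

    def test_accepted_iff_no_reasons_invariant(self, kpn_locus):
        for aca2 in (kpn_locus.template[0:3], "GGG"):
            v = scan_homolog(kpn_locus.template, (0, 3), aca2,
                             junction_nt=kpn_locus.junction_nt)
            assert v.accepted == (not v.rejection_reasons)
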