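"""Translation, profile building/calibration, scanning and classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from ltrcensus import (DegradationParams, DomainHit, build_element_template,
                       build_profile_from_alignment, classify_element,
                       render_element, scan_element, six_frame_translate)
from ltrcensus.seedbank import AMINO_ACIDS, BACKGROUND, seed_alignments
from ltrcensus.simulate import degrade_element


class TestSixFrameTranslate:
    def test_standard_code(self):
        frames = {f.frame: f.protein for f in six_frame_translate("ATGGCC")}
        assert frames[1] == "MA"

    def test_stop_rendered_as_star(self):
        frames = {f.frame: f.protein for f in six_frame_translate("TAA")}
        assert frames[1] == "*"

    def test_reverse_complement_swaps_frame_sets(self):
        dna = "ATGGCCATTGTAATGGGCCGCTGAAAGGGTGCCCGATAG"
        rc = str(Seq(dna).reverse_complement())
        fwd = {f.frame: f.protein for f in six_frame_translate(dna)}
        rev = {f.frame: f.protein for f in six_frame_translate(rc)}
        assert {fwd[k] for k in (1, 2, 3)} == {rev[k] for k in (-1, -2, -3)}
        assert {fwd[k] for k in (-1, -2, -3)} == {rev[k] for k in (1, 2, 3)}

    def test_too_short_input(self):
        assert all(f.protein == "" for f in six_frame_translate("AC"))

    def test_coordinate_maps_round_trip(self):
        dna = "ATGGCCATTGTAATGGGCCGCTGAAAGGGTGCCCGA"
        for fr in six_frame_translate(dna):
            if len(fr.protein) < 2:
                continue
            s, e = fr.aa_to_nt(0, 2)
            sub = dna[s:e]
            if fr.frame < 0:
                sub = str(Seq(sub).reverse_complement())
            assert str(Seq(sub).translate()) == fr.protein[:2]


class TestProfiles:
    def test_too_few_seed_sequences(self):
        with pytest.raises(ValueError, match="at least 5"):
            build_profile_from_alignment(["MKV"] * 4)

    def test_degenerate_alignment_consensus_attains_maximum(self):
        seq = "MKVLAWHEAGAWGHEEDINMKVLAW"
        p = build_profile_from_alignment([seq] * 6, name="deg")
        enc = np.array([AMINO_ACIDS.index(a) for a in seq])
        score = p.matrix[np.arange(len(seq)), enc].sum()
        assert score == pytest.approx(p.max_score)

    def test_background_frequency_column_scores_near_zero(self):
        # every column holds each residue exactly once (frequency 1/20) under
        # a uniform background: with a vanishing pseudocount log-odds ~ 0
        bg = np.full(20, 0.05)
        aln = [AMINO_ACIDS[i] * 10 for i in range(20)]
        p = build_profile_from_alignment(aln, pseudocount=1e-9, background=bg,
                                         name="bgcol")
        assert np.abs(p.matrix[:, :20]).max() < 1e-5

    def test_null_calibration_specificity(self, profiles):
        """<=1% of shuffled decoys score above threshold for every profile."""
        rng = np.random.default_rng(42)
        for p in profiles.values():
            decoys = rng.choice(20, size=(1000, p.length), p=BACKGROUND)
            scores = p.matrix[np.arange(p.length), decoys].sum(axis=1)
            assert (scores >= p.score_threshold).mean() <= 0.01

    def test_associations(self, profiles):
        assert profiles["RT_RVT1"].superfamily_association == "Gypsy"
        assert profiles["RT_RVT2"].superfamily_association == "Copia"
        assert profiles["AP_RVP"].superfamily_association == "Copia"
        assert profiles["AP_RVP2"].superfamily_association == "Gypsy"


class TestScanning:
    def test_intact_gypsy_hits_in_layout_order(self, gypsy_template, profiles):
        hits = scan_element(render_element(gypsy_template), profiles, "e")
        plus_one = [h for h in hits if h.frame == 1 and h.domain in
                    {"GAG", "AP_RVP2", "RT_RVT1", "RH_LTR", "INT_rve", "CHROMO"}]
        assert [h.domain for h in sorted(plus_one, key=lambda h: h.nt_start)] \
            == ["GAG", "AP_RVP2", "RT_RVT1", "RH_LTR", "INT_rve", "CHROMO"]

    def test_frameshift_splits_hits_across_frames(self, gypsy_template, profiles):
        seq = render_element(gypsy_template)
        # single-base insertion between AP and RT shifts downstream domains
        cut = gypsy_template.layout_in_element_coords()[1][2] + 10
        shifted = seq[:cut] + "A" + seq[cut:]
        hits = scan_element(shifted, profiles, "e")
        domains = {h.domain: h.frame for h in hits}
        assert domains["GAG"] != domains["RT_RVT1"]
        assert {"GAG", "AP_RVP2", "RT_RVT1", "RH_LTR", "INT_rve"} <= set(domains)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequence_yields_no_hits(self, profiles, seed):
        rng = np.random.default_rng(300 + seed)
        dna = "".join("ACGT"[i] for i in rng.integers(4, size=6000))
        assert scan_element(dna, profiles) == []


def _hit(domain, frame, nt_start, nt_end, score=100.0):
    return DomainHit(element_id="e", domain=domain, frame=frame,
                     aa_start=0, aa_end=10, nt_start=nt_start, nt_end=nt_end,
                     score=score)


class TestClassification:
    def test_gypsy_chromoviral(self):
        hits = [_hit("RT_RVT1", 1, 1000, 1500),
                _hit("RH_LTR", 1, 1600, 2000),
                _hit("INT_rve", 1, 2100, 2500),
                _hit("CHROMO", 1, 2600, 2750)]
        c = classify_element(hits)
        assert (c.superfamily, c.chromoviral, c.functional) == ("Gypsy", True, True)
        assert c.order_consistent

    def test_empty_hits_unclassified(self):
        c = classify_element([])
        assert (c.superfamily, c.chromoviral, c.functional) == \
            ("unclassified", False, False)

    def test_copia_from_order_and_profiles(self):
        hits = [_hit("AP_RVP", 1, 500, 800),
                _hit("INT_rve", 1, 900, 1300),
                _hit("RT_RVT2", 1, 1400, 1900)]
        c = classify_element(hits)
        assert (c.superfamily, c.chromoviral, c.functional) == ("Copia", False, True)

    def test_rt_flanking_domains_do_not_vote(self):
        c = classify_element([_hit("RVT_thumb", 1, 100, 300),
                              _hit("RVT_connect", 1, 350, 500)])
        assert c.superfamily == "unclassified"
        assert not c.functional  # thumb/connect alone is not functionality

    def test_both_superfamilies_flagged_complex(self):
        c = classify_element([_hit("RT_RVT1", 1, 100, 600),
                              _hit("RT_RVT2", 2, 5000, 5500),
                              _hit("AP_RVP", 2, 4000, 4400)])
        assert c.complex_locus
        assert c.superfamily == "Copia"  # 2 Copia votes vs 1 Gypsy

    def test_chromo_on_copia_not_chromoviral(self):
        c = classify_element([_hit("RT_RVT2", 1, 100, 600),
                              _hit("CHROMO", 1, 700, 850)])
        assert c.superfamily == "Copia" and not c.chromoviral

    def test_tie_broken_by_integrase_position(self):
        # one vote each; INT after RH -> Gypsy
        hits = [_hit("RT_RVT1", 1, 1000, 1500),
                _hit("AP_RVP", 1, 500, 800),
                _hit("RH_LTR", 1, 1600, 2000),
                _hit("INT_rve", 1, 2100, 2500)]
        assert classify_element(hits).superfamily == "Gypsy"


class TestStrandSymmetryAndAccuracy:
    def test_strand_symmetry(self, gypsy_template, profiles):
        seq = render_element(gypsy_template)
        rc = str(Seq(seq).reverse_complement())
        a = classify_element(scan_element(seq, profiles))
        b = classify_element(scan_element(rc, profiles))
        assert (a.superfamily, a.chromoviral, a.functional, a.order_consistent) \
            == (b.superfamily, b.chromoviral, b.functional, b.order_consistent)

    @pytest.mark.parametrize("seed", range(3))
    def test_classification_accuracy_on_intact_population(self, profiles, seed):
        from ltrcensus import default_templates
        rng = np.random.default_rng(500 + seed)
        for t in default_templates(seed):
            for _ in range(3):
                seq, _n = degrade_element(t, DegradationParams(), rng)
                c = classify_element(scan_element(seq, profiles))
                assert c.superfamily == t.superfamily
                assert c.chromoviral == t.chromoviral
                assert c.functional
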