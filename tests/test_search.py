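import math

import numpy as np
import pytest

from egvscan.scoring import ScoringScheme, compute_evalue
from egvscan.search import (
    SearchHit,
    revcomp,
    six_frame_translate,
    translated_search,
)
from egvscan.simulate import encode_protein

from _oracles import sw_score
from conftest import random_dna, random_protein


class TestSixFrameTranslate:
    @pytest.mark.parametrize(
        "seq,frame,expected",
        [
            ("ATGAAA", 1, "MK"),
            ("ATG", -1, "H"),  # revcomp CAT
            ("ATGNAA", 1, "MX"),
            ("ATGTAA", 1, "M*"),
            ("ATGAAAG", 2, "*K"),  # offset 1: TGA AAG, trailing G dropped
        ],
    )
    def test_known_frames(self, seq, frame, expected):
        assert six_frame_translate(seq)[frame] == expected

    def test_six_frames_and_lengths(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 100)
        frames = six_frame_translate(seq)
        assert set(frames) == {1, 2, 3, -1, -2, -3}
        for off in (1, 2, 3):
            assert len(frames[off]) == (100 - (off - 1)) // 3
            assert frames[-off] == six_frame_translate(revcomp(seq))[off]

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            six_frame_translate("ATGU")


class TestEvalue:
    def test_linear_in_search_space(self, scheme):
        _, e1 = compute_evalue(50, 100, 10**6, scheme)
        _, e2 = compute_evalue(50, 100, 2 * 10**6, scheme)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_zero_bit_fixed_point(self, scheme):
        s0 = math.log(scheme.K) / scheme.lam
        bit, ev = compute_evalue(s0, 100, 1000, scheme)
        assert bit == pytest.approx(0.0, abs=1e-9)
        assert ev == pytest.approx(100 * 1000, rel=1e-9)

    def test_independent_formula(self, scheme):
        lam, K, S, m, n = 0.267, 0.041, 100, 100, 10**6
        bit, ev = compute_evalue(S, m, n, ScoringScheme(lam=lam, K=K))
        expect_bit = (lam * S - math.log(K)) / math.log(2)
        expect_ev = m * n * 2.0**-expect_bit
        assert bit == pytest.approx(expect_bit, rel=1e-12)
        assert ev == pytest.approx(expect_ev, rel=1e-12)

    def test_monotone_in_score(self, scheme):
        evs = [compute_evalue(s, 50, 1000, scheme)[1] for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))


class TestTranslatedSearch:
    def test_exact_implant_recovered_at_truth_coordinates(self, scheme):
        rng = np.random.default_rng(1)
        prot = random_protein(rng, 100)
        cds = encode_protein(prot, rng, add_stop=False)
        subject = random_dna(rng, 1500) + cds + random_dna(rng, 1500)
        hits = translated_search({"q": prot}, {"c": subject}, scheme, e_max=1e-5)
        top = max(hits, key=lambda h: h.raw_score)
        assert top.pct_identity == 1.0
        assert (top.start, top.end) == (1500, 1500 + 300)
        assert top.strand == "+"

    def test_strand_symmetry(self, scheme):
        rng = np.random.default_rng(2)
        prot = random_protein(rng, 80)
        cds = encode_protein(prot, rng, add_stop=False)
        flank5, flank3 = random_dna(rng, 700), random_dna(rng, 700)
        fwd = translated_search({"q": prot}, {"c": flank5 + cds + flank3}, scheme, e_max=1e-3)
        rev = translated_search({"q": prot}, {"c": flank5 + revcomp(cds) + flank3}, scheme, e_max=1e-3)
        tf = max(fwd, key=lambda h: h.raw_score)
        tr = max(rev, key=lambda h: h.raw_score)
        assert tr.strand == "-" and tf.strand == "+"
        assert tr.raw_score == tf.raw_score
        assert (tr.start, tr.end) == (tf.start, tf.end)

    def test_coordinate_roundtrip(self, scheme):
        """Translating subject[start:end) in the reported frame reproduces
        the aligned subject segment."""
        rng = np.random.default_rng(3)
        prot = random_protein(rng, 90)
        cds = encode_protein(prot, rng, add_stop=False)
        subject = random_dna(rng, 400) + revcomp(cds) + random_dna(rng, 400)
        hits = translated_search({"q": prot}, {"c": subject}, scheme, e_max=1e-3)
        for h in hits:
            seg = subject[h.start : h.end]
            if h.strand == "-":
                seg = revcomp(seg)
            faa = six_frame_translate(subject)[h.frame]
            assert six_frame_translate(seg)[1] == faa[h.subject_aa_from : h.subject_aa_to]

    def test_matches_full_dp_oracle_small(self, scheme):
        rng = np.random.default_rng(4)
        for _ in range(10):
            q = random_protein(rng, int(rng.integers(20, 60)))
            s = random_dna(rng, int(rng.integers(300, 700)))
            hits = translated_search({"q": q}, {"c": s}, scheme, e_max=1e12)
            got = max(h.raw_score for h in hits)
            want = max(sw_score(q, f, scheme.matrix) for f in six_frame_translate(s).values())
            assert got == pytest.approx(want)

    def test_short_query_warned_and_skipped(self, scheme):
        with pytest.warns(UserWarning, match="shorter than word size"):
            hits = translated_search({"q": "MK"}, {"c": "ATGAAA" * 50}, scheme)
        assert hits == []

    def test_empty_subject_is_empty_result(self, scheme):
        assert translated_search({"q": "MKVLAW" * 5}, {}, scheme) == []

    def test_seeded_path_agrees_with_exhaustive(self, scheme):
        """The windowed seed-and-extend path finds the same top hit as full
        per-frame DP when forced onto a long subject."""
        rng = np.random.default_rng(5)
        prot = random_protein(rng, 120)
        cds = encode_protein(prot, rng, add_stop=False)
        subject = random_dna(rng, 9000) + cds + random_dna(rng, 9000)
        seeded = translated_search({"q": prot}, {"c": subject}, scheme, e_max=1e-5, exhaustive_limit=10)
        full = translated_search({"q": prot}, {"c": subject}, scheme, e_max=1e-5)
        assert max(h.raw_score for h in seeded) == max(h.raw_score for h in full)
        assert max(h.raw_score for h in seeded) == pytest.approx(
            max(sw_score(prot, f, scheme.matrix) for f in six_frame_translate(subject).values())
        )
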