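import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egvscan.loci import (
    ExtendedLocus,
    MergedInterval,
    extend_locus,
    merge_hits,
    predict_rep_protein,
    reciprocal_classify,
)
from egvscan.search import SearchHit, revcomp
from egvscan.simulate import (
    ancestral_proteins,
    encode_protein,
    make_reference_library,
    mutate_protein,
)

from _oracles import merge_closure
from conftest import random_dna, random_protein


def _hit(contig, strand, start, end):
    return SearchHit(
        query_id="q", contig_id=contig, start=start, end=end, strand=strand,
        frame=1 if strand == "+" else -1, raw_score=100, bitscore=40,
        evalue=1e-9, pct_identity=0.9, query_from=0, query_to=(end - start) // 3,
    )


class TestMergeHits:
    def test_overlap_merges(self):
        out = merge_hits([_hit("c", "+", 100, 200), _hit("c", "+", 150, 250)])
        assert [(m.start, m.end, m.strand) for m in out] == [(100, 250, "+")]

    def test_strands_kept_separate(self):
        out = merge_hits([_hit("c", "+", 100, 200), _hit("c", "-", 150, 250)])
        assert len(out) == 2

    def test_half_open_adjacency_does_not_merge(self):
        out = merge_hits([_hit("c", "+", 100, 200), _hit("c", "+", 200, 300)])
        assert len(out) == 2

    def test_max_gap_merges_nearby(self):
        out = merge_hits([_hit("c", "+", 100, 200), _hit("c", "+", 205, 300)], max_gap=10)
        assert [(m.start, m.end) for m in out] == [(100, 300)]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=200))
    def test_matches_transitive_closure_oracle(self, raw):
        hits = [_hit("c", "+", a, a + w) for a, w in raw]
        got = sorted((m.start, m.end) for m in merge_hits(hits))
        assert got == merge_closure([(a, a + w) for a, w in raw])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))), st.data())
    def test_idempotent_and_permutation_invariant(self, perm, data):
        raw = [(10 * i, 10 * i + data.draw(st.integers(5, 25))) for i in range(8)]
        base = [(m.start, m.end) for m in merge_hits([_hit("c", "+", a, b) for a, b in raw])]
        permuted = [(m.start, m.end) for m in merge_hits([_hit("c", "+", *raw[i]) for i in perm])]
        assert sorted(base) == sorted(permuted)
        remerged = merge_hits([_hit("c", "+", a, b) for a, b in base])
        assert sorted((m.start, m.end) for m in remerged) == sorted(base)


class TestExtendLocus:
    @pytest.mark.parametrize(
        "core,contig_len,flank,expected",
        [
            ((1200, 1500), 2000, 1000, (200, 2000)),
            ((0, 90), 100000, 1000, (0, 1090)),
            ((500, 600), 100000, 0, (500, 600)),
        ],
    )
    def test_clamped_extension(self, core, contig_len, flank, expected):
        iv = MergedInterval("c", "+", core[0], core[1])
        l = extend_locus(iv, contig_len, flank=flank)
        assert (l.ext_start, l.ext_end) == expected
        assert l.ext_start <= l.core_start < l.core_end <= l.ext_end

    def test_interval_outside_contig_rejected(self):
        with pytest.raises(ValueError):
            extend_locus(MergedInterval("c", "+", 100, 300), 200)


class TestPredictRepProtein:
    def test_intron_free_implant(self, scheme):
        rng = np.random.default_rng(10)
        prot = random_protein(rng, 150)
        locus = random_dna(rng, 500) + encode_protein(prot, rng, add_stop=False) + random_dna(rng, 500)
        result = predict_rep_protein(locus, prot, scheme)
        assert result is not None
        protein, intron, _score, strand = result
        assert intron is None and strand == "+"
        assert protein == prot

    def test_single_gtag_intron_spliced_out(self, scheme):
        rng = np.random.default_rng(11)
        prot = random_protein(rng, 160)
        cds = encode_protein(prot, rng, add_stop=False)
        # split at a codon boundary; intron length not a multiple of 3
        cut = 3 * 80
        intron = "GT" + random_dna(rng, 96) + "AG"  # 100 nt
        locus = random_dna(rng, 400) + cds[:cut] + intron + cds[cut:] + random_dna(rng, 400)
        result = predict_rep_protein(locus, prot, scheme)
        assert result is not None
        protein, intron_model, _score, _strand = result
        assert intron_model is not None
        assert protein == prot

    def test_minus_strand_gene(self, scheme):
        rng = np.random.default_rng(12)
        prot = random_protein(rng, 120)
        locus = random_dna(rng, 300) + revcomp(encode_protein(prot, rng, add_stop=False)) + random_dna(rng, 300)
        protein, intron, _score, strand = predict_rep_protein(locus, prot, scheme)
        assert strand == "-" and protein == prot

    def test_pure_background_yields_no_classified_locus(self, scheme):
        """A locus of host background either fails protein prediction or
        produces a junk fragment that reciprocal classification excludes."""
        rng = np.random.default_rng(13)
        anc = ancestral_proteins()
        result = predict_rep_protein(random_dna(rng, 600), anc["rep"], scheme)
        if result is not None:
            protein, _intron, _score, _strand = result
            classified, excluded = reciprocal_classify(
                {"bg": protein}, make_reference_library(0), scheme
            )
            assert classified == [] and "bg" in excluded


@pytest.fixture(scope="module")
def library():
    return make_reference_library(seed=0)


class TestReciprocalClassify:
    def test_minimum_length_boundary(self, scheme, library):
        anc = ancestral_proteins()
        short = anc["rep"][:89]
        exact = anc["rep"][:90]
        classified, excluded = reciprocal_classify({"short": short, "exact": exact}, library, scheme)
        assert "short" in excluded and "length 89" in excluded["short"]
        assert [c.source_id for c in classified] == ["exact"]

    def test_reference_self_classification(self, scheme, library):
        rid, (label, seq) = next(iter(library.items()))
        classified, _ = reciprocal_classify({rid: seq}, library, scheme)
        assert classified[0].best_ref_label == label
        assert classified[0].best_ref_id == rid
        assert classified[0].best_evalue < 1e-50

    def test_genomovirus_protein_labeled_as_outgroup(self, scheme, library):
        rng = np.random.default_rng(14)
        anc = ancestral_proteins()
        prot = mutate_protein(anc["rep_genomovirus"], 0.05, rng)
        classified, _ = reciprocal_classify({"p": prot}, library, scheme)
        assert classified[0].best_ref_label == "genomovirus"

    def test_empty_library_rejected(self, scheme):
        with pytest.raises(ValueError):
            reciprocal_classify({"p": "MKV" * 40}, {}, scheme)

    def test_unrelated_protein_excluded(self, scheme, library):
        rng = np.random.default_rng(15)
        classified, excluded = reciprocal_classify({"x": random_protein(rng, 120)}, library, scheme)
        assert classified == [] and "no reference hit" in excluded["x"]
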