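import numpy as np
import pytest

from egvscan.selection import (
    CodonAlignment,
    build_codon_alignment,
    codon_differences,
    codon_opportunities,
    site_dnds_test,
    translate_cds,
)
from egvscan.simulate import _evolve_cds, encode_protein

from conftest import random_protein


class TestBuildCodonAlignment:
    def test_gap_expansion_example(self):
        aln = build_codon_alignment({"a": "M-K", "b": "MGK"}, {"a": "ATGAAA", "b": "ATGGGAAAA"})
        assert aln.rows == {"a": "ATG---AAA", "b": "ATGGGAAAA"}

    def test_single_sequence_identity(self):
        aln = build_codon_alignment({"a": "MKV"}, {"a": "ATGAAAGTT"})
        assert aln.rows["a"] == "ATGAAAGTT"

    def test_trailing_stop_trimmed(self):
        aln = build_codon_alignment({"a": "MK"}, {"a": "ATGAAATAA"})
        assert aln.rows["a"] == "ATGAAA"

    def test_translation_mismatch_rejected_with_position(self):
        with pytest.raises(ValueError, match="'b' at protein position 1"):
            build_codon_alignment({"a": "MK", "b": "MR"}, {"a": "ATGAAA", "b": "ATGAAA"})

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            build_codon_alignment({"a": "MK"}, {"a": "ATGAAAA"})

    def test_roundtrip_random_families(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, L = int(rng.integers(3, 8)), int(rng.integers(10, 60))
            prots, cds, rows = {}, {}, {}
            for i in range(n):
                p = random_protein(rng, L)
                gaps = sorted(rng.choice(L + 1, size=int(rng.integers(0, 5)), replace=False))
                row = p
                for g in reversed(gaps):
                    row = row[:g] + "-" + row[g:]
                prots[f"s{i}"] = row
                cds[f"s{i}"] = encode_protein(p, rng, add_stop=False)
            lens = {len(r) for r in prots.values()}
            if len(lens) > 1:  # unequal gap counts -> pad to common length
                m = max(lens)
                prots = {k: v + "-" * (m - len(v)) for k, v in prots.items()}
            aln = build_codon_alignment(prots, cds)
            for k, row in aln.rows.items():
                degapped = row.replace("---", "")
                assert degapped == cds[k]
                assert translate_cds(degapped) == prots[k].replace("-", "")


class TestCountingMachinery:
    def test_synonymous_only_codon_pair(self):
        sd, nd = codon_differences("GGT", "GGC")
        assert (sd, nd) == (1.0, 0.0)

    def test_nonsynonymous_only_codon_pair(self):
        sd, nd = codon_differences("ATG", "CTG")  # M -> L
        assert (sd, nd) == (0.0, 1.0)

    def test_two_step_path_averaging(self):
        sd, nd = codon_differences("TTT", "GTA")
        assert sd + nd == pytest.approx(2.0)

    def test_opportunities_sum_to_non_stop_neighbors(self):
        for codon in ("ATG", "GGG", "TTA", "TGG"):
            s, n = codon_opportunities(codon)
            assert 0 <= s <= 3 and 0 <= n <= 3
            assert s + n <= 3.0 + 1e-9


class TestSiteDnds:
    def _aln(self, rows):
        return CodonAlignment(rows=rows, n_sites=len(next(iter(rows.values()))) // 3)

    def test_invariant_alignment_all_neutral(self):
        rows = {f"s{i}": "ATGAAAGGG" for i in range(4)}
        sites, omega, skipped = site_dnds_test(self._aln(rows))
        assert all(s.dN == 0 and s.dS == 0 and s.classification == "neutral" for s in sites)
        assert omega == 0.0 and skipped == []

    def test_third_position_synonymous_site(self):
        rows = {"a": "GGT", "b": "GGC", "c": "GGA"}
        sites, _, _ = site_dnds_test(self._aln(rows))
        assert sites[0].dS > 0 and sites[0].dN == 0

    def test_all_gap_site_skipped(self):
        rows = {"a": "---AAA", "b": "---AAA", "c": "---AAA"}
        sites, _, skipped = site_dnds_test(self._aln(rows))
        assert skipped == [0] and len(sites) == 1

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        prot = random_protein(rng, 50)
        anc = encode_protein(prot, rng, add_stop=False)
        rows = {f"s{i}": _evolve_cds(anc, 0.5, 0.2, rng) for i in range(5)}
        a = site_dnds_test(self._aln(rows))
        rows2 = dict(reversed(list(rows.items())))
        b = site_dnds_test(self._aln(rows2))
        assert [(s.dN, s.dS, s.p_value) for s in a[0]] == [(s.dN, s.dS, s.p_value) for s in b[0]]
        assert a[1] == b[1]

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            site_dnds_test(self._aln({"a": "AAA", "b": "AAA"}))

    def test_omega_recovery_single_replicate(self):
        rng = np.random.default_rng(2)
        prot = random_protein(rng, 300)
        anc = encode_protein(prot, rng, add_stop=False)
        rows = {f"s{i}": _evolve_cds(anc, 0.2, 0.3, rng) for i in range(8)}
        _, omega, _ = site_dnds_test(self._aln(rows))
        assert omega == pytest.approx(0.2, abs=0.1)

    def test_tree_mode_runs_and_bounds(self):
        rng = np.random.default_rng(3)
        prot = random_protein(rng, 40)
        anc = encode_protein(prot, rng, add_stop=False)
        rows = {f"s{i}": _evolve_cds(anc, 0.5, 0.2, rng) for i in range(4)}
        tree = "((s0,s1),(s2,s3));"
        sites, omega, _ = site_dnds_test(self._aln(rows), tree_newick=tree)
        assert all(0 <= s.p_value <= 1 for s in sites)
        assert omega >= 0
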