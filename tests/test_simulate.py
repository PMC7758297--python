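import numpy as np
import pytest

from egvscan.search import revcomp
from egvscan.selection import site_dnds_test, CodonAlignment, translate_cds
from egvscan.simulate import (
    DegradationModel,
    generate_cotranscripts,
    generate_host_genome,
    generate_methylation_track,
    generate_viral_genome,
    implant_fragments,
    make_bundle,
    make_reference_library,
)
from egvscan.methyl import Feature


class TestHostGenome:
    def test_no_repeats_requested(self):
        contigs, bed = generate_host_genome(1, [1000], 0.5, 0.0, seed=7)
        assert set(contigs) == {"contig1"}
        assert len(contigs["contig1"]) == 1000
        assert set(contigs["contig1"]) <= set("ACGT")
        assert bed == []

    def test_determinism(self):
        a = generate_host_genome(2, [5000, 3000], 0.4, 0.1, seed=7)
        b = generate_host_genome(2, [5000, 3000], 0.4, 0.1, seed=7)
        assert a[0] == b[0]
        assert [(f.contig, f.start, f.end) for f in a[1]] == [(f.contig, f.start, f.end) for f in b[1]]

    def test_gc_within_three_binomial_sd(self):
        contigs, _ = generate_host_genome(1, [100_000], 0.3, 0.0, seed=11)
        s = contigs["contig1"]
        gc = s.count("G") + s.count("C")
        sd = np.sqrt(100_000 * 0.3 * 0.7)
        assert abs(gc - 30_000) <= 3 * sd

    def test_repeats_recorded_and_planted(self):
        contigs, bed = generate_host_genome(1, [200_000], 0.4, 0.08, seed=3)
        total = sum(f.end - f.start for f in bed)
        assert total >= 0.07 * 200_000
        for f in bed:
            assert 0 <= f.start < f.end <= 200_000
            assert f.category == "repeat"

    @pytest.mark.parametrize("kwargs", [
        {"n_contigs": 1, "lengths": [0], "gc": 0.5},
        {"n_contigs": 1, "lengths": [100], "gc": 1.5},
        {"n_contigs": 2, "lengths": [100], "gc": 0.5},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_host_genome(seed=0, repeat_density=0.0, **kwargs)


class TestViralGenome:
    def test_origin_at_position_zero_and_unique(self):
        seq, _ = generate_viral_genome(3500, seed=1)
        assert seq[:9] == "TAATATTAC"
        assert seq.count("TAATATTAC") == 1
        assert "TAATATTAC" not in revcomp(seq)

    def test_rep_at_least_264_aa(self):
        _, truth = generate_viral_genome(3000, seed=2)
        assert len(truth.proteins["rep"]) >= 264

    def test_truth_cds_translate_to_truth_proteins(self):
        seq, truth = generate_viral_genome(3700, seed=3)
        for gene, (s, e) in truth.cds.items():
            assert translate_cds(seq[s:e]) == truth.proteins[gene] + "*"

    def test_seeds_differ_and_determinism(self):
        a1, _ = generate_viral_genome(2800, seed=4)
        a2, _ = generate_viral_genome(2800, seed=4)
        b, _ = generate_viral_genome(2800, seed=5)
        assert a1 == a2 and a1 != b

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_viral_genome(2000, seed=0)


@pytest.fixture(scope="module")
def setup():
    genome, _ = generate_host_genome(2, [300_000, 200_000], 0.4, 0.0, seed=5)
    viral, truth = generate_viral_genome(3500, seed=5)
    return genome, viral, truth


class TestImplantFragments:
    def test_n_zero_is_identity(self, setup):
        genome, viral, _ = setup
        out, truth = implant_fragments(genome, viral, 0, seed=1)
        assert out == genome and truth == []

    def test_zero_degradation_exact_substring(self, setup):
        genome, viral, _ = setup
        out, truth = implant_fragments(genome, viral, 10, DegradationModel(), seed=2)
        for t in truth:
            seg = out[t.contig][t.start : t.end]
            if t.strand == "-":
                seg = revcomp(seg)
            assert seg == t.fragment
            a0, a1 = t.source_span
            assert (viral + viral)[a0:a1] == t.fragment

    def test_hotspot_fraction_one_in_single_window(self, setup):
        genome, viral, _ = setup
        _, truth = implant_fragments(
            genome, viral, 12, DegradationModel(), hotspot_fraction=1.0, seed=3,
            frag_len_range=(600, 1200),
        )
        assert all(t.in_hotspot for t in truth)
        contigs = {t.contig for t in truth}
        assert len(contigs) == 1
        span = max(t.end for t in truth) - min(t.start for t in truth)
        # window plus the material the insertions themselves added
        assert span <= 100_000 + sum(t.end - t.start for t in truth)

    def test_truth_self_consistency_under_degradation(self, setup):
        genome, viral, _ = setup
        model = DegradationModel(sub_rate=0.1, indel_mean=2.0, n_stops=2, truncation_max=0.4)
        out, truth = implant_fragments(genome, viral, 15, model, seed=4)
        for t in truth:
            seg = out[t.contig][t.start : t.end]
            if t.strand == "-":
                seg = revcomp(seg)
            assert seg == t.fragment

    def test_truth_intervals_disjoint(self, setup):
        genome, viral, _ = setup
        _, truth = implant_fragments(genome, viral, 25, DegradationModel(), seed=6)
        by_contig: dict[str, list] = {}
        for t in truth:
            by_contig.setdefault(t.contig, []).append((t.start, t.end))
        for ivs in by_contig.values():
            ivs.sort()
            for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                assert a1 <= b0

    def test_determinism(self, setup):
        genome, viral, _ = setup
        a = implant_fragments(genome, viral, 8, DegradationModel(sub_rate=0.05), seed=9)
        b = implant_fragments(genome, viral, 8, DegradationModel(sub_rate=0.05), seed=9)
        assert a[0] == b[0]
        assert [(t.start, t.end, t.fragment) for t in a[1]] == [(t.start, t.end, t.fragment) for t in b[1]]

    def test_oversized_fragment_rejected(self):
        genome = {"tiny": "ACGT" * 100}
        viral, _ = generate_viral_genome(3500, seed=5)
        with pytest.raises(ValueError, match="longer than"):
            implant_fragments(genome, viral, 1, arcs=[(0, 3500)], seed=0)


class TestCotranscripts:
    def test_single_species_is_ancestor(self):
        tr, coords, cds = generate_cotranscripts(1, seed=1)
        name = next(iter(tr))
        h0, h1 = coords[name]["hsp70"]
        r0, r1 = coords[name]["rep"]
        assert tr[name][h0:h1] == cds["hsp70"][name]
        assert tr[name][r0:r1] == cds["rep"][name]

    def test_omega_zero_all_differences_synonymous(self):
        _, _, cds = generate_cotranscripts(5, omega=0.0, tree_depth=0.3, seed=2)
        prots = {translate_cds(c) for c in cds["rep"].values()}
        assert len(prots) == 1  # no amino-acid change anywhere
        assert len(set(cds["rep"].values())) > 1  # but nucleotides diverged

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            generate_cotranscripts(4, omega=-0.1, seed=0)

    def test_selection_module_recovers_omega(self):
        _, _, cds = generate_cotranscripts(8, omega=0.2, tree_depth=0.3, seed=3)
        rows = cds["rep"]
        aln = CodonAlignment(rows={k: v[:-3] for k, v in rows.items()},
                             n_sites=(len(next(iter(rows.values()))) - 3) // 3)
        _, omega, _ = site_dnds_test(aln)
        assert omega == pytest.approx(0.2, abs=0.1)


class TestMethylationTrack:
    def test_zero_noise_gives_exact_means(self):
        genome = {"c": "CCGG" * 200}
        feats = [Feature("f", "c", 0, 400, "EGV")]
        means = {"EGV": {"CG": 0.8, "CHG": 0.6, "CHH": 0.4}}
        sites = generate_methylation_track(genome, feats, means, noise_sd=0.0, seed=1)
        assert sites, "expected cytosine sites"
        for s in sites:
            assert s.level == means["EGV"][s.context]

    def test_context_assignment_follows_sequence(self):
        genome = {"c": "CGACAGCTT"}  # pos0 CG, pos3 CHG? C-A-G => CHG, pos6 C-T-T => CHH
        feats = [Feature("f", "c", 0, 9, "gene")]
        sites = generate_methylation_track(genome, feats, noise_sd=0.0, seed=0)
        ctx = {s.position: s.context for s in sites}
        assert ctx[0] == "CG" and ctx[3] == "CHG" and ctx[6] == "CHH"

    def test_empty_features_empty_track(self):
        assert generate_methylation_track({"c": "ACGT" * 10}, [], noise_sd=0.1, seed=0) == []

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown feature category"):
            generate_methylation_track(
                {"c": "CCCC"}, [Feature("f", "c", 0, 4, "EGV")],
                mean_levels={"gene": {"CG": 0.1, "CHG": 0.1, "CHH": 0.1}},
            )


class TestBundle:
    def test_bundle_determinism_and_consistency(self):
        a = make_bundle(seed=3, n_contigs=1, contig_length=120_000, n_implants=5, n_genes=8)
        b = make_bundle(seed=3, n_contigs=1, contig_length=120_000, n_implants=5, n_genes=8)
        assert a.genome == b.genome
        assert [(t.start, t.end) for t in a.truth] == [(t.start, t.end) for t in b.truth]
        assert a.transcripts == b.transcripts
        assert [(s.position, s.level) for s in a.methylation] == [(s.position, s.level) for s in b.methylation]
        labels = {label for label, _ in a.viral_refs.values()}
        assert labels == {"geminivirus", "genomovirus", "phytoplasma_plasmid"}
        for t in a.truth:
            assert 0 <= t.start < t.end <= len(a.genome[t.contig])
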