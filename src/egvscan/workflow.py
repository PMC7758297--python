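"""End-to-end orchestration of the EGV survey on a synthetic bundle.

The pipeline mirrors the survey design: generate (or load) inputs, run the
translated Rep search, merge and extend hits into loci, reconstruct and
reciprocally classify the encoded proteins, cluster them, test genomic
hotspot enrichment, scan flanks and transcripts for domain context,
attempt integron reassembly, run the co-transcript selection test, and
compare methylation across feature categories.  The report is a plain
dictionary (JSON-serializable) with per-stage counts, exclusion reasons and
— because the synthetic truth is known — a truth-vs-found confusion table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import assemble as asm
from . import cluster as clu
from . import domains as dom
from . import hotspot as hot
from . import loci as loc
from . import methyl as met
from . import selection as sel
from . import simulate as sim
from .scoring import ScoringScheme
from .search import translated_search

STAGES = ("search", "loci", "cluster", "hotspot", "domains", "assemble", "selection", "methyl")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the survey's documented defaults."""

    seed: int = 0
    # synthetic bundle
    n_contigs: int = 2
    contig_length: int = 500_000
    gc: float = 0.38
    repeat_density: float = 0.05
    n_implants: int = 30
    sub_rate: float = 0.05
    indel_mean: float = 1.0
    n_stops: int = 0
    truncation_max: float = 0.3
    hotspot_fraction: float = 0.4
    viral_length: int = 3500
    n_species: int = 6
    omega: float = 0.2
    tree_depth: float = 0.1
    n_genes: int = 40
    meth_noise_sd: float = 0.1
    arc_mode: str = "random"
    # thresholds
    search_evalue: float = 1e-5
    classify_evalue: float = 1e-5
    group_evalue: float = 1e-20
    domain_evalue: float = 1e-3
    identity_species: float = 0.8
    identity_global: float = 0.7
    min_protein_aa: int = 90
    phylo_min_aa: int = 180
    al1_min_nt: int = 150
    locus_flank: int = 1000
    domain_flank: int = 5000
    merge_max_gap: int = 0
    bin_size: int = 100_000
    k_values: tuple = (21, 33, 55, 77, 99, 127)
    min_cov: float = 5.0
    orf_min_aa: int = 75
    size_range: tuple = (2500, 5000)
    # stage toggles
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        if not (0 < self.identity_global <= self.identity_species <= 1):
            raise ValueError("identity thresholds must satisfy 0 < global <= species <= 1")
        for name in ("search_evalue", "classify_evalue", "group_evalue", "domain_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.locus_flank < 0 or self.domain_flank < 0 or self.bin_size <= 0:
            raise ValueError("flanks must be non-negative and bin_size positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_values"] = list(self.k_values)
        d["size_range"] = list(self.size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "k_values" in d:
            d["k_values"] = tuple(d["k_values"])
        if "size_range" in d:
            d["size_range"] = tuple(d["size_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _flanks(genome: dict[str, str], locus: loc.ExtendedLocus, flank: int) -> dict[str, str]:
    seq = genome[locus.contig_id]
    up = seq[max(0, locus.core_start - flank) : locus.core_start]
    down = seq[locus.core_end : locus.core_end + flank]
    return {f"{locus.locus_id}|up": up, f"{locus.locus_id}|down": down}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured stages on a freshly generated synthetic bundle."""
    report: dict = {"config": config.to_dict(), "stages": {}}
    if not any(config.stages.values()):
        if outdir is not None:
            _write_report(report, outdir)
        return report

    scheme = ScoringScheme()
    bundle = sim.make_bundle(
        seed=config.seed,
        n_contigs=config.n_contigs,
        contig_length=config.contig_length,
        gc=config.gc,
        repeat_density=config.repeat_density,
        n_implants=config.n_implants,
        degradation=sim.DegradationModel(
            sub_rate=config.sub_rate,
            indel_mean=config.indel_mean,
            n_stops=config.n_stops,
            truncation_max=config.truncation_max,
        ),
        hotspot_fraction=config.hotspot_fraction,
        viral_length=config.viral_length,
        n_species=config.n_species,
        omega=config.omega,
        tree_depth=config.tree_depth,
        n_genes=config.n_genes,
        meth_noise_sd=config.meth_noise_sd,
        arc_mode=config.arc_mode,
    )
    report["stages"]["simulate"] = {
        "n_contigs": len(bundle.genome),
        "genome_nt": sum(len(s) for s in bundle.genome.values()),
        "n_implants": len(bundle.truth),
        "n_refs": len(bundle.viral_refs),
        "n_transcripts": len(bundle.transcripts),
        "n_features": len(bundle.features),
        "n_methylation_sites": len(bundle.methylation),
    }

    queries = {rid: seq for rid, (label, seq) in bundle.viral_refs.items() if label == "geminivirus"}
    hits = []
    if config.stages["search"]:
        hits = translated_search(queries, bundle.genome, scheme, e_max=config.search_evalue)
        report["stages"]["search"] = {"n_hits": len(hits), "n_queries": len(queries)}

    extended: list[loc.ExtendedLocus] = []
    gemini: list[loc.ClassifiedRep] = []
    proteins: dict[str, str] = {}
    if config.stages["loci"] and hits:
        merged = loc.merge_hits(hits, max_gap=config.merge_max_gap)
        extended = [
            loc.extend_locus(m, len(bundle.genome[m.contig_id]), flank=config.locus_flank, locus_id=f"locus{i}")
            for i, m in enumerate(merged)
        ]
        dropped: dict[str, str] = {}
        intron_count = 0
        for l in extended:
            guide_hit = max((hits[i] for i in l.source_hits), key=lambda h: h.bitscore)
            locus_seq = bundle.genome[l.contig_id][l.ext_start : l.ext_end]
            pred = loc.predict_rep_protein(locus_seq, queries[guide_hit.query_id], scheme)
            if pred is None:
                dropped[l.locus_id] = "no alignment above zero against guide query"
                continue
            protein, intron, _score, _strand = pred
            proteins[l.locus_id] = protein
            if intron is not None:
                intron_count += 1
        classified, excluded = loc.reciprocal_classify(
            proteins, bundle.viral_refs, scheme, e_max=config.classify_evalue, min_len=config.min_protein_aa
        )
        gemini = [c for c in classified if c.best_ref_label == "geminivirus"]
        report["stages"]["loci"] = {
            "n_merged_loci": len(merged),
            "n_extended_loci": len(extended),
            "n_predicted_proteins": len(proteins),
            "n_with_intron_model": intron_count,
            "n_classified": len(classified),
            "n_geminivirus": len(gemini),
            "n_outgroup": len(classified) - len(gemini),
            "dropped": dropped,
            "excluded": excluded,
        }

    if config.stages["cluster"] and gemini:
        prot_map = {c.source_id: c.protein for c in gemini}
        species_clusters = clu.greedy_cluster(prot_map, config.identity_species, scheme)
        reps = {c.representative_id: prot_map[c.representative_id] for c in species_clusters}
        global_clusters = clu.greedy_cluster(reps, config.identity_global, scheme)
        phylo = {k: v for k, v in reps.items() if len(v) > config.phylo_min_aa}
        groups, ungrouped = clu.similarity_groups(
            {**prot_map, **{rid: s for rid, (_l, s) in bundle.viral_refs.items()}},
            scheme,
            e_threshold=config.group_evalue,
        )
        report["stages"]["cluster"] = {
            "n_species_clusters": len(species_clusters),
            "n_representatives": len(reps),
            "n_global_clusters": len(global_clusters),
            "n_phylo_grade": len(phylo),
            "n_similarity_groups": len(groups),
            "n_ungrouped": len(ungrouped),
        }

    if config.stages["hotspot"] and gemini:
        locus_by_id = {l.locus_id: l for l in extended}
        starts = [(locus_by_id[c.source_id].contig_id, locus_by_id[c.source_id].core_start) for c in gemini]
        counts, widths, _ = hot.bin_counts(starts, {c: len(s) for c, s in bundle.genome.items()}, config.bin_size)
        result = hot.hotspot_pvalue(counts, widths)
        report["stages"]["hotspot"] = {
            "n_bins": result.n_bins,
            "n_loci": result.n_loci,
            "max_count": result.max_count,
            "p_raw": result.p_raw,
            "p_adj": result.p_adj,
        }

    if config.stages["domains"] and gemini:
        locus_by_id = {l.locus_id: l for l in extended}
        contexts: dict[str, str] = {}
        al1_retained: list[str] = []
        core_seqs: dict[str, str] = {}
        al1_profile = next(p for p in bundle.profiles if p.profile_id == "Rep_AL1")
        for c in gemini:
            l = locus_by_id[c.source_id]
            fl = _flanks(bundle.genome, l, config.domain_flank)
            fhits = dom.scan_domains(fl, bundle.profiles, e_max=config.domain_evalue, is_nucleotide=True)
            contexts[l.locus_id] = dom.classify_locus_context(fhits, bundle.profiles)
            core_seqs[l.locus_id] = bundle.genome[l.contig_id][l.core_start : l.core_end]
        al1_retained = dom.filter_al1_fraction(core_seqs, al1_profile, min_nt=config.al1_min_nt, e_max=config.domain_evalue)
        thits = {
            tid: dom.scan_domains({tid: seq}, bundle.profiles, e_max=config.domain_evalue, is_nucleotide=True)
            for tid, seq in bundle.transcripts.items()
        }
        cotx = dom.flag_cotranscripts(thits, bundle.profiles)
        ctx_counts: dict[str, int] = {}
        for v in contexts.values():
            ctx_counts[v] = ctx_counts.get(v, 0) + 1
        report["stages"]["domains"] = {
            "context_counts": ctx_counts,
            "n_al1_retained": len(al1_retained),
            "n_cotranscripts": len(cotx),
            "cotranscripts": cotx,
        }

    if config.stages["assemble"] and gemini:
        locus_by_id = {l.locus_id: l for l in extended}
        slices = []
        for c in gemini:
            l = locus_by_id[c.source_id]
            seq = bundle.genome[l.contig_id]
            slices.append(seq[max(0, l.core_start - config.domain_flank) : l.core_end + config.domain_flank])
        try:
            best, per_k = asm.assemble_loci(slices, config.k_values, min_cov=config.min_cov, size_range=tuple(config.size_range))
        except ValueError:
            best, per_k = [], {}
        entry = {"n_candidates": len(best), "per_k": {str(k): len(v) for k, v in per_k.items()}}
        if best:
            cand = best[0]
            if cand.circular:
                asm.circularize_at_origin(cand)
            orfs = asm.find_orfs(
                cand.sequence, cand.circular, min_aa=config.orf_min_aa,
                reference_proteins={g: p for g, p in bundle.viral_truth.proteins.items()}, scheme=scheme,
            )
            cand.orfs = orfs
            entry.update({
                "best_length": len(cand.sequence),
                "best_circular": cand.circular,
                "best_coverage": round(cand.mean_coverage, 2),
                "origin_flag": cand.origin_flag,
                "n_orfs": len(orfs),
            })
        report["stages"]["assemble"] = entry

    if config.stages["selection"] and len(bundle.transcripts) >= 3:
        sel_entry = {}
        for gene in ("rep", "hsp70"):
            cds = {
                t: bundle.transcripts[t][bundle.transcript_cds[t][gene][0] : bundle.transcript_cds[t][gene][1]]
                for t in bundle.transcripts
            }
            prot_rows = {t: sel.translate_cds(c)[:-1] for t, c in cds.items()}
            aln = sel.build_codon_alignment(prot_rows, cds)
            sites, omega_hat, skipped = sel.site_dnds_test(aln)
            sel_entry[gene] = {
                "global_omega": round(omega_hat, 4),
                "n_sites": len(sites),
                "n_purifying": sum(1 for s in sites if s.classification == "purifying"),
                "n_positive": sum(1 for s in sites if s.classification == "positive"),
                "n_skipped": len(skipped),
            }
        report["stages"]["selection"] = sel_entry

    if config.stages["methyl"]:
        values = met.feature_methylation(bundle.features, bundle.methylation)
        table, skipped = met.compare_methylation(values)
        report["stages"]["methyl"] = {
            "tests": [
                {"context": t.context, "pair": f"{t.category_a}-vs-{t.category_b}", "statistic": t.statistic,
                 "p": t.p_value, "method": t.method}
                for t in table
            ],
            "skipped": skipped,
        }

    # truth-vs-found confusion table
    if config.stages["loci"]:
        locus_by_id = {l.locus_id: l for l in extended}
        gem_loci = [locus_by_id[c.source_id] for c in gemini]
        # an implant counts as discoverable when it retains >= 90 aa of Rep;
        # it is recovered when some classified locus core covers >= 80% of
        # that Rep-bearing sub-interval
        recovered = 0
        n_discoverable = 0
        matched_loci: set[str] = set()
        for t in bundle.truth:
            for l in gem_loci:
                if l.contig_id == t.contig and min(l.core_end, t.end) - max(l.core_start, t.start) > 0:
                    matched_loci.add(l.locus_id)
            det = sim.detectable_rep_interval(t, bundle.viral_truth, len(bundle.viral_genome))
            if det is None or det[1] - det[0] < 3 * config.min_protein_aa:
                continue
            n_discoverable += 1
            best_frac = 0.0
            for l in gem_loci:
                if l.contig_id != t.contig:
                    continue
                ov = min(l.core_end, det[1]) - max(l.core_start, det[0])
                if ov > 0:
                    best_frac = max(best_frac, ov / (det[1] - det[0]))
            if best_frac >= 0.8:
                recovered += 1
        false_loci = [l.locus_id for l in gem_loci if l.locus_id not in matched_loci]
        report["confusion"] = {
            "n_truth": len(bundle.truth),
            "n_discoverable": n_discoverable,
            "n_recovered": recovered,
            "recall": recovered / n_discoverable if n_discoverable else 1.0,
            "n_false_loci": len(false_loci),
            "false_loci": false_loci,
        }

    if outdir is not None:
        _write_outputs(report, bundle, extended, gemini, proteins, outdir)
    return report


def _write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_outputs(report, bundle, extended, gemini, proteins, outdir) -> None:
    from . import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(bundle.genome, outdir / "genome.fna")
    eio.write_fasta({rid: s for rid, (_l, s) in bundle.viral_refs.items()}, outdir / "viral_refs.faa")
    eio.write_fasta(bundle.transcripts, outdir / "transcripts.fna")
    eio.write_bed(bundle.features, outdir / "features.bed")
    eio.write_methylation_tsv(bundle.methylation, outdir / "methylation.tsv")
    truth_features = [
        met.Feature(f"{t.source_id}|{t.strand}", t.contig, t.start, t.end, "EGV") for t in bundle.truth
    ]
    eio.write_bed(truth_features, outdir / "truth.bed")
    if proteins:
        eio.write_fasta(proteins, outdir / "predicted_proteins.faa")
    if extended:
        gem_ids = {c.source_id for c in gemini}
        eio.write_loci_bed([l for l in extended if l.locus_id in gem_ids], {}, outdir / "egv_loci.bed")
    _write_report(report, outdir)
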