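"""End-to-end orchestration: simulate -> search -> loci -> annotate ->
subtype -> copy number -> phylogenetics, with a species-level summary.

Each stage writes its artifacts under the output directory; the summary TSV
is the machine twin of the published presence/characteristics tables
(core-gene count, classification, locus/subtype counts, copy number,
fusion status, intactness)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate as ann
from . import copynum as cn
from . import loci as loci_mod
from . import phylo as ph
from . import subtypes as st
from ._seq import revcomp
from .config import RunConfig
from .genome import GenomeAssembly, write_fastq, write_protein_fasta
from .loci import build_presence, classify_species, extract_locus_sequence, merge_hit_loci
from .search import Hit, ProteinQuery, search_many, write_hits_tsv
from .simulate import (
    CORE_GENES,
    EXTRA_GENES,
    TRANSPOSASE,
    DEFAULT_CATALOG,
    DEFAULT_GENE_LENGTHS,
    build_viral_element,
    insert_element_copies,
    simulate_host_genome,
    simulate_reads,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SpeciesSummary:
    species_id: str
    gene_presence: dict[str, bool]
    n_genes_present: int
    classification: str
    n_loci: int
    n_subtypes: int | None = None
    copy_number: float | None = None
    copy_number_ci: tuple[float, float] | None = None
    fusion_status: list[str] = field(default_factory=list)
    fusion_neighbors: list[str] = field(default_factory=list)
    tir_found: list[bool] = field(default_factory=list)
    tsd: list[str] = field(default_factory=list)
    intactness: list[str] = field(default_factory=list)
    rf: int | None = None
    rf_normalized: float | None = None


SUMMARY_COLUMNS = (
    ["species"]
    + list(CORE_GENES)
    + [
        "n_genes",
        "classification",
        "n_loci",
        "n_subtypes",
        "copy_number",
        "copy_number_ci_lo",
        "copy_number_ci_hi",
        "fusion_status",
        "fusion_neighbors",
        "tir_found",
        "tsd",
        "intactness",
        "rf",
        "rf_normalized",
    ]
)


def write_summary(summaries: list[SpeciesSummary], path: str | Path) -> None:
    """One row per species; missing stages render as explicit NA."""

    def fmt(value) -> str:
        if value is None or value == [] or value == "":
            return "NA"
        if isinstance(value, float):
            return f"{value:.4f}"
        if isinstance(value, list):
            return ",".join(str(v) for v in value) or "NA"
        return str(value)

    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            ci = s.copy_number_ci or (None, None)
            row = (
                [s.species_id]
                + ["1" if s.gene_presence.get(g) else "0" for g in CORE_GENES]
                + [
                    fmt(s.n_genes_present),
                    s.classification,
                    fmt(s.n_loci),
                    fmt(s.n_subtypes),
                    fmt(s.copy_number),
                    fmt(ci[0]),
                    fmt(ci[1]),
                    fmt(s.fusion_status),
                    fmt(s.fusion_neighbors),
                    fmt([int(b) for b in s.tir_found] if s.tir_found else None),
                    fmt(s.tsd),
                    fmt(s.intactness),
                    fmt(s.rf),
                    fmt(s.rf_normalized),
                ]
            )
            fh.write("\t".join(row) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _derived_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2**31)


def run_pipeline(config: RunConfig, outdir: str | Path) -> SpeciesSummary:
    """Run all stages under one config and seed; returns the summary row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log: list[str] = [f"config: {json.dumps(dataclasses.asdict(config), sort_keys=True)}"]

    # --- stage: simulate -------------------------------------------------
    stage = "simulate"
    try:
        host, host_truth = simulate_host_genome(
            config.n_contigs,
            config.contig_length,
            config.gc,
            config.n_host_genes,
            seed=_derived_seed(config.seed, 1),
            gene_length=config.host_gene_length,
        )
        template = build_viral_element(
            DEFAULT_CATALOG,
            transposase_placement=config.transposase_placement,
            tir_length=config.tir_length,
            seed=_derived_seed(config.seed, 2),
            spacer_length=config.spacer_length,
        )
        subtype_spec = [tuple(s) for s in config.subtype_spec]
        genome, truth = insert_element_copies(
            host,
            template,
            subtype_spec,
            degrade=list(config.degrade),
            seed=_derived_seed(config.seed, 3),
            ts_tv_ratio=config.ts_tv_bias,
            min_separation=config.insertion_min_separation,
            host_truth=host_truth,
        )
        genome.to_fasta(outdir / "genome.fa")
        truth.to_tsv(outdir / "truth.tsv")
        truth.cds_to_bed(outdir / "host_cds.bed", "host")
        truth.cds_to_bed(outdir / "element_cds.bed", "element")
        queries = {name: prot for name, prot in template.proteins().items()}
        write_protein_fasta(queries, outdir / "queries.faa")
        expected_lengths = {name: len(p) for name, p in queries.items()}
        log.append(f"{stage}: genome={_checksum(outdir / 'genome.fa')}")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- stage: search ----------------------------------------------------
    stage = "search"
    try:
        params = config.search_params()
        protein_queries = [ProteinQuery(n, s) for n, s in queries.items()]
        hits_by_gene = search_many(protein_queries, genome, params)
        all_hits = [h for hs in hits_by_gene.values() for h in hs]
        write_hits_tsv(all_hits, outdir / "hits.tsv")
        log.append(f"{stage}: n_hits={len(all_hits)}")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: loci ------------------------------------------------------
    stage = "loci"
    try:
        viral_genes = set(CORE_GENES) | set(EXTRA_GENES)
        viral_hits = [h for h in all_hits if h.gene_name in viral_genes]
        tp_hits = [h for h in all_hits if h.gene_name == TRANSPOSASE]
        loci = merge_hit_loci(viral_hits, config.merge_distance)
        for locus in loci:
            extract_locus_sequence(genome, locus, config.flank)
        presence = build_presence(config.species_id, hits_by_gene, CORE_GENES, config.evalue)
        classification = classify_species(presence, config.min_genes)
        loci_mod.write_loci_bed(loci, outdir / "loci_core.bed")
        loci_mod.write_loci_bed(loci, outdir / "loci_flanked.bed", flanked=True)
        loci_mod.write_presence_tsv([presence], outdir / "presence.tsv")
        log.append(f"{stage}: n_loci={len(loci)} classification={classification}")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    summary = SpeciesSummary(
        species_id=config.species_id,
        gene_presence={
            g: presence.best_evalues[g] < config.evalue for g in CORE_GENES
        },
        n_genes_present=presence.n_genes_present,
        classification=classification,
        n_loci=len(loci),
    )

    # --- stage: annotate --------------------------------------------------
    stage = "annotate"
    try:
        fusion_rows = []
        for li, locus in enumerate(loci, 1):
            offset = locus.flank_start or 0
            local_viral = [_shift_hit(h, -offset) for h in locus.member_hits]
            local_tp = [
                _shift_hit(h, -offset)
                for h in tp_hits
                if h.contig_id == locus.contig_id
                and locus.flank_start <= h.nt_start < locus.flank_end
            ]
            orfs = ann.call_orfs(locus.sequence, config.orf_min_length_aa)
            verdicts, element_verdict = ann.assess_intactness(
                orfs, local_viral + local_tp, expected_lengths, config.intact_fraction
            )
            fusion = ann.classify_fusion(
                local_viral, local_tp, flank=config.flank
            )
            tir, tsd = _locate_tirs_and_tsd(locus, local_viral, local_tp, config)
            summary.fusion_status.append(fusion.status)
            if fusion.neighbor_genes:
                summary.fusion_neighbors.append("|".join(fusion.neighbor_genes))
            summary.tir_found.append(tir is not None)
            summary.tsd.append(tsd or "absent")
            summary.intactness.append(element_verdict)
            ann.write_gff3(
                orfs, local_viral + local_tp, tir, f"locus_{li}", outdir / f"locus_{li}.gff3"
            )
            fusion_rows.append(
                {
                    "locus": f"locus_{li}",
                    "status": fusion.status,
                    "neighbors": "|".join(fusion.neighbor_genes or ()) or "NA",
                    "tir": "yes" if tir else "no",
                    "tsd": tsd or "absent",
                    "intactness": element_verdict,
                }
            )
        ann.write_fusion_report(fusion_rows, outdir / "fusion_report.tsv")
        log.append(f"{stage}: loci_annotated={len(loci)}")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: subtype ---------------------------------------------------
    stage = "subtype"
    clustering = None
    try:
        if loci:
            core_seqs = {
                f"locus_{i + 1}": genome[loc.contig_id][loc.core_start : loc.core_end]
                for i, loc in enumerate(loci)
            }
            clustering = st.cluster_subtypes(core_seqs, config.subtype_identity)
            warnings = st.validate_within_subtype(
                clustering, config.within_subtype_identity
            )
            summary.n_subtypes = clustering.n_subtypes
            st.write_subtypes_tsv(clustering, outdir / "subtypes.tsv")
            st.write_identity_matrix_tsv(clustering, outdir / "subtype_identity.tsv")
            for w in warnings:
                log.append(f"{stage}: warning {w}")
        log.append(f"{stage}: n_subtypes={summary.n_subtypes}")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: copynum ---------------------------------------------------
    stage = "copynum"
    try:
        if config.mean_depth > 0 and loci and clustering is not None:
            reads = simulate_reads(
                genome,
                config.mean_depth,
                config.read_length,
                config.error_rate,
                seed=_derived_seed(config.seed, 4),
            )
            write_fastq(reads, outdir / "reads.fq")
            # one appended reference per subtype (its representative locus)
            element_seqs: dict[str, str] = {}
            for label, rep_id in sorted(clustering.representatives.items()):
                rep_locus = loci[int(rep_id.split("_")[1]) - 1]
                element_seqs[f"element_{label}"] = genome[rep_locus.contig_id][
                    rep_locus.core_start : rep_locus.core_end
                ]
            masked = cn.build_masked_reference(
                genome,
                [(l.contig_id, l.core_start, l.core_end) for l in loci],
                element_seqs,
            )
            intervals = _coverage_intervals(truth, queries, config, element_seqs)
            placements = cn.map_reads(
                reads,
                masked,
                seed_kmer=config.seed_kmer,
                max_mismatches=config.max_mismatches,
                seed=_derived_seed(config.seed, 5),
            )
            profile = cn.per_base_depth(placements, intervals, masked, config.read_length)
            per_subtype, total = cn.estimate_copy_number_total(
                profile, n_bootstrap=config.copy_number_bootstrap,
                seed=_derived_seed(config.seed, 6),
            )
            summary.copy_number = total.copy_number
            summary.copy_number_ci = total.bootstrap_ci
            cn.write_copy_number_report(profile, total, outdir / "copy_number.tsv")
            log.append(f"{stage}: copy_number={total.copy_number:.3f}")
        else:
            log.append(f"{stage}: skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: phylo -----------------------------------------------------
    stage = "phylo"
    try:
        if (
            config.run_phylo
            and len(loci) >= 4
            and config.transposase_placement != "absent"
        ):
            result = _congruence_from_loci(genome, loci, tp_hits, config)
            if result is not None:
                rf_res, t_tree, v_tree = result
                summary.rf = rf_res.rf
                summary.rf_normalized = rf_res.rf_normalized
                ph.write_newick(t_tree, outdir / "transposase_nj.nwk")
                ph.write_newick(v_tree, outdir / "viral_genes_nj.nwk")
                log.append(f"{stage}: rf={rf_res.rf}")
            else:
                log.append(f"{stage}: skipped (incomplete gene recovery)")
        else:
            log.append(f"{stage}: skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    write_summary([summary], outdir / "summary.tsv")
    log.append(f"summary: {_checksum(outdir / 'summary.tsv')}")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary


def _shift_hit(h: Hit, delta: int) -> Hit:
    return dataclasses.replace(h, nt_start=h.nt_start + delta, nt_end=h.nt_end + delta)


def _locate_tirs_and_tsd(locus, local_viral, local_tp, config):
    """TIR search around the hit envelope, TSD check just outside the TIRs."""
    hits = local_viral + local_tp
    env_start = min(h.nt_start for h in hits)
    env_end = max(h.nt_end for h in hits)
    # the element terminus sits one spacer beyond the outermost gene hit;
    # a tight window keeps chance inverted-repeat pairs rare
    margin = config.spacer_length + config.tir_max_len + 20
    a = max(0, env_start - margin)
    b = min(len(locus.sequence), env_end + margin)
    segment = locus.sequence[a:b]
    window = min(2 * margin, (len(segment) - 1) // 2)
    try:
        tir = ann.find_tirs(
            segment,
            min_len=config.tir_min_len,
            max_len=config.tir_max_len,
            max_mismatch=config.tir_max_mismatch,
            window=window,
        )
    except ValueError:
        return None, None
    if tir is None:
        return None, None
    shifted = ann.TIRCall(
        left=(tir.left[0] + a, tir.left[1] + a),
        right=(tir.right[0] + a, tir.right[1] + a),
        length=tir.length,
        mismatches=tir.mismatches,
    )
    # The detected repeat may have absorbed the duplicated TTAA itself
    # (revcomp(TTAA) == TTAA) plus chance-matching flank bases, shifting
    # both boundaries outward. Probe inward shifts and accept only the
    # canonical piggyBac TTAA duplication.
    tsd = None
    max_shift = max(tir.length - config.tir_min_len + 4, 8)
    for k in range(0, max_shift + 1):
        hit = None
        for dr in (k, k - 1, k + 1):
            if dr < 0:
                continue
            cand = ann.detect_tsd(
                locus.sequence, shifted.left[0] + k, shifted.right[1] - dr
            )
            if cand == "TTAA":
                hit = (k, dr)
                break
        if hit is not None:
            k, dr = hit
            tsd = "TTAA"
            # The TSD delimits the element: trim the repeats back to it.
            # Outward extension lengthens the pair by the boundary shift,
            # so each repeat loses only its own outer overhang.
            new_len = shifted.length - max(k, dr)
            shifted = ann.TIRCall(
                left=(shifted.left[0] + k, shifted.left[0] + k + new_len),
                right=(shifted.right[1] - dr - new_len, shifted.right[1] - dr),
                length=new_len,
                mismatches=shifted.mismatches,
                tsd=tsd,
            )
            break
    return shifted, tsd


def _coverage_intervals(truth, queries, config, element_seqs: dict[str, str]):
    """Viral CDS intervals on each appended element contig + host CDSs.

    Viral gene positions on the element references are found by searching
    the query proteins against the appended contigs themselves, so the
    stage does not peek at simulator truth for the element side.
    """
    from .search import GenomeIndex, ProteinQuery, search

    intervals = [
        cn.GeneInterval(iv.contig_id, iv.start, iv.end, iv.gene_id, "host")
        for iv in truth.host_cds_intervals
    ]
    element_genome = GenomeAssembly(dict(element_seqs))
    index = GenomeIndex(element_genome, config.word_size)
    params = config.search_params()
    viral_genes = set(CORE_GENES) | set(EXTRA_GENES)
    for gene in sorted(viral_genes):
        if gene not in queries:
            continue
        ehits = search(ProteinQuery(gene, queries[gene]), index, params)
        best_per_contig: dict[str, object] = {}
        for h in ehits:
            if h.contig_id not in best_per_contig:
                best_per_contig[h.contig_id] = h
        for cid, h in sorted(best_per_contig.items()):
            intervals.append(
                cn.GeneInterval(cid, h.nt_start, h.nt_end, f"{cid}:{gene}", "viral")
            )
    return intervals


def _congruence_from_loci(genome, loci, tp_hits, config):
    """Per-locus gene sequences from best hits; None if recovery incomplete."""
    gene_alns: dict[str, dict[str, str]] = {g: {} for g in ph.CONCAT_ORDER}
    tp_aln: dict[str, str] = {}
    taxa = []
    for i, locus in enumerate(loci):
        label = f"locus_{i + 1}"
        taxa.append(label)
        by_gene: dict[str, list[Hit]] = {}
        for h in locus.member_hits:
            by_gene.setdefault(h.gene_name, []).append(h)
        for g in ph.CONCAT_ORDER:
            hs = by_gene.get(g)
            if not hs:
                return None
            best = max(hs, key=lambda h: h.bitscore)
            gene_alns[g][label] = _hit_sequence(genome, best)
        ltp = [
            h
            for h in tp_hits
            if h.contig_id == locus.contig_id
            and locus.flank_start <= h.nt_start < locus.flank_end
        ]
        if not ltp:
            return None
        tp_aln[label] = _hit_sequence(genome, max(ltp, key=lambda h: h.bitscore))
    # equal-length check: trim each gene's sequences to the shortest
    for g, seqs in list(gene_alns.items()):
        m = min(len(s) for s in seqs.values())
        gene_alns[g] = {k: s[:m] for k, s in seqs.items()}
    m = min(len(s) for s in tp_aln.values())
    tp_aln = {k: s[:m] for k, s in tp_aln.items()}
    return ph.congruence_test(tp_aln, gene_alns, taxa)


def _hit_sequence(genome: GenomeAssembly, hit: Hit) -> str:
    seq = genome[hit.contig_id][hit.nt_start : hit.nt_end]
    return seq if hit.strand == "+" else revcomp(seq)
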