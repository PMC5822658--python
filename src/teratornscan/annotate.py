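"""Annotation of candidate element loci: ORFs, intactness, TIRs, TSDs and
the fusion status of the piggyBac-like transposase relative to viral genes.

All coordinates are locus-local, 0-based half-open on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._seq import encode
from .search import Hit, six_frame_translate


@dataclass(frozen=True)
class ORF:
    """Maximal ATG-to-stop open reading frame; interval includes the stop."""

    start: int
    end: int
    strand: str
    protein: str  # translation without the stop


@dataclass(frozen=True)
class TIRCall:
    left: tuple[int, int]
    right: tuple[int, int]
    length: int
    mismatches: int
    tsd: str | None = None


@dataclass(frozen=True)
class FusionCall:
    status: str  # fused_internal | fused_edge | co_localized | none
    transposase_hit: Hit | None = None
    neighbor_genes: tuple[str, str] | None = None  # gene names or 'element_boundary'
    distance_to_element: int | None = None


def call_orfs(seq: str, min_length_aa: int = 100) -> list[ORF]:
    """All maximal ATG-to-stop ORFs of at least ``min_length_aa`` codons,
    both strands, all frames. Within each stop-delimited segment the first
    ATG opens the ORF; a terminal stop inside the sequence is required."""
    orfs: list[ORF] = []
    if len(seq) < 3:
        return orfs
    for fr in six_frame_translate(seq):
        prot = fr.protein
        seg_start = 0
        i = 0
        while i <= len(prot):
            if i == len(prot) or prot[i] == "*":
                if i < len(prot):  # segment closed by a stop
                    m = prot.find("M", seg_start, i)
                    if m != -1 and i - m >= min_length_aa:
                        nt = fr.aa_to_nt(m, i + 1)  # include the stop codon
                        orfs.append(ORF(nt[0], nt[1], fr.strand, prot[m:i]))
                seg_start = i + 1
            i += 1
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def assess_intactness(
    orfs: list[ORF],
    viral_hits: list[Hit],
    expected_lengths: dict[str, int],
    min_fraction: float = 0.8,
) -> tuple[dict[str, str], str]:
    """Per-gene and element-level ORF intactness.

    A gene is intact iff an ORF on the hit's strand overlapping its best hit
    reaches at least ``min_fraction`` of the expected protein length;
    otherwise degraded (premature stops and frameshifts both shorten the
    longest in-frame ORF). Element verdict: intact (all genes), degraded
    (none), partially degraded otherwise.
    """
    by_gene: dict[str, list[Hit]] = {}
    for h in viral_hits:
        by_gene.setdefault(h.gene_name, []).append(h)
    unknown = set(by_gene) - set(expected_lengths)
    if unknown:
        raise KeyError(f"no expected length for genes: {sorted(unknown)}")
    verdicts: dict[str, str] = {}
    for gene, hits in by_gene.items():
        best = max(hits, key=lambda h: h.bitscore)
        longest = 0
        for orf in orfs:
            if orf.strand != best.strand:
                continue
            if orf.start < best.nt_end and best.nt_start < orf.end:
                longest = max(longest, len(orf.protein))
        verdicts[gene] = (
            "intact" if longest >= min_fraction * expected_lengths[gene] else "degraded"
        )
    n_intact = sum(1 for v in verdicts.values() if v == "intact")
    if not verdicts:
        element = "degraded"
    elif n_intact == len(verdicts):
        element = "intact"
    elif n_intact == 0:
        element = "degraded"
    else:
        element = "partially_degraded"
    return verdicts, element


def find_tirs(
    element_seq: str,
    min_len: int = 10,
    max_len: int = 40,
    max_mismatch: int = 1,
    window: int = 200,
) -> TIRCall | None:
    """Best terminal inverted repeat pair, or None.

    The left repeat must start within the first ``window`` bp and the right
    repeat end within the last ``window`` bp. Longest wins, then fewest
    mismatches, then leftmost (left start, then right start).
    """
    L = len(element_seq)
    if L <= 2 * window:
        raise ValueError("element shorter than twice the search window")
    left_codes = encode(element_seq[:window])
    right_codes = encode(element_seq[-window:])
    right_offset = L - window
    for tl in range(max_len, min_len - 1, -1):
        n_left = window - tl + 1
        if n_left <= 0:
            continue
        # rows: candidate left repeats (as revcomp, to compare directly)
        idx = np.arange(tl)
        lefts = left_codes[np.arange(n_left)[:, None] + idx[None, :]]
        lefts_rc = np.where(lefts < 4, 3 - lefts, lefts)[:, ::-1]
        rights = right_codes[np.arange(n_left)[:, None] + idx[None, :]]
        mism = (lefts_rc[:, None, :] != rights[None, :, :]).sum(axis=2)
        ok = np.argwhere(mism <= max_mismatch)
        if len(ok):
            best = min(
                ((int(mism[i, j]), int(i), int(j)) for i, j in ok),
                key=lambda t: (t[0], t[1], t[2]),
            )
            mm, i, j = best
            return TIRCall(
                left=(i, i + tl),
                right=(right_offset + j, right_offset + j + tl),
                length=tl,
                mismatches=mm,
            )
    return None


def detect_tsd(contig_seq: str, element_start: int, element_end: int) -> str | None:
    """The duplicated 4-mer flanking an insertion, or None.

    Returns the 4 bp immediately 5' of the element iff it equals the 4 bp
    immediately 3' of it (the piggyBac TTAA target-site duplication leaves
    identical flanks)."""
    if element_start < 4 or element_end + 4 > len(contig_seq):
        return None
    left = contig_seq[element_start - 4 : element_start]
    right = contig_seq[element_end : element_end + 4]
    return left if left == right else None


def classify_fusion(
    viral_hits: list[Hit],
    transposase_hits: list[Hit],
    flank: int = 40_000,
    edge_margin: int = 1000,
) -> FusionCall:
    """Position of the transposase relative to the viral-gene envelope.

    fused_internal: transposase between two viral gene hits inside the
    element; fused_edge: inside the element (within ``edge_margin`` of the
    envelope) with the element boundary as one neighbor; co_localized: in
    the flank, within ``flank`` bp of the envelope; none otherwise.
    Neighbors are determined by hit midpoints; overlapping hits tie-break
    by bitscore.
    """
    if not transposase_hits or not viral_hits:
        return FusionCall("none")
    tp = max(transposase_hits, key=lambda h: h.bitscore)
    env_start = min(h.nt_start for h in viral_hits)
    env_end = max(h.nt_end for h in viral_hits)
    mid = tp.midpoint
    ordered = sorted(viral_hits, key=lambda h: (h.midpoint, -h.bitscore))
    if env_start - edge_margin <= mid <= env_end + edge_margin:
        left = [h for h in ordered if h.midpoint < mid]
        right = [h for h in ordered if h.midpoint > mid]
        if left and right:
            return FusionCall(
                "fused_internal", tp, (left[-1].gene_name, right[0].gene_name)
            )
        neighbors = (
            ("element_boundary", right[0].gene_name)
            if right
            else (left[-1].gene_name, "element_boundary")
        )
        return FusionCall("fused_edge", tp, neighbors)
    distance = int(env_start - tp.nt_end) if mid < env_start else int(tp.nt_start - env_end)
    if distance <= flank:
        return FusionCall("co_localized", tp, None, max(distance, 0))
    return FusionCall("none")


# ---------------------------------------------------------------------------
# reporting


def write_gff3(
    orfs: list[ORF],
    hits: list[Hit],
    tir: TIRCall | None,
    seqid: str,
    path: str | Path,
) -> None:
    """ORFs, hits and TIRs on locus coordinates as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, o in enumerate(orfs, 1):
            fh.write(
                f"{seqid}\tteratornscan\tORF\t{o.start + 1}\t{o.end}\t.\t{o.strand}\t0"
                f"\tID=orf_{i};length_aa={len(o.protein)}\n"
            )
        for h in hits:
            fh.write(
                f"{seqid}\tteratornscan\tprotein_match\t{h.nt_start + 1}\t{h.nt_end}"
                f"\t{h.bitscore:.1f}\t{h.strand}\t.\tName={h.gene_name};evalue={h.evalue:.3g}\n"
            )
        if tir is not None:
            for (a, b), which in ((tir.left, "left"), (tir.right, "right")):
                fh.write(
                    f"{seqid}\tteratornscan\tterminal_inverted_repeat\t{a + 1}\t{b}\t.\t+\t."
                    f"\tID=tir_{which};mismatches={tir.mismatches}\n"
                )


def write_fusion_report(rows: list[dict], path: str | Path) -> None:
    cols = ["locus", "status", "neighbors", "tir", "tsd", "intactness"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "NA")) for c in cols) + "\n")
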