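"""Synthetic genomes with planted herpesvirus-like elements, plus short reads.

The generator emulates the data regime the detection pipeline assumes: a host
genome with single-copy CDSs, a viral element carrying an ordered gene set
(optionally fused with a piggyBac-like transposase, bordered by terminal
inverted repeats), multiple inserted copies structured into subtypes,
optional ORF degradation, and uniform-coverage error-bearing short reads.
Every stochastic choice flows from a single integer seed and a ground-truth
table records what was planted where.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import (
    AMINO_ACIDS,
    CODON_TABLE,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    decode,
    encode,
    revcomp,
)
from .genome import GenomeAssembly, Read

#: the 13 alloherpesvirus core genes used for presence classification
CORE_GENES = (
    "pol", "hel", "pri", "mcp", "tri", "mem", "ter", "pro",
    "ORF37", "ORF54", "ORF56", "ORF60", "ORF64",
)

#: the two additional query genes carried by the full 15-gene query set
EXTRA_GENES = ("ORF34", "ORF44")

TRANSPOSASE = "transposase"

#: default protein lengths (aa) for planted genes; compact stand-ins for the
#: real genes so a full element stays in the 10-15 kb range
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "pol": 420, "hel": 360, "pri": 300, "mcp": 450, "tri": 260,
    "mem": 300, "ter": 350, "pro": 250, "ORF37": 200, "ORF54": 200,
    "ORF56": 150, "ORF60": 150, "ORF64": 200, "ORF34": 180, "ORF44": 180,
    TRANSPOSASE: 300,
}

DEFAULT_CATALOG: list[tuple[str, int]] = [
    (g, DEFAULT_GENE_LENGTHS[g]) for g in CORE_GENES + EXTRA_GENES
]

ELEMENT_REF_NAME = "Teratorn_element"


class PlacementError(ValueError):
    """Raised when requested features cannot be placed on the genome."""


class NoInsertionSiteError(PlacementError):
    """Raised when a contig offers no usable TTAA insertion site."""


@dataclass(frozen=True)
class ElementGene:
    """One CDS inside the element, in element-local forward coordinates."""

    name: str
    cds: str  # coding-strand sequence incl. terminal stop
    strand: str  # '+' or '-'
    start: int
    end: int


@dataclass
class ElementTemplate:
    """A viral element: ordered genes, optional TIRs and transposase."""

    genes: list[ElementGene]
    sequence: str
    tir: tuple[str, str] | None  # (left_seq, right_seq = revcomp(left))
    transposase_placement: str  # internal | edge | absent

    @property
    def total_length(self) -> int:
        return len(self.sequence)

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def gene(self, name: str) -> ElementGene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def proteins(self) -> dict[str, str]:
        """Translations of each gene (terminal stop removed)."""
        from ._seq import translate

        return {g.name: translate(g.cds)[:-1] for g in self.genes}


@dataclass(frozen=True)
class CdsInterval:
    contig_id: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval for {self.gene_id}")


@dataclass(frozen=True)
class Insertion:
    contig_id: str
    insertion_position: int  # on the pre-insertion contig
    subtype_label: str
    copy_id: str
    degraded: bool
    tsd: str
    start: int  # element span on the post-insertion contig
    end: int


@dataclass
class TruthTable:
    """Ground truth of planted features, for parameter-recovery tests."""

    insertions: list[Insertion] = field(default_factory=list)
    host_cds_intervals: list[CdsInterval] = field(default_factory=list)
    element_cds_intervals: list[CdsInterval] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "contig_id\tinsertion_position\tsubtype_label\tcopy_id"
                "\tdegraded\ttsd\tstart\tend\n"
            )
            for ins in self.insertions:
                fh.write(
                    f"{ins.contig_id}\t{ins.insertion_position}\t{ins.subtype_label}"
                    f"\t{ins.copy_id}\t{int(ins.degraded)}\t{ins.tsd}"
                    f"\t{ins.start}\t{ins.end}\n"
                )

    def cds_to_bed(self, path, which: str = "host") -> None:
        rows = self.host_cds_intervals if which == "host" else self.element_cds_intervals
        with open(path, "w") as fh:
            for iv in rows:
                fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.gene_id}\n")


# ---------------------------------------------------------------------------
# host genome


def simulate_host_genome(
    n_contigs: int,
    contig_length: int,
    gc_fraction: float,
    n_host_genes: int,
    seed: int,
    gene_length: int = 1500,
) -> tuple[GenomeAssembly, TruthTable]:
    """I.i.d. host genome with non-overlapping single-copy CDS intervals.

    Host CDSs are plain intervals over the random background (single-copy by
    construction); they anchor the denominator of the coverage-ratio
    copy-number estimator and serve as negative-control targets.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if contig_length < 10 * gene_length:
        raise PlacementError("contig_length must be at least 10x the gene length")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    contigs: dict[str, str] = {}
    truth = TruthTable()
    genes_per_contig = _split_count(n_host_genes, n_contigs)
    gene_counter = itertools.count(1)
    for ci in range(n_contigs):
        cid = f"contig_{ci + 1}"
        codes = rng.choice(4, size=contig_length, p=p).astype(np.uint8)
        contigs[cid] = decode(codes)
        placed: list[int] = []
        for _ in range(genes_per_contig[ci]):
            start = _place_interval(rng, contig_length, gene_length, placed)
            placed.append(start)
            truth.host_cds_intervals.append(
                CdsInterval(cid, start, start + gene_length, f"host_g{next(gene_counter):04d}")
            )
        truth.host_cds_intervals.sort(key=lambda iv: (iv.contig_id, iv.start))
    return GenomeAssembly(contigs), truth


def _split_count(total: int, bins: int) -> list[int]:
    base = total // bins
    out = [base] * bins
    for i in range(total - base * bins):
        out[i] += 1
    return out


def _place_interval(
    rng: np.random.Generator,
    contig_length: int,
    length: int,
    placed_starts: list[int],
    margin: int = 200,
    max_tries: int = 10000,
) -> int:
    for _ in range(max_tries):
        start = int(rng.integers(margin, contig_length - length - margin))
        if all(abs(start - s) >= length + margin for s in placed_starts):
            return start
    raise PlacementError(
        f"could not place an interval of {length} bp on a {contig_length} bp contig "
        f"holding {len(placed_starts)} features"
    )


# ---------------------------------------------------------------------------
# element construction


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(len(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(AMINO_ACIDS[i] for i in body)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = SYNONYMOUS_CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    stops = sorted(STOP_CODONS)
    codons.append(stops[int(rng.integers(len(stops)))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return decode(rng.choice(4, size=length).astype(np.uint8))


def build_viral_element(
    gene_catalog: list[tuple[str, int]],
    transposase_placement: str = "absent",
    tir_length: int = 13,
    seed: int = 0,
    spacer_length: int = 150,
) -> ElementTemplate:
    """Assemble a viral element template from a gene catalog.

    Genes are random-codon back-translations of random proteins of the stated
    lengths, separated by i.i.d. intergenic spacers. With ``internal``
    placement the transposase is inserted between ORF60 and ORF54 (its
    invariant neighbors in the fused elements); with ``edge`` it becomes the
    terminal gene. A right TIR is the reverse complement of the left TIR.
    """
    if transposase_placement not in ("internal", "edge", "absent"):
        raise ValueError(f"unknown transposase_placement {transposase_placement!r}")
    rng = np.random.default_rng(seed)
    order = [(n, l) for n, l in gene_catalog if n != TRANSPOSASE]
    tp_len = dict(gene_catalog).get(TRANSPOSASE, DEFAULT_GENE_LENGTHS[TRANSPOSASE])
    names = [n for n, _ in order]
    if transposase_placement == "internal":
        if "ORF60" not in names or "ORF54" not in names:
            raise ValueError("internal placement requires ORF60 and ORF54 in the catalog")
        # make ORF54 immediately follow ORF60, then split them with the transposase
        i60 = names.index("ORF60")
        entry54 = order.pop(names.index("ORF54"))
        names.remove("ORF54")
        i60 = names.index("ORF60")
        order.insert(i60 + 1, entry54)
        order.insert(i60 + 1, (TRANSPOSASE, tp_len))
    elif transposase_placement == "edge":
        if int(rng.integers(2)):
            order.append((TRANSPOSASE, tp_len))
        else:
            order.insert(0, (TRANSPOSASE, tp_len))

    tir_left = _random_nt(rng, tir_length) if tir_length > 0 else ""
    parts: list[str] = [tir_left]
    pos = len(tir_left)
    genes: list[ElementGene] = []
    for name, aa_len in order:
        spacer = _random_nt(rng, spacer_length)
        parts.append(spacer)
        pos += spacer_length
        cds = _back_translate(rng, _random_protein(rng, aa_len))
        strand = "+" if int(rng.integers(2)) else "-"
        parts.append(cds if strand == "+" else revcomp(cds))
        genes.append(ElementGene(name, cds, strand, pos, pos + len(cds)))
        pos += len(cds)
    parts.append(_random_nt(rng, spacer_length))
    pos += spacer_length
    if tir_left:
        parts.append(revcomp(tir_left))
        pos += len(tir_left)
    sequence = "".join(parts)
    assert len(sequence) == pos
    tir = (tir_left, revcomp(tir_left)) if tir_left else None
    return ElementTemplate(genes, sequence, tir, transposase_placement)


# ---------------------------------------------------------------------------
# sequence evolution (Kimura 2-parameter generative process)


def _k2p_transition_matrix(branch_length: float, ts_tv_ratio: float) -> np.ndarray:
    """4x4 substitution-probability matrix (A,C,G,T order) for a K2P process.

    Rates are normalized so branch_length is the expected number of
    substitutions per site; ts_tv_ratio R is the transition:transversion
    *rate total* ratio (alpha / 2 beta), the convention of the distance
    estimator's bias parameter.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be non-negative")
    r = ts_tv_ratio
    beta = 1.0 / (2.0 * (r + 1.0))  # per-target transversion rate
    alpha = r / (r + 1.0)  # transition rate
    t = branch_length
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # order A,C,G,T; transitions: A<->G, C<->T
    P = np.empty((4, 4))
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            if i == j:
                P[i, j] = p_same
            elif (a in "AG") == (b in "AG"):
                P[i, j] = p_ts
            else:
                P[i, j] = p_tv
    return P


def evolve_sequence(
    seq: str, branch_length: float, ts_tv_ratio: float = 2.0, seed: int = 0
) -> str:
    """Evolve a nucleotide sequence under a K2P substitution process.

    Length-preserving, per-site independent; non-ACGT characters are left
    untouched. ``branch_length`` is in expected substitutions per site.
    """
    P = _k2p_transition_matrix(branch_length, ts_tv_ratio)
    rng = np.random.default_rng(seed)
    codes = encode(seq)
    valid = codes < 4
    cum = np.cumsum(P, axis=1)
    u = rng.random(codes.shape)
    drawn = (u[:, None] > cum[np.minimum(codes, 3)]).sum(axis=1).astype(np.uint8)
    out = np.where(valid, drawn, codes)
    return decode(out)


def evolve_cds_purifying(
    cds: str,
    branch_length: float,
    ts_tv_ratio: float = 2.0,
    nonsyn_factor: float = 0.1,
    seed: int = 0,
) -> str:
    """Evolve a coding sequence with nonsynonymous changes suppressed.

    Proposes K2P substitutions and accepts nonsynonymous ones with
    probability ``nonsyn_factor`` (synonymous ones always); changes creating
    stop codons are rejected. A simple purifying-selection regime whose
    realized dN/dS is approximately ``nonsyn_factor``.
    """
    if len(cds) % 3:
        raise ValueError("cds length must be divisible by 3")
    rng = np.random.default_rng(seed)
    proposed = evolve_sequence(cds, branch_length, ts_tv_ratio, seed=int(rng.integers(2**31)))
    out = list(cds)
    for i, (old, new) in enumerate(zip(cds, proposed)):
        if old == new:
            continue
        codon_i = i // 3
        codon = "".join(out[codon_i * 3 : codon_i * 3 + 3])
        new_codon = codon[: i % 3] + new + codon[i % 3 + 1 :]
        if new_codon in STOP_CODONS:
            continue
        if CODON_TABLE[new_codon] != CODON_TABLE[codon]:
            if rng.random() >= nonsyn_factor:
                continue
        out[i] = new
    return "".join(out)


# ---------------------------------------------------------------------------
# insertion of element copies


def _evolve_element(
    seq: str,
    template: ElementTemplate,
    branch_length: float,
    ts_tv_ratio: float,
    seed: int,
) -> str:
    """Evolve an element copy: CDS regions stop-free, the rest plain K2P.

    Keeps each gene's terminal stop codon fixed so neutral divergence does
    not masquerade as ORF degradation — the copies the pipeline hunts are
    maintained elements with intact ORFs.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    prev = 0
    for g in template.genes:
        parts.append(
            evolve_sequence(seq[prev : g.start], branch_length, ts_tv_ratio,
                            seed=int(rng.integers(2**31)))
        )
        seg = seq[g.start : g.end]
        coding = seg if g.strand == "+" else revcomp(seg)
        # start and stop codons held fixed (initiation/termination constraint)
        body = evolve_cds_purifying(
            coding[3:-3], branch_length, ts_tv_ratio, nonsyn_factor=1.0,
            seed=int(rng.integers(2**31)),
        )
        coding_out = coding[:3] + body + coding[-3:]
        parts.append(coding_out if g.strand == "+" else revcomp(coding_out))
        prev = g.end
    parts.append(
        evolve_sequence(seq[prev:], branch_length, ts_tv_ratio,
                        seed=int(rng.integers(2**31)))
    )
    out = "".join(parts)
    if template.tir is not None:
        # TIRs are required for transposition and are held fixed (functional
        # constraint), so all copies keep recognizable inverted termini
        tl = len(template.tir[0])
        out = seq[:tl] + out[tl : len(out) - tl] + seq[len(seq) - tl :]
    return out


def _find_ttaa_sites(seq: str) -> np.ndarray:
    codes = encode(seq)
    if len(codes) < 4:
        return np.array([], dtype=int)
    hit = (codes[:-3] == 3) & (codes[1:-2] == 3) & (codes[2:-1] == 0) & (codes[3:] == 0)
    return np.flatnonzero(hit)


def _degrade_copy(
    seq: str, template: ElementTemplate, rng: np.random.Generator
) -> str:
    """Plant a premature stop or a 1-bp frameshift in one viral CDS."""
    candidates = [g for g in template.genes if g.name != TRANSPOSASE]
    gene = candidates[int(rng.integers(len(candidates)))]
    n_codons = (gene.end - gene.start) // 3
    mid_codon = n_codons // 2
    if int(rng.integers(2)):
        # premature stop at the CDS midpoint
        cds = seq[gene.start : gene.end] if gene.strand == "+" else revcomp(
            seq[gene.start : gene.end]
        )
        cds = cds[: mid_codon * 3] + "TAA" + cds[mid_codon * 3 + 3 :]
        block = cds if gene.strand == "+" else revcomp(cds)
        return seq[: gene.start] + block + seq[gene.end :]
    # 1-bp deletion at the CDS midpoint (element coordinates)
    cut = gene.start + mid_codon * 3
    return seq[:cut] + seq[cut + 1 :]


def insert_element_copies(
    genome: GenomeAssembly,
    template: ElementTemplate,
    subtype_spec: list[tuple[int, float, float]],
    degrade: list[str] | None = None,
    seed: int = 0,
    ts_tv_ratio: float = 2.0,
    min_separation: int = 2000,
    edge_margin: int = 1000,
    host_truth: TruthTable | None = None,
) -> tuple[GenomeAssembly, TruthTable]:
    """Insert evolved element copies at TTAA sites with target-site duplication.

    Each subtype in ``subtype_spec`` is ``(n_copies, between_subtype_divergence,
    within_subtype_divergence)`` in K2P substitutions/site: the subtype
    ancestor sits ``between/2`` from the template and each copy ``within/2``
    from its ancestor, so pairwise distances are ≈ ``within`` inside a subtype
    and ≈ ``between`` across subtypes. Copies listed in ``degrade`` (by
    copy_id, e.g. ``"s1c3"``) receive a premature stop or a 1-bp frameshift
    in one viral CDS. Every copy lands at a TTAA site and is flanked by TTAA
    on both sides (piggyBac-style target-site duplication).
    """
    degrade = list(degrade or [])
    rng = np.random.default_rng(seed)
    # build all copy sequences first (rng order is fixed and documented)
    copies: list[tuple[str, str, str, bool]] = []  # (copy_id, subtype, seq, degraded)
    for s_idx, (n_copies, between, within) in enumerate(subtype_spec):
        label = f"subtype_{s_idx + 1}"
        ancestor = _evolve_element(
            template.sequence, template, between / 2.0, ts_tv_ratio,
            seed=int(rng.integers(2**31)),
        )
        for c_idx in range(n_copies):
            copy_id = f"s{s_idx + 1}c{c_idx + 1}"
            seq = _evolve_element(
                ancestor, template, within / 2.0, ts_tv_ratio,
                seed=int(rng.integers(2**31)),
            )
            flagged = copy_id in degrade
            if flagged:
                seq = _degrade_copy(seq, template, rng)
            copies.append((copy_id, label, seq, flagged))
    unknown = set(degrade) - {c[0] for c in copies}
    if unknown:
        raise ValueError(f"degrade lists unknown copy ids: {sorted(unknown)}")

    # choose insertion sites
    host_cds = list(host_truth.host_cds_intervals) if host_truth else []
    cds_by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in host_cds:
        cds_by_contig.setdefault(iv.contig_id, []).append((iv.start, iv.end))
    contig_ids = list(genome.contigs)
    lengths = np.array([len(genome[c]) for c in contig_ids], dtype=float)
    weights = lengths / lengths.sum()
    chosen: dict[str, list[tuple[int, tuple[str, str, str, bool]]]] = {c: [] for c in contig_ids}
    for copy in copies:
        cid = contig_ids[int(rng.choice(len(contig_ids), p=weights))]
        sites = _find_ttaa_sites(genome[cid])
        sites = sites[(sites >= edge_margin) & (sites <= len(genome[cid]) - edge_margin)]
        ok = []
        taken = [s for s, _ in chosen[cid]]
        for s in sites:
            if any(abs(int(s) - t) < min_separation for t in taken):
                continue
            if any(a - 200 <= s < b + 200 for a, b in cds_by_contig.get(cid, [])):
                continue
            ok.append(int(s))
        if not ok:
            raise NoInsertionSiteError(f"no usable TTAA site left on contig {cid!r}")
        site = ok[int(rng.integers(len(ok)))]
        chosen[cid].append((site, copy))

    # apply insertions contig by contig, left to right
    new_contigs: dict[str, str] = {}
    truth = TruthTable()
    truth.element_cds_intervals = [
        CdsInterval(ELEMENT_REF_NAME, g.start, g.end, g.name) for g in template.genes
    ]
    for cid in contig_ids:
        seq = genome[cid]
        events = sorted(chosen[cid], key=lambda x: x[0])
        parts: list[str] = []
        prev = 0
        shift = 0
        shifts: list[tuple[int, int]] = []  # (pre-insertion pos, total shift after it)
        for site, (copy_id, label, cseq, flagged) in events:
            parts.append(seq[prev : site + 4])
            parts.append(cseq)
            parts.append("TTAA")
            start = site + 4 + shift
            truth.insertions.append(
                Insertion(cid, site, label, copy_id, flagged, "TTAA", start, start + len(cseq))
            )
            shift += len(cseq) + 4
            shifts.append((site, shift))
            prev = site + 4
        parts.append(seq[prev:])
        new_contigs[cid] = "".join(parts)
        # shift host CDS coordinates past insertion points
        for iv in (x for x in host_cds if x.contig_id == cid):
            delta = 0
            for site, total in shifts:
                if iv.start > site:
                    delta = total
            truth.host_cds_intervals.append(replace(iv, start=iv.start + delta, end=iv.end + delta))
    truth.host_cds_intervals.sort(key=lambda iv: (iv.contig_id, iv.start))
    truth.insertions.sort(key=lambda i: (i.contig_id, i.insertion_position))
    return GenomeAssembly(new_contigs), truth


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: GenomeAssembly,
    mean_depth: float,
    read_length: int,
    error_rate: float,
    seed: int = 0,
) -> list[Read]:
    """Uniform single-end reads with substitution errors and fixed quality.

    Read count is ``mean_depth * genome_length / read_length``; start
    positions are uniform per contig (weighted by contig length) and both
    strands are equiprobable.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    shortest = min(len(s) for s in genome.contigs.values())
    if read_length > shortest:
        raise ValueError("read_length exceeds the shortest contig")
    rng = np.random.default_rng(seed)
    total = genome.total_length
    n_reads = int(round(mean_depth * total / read_length))
    contig_ids = list(genome.contigs)
    n_starts = np.array([len(genome[c]) - read_length + 1 for c in contig_ids], dtype=float)
    p = n_starts / n_starts.sum()
    counts = rng.multinomial(n_reads, p)
    qual = "I" * read_length
    reads: list[Read] = []
    for cid, k in zip(contig_ids, counts):
        if k == 0:
            continue
        codes = encode(genome[cid])
        starts = rng.integers(0, len(codes) - read_length + 1, size=k)
        mat = codes[starts[:, None] + np.arange(read_length)[None, :]].copy()
        rev = rng.integers(0, 2, size=k).astype(bool)
        if rev.any():
            sub = mat[rev][:, ::-1]
            comp = np.where(sub < 4, 3 - sub, sub).astype(np.uint8)
            mat[rev] = comp
        if error_rate > 0:
            err = (rng.random(mat.shape) < error_rate) & (mat < 4)
            offsets = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat = np.where(err, (mat + offsets) % 4, mat).astype(np.uint8)
        for i in range(k):
            strand = "-" if rev[i] else "+"
            reads.append(
                Read(f"{cid}:{int(starts[i])}:{strand}:{i}", decode(mat[i]), qual)
            )
    return reads


# ---------------------------------------------------------------------------
# co-simulation along trees (for congruence experiments)


def random_tree(n_taxa: int, seed: int = 0, min_bl: float = 0.02, max_bl: float = 0.15):
    """Random binary tree over taxa t1..tn with uniform branch lengths."""
    import dendropy

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=t)
        node.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_bl, max_bl))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        tree.seed_node.add_child(n)
    tree.is_rooted = False
    return tree


def evolve_cds_along_tree(
    root_cds: str,
    tree,
    ts_tv_ratio: float = 2.0,
    nonsyn_factor: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a coding sequence down a tree, never creating stop codons.

    ``nonsyn_factor`` < 1 imposes purifying selection (see
    :func:`evolve_cds_purifying`); 1.0 is neutral apart from stop avoidance.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[int, str] = {id(tree.seed_node): root_cds}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        seq = evolve_cds_purifying(
            parent_seq, bl, ts_tv_ratio, nonsyn_factor, seed=int(rng.integers(2**31))
        )
        seqs[id(node)] = seq
        if node.taxon is not None:
            out[node.taxon.label] = seq
    return out


def evolve_along_tree(
    root_seq: str, tree, ts_tv_ratio: float = 2.0, seed: int = 0
) -> dict[str, str]:
    """Evolve a sequence down a dendropy tree; returns taxon-label -> sequence."""
    rng = np.random.default_rng(seed)
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        seq = evolve_sequence(parent_seq, bl, ts_tv_ratio, seed=int(rng.integers(2**31)))
        seqs[id(node)] = seq
        if node.taxon is not None:
            out[node.taxon.label] = seq
    return out
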