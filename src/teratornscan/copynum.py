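"""Coverage-ratio copy-number estimation with a mask-and-append reference.

Known element copies are N-masked out of the assembly and a single element
reference contig is appended, so that reads from every copy pile onto one
target. Copy number per haploid genome is then the mean per-base depth over
viral CDSs divided by the mean depth over single-copy host CDSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeAssembly, Read
from .simulate import ELEMENT_REF_NAME

_BASE_LUT = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i


@dataclass(frozen=True)
class GeneInterval:
    contig_id: str
    start: int
    end: int
    gene_id: str
    gene_class: str  # 'viral' or 'host'


@dataclass(frozen=True)
class Placement:
    read_id: str
    contig_id: str
    start: int
    strand: str
    mismatches: int


@dataclass
class CoverageProfile:
    """Per-base depth over a set of CDS intervals."""

    intervals: list[GeneInterval]
    depths: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv, d in zip(self.intervals, self.depths):
            if len(d) != iv.end - iv.start:
                raise ValueError(f"depth array length mismatch for {iv.gene_id}")
            if (d < 0).any():
                raise ValueError(f"negative depth for {iv.gene_id}")

    def pooled_mean(self, gene_class: str) -> float:
        arrs = [d for iv, d in zip(self.intervals, self.depths) if iv.gene_class == gene_class]
        if not arrs:
            raise ValueError(f"no intervals of class {gene_class!r}")
        total = sum(float(d.sum()) for d in arrs)
        nbases = sum(len(d) for d in arrs)
        return total / nbases


@dataclass
class CopyNumberEstimate:
    mean_viral_depth: float
    mean_host_depth: float
    copy_number: float
    bootstrap_ci: tuple[float, float] | None = None


def build_masked_reference(
    genome: GenomeAssembly,
    element_intervals: list[tuple[str, int, int]],
    element_seqs: str | dict[str, str],
    element_contig_id: str = ELEMENT_REF_NAME,
) -> GenomeAssembly:
    """N-mask known element copies and append element reference contigs.

    ``element_seqs`` may be a single sequence (appended as one contig) or a
    mapping of contig name -> sequence, one per subtype, so that reads from
    diverged subtypes each find a close reference.
    """
    contigs = dict(genome.contigs)
    for cid, start, end in element_intervals:
        if cid not in contigs:
            raise KeyError(f"unknown contig {cid!r}")
        seq = contigs[cid]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"interval [{start},{end}) outside contig {cid!r}")
        contigs[cid] = seq[:start] + "N" * (end - start) + seq[end:]
    if isinstance(element_seqs, str):
        element_seqs = {element_contig_id: element_seqs}
    for name, seq in element_seqs.items():
        if name in contigs:
            raise ValueError(f"contig id {name!r} already present")
        contigs[name] = seq
    return GenomeAssembly(contigs)


class _ReferenceIndex:
    """Sorted 2-bit k-mer index over the concatenated reference."""

    def __init__(self, reference: GenomeAssembly, k: int):
        if reference.total_length == 0 or len(reference) == 0:
            raise ValueError("reference is empty")
        self.k = k
        self.contig_ids = list(reference.contigs)
        self.offsets: dict[str, int] = {}
        parts = []
        pos = 0
        for cid in self.contig_ids:
            self.offsets[cid] = pos
            parts.append(reference[cid])
            parts.append("N" * k)  # spacer: no k-mer spans two contigs
            pos += len(reference[cid]) + k
        concat = "".join(parts)
        self.codes = _BASE_LUT[np.frombuffer(concat.encode("ascii"), dtype=np.uint8)]
        valid = self.codes < 4
        n = len(self.codes) - k + 1
        kcodes = np.zeros(n, dtype=np.uint64)
        ok = np.ones(n, dtype=bool)
        for i in range(k):
            kcodes = (kcodes << np.uint64(2)) | self.codes[i : i + n].astype(np.uint64)
            ok &= valid[i : i + n]
        self.kmer_positions = np.flatnonzero(ok)
        kk = kcodes[self.kmer_positions]
        order = np.argsort(kk, kind="stable")
        self.sorted_codes = kk[order]
        self.sorted_positions = self.kmer_positions[order]
        self._bounds = np.array([self.offsets[c] for c in self.contig_ids] + [len(self.codes)])
        self._extents = {
            cid: (self.offsets[cid], self.offsets[cid] + len(reference[cid]))
            for cid in self.contig_ids
        }

    def within_one_contig(self, start: int, length: int) -> bool:
        i = int(np.searchsorted(self._bounds, start, side="right")) - 1
        if i < 0 or i >= len(self.contig_ids):
            return False
        a, b = self._extents[self.contig_ids[i]]
        return a <= start and start + length <= b

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.sorted_positions[lo:hi]

    def locate(self, global_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._bounds, global_pos, side="right")) - 1
        cid = self.contig_ids[i]
        return cid, global_pos - self.offsets[cid]


def map_reads(
    reads: list[Read],
    reference: GenomeAssembly,
    seed_kmer: int = 21,
    max_mismatches: int = 8,
    seed: int = 0,
) -> list[Placement]:
    """k-mer-seeded read placement with full-read Hamming verification.

    Candidates come from exact seed k-mers at five anchor offsets on both
    strands; the placement with the fewest mismatches wins, and ties are
    broken uniformly at random under the stated seed. N positions in the
    reference never match, so masked loci attract no reads. Reads are
    processed in vectorized batches of equal length.
    """
    index = _ReferenceIndex(reference, seed_kmer)
    rng = np.random.default_rng(seed)
    placements: list[Placement] = []
    by_length: dict[int, list[int]] = {}
    for ri, read in enumerate(reads):
        L = len(read.sequence)
        if L <= seed_kmer:
            raise ValueError(f"read {read.read_id} is not longer than the seed k-mer")
        by_length.setdefault(L, []).append(ri)
    for L, indices in sorted(by_length.items()):
        placements.extend(
            _map_batch(reads, indices, L, index, seed_kmer, max_mismatches, rng)
        )
    return placements


def _map_batch(
    reads: list[Read],
    indices: list[int],
    L: int,
    index: _ReferenceIndex,
    k: int,
    max_mismatches: int,
    rng: np.random.Generator,
) -> list[Placement]:
    n = len(indices)
    fwd = np.empty((n, L), dtype=np.uint8)
    for row, ri in enumerate(indices):
        fwd[row] = _BASE_LUT[np.frombuffer(reads[ri].sequence.encode("ascii"), dtype=np.uint8)]
    rev = np.where(fwd < 4, 3 - fwd, fwd)[:, ::-1].astype(np.uint8)
    anchors = sorted({round(f * (L - k)) for f in (0.0, 0.25, 0.5, 0.75, 1.0)})
    cand_read: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    cand_strand: list[np.ndarray] = []
    for s_flag, mat in ((0, fwd), (1, rev)):
        for a in anchors:
            window = mat[:, a : a + k]
            valid = (window < 4).all(axis=1)
            codes = np.zeros(n, dtype=np.uint64)
            for i in range(k):
                codes = (codes << np.uint64(2)) | window[:, i].astype(np.uint64)
            lo = np.searchsorted(index.sorted_codes, codes, side="left")
            hi = np.searchsorted(index.sorted_codes, codes, side="right")
            counts = np.where(valid, hi - lo, 0)
            total = int(counts.sum())
            if total == 0:
                continue
            starts_off = np.cumsum(counts) - counts
            offsets = np.arange(total) - np.repeat(starts_off, counts)
            pos = index.sorted_positions[np.repeat(lo, counts) + offsets]
            start = pos.astype(np.int64) - a
            rid = np.repeat(np.arange(n), counts)
            ok = (start >= 0) & (start + L <= len(index.codes))
            cand_read.append(rid[ok])
            cand_start.append(start[ok])
            cand_strand.append(np.full(int(ok.sum()), s_flag, dtype=np.uint8))
    if not cand_read:
        return []
    rid = np.concatenate(cand_read)
    start = np.concatenate(cand_start)
    strand = np.concatenate(cand_strand)
    # dedupe (read, start, strand) triples from multiple anchors
    order = np.lexsort((strand, start, rid))
    rid, start, strand = rid[order], start[order], strand[order]
    keep = np.ones(len(rid), dtype=bool)
    keep[1:] = (rid[1:] != rid[:-1]) | (start[1:] != start[:-1]) | (strand[1:] != strand[:-1])
    rid, start, strand = rid[keep], start[keep], strand[keep]
    # contig-boundary validity (vectorized against contig extents)
    ext_lo = np.array([index._extents[c][0] for c in index.contig_ids])
    ext_hi = np.array([index._extents[c][1] for c in index.contig_ids])
    ci = np.searchsorted(index._bounds, start, side="right") - 1
    ci_ok = (ci >= 0) & (ci < len(index.contig_ids))
    ci_clip = np.clip(ci, 0, len(index.contig_ids) - 1)
    within = ci_ok & (start >= ext_lo[ci_clip]) & (start + L <= ext_hi[ci_clip])
    rid, start, strand = rid[within], start[within], strand[within]
    if len(rid) == 0:
        return []
    # full-read Hamming verification, chunked to bound memory
    mm = np.empty(len(rid), dtype=np.int32)
    arangeL = np.arange(L)
    for c0 in range(0, len(rid), 200_000):
        c1 = min(c0 + 200_000, len(rid))
        slices = index.codes[start[c0:c1, None] + arangeL[None, :]]
        chunk_reads = np.where(
            (strand[c0:c1] == 0)[:, None], fwd[rid[c0:c1]], rev[rid[c0:c1]]
        )
        mm[c0:c1] = ((slices != chunk_reads) | (slices >= 4)).sum(axis=1)
    ok = mm <= max_mismatches
    rid, start, strand, mm = rid[ok], start[ok], strand[ok], mm[ok]
    if len(rid) == 0:
        return []
    # pick per read: fewest mismatches, random tie-break
    tiebreak = rng.random(len(rid))
    order = np.lexsort((tiebreak, mm, rid))
    rid, start, strand, mm = rid[order], start[order], strand[order], mm[order]
    first = np.ones(len(rid), dtype=bool)
    first[1:] = rid[1:] != rid[:-1]
    out = []
    for r, s, st, m in zip(rid[first], start[first], strand[first], mm[first]):
        cid, local = index.locate(int(s))
        out.append(
            Placement(reads[indices[int(r)]].read_id, cid, local, "+-"[int(st)], int(m))
        )
    return out


def per_base_depth(
    placements: list[Placement],
    intervals: list[GeneInterval],
    reference: GenomeAssembly,
    read_length: int,
) -> CoverageProfile:
    """Exact per-base read depth over each interval (coverageBed -d style)."""
    diff: dict[str, np.ndarray] = {
        cid: np.zeros(len(seq) + 1, dtype=np.int64) for cid, seq in reference.items()
    }
    for p in placements:
        d = diff[p.contig_id]
        d[p.start] += 1
        d[min(p.start + read_length, len(d) - 1)] -= 1
    cov = {cid: np.cumsum(d[:-1]) for cid, d in diff.items()}
    depths = []
    for iv in intervals:
        if iv.contig_id not in cov:
            raise KeyError(f"interval contig {iv.contig_id!r} not in reference")
        if iv.end > len(reference[iv.contig_id]):
            raise ValueError(f"interval {iv.gene_id} outside reference")
        depths.append(cov[iv.contig_id][iv.start : iv.end].copy())
    return CoverageProfile(list(intervals), depths)


def write_depth_table(profile: CoverageProfile, path: str | Path) -> None:
    """Three-column depth dialect: contig, 1-based position, depth."""
    with open(path, "w") as fh:
        for iv, d in zip(profile.intervals, profile.depths):
            for off, val in enumerate(d.tolist()):
                fh.write(f"{iv.contig_id}\t{iv.start + off + 1}\t{val}\n")


def read_depth_table(path: str | Path, intervals: list[GeneInterval]) -> CoverageProfile:
    """Load per-base depths computed externally (1-based positions)."""
    table: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed depth row at line {ln}")
            try:
                pos = int(parts[1])
                depth = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed depth row at line {ln}") from exc
            table[(parts[0], pos - 1)] = depth
    depths = []
    for iv in intervals:
        arr = np.array(
            [table.get((iv.contig_id, pos), 0) for pos in range(iv.start, iv.end)],
            dtype=np.int64,
        )
        depths.append(arr)
    return CoverageProfile(list(intervals), depths)


def estimate_copy_number(
    profile: CoverageProfile,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CopyNumberEstimate:
    """Viral/host pooled-depth ratio with a gene-bootstrap 95% CI.

    The point estimate is the grand mean depth over all viral CDS bases
    divided by the grand mean over all host CDS bases; the CI resamples
    genes with replacement within each class.
    """
    viral = [(iv, d) for iv, d in zip(profile.intervals, profile.depths) if iv.gene_class == "viral"]
    host = [(iv, d) for iv, d in zip(profile.intervals, profile.depths) if iv.gene_class == "host"]
    if not viral or not host:
        raise ValueError("both viral and host gene sets must be non-empty")
    mean_host = profile.pooled_mean("host")
    if mean_host == 0:
        raise ZeroDivisionError("zero host depth: copy-number ratio undefined")
    mean_viral = profile.pooled_mean("viral")
    ratio = mean_viral / mean_host
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        v_sums = np.array([float(d.sum()) for _, d in viral])
        v_lens = np.array([len(d) for _, d in viral], dtype=float)
        h_sums = np.array([float(d.sum()) for _, d in host])
        h_lens = np.array([len(d) for _, d in host], dtype=float)
        ratios = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            vi = rng.integers(0, len(viral), size=len(viral))
            hi = rng.integers(0, len(host), size=len(host))
            denom = h_sums[hi].sum() / h_lens[hi].sum()
            ratios[b] = (v_sums[vi].sum() / v_lens[vi].sum()) / denom if denom > 0 else np.nan
        lo, hi_ = np.nanpercentile(ratios, [2.5, 97.5])
        ci = (float(lo), float(hi_))
    return CopyNumberEstimate(mean_viral, mean_host, ratio, ci)


def estimate_copy_number_total(
    profile: CoverageProfile,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, CopyNumberEstimate], CopyNumberEstimate]:
    """Per-subtype-reference ratios plus their total.

    Viral intervals are grouped by reference contig (one appended contig per
    subtype); each group's pooled depth is divided by the shared host mean,
    and the species total is the sum over groups — mirroring per-subtype
    copy numbers that add up to the whole-element count.
    """
    host = [(iv, d) for iv, d in zip(profile.intervals, profile.depths) if iv.gene_class == "host"]
    groups: dict[str, list[tuple[GeneInterval, np.ndarray]]] = {}
    for iv, d in zip(profile.intervals, profile.depths):
        if iv.gene_class == "viral":
            groups.setdefault(iv.contig_id, []).append((iv, d))
    if not host or not groups:
        raise ValueError("need host intervals and at least one viral group")
    mean_host = profile.pooled_mean("host")
    if mean_host == 0:
        raise ZeroDivisionError("zero host depth: copy-number ratio undefined")
    per_group: dict[str, CopyNumberEstimate] = {}
    for name, items in sorted(groups.items()):
        mv = sum(float(d.sum()) for _, d in items) / sum(len(d) for _, d in items)
        per_group[name] = CopyNumberEstimate(mv, mean_host, mv / mean_host)
    total_ratio = sum(e.copy_number for e in per_group.values())
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        h_sums = np.array([float(d.sum()) for _, d in host])
        h_lens = np.array([len(d) for _, d in host], dtype=float)
        g_sums = {g: np.array([float(d.sum()) for _, d in items]) for g, items in groups.items()}
        g_lens = {g: np.array([len(d) for _, d in items], dtype=float) for g in groups}
        totals = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            hi = rng.integers(0, len(host), size=len(host))
            denom = h_sums[hi].sum() / h_lens[hi].sum()
            tot = 0.0
            for g in groups:
                gi = rng.integers(0, len(g_sums[g]), size=len(g_sums[g]))
                tot += (g_sums[g][gi].sum() / g_lens[g][gi].sum()) / denom
            totals[b] = tot
        lo, hi_ = np.percentile(totals, [2.5, 97.5])
        ci = (float(lo), float(hi_))
    total = CopyNumberEstimate(
        sum(e.mean_viral_depth for e in per_group.values()),
        mean_host,
        total_ratio,
        ci,
    )
    return per_group, total


def write_copy_number_report(
    profile: CoverageProfile, estimate: CopyNumberEstimate, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\tmean_depth\n")
        for iv, d in zip(profile.intervals, profile.depths):
            fh.write(f"{iv.gene_id}\t{iv.gene_class}\t{d.mean():.3f}\n")
        fh.write(f"#mean_viral_depth\t{estimate.mean_viral_depth:.4f}\n")
        fh.write(f"#mean_host_depth\t{estimate.mean_host_depth:.4f}\n")
        fh.write(f"#copy_number\t{estimate.copy_number:.4f}\n")
        if estimate.bootstrap_ci:
            lo, hi = estimate.bootstrap_ci
            fh.write(f"#bootstrap_ci_95\t{lo:.4f}\t{hi:.4f}\n")
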