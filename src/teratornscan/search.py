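"""Six-frame translated homology search of protein queries against contigs.

A compact tblastn-style search: exact amino-acid word seeding, ungapped
X-drop extension along the diagonal, then gapped local alignment (affine
gaps, BLOSUM62) around surviving seeds, with Karlin–Altschul E-values used
for significance filtering. Coordinates are 0-based half-open on the
forward strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from ._seq import revcomp, translate
from .genome import GenomeAssembly

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_X_INDEX = _ALPHABET.index("X")
_CHAR_TO_IDX = np.full(128, _X_INDEX, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _CHAR_TO_IDX[ord(_c)] = _i
_SCORE = np.asarray(_BLOSUM62, dtype=np.int32)


@dataclass(frozen=True)
class ProteinQuery:
    """A named protein query (20-letter alphabet, optional X)."""

    gene_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty query sequence")
        if "*" in self.sequence:
            raise ValueError("query contains stop symbols")


@dataclass(frozen=True)
class Hit:
    """One translated-search local alignment, forward-strand coordinates."""

    gene_name: str
    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2
    nt_start: int
    nt_end: int
    aa_query_start: int
    aa_query_end: int
    raw_score: float
    bitscore: float
    evalue: float
    aligned_identity: float

    @property
    def midpoint(self) -> float:
        return (self.nt_start + self.nt_end) / 2.0


@dataclass
class SearchParams:
    word_size: int = 4
    gap_open: float = -11.0
    gap_extend: float = -1.0
    x_drop: float = 20.0
    evalue_keep: float = 1e-3
    karlin_lambda: float = 0.3176
    karlin_k: float = 0.134
    ungapped_trigger: float = 30.0


def estimate_evalue(
    raw_score: float,
    query_length: int,
    database_length: int,
    K: float = 0.134,
    lam: float = 0.3176,
) -> float:
    """Karlin–Altschul expected chance-hit count E = K·m·n·exp(−λS)."""
    if query_length <= 0 or database_length <= 0:
        raise ValueError("lengths must be positive")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return K * query_length * database_length * math.exp(-lam * raw_score)


def bitscore(raw_score: float, K: float = 0.134, lam: float = 0.3176) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2.0)


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six reading frames of a contig, with its coordinate map."""

    contig_id: str
    strand: str
    frame: int
    protein: str
    contig_length: int

    def aa_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa interval [aa_start, aa_end) to forward-genome bp."""
        if self.strand == "+":
            return self.frame + 3 * aa_start, self.frame + 3 * aa_end
        L = self.contig_length
        return L - self.frame - 3 * aa_end, L - self.frame - 3 * aa_start


def six_frame_translate(contig: str, contig_id: str = "contig") -> list[FrameTranslation]:
    """All six frame translations of a contig (ambiguous codons -> X)."""
    if len(contig) < 3:
        raise ValueError("contig shorter than one codon")
    frames = []
    rc = revcomp(contig)
    for frame in range(3):
        frames.append(
            FrameTranslation(contig_id, "+", frame, translate(contig[frame:]), len(contig))
        )
        frames.append(
            FrameTranslation(contig_id, "-", frame, translate(rc[frame:]), len(contig))
        )
    return frames


class GenomeIndex:
    """Precomputed six-frame translations and word arrays for a genome.

    Building the index once amortizes translation across the 15 query genes.
    """

    def __init__(self, genome: GenomeAssembly, word_size: int = 4):
        self.word_size = word_size
        self.frames: list[FrameTranslation] = []
        self._idx: list[np.ndarray] = []
        self._words: list[np.ndarray] = []
        for cid, seq in genome.items():
            self.frames.extend(six_frame_translate(seq, cid))
        base = np.int64(len(_ALPHABET))
        for fr in self.frames:
            idx = _CHAR_TO_IDX[
                np.frombuffer(fr.protein.encode("ascii"), dtype=np.uint8)
            ]
            self._idx.append(idx)
            n = len(idx) - word_size + 1
            if n <= 0:
                self._words.append(np.empty(0, dtype=np.int64))
                continue
            w = np.zeros(n, dtype=np.int64)
            for k in range(word_size):
                w = w * base + idx[k : k + n]
            self._words.append(w)
        self.database_length = sum(len(fr.protein) for fr in self.frames)


def _word_codes(seq_idx: np.ndarray, word_size: int) -> np.ndarray:
    base = np.int64(len(_ALPHABET))
    n = len(seq_idx) - word_size + 1
    w = np.zeros(max(n, 0), dtype=np.int64)
    for k in range(word_size):
        w = w * base + seq_idx[k : k + n]
    return w


def _xdrop_run(scores: np.ndarray, x_drop: float) -> float:
    """Best prefix sum before the running maximum drops by more than x_drop."""
    if len(scores) == 0:
        return 0.0
    cs = np.cumsum(scores)
    run_max = np.maximum.accumulate(np.maximum(cs, 0.0))
    stopped = np.flatnonzero(run_max - cs > x_drop)
    end = stopped[0] if len(stopped) else len(cs)
    if end == 0:
        return 0.0
    return float(max(cs[:end].max(), 0.0))


def _make_aligner(params: SearchParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _sanitize(seq: str) -> str:
    return "".join(c if c in _ALPHABET else "X" for c in seq.upper())


def search(
    query: ProteinQuery,
    genome: GenomeAssembly | GenomeIndex,
    params: SearchParams | None = None,
) -> list[Hit]:
    """Seeded, gapped translated search of one protein query against a genome.

    Returns hits with ``evalue < params.evalue_keep``, overlapping same-frame
    hits merged to the best-scoring one, sorted by bitscore descending.
    """
    params = params or SearchParams()
    if len(query.sequence) < params.word_size:
        raise ValueError("query shorter than word size")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, params.word_size)
    if index.word_size != params.word_size:
        raise ValueError("index word size does not match params.word_size")

    qseq = _sanitize(query.sequence)
    q_idx = _CHAR_TO_IDX[np.frombuffer(qseq.encode("ascii"), dtype=np.uint8)]
    q_words = _word_codes(q_idx, params.word_size)
    q_order = np.argsort(q_words, kind="stable")
    q_sorted = q_words[q_order]

    aligner = _make_aligner(params)
    m = len(qseq)
    hits: list[Hit] = []
    for fi, fr in enumerate(index.frames):
        s_idx = index._idx[fi]
        s_words = index._words[fi]
        if len(s_words) == 0:
            continue
        s_cand = np.flatnonzero(np.isin(s_words, q_sorted))
        if len(s_cand) == 0:
            continue
        qpos_arr, spos_arr = _expand_seeds(q_sorted, q_order, s_words, s_cand)
        qpos_arr, spos_arr = _prefilter_seeds(
            q_idx, s_idx, qpos_arr, spos_arr, params.word_size
        )
        windows: list[tuple[int, int]] = []
        diag_done: dict[int, int] = {}
        order = np.lexsort((spos_arr, spos_arr - qpos_arr))
        for k in order.tolist():
            qpos, spos = int(qpos_arr[k]), int(spos_arr[k])
            diag = spos - qpos
            if diag_done.get(diag, -1) >= spos:
                continue
            score = _ungapped_score(
                q_idx, s_idx, qpos, spos, params.word_size, params.x_drop
            )
            diag_done[diag] = spos + params.word_size
            if score >= params.ungapped_trigger:
                ws = max(0, spos - m - 50)
                we = min(len(s_idx), spos + params.word_size + m + 50)
                windows.append((ws, we))
        if not windows:
            continue
        for ws, we in _merge_windows(windows):
            hit = _align_window(query, qseq, fr, ws, we, aligner, params, index.database_length)
            if hit is not None:
                hits.append(hit)
    hits = _merge_same_frame(hits)
    hits = [h for h in hits if h.evalue < params.evalue_keep]
    hits.sort(key=lambda h: (-h.bitscore, h.contig_id, h.nt_start))
    return hits


def _expand_seeds(
    q_sorted: np.ndarray,
    q_order: np.ndarray,
    s_words: np.ndarray,
    s_cand: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """All (query pos, subject pos) word-match seeds, fully vectorized."""
    codes = s_words[s_cand]
    lo = np.searchsorted(q_sorted, codes, side="left")
    hi = np.searchsorted(q_sorted, codes, side="right")
    counts = hi - lo
    total = int(counts.sum())
    starts = np.cumsum(counts) - counts
    offsets = np.arange(total) - np.repeat(starts, counts)
    qpos = q_order[np.repeat(lo, counts) + offsets]
    spos = np.repeat(s_cand, counts)
    return qpos, spos


_PREFILTER_HALF = 12
_PREFILTER_MIN = 40.0


def _prefilter_seeds(
    q_idx: np.ndarray,
    s_idx: np.ndarray,
    qpos: np.ndarray,
    spos: np.ndarray,
    word_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep seeds whose fixed diagonal window scores above a weak floor.

    An exact word on a chance diagonal is surrounded by background-scoring
    residues (expected negative), while a word inside a real alignment sits
    in a positively scoring neighborhood; a +/-12 aa window separates the
    two regimes cheaply before the exact X-drop extension runs.
    """
    if len(qpos) == 0:
        return qpos, spos
    rel = np.arange(-_PREFILTER_HALF, word_size + _PREFILTER_HALF)
    qi = qpos[:, None] + rel[None, :]
    si = spos[:, None] + rel[None, :]
    valid = (qi >= 0) & (qi < len(q_idx)) & (si >= 0) & (si < len(s_idx))
    qi = np.clip(qi, 0, len(q_idx) - 1)
    si = np.clip(si, 0, len(s_idx) - 1)
    scores = _SCORE[q_idx[qi], s_idx[si]] * valid
    keep = scores.sum(axis=1) >= _PREFILTER_MIN
    return qpos[keep], spos[keep]


def _ungapped_score(
    q_idx: np.ndarray,
    s_idx: np.ndarray,
    qpos: int,
    spos: int,
    word_size: int,
    x_drop: float,
) -> float:
    diag = spos - qpos
    word = float(_SCORE[q_idx[qpos : qpos + word_size], s_idx[spos : spos + word_size]].sum())
    # rightward
    q_r = np.arange(qpos + word_size, len(q_idx))
    q_r = q_r[q_r + diag < len(s_idx)]
    right = _xdrop_run(
        _SCORE[q_idx[q_r], s_idx[q_r + diag]].astype(float), x_drop
    ) if len(q_r) else 0.0
    # leftward
    q_l = np.arange(qpos - 1, -1, -1)
    q_l = q_l[q_l + diag >= 0]
    left = _xdrop_run(
        _SCORE[q_idx[q_l], s_idx[q_l + diag]].astype(float), x_drop
    ) if len(q_l) else 0.0
    return word + left + right


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    windows = sorted(windows)
    merged = [list(windows[0])]
    for ws, we in windows[1:]:
        if ws <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], we)
        else:
            merged.append([ws, we])
    return [(a, b) for a, b in merged]


def _align_window(
    query: ProteinQuery,
    qseq: str,
    fr: FrameTranslation,
    ws: int,
    we: int,
    aligner: PairwiseAligner,
    params: SearchParams,
    database_length: int,
) -> Hit | None:
    window = _sanitize(fr.protein[ws:we])
    if not window:
        return None
    alns = aligner.align(qseq, window)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    q_blocks, t_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None
    aa_q0, aa_q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    aa_s0, aa_s1 = int(t_blocks[0][0]) + ws, int(t_blocks[-1][1]) + ws
    matches = 0
    cols = 0
    for (qa, qb), (ta, tb) in zip(q_blocks, t_blocks):
        for k in range(qb - qa):
            cols += 1
            if qseq[qa + k] == window[ta + k]:
                matches += 1
    # gap columns count toward alignment length
    gap_cols = (aa_q1 - aa_q0 - sum(b - a for a, b in q_blocks)) + (
        aa_s1 - aa_s0 - sum(b - a for a, b in t_blocks)
    )
    identity = matches / max(cols + gap_cols, 1)
    nt_start, nt_end = fr.aa_to_nt(aa_s0, aa_s1)
    score = float(alns.score)
    return Hit(
        gene_name=query.gene_name,
        contig_id=fr.contig_id,
        strand=fr.strand,
        frame=fr.frame,
        nt_start=nt_start,
        nt_end=nt_end,
        aa_query_start=aa_q0,
        aa_query_end=aa_q1,
        raw_score=score,
        bitscore=bitscore(score, params.karlin_k, params.karlin_lambda),
        evalue=estimate_evalue(
            score, len(qseq), database_length, params.karlin_k, params.karlin_lambda
        ),
        aligned_identity=identity,
    )


def _merge_same_frame(hits: list[Hit]) -> list[Hit]:
    """Keep the best-scoring hit among overlapping same-frame hits."""
    groups: dict[tuple[str, str, int, str], list[Hit]] = {}
    for h in hits:
        groups.setdefault((h.contig_id, h.strand, h.frame, h.gene_name), []).append(h)
    out: list[Hit] = []
    for group in groups.values():
        group.sort(key=lambda h: h.nt_start)
        cluster: list[Hit] = []
        end = -1
        for h in group:
            if h.nt_start < end:
                cluster.append(h)
                end = max(end, h.nt_end)
            else:
                if cluster:
                    out.append(max(cluster, key=lambda x: (x.raw_score, -x.nt_start)))
                cluster = [h]
                end = h.nt_end
        if cluster:
            out.append(max(cluster, key=lambda x: (x.raw_score, -x.nt_start)))
    return out


def search_many(
    queries: list[ProteinQuery],
    genome: GenomeAssembly,
    params: SearchParams | None = None,
) -> dict[str, list[Hit]]:
    """Search several queries against one genome, sharing the frame index."""
    params = params or SearchParams()
    index = GenomeIndex(genome, params.word_size)
    return {q.gene_name: search(q, index, params) for q in queries}


def write_hits_tsv(hits: list[Hit], path: str | Path) -> None:
    """BLAST outfmt-6-like table plus strand and frame columns."""
    cols = (
        "query\tsubject\tpident\tlength\tqstart\tqend\tsstart\tsend"
        "\tevalue\tbitscore\tstrand\tframe\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for h in hits:
            fh.write(
                f"{h.gene_name}\t{h.contig_id}\t{100 * h.aligned_identity:.2f}"
                f"\t{(h.nt_end - h.nt_start) // 3}\t{h.aa_query_start}\t{h.aa_query_end}"
                f"\t{h.nt_start}\t{h.nt_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}"
                f"\t{h.strand}\t{h.frame}\n"
            )
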