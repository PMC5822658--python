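"""Pairwise divergence: identity, Kimura-2-parameter distance, and
modified Nei–Gojobori dN/dS with transition/transversion bias R.

Gap handling is pairwise deletion throughout: a column is compared only when
both rows carry an unambiguous nucleotide.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from ._seq import CODON_TABLE, STOP_CODONS, is_transition

_NT = frozenset("ACGTN")


class SaturationError(ValueError):
    """Distance undefined: substitution fractions exceed the model's domain."""


@dataclass(frozen=True)
class PairwiseAlignment:
    seq_a_aligned: str
    seq_b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a_aligned) != len(self.seq_b_aligned):
            raise ValueError("aligned rows differ in length")

    def columns(self):
        return zip(self.seq_a_aligned, self.seq_b_aligned)


@dataclass
class DivergenceEstimate:
    """Holder for pairwise divergence quantities (unused fields are None)."""

    p_identity: float | None = None
    d: float | None = None  # K2P distance, substitutions/site
    P: float | None = None  # transition difference fraction
    Q: float | None = None  # transversion difference fraction
    dN: float | None = None
    dS: float | None = None
    ratio: float | None = None
    ratio_undefined: bool = False


def global_align_nt(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch) alignment with affine gaps.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``. Tie-breaking is
    the aligner's canonical deterministic order, so repeated runs reproduce
    the same alignment; the optimal score itself is tie-independent.
    """
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        extra = set(s) - _NT
        if extra:
            raise ValueError(f"sequence {name} has characters outside ACGTN: {sorted(extra)}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def pairwise_identity(
    alignment: PairwiseAlignment, mode: str = "exclude_gap_columns"
) -> float | None:
    """Matches / compared columns; gap-bearing columns are excluded.

    Returns None when no column is comparable.
    """
    if mode != "exclude_gap_columns":
        raise ValueError(f"unknown identity mode {mode!r}")
    matches = 0
    cols = 0
    for x, y in alignment.columns():
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        return None
    return matches / cols


def _as_alignment(alignment) -> PairwiseAlignment:
    if isinstance(alignment, PairwiseAlignment):
        return alignment
    a, b = alignment
    return PairwiseAlignment(a, b, float("nan"))


def k2p_distance(alignment) -> DivergenceEstimate:
    """Kimura-2-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are transition and transversion difference fractions over the
    pairwise-deleted columns. Accepts a PairwiseAlignment or an
    (aligned_a, aligned_b) pair.
    """
    aln = _as_alignment(alignment)
    n = ts = tv = 0
    for x, y in aln.columns():
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P distance undefined (P={P:.4f}, Q={Q:.4f})")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    ident = pairwise_identity(aln)
    return DivergenceEstimate(p_identity=ident, d=d, P=P, Q=Q)


# ---------------------------------------------------------------------------
# modified Nei-Gojobori


def _codon_sites(codon: str, R: float) -> tuple[float, float]:
    """Weighted (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes one site, split by the R-weighted fraction of
    its single-nucleotide changes that are synonymous; changes producing a
    stop codon count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        wsum = 0.0
        wsyn = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            w = R if is_transition(codon[pos], alt) else 1.0
            wsum += w
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if mutated not in STOP_CODONS and CODON_TABLE[mutated] == aa:
                wsyn += w
        s += wsyn / wsum
    return s, 3.0 - s


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orderings of the differing positions are enumerated; paths passing
    through a stop codon are discarded (all paths are kept if every path
    hits a stop).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if CODON_TABLE.get(nxt, "*") == CODON_TABLE.get(cur, "*") and nxt not in STOP_CODONS and cur not in STOP_CODONS:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((through_stop, sd, nd))
    usable = [(s, n) for stop, s, n in paths if not stop] or [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} exceeds the Jukes-Cantor domain")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng_dnds(alignment, ts_tv_bias: float = 2.0) -> DivergenceEstimate:
    """Modified Nei–Gojobori dN/dS for one aligned coding-sequence pair.

    Site counting weights transitions ``ts_tv_bias`` relative to
    transversions; difference counting averages equally over minimal
    mutational pathways; pN and pS are Jukes–Cantor corrected. When dS = 0
    the ratio is flagged undefined rather than infinite.
    """
    aln = _as_alignment(alignment)
    a, b = aln.seq_a_aligned, aln.seq_b_aligned
    if len(a) % 3:
        raise ValueError("alignment length not divisible by 3")
    S = N = Sd = Nd = 0.0
    for ci in range(len(a) // 3):
        c1 = a[3 * ci : 3 * ci + 3]
        c2 = b[3 * ci : 3 * ci + 3]
        if "-" in c1 or "-" in c2 or set(c1 + c2) - set("ACGT"):
            continue
        for c in (c1, c2):
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon at codon index {ci}")
        s1, n1 = _codon_sites(c1, ts_tv_bias)
        s2, n2 = _codon_sites(c2, ts_tv_bias)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_differences(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    pS, pN = Sd / S, Nd / N
    dS, dN = _jc_correct(pS), _jc_correct(pN)
    if dS == 0.0:
        return DivergenceEstimate(dN=dN, dS=dS, ratio=None, ratio_undefined=True)
    return DivergenceEstimate(dN=dN, dS=dS, ratio=dN / dS)


def trim_alignment(
    msa: list[str], max_gap_fraction: float, codon_aware: bool = False
) -> list[str]:
    """Drop columns whose gap fraction exceeds the threshold.

    With ``codon_aware`` the filter acts on whole codon triplets (a triplet
    is dropped if any of its columns fails).
    """
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0])
    if any(len(s) != L for s in msa):
        raise ValueError("alignment is not rectangular")
    n = len(msa)
    keep_col = [
        sum(s[j] == "-" for s in msa) / n <= max_gap_fraction for j in range(L)
    ]
    if codon_aware:
        if L % 3:
            raise ValueError("codon-aware trimming requires length divisible by 3")
        keep = []
        for ci in range(L // 3):
            ok = all(keep_col[3 * ci : 3 * ci + 3])
            keep.extend([ok] * 3)
        keep_col = keep
    out = ["".join(s[j] for j in range(L) if keep_col[j]) for s in msa]
    if not out[0]:
        raise ValueError("all columns removed by trimming")
    return out
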