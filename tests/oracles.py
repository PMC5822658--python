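"""Independent brute-force oracles used only by the test suite.

Each function here is written from first principles (full DP tables,
exhaustive enumeration, per-base recounting) and deliberately shares no
code with the package implementation it checks.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_B62 = substitution_matrices.load("BLOSUM62")


def smith_waterman(query: str, subject: str, gap_open: float = -11.0, gap_extend: float = -1.0) -> float:
    """Full affine-gap local alignment score (Gotoh), no heuristics.

    A gap of length L costs gap_open + (L-1)*gap_extend, matching the
    search module's convention.
    """
    m, n = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (horizontal)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (vertical)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = _B62[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_score_enumerate(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Optimal global alignment score by exhaustive recursion (tiny inputs).

    State tracks whether the previous column ended in a gap in a or b so
    affine costs are charged exactly.
    """

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if prev == "a" else gap_open
            options.append(cost + rec(i + 1, j, "a"))
        if j < len(b):
            cost = gap_extend if prev == "b" else gap_open
            options.append(cost + rec(i, j + 1, "b"))
        return max(options)

    return rec(0, 0, "m")


def transitive_closure_loci(
    intervals: list[tuple[str, int, int]], merge_distance: int
) -> list[set[int]]:
    """O(n^2) transitive closure of the 'gap <= merge_distance' relation.

    Returns groups of input indices (same-contig chains only).
    """
    n = len(intervals)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci != cj:
                continue
            gap = max(sj - ei, si - ej)
            if gap <= merge_distance:
                adj[i][j] = True
    groups: list[set[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        stack = [i]
        comp = set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        groups.append(comp)
        seen |= comp
    return groups


# ---------------------------------------------------------------------------
# divergence oracles


def k2p_oracle(a: str, b: str) -> float:
    """K2P distance recomputed from scratch on two aligned rows."""
    import math

    pairs = [
        (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
    ]
    n = len(pairs)
    ts = sum(1 for x, y in pairs if x != y and {x, y} in ({"A", "G"}, {"C", "T"}))
    tv = sum(1 for x, y in pairs if x != y) - ts
    P, Q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng_oracle(a: str, b: str, R: float = 2.0) -> tuple[float, float, float, float]:
    """Modified Nei-Gojobori (S, N, Sd, Nd) by exhaustive enumeration.

    Site counting: each codon position contributes the R-weighted fraction
    of its three single-nucleotide changes that are synonymous (changes to
    stops count as nonsynonymous). Differences: equal-weight average over
    orderings of the differing positions, discarding orderings that pass
    through a stop codon unless all do.
    """
    S = N = Sd = Nd = 0.0
    for k in range(0, len(a), 3):
        c1, c2 = a[k : k + 3], b[k : k + 3]
        if "-" in c1 + c2 or any(ch not in "ACGT" for ch in c1 + c2):
            continue
        for codon in (c1, c2):
            s_codon = 0.0
            for pos in range(3):
                num = den = 0.0
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    transition = {codon[pos], nt} in ({"A", "G"}, {"C", "T"})
                    w = R if transition else 1.0
                    den += w
                    mut = codon[:pos] + nt + codon[pos + 1 :]
                    if _aa(mut) != "*" and _aa(mut) == _aa(codon):
                        num += w
                s_codon += num / den
            S += s_codon / 2.0
            N += (3.0 - s_codon) / 2.0
        positions = [p for p in range(3) if c1[p] != c2[p]]
        if not positions:
            continue
        results = []
        for path in itertools.permutations(positions):
            cur = c1
            sd = nd = 0.0
            hit_stop = False
            for p in path:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if _aa(nxt) == "*":
                    hit_stop = True
                if (
                    _aa(nxt) != "*"
                    and _aa(cur) != "*"
                    and _aa(nxt) == _aa(cur)
                ):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((hit_stop, sd, nd))
        clean = [(s, n_) for h, s, n_ in results if not h] or [
            (s, n_) for _, s, n_ in results
        ]
        Sd += sum(s for s, _ in clean) / len(clean)
        Nd += sum(n_ for _, n_ in clean) / len(clean)
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# coverage / mapping / annotation oracles


def per_base_recount(
    placements: list[tuple[str, int]],
    read_length: int,
    intervals: list[tuple[str, int, int]],
) -> list[list[int]]:
    """Per-base depth by direct counting over every interval base."""
    out = []
    for cid, start, end in intervals:
        depth = []
        for pos in range(start, end):
            depth.append(
                sum(
                    1
                    for pc, ps in placements
                    if pc == cid and ps <= pos < ps + read_length
                )
            )
        out.append(depth)
    return out


def exhaustive_substring_placements(read: str, contigs: dict[str, str]) -> list[tuple[str, int, str]]:
    """All exact placements of a read (either strand) by substring scan."""
    from Bio.Seq import Seq

    rc = str(Seq(read).reverse_complement())
    out = []
    for cid, seq in contigs.items():
        for probe, strand in ((read, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                out.append((cid, start, strand))
                start = seq.find(probe, start + 1)
    return out


def six_frame_orfs(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """Exhaustive ATG-to-stop ORF scan, both strands, all frames."""
    from Bio.Seq import Seq

    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            prot = str(Seq(s[frame : frame + 3 * ((L - frame) // 3)]).translate())
            last_stop = -1
            for i, ch in enumerate(prot):
                if ch != "*":
                    continue
                seg = prot[last_stop + 1 : i]
                m = seg.find("M")
                if m != -1 and len(seg) - m >= min_aa:
                    aa_start = last_stop + 1 + m
                    nt0 = frame + 3 * aa_start
                    nt1 = frame + 3 * (i + 1)
                    if strand == "-":
                        nt0, nt1 = L - nt1, L - nt0
                    found.add((nt0, nt1, strand))
                last_stop = i
    return found


def all_pairs_tirs(
    seq: str, min_len: int, max_len: int, max_mismatch: int, window: int
) -> tuple[int, int, int, int] | None:
    """Best TIR pair by scanning every (left, right, length) combination.

    Returns (left_start, right_start, length, mismatches) under the same
    preference order as the implementation: longest, fewest mismatches,
    leftmost."""
    from Bio.Seq import Seq

    L = len(seq)
    best = None
    for tl in range(max_len, min_len - 1, -1):
        cands = []
        for i in range(0, window - tl + 1):
            left_rc = str(Seq(seq[i : i + tl]).reverse_complement())
            for rs in range(L - window, L - tl + 1):
                mm = sum(1 for x, y in zip(left_rc, seq[rs : rs + tl]) if x != y)
                if mm <= max_mismatch:
                    cands.append((mm, i, rs))
        if cands:
            mm, i, rs = min(cands)
            return (i, rs, tl, mm)
    return best
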