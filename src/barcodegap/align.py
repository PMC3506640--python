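"""Pairwise overlap alignment and a small star-alignment fallback.

The overlap aligner is a semiglobal dynamic program with free end gaps on
both sequences (scores: match +1, mismatch -1, gap -2), the alignment mode
needed for read-overlap detection and reference matching.  Percent identity
is computed over the aligned overlap columns with internal gaps counted as
mismatches.  An optional band around a seed diagonal accelerates large runs;
the unbanded program is exact and is the reference semantics.

``star_align`` is a deliberately minimal multiple-alignment fallback (centre
= longest sequence, pairwise global alignments merged column-wise) intended
for fixture-scale work; real analyses should consume an external aligner's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from numba import njit

from .iupac import degap, encode, revcomp, revcomp_codes

NEG = -(1 << 29)

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


@njit(cache=True, nogil=True)
def _overlap_dp(a, b, d0, half, ops_out):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    P = np.zeros((n + 1, m + 1), np.uint8)  # 0 border, 1 diag, 2 up, 3 left
    banded = half >= 0
    if banded:
        H[:] = NEG
        for j in range(m + 1):
            H[0, j] = 0
        for i in range(n + 1):
            H[i, 0] = 0
    for i in range(1, n + 1):
        if banded:
            jlo = i - d0 - half
            if jlo < 1:
                jlo = 1
            jhi = i - d0 + half
            if jhi > m:
                jhi = m
            if jlo > jhi:
                continue
        else:
            jlo = 1
            jhi = m
        ai = a[i - 1]
        for j in range(jlo, jhi + 1):
            s = MATCH_SCORE if (ai == b[j - 1] and ai < 4) else MISMATCH_SCORE
            best = H[i - 1, j - 1] + s
            ptr = 1
            t = H[i - 1, j] + GAP_SCORE
            if t > best:
                best = t
                ptr = 2
            t = H[i, j - 1] + GAP_SCORE
            if t > best:
                best = t
                ptr = 3
            H[i, j] = best
            P[i, j] = ptr
    bscore = NEG
    bi = n
    bj = 0
    for j in range(m + 1):
        if H[n, j] > bscore:
            bscore = H[n, j]
            bi = n
            bj = j
    for i in range(n + 1):
        if H[i, m] > bscore:
            bscore = H[i, m]
            bi = i
            bj = m
    i = bi
    j = bj
    matches = 0
    cols = 0
    nops = 0
    while i > 0 and j > 0:
        p = P[i, j]
        if p == 0:
            break
        ops_out[nops] = p
        nops += 1
        cols += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    for k in range(nops // 2):
        tmp = ops_out[k]
        ops_out[k] = ops_out[nops - 1 - k]
        ops_out[nops - 1 - k] = tmp
    return bscore, matches, cols, i, j, bi, bj, nops


@njit(cache=True, nogil=True)
def _gapless_diag(a, b, d):  # pragma: no cover - numba
    """Matches/length of the full gapless overlap on diagonal d (= astart-bstart)."""
    if d >= 0:
        a0 = d
        b0 = 0
    else:
        a0 = 0
        b0 = -d
    length = min(a.shape[0] - a0, b.shape[0] - b0)
    if length <= 0:
        return 0, 0
    matches = 0
    for k in range(length):
        if a[a0 + k] == b[b0 + k] and a[a0 + k] < 4:
            matches += 1
    return matches, length


@dataclass
class Overlap:
    """Best semiglobal overlap between two sequences.

    ``orientation`` is '+' if b matched as given, '-' if its reverse
    complement matched; coordinates on b refer to the oriented sequence.
    ``offset`` is the start of b relative to the start of a (negative when
    b overhangs to the left).
    """

    length: int
    identity: float
    orientation: str
    offset: int
    score: int
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0
    ops: np.ndarray = field(default=None, repr=False)


def _run(a_codes: np.ndarray, b_codes: np.ndarray, diag: int, half: int) -> tuple:
    ops = np.empty(a_codes.shape[0] + b_codes.shape[0], dtype=np.uint8)
    res = _overlap_dp(a_codes, b_codes, diag, half, ops)
    return res, ops


def best_overlap(a: str, b: str, band: tuple[int, int] | None = None) -> Overlap:
    """Maximal-scoring free-end-gap overlap of ``a`` and ``b``, both orientations.

    ``band``: optional ``(diagonal, half_width)`` seed restricting the search
    (exact when omitted).  Ties between orientations go to '+'.
    """
    a_codes = encode(a)
    b_f = encode(b)
    b_r = revcomp_codes(b_f)
    diag, half = band if band is not None else (0, -1)
    (sf, mf, cf, asf, bsf, aef, bef, nf), ops_f = _run(a_codes, b_f, diag, half)
    (sr, mr, cr, asr, bsr, aer, ber, nr), ops_r = _run(a_codes, b_r, diag, half)
    if sr > sf:
        score, matches, cols, a0, b0, a1, b1, nops = sr, mr, cr, asr, bsr, aer, ber, nr
        ops = ops_r
        orient = "-"
    else:
        score, matches, cols, a0, b0, a1, b1, nops = sf, mf, cf, asf, bsf, aef, bef, nf
        ops = ops_f
        orient = "+"
    identity = 100.0 * matches / cols if cols else 0.0
    return Overlap(
        length=cols,
        identity=identity,
        orientation=orient,
        offset=a0 - b0,
        score=score,
        a_start=a0,
        a_end=a1,
        b_start=b0,
        b_end=b1,
        ops=ops[:nops],
    )


def gapless_identity(a_codes: np.ndarray, b_codes: np.ndarray, diag: int) -> tuple[int, int]:
    """(matches, length) of the full gapless overlap at a fixed diagonal."""
    return _gapless_diag(a_codes, b_codes, diag)


def shared_kmer_diagonals(
    a: str, b: str, k: int = 16, top: int = 3
) -> list[tuple[int, int]]:
    """Most-supported overlap diagonals between a and b (as given).

    Returns up to ``top`` ``(diagonal, hits)`` pairs, hits descending; the
    diagonal convention matches :class:`Overlap` (astart - bstart).
    """
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    counts: dict[int, int] = {}
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            d = i - j
            counts[d] = counts.get(d, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top]


def edlib_identity(a: str, b: str) -> float:
    """Global-alignment fractional identity (matches / alignment columns)."""
    res = edlib.align(a, b, task="path", mode="NW")
    matches = 0
    cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches / cols if cols else 0.0


def star_align(entries: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Star multiple alignment around the longest sequence (fixture-scale).

    Each sequence is globally aligned to the centre; insertions relative to
    the centre are merged column-wise.  Adequate for low-divergence,
    near-equal-length inputs; not a substitute for a real MSA tool.
    """
    if not entries:
        return []
    seqs = [(sid, degap(s).upper()) for sid, s in entries]
    centre_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i][1]), -i))
    centre = seqs[centre_idx][1]
    lc = len(centre)
    # Parse each pairwise alignment into (ins_before[j], aligned chars per centre col).
    parsed = []
    for sid, seq in seqs:
        if seq == centre:
            parsed.append((sid, [""] * (lc + 1), list(seq)))
            continue
        res = edlib.align(seq, centre, task="path", mode="NW")
        ins_before = [""] * (lc + 1)
        cols = [""] * lc
        qi = 0
        tj = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "=X":
                for _ in range(n):
                    cols[tj] = seq[qi]
                    qi += 1
                    tj += 1
            elif ch == "D":  # gap in query relative to centre
                for _ in range(n):
                    cols[tj] = "-"
                    tj += 1
            elif ch == "I":  # insertion in query before centre column tj
                ins_before[tj] += seq[qi : qi + n]
                qi += n
        parsed.append((sid, ins_before, cols))
    ins_len = [0] * (lc + 1)
    for _, ins_before, _ in parsed:
        for j in range(lc + 1):
            if len(ins_before[j]) > ins_len[j]:
                ins_len[j] = len(ins_before[j])
    out = []
    for sid, ins_before, cols in parsed:
        parts = []
        for j in range(lc):
            parts.append(ins_before[j].ljust(ins_len[j], "-"))
            parts.append(cols[j])
        parts.append(ins_before[lc].ljust(ins_len[lc], "-"))
        out.append((sid, "".join(parts)))
    order = {sid: i for i, (sid, _) in enumerate(entries)}
    out.sort(key=lambda e: order[e[0]])
    return out
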