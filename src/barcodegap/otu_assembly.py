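"""Minimal greedy overlap-consensus assembler for barcode amplicon reads.

Reads (and subsequently contigs) are repeatedly merged pairwise, always
taking the globally best qualifying overlap first, where an overlap
qualifies when its percent identity is at least ``mi`` and its aligned
length at least ``ml`` - the two swept assembly parameters.  Ties are broken
by longer overlap, then lexicographically smaller ids, so assemblies are
fully deterministic.  After each merge the contig consensus is recomputed by
per-column majority vote over base counts (ties resolved in fixed order
A < C < G < T; columns where gaps outvote every base are dropped).  Contigs
with at least two member reads are OTUs; unmerged reads are singletons.

This is a deliberately small stand-in for a production assembler: no
quality weighting, no read re-placement, no scaffolding.  A consequence of
pairwise greedy merging is that two templates whose mutual identity exceeds
``mi`` will end up in one OTU; separating templates at, say, 96% identity
requires mi above 96.

For large read sets an exact all-pairs search is replaced by a k-mer-seeded
candidate search with a gapless-diagonal fast path and banded alignment
fallback; the exact semantics (used automatically at small scale) is the
reference behaviour.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .align import Overlap, _run, gapless_identity
from .iupac import decode, encode, revcomp

_EXACT_LIMIT = 220  # below this many reads, use exact all-pairs semantics
_KMER = 16
_STRIDE = 4
_BAND = 32
_SEED_MARGIN = 4.0  # percent identity slack before banded DP is consulted


@dataclass(frozen=True)
class AssemblyParams:
    """The two swept assembler parameters."""

    ml: int = 100  # minimum overlap length, nucleotides
    mi: float = 92.0  # minimum overlap identity, percent

    def __post_init__(self) -> None:
        if self.ml < 1:
            raise ValueError("ml must be >= 1")
        if not (0.0 < self.mi <= 100.0):
            raise ValueError("mi must be in (0, 100]")


@dataclass
class Otu:
    otu_id: str
    members: list[str]
    consensus: str
    coverage: np.ndarray = field(repr=False, default=None)


@dataclass
class AssemblyResult:
    otus: list[Otu]
    singletons: list[str]
    params: AssemblyParams

    @property
    def n_reads(self) -> int:
        return sum(len(o.members) for o in self.otus) + len(self.singletons)

    def membership(self) -> dict[str, str]:
        out = {rid: "singleton" for rid in self.singletons}
        for otu in self.otus:
            for rid in otu.members:
                out[rid] = otu.otu_id
        return out

    def percent_singletons(self) -> float:
        return 100.0 * len(self.singletons) / self.n_reads if self.n_reads else 0.0

    def write_consensus_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for otu in self.otus:
                fh.write(f">{otu.otu_id} n_members={len(otu.members)}\n{otu.consensus}\n")

    def write_membership(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\totu_id\n")
            for rid, oid in sorted(self.membership().items()):
                fh.write(f"{rid}\t{oid}\n")


class _Contig:
    __slots__ = ("cid", "counts", "codes", "seq", "rc_seq", "members", "_kmer_pos")

    def __init__(self, cid: str, counts: np.ndarray, codes: np.ndarray, members: list[str]):
        self.cid = cid
        self.counts = counts
        self.codes = codes
        self.seq = decode(codes)
        self.rc_seq = revcomp(self.seq)
        self.members = members
        self._kmer_pos: dict[str, list[int]] | None = None

    def kmer_pos(self) -> dict[str, list[int]]:
        if self._kmer_pos is None:
            pos: dict[str, list[int]] = {}
            s = self.seq
            for i in range(len(s) - _KMER + 1):
                pos.setdefault(s[i : i + _KMER], []).append(i)
            self._kmer_pos = pos
        return self._kmer_pos


def _read_contig(rid: str, seq: str) -> _Contig:
    codes = encode(seq.upper())
    counts = np.zeros((codes.size, 5), dtype=np.int32)
    ok = codes < 4  # ambiguous bases keep their position but carry no vote
    counts[np.nonzero(ok)[0], codes[ok]] = 1
    return _Contig(rid, counts, codes, [rid])


def _consensus_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority consensus; gap-majority columns are dropped, base ties A<C<G<T."""
    base_best = counts[:, :4].max(axis=1)
    keep = counts[:, 4] <= base_best
    kept = counts[keep]
    codes = np.argmax(kept[:, :4], axis=1).astype(np.uint8)
    return kept, codes


class _Score(NamedTuple):
    identity: float
    length: int
    orientation: str
    diag: int
    exact: bool  # True when identity/length are DP-exact already


def _oriented_overlap(
    a_codes: np.ndarray, b_codes: np.ndarray, diag: int, half: int
) -> tuple:
    return _run(a_codes, b_codes, diag, half)


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _score_fast(a: _Contig, b: _Contig, params: AssemblyParams) -> _Score | None:
    """Seeded overlap score: gapless fast path, banded DP when borderline."""
    apos = a.kmer_pos()
    best: _Score | None = None
    for orient, bseq in (("+", b.seq), ("-", b.rc_seq)):
        votes: dict[int, int] = {}
        limit = len(bseq) - _KMER + 1
        for j in range(0, limit, _STRIDE):
            for i in apos.get(bseq[j : j + _KMER], ()):
                d = i - j
                votes[d] = votes.get(d, 0) + 1
        if not votes:
            continue
        b_codes = encode(bseq)
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
        for d, _hits in ranked:
            matches, length = gapless_identity(a.codes, b_codes, d)
            if length == 0:
                continue
            ident = 100.0 * matches / length
            if matches == length:
                cand = _Score(100.0, length, orient, d, True)
            elif ident >= params.mi - _SEED_MARGIN:
                (score, m, cols, *_rest), _ops = _oriented_overlap(a.codes, b_codes, d, _BAND)
                if cols == 0:
                    continue
                cand = _Score(100.0 * m / cols, cols, orient, d, True)
            else:
                continue
            key = (cand.identity, cand.length, cand.orientation == "+")
            if best is None or key > (best.identity, best.length, best.orientation == "+"):
                best = cand
    return best


def _score_exact(a: _Contig, b: _Contig) -> _Score:
    best = None
    for orient, bseq in (("+", b.seq), ("-", b.rc_seq)):
        b_codes = encode(bseq)
        (score, m, cols, *_rest), _ops = _oriented_overlap(a.codes, b_codes, 0, -1)
        ident = 100.0 * m / cols if cols else 0.0
        key = (score, orient == "+")
        if best is None or key > best[0]:
            best = (key, _Score(ident, cols, orient, 0, True))
    return best[1]


def _full_overlap(a: _Contig, b: _Contig, sc: _Score, fast: bool) -> Overlap:
    """Recompute the overlap with traceback, for merging."""
    bseq = b.seq if sc.orientation == "+" else b.rc_seq
    b_codes = encode(bseq)
    if fast:
        matches, length = gapless_identity(a.codes, b_codes, sc.diag)
        if matches == length and length == sc.length:
            a0 = max(sc.diag, 0)
            b0 = max(-sc.diag, 0)
            ops = np.ones(length, dtype=np.uint8)
            return Overlap(
                length, 100.0, sc.orientation, sc.diag, length, a0, a0 + length,
                b0, b0 + length, ops,
            )
        res, ops_buf = _run(a.codes, b_codes, sc.diag, _BAND)
    else:
        res, ops_buf = _run(a.codes, b_codes, 0, -1)
    score, m, cols, a0, b0, a1, b1, nops = res
    ops = ops_buf[:nops]
    ident = 100.0 * m / cols if cols else 0.0
    return Overlap(cols, ident, sc.orientation, a0 - b0, score, a0, a1, b0, b1, ops)


def _merge(a: _Contig, b: _Contig, ov: Overlap, new_id: str) -> _Contig:
    bc = b.counts
    if ov.orientation == "-":
        bc = bc[::-1][:, [3, 2, 1, 0, 4]]
    rows: list[np.ndarray] = []
    if ov.a_start > 0:
        rows.append(a.counts[: ov.a_start])
    elif ov.b_start > 0:
        rows.append(bc[: ov.b_start])
    i, j = ov.a_start, ov.b_start
    mid = np.zeros((len(ov.ops), 5), dtype=np.int32)
    la, lb = a.counts.shape[0], bc.shape[0]
    for r, op in enumerate(ov.ops):
        if op == 1:
            mid[r] = a.counts[i] + bc[j]
            i += 1
            j += 1
        elif op == 2:  # column consumed by a only -> b votes gap
            cov_b = int(bc[min(j, lb - 1), :4].sum())
            mid[r] = a.counts[i]
            mid[r, 4] += cov_b
            i += 1
        else:  # column consumed by b only -> a votes gap
            cov_a = int(a.counts[min(i, la - 1), :4].sum())
            mid[r] = bc[j]
            mid[r, 4] += cov_a
            j += 1
    rows.append(mid)
    if ov.a_end < la:
        rows.append(a.counts[ov.a_end :])
    elif ov.b_end < lb:
        rows.append(bc[ov.b_end :])
    counts = np.vstack(rows)
    counts, codes = _consensus_from_counts(counts)
    return _Contig(new_id, counts, codes, a.members + b.members)


def best_overlap_pair(a_seq: str, b_seq: str):
    """Public exact overlap (see :func:`barcodegap.align.best_overlap`)."""
    from .align import best_overlap

    return best_overlap(a_seq, b_seq)


def assemble(
    reads: Sequence[tuple[str, str]] | Iterable,
    params: AssemblyParams | None = None,
    fast: bool | None = None,
) -> AssemblyResult:
    """Greedy best-first overlap assembly of reads into OTUs.

    ``reads`` are (id, sequence) pairs (a third quality element is
    ignored).  Every input read ends up in exactly one OTU or in the
    singleton list.  ``fast=None`` selects exact all-pairs search for small
    inputs and the seeded search for large ones.
    """
    params = params or AssemblyParams()
    items = [(r[0], r[1]) for r in reads]
    if not items:
        raise ValueError("need at least one read")
    ids = [rid for rid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("read ids must be unique")
    if fast is None:
        fast = len(items) > _EXACT_LIMIT

    contigs: dict[str, _Contig] = {}
    for rid, seq in items:
        contigs[rid] = _read_contig(rid, seq)

    heap: list[tuple[float, int, str, str]] = []

    def _push(x: str, y: str, sc: _Score | None) -> None:
        if sc is None:
            return
        if sc.identity >= params.mi and sc.length >= params.ml:
            if y < x:
                x, y = y, x
            heapq.heappush(heap, (-sc.identity, -sc.length, x, y))

    index: dict[str, list[str]] = {}

    def _register(c: _Contig) -> None:
        s = c.seq
        for i in range(0, max(len(s) - _KMER + 1, 0), _STRIDE):
            index.setdefault(_canon(s[i : i + _KMER]), []).append(c.cid)

    def _candidates(c: _Contig, stride: int = 1) -> list[str]:
        # store is stride-sampled; querying every k-mer (stride 1) guarantees
        # discovery of any exact run >= _KMER + _STRIDE - 1
        found: set[str] = set()
        s = c.seq
        for i in range(0, max(len(s) - _KMER + 1, 0), stride):
            for cid in index.get(_canon(s[i : i + _KMER]), ()):
                if cid != c.cid and cid in contigs:
                    found.add(cid)
        return sorted(found)

    score_cache_pairs: set[tuple[str, str]] = set()

    def _score_and_push(x: str, y: str) -> None:
        key = (x, y) if x <= y else (y, x)
        if key in score_cache_pairs:
            return
        score_cache_pairs.add(key)
        a, b = contigs[key[0]], contigs[key[1]]
        sc = _score_fast(a, b, params) if fast else _score_exact(a, b)
        _push(key[0], key[1], sc)

    if fast:
        for c in contigs.values():
            _register(c)
        for rid in ids:
            for other in _candidates(contigs[rid], stride=_STRIDE):
                _score_and_push(rid, other)
    else:
        for xi in range(len(ids)):
            for yi in range(xi + 1, len(ids)):
                _score_and_push(ids[xi], ids[yi])

    merge_counter = 0
    while heap:
        _nid, _nlen, x, y = heapq.heappop(heap)
        if x not in contigs or y not in contigs:
            continue
        a = contigs[x]
        b = contigs[y]
        sc = _score_fast(a, b, params) if fast else _score_exact(a, b)
        if sc is None or sc.identity < params.mi or sc.length < params.ml:
            continue
        ov = _full_overlap(a, b, sc, fast)
        if ov.identity < params.mi or ov.length < params.ml:
            continue
        del contigs[x], contigs[y]
        merge_counter += 1
        new_id = f"C{merge_counter:06d}"
        merged = _merge(a, b, ov, new_id)
        contigs[new_id] = merged
        if fast:
            _register(merged)
            partners = _candidates(merged)
        else:
            partners = sorted(c for c in contigs if c != new_id)
        for other in partners:
            _score_and_push(new_id, other)

    otus: list[Otu] = []
    singletons: list[str] = []
    finished = sorted(
        contigs.values(), key=lambda c: (-len(c.members), c.members[0])
    )
    for c in finished:
        if len(c.members) >= 2:
            coverage = c.counts[:, :4].sum(axis=1)
            otus.append(
                Otu(f"OTU_{len(otus) + 1:03d}", sorted(c.members), c.seq, coverage)
            )
        else:
            singletons.append(c.members[0])
    singletons.sort()
    return AssemblyResult(otus, singletons, params)
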