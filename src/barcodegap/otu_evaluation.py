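"""OTU assembly evaluation: confusion counts, Sn/Sp/residual error, cleanup.

Every assembled read and every OTU consensus is assigned its best-matching
reference template by exhaustive semiglobal (free-end-gap) alignment, then
per-OTU confusion counts follow the reference-concordance definitions:

* TP - reads in the OTU matching the same reference as its consensus;
* FP - reads in the OTU matching a different reference;
* TN - reads in *other* OTUs matching their own OTU's consensus reference,
  when that reference differs from the evaluated OTU's;
* FN - reads assembled into other OTUs that match the evaluated OTU's
  consensus reference.

Specificity Sp = TN/(TN+FP), sensitivity Sn = TP/(TP+FN), and the residual
error of an OTU is the Euclidean distance of (Sp, Sn) from the perfect
corner (1, 1): E = sqrt((1-Sp)^2 + (1-Sn)^2), so 0 <= E <= sqrt(2).  Total
assembly error is the sum of E over OTUs.  Singleton reads are data loss,
reported separately, and never enter the confusion counts.  Degenerate
denominators (for instance a single-OTU assembly, where TN+FP = 0) define
the affected ratio as 1.0 and set a flag.

Post-assembly cleanup mirrors the standard pipeline: amplification primer
footprints are trimmed from consensus ends, OTUs whose trimmed consensus is
identical to (or an exact substring of) another's are collapsed, and an OTU
is flagged chimeric when its 5'-150 bp and 3'-150 bp segments best-match
different references.  ``sweep`` drives assemblies over grids of the two
assembler parameters and tabulates total error, OTU count and singleton
percentage at each cleanup stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import _run, best_overlap, gapless_identity
from .barcode_delineation import PrimerPair
from .iupac import encode, encode_bits, revcomp
from .otu_assembly import AssemblyParams, AssemblyResult, Otu, assemble

_KMER = 16
_BAND = 48


@dataclass(frozen=True)
class ReferenceMatch:
    query_id: str
    reference_id: str
    identity: float  # percent over the aligned overlap
    query_span: tuple[int, int]  # aligned span on the query, 0-based half-open


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class OtuEvaluation:
    otu_id: str
    counts: ConfusionCounts
    sp: float
    sn: float
    residual_error: float
    degenerate_sp: bool = False
    degenerate_sn: bool = False
    chimeric: bool = False
    chimera_status: str = "ok"


@dataclass
class AssemblyEvaluation:
    stage: str
    per_otu: list[OtuEvaluation]
    percent_singletons: float
    n_unmatched_reads: int = 0
    n_unmatched_otus: int = 0

    @property
    def n_otus(self) -> int:
        return len(self.per_otu)

    @property
    def total_error(self) -> float:
        """Total assembly error: the sum of residual errors over OTUs."""
        return float(sum(e.residual_error for e in self.per_otu))


class ReferenceSet:
    """Reference templates with cached k-mer indexes for fast matching."""

    def __init__(self, references: Sequence[tuple[str, str]]):
        if not references:
            raise ValueError("references must be non-empty")
        self.entries = [(rid, seq.upper()) for rid, seq in references]
        self.codes = {rid: encode(seq) for rid, seq in self.entries}
        self._kmers: dict[str, dict[str, list[int]]] = {}
        for rid, seq in self.entries:
            pos: dict[str, list[int]] = {}
            for i in range(len(seq) - _KMER + 1):
                pos.setdefault(seq[i : i + _KMER], []).append(i)
            self._kmers[rid] = pos

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.entries]

    def kmer_pos(self, rid: str) -> dict[str, list[int]]:
        return self._kmers[rid]


def _as_refset(references) -> ReferenceSet:
    return references if isinstance(references, ReferenceSet) else ReferenceSet(list(references))


def _fast_candidates(refset: ReferenceSet, query: str) -> list[tuple[float, int, str, str, int]]:
    """Per-reference best gapless diagonal: (identity, length, rid, orient, diag)."""
    out = []
    variants = (("+", query), ("-", revcomp(query)))
    for rid, _seq in refset.entries:
        rpos = refset.kmer_pos(rid)
        rcodes = refset.codes[rid]
        best = None
        for orient, q in variants:
            votes: dict[int, int] = {}
            for j in range(0, max(len(q) - _KMER + 1, 0), 2):
                for i in rpos.get(q[j : j + _KMER], ()):
                    d = i - j
                    votes[d] = votes.get(d, 0) + 1
            if not votes:
                continue
            qc = encode(q)
            for d, _h in sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:3]:
                m, length = gapless_identity(rcodes, qc, d)
                if length == 0:
                    continue
                ident = 100.0 * m / length
                if best is None or (ident, length) > (best[0], best[1]):
                    best = (ident, length, rid, orient, d)
        if best is not None:
            out.append(best)
    return out


def best_reference_match(
    query: str,
    references,
    min_identity: float = 55.0,
    query_id: str = "",
    fast: bool | None = None,
    min_coverage: float = 0.5,
) -> ReferenceMatch | None:
    """Highest-identity semiglobal match of a query against the references.

    Both query orientations are tried; ties go to the lexicographically
    smallest reference id; matches below ``min_identity`` percent yield
    None.  A match must also cover at least ``min_coverage`` of the shorter
    sequence, so short incidental end-overlaps between unrelated sequences
    never qualify.  The seeded fast path falls back to exhaustive exact
    alignment whenever it finds nothing convincing.
    """
    if not query:
        raise ValueError("empty query sequence")
    refset = _as_refset(references)
    if fast is None:
        fast = True

    def _covers(cols: int, rid: str) -> bool:
        return cols >= min_coverage * min(len(query), len(dict(refset.entries)[rid]))

    best: tuple[float, int, str, tuple[int, int]] | None = None
    if fast:
        cands = sorted(_fast_candidates(refset, query), key=lambda t: (-t[0], -t[1], t[2]))
        for ident, length, rid, orient, d in cands[:3]:
            rcodes = refset.codes[rid]
            q = query if orient == "+" else revcomp(query)
            qc = encode(q)
            if ident == 100.0:
                m, cols, b0 = length, length, max(-d, 0)
                span = (b0, b0 + length)
                cand = (100.0, cols, rid, span)
            else:
                res, _ops = _run(rcodes, qc, d, _BAND)
                _score, m, cols, _a0, b0, _a1, b1, _n = res
                if cols == 0:
                    continue
                cand = (100.0 * m / cols, cols, rid, (b0, b1))
            if not _covers(cand[1], cand[2]):
                continue
            if best is None or (cand[0], -_ref_rank(refset, cand[2])) > (
                best[0],
                -_ref_rank(refset, best[2]),
            ):
                best = cand
    if best is None or best[0] < min_identity:
        # exhaustive exact search
        best = None
        for rid, seq in refset.entries:
            ov = best_overlap(seq, query)
            cand = (ov.identity, ov.length, rid, (ov.b_start, ov.b_end))
            if not _covers(cand[1], cand[2]):
                continue
            if best is None or (cand[0], -_ref_rank(refset, cand[2])) > (
                best[0],
                -_ref_rank(refset, best[2]),
            ):
                best = cand
    if best is None or best[0] < min_identity:
        return None
    return ReferenceMatch(query_id, best[2], best[0], best[3])


def _ref_rank(refset: ReferenceSet, rid: str) -> int:
    # lexicographic tie-break helper (smaller rank = preferred)
    ids = refset.ids()
    return ids.index(rid)


def match_reads_and_otus(
    assembly: AssemblyResult,
    reads: Sequence[tuple[str, str]],
    references,
    min_identity: float = 55.0,
    read_matches: Mapping[str, ReferenceMatch | None] | None = None,
) -> tuple[dict[str, str | None], dict[str, str | None]]:
    """Best-reference assignment for every assembled read and every consensus."""
    refset = _as_refset(references)
    seq_of = dict((rid, seq) for rid, seq in ((r[0], r[1]) for r in reads))
    assembled = [rid for otu in assembly.otus for rid in otu.members]
    read_ref: dict[str, str | None] = {}
    for rid in assembled:
        if read_matches is not None and rid in read_matches:
            m = read_matches[rid]
        else:
            m = best_reference_match(seq_of[rid], refset, min_identity, rid)
        read_ref[rid] = m.reference_id if m else None
    otu_ref: dict[str, str | None] = {}
    for otu in assembly.otus:
        m = best_reference_match(otu.consensus, refset, min_identity, otu.otu_id)
        otu_ref[otu.otu_id] = m.reference_id if m else None
    return read_ref, otu_ref


def _confusion_from_maps(
    target_id: str,
    assembly: AssemblyResult,
    read_ref: Mapping[str, str | None],
    otu_ref: Mapping[str, str | None],
) -> ConfusionCounts:
    target_ref = otu_ref[target_id]
    tp = fp = tn = fn = 0
    for otu in assembly.otus:
        if otu_ref.get(otu.otu_id) is None:
            continue
        for rid in otu.members:
            ref = read_ref.get(rid)
            if ref is None:
                continue
            if otu.otu_id == target_id:
                if ref == target_ref:
                    tp += 1
                else:
                    fp += 1
            else:
                if ref == target_ref:
                    fn += 1
                elif ref == otu_ref[otu.otu_id]:
                    tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def confusion_counts(
    target_id: str,
    assembly: AssemblyResult,
    reads: Sequence[tuple[str, str]],
    references,
    min_identity: float = 55.0,
) -> ConfusionCounts:
    """Confusion counts of one OTU against the rest of the assembly."""
    if target_id not in {o.otu_id for o in assembly.otus}:
        raise KeyError(f"OTU '{target_id}' not in assembly")
    read_ref, otu_ref = match_reads_and_otus(assembly, reads, references, min_identity)
    return _confusion_from_maps(target_id, assembly, read_ref, otu_ref)


def _ratios(counts: ConfusionCounts) -> tuple[float, float, bool, bool, float]:
    deg_sp = (counts.tn + counts.fp) == 0
    deg_sn = (counts.tp + counts.fn) == 0
    sp = 1.0 if deg_sp else counts.tn / (counts.tn + counts.fp)
    sn = 1.0 if deg_sn else counts.tp / (counts.tp + counts.fn)
    e = math.sqrt((1.0 - sp) ** 2 + (1.0 - sn) ** 2)
    return sp, sn, deg_sp, deg_sn, e


def evaluate_assembly(
    assembly: AssemblyResult,
    reads: Sequence[tuple[str, str]],
    references,
    min_identity: float = 55.0,
    stage: str = "raw",
    read_matches: Mapping[str, ReferenceMatch | None] | None = None,
) -> AssemblyEvaluation:
    """Per-OTU Sp/Sn/residual error and the total assembly error.

    Reads or consensuses without any reference match are excluded from the
    counts and reported via ``n_unmatched_*``.
    """
    refset = _as_refset(references)
    read_ref, otu_ref = match_reads_and_otus(
        assembly, reads, refset, min_identity, read_matches
    )
    per_otu: list[OtuEvaluation] = []
    n_unmatched_otus = sum(1 for v in otu_ref.values() if v is None)
    n_unmatched_reads = sum(1 for v in read_ref.values() if v is None)
    for otu in assembly.otus:
        if otu_ref[otu.otu_id] is None:
            continue
        counts = _confusion_from_maps(otu.otu_id, assembly, read_ref, otu_ref)
        sp, sn, deg_sp, deg_sn, e = _ratios(counts)
        per_otu.append(
            OtuEvaluation(otu.otu_id, counts, sp, sn, e, deg_sp, deg_sn)
        )
    return AssemblyEvaluation(
        stage=stage,
        per_otu=per_otu,
        percent_singletons=assembly.percent_singletons(),
        n_unmatched_reads=n_unmatched_reads,
        n_unmatched_otus=n_unmatched_otus,
    )


# ---------------------------------------------------------------------------
# Post-assembly cleanup
# ---------------------------------------------------------------------------


def _mismatches_at(seq_bits: np.ndarray, primer_bits: np.ndarray, pos: int) -> int:
    lp = primer_bits.size
    if pos < 0 or pos + lp > seq_bits.size:
        return lp
    window = seq_bits[pos : pos + lp]
    return int(((window & primer_bits) == 0).sum())


def trim_primers(
    consensus: str,
    pair: PrimerPair,
    max_mismatches: int = 3,
    end_slack: int = 5,
) -> str:
    """Remove amplification-primer footprints from the consensus ends.

    A degenerate-aware primer match starting within ``end_slack`` bases of
    the 5' end (or ending within ``end_slack`` of the 3' end), in either
    consensus orientation, is removed together with anything outside it.
    The interior is never touched.
    """
    bits = encode_bits(consensus)
    n = bits.size
    five_prime = (pair.forward, pair.reverse)  # sense / antisense consensus
    three_prime = (revcomp(pair.reverse), revcomp(pair.forward))
    start = 0
    best = None
    for pseq in five_prime:
        pb = encode_bits(pseq)
        for pos in range(0, end_slack + 1):
            mm = _mismatches_at(bits, pb, pos)
            if mm <= max_mismatches and (best is None or (mm, pos) < best[:2]):
                best = (mm, pos, pos + pb.size)
    if best is not None:
        start = best[2]
    end = n
    best = None
    for pseq in three_prime:
        pb = encode_bits(pseq)
        for back in range(0, end_slack + 1):
            pos = n - pb.size - back
            mm = _mismatches_at(bits, pb, pos)
            if mm <= max_mismatches and (best is None or (mm, back) < best[:2]):
                best = (mm, back, pos)
    if best is not None:
        end = best[2]
    if start >= end:
        return consensus
    return consensus[start:end]


def trim_assembly(assembly: AssemblyResult, pair: PrimerPair, **kw) -> AssemblyResult:
    """New assembly with every OTU consensus primer-trimmed."""
    otus = [
        Otu(o.otu_id, list(o.members), trim_primers(o.consensus, pair, **kw), o.coverage)
        for o in assembly.otus
    ]
    return AssemblyResult(otus, list(assembly.singletons), assembly.params)


def collapse_identical(otus: Sequence[Otu]) -> list[Otu]:
    """Merge OTUs whose consensus is identical to, or an exact substring of,
    another's (either orientation); the longer consensus wins, members union."""
    ordered = sorted(otus, key=lambda o: (-len(o.consensus), o.otu_id))
    kept: list[Otu] = []
    for otu in ordered:
        host = None
        for k in kept:
            if otu.consensus in k.consensus or revcomp(otu.consensus) in k.consensus:
                host = k
                break
        if host is None:
            kept.append(Otu(otu.otu_id, list(otu.members), otu.consensus, otu.coverage))
        else:
            host.members = sorted(set(host.members) | set(otu.members))
    kept.sort(key=lambda o: o.otu_id)
    return kept


def collapse_assembly(assembly: AssemblyResult) -> AssemblyResult:
    return AssemblyResult(
        collapse_identical(assembly.otus), list(assembly.singletons), assembly.params
    )


def chimera_status(
    consensus: str,
    references,
    segment: int = 150,
    min_identity: float = 55.0,
) -> str:
    """'chimeric' when the 5' and 3' terminal segments best-match different
    references; 'too_short' below 2 x segment (not evaluable); else 'ok'."""
    if len(consensus) < 2 * segment:
        return "too_short"
    refset = _as_refset(references)
    head = best_reference_match(consensus[:segment], refset, min_identity)
    tail = best_reference_match(consensus[-segment:], refset, min_identity)
    if head is not None and tail is not None and head.reference_id != tail.reference_id:
        return "chimeric"
    return "ok"


def flag_chimera(consensus: str, references, segment: int = 150) -> bool:
    """True iff the consensus terminal segments name different references."""
    return chimera_status(consensus, references, segment) == "chimeric"


def remove_chimeras(
    assembly: AssemblyResult, references, segment: int = 150
) -> tuple[AssemblyResult, list[Otu]]:
    """Drop chimeric OTUs; their reads become unassembled (excluded, reported)."""
    kept: list[Otu] = []
    removed: list[Otu] = []
    for otu in assembly.otus:
        if chimera_status(otu.consensus, references, segment) == "chimeric":
            removed.append(otu)
        else:
            kept.append(otu)
    return AssemblyResult(kept, list(assembly.singletons), assembly.params), removed


# ---------------------------------------------------------------------------
# Parameter sweep driver
# ---------------------------------------------------------------------------


def sweep(
    reads: Sequence[tuple[str, str]],
    references,
    ml_values: Iterable[int],
    mi_values: Iterable[float],
    primer_pair: PrimerPair,
    min_identity: float = 55.0,
    fast: bool | None = None,
) -> pd.DataFrame:
    """Assemble/evaluate over a parameter grid at all three cleanup stages.

    Returns a tidy table with one row per (ml, mi, stage), carrying total
    error, OTU count and singleton percentage - the machine-readable twin of
    the error trade-off figure.
    """
    refset = _as_refset(references)
    read_list = [(r[0], r[1]) for r in reads]
    match_cache: dict[str, ReferenceMatch | None] = {
        rid: best_reference_match(seq, refset, min_identity, rid)
        for rid, seq in read_list
    }
    rows = []
    for ml in ml_values:
        for mi in mi_values:
            params = AssemblyParams(ml=ml, mi=mi)
            asm = assemble(read_list, params, fast=fast)
            stages = [("raw", asm)]
            cleaned = collapse_assembly(trim_assembly(asm, primer_pair))
            stages.append(("trimmed+clustered", cleaned))
            dechim, removed = remove_chimeras(cleaned, refset)
            stages.append(("chimera-removed", dechim))
            for stage, stage_asm in stages:
                ev = evaluate_assembly(
                    stage_asm, read_list, refset, min_identity, stage, match_cache
                )
                rows.append(
                    {
                        "ml": ml,
                        "mi": mi,
                        "stage": stage,
                        "total_error": ev.total_error,
                        "n_otus": ev.n_otus,
                        "percent_singletons": ev.percent_singletons,
                        "n_chimeric_removed": len(removed) if stage == "chimera-removed" else 0,
                    }
                )
    return pd.DataFrame(rows)


def write_per_otu_table(evaluation: AssemblyEvaluation, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tTP\tFP\tTN\tFN\tSp\tSn\tE\tdegenerate\tchimera\n")
        for e in evaluation.per_otu:
            c = e.counts
            deg = "Sp" * e.degenerate_sp + ("," if e.degenerate_sp and e.degenerate_sn else "") + "Sn" * e.degenerate_sn
            fh.write(
                f"{e.otu_id}\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}\t{e.sp:.4f}\t"
                f"{e.sn:.4f}\t{e.residual_error:.4f}\t{deg or '-'}\t{e.chimera_status}\n"
            )
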