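"""Barcode region definition from PCR primer pairs.

A barcode region is the amplicon interior delimited by a primer pair: the
sequence strictly between the two annealing footprints, primers excluded.
Primer matching is degenerate-aware (IUPAC codes expand; inosine matches any
base) with a configurable Hamming mismatch tolerance.  Reverse primers are
stored 5'->3' on the antisense strand, as primers are written, so their
plus-strand footprint is the reverse complement.

The shipped primer table covers the standard 16S rRNA variable-region pairs
(V1-V3, V2-V4, V3-V5, V6, V6-alternate) and the cpn60 universal-target pair
H279/H280 (E. coli chaperonin nucleotides 274-828).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .iupac import GAP_CHARS, encode_bits, revcomp


@dataclass(frozen=True)
class PrimerPair:
    name: str
    gene: str
    region: str
    forward: str
    reverse: str  # 5'->3' on the antisense strand
    ecoli_start: int  # 1-based inclusive on the E. coli reference gene
    ecoli_end: int

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if not self.ecoli_start < self.ecoli_end:
            raise ValueError("reference coordinates must satisfy start < end")


@dataclass(frozen=True)
class AnnealingSite:
    seq_id: str
    strand: str  # '+' primer as given, '-' reverse complement footprint
    start: int  # 0-based half-open on the degapped sequence
    end: int
    mismatches: int


@dataclass(frozen=True)
class BarcodeRegion:
    seq_id: str
    sequence: str  # gap-free amplicon interior
    start: int  # 0-based half-open interval on the degapped source
    end: int


def load_primer_pairs() -> dict[str, PrimerPair]:
    """The packaged primer table, keyed by region label."""
    pairs: dict[str, PrimerPair] = {}
    text = resources.files("barcodegap").joinpath("data/primers.tsv").read_text()
    header = None
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        pair = PrimerPair(
            name=f"{row['forward_name']}/{row['reverse_name']}",
            gene=row["gene"],
            region=row["region"],
            forward=row["forward"],
            reverse=row["reverse"],
            ecoli_start=int(row["ecoli_start"]),
            ecoli_end=int(row["ecoli_end"]),
        )
        pairs[pair.region] = pair
    return pairs


def _scan(seq_bits: np.ndarray, primer: str) -> np.ndarray:
    """Mismatch count of the primer at every start position (vectorized)."""
    pb = encode_bits(primer)
    lp = len(pb)
    if len(seq_bits) < lp:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, lp)
    return ((windows & pb) == 0).sum(axis=1)


def match_primer(
    sequence: str,
    primer: str,
    max_mismatches: int = 3,
    seq_id: str = "",
) -> list[AnnealingSite]:
    """All annealing sites of a degenerate primer, best (fewest mismatches) first.

    Both orientations are searched: strand '+' is the primer as given,
    strand '-' its reverse complement (the plus-strand footprint of a
    reverse primer).  Gap characters in the input are skipped; reported
    coordinates are on the degapped sequence.
    """
    if len(primer.replace("I", "").replace("i", "")) == 0:
        raise ValueError("primer must contain at least one defined base")
    clean = sequence
    for g in GAP_CHARS:
        clean = clean.replace(g, "")
    bits = encode_bits(clean)
    sites: list[AnnealingSite] = []
    lp = len(primer)
    for strand, pseq in (("+", primer), ("-", revcomp(primer))):
        mm = _scan(bits, pseq)
        for pos in np.nonzero(mm <= max_mismatches)[0]:
            sites.append(
                AnnealingSite(seq_id, strand, int(pos), int(pos) + lp, int(mm[pos]))
            )
    sites.sort(key=lambda s: (s.mismatches, s.start, s.strand))
    return sites


def delineate_with_report(
    alignment: list[tuple[str, str]],
    pair: PrimerPair,
    max_mismatches: int = 3,
) -> tuple[list[BarcodeRegion], list[str]]:
    """Extract the inter-primer interior of every sequence; report failures.

    Returns ``(regions, skipped_ids)``.  For each sequence the best forward
    site ('+' strand of the forward primer) and the best reverse site ('-'
    strand footprint of the reverse primer downstream of it) bound the
    region; sequences missing either site are skipped.  Multiple candidate
    sites are resolved best-mismatch-first, then leftmost (forward) /
    rightmost (reverse); further hits are ignored by design.
    """
    regions: list[BarcodeRegion] = []
    skipped: list[str] = []
    for seq_id, gapped in alignment:
        clean = gapped
        for g in GAP_CHARS:
            clean = clean.replace(g, "")
        clean = clean.upper()
        fwd_sites = [
            s
            for s in match_primer(clean, pair.forward, max_mismatches, seq_id)
            if s.strand == "+"
        ]
        if not fwd_sites:
            skipped.append(seq_id)
            continue
        fwd = fwd_sites[0]
        rev_sites = [
            s
            for s in match_primer(clean, pair.reverse, max_mismatches, seq_id)
            if s.strand == "-" and s.start >= fwd.end
        ]
        if not rev_sites:
            skipped.append(seq_id)
            continue
        rev = min(rev_sites, key=lambda s: (s.mismatches, -s.start))
        regions.append(
            BarcodeRegion(seq_id, clean[fwd.end : rev.start], fwd.end, rev.start)
        )
    if alignment and not regions:
        warnings.warn(
            f"no sequence contained both {pair.name} annealing sites "
            f"(max_mismatches={max_mismatches})",
            stacklevel=2,
        )
    return regions, skipped


def delineate_region(
    alignment: list[tuple[str, str]],
    pair: PrimerPair,
    max_mismatches: int = 3,
) -> list[BarcodeRegion]:
    """:func:`delineate_with_report` without the skip list."""
    regions, _ = delineate_with_report(alignment, pair, max_mismatches)
    return regions
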