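"""Sliding-window nearest-neighbour identity profiles along a marker.

For every 120-bp window (default) along a reference sequence of the
alignment, each covering sequence is compared to its closest neighbour from
a *different genome* over the window's columns, and the median of those
per-sequence best identities is reported at the window midpoint.  Uniformly
high medians indicate conserved stretches; a flat profile well below 100%
is the signature of evenly distributed diversity (the cpn60 universal
target behaves this way, while 16S rRNA alternates conserved and variable
regions).

A window is emitted only when at least ``coverage_fraction`` (default 95%)
of the sequences span it fully, which suppresses edge windows where target
length variation would bias the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .iupac import GAP_CHARS


@dataclass
class WindowPoint:
    midpoint: int  # 1-based position on the (degapped) reference
    median_identity: float
    n_sequences: int


@dataclass
class WindowProfile:
    window_length: int
    coverage_fraction: float
    reference_id: str
    points: list[WindowPoint]

    def to_rows(self) -> list[tuple[int, float, int]]:
        return [(p.midpoint, p.median_identity, p.n_sequences) for p in self.points]


def _matrix(entries: Sequence[tuple[str, str]]) -> np.ndarray:
    """Alignment as a char matrix; gaps are encoded per-row-unique so a gap
    never matches anything, including another gap."""
    n = len(entries)
    length = len(entries[0][1])
    mat = np.empty((n, length), dtype=np.int32)
    for i, (_, seq) in enumerate(entries):
        if len(seq) != length:
            raise ValueError("alignment rows must have equal length")
        row = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).astype(np.int32)
        for g in GAP_CHARS:
            row[row == ord(g)] = 1000 + i
        mat[i] = row
    return mat


def _spans(mat: np.ndarray) -> list[tuple[int, int]]:
    spans = []
    for i in range(mat.shape[0]):
        non_gap = np.nonzero(mat[i] < 1000)[0]
        if non_gap.size == 0:
            spans.append((0, -1))
        else:
            spans.append((int(non_gap[0]), int(non_gap[-1])))
    return spans


def nearest_neighbor_identity(
    seq_index: int,
    cols: np.ndarray,
    mat: np.ndarray,
    genomes: Sequence[str],
    covering: np.ndarray,
) -> float | None:
    """Best percent identity of one sequence to any covering sequence from
    another genome, over the given alignment columns (gaps mismatch).

    Returns None when no eligible neighbour covers the window.
    """
    row = mat[seq_index][cols]
    best = None
    for j in np.nonzero(covering)[0]:
        if j == seq_index or genomes[j] == genomes[seq_index]:
            continue
        ident = 100.0 * float((mat[j][cols] == row).sum()) / cols.size
        if best is None or ident > best:
            best = ident
    return best


def window_profile(
    entries: Sequence[tuple[str, str]],
    genome_of: Mapping[str, str],
    window_length: int = 120,
    coverage_fraction: float = 0.95,
    step: int = 1,
    reference_id: str | None = None,
) -> WindowProfile:
    """Median nearest-neighbour identity in sliding windows along a reference.

    ``entries`` is the gapped alignment; ``genome_of`` maps sequence id to
    genome id (same-genome paralogs are never counted as neighbours).
    Windows are positioned on the degapped coordinates of the reference
    (default: the longest degapped sequence) and advanced by ``step``.
    """
    if not entries:
        raise ValueError("alignment is empty")
    mat = _matrix(entries)
    ids = [sid for sid, _ in entries]
    genomes = [genome_of.get(sid, sid) for sid in ids]
    if reference_id is None:
        lengths = [(mat[i] < 1000).sum() for i in range(len(ids))]
        ref_idx = int(np.argmax(lengths))
    else:
        ref_idx = ids.index(reference_id)
    ref_cols = np.nonzero(mat[ref_idx] < 1000)[0]
    if window_length > ref_cols.size:
        raise ValueError(
            f"window ({window_length}) longer than the reference ({ref_cols.size} bp)"
        )
    spans = _spans(mat)
    n_total = len(ids)
    points: list[WindowPoint] = []
    for start in range(0, ref_cols.size - window_length + 1, step):
        cols = ref_cols[start : start + window_length]
        covering = np.array(
            [s[0] <= cols[0] and s[1] >= cols[-1] for s in spans], dtype=bool
        )
        if covering.sum() < coverage_fraction * n_total:
            continue
        idents = []
        for i in np.nonzero(covering)[0]:
            best = nearest_neighbor_identity(int(i), cols, mat, genomes, covering)
            if best is not None:
                idents.append(best)
        if not idents:
            continue
        points.append(
            WindowPoint(
                midpoint=start + window_length // 2 + 1,
                median_identity=float(np.median(idents)),
                n_sequences=int(covering.sum()),
            )
        )
    return WindowProfile(
        window_length, coverage_fraction, ids[ref_idx], points
    )


def write_profile(profile: WindowProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("midpoint\tmedian_identity\tn_sequences\n")
        for mid, med, n in profile.to_rows():
            fh.write(f"{mid}\t{med:.3f}\t{n}\n")
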