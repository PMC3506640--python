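"""Pairwise nucleotide distances and the barcode-gap statistic.

Distances are computed on a multiple alignment of extracted barcode regions
under three closed-form substitution models: F84 (default; the model behind
PHYLIP's DNADIST), Kimura two-parameter, and Jukes-Cantor.  Sites with a gap
or ambiguity code in either sequence of a pair are excluded pairwise, and
F84 base frequencies are estimated empirically from the two sequences being
compared (pooled over the comparable sites).

For the F84 distance, with transition proportion P, transversion proportion
Q and base frequencies pi, let R = piA+piG, Y = piC+piT and

    a = piA*piG/R + piC*piT/Y,   b = piA*piG + piC*piT,   c = R*Y

then  d = -2a ln(1 - P/(2a) - (a-b)Q/(2ac)) + 2(a-b-c) ln(1 - Q/(2c)).
At equal base frequencies this collapses to the K2P distance.  A
non-positive logarithm argument means the pair is saturated; such pairs get
distance +inf, are excluded from medians, and are counted separately.

The barcode gap of a region is the difference between the median
inter-specific and median intra-specific distance; paralogs within one
genome count as intra-specific comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .iupac import encode

MODELS = ("f84", "k2p", "jc")

#: transition pairs on the 2-bit code (A<->G, C<->T)
_TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}


class UndefinedDistanceError(ValueError):
    """No comparable (unambiguous, ungapped) sites shared by the pair."""


@dataclass(frozen=True)
class PairModelFit:
    """Empirical quantities a model distance is computed from, for one pair."""

    model: str
    n_sites: int  # comparable sites after pairwise deletion
    transition_proportion: float  # P
    transversion_proportion: float  # Q
    base_frequencies: tuple[float, float, float, float]  # piA, piC, piG, piT

    def __post_init__(self) -> None:
        if not (self.transition_proportion >= 0 and self.transversion_proportion >= 0):
            raise ValueError("P and Q must be non-negative")
        if self.transition_proportion + self.transversion_proportion > 1 + 1e-12:
            raise ValueError("P + Q cannot exceed 1")


def pair_model_fit(aligned_a: str, aligned_b: str, model: str = "f84") -> PairModelFit:
    """Observed P, Q and pooled base frequencies for one aligned pair."""
    n, ts, tv, freqs = _pair_site_stats(encode(aligned_a), encode(aligned_b))
    return PairModelFit(model.lower(), n, ts / n, tv / n, tuple(float(f) for f in freqs))


@dataclass(frozen=True)
class DistanceRecord:
    id_a: str
    id_b: str
    distance: float  # substitutions/site; +inf marks a saturated pair
    relation: str  # "intra" | "inter"


@dataclass
class GapSummary:
    """Distribution summary for one barcode region (one row of a gap table)."""

    region: str
    average_length: float | None
    n_intra: int
    n_inter: int
    min_intra: float
    max_intra: float
    median_intra: float
    min_inter: float
    max_inter: float
    median_inter: float
    n_saturated_intra: int = 0
    n_saturated_inter: int = 0

    @property
    def gap(self) -> float:
        """Median inter-specific minus median intra-specific distance."""
        return self.median_inter - self.median_intra


@dataclass
class DistanceHistogram:
    """Binned intra/inter distance distributions as percent of comparisons.

    Bins are left-closed right-open with a common width starting at 0.
    Percentages are normalized within each relation over all finite
    distances, so each side sums to 100 regardless of any display cap.
    """

    bin_width: float
    bin_left: np.ndarray
    intra_percent: np.ndarray
    inter_percent: np.ndarray
    n_intra: int = 0
    n_inter: int = 0
    cap: float | None = None

    def capped(self) -> "DistanceHistogram":
        """View truncated at the display cap (normalization unchanged)."""
        if self.cap is None:
            return self
        keep = self.bin_left < self.cap
        return DistanceHistogram(
            self.bin_width,
            self.bin_left[keep],
            self.intra_percent[keep],
            self.inter_percent[keep],
            self.n_intra,
            self.n_inter,
            self.cap,
        )


def _pair_site_stats(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, np.ndarray]:
    mask = (a < 4) & (b < 4)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between the pair")
    aa = a[mask]
    bb = b[mask]
    diff = aa != bb
    transitions = int((diff & (((aa ^ bb) == 2))).sum())
    # A(0)^G(2)=2 and C(1)^T(3)=2; all other differing pairs are transversions
    transversions = int(diff.sum()) - transitions
    counts = np.bincount(aa, minlength=4) + np.bincount(bb, minlength=4)
    freqs = counts / counts.sum()
    return n, transitions, transversions, freqs


def _jc(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.inf
    return -0.75 * math.log(arg)


def _k2p(P: float, Q: float) -> float:
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.inf
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def _f84(P: float, Q: float, freqs: np.ndarray) -> float:
    piA, piC, piG, piT = (float(x) for x in freqs)
    R = piA + piG
    Y = piC + piT
    if R <= 0.0 or Y <= 0.0:
        return math.inf
    a = piA * piG / R + piC * piT / Y
    b = piA * piG + piC * piT
    c = R * Y
    if a <= 0.0 or c <= 0.0:
        return math.inf
    arg1 = 1.0 - P / (2.0 * a) - (a - b) * Q / (2.0 * a * c)
    arg2 = 1.0 - Q / (2.0 * c)
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.inf
    return -2.0 * a * math.log(arg1) + 2.0 * (a - b - c) * math.log(arg2)


def pairwise_distance(aligned_a: str, aligned_b: str, model: str = "f84") -> float:
    """Substitutions/site between two equal-length gapped sequences.

    Saturated pairs (non-positive log argument) return ``math.inf``.
    Raises :class:`UndefinedDistanceError` when no site is comparable.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model '{model}'; expected one of {MODELS}")
    n, ts, tv, freqs = _pair_site_stats(encode(aligned_a), encode(aligned_b))
    P = ts / n
    Q = tv / n
    if model == "jc":
        return _jc(P + Q)
    if model == "k2p":
        return _k2p(P, Q)
    return _f84(P, Q, freqs)


def partition_distances(
    entries: Sequence[tuple[str, str]],
    species_of: Mapping[str, str],
    model: str = "f84",
) -> list[DistanceRecord]:
    """All unordered pairwise distances, labeled intra-/inter-specific.

    ``entries`` are (marker_id, aligned sequence); every id must have a
    species label.  Pairs with equal species labels (including paralogs from
    one genome) are intra-specific.
    """
    if len(entries) < 2:
        raise ValueError("need at least 2 sequences to compute distances")
    ids = [e[0] for e in entries]
    missing = [i for i in ids if i not in species_of]
    if missing:
        raise KeyError(f"no species label for marker(s): {missing[:5]}")
    codes = [encode(e[1]) for e in entries]
    records: list[DistanceRecord] = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            n, ts, tv, freqs = _pair_site_stats(codes[i], codes[j])
            P, Q = ts / n, tv / n
            if model == "jc":
                d = _jc(P + Q)
            elif model == "k2p":
                d = _k2p(P, Q)
            else:
                d = _f84(P, Q, freqs)
            rel = "intra" if species_of[ids[i]] == species_of[ids[j]] else "inter"
            records.append(DistanceRecord(ids[i], ids[j], d, rel))
    return records


def gap_statistic(
    records: Iterable[DistanceRecord],
    region: str = "",
    average_length: float | None = None,
) -> GapSummary:
    """Summary statistics and barcode gap from labeled distance records.

    Saturated (+inf) distances are excluded from medians but counted; the
    reported maxima cover finite values only, with saturation flagged via
    the ``n_saturated_*`` counts.
    """
    intra = [r.distance for r in records if r.relation == "intra"]
    inter = [r.distance for r in records if r.relation == "inter"]
    if not intra:
        raise ValueError("empty intra-specific partition")
    if not inter:
        raise ValueError("empty inter-specific partition")
    fin_intra = [d for d in intra if math.isfinite(d)]
    fin_inter = [d for d in inter if math.isfinite(d)]
    if not fin_intra or not fin_inter:
        raise ValueError("a partition contains only saturated distances")
    return GapSummary(
        region=region,
        average_length=average_length,
        n_intra=len(intra),
        n_inter=len(inter),
        min_intra=float(min(fin_intra)),
        max_intra=float(max(fin_intra)),
        median_intra=float(np.median(fin_intra)),
        min_inter=float(min(fin_inter)),
        max_inter=float(max(fin_inter)),
        median_inter=float(np.median(fin_inter)),
        n_saturated_intra=len(intra) - len(fin_intra),
        n_saturated_inter=len(inter) - len(fin_inter),
    )


def histogram(
    records: Iterable[DistanceRecord],
    bin_width: float = 0.01,
    cap: float | None = None,
) -> DistanceHistogram:
    """Binned intra/inter distributions as percent of comparisons per relation."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intra = np.array(
        [r.distance for r in records if r.relation == "intra" and math.isfinite(r.distance)]
    )
    inter = np.array(
        [r.distance for r in records if r.relation == "inter" and math.isfinite(r.distance)]
    )
    hi = max(
        float(intra.max(initial=0.0)), float(inter.max(initial=0.0)), bin_width
    )
    n_bins = int(math.floor(hi / bin_width)) + 1
    left = np.arange(n_bins) * bin_width
    def _pct(vals: np.ndarray) -> np.ndarray:
        counts = np.zeros(n_bins)
        if vals.size:
            idx = np.floor(vals / bin_width).astype(int)
            np.add.at(counts, idx, 1.0)
            counts = 100.0 * counts / vals.size
        return counts
    return DistanceHistogram(
        bin_width, left, _pct(intra), _pct(inter), intra.size, inter.size, cap
    )


def write_pair_table(records: Iterable[DistanceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tdistance\trelation\n")
        for r in records:
            d = "saturated" if math.isinf(r.distance) else f"{r.distance:.6f}"
            fh.write(f"{r.id_a}\t{r.id_b}\t{d}\t{r.relation}\n")


def write_phylip_matrix(
    ids: Sequence[str], records: Iterable[DistanceRecord], path
) -> None:
    """Square PHYLIP distance matrix (saturated pairs written as -1.0)."""
    index = {name: i for i, name in enumerate(ids)}
    n = len(ids)
    mat = np.zeros((n, n))
    for r in records:
        d = r.distance if math.isfinite(r.distance) else -1.0
        i, j = index[r.id_a], index[r.id_b]
        mat[i, j] = mat[j, i] = d
    with open(path, "w") as fh:
        fh.write(f"{n:5d}\n")
        for i, name in enumerate(ids):
            row = "  ".join(f"{mat[i, j]:.6f}" for j in range(n))
            fh.write(f"{name[:10]:<10}  {row}\n")


def write_gap_table(summaries: Sequence[GapSummary], path) -> None:
    """Gap-analysis table, one region per row (the Table-2-style report)."""
    cols = (
        "region\taverage_length\tbarcode_gap\tn_intra\tmin_intra\tmax_intra\t"
        "median_intra\tn_inter\tmin_inter\tmax_inter\tmedian_inter\t"
        "n_saturated_intra\tn_saturated_inter\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for s in summaries:
            avg = "" if s.average_length is None else f"{s.average_length:g}"
            fh.write(
                f"{s.region}\t{avg}\t{s.gap:.4f}\t{s.n_intra}\t{s.min_intra:.4f}\t"
                f"{s.max_intra:.4f}\t{s.median_intra:.4f}\t{s.n_inter}\t"
                f"{s.min_inter:.4f}\t{s.max_inter:.4f}\t{s.median_inter:.4f}\t"
                f"{s.n_saturated_intra}\t{s.n_saturated_inter}\n"
            )
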