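"""Synthetic data generation: template panels, amplicon reads, genome fixtures.

Three generators emulate the study conditions at desk scale:

* :func:`generate_panel` - a panel of cpn60-UT-like template sequences
  (default 20 templates, 552-558 bp, pairwise identities inside the 56-96%
  envelope of the cloned synthetic community) produced by mutating a random
  ancestor along a star tree.  The sequences of the real clones are not
  public, so the panel is a seeded synthetic stand-in with the same
  cardinality, length class and identity envelope.
* :func:`simulate_reads` - pyrosequencing-style amplicon reads taken
  alternately from the 5' and 3' ends of primer-flanked amplicons, with a
  truncated-normal length distribution (default median 394 bp), optional
  substitution errors and homopolymer-length wobble, plus complete truth
  labels.
* :func:`generate_genome_fixture` - GenBank-formatted annotated genomes
  with designed intra-/inter-species divergence for the barcode-gap
  pipeline (16S-like gene with conserved/variable blocks, uniformly
  diverging cpn60-like gene, optional highly divergent paralogs, primer
  footprints held conserved so in-silico PCR works).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .align import edlib_identity
from .barcode_delineation import PrimerPair, load_primer_pairs
from .iupac import decode, encode, revcomp

_BASES = "ACGT"

#: bases compatible with each IUPAC/inosine code, for primer instantiation
_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "I": "ACGT",
}


class PanelGenerationError(RuntimeError):
    """Identity bounds could not be satisfied within the retry budget."""


@dataclass
class TemplatePanel:
    """Barcode template panel with primer-flanked amplicons and truth structure."""

    templates: list[tuple[str, str]]
    lo: float
    hi: float
    primer_pair: PrimerPair
    seed: int
    amplicons: dict[str, str] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return [tid for tid, _ in self.templates]

    def template(self, tid: str) -> str:
        return dict(self.templates)[tid]

    def identity_matrix(self) -> np.ndarray:
        """All-pairs fractional global-alignment identity."""
        n = len(self.templates)
        mat = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ident = edlib_identity(self.templates[i][1], self.templates[j][1])
                mat[i, j] = mat[j, i] = ident
        return mat


@dataclass
class SimulatedReadSet:
    """Simulated amplicon reads with complete truth labels."""

    reads: list[tuple[str, str, str]]  # (read id, sequence, quality placeholder)
    truth: dict[str, str]  # read id -> template id
    median_length_target: int
    error_rate: float
    homopolymer_bias: float
    seed: int

    def read_tuples(self) -> list[tuple[str, str]]:
        return [(rid, seq) for rid, seq, _ in self.reads]

    def median_length(self) -> float:
        return float(np.median([len(seq) for _, seq, _ in self.reads]))

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq, _ in self.reads:
                fh.write(f">{rid}\n{seq}\n")

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttemplate_id\n")
            for rid, _, _ in self.reads:
                fh.write(f"{rid}\t{self.truth[rid]}\n")


def instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve degenerate positions to one concrete compatible base."""
    out = []
    for ch in primer.upper():
        opts = _EXPAND[ch]
        out.append(opts if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)


def _solve_equal_pair_divergence(target_identity: float) -> float:
    """g such that two leaves mutated at fraction g sit at the target identity.

    Expected identity of two leaves independently mutated at random
    positions: 1 - 2g + (4/3) g^2.
    """
    disc = 4.0 - (16.0 / 3.0) * (1.0 - target_identity)
    if disc < 0:
        raise PanelGenerationError(f"identity target {target_identity} infeasible")
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def _mutate(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    if positions.size:
        out[positions] = (out[positions] + rng.integers(1, 4, positions.size)) % 4
    return out


def generate_panel(
    n: int = 20,
    lo: float = 0.56,
    hi: float = 0.96,
    length: int = 555,
    seed: int = 42,
    primer_pair: PrimerPair | None = None,
    codon_indels: bool = True,
    max_retries: int = 50,
) -> TemplatePanel:
    """Template panel with all pairwise identities inside ``[lo, hi]``.

    Leaves of a star tree around a random ancestor receive divergence
    fractions spaced so realized identities fill the interior of the
    envelope; pairs that still violate the bounds (beyond the 1/length
    quantization) are rejection-adjusted.  ``codon_indels`` adds the +/-1
    codon length variation characteristic of the chaperonin target
    (lengths ``length`` - 3 .. ``length`` + 3).

    The divergence targets deliberately keep the closest pair near the
    envelope's upper interior rather than at ``hi`` itself: a pairwise
    greedy merger cannot hold apart templates more similar than its merge
    identity threshold, so near-threshold pairs are a separate, explicit
    test scenario rather than a default-panel feature (see the methods
    note).
    """
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("need 0 < lo <= hi < 1")
    if n < 2:
        raise ValueError("need at least two templates")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, length).astype(np.uint8)
    tol = 1.0 / length

    if n == 2 and math.isclose(lo, hi):
        total = int(round((1.0 - lo) * length))
        pos = rng.permutation(length)[:total]
        leaves = [
            _mutate(ancestor, pos[: total // 2], rng),
            _mutate(ancestor, pos[total // 2 :], rng),
        ]
    else:
        span = hi - lo
        top = hi - 0.20 * span
        bottom = lo + 0.05 * span
        g_lo = _solve_equal_pair_divergence(top)
        g_hi = _solve_equal_pair_divergence(bottom)
        gs = np.linspace(g_lo, g_hi, n)
        leaves = []
        for g in gs:
            m = int(round(g * length))
            pos = rng.choice(length, size=m, replace=False)
            leaves.append(_mutate(ancestor, pos, rng))

    seqs = [decode(leaf) for leaf in leaves]
    if codon_indels:
        deltas = rng.choice([-3, 0, 3], size=n, p=[0.25, 0.5, 0.25])
        for i, delta in enumerate(deltas):
            if delta == 0:
                continue
            codon_start = 3 * int(rng.integers(1, (length - 6) // 3))
            if delta < 0:
                seqs[i] = seqs[i][:codon_start] + seqs[i][codon_start + 3 :]
            else:
                ins = "".join(_BASES[rng.integers(4)] for _ in range(3))
                seqs[i] = seqs[i][:codon_start] + ins + seqs[i][codon_start:]

    ids = [f"T{i + 1:02d}" for i in range(n)]
    for _ in range(max_retries):
        violation = None
        for i in range(n):
            for j in range(i + 1, n):
                ident = edlib_identity(seqs[i], seqs[j])
                if ident > hi + tol or ident < lo - tol:
                    violation = (i, j, ident)
                    break
            if violation:
                break
        if violation is None:
            break
        i, j, ident = violation
        if ident > hi + tol:
            # push the pair apart: extra mutations on the later leaf
            extra = max(1, int(math.ceil((ident - hi) * length)) + 1)
            arr = encode(seqs[j])
            pos = rng.choice(len(arr), size=min(extra, len(arr)), replace=False)
            seqs[j] = decode(_mutate(arr, pos, rng))
        else:
            # pull the pair together: re-copy ancestor bases into the later leaf
            arr = encode(seqs[j])
            k = min(len(arr), len(ancestor))
            mism = np.nonzero(arr[:k] != ancestor[:k])[0]
            take = min(mism.size, max(1, int(math.ceil((lo - ident) * length)) + 1))
            if take:
                sel = rng.choice(mism, size=take, replace=False)
                arr[sel] = ancestor[sel]
            seqs[j] = decode(arr)
    else:
        raise PanelGenerationError(
            f"could not satisfy identity bounds [{lo}, {hi}] for n={n} "
            f"after {max_retries} adjustment rounds"
        )

    if primer_pair is None:
        primer_pair = load_primer_pairs()["UT"]
    panel = TemplatePanel(list(zip(ids, seqs)), lo, hi, primer_pair, seed)
    for tid, seq in panel.templates:
        fwd = instantiate_primer(primer_pair.forward, rng)
        rev = instantiate_primer(primer_pair.reverse, rng)
        panel.amplicons[tid] = fwd + seq + revcomp(rev)
    return panel


def _draw_length(
    rng: np.random.Generator, median: int, upper: int, lower: int = 80
) -> int:
    """Truncated-normal read length (sd = 0.15 x median, bounds [lower, upper])."""
    sd = 0.15 * median
    for _ in range(1000):
        val = int(round(rng.normal(median, sd)))
        if lower <= val <= upper:
            return val
    return min(max(median, lower), upper)


def _apply_errors(
    seq: str, error_rate: float, homopolymer_bias: float, rng: np.random.Generator
) -> str:
    if error_rate > 0.0:
        arr = encode(seq)
        mask = rng.random(arr.size) < error_rate
        idx = np.nonzero(mask)[0]
        if idx.size:
            arr[idx] = (arr[idx] + rng.integers(1, 4, idx.size)) % 4
        seq = decode(arr)
    if homopolymer_bias > 0.0:
        out = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            run = seq[i:j]
            if len(run) >= 3 and rng.random() < homopolymer_bias:
                if rng.random() < 0.5 and len(run) > 1:
                    run = run[:-1]
                else:
                    run = run + run[0]
            out.append(run)
            i = j
        seq = "".join(out)
    return seq


def simulate_reads(
    panel: TemplatePanel,
    reads_per_template: int = 172,
    median_length: int = 394,
    error_rate: float = 0.0,
    homopolymer_bias: float = 0.0,
    seed: int = 0,
) -> SimulatedReadSet:
    """Amplicon reads from both ends of each template's primer-flanked amplicon.

    Reads alternate between the 5' end (forward orientation) and the 3' end
    (reverse complement of the amplicon suffix); equimolar template input.
    Substitution errors are applied per base at ``error_rate``; homopolymer
    runs of length >= 3 gain or lose one base with probability
    ``homopolymer_bias`` each.
    """
    amp_min = min(len(a) for a in panel.amplicons.values())
    if median_length > amp_min:
        raise ValueError(
            f"median_length {median_length} exceeds shortest amplicon ({amp_min} bp)"
        )
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    truth: dict[str, str] = {}
    counter = 0
    for tid in panel.ids:
        amp = panel.amplicons[tid]
        for r in range(reads_per_template):
            length = _draw_length(rng, median_length, len(amp))
            if r % 2 == 0:
                seq = amp[:length]
            else:
                seq = revcomp(amp[-length:])
            seq = _apply_errors(seq, error_rate, homopolymer_bias, rng)
            rid = f"R{counter:05d}"
            counter += 1
            reads.append((rid, seq, "I" * len(seq)))
            truth[rid] = tid
    return SimulatedReadSet(
        reads, truth, median_length, error_rate, homopolymer_bias, seed
    )


# ---------------------------------------------------------------------------
# Genome fixtures for the barcode-gap pipeline
# ---------------------------------------------------------------------------


@dataclass
class GenomeFixtureParams:
    n_species: int = 5
    genomes_per_species: int = 3
    cpn60_paralogs: int = 1
    paralog_divergence: float = 0.40
    intra_divergence: float = 0.01  # designed pairwise distance within species
    inter_divergence: float = 0.30  # designed pairwise distance between species
    cpn60_core_length: int = 555
    r16s_core_length: int = 1200
    flank_length: int = 250

    def __post_init__(self) -> None:
        if not self.inter_divergence > self.intra_divergence:
            raise ValueError("inter_divergence must exceed intra_divergence")
        if min(self.n_species, self.genomes_per_species, self.cpn60_paralogs) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SynthGenome:
    genome_id: str
    taxon_id: str
    species: str
    sequence: str
    # (feature type, product, gene qualifier, start0, end0, strand)
    features: list[tuple[str, str, str, int, int, int]]


@dataclass
class GenomeFixture:
    params: GenomeFixtureParams
    seed: int
    genomes: list[SynthGenome]
    taxonomy: dict[str, tuple[str, str]]

    def to_genbank(self) -> str:
        """All genomes as a multi-record GenBank flat-file string."""
        out = io.StringIO()
        for g in self.genomes:
            rec = SeqRecord(
                Seq(g.sequence),
                id=g.genome_id,
                name=g.genome_id[:16],
                description=f"{g.species} synthetic genome",
                annotations={"molecule_type": "DNA", "topology": "linear"},
            )
            rec.features.append(
                SeqFeature(
                    FeatureLocation(0, len(g.sequence), strand=1),
                    type="source",
                    qualifiers={
                        "organism": [g.species],
                        "db_xref": [f"taxon:{g.taxon_id}"],
                    },
                )
            )
            for ftype, product, gene, start, end, strand in g.features:
                quals: dict[str, list[str]] = {"product": [product]}
                if gene:
                    quals["gene"] = [gene]
                rec.features.append(
                    SeqFeature(
                        FeatureLocation(start, end, strand=strand),
                        type=ftype,
                        qualifiers=quals,
                    )
                )
            SeqIO.write(rec, out, "genbank")
        return out.getvalue()

    def genbank_records(self) -> list[str]:
        """One GenBank string per genome (round-trippable via parse_genome)."""
        chunks = []
        text = self.to_genbank()
        for part in text.split("//\n"):
            if part.strip():
                chunks.append(part + "//\n")
        return chunks

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for g, chunk in zip(self.genomes, self.genbank_records()):
            (directory / f"{g.genome_id}.gbk").write_text(chunk)
        with open(directory / "taxonomy.tsv", "w") as fh:
            fh.write("taxon_id\tspecies\tlineage\n")
            for taxon_id, (species, lineage) in self.taxonomy.items():
                fh.write(f"{taxon_id}\t{species}\t{lineage}\n")


def _jc_site_prob(t: float) -> float:
    """Probability a site shows a different base after branch length t (JC)."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _evolve(
    arr: np.ndarray, t: float, rng: np.random.Generator, weights: np.ndarray | None = None
) -> np.ndarray:
    """One JC branch of length t substitutions/site (optionally rate-weighted)."""
    if weights is None:
        p = np.full(arr.size, _jc_site_prob(t))
    else:
        p = 0.75 * (1.0 - np.exp(-4.0 * t * weights / 3.0))
    mask = rng.random(arr.size) < p
    out = arr.copy()
    idx = np.nonzero(mask)[0]
    if idx.size:
        out[idx] = (out[idx] + rng.integers(1, 4, idx.size)) % 4
    return out


def _r16s_weights(length: int) -> np.ndarray:
    """Alternating conserved/variable blocks, 16S-style (9 segments)."""
    bounds = np.linspace(0, length, 10).astype(int)
    w = np.empty(length)
    for k in range(9):
        w[bounds[k] : bounds[k + 1]] = 0.05 if k % 2 == 0 else 2.0
    return w


def generate_genome_fixture(
    params: GenomeFixtureParams | None = None, seed: int = 0
) -> GenomeFixture:
    """Annotated genome collection with designed divergence structure.

    Gene trees are stars: species ancestors sit ``(b - a)/2`` from the root
    and genomes ``a/2`` from their species ancestor, so expected pairwise
    distances are ``a`` within and ``b`` between species.  Primer footprints
    (27F/534R for the 16S-like gene, H279/H280 for the cpn60-like gene) are
    held invariant so region delineation succeeds on every genome.  Extra
    cpn60 paralogs (``cpn60_paralogs`` > 1) diverge from the genome's first
    copy by ``paralog_divergence``, populating the intra-specific right
    tail.  Decoy co-chaperonin (groES) annotations are included so keyword
    matching has true negatives.
    """
    params = params or GenomeFixtureParams()
    rng = np.random.default_rng(seed)
    pairs = load_primer_pairs()
    ut, v13 = pairs["UT"], pairs["V1-V3"]
    site_h279 = instantiate_primer(ut.forward, rng)
    site_h280 = revcomp(instantiate_primer(ut.reverse, rng))
    site_27f = instantiate_primer(v13.forward, rng)
    site_534r = revcomp(instantiate_primer(v13.reverse, rng))

    root_cpn = rng.integers(0, 4, params.cpn60_core_length).astype(np.uint8)
    root_16s = rng.integers(0, 4, params.r16s_core_length).astype(np.uint8)
    w16 = _r16s_weights(params.r16s_core_length)

    a, b = params.intra_divergence, params.inter_divergence
    t_species = (b - a) / 2.0
    t_genome = a / 2.0

    cpn60_products = ["60 kDa chaperonin", "chaperonin GroEL", "heat shock protein Hsp60"]
    cpn60_genes = ["groEL", "cpn60", "groL"]

    genomes: list[SynthGenome] = []
    taxonomy: dict[str, tuple[str, str]] = {}
    for s in range(params.n_species):
        species = f"Synthetica sp{s + 1:02d}"
        taxon_id = f"91{s + 1:04d}"
        taxonomy[taxon_id] = (species, "Bacteria; Synthphyla; Synthetica")
        sp_cpn = _evolve(root_cpn, t_species, rng)
        sp_16s = _evolve(root_16s, t_species, rng, w16)
        for g in range(params.genomes_per_species):
            genome_id = f"SG{s + 1:02d}G{g + 1:02d}"
            cores_cpn = [_evolve(sp_cpn, t_genome, rng)]
            for _ in range(params.cpn60_paralogs - 1):
                cores_cpn.append(_evolve(cores_cpn[0], params.paralog_divergence, rng))
            core_16s = _evolve(sp_16s, t_genome, rng, w16)

            gene_16s = site_27f + decode(core_16s) + site_534r
            genes_cpn = [site_h279 + decode(c) + site_h280 for c in cores_cpn]

            parts: list[str] = []
            features: list[tuple[str, str, str, int, int, int]] = []
            pos = 0

            def _emit(seq: str, ftype: str, product: str, gene: str, strand: int):
                nonlocal pos
                emitted = seq if strand == 1 else revcomp(seq)
                parts.append(emitted)
                features.append((ftype, product, gene, pos, pos + len(seq), strand))
                pos += len(seq)

            def _spacer(n: int):
                nonlocal pos
                parts.append(decode(rng.integers(0, 4, n).astype(np.uint8)))
                pos += n

            _spacer(params.flank_length)
            strand_16s = 1 if g % 2 == 0 else -1
            _emit(gene_16s, "rRNA", "16S ribosomal RNA", "rrs", strand_16s)
            _spacer(params.flank_length)
            for k, gene_cpn in enumerate(genes_cpn):
                strand_cpn = 1 if (g + k) % 2 == 0 else -1
                _emit(
                    gene_cpn,
                    "CDS",
                    cpn60_products[(g + k) % len(cpn60_products)],
                    cpn60_genes[(g + k) % len(cpn60_genes)],
                    strand_cpn,
                )
                _spacer(60)
            # decoy: must never match the cpn60 keyword set
            decoy = decode(rng.integers(0, 4, 291).astype(np.uint8))
            _emit(decoy, "CDS", "co-chaperonin GroES", "groES", 1)
            _spacer(params.flank_length)

            genomes.append(
                SynthGenome(genome_id, taxon_id, species, "".join(parts), features)
            )
    return GenomeFixture(params, seed, genomes, taxonomy)
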