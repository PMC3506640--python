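"""Extraction of marker gene copies (16S rRNA, cpn60) from annotated genomes.

Parses GenBank flat files into a light :class:`GenomeRecord`, then pulls out
every annotated copy of a requested marker by keyword matching on feature
names.  There is no single annotation convention for the 60 kDa chaperonin
gene (cpn60 / groEL / hsp60 / "60 kDa chaperonin" ...), so matching is
driven by a user-extensible :class:`KeywordSet`; the shipped defaults cover
the common synonyms.  Matching is case-insensitive on whole tokens, so
"groEL" matches "chaperonin GroEL" but not "groES".

All paralogous copies are kept (``copy_index`` 1..k in genome order) and
reverse-strand features are reverse-complemented onto the gene sense strand.
Species labels come from a 3-column taxonomy table (taxon_id, species,
lineage); unknown taxa get species "unknown".
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .iupac import revcomp


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be parsed."""


@dataclass
class Feature:
    """One annotated feature on a replicon (0-based half-open internally)."""

    replicon_id: str
    type: str
    names: tuple[str, ...]
    start: int
    end: int
    strand: int  # +1 / -1

    @property
    def location_1based(self) -> tuple[int, int]:
        """1-based inclusive coordinates, as GenBank reports them."""
        return self.start + 1, self.end


@dataclass
class GenomeRecord:
    genome_id: str
    taxon_id: str
    replicons: list[tuple[str, str]]
    features: list[Feature]

    def replicon_seq(self, replicon_id: str) -> str:
        for rid, seq in self.replicons:
            if rid == replicon_id:
                return seq
        raise KeyError(replicon_id)


@dataclass
class MarkerSequence:
    """One extracted gene copy with genome/species/paralog identity."""

    genome_id: str
    species: str
    taxon_id: str
    gene: str  # "16S" or "cpn60"
    copy_index: int
    sequence: str

    @property
    def marker_id(self) -> str:
        return f"{self.genome_id}|{self.gene}|{self.copy_index}"


@dataclass
class KeywordSet:
    """Terms identifying a marker in feature annotations.

    ``terms`` match case-insensitively as consecutive whole tokens within the
    feature's gene/product strings; ``feature_types`` restricts which GenBank
    feature types are searched.
    """

    gene: str
    terms: tuple[str, ...]
    feature_types: tuple[str, ...] = ("CDS", "rRNA", "gene")

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("KeywordSet needs at least one term")

    def matches(self, text: str) -> bool:
        tokens = _tokenize(text)
        for term in self.terms:
            want = _tokenize(term)
            n = len(want)
            if n == 0:
                continue
            for i in range(len(tokens) - n + 1):
                if tokens[i : i + n] == want:
                    return True
        return False


def _tokenize(text: str) -> list[str]:
    return [t for t in re.split(r"[^0-9a-zA-Z]+", text.lower()) if t]


#: Default keyword sets. The cpn60 list is a superset judgement call: genome
#: annotations are inconsistent, so the set is exposed for extension.
DEFAULT_KEYWORDS: dict[str, KeywordSet] = {
    "16S": KeywordSet("16S", ("16S",), feature_types=("rRNA",)),
    "cpn60": KeywordSet(
        "cpn60",
        (
            "cpn60",
            "cpn-60",
            "groEL",
            "groL",
            "hsp60",
            "hsp-60",
            "60 kDa chaperonin",
            "chaperonin 60",
            "chaperonin GroEL",
            "heat shock protein 60",
            "mopA",
        ),
        feature_types=("CDS",),
    ),
}

_NAME_QUALIFIERS = ("gene", "product", "note", "gene_synonym", "standard_name")


def parse_genome(source) -> GenomeRecord:
    """Parse a GenBank flat file (text, handle or path) into a GenomeRecord.

    Multi-record files are treated as replicons of one genome.  A missing
    taxon db_xref yields an empty taxon_id and a warning, not an error.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source)
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    try:
        records = list(SeqIO.parse(handle, "genbank"))
    except Exception as err:  # Biopython raises bare ValueError on bad input
        raise GenBankParseError(f"malformed GenBank record: {err}") from err
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise GenBankParseError("malformed GenBank record: no LOCUS entries found")

    replicons: list[tuple[str, str]] = []
    features: list[Feature] = []
    taxon_id = ""
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise GenBankParseError(
                f"malformed GenBank record '{rec.id}': record has no sequence"
            )
        replicons.append((rec.id, seq))
        for feat in rec.features:
            if feat.type == "source":
                for xref in feat.qualifiers.get("db_xref", []):
                    if xref.startswith("taxon:"):
                        taxon_id = xref.split(":", 1)[1]
            if feat.type not in ("CDS", "rRNA", "gene", "misc_feature"):
                continue
            names = []
            for qual in _NAME_QUALIFIERS:
                names.extend(feat.qualifiers.get(qual, []))
            start = int(feat.location.start)
            end = int(feat.location.end)
            if not (0 <= start < end <= len(seq)):
                raise GenBankParseError(
                    f"feature {feat.type} {start + 1}..{end} outside replicon "
                    f"'{rec.id}' of length {len(seq)}"
                )
            strand = -1 if feat.location.strand == -1 else 1
            features.append(
                Feature(rec.id, feat.type, tuple(names), start, end, strand)
            )
    genome_id = records[0].name or records[0].id
    if not taxon_id:
        warnings.warn(f"genome '{genome_id}' has no taxon db_xref", stacklevel=2)
    return GenomeRecord(genome_id, taxon_id, replicons, features)


def extract_markers(
    record: GenomeRecord,
    keywords: KeywordSet,
    taxonomy: Mapping[str, tuple[str, str]] | None = None,
) -> list[MarkerSequence]:
    """All marker copies in ``record`` matching ``keywords``.

    Reverse-strand features are reverse-complemented; copies are numbered in
    genome order.  Returns an empty list when nothing matches.
    """
    taxonomy = taxonomy or {}
    species, _lineage = taxonomy.get(record.taxon_id, ("unknown", ""))
    out: list[MarkerSequence] = []
    copy_index = 0
    for feat in record.features:
        if feat.type not in keywords.feature_types:
            continue
        if not any(keywords.matches(name) for name in feat.names):
            continue
        seq = record.replicon_seq(feat.replicon_id)[feat.start : feat.end]
        if feat.strand == -1:
            seq = revcomp(seq)
        copy_index += 1
        out.append(
            MarkerSequence(
                genome_id=record.genome_id,
                species=species,
                taxon_id=record.taxon_id,
                gene=keywords.gene,
                copy_index=copy_index,
                sequence=seq,
            )
        )
    return out


def read_taxonomy(path) -> dict[str, tuple[str, str]]:
    """Read a 3-column TSV (taxon_id, species, lineage) into a mapping."""
    taxonomy: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "taxon_id":
                continue
            taxon_id = parts[0]
            species = parts[1] if len(parts) > 1 else "unknown"
            lineage = parts[2] if len(parts) > 2 else ""
            taxonomy[taxon_id] = (species, lineage)
    return taxonomy


def write_markers(
    markers: Iterable[MarkerSequence], fasta_path, manifest_path=None
) -> None:
    """Write markers as FASTA (headers genome|gene|copy|species) plus a TSV manifest."""
    markers = list(markers)
    with open(fasta_path, "w") as fh:
        for m in markers:
            fh.write(f">{m.genome_id}|{m.gene}|{m.copy_index}|{m.species}\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i : i + 70] + "\n")
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            fh.write("marker_id\tgenome_id\tgene\tcopy_index\tspecies\ttaxon_id\tlength\n")
            for m in markers:
                fh.write(
                    f"{m.marker_id}\t{m.genome_id}\t{m.gene}\t{m.copy_index}\t"
                    f"{m.species}\t{m.taxon_id}\t{len(m.sequence)}\n"
                )


def read_manifest(path) -> dict[str, dict[str, str]]:
    """Read a marker manifest TSV into {marker_id: row dict}."""
    rows: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            rows[parts[0]] = dict(zip(header, parts))
    return rows
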