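"""Proteome FASTA I/O, CCDS header handling, and gene-symbol mapping.

The screen's reference input is the NCBI Consensus Coding Sequence (CCDS)
protein set, whose FASTA headers are '|'-delimited with the versioned CCDS
accession as the first token (e.g. ``>CCDS30547.1|Hs110|chr1``).  Accessions
are mapped to Ensembl gene symbols through a two-column TSV as exported from
Ensembl BioMart.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

_SEQ_CHARS = re.compile(r"^[A-Z]+$")


class FastaParseError(ValueError):
    """Malformed FASTA input (message includes the offending line number)."""


class DuplicateAccessionError(ValueError):
    """Two entries share an accession but carry different sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry.

    ``sequence`` is upper-case with any trailing stop character ('*') already
    stripped; ``source_header`` keeps the raw FASTA header for provenance.
    """

    accession: str
    sequence: str
    gene: Optional[str] = None
    source_header: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if not _SEQ_CHARS.match(self.sequence):
            raise ValueError(f"{self.accession}: sequence contains non-letter characters")


def _accession_from_header(header: str, dialect: str) -> str:
    if dialect == "ccds":
        return header.split("|")[0].strip()
    return header.split()[0]


def read_fasta(
    path: Union[str, Path], dialect: str = "generic"
) -> list[ProteinRecord]:
    """Parse a protein FASTA into deduplicated :class:`ProteinRecord` entries.

    dialect='ccds' takes the accession from the first '|'-delimited header
    token; 'generic' uses the first whitespace token.  Sequences are
    upper-cased and a trailing '*' is removed.  Entries duplicated verbatim
    (same accession and sequence) collapse to one record; the same accession
    with a different sequence raises :class:`DuplicateAccessionError`.
    """
    if dialect not in ("generic", "ccds"):
        raise ValueError(f"unknown FASTA dialect {dialect!r}")
    path = Path(path)

    # Biopython silently yields nothing on junk before the first '>'; check here
    # so a malformed file fails loudly with a line number.
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header '>' as first content line"
                )
            break
        else:
            return []

    records: list[ProteinRecord] = []
    by_accession: dict[str, ProteinRecord] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        accession = _accession_from_header(header, dialect)
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise FastaParseError(f"{path}: entry {accession!r} has an empty sequence")
        if not _SEQ_CHARS.match(seq):
            raise FastaParseError(
                f"{path}: entry {accession!r} contains non-letter sequence characters"
            )
        previous = by_accession.get(accession)
        if previous is not None:
            if previous.sequence == seq:
                continue  # exact duplicate: keep one
            raise DuplicateAccessionError(
                f"{path}: accession {accession!r} occurs with two different sequences"
            )
        rec = ProteinRecord(accession=accession, sequence=seq, source_header=header)
        by_accession[accession] = rec
        records.append(rec)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA, preserving original headers where known."""
    with Path(path).open("w") as fh:
        for r in records:
            header = r.source_header if r.source_header else r.accession
            fh.write(f">{header}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


class GeneMap:
    """Accession (version-stripped) to gene-symbol lookup.

    Lookup ignores any '.n' version suffix.  Unmapped accessions are reported
    by :meth:`get` returning None and collected by callers, never dropped
    silently.
    """

    def __init__(self, mapping: dict[str, str], bad_rows: Optional[list[tuple[int, str]]] = None):
        self._mapping = dict(mapping)
        self.bad_rows = bad_rows or []

    @staticmethod
    def strip_version(accession: str) -> str:
        return accession.split(".")[0]

    def get(self, accession: str) -> Optional[str]:
        return self._mapping.get(self.strip_version(accession))

    def __contains__(self, accession: str) -> bool:
        return self.strip_version(accession) in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()


_HEADER_TOKENS = {
    "accession", "ccds", "ccds_id", "ccdsid", "id",
    "gene", "gene_name", "gene_symbol", "symbol", "name",
}


def load_gene_map(path: Union[str, Path]) -> GeneMap:
    """Load a two-column accession→gene TSV (header auto-detected).

    Rows without exactly two non-empty fields are collected into
    ``GeneMap.bad_rows`` and logged, not silently dropped.  Version suffixes
    on accessions are removed for the lookup key; many accessions may map to
    one gene.
    """
    mapping: dict[str, str] = {}
    bad_rows: list[tuple[int, str]] = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row]
            if not any(row):
                continue
            if lineno == 1 and any(c.lower() in _HEADER_TOKENS for c in row):
                continue
            if len(row) != 2 or not row[0] or not row[1]:
                bad_rows.append((lineno, "\t".join(row)))
                continue
            mapping[GeneMap.strip_version(row[0])] = row[1]
    if bad_rows:
        logger.warning("%s: %d malformed gene-map rows skipped", path, len(bad_rows))
    return GeneMap(mapping, bad_rows=bad_rows)


def unique_genes(
    records: Iterable[ProteinRecord], gene_map: GeneMap
) -> tuple[int, set, list]:
    """Count distinct mapped gene symbols over the records.

    Returns ``(count, gene_set, unmapped_accessions)``.  Symbols are compared
    exactly (case-preserving); unmapped records are reported separately and do
    not contribute to the count.
    """
    genes: set = set()
    unmapped: list = []
    for rec in records:
        gene = gene_map.get(rec.accession)
        if gene is None:
            unmapped.append(rec.accession)
        else:
            genes.add(gene)
    return len(genes), genes, unmapped
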