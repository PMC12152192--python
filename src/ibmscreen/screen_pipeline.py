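"""Genome-wide screen for IAP-binding motifs hidden behind DPP8/9 sites.

Walks every proteome record through the processing rules, tests the exposed
termini against the IBM consensus, and aggregates the counts reported by such
screens: proteins with an IBM directly behind the initiator methionine,
proteins with DPP8/9 cleavage sites (M-X-P "long" and M-P "short" forms), and
proteins where DPP8/9 processing would unmask a hidden IBM.  The counting
unit for protein-level counts is the CCDS entry; gene-level counts collapse
entries through the accession→gene map.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .motif_scan import IBM_PATTERN, MotifPattern, scan_record
from .processing_rules import CleavageRule, builtin_rules
from .proteome_io import GeneMap, ProteinRecord, unique_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenSummary:
    """Aggregate screen counts (protein counts are CCDS entries)."""

    n_ccds: int
    n_genes: int
    n_ibm_p2: int
    n_ibm_p2_genes: int
    n_dpp9_long: int
    n_dpp9_short: int
    n_dpp9_total: int
    n_hidden_ibm: int
    n_hidden_ibm_genes: int

    def __post_init__(self) -> None:
        assert self.n_dpp9_total == self.n_dpp9_long + self.n_dpp9_short
        assert self.n_hidden_ibm <= self.n_dpp9_total


@dataclass(frozen=True)
class CandidateRow:
    """One hidden-IBM candidate: a record/exposing-state pair."""

    accession: str
    gene: Optional[str]
    rule: str
    offset: int
    tetrapeptide: str
    neo_nterm_10mer: str


def run_screen(
    records: Sequence[ProteinRecord],
    gene_map: Optional[GeneMap] = None,
    rules: Optional[Iterable[CleavageRule]] = None,
    pattern: MotifPattern = IBM_PATTERN,
) -> tuple[ScreenSummary, list[CandidateRow]]:
    """Scan every record and return summary counts plus the candidate table.

    Records with unmapped accessions contribute to protein counts but not to
    gene counts.  Output order is deterministic (candidates by accession, then
    offset).  With ``gene_map=None`` all gene counts are zero.
    """
    gene_map = gene_map if gene_map is not None else GeneMap({})
    rules = list(rules) if rules is not None else list(builtin_rules().values())

    ibm_p2_records: list[ProteinRecord] = []
    hidden_records: list[ProteinRecord] = []
    n_long = n_short = 0
    candidates: list[CandidateRow] = []

    for rec in records:
        flags = scan_record(rec, rules=rules, pattern=pattern)
        if flags.ibm_at_p2:
            ibm_p2_records.append(rec)
        n_long += flags.dpp9_long
        n_short += flags.dpp9_short
        if flags.hidden_ibm:
            hidden_records.append(rec)
            gene = gene_map.get(rec.accession)
            for state in flags.exposing_states:
                candidates.append(
                    CandidateRow(
                        accession=rec.accession,
                        gene=gene,
                        rule=state.rule_chain[-1],
                        offset=state.start_offset,
                        tetrapeptide=state.neo_seq[:4],
                        neo_nterm_10mer=state.neo_seq[:10],
                    )
                )

    candidates.sort(key=lambda c: (c.accession, c.offset))
    n_genes, _, unmapped = unique_genes(records, gene_map)
    if unmapped and len(gene_map):
        logger.warning("%d records had no gene mapping", len(unmapped))

    summary = ScreenSummary(
        n_ccds=len(records),
        n_genes=n_genes,
        n_ibm_p2=len(ibm_p2_records),
        n_ibm_p2_genes=unique_genes(ibm_p2_records, gene_map)[0],
        n_dpp9_long=n_long,
        n_dpp9_short=n_short,
        n_dpp9_total=n_long + n_short,
        n_hidden_ibm=len(hidden_records),
        n_hidden_ibm_genes=unique_genes(hidden_records, gene_map)[0],
    )
    return summary, candidates


@dataclass(frozen=True)
class OverlapReport:
    """Intersection of candidate genes with an external gene list."""

    matched: tuple[str, ...]
    candidate_only: tuple[str, ...]
    external_only: tuple[str, ...]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def compare_candidates(
    candidates: Sequence[CandidateRow], external: Iterable[str]
) -> OverlapReport:
    """Case-insensitive exact gene-symbol intersection with an external list.

    Symbols are compared as given (no ortholog mapping); matched symbols are
    reported in the candidates' casing.
    """
    external_list = [g.strip() for g in external if g and g.strip()]
    if not external_list:
        logger.warning("external gene list is empty; overlap is empty")
    cand_genes = {c.gene for c in candidates if c.gene}
    cand_by_lower = {g.lower(): g for g in sorted(cand_genes)}
    ext_by_lower = {g.lower(): g for g in sorted(set(external_list))}

    matched = sorted(cand_by_lower[k] for k in cand_by_lower.keys() & ext_by_lower.keys())
    cand_only = sorted(cand_by_lower[k] for k in cand_by_lower.keys() - ext_by_lower.keys())
    ext_only = sorted(ext_by_lower[k] for k in ext_by_lower.keys() - cand_by_lower.keys())
    return OverlapReport(tuple(matched), tuple(cand_only), tuple(ext_only))


CANDIDATE_COLUMNS = ("accession", "gene", "rule", "offset", "tetrapeptide", "neo_nterm_10mer")


def write_report(
    summary: ScreenSummary,
    candidates: Sequence[CandidateRow],
    outdir: Union[str, Path],
) -> dict[str, Path]:
    """Write ``summary.tsv``, ``candidates.tsv`` and ``summary.txt`` under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary_path = outdir / "summary.tsv"
    with summary_path.open("w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in asdict(summary).items():
            fh.write(f"{key}\t{value}\n")

    cand_path = outdir / "candidates.tsv"
    with cand_path.open("w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                f"{c.accession}\t{c.gene or ''}\t{c.rule}\t{c.offset}\t"
                f"{c.tetrapeptide}\t{c.neo_nterm_10mer}\n"
            )

    text_path = outdir / "summary.txt"
    text_path.write_text(format_summary(summary))
    return {"summary": summary_path, "candidates": cand_path, "text": text_path}


def read_candidates(path: Union[str, Path]) -> list[CandidateRow]:
    """Re-read a candidates.tsv written by :func:`write_report`."""
    rows: list[CandidateRow] = []
    lines = Path(path).read_text().splitlines()
    header = tuple(lines[0].split("\t"))
    if header != CANDIDATE_COLUMNS:
        raise ValueError(f"{path}: unexpected candidate table columns {header}")
    for line in lines[1:]:
        acc, gene, rule, offset, tetra, tenmer = line.split("\t")
        rows.append(
            CandidateRow(
                accession=acc,
                gene=gene or None,
                rule=rule,
                offset=int(offset),
                tetrapeptide=tetra,
                neo_nterm_10mer=tenmer,
            )
        )
    return rows


def format_summary(summary: ScreenSummary) -> str:
    return (
        f"proteome entries (CCDS): {summary.n_ccds} ({summary.n_genes} unique genes)\n"
        f"IBM directly behind Met (residues 2-5): {summary.n_ibm_p2} "
        f"({summary.n_ibm_p2_genes} unique genes)\n"
        f"DPP8/9 cleavage sites: {summary.n_dpp9_total} "
        f"({summary.n_dpp9_long} MXP long, {summary.n_dpp9_short} MP short)\n"
        f"hidden IBM behind a DPP8/9 site: {summary.n_hidden_ibm} "
        f"({summary.n_hidden_ibm_genes} unique genes)\n"
    )
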