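"""Tetrapeptide consensus matching for IAP-binding motifs (IBMs).

An IBM is a loose four-residue consensus that, when free and unmodified at a
protein's very N-terminus, binds inhibitor-of-apoptosis proteins (IAPs).  The
default pattern is::

    [AS][DEFGILMQRSTV][ACGKMPRSV][ADEFGILVWY]

SMAC/DIABLO's AVPI and the DPP8/9-exposed SVPA of adenylate kinase 2 match
it; STXBP2's SGLK does not.  A "hidden" IBM is one that sits immediately
behind a DPP8/9 cleavage site and is only exposed once the dipeptidase has
trimmed the N-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Union

from .processing_rules import (
    CleavageRule,
    NeoTerminus,
    RuleSyntaxError,
    builtin_rules,
    parse_residue_classes,
)

if TYPE_CHECKING:  # pragma: no cover
    from .proteome_io import ProteinRecord

IBM_CONSENSUS_TEXT = "[AS][DEFGILMQRSTV][ACGKMPRSV][ADEFGILVWY]"


@dataclass(frozen=True)
class MotifPattern:
    """Ordered allowed-residue sets defining a short N-terminal consensus."""

    name: str
    classes: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.classes or any(not c for c in self.classes):
            raise ValueError(f"pattern {self.name}: classes must be non-empty")

    @classmethod
    def from_text(cls, name: str, text: str) -> "MotifPattern":
        classes, cut = parse_residue_classes(text)
        if cut is not None:
            raise RuleSyntaxError(f"pattern {name}: cut point not allowed")
        return cls(name=name, classes=classes)

    def __len__(self) -> int:
        return len(self.classes)


IBM_PATTERN = MotifPattern.from_text("IBM", IBM_CONSENSUS_TEXT)


def matches_motif(peptide: str, pattern: MotifPattern = IBM_PATTERN) -> bool:
    """True iff the first len(pattern) residues of ``peptide`` fit the consensus.

    Peptides shorter than the pattern never match; non-standard residues fail
    every class.
    """
    if len(peptide) < len(pattern.classes):
        return False
    return all(peptide[i] in cls_ for i, cls_ in enumerate(pattern.classes))


@dataclass(frozen=True)
class ScanFlags:
    """Per-protein outcome of the IBM screen.

    ibm_at_p2    -- the consensus matches residues 2-5 (the MAP-exposed
                    terminus; the IBM position-1 class {A,S} already implies
                    MAP cleavability under M|[^D]).
    dpp9_long    -- the protein carries an M-X-P site (X not D/E, residue 4 != P).
    dpp9_short   -- the protein carries an M-P site (residue 3 != P).
    hidden_ibm   -- some DPP9-exposed neo-terminus (offset 3 or 4) matches.
    exposing_states -- the neo-termini whose first four residues match.
    """

    ibm_at_p2: bool
    dpp9_long: bool
    dpp9_short: bool
    hidden_ibm: bool
    exposing_states: tuple[NeoTerminus, ...] = field(default_factory=tuple)


def scan_sequence(
    seq: str,
    rules: Optional[Iterable[CleavageRule]] = None,
    pattern: MotifPattern = IBM_PATTERN,
) -> ScanFlags:
    """Apply the processing rules to ``seq`` and test exposed termini for the motif."""
    rule_map = {r.name: r for r in (rules if rules is not None else builtin_rules().values())}
    long_rule = rule_map.get("DPP9_LONG")
    short_rule = rule_map.get("DPP9_SHORT")

    dpp9_long = long_rule.matches(seq) if long_rule else False
    dpp9_short = short_rule.matches(seq) if short_rule else False
    ibm_at_p2 = matches_motif(seq[1:], pattern)

    exposing: list[NeoTerminus] = []
    for rule, hit in ((long_rule, dpp9_long), (short_rule, dpp9_short)):
        if not hit:
            continue
        neo = rule.apply(seq)
        if neo is not None and matches_motif(neo.neo_seq, pattern):
            if rule.name == "DPP9_LONG":
                neo = NeoTerminus(("MAP", "DPP9_LONG"), neo.start_offset, neo.neo_seq)
            exposing.append(neo)
    exposing.sort(key=lambda s: s.start_offset)

    return ScanFlags(
        ibm_at_p2=ibm_at_p2,
        dpp9_long=dpp9_long,
        dpp9_short=dpp9_short,
        hidden_ibm=bool(exposing),
        exposing_states=tuple(exposing),
    )


def scan_record(
    record: "ProteinRecord",
    rules: Optional[Iterable[CleavageRule]] = None,
    pattern: MotifPattern = IBM_PATTERN,
) -> ScanFlags:
    """Scan one proteome record (see :func:`scan_sequence`)."""
    return scan_sequence(record.sequence, rules=rules, pattern=pattern)


def load_motifs(path: Union[str, Path]) -> dict[str, MotifPattern]:
    """Load motif patterns from a text file, one ``NAME: [..][..]...`` per line."""
    motifs: dict[str, MotifPattern] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise RuleSyntaxError(f"{path}:{lineno}: expected 'NAME: PATTERN'")
        name, _, text = line.partition(":")
        motifs[name.strip()] = MotifPattern.from_text(name.strip(), text.strip())
    return motifs
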