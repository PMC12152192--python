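"""N-terminal in silico processing rules.

Methionine aminopeptidases (MAP) and the dipeptidyl peptidases DPP8/9 trim
the N-terminus of nascent cytosolic proteins.  Each peptidase is modelled as
an anchored residue-class pattern plus a cut point: the pattern is matched
against positions 1..k of the unmodified sequence and, on a match, the
residues before the cut point are removed, exposing a neo-N-terminus.

Rules are data, not code.  The textual grammar mirrors the notation used in
the N-terminomics literature::

    MAP:        M | [^D]
    DPP9_LONG:  M[^D^E]P | [^P]
    DPP9_SHORT: MP | [^P]

A bare letter is a single-residue class, ``[XYZ]`` an allowed set, ``[^XYZ]``
an excluded set, and ``|`` the cut point.  A position constraint is satisfied
only by a *standard* residue permitted at that position: non-standard letters
(B, J, O, U, X, Z) never match, even against negated classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_CLASS_TOKEN = re.compile(r"\[(\^?[A-Z^]+)\]|([A-Z])|(\|)|(\s+)")


class RuleSyntaxError(ValueError):
    """Raised when a rule or pattern string cannot be parsed."""


def parse_residue_classes(text: str) -> tuple[tuple[frozenset, ...], Optional[int]]:
    """Parse pattern text into residue classes and an optional cut index.

    Returns ``(classes, cut_after)`` where ``cut_after`` is the number of
    positions preceding the ``|`` sign, or None if the text has no cut point.
    """
    classes: list[frozenset] = []
    cut_after: Optional[int] = None
    pos = 0
    while pos < len(text):
        m = _CLASS_TOKEN.match(text, pos)
        if m is None:
            raise RuleSyntaxError(f"cannot parse pattern at {text[pos:]!r}")
        bracket, literal, cut, _ws = m.groups()
        if bracket is not None:
            negated = "^" in bracket
            letters = frozenset(bracket.replace("^", ""))
            bad = letters - STANDARD_RESIDUES
            if bad:
                raise RuleSyntaxError(f"non-standard residues {sorted(bad)} in {text!r}")
            if not letters:
                raise RuleSyntaxError(f"empty residue class in {text!r}")
            classes.append(STANDARD_RESIDUES - letters if negated else letters)
        elif literal is not None:
            if literal not in STANDARD_RESIDUES:
                raise RuleSyntaxError(f"non-standard residue {literal!r} in {text!r}")
            classes.append(frozenset(literal))
        elif cut is not None:
            if cut_after is not None:
                raise RuleSyntaxError(f"more than one cut point in {text!r}")
            cut_after = len(classes)
        pos = m.end()
    return tuple(classes), cut_after


@dataclass(frozen=True)
class CleavageRule:
    """An anchored N-terminal cleavage pattern.

    ``site_pattern`` holds one allowed-residue set per position (negations are
    resolved against the 20 standard residues at parse time); ``cut_after`` is
    how many N-terminal residues are removed on a match.  At least one matched
    residue must survive as the neo-terminus.
    """

    name: str
    site_pattern: tuple[frozenset, ...]
    cut_after: int

    def __post_init__(self) -> None:
        if not 1 <= self.cut_after < len(self.site_pattern):
            raise ValueError(
                f"rule {self.name}: cut_after must be in [1, {len(self.site_pattern) - 1}]"
            )

    @classmethod
    def from_text(cls, name: str, text: str) -> "CleavageRule":
        classes, cut_after = parse_residue_classes(text)
        if cut_after is None:
            raise RuleSyntaxError(f"rule {name}: no cut point ('|') in {text!r}")
        return cls(name=name, site_pattern=classes, cut_after=cut_after)

    def matches(self, seq: str) -> bool:
        if len(seq) < len(self.site_pattern):
            return False
        return all(seq[i] in cls_ for i, cls_ in enumerate(self.site_pattern))

    def apply(self, seq: str) -> Optional["NeoTerminus"]:
        """Apply the rule; returns the neo-terminus or None on no-match."""
        if not self.matches(seq):
            return None
        return NeoTerminus(
            rule_chain=(self.name,),
            start_offset=self.cut_after + 1,
            neo_seq=seq[self.cut_after:],
        )


@dataclass(frozen=True)
class NeoTerminus:
    """One processing state of a protein.

    ``start_offset`` is the 1-based index of the neo-N-terminal residue in the
    unmodified sequence (initiator methionine = position 1), so
    ``start_offset = 1 + residues removed``.
    """

    rule_chain: tuple[str, ...]
    start_offset: int
    neo_seq: str


MAP_RULE = CleavageRule.from_text("MAP", "M | [^D]")
DPP9_LONG = CleavageRule.from_text("DPP9_LONG", "M[^D^E]P | [^P]")
DPP9_SHORT = CleavageRule.from_text("DPP9_SHORT", "MP | [^P]")


def builtin_rules() -> dict[str, CleavageRule]:
    """The three processing rules of the screen: MAP, DPP9 long, DPP9 short."""
    return {r.name: r for r in (MAP_RULE, DPP9_LONG, DPP9_SHORT)}


def apply_rule(seq: str, rule: CleavageRule) -> Optional[NeoTerminus]:
    """Apply one rule to the unmodified sequence (no-match returns None)."""
    return rule.apply(seq)


def enumerate_neo_termini(
    seq: str, rules: Optional[Iterable[CleavageRule]] = None
) -> list[NeoTerminus]:
    """All processing states of ``seq`` under the given (default: builtin) rules.

    Always includes the unprocessed state at offset 1.  The DPP9 long site
    subsumes MAP cleavability (its position-2 class is a subset of MAP's), so
    its state is recorded with the chain (MAP, DPP9_LONG).
    """
    if rules is None:
        rules = builtin_rules().values()
    states = [NeoTerminus(rule_chain=("none",), start_offset=1, neo_seq=seq)]
    for rule in rules:
        neo = rule.apply(seq)
        if neo is None:
            continue
        if rule.name == "DPP9_LONG":
            neo = NeoTerminus(("MAP", "DPP9_LONG"), neo.start_offset, neo.neo_seq)
        states.append(neo)
    states.sort(key=lambda s: s.start_offset)
    return states


def load_rules(path: Union[str, Path]) -> dict[str, CleavageRule]:
    """Load rules from a text file, one ``NAME: PATTERN`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    rules: dict[str, CleavageRule] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise RuleSyntaxError(f"{path}:{lineno}: expected 'NAME: PATTERN'")
        name, _, pattern = line.partition(":")
        name = name.strip()
        if name in rules:
            raise RuleSyntaxError(f"{path}:{lineno}: duplicate rule name {name!r}")
        rules[name] = CleavageRule.from_text(name, pattern.strip())
    return rules
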