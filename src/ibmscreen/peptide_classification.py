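"""Assign observed MS N-terminal peptides to protein processing states.

An N-terminomics experiment yields semi-tryptic peptides whose start position
within the parent protein reveals its N-terminal processing history: a match
at position 1 is the unprocessed protein, position 2 the MAP-cleaved form,
positions 3/4 the DPP8/9-processed forms (when the corresponding cleavage
rule actually applies to the protein), anything else an internal peptide.
N-terminal acetylation is an input flag from the upstream search engine, not
predicted here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .processing_rules import CleavageRule, builtin_rules


class PeptideState(str, enum.Enum):
    UNPROCESSED = "UNPROCESSED"
    MAP_ONLY = "MAP_ONLY"
    DPP9_SHORT = "DPP9_SHORT"
    MAP_DPP9 = "MAP_DPP9"
    INTERNAL = "INTERNAL"
    UNMATCHED = "UNMATCHED"


@dataclass(frozen=True)
class ObservedPeptide:
    """One search-engine peptide observation."""

    protein_accession: str
    peptide: str
    nterm_acetyl: bool = False
    sample: Optional[str] = None
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class PeptideStateCall:
    """State assignment for one observed peptide.

    ``offset`` is the smallest 1-based match position of the peptide in the
    protein (None if unmatched); ``all_offsets`` retains every match position
    for audit.
    """

    state: PeptideState
    acetylated: bool
    offset: Optional[int]
    all_offsets: tuple[int, ...] = ()


# offset -> (state, rule that must apply to the *protein* at that offset)
_OFFSET_STATES = {
    2: (PeptideState.MAP_ONLY, "MAP"),
    3: (PeptideState.DPP9_SHORT, "DPP9_SHORT"),
    4: (PeptideState.MAP_DPP9, "DPP9_LONG"),
}


def _all_match_offsets(protein_seq: str, peptide: str) -> tuple[int, ...]:
    offsets = []
    start = protein_seq.find(peptide)
    while start != -1:
        offsets.append(start + 1)
        start = protein_seq.find(peptide, start + 1)
    return tuple(offsets)


def classify_peptide(
    protein_seq: str,
    pep: ObservedPeptide,
    rules: Optional[Mapping[str, CleavageRule]] = None,
) -> PeptideStateCall:
    """Classify one peptide against its parent protein sequence.

    The smallest match offset wins.  Offsets 2/3/4 are only called as
    processing states when the corresponding cleavage rule matches the
    unmodified protein; otherwise the peptide is INTERNAL.
    """
    rules = dict(rules) if rules is not None else builtin_rules()
    protein_seq = protein_seq.upper()
    peptide = pep.peptide.upper()

    offsets = _all_match_offsets(protein_seq, peptide)
    if not offsets:
        return PeptideStateCall(PeptideState.UNMATCHED, pep.nterm_acetyl, None, ())

    offset = offsets[0]
    if offset == 1:
        state = PeptideState.UNPROCESSED
    elif offset in _OFFSET_STATES:
        state, rule_name = _OFFSET_STATES[offset]
        rule = rules.get(rule_name)
        if rule is None or not rule.matches(protein_seq):
            state = PeptideState.INTERNAL
    else:
        state = PeptideState.INTERNAL
    return PeptideStateCall(state, pep.nterm_acetyl, offset, offsets)


def classify_peptides(
    proteins: Mapping[str, str],
    peptides: Iterable[ObservedPeptide],
    rules: Optional[Mapping[str, CleavageRule]] = None,
) -> pd.DataFrame:
    """Classify many peptides; returns a tidy DataFrame of calls.

    Raises KeyError for peptides whose accession has no sequence.
    """
    rows = []
    for pep in peptides:
        if pep.protein_accession not in proteins:
            raise KeyError(f"no sequence for accession {pep.protein_accession!r}")
        call = classify_peptide(proteins[pep.protein_accession], pep, rules=rules)
        rows.append(
            {
                "accession": pep.protein_accession,
                "peptide": pep.peptide,
                "acetylated": pep.nterm_acetyl,
                "sample": pep.sample,
                "intensity": pep.intensity,
                "state": call.state.value,
                "offset": call.offset,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["accession", "peptide", "acetylated", "sample", "intensity", "state", "offset"],
    )


def summarize_states(
    calls: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate intensities per (state, acetylated, condition).

    ``calls`` is the output of :func:`classify_peptides` with intensities and
    sample labels present; ``groups`` maps sample → condition.  Returns the
    per-state sum/mean table plus the mean intensity of INTERNAL peptides per
    condition (the "peptides w/o N-terminus" baseline).
    """
    df = calls.dropna(subset=["intensity", "sample"]).copy()
    df["condition"] = df["sample"].map(dict(groups))
    if df["condition"].isna().any():
        missing = sorted(df.loc[df["condition"].isna(), "sample"].unique())
        raise ValueError(f"samples without a condition assignment: {missing}")

    table = (
        df.groupby(["state", "acetylated", "condition"], observed=True)["intensity"]
        .agg(["sum", "mean", "count"])
        .reset_index()
    )
    internal = df[df["state"] == PeptideState.INTERNAL.value]
    baseline = internal.groupby("condition", observed=True)["intensity"].mean()
    baseline.name = "internal_mean_intensity"
    return table, baseline


PEPTIDE_COLUMNS = ("accession", "peptide", "acetyl", "sample", "intensity")


def read_peptides_tsv(path: Union[str, Path]) -> list[ObservedPeptide]:
    """Read observed peptides from TSV: accession, peptide, acetyl(0/1), sample, intensity."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "peptide": str, "sample": str})
    missing = set(PEPTIDE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    peptides = []
    for row in df.itertuples(index=False):
        intensity = getattr(row, "intensity", None)
        peptides.append(
            ObservedPeptide(
                protein_accession=row.accession,
                peptide=row.peptide,
                nterm_acetyl=bool(int(row.acetyl)),
                sample=getattr(row, "sample", None),
                intensity=None if intensity is None or pd.isna(intensity) else float(intensity),
            )
        )
    return peptides


def write_peptides_tsv(peptides: Sequence[ObservedPeptide], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(PEPTIDE_COLUMNS) + "\n")
        for p in peptides:
            fh.write(
                f"{p.protein_accession}\t{p.peptide}\t{int(p.nterm_acetyl)}\t"
                f"{p.sample or ''}\t{'' if p.intensity is None else p.intensity}\n"
            )
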