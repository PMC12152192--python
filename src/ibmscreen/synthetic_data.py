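"""Seeded generators with planted ground truth for every pipeline stage.

Three generators emulate the pipeline's inputs:

* :func:`gen_proteome` — proteomes whose records realize prescribed classes
  (IBM at position 2, DPP9 long/short site with or without a hidden IBM, or
  none) by constructive prefixes, so screen counts are exactly checkable.
* :func:`gen_peptides` — N-terminal and internal peptides at known offsets,
  emulating N-terminomics observations.
* :func:`gen_lfq` — LFQ matrices with planted enriched proteins and
  intensity-dependent (lower-tail, MNAR) missingness.

Every record of a planted proteome is verified against a naive,
independently coded checker at generation time; a mismatch is a hard error.
The background residue distribution is uniform over the 20 standard residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .enrichment_stats import LFQMatrix
from .peptide_classification import ObservedPeptide, PeptideState
from .proteome_io import ProteinRecord

_STD = "ACDEFGHIKLMNPQRSTVWY"

# IBM consensus, spelled out independently of motif_scan for the naive checker
_IBM1, _IBM2, _IBM3, _IBM4 = "AS", "DEFGILMQRSTV", "ACGKMPRSV", "ADEFGILVWY"

PROTEOME_CLASSES = (
    "ibm_p2",
    "dpp9_long_hidden_ibm",
    "dpp9_long_no_ibm",
    "dpp9_short_hidden_ibm",
    "dpp9_short_no_ibm",
    "none",
)


def naive_flags(seq: str) -> dict[str, bool]:
    """Straight-line re-derivation of the screen flags (the test oracle).

    Written position-by-position from the rule definitions, with no shared
    code with the rule engine or motif scanner.
    """
    def ibm(s: str) -> bool:
        return (
            len(s) >= 4
            and s[0] in _IBM1 and s[1] in _IBM2 and s[2] in _IBM3 and s[3] in _IBM4
        )

    long_site = (
        len(seq) >= 4
        and seq[0] == "M"
        and seq[1] in _STD and seq[1] not in "DE"
        and seq[2] == "P"
        and seq[3] in _STD and seq[3] != "P"
    )
    short_site = (
        len(seq) >= 3
        and seq[0] == "M"
        and seq[1] == "P"
        and seq[2] in _STD and seq[2] != "P"
    )
    return {
        "ibm_p2": ibm(seq[1:5]),
        "dpp9_long": long_site,
        "dpp9_short": short_site,
        "hidden_ibm": (long_site and ibm(seq[3:7])) or (short_site and ibm(seq[2:6])),
    }


@dataclass
class PlantedProteome:
    records: list[ProteinRecord]
    truth: pd.DataFrame  # index accession, columns: class + the four flags


def _random_ibm(rng: np.random.Generator) -> str:
    return "".join(cls[rng.integers(len(cls))] for cls in (_IBM1, _IBM2, _IBM3, _IBM4))


def _random_non_ibm(rng: np.random.Generator, first_not: str = "") -> str:
    """A tetrapeptide failing the IBM consensus, first residue outside first_not."""
    while True:
        tetra = "".join(rng.choice(list(_STD), size=4))
        if tetra[0] in first_not:
            continue
        if not (tetra[0] in _IBM1 and tetra[1] in _IBM2 and tetra[2] in _IBM3 and tetra[3] in _IBM4):
            return tetra


def _class_flags(cls: str) -> dict[str, bool]:
    return {
        "ibm_p2": cls == "ibm_p2",
        "dpp9_long": cls.startswith("dpp9_long"),
        "dpp9_short": cls.startswith("dpp9_short"),
        "hidden_ibm": cls.endswith("hidden_ibm"),
    }


def _build_prefix(cls: str, rng: np.random.Generator) -> str:
    """Construct an N-terminal prefix realizing exactly the requested class.

    The IBM residue classes make the realizations non-overlapping: class 1
    {A,S} excludes P (no accidental DPP9 short behind an IBM at P2) and class
    2 excludes P (no accidental DPP9 long).
    """
    if cls == "ibm_p2":
        return "M" + _random_ibm(rng)
    if cls == "dpp9_long_hidden_ibm":
        x = _STD[rng.integers(len(_STD))]
        while x in "DE":
            x = _STD[rng.integers(len(_STD))]
        return "M" + x + "P" + _random_ibm(rng)
    if cls == "dpp9_long_no_ibm":
        x = _STD[rng.integers(len(_STD))]
        while x in "DE":
            x = _STD[rng.integers(len(_STD))]
        return "M" + x + "P" + _random_non_ibm(rng, first_not="P")
    if cls == "dpp9_short_hidden_ibm":
        return "MP" + _random_ibm(rng)
    if cls == "dpp9_short_no_ibm":
        return "MP" + _random_non_ibm(rng, first_not="P")
    if cls == "none":
        first = _STD[rng.integers(len(_STD))]
        while first == "M":
            first = _STD[rng.integers(len(_STD))]
        return first + _random_non_ibm(rng)
    raise ValueError(f"unknown proteome class {cls!r}")


def gen_proteome(
    n: int,
    class_fractions: Optional[Mapping[str, float]] = None,
    length_range: tuple[int, int] = (50, 300),
    seed: Optional[int] = None,
) -> PlantedProteome:
    """Generate ``n`` records whose screen flags are known by construction.

    ``class_fractions`` maps class names (see :data:`PROTEOME_CLASSES`) to
    fractions summing to 1; counts per class are ``round(n * fraction)`` fixed
    up to total n (largest class absorbs rounding), so planted counts are
    exact.  Every record is re-verified with :func:`naive_flags`; a prefix
    that accidentally realizes extra flags is resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fractions = dict(class_fractions) if class_fractions is not None else {"none": 1.0}
    unknown = set(fractions) - set(PROTEOME_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("class fractions must be non-negative")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")

    counts = {cls: int(round(n * f)) for cls, f in fractions.items()}
    largest = max(counts, key=lambda c: counts[c])
    counts[largest] += n - sum(counts.values())

    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth_rows = []
    idx = 0
    for cls in PROTEOME_CLASSES:
        for _ in range(counts.get(cls, 0)):
            idx += 1
            accession = f"SYN{idx:05d}.1"
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            want = _class_flags(cls)
            for _attempt in range(1000):
                prefix = _build_prefix(cls, rng)
                tail_len = max(length - len(prefix), 8)
                tail = "".join(rng.choice(list(_STD), size=tail_len))
                seq = prefix + tail
                if naive_flags(seq) == want:
                    break
            else:  # pragma: no cover - constructive prefixes converge immediately
                raise RuntimeError(f"could not realize class {cls!r}")
            records.append(
                ProteinRecord(
                    accession=accession,
                    sequence=seq,
                    source_header=f"{accession}|synthetic|{cls}",
                )
            )
            truth_rows.append({"accession": accession, "class": cls, **want})

    truth = pd.DataFrame(truth_rows).set_index("accession")
    for rec in records:  # hard invariant: planted truth == naive oracle
        assert naive_flags(rec.sequence) == truth.loc[
            rec.accession, ["ibm_p2", "dpp9_long", "dpp9_short", "hidden_ibm"]
        ].to_dict()
    return PlantedProteome(records=records, truth=truth)


def default_gene_map(proteome: PlantedProteome) -> dict[str, str]:
    """A trivial one-gene-per-record mapping for planted proteomes."""
    return {
        rec.accession.split(".")[0]: f"GENE{i + 1:05d}"
        for i, rec in enumerate(proteome.records)
    }


_STATE_OFFSETS = {
    PeptideState.UNPROCESSED: 1,
    PeptideState.MAP_ONLY: 2,
    PeptideState.DPP9_SHORT: 3,
    PeptideState.MAP_DPP9: 4,
}


def _state_applicable(seq: str, state: PeptideState) -> bool:
    flags = naive_flags(seq)
    if state == PeptideState.UNPROCESSED:
        return True
    if state == PeptideState.MAP_ONLY:
        return len(seq) >= 2 and seq[0] == "M" and seq[1] in _STD and seq[1] != "D"
    if state == PeptideState.DPP9_SHORT:
        return flags["dpp9_short"]
    if state == PeptideState.MAP_DPP9:
        return flags["dpp9_long"]
    return True


@dataclass
class PlantedPeptides:
    peptides: list[ObservedPeptide]
    truth: pd.DataFrame  # accession, peptide, true_state, offset


def gen_peptides(
    records: Sequence[ProteinRecord],
    states: Sequence[tuple[PeptideState, bool]] = (
        (PeptideState.UNPROCESSED, True),
        (PeptideState.MAP_ONLY, False),
        (PeptideState.MAP_DPP9, False),
    ),
    n_internal: int = 2,
    length_range: tuple[int, int] = (8, 14),
    seed: Optional[int] = None,
) -> PlantedPeptides:
    """Emit the exact N-terminal peptide for each requested (state, acetyl) pair.

    States not applicable to a protein (e.g. MAP_DPP9 on an 'MD...' start) are
    skipped for that protein.  ``n_internal`` tryptic-like internal peptides
    per protein are added with true state INTERNAL.
    """
    rng = np.random.default_rng(seed)
    peptides: list[ObservedPeptide] = []
    truth_rows = []
    for rec in records:
        seq = rec.sequence
        for state, acetyl in states:
            if not _state_applicable(seq, state):
                continue
            offset = _STATE_OFFSETS[state]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            pep = seq[offset - 1 : offset - 1 + length]
            if len(pep) < 4:
                continue
            peptides.append(ObservedPeptide(rec.accession, pep, nterm_acetyl=acetyl))
            truth_rows.append(
                {"accession": rec.accession, "peptide": pep,
                 "true_state": state.value, "offset": offset}
            )
        for _ in range(n_internal):
            # start deep enough that the peptide cannot also match offsets 1-4
            lo = 6
            hi = max(lo + 1, len(seq) - length_range[0])
            start = int(rng.integers(lo, hi))
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            pep = seq[start : start + length]
            if len(pep) < 6 or seq.find(pep) + 1 <= 4:
                continue
            peptides.append(ObservedPeptide(rec.accession, pep, nterm_acetyl=False))
            truth_rows.append(
                {"accession": rec.accession, "peptide": pep,
                 "true_state": PeptideState.INTERNAL.value, "offset": seq.find(pep) + 1}
            )
    truth = pd.DataFrame(truth_rows)
    return PlantedPeptides(peptides=peptides, truth=truth)


@dataclass
class PlantedLFQ:
    matrix: LFQMatrix
    enriched: frozenset
    params: dict


def gen_lfq(
    n_proteins: int = 100,
    n_enriched: int = 10,
    effect_log2: float = 3.0,
    sd: float = 0.5,
    n_per_group: int = 3,
    baseline: float = 25.0,
    missing_slope: float = 2.0,
    missing_threshold: float = 23.8,
    seed: Optional[int] = None,
) -> PlantedLFQ:
    """LFQ matrix with planted group-A enrichment and lower-tail missingness.

    Log2 intensities are Normal(baseline, sd²) for null proteins in both
    groups; enriched proteins have their group-A mean shifted by
    ``effect_log2``.  Each cell goes missing with probability
    expit(missing_slope · (missing_threshold − value)), which is
    non-increasing in the true intensity (MNAR).  ``missing_threshold=-inf``
    yields a complete matrix.  The stored matrix is on the raw (2**x) scale.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must be <= n_proteins")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    enriched = frozenset(proteins[:n_enriched])
    samples = [f"A{j + 1}" for j in range(n_per_group)] + [
        f"B{j + 1}" for j in range(n_per_group)
    ]
    groups = {s: s[0] for s in samples}

    means = np.full((n_proteins, 2 * n_per_group), baseline, dtype=float)
    means[:n_enriched, :n_per_group] += effect_log2
    log_values = rng.normal(means, sd)

    if np.isneginf(missing_threshold):
        missing = np.zeros_like(log_values, dtype=bool)
    else:
        p_missing = expit(missing_slope * (missing_threshold - log_values))
        missing = rng.random(log_values.shape) < p_missing
    if missing.all(axis=0).any():
        raise ValueError("missingness parameters produced an all-missing column")

    raw = np.power(2.0, log_values)
    raw[missing] = np.nan
    matrix = LFQMatrix(
        intensities=pd.DataFrame(raw, index=proteins, columns=samples),
        groups=groups,
    )
    params = {
        "n_proteins": n_proteins,
        "n_enriched": n_enriched,
        "effect_log2": effect_log2,
        "sd": sd,
        "n_per_group": n_per_group,
        "baseline": baseline,
        "missing_slope": missing_slope,
        "missing_threshold": missing_threshold,
        "seed": seed,
    }
    return PlantedLFQ(matrix=matrix, enriched=enriched, params=params)


def write_proteome(proteome: PlantedProteome, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write FASTA + truth TSV + manifest for a planted proteome."""
    from .proteome_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "proteome.fasta"
    write_fasta(proteome.records, fasta)
    truth = outdir / "truth.tsv"
    proteome.truth.to_csv(truth, sep="\t")
    manifest = outdir / "manifest.tsv"
    counts = proteome.truth["class"].value_counts()
    with manifest.open("w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"n_records\t{len(proteome.records)}\n")
        for cls in PROTEOME_CLASSES:
            fh.write(f"n_{cls}\t{int(counts.get(cls, 0))}\n")
    return {"fasta": fasta, "truth": truth, "manifest": manifest}


def write_lfq(planted: PlantedLFQ, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write intensity TSV + groups TSV + truth TSV + manifest for a planted matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    intensities = outdir / "lfq.tsv"
    planted.matrix.intensities.to_csv(intensities, sep="\t", index_label="protein")
    groups = outdir / "groups.tsv"
    with groups.open("w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in planted.matrix.groups.items():
            fh.write(f"{s}\t{g}\n")
    truth = outdir / "truth.tsv"
    with truth.open("w") as fh:
        fh.write("protein\tenriched\n")
        for p in planted.matrix.intensities.index:
            fh.write(f"{p}\t{int(p in planted.enriched)}\n")
    manifest = outdir / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("key\tvalue\n")
        for k, v in planted.params.items():
            fh.write(f"{k}\t{v}\n")
    return {"intensities": intensities, "groups": groups, "truth": truth, "manifest": manifest}
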