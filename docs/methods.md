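# Methods

## Biological model

Cytosolic proteins mature through N-terminal processing. Methionine
aminopeptidases (MAP) remove the initiator methionine when the second residue
permits it; the dipeptidyl peptidases DPP8 and DPP9 then remove an N-terminal
dipeptide ending in proline, exposing a neo-N-terminus. Certain exposed
tetrapeptides are IAP-binding motifs (IBMs): when free and unmodified at the
very N-terminus they recruit inhibitor-of-apoptosis proteins (XIAP, BIRC2/3/6),
E3 ligases that ubiquitinate the bearer and route it to the proteasome.
N-terminal acetylation by NatA blocks the interaction. The package asks, for
every protein in a proteome: would DPP8/9 processing unmask an IBM that is
invisible in the mature (MAP-processed) protein?

## Processing rules

The three rules are anchored residue-class patterns with a cut point:

| rule | pattern | residues removed | neo-terminus offset |
|---|---|---|---|
| MAP | `M \| [^D]` | 1 | 2 |
| DPP9 long | `M[^D^E]P \| [^P]` | 3 | 4 |
| DPP9 short | `MP \| [^P]` | 2 | 3 |

`[^X]` excludes the listed residues; the cut is at `|`. Positions are matched
against the unmodified sequence only (rules never match internally) and a
constraint is satisfied only by one of the 20 standard residues permitted at
that position — non-standard letters (B, J, O, U, X, Z) fail every class,
including negated ones. This is deliberately conservative: an ambiguous
residue can never create a motif call.

The MAP rule is a coarse simplification of true MAP specificity (which depends
on the gyration radius of residue 2, not just "not aspartate"). It is kept as
is because the screen is defined by these three rules; substituting a canonical
MAP rule would change every downstream count. Sequential rule composition
(MAP product re-entering the DPP9 rules) is intentionally not modelled: the
DPP9 long pattern already encodes the MAP-then-DPP9 route on the unmodified
sequence, and its position-2 class is a strict subset of MAP's, so "long site
implies MAP site" holds by construction (asserted as a property test).

The long and short sites are mutually exclusive on any sequence (position 3
must be proline for the long form and not proline for the short form), so
DPP9-site counts decompose exactly into long + short, and at most one DPP9
state can expose an IBM per protein.

## IBM consensus

The default motif is `[AS][DEFGILMQRSTV][ACGKMPRSV][ADEFGILVWY]`, matched
against the first four residues of an exposed terminus. SMAC/DIABLO's AVPI,
the AVPA positive-control motif, AK2's SVPA and EIF2A's STPL match; STXBP2's
SGLK and mouse AK2's NVLA do not. A known wrinkle: HtrA2's AVPS — an
experimentally validated IBM — fails this consensus because serine is not in
the position-4 class. We keep the consensus as configured and document the
discrepancy; patterns are data, so a widened position-4 class (e.g. adding S)
can be supplied in a motif file without code changes.

"IBM directly behind the initiator methionine" is implemented as residues 2–5
matching the consensus, with no explicit MAP-cleavability check: the
position-1 class {A, S} already satisfies `M | [^D]`, so the check is implied
(and asserted in tests, together with the mutual exclusivity of a P2 IBM and
either DPP9 site).

## Screen semantics

The counting unit for protein-level counts is the proteome entry (for CCDS
input, the CCDS), not the gene; gene-level counts collapse entries through an
accession→gene map with accession versions ignored. Entries are deduplicated
on (accession, sequence); the same accession with two different sequences is a
hard error so that "unique entries" is auditable. Records without a gene
mapping contribute to protein counts but not gene counts and are listed in an
unmapped report — this keeps protein counts independent of mapping coverage,
since it is not knowable whether published gene counts were computed before or
after dropping unmapped entries (both counts are emitted). The screen path
contains no randomness; candidate tables are sorted by accession and two runs
are byte-identical.

## Peptide state assignment

An observed N-terminal peptide is located in its parent protein by exact
substring match (upper-cased; I/L are not merged). The smallest match offset
wins, with all offsets retained for audit. Offset 1 is the unprocessed
protein; offsets 2/3/4 are called MAP-only / DPP9-short / MAP+DPP9 **only if
the corresponding rule matches the unmodified protein** — otherwise the
peptide is internal, as is any deeper offset. Acetylation is carried through
from the search-engine flag, never predicted. Intensity summaries aggregate
sum and mean per (state, acetylated, condition), with the mean over internal
peptides as the abundance baseline.

## Enrichment statistics

The pull-down/IP pipeline follows the standard Perseus workflow:

1. **Filter:** keep a protein if quantified in ≥ `min_valid` replicates in at
   least one group (default; an "each group" mode is available). Presets:
   pull-down 2-of-3, IP 3-of-3.
2. **Log-transform:** base 2 by default. The base only rescales differences,
   never p-values; it is configurable.
3. **Impute:** missing cells are drawn independently from
   Normal(μ − downshift·σ, (width·σ)²), with μ, σ taken from all present
   values of the whole matrix (default, matching the global-distribution
   wording of the workflow this reproduces) or per column (the common Perseus
   default, available as `scope="column"`). Presets: pull-down downshift 1.8,
   IP downshift 2.0, width 0.3 in both. Degenerate scopes (fewer than two
   present values, or zero variance) raise rather than silently imputing a
   constant.
4. **Test:** equal-variance two-sample Student t per protein, two-sided p from
   the t distribution with n_A + n_B − 2 df; difference = mean(A) − mean(B) in
   log units.
5. **Call hits:** significant ⇔ −log10(p) ≥ 2 and (by default) positive
   difference. No multiple-testing correction enters the hit call; a
   Benjamini–Hochberg FDR column is emitted for reference only.

Imputation is seeded and bit-reproducible; it touches only missing cells.

## Synthetic data

The generators exist so every pipeline stage can be checked against planted
ground truth.

**Proteomes** (`gen_proteome`): each record realizes one of six classes (IBM
at P2; DPP9 long/short site with or without a hidden IBM; none) by a
constructive prefix — e.g. `M`, a non-{D,E} residue, `P`, then a tetrapeptide
drawn uniformly from the product of the IBM classes. Class counts are
`round(n·fraction)` so planted counts are exact, not expected values. Every
record is re-verified against a naive, independently coded flag checker
(`naive_flags`, written position-by-position with no shared code with the rule
engine); accidental extra matches in the prefix window trigger resampling, and
a truth/oracle mismatch is a hard assertion. Background residues are uniform
over the 20 standard residues — human composition would only change
accidental-match rates, which the verify/resample step neutralizes.

**Peptides** (`gen_peptides`): emits the exact N-terminal peptide (length
8–14) for each requested state at offsets 1/2/3/4, skipping states the
protein cannot realize, plus internal peptides starting at position ≥ 7.

**LFQ matrices** (`gen_lfq`): null proteins are Normal(baseline, sd²) on the
log2 scale in both groups; enriched proteins have the group-A mean shifted by
`effect_log2`. Each cell goes missing with probability
expit(slope·(threshold − value)) — non-increasing in intensity, i.e. MNAR
lower-tail missingness; `threshold = −inf` yields a complete matrix. Defaults
are the study conditions used throughout tests and the acceptance script:
baseline 25.0 (a typical log2 LFQ magnitude), sd 0.5 (typical within-group
replicate scatter for pull-downs), effect 3 log2 units, 3 vs 3 replicates,
threshold baseline − 1.2 with slope 2 (≈ 9% missing cells overall,
concentrated in the lower tail). Matrices are stored on the raw 2^x scale so
they enter the pipeline through the same `prepare` step as real data.

What the generators do *not* emulate: human length/composition statistics,
peptide-level quantification noise, correlated missingness across samples,
match-between-runs artefacts, and contaminant/reverse hits. Passing tests
therefore demonstrate correctness of the algorithms under the stated model,
not robustness to every pathology of real MS data.

## Problem sizes and numerical choices

- Oracle-equivalence checks use 10⁵ random sequences of length 0–11 (long
  enough to cover every rule/motif window plus slack).
- The enrichment parameter-recovery simulation uses 200 seeded matrices of
  100 proteins (10 enriched) at 3 vs 3; recall is pooled over 2,000 enriched
  proteins and the null false-hit rate over ≈ 18,000 nulls.
- The imputation calibration uses a 6,000 × 6 matrix with ~35% missingness
  (≈ 12,600 imputed cells), comparing the empirical imputed mean within 3
  standard errors of μ − 1.8σ and the sd within 5% of 0.3σ.
- Ties/degenerate inputs: empty proteomes yield all-zero summaries; peptides
  shorter than the motif never match; a peptide matching at several offsets is
  assigned the smallest; σ = 0 imputation scopes raise.

## Known limitations

- The rules are binary site predicates, not kinetics: no partial processing,
  no co-translational timing, no tissue-specific DPP8/9 activity.
- Cross-species gene symbols in external candidate lists are compared as
  given; no ortholog mapping.
- Structure/disorder-based accessibility of the neo-terminus is out of scope;
  a matched motif on a buried terminus would still be flagged.
- The genome-scale reproduction requires the NCBI CCDS Release 24 protein
  FASTA and an Ensembl BioMart CCDS→gene export, which must be downloaded by
  the user (see README); the test suite covers the identical code path on
  bundled and generated inputs.
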