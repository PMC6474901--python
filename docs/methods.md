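# Methods

## Problem and pipeline

Freshwater mussels (the quagga mussel *Dreissena bugensis* and its
relatives) anchor themselves with the byssus, a secreted protein
adhesive. Because little genomic data exists for these species, byssal
proteins are "fingerprinted": tandem-MS peptide spectra from induced
byssal secretions are matched against a six-frame translation of a de
novo assembled foot transcriptome, and transcriptome ORFs supported by
enough high-confidence peptide evidence are accepted as byssal-protein
candidates. `byssomap` re-implements this analysis as a reusable,
tested pipeline:

1. **Transcriptome model** — FASTA ingestion with Trinity-style
   `comp<N>_c<K>` component parsing, six-frame translation under the
   standard genetic code, ORF extraction between stop codons, and
   Greek-letter variant naming within a component by decreasing mature
   mass (α = heaviest).
2. **Peptide evidence** — in-silico tryptic digestion
   (cleave after K/R, not before P, ≤2 missed cleavages),
   modification-aware exact-substring matching of PSM backbones to
   isoforms (lower-case `n`/`q` = deamidation, `y` = Tyr hydroxylation
   to DOPA; marks annotate, they never change what matches), spectral
   counting per sample, coverage over the mature sequence, and
   parsimony protein grouping (subset peptide sets merge into the
   largest set's anchor).
3. **Candidate selection** — protein −10lgP ≥ 50, ≥ 2 qualifying
   spectra whose peptides score ≥ 15 (purely de novo peptides also
   need ALC ≥ 80 % and by default never count toward the spectrum
   minimum), rejection on homology to a cellular contaminant at
   E < 1e−6 (strictly below; allowlisted byssal homologs never
   reject), and a signal-peptide gate. Named overrides bypass the
   score gate with a logged justification — the automatable analogue
   of accepting a borderline protein after manual spectrum inspection.
4. **Characterization** — average mass, Henderson–Hasselbalch net
   charge and pI, mol% composition, Kyte–Doolittle hydropathy,
   compositional category, terminal-segment ("block") pIs, and a
   charge–hydropathy disorder proxy, all on the mature sequence.
5. **Repeats and motifs** — exact tandem-repeat detection and
   degenerate-motif counting with `(Y/S)`-style alternation notation
   and `x` wildcards.
6. **Synthetic data** — a seeded generator planting ground truth so
   the whole pipeline is testable without external downloads.

## Charge and pI model

Net charge at a given pH is the Henderson–Hasselbalch sum

    z(pH) = Σ_pos 1/(1+10^(pH−pKa)) − Σ_neg 1/(1+10^(pKa−pH))

with positive groups N-terminus, K, R, H and negative groups
C-terminus, D, E, C, Y. Cys and Tyr are ionizable by default (the
pepstats convention; a toggle exists because charge values at pH 7 are
sensitive to this). The default pKa set is the EMBOSS set (N-term 8.6,
C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1);
Bjellqvist and Lehninger sets are selectable. z(pH) is strictly
decreasing, so the pI is the unique root, found by bisection on
[0, 14] to < 1e−4 pH units. Under this model the curated mature
sequences reproduce the published MW/pI table at its printed precision
for 16 of 17 entries (the exception, Dbfp8, is discussed below).

Masses are average masses (Biopython residue weights + one water), the
"theoretical mass" convention of pepstats; monoisotopic masses are
available by flag. `X` residues are an error with positions listed.

### Known irreproducible published values

Two published numbers cannot be reproduced under any standard pKa set
and are reported as computed, not as printed:

- The Dbfp9 N-terminal segment `RFVYGDYDDDYGYGG` computes to pI 3.66
  with free termini (the published 3.4 is obtained only if *both*
  termini are treated as non-ionizable, i.e. as an internal fragment —
  a convention inconsistent with the Dbfp15 segment, which reproduces
  its published 3.3 only *with* free termini).
- Mature Dbfp5 computes to +4.8 at pH 7 (EMBOSS) or +4.7 (Bjellqvist)
  against a published +4.2.

### Curated signal boundaries

The reference set stores published precursor sequences with curated
signal-peptide lengths. Boundaries were fixed per protein so that the
mature residue count, mass and pI jointly match the published values;
where those are mutually inconsistent (Dbfp6, Dbfp9β, Dbfp12δ,
Dbfp17), the boundary reproducing mass *and* pI was chosen. Dbfp8 is
irreconcilable: its published composition row implies a 150-residue
mature (and names lysine, 12.0 mol%, misprinted as "L"), while its
published MW/pI imply 152; the curation follows the composition.

## Compositional categories

The category rule is reverse-engineered to reproduce the published
sixteen-row classification and documented as such: **C-rich** iff
C ≥ 10 mol%; else **G/Y-rich** iff G ≥ 15 and Y ≥ 10; else **P-rich**
iff P ≥ 8.5 or P is the single most abundant residue; else
uncategorized. Both the published prominent-mol% rows and compositions
recomputed from the full sequences classify identically (golden test).

## Signal-peptide heuristic

A lightweight classical stand-in, not a trained predictor: cleavage in
positions 15–35 requires a non-negatively charged n-region (positions
1–5), a hydrophobic h-core (≥ 6 residues, mean Kyte–Doolittle ≥ 1.6,
within positions 3–20), and small residues (A/G/S/C/T/V) at −3/−1.
Candidate sites score core hydrophobicity + 0.2 per A/G/S at −3/−1
− 0.3·|pos − (core end + 6)|; ties take the smallest position. The
distance term encodes the typical ~6-residue c-region. On the curated
precursors the heuristic lands within ±3 residues of the annotated
site for 12 of 15 signal-bearing proteins; annotation files always
override it, and variant completion (extending a truncated N-terminus
from a same-component variant whose signal region overlaps exactly
over ≥ 10 residues) outranks the heuristic as evidence of secretion.

## Tandem repeats and motifs

Repeats are exact (degenerate variation belongs to the motif layer).
For each unit length 2–12 the sequence is scanned for maximal periodic
regions; within a region every phase (unit rotation) achieving the
maximal copy count is reported, so the biologically conventional unit
(e.g. `PKYPGGGN` ×4) appears even when the periodic region begins two
residues earlier. Runs wholly explained by a shorter unit over the
same span (ABAB×2 inside AB×4) are suppressed. Motif counting is
overlapping by default — required to reproduce the published count of
five `GNYG` in Dbfp9β, where occurrences share a glycine.

## Disorder proxy

The Uversky charge–hydropathy boundary: a sequence (≥ 20 residues) is
flagged disorder-prone when mean |net charge|/residue at pH 7 exceeds
2.785·⟨H⟩ − 1.151, with ⟨H⟩ the Kyte–Doolittle mean rescaled to
[0, 1]. This is reported only as a proxy flag, not as an energy-based
disorder score.

## Synthetic data generator

The generator emulates the study conditions at toy scale: by default
6 secreted families × 2 variants plus 3 contaminants; mature masses
uniform in 4–22 kDa (the published mass range); signal peptides built
as n/h/c regions that satisfy the heuristic; variants derived by
internal deletions (splicing-like); optional planted exact repeats
from a library of published-style units; contaminants with acidic
N-termini (no signal) and homology hits at E ≪ 1e−6. Transcripts are
reverse-translated with seeded uniform codon choice, 0–60 nt UTRs and
stop codons framing the CDS; a fraction of variant transcripts is
5′-truncated inside the signal (leaving ≥ 10 overlap residues so
variant completion can fire). PSM scores straddle the thresholds:
true peptides ~N(35, 8) truncated at 0 (with the first two
whole-extract spectra of each secreted protein guaranteed ≥ 20),
shuffled-decoy noise ~N(10, 5); protein scores ≥ 55 for secreted
proteins while a configurable fraction of contaminants also exceeds
50, so the homology filter — not the score gate — must remove them.
Gel-band samples only contain proteins whose mature mass falls in
6 ± 1.5, 7 ± 1.5 or 14 ± 3 kDa windows. All outputs are byte-stable
functions of (config, seed).

What the generator does **not** emulate: spectrum-level physics (m/z
peaks, retention time), assembly fragmentation beyond simple 5′
truncation, sequencing error, allelic variation, or realistic score
correlation structure. Passing recovery tests therefore demonstrates
the correctness of the pipeline's logic under the stated score model,
not search-engine performance on real spectra.

## Numerical and design choices

- Standard genetic code only; any codon containing N translates to
  `X`, and `X` never matches a peptide.
- ORF policy defaults to `keep_all` (segments between stops kept
  without requiring Met) because several byssal proteins were
  recovered without start codons; `require_start` is available.
- Minimum ORF length defaults to 30 aa (the smallest reported mature
  protein is ~40 aa; margin for fragments).
- I/L are equivalent in matching by default (MS cannot distinguish
  them); strict mode available. Peptides may match non-tryptic
  positions but are flagged.
- Protein score is the best upstream protein-level score; when absent
  it is recomputed as the sum of per-peptide best scores (documented
  fallback, not the upstream engine's method).
- Hydropathy window defaults to 9 (ProtScale default); block segments
  default to the terminal 15 residues unless explicit boundaries are
  given.
- Test problem sizes (transcript counts, PSM counts, seed counts) are
  kept at desk scale — every quantity checked is either exact integer
  counting or a deterministic formula, so scale adds nothing.

## Limitations

- Sequence-level matching only: mass tolerances are carried as
  metadata; no rescoring, no FDR estimation from decoys.
- The signal heuristic is intentionally simple and is wrong ~1 in 5
  times on real signal peptides; it exists so the pipeline can run
  without external predictions, not to replace them.
- Homology searching is not performed; hit tables are inputs, and the
  contaminant/allowlist split is user-supplied.
- Expression estimation, assembly, and spectrum processing are out of
  scope.
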