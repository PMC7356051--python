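# Methods

## Rule model

The package encodes the mammalian Arg/N-degron hierarchy as a residue →
class map plus enzymatic cascades. The default table assigns primary
type-1 = {R, K, H}, primary type-2 = {F, W, Y, L, I}, secondary = {D, E},
tertiary = {N, Q, C}; the stabilizing set {A, G, M, P, S, T, V} is the
complement of the destabilizing residues among the 20 canonical amino
acids (consistent with Val serving as the stable control in degradation
assays). Ambiguity codes (B, J, O, U, X, Z) classify UNKNOWN and are never
counted as destabilizing. Cascades exist exactly for secondary/tertiary
residues and terminate at Arg in at most two steps (N→D→R via NTAN1/ATE1,
Q→E→R via NTAQ1/ATE1, C→C*→R via oxidation/ATE1, D/E→R via ATE1); the
recognin-site map routes R/K/H and all arginylation-funnelled residues to
the type-1 UBR site and the bulky hydrophobics to the type-2 site. Tables
load from YAML so alternative degron grammars can be screened; the loader
validates the partition, cascade chaining and termination invariants.

Deliberate simplifications: N-terminal acetylation is not modelled (all
inputs are treated as nonacetylated; a per-site `acetylated` flag forces
UNKNOWN for sites known to escape the Arg branch), and the second N-degron
determinant — an accessible internal lysine — is not modelled at all, so
every "destabilizing" call is a candidate degron, not a degradation
prediction. MetAP initiator-Met excision uses the canonical
small-side-chain rule (second residue in A, C, G, P, S, T, V), exposed as
a configurable set because enzymatic specificity tables differ at the
margins.

## Coordinates, octamers, windows

All user-facing coordinates are 1-based and inclusive. A site is keyed by
its P1 position; cleavage occurs between P1 and P1′, and a fragment is
named by its first residue (the P1′ position), so fragment "Asn120" means
P1 = 119. The octamer covers positions P1−3..P1+4 and is '-'-padded where
it overhangs a terminus, keeping P1′ at string index 4. The context window
covers the octamer ± `flank` residues (default flank 26, i.e. a 60-residue
window with P1′ at offset 31 when complete); at the termini the window is
truncated, never padded, and the recorded offset tracks where P1′ actually
falls. Sites that leave no C-terminal fragment are per-site errors; a
screen never aborts on one bad row.

Fragment-level counting deduplicates alternative sites sharing a
`fragment_id` and classifies the fragment by its flagged primary site;
this is what makes the bundled panel count 14 fragments over 15 sites
(Ataxin-3: Glu245 primary, Leu249 alternative). The headline destabilizing
fraction uses classified (non-UNKNOWN) sites as its denominator.

## Alignment

Ortholog P1′ residues are located by optimal global alignment of the
reference window against each family member (three-state Gotoh). Scoring
is BLOSUM62 with gap magnitudes open 11 / extend 1 by default — the
protein-BLAST convention, chosen because homolog sets for this kind of
screen come from BLAST searches — with a gap run of k columns costing
open + k·extend. Letters outside the matrix alphabet score 0. Traceback
ties are broken with the fixed precedence diagonal > vertical (gap in the
query) > horizontal (gap in the reference), at the final cell and at every
step, so the reported alignment is bit-reproducible, not just its score.
The aligner is verified two independent ways: against exhaustive
enumeration of every global alignment for thousands of short pairs, and
against Biopython's `PairwiseAligner` scores under the same gap
convention. Two provable monotonicity properties are tested: raising the
extend penalty never increases the number of gap columns, and raising the
open penalty never increases the number of gap runs.

A member whose alignment places a gap in the P1′ column is missing data:
counted in `n_gap` and excluded from both conservation denominators. A
member that cannot be aligned at all is recorded as a gap with a warning.
When the reference P1′ is destabilizing, identity conservation ≤ property
conservation by construction.

## Synthetic data

The substrate generator emulates a protease-substrate screen: uniform
random sequences (length 80–300), one or more cut sites per substrate
placed uniformly over the flank-respecting range, and the P1′ residue
implanted from the destabilizing set with probability `p_destab`
(otherwise stabilizing), uniformly within the set unless a weight vector
is supplied. The default `p_destab = 0.21` and panel size of 125
substrates mirror the screen this package models (120+ substrates, 21%
destabilizing). The family generator is star-topology: each member derives
independently from the reference window via background substitutions
(uniform replacement at `sub_rate` per site — the simplest null adequate
for exercising alignment mapping), a P1′ column governed by
(`p1prime_sub_rate`, `p_property_preserving`), and indels of 1–2 residues
at `indel_rate` per position outside a protected ±3 zone around P1′, so
the truth label at the column is controlled solely by the P1′ model.
Property conservation therefore has the analytic expectation
(1−p) + p·q. All generators require an explicit seed and are
byte-reproducible; every generated object carries bookkept truth that the
pipeline must recover exactly (classes) or within 95% binomial CIs
(fractions, at 500 draws).

What the generators do not emulate: phylogenetic correlation among family
members (no tree, no rate variation), realistic residue composition or
cleavage-motif preferences, and real ortholog divergence profiles. Passing
recovery tests therefore demonstrates that the pipeline measures what was
implanted without bias — not that real ortholog panels behave like the
synthetic ones.

## The bundled panel

The panel stores the 14 proinflammatory fragments (9 caspase-1-generated:
the caspase-1/-4/-5 self-cleavage fragments, Rab39a, IL-18, CCL3,
Ataxin-3, hnRNPA2/B1, Matrin-3; plus granzymes A/M/K via DPP1 and
IL-36β/γ via proteinase-3) with their reported P1′ residues and positions.
Full substrate sequences are not deposited with such fragment lists, so
the context is deterministic synthetic filler (stabilizing residues, Asp
implanted at P1 for caspase sites) flagged non-biological in every record;
no count depends on it. Two reported-position discrepancies are resolved in
favour of the primary listing and noted on the records: CASP5 Gln138 (vs
137 elsewhere) and RAB39a Cys149 (vs 144 elsewhere). The panel's ortholog
families are generated (seeded) to emulate the reported conservation
behaviour — P1′ substitutions rare and always property-preserving — and
are clearly a model of that claim, not species data.

## Numerical and design choices

- Output ordering is always deterministic: sites by (substrate_id,
  p1_position), families by family_id; fractions print at 6 significant
  digits. Writers are atomic (temp file + rename).
- The 21%-fraction and conservation recovery checks run at 500 draws —
  large enough for a ±3.6-percentage-point binomial CI at p = 0.21, small
  enough to keep the default suite fast.
- The live substrate-database retrieval behind "120+ substrates, 21%"
  is out of scope (version-dependent, network-dependent); the synthetic
  screen at the same scale is the in-repo substitute.
- The alignment brute-force oracle sweep covers all pairs of length ≤ 3
  over a 4-letter alphabet exhaustively plus seeded random pairs of
  lengths 4–6; longer pairs are checked against Biopython instead because
  enumeration grows exponentially.

## Known limitations

Candidate N-degrons only (no internal-lysine, ubiquitylation or
proteasome modelling); no cleavage-site prediction (sites are inputs); no
multiple sequence alignment or phylogenetics; single-residue indel model;
the panel's sequence context is synthetic. UNKNOWN-heavy inputs shrink the
classified denominator and widen the effective uncertainty of the reported
fractions.
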