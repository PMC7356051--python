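# ndegron

Arg/N-degron annotation of protease-generated neo-N-termini, with ortholog
conservation screening of the P1′ position.

## The problem

Inflammatory proteases (caspase-1/-4/-5, granzyme-processing DPP1,
proteinase-3) cleave their targets irreversibly; the proinflammatory
fragments they release must be sequestered or degraded for inflammation to
resolve. The Arg/N-degron pathway degrades proteins whose N-terminal
residue is *destabilizing*: primary type-1 residues (Arg, Lys, His) and
type-2 residues (Phe, Trp, Tyr, Leu, Ile) are bound directly by UBR-family
N-recognins; secondary residues (Asp, Glu) require ATE1 arginylation; and
tertiary residues (Asn, Gln, Cys) are first deamidated (NTAN1, NTAQ1) or
oxidized before arginylation:

```
N --NTAN1--> D --ATE1--> R        Q --NTAQ1--> E --ATE1--> R
C --oxidation--> C* --ATE1--> R   D/E --ATE1--> R
```

A cleavage between P1 and P1′ exposes the P1′ residue as the fragment's new
N-terminus, so whether a protease-generated fragment is short-lived can be
read off the cleavage site. This package turns that reading into a tested
pipeline: it classifies P1′ residues under a configurable rule table,
extracts P4–P4′ octamers and 60-residue context windows, screens substrate
tables for candidate N-degron fragments, and quantifies — by global
pairwise alignment of the context window against ortholog sequences — how
well the *destabilizing property* (not necessarily the residue identity) of
the P1′ position is conserved:

- identity conservation = fraction of non-gap orthologs whose P1′ equals
  the reference residue;
- property conservation = fraction whose P1′ is destabilizing at all.

A bundled panel holds the 14 proinflammatory fragments with candidate
N-degrons (9 generated by caspase-1 activity, including the self-cleavage
fragments of caspases-1/-4/-5, and 5 by other endopeptidases), over 15
sites — Ataxin-3 carries two alternative sites releasing one fragment. The
panel's sequence context is synthetic non-biological filler around the
reported P1′ residues; classification depends only on P1′. A seeded
synthetic-data module generates substrate screens with a controlled
destabilizing fraction and star-topology ortholog families with controlled
P1′ substitution behaviour, so every stage is testable against exact
ground truth without database downloads.

## Worked example

```
$ ndegron classify N
id      residue class   destabilizing   recognin_site   cascade
N       N       TERTIARY        true    TYPE1_SITE      NTAN1:N>D;ATE1:D>R
```

Asn is a tertiary destabilizing residue: deamidated by NTAN1 to Asp, then
arginylated by ATE1 to Arg, which the type-1 UBR site recognizes.

Screening the bundled fragment panel end to end:

```
$ ndegron fixture --out fx
$ ndegron scan --substrates fx/panel_substrates.fasta \
               --sites fx/panel_sites.tsv --out scan_out
15 sites, 14 fragments, 14 fragments with destabilizing P1' (fraction of classified sites: 1)
```

All 15 sites classify as destabilizing (none UNKNOWN), giving 14 candidate
short-lived fragments; restricting to the caspase-1 sites gives 9.
`scan_out/annotations.tsv` holds the per-site classes, cascades and context
windows; `scan_out/summary.json` the counts. The drivers under `analysis/`
run the same screens as scripts (panel screen, conservation screen,
parameter recovery) and write their tables under `results/`; the
conservation screen reports 14/14 families with property conservation 1.0,
several of them with P1′ identity drift — the destabilizing property is
what the emulated evolution preserves.

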