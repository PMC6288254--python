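# Methods

## Fixture gene models

Each fixture allele is a synthetic single-strand (plus-strand) genomic
sequence with nine exons and canonical GT..AG introns, laid out in the KIR
architecture: exons 1–2 leader peptide, exons 3–5 the Ig-like domains
D0/D1/D2, exon 6 stem, exon 7 transmembrane region, exons 8–9 cytoplasmic
tail.  Exon sizes follow the sizes implied by the published event repertoire:

| element | size (bp) | note |
|---|---|---|
| exon 4 | 300 | so exons 4+5 = 594 |
| exon 5 | 294 | 287 in Mamu-KIR1D (7-bp gDNA deletion) |
| exon 6 | 51 | |
| exon 7 | 104 / 105 | 9A vs 10A KIR2DL4 alleles; 101 in macaque lineage II |
| exon 8 | 53 | KIR2DL4 / Mamu-KIR2DL04 |
| exons 1, 2, 3, 9 | 34, 36, 300, 300 | fixture choices (not printed anywhere); exon 3 exceeds the 198-bp alternative-donor deletion it must host |
| introns | 600 | default; lineage-II macaque introns 5/6 = 2000/914, Mamu-KIR1D introns 5/6 = 3290/4330, Mamu-KIR3DL20 intron 3 = 100, Mamu-KIR2DL04 intron 8 = 98/99 by allele |

Because the human fixture introns are kept at the desk-scale default of
600 bp, intra-intron feature offsets quoted for the real genes (cryptic exons
~837 bp into intron 5 and ~1426 bp into intron 6) are compressed to 250 bp in
the human fixtures; Mamu-KIR1D keeps its published intron sizes and the
1426-bp cryptic-exon offset.

Background sequence is seeded-random at ~40% GC.  Splice elements are stamped
deterministically: donor hexamers (`GTAAGT`, or the frame-safe weakened
variant `GTACGT` where an intron start can end up inside mature mRNA and for
the deliberately suboptimal KIR2DL4-like exon-7 donors), an acceptor tail
`TTTCAG`, a YUNAY-conformant branch point `CTCAC` 30 bp upstream of each
acceptor, a 14-nt polypyrimidine tract (with the two adenine interruptions
characteristic of the KIR2DL4/KIR3DL2 exon-7 acceptor where configured), the
33-bp purine element in intron 2 of every non-lineage-III gene, `AG`/`GT`
boundary motifs at every annotated alternative splice site and cryptic exon,
and the poly-adenine run (9 or 10 A) ending KIR2DL4 exon 7.

### Deterministic reading-frame control

Two construction rules make ORF consequences reproducible for *every* seed,
not just a lucky one:

* All background positions that can appear in mature mRNA (exons, inclusion
  regions, retainable introns) are sampled **stop-free in all three frames**:
  at each position the sampler excludes any base that would complete
  TAA/TAG/TGA in any frame.  A stop codon therefore exists only where the
  builder placed one.
* Premature termination of frameshifted transcripts is guaranteed by **PTC
  traps** — the 9-mer `ATAAATAAA`, which reads Ile-Asn-Lys in the designed
  frame but contains TAA in both shifted frames — stamped at the first codon
  boundary of exons 8 and 9 (also exon 7 for Mamu-KIR1D).  Inclusions whose
  annotated consequence is "stopcodon introduced" additionally carry a TAA at
  their first in-reading-frame codon.

Each allele carries a *designed ORF grid*: the reading-frame phase of every
exon on a reference layout (the 10A layout for the 9A KIR2DL4 allele, whose
genome then has one fewer adenine; the exon-5-less layout for Mamu-KIR1D,
whose constitutive transcript is therefore itself PTC-bearing).  Chimeric
codons at novel junctions can still create a stop by chance, so the builder
finally verifies every isoform declared in the catalog with a direct codon
scan and, on violation, re-samples the background with a seed-derived attempt
counter (bounded at 64; in practice 0–4 attempts).  Construction is fully
deterministic for a given seed.

## Cohort simulation

Reads are error-free, full-length transcripts (circular-consensus amplicons
are the emulated technology; a substitution-error rate and a truncation
fraction exist as options for robustness experiments and default to 0).
Individual identity travels in the read header, standing in for barcode
demultiplexing.  Per-isoform read counts are fixed integers from the config —
confirmation counts must be exact — with family structure (founder/offspring
links) carried alongside for pedigree checks.  The built-in cohorts inject
every event of the human (18 rows) and macaque (29 rows) repertoires into two
individuals at two reads each (4 supporting reads ≥ the 3-read threshold)
plus three decoy events at one individual × two reads (below both
thresholds), and the Mamu-KIR1D cohort realises nineteen distinct isoform
structures, fifteen of them in one individual at three reads each.

What the generator does **not** emulate: sequencing error profiles, chimeric
molecules, barcode chemistry, amplification bias, or expression-level
variation.  Green tests therefore demonstrate the correctness of the
assignment/classification/confirmation logic on structurally faithful reads,
not robustness to raw instrument error.

## Assignment

Pass 1 compares reads to known allele transcripts: zero mismatches, unique
candidate (ambiguity cap 1), equality or containment with ≥ 400 nt overlap.
A mapper's mapping-quality filter has no analogue for exact in-memory
comparison and is replaced by the uniqueness rule.  Pass 2 aligns leftover
reads to genomic models: exact k-mer anchors (k = 21, collision-safe in
≤ 15 kb genes), merged along diagonals into maximal exact blocks, chained by
an O(B²) DP maximising read coverage; accepted when read coverage ≥ 100 nt
and ≥ 80% of the read, zero within-block mismatches, and at most 10 novel
junctions (junctions matching annotated intron excisions are free).  Reads go
to the single best gene by covered length; ties are left unassigned as
ambiguous.

Junctions in repeated sequence admit several equivalent placements; the
aligner snaps them onto annotated exon boundaries when the ambiguity interval
allows (preferring both-edge, then donor-edge, then acceptor-edge matches)
and left-normalizes otherwise, recording the ambiguity range (this preserves
the "X/Y bp" dual-size reporting convention for twin events such as the
98/99-bp intron-8 retention).  Canonical event ids are defined on normalized
chains.  On models ≤ 3 kb the chain is verified in tests against an
independent affine-gap dynamic-programming alignment oracle.

## Event classification and confirmation

Raw edits (absent exons, boundary shifts, novel intronic blocks, retained
introns) are grouped per junction and merged: consecutive absences form one
skipping event; an absence adjacent to a boundary shift merges into a
skip-plus-alternative-splice-site event; paired donor+acceptor shifts form a
single alt-both event (across two exons or within one).  The contiguity rule
separates alternative-splice-site inclusions (novel sequence abutting the
annotated exon) from cryptic exons (spliced gaps on both sides).  Novel
junction dinucleotides are annotated, never filtered.  Exons absent at the
gDNA level (Mamu-KIR1D exon 3, attributable to the missing intron-2 purine
element) are excluded from skipping calls via a model attribute.

Confirmation defaults to cohort-wide ≥ 3 supporting reads in ≥ 2 individuals.
The wording of the underlying rule is ambiguous about whether the read count
is per individual; both interpretations are implemented
(``per_individual=True``) and the cohort-wide reading is the documented
default.  The ``high_coverage`` preset (≥ 10 reads OR ≥ 2 individuals)
matches the relaxed rule used for deeply sequenced samples.  Isoform
inventories count distinct (gene, ordered-event-set) structures per
individual at ≥ 3 reads in that individual; the constitutive structure counts
as one (for Mamu-KIR1D even the "constitutive" transcript is an isoform of
interest, since its full-length exon 5 is frame-breaking).

## ORF annotation

Translation starts at the annotated initiator (ATG at exon-1 start).  Frame
status comes from phase arithmetic against the designed ORF grid; the stop
codon itself from a direct scan (the two paths are cross-checked in tests on
every fixture isoform).  A premature stop with non-zero local shift is a
frameshift; with zero shift, a direct stop introduced by novel sequence.
In-frame isoforms of PTC-bearing alleles are labelled ``restored_orf``.
Domain segments are those whose exon bases are read in frame upstream of the
stop; inserted residues are insert bases upstream of the stop divided by 3
(78-bp cryptic exon → 26, 99-bp retention → 33).  The NMD hint (stop > 50 nt
upstream of the last junction) annotates and never filters.  One deliberate
asymmetry follows the source tables rather than a single rule: out-of-frame
transcripts missing the transmembrane exon are still labelled "possible
soluble receptor".

## Splice-signal scoring

Log-odds position weight matrices with pseudocount 1 against a uniform
background, trained on the constitutive site windows of the fixture models
(a loader for user-supplied site FASTA exists).  The consensus value rescales
the raw score to 0–100 between the per-position minimum and maximum.  Donor
windows are 3 exonic + 6 intronic nt; the acceptor region is the last 20
intronic + first 3 exonic nt.  Scores carry no absolute threshold — they are
used only to rank related sites, e.g. the weakened KIR2DL4-like exon-7 donor
below the lineage-III consensus.  Branch-point search takes the best YUNAY
match (≥ 4/5 positions) in −50..−15, ties broken toward the acceptor.

## Problem sizes and runtime

All analyses are desk-scale by design: 6 human and 11 macaque fixture alleles
(6–13 kb genomes), cohorts of 63–302 reads, single-read worked examples of
0.9–1.6 kb.  The full test suite runs in well under a minute; the acceptance
script in ~10 s.

## Known limitations

* Fixture sequences are synthetic; nothing here claims nucleotide-level
  fidelity to real KIR alleles, and quantities that depend on the real cohort
  (read fractions per gene, the KIR2DL5 similarity) are out of scope.
* The matcher assumes collinear reads (no chimeras or fusions) and exact
  anchors, i.e. it is tuned for consensus-accuracy reads.
* The 9A/10A poly-adenine logic is realised at the sequence level (9 vs 10
  adenines on a shared design grid) rather than via an attribute switch, so
  the frame consequences are computed, not asserted.
* Only the plus strand is modelled; amplicon transcripts are single-stranded
  cDNA.
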