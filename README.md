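# genedecay

Tools for studying **gene pseudogenization** across species: detecting
gene-disrupting lesions in coding and genomic sequences, counting and
dating independent loss events on a phylogeny, and quantifying
conservation and relaxation of selection. The package was built around
the comparative biology of *PCSK9* — a cholesterol-homeostasis gene kept
under strong purifying selection in some placental-mammal clades while
being repeatedly and independently lost in others — but every stage is
generic over a reference gene model.

It is aimed at molecular evolutionary biologists who assemble ortholog
and pseudogene sequences across a clade and want a reproducible,
scriptable version of the usual desk analysis: call the inactivating
lesions, decide functional / pseudogene / uncertain per species, match
shared lesions across species, bracket when each loss happened, and test
whether selection is relaxed where the gene survives.

## The methods at the core

**Lesion calling.** A query CDS is globally aligned to the reference
(affine gaps, frame-aware bookkeeping). Alterations are classified by
functional impact: premature stop codons before a late-truncation
threshold (residue 681 for PCSK9), frameshifting indels, exon-scale or
whole-gene deletions, splice-site disruptions, start-codon loss and
substitutions of the residues required for autocatalytic maturation
(catalytic triad D186/H226/S386 plus the oxyanion-hole N317) are *hard*
(inactivating); conserved structural cysteine substitutions are *soft*
(suspicious only); in-frame indels and late truncations are *neutral*.
A species is a pseudogene iff it carries a hard lesion; lesion-free,
near-complete (>85%) sequences are functional; low-coverage (<40%)
sequences are excluded as unclassifiable.

**Loss counting and dating.** Gene loss is a Dollo character — losable
any number of times, never regained — so the minimum number of
independent losses is exact: an internal node retains the gene iff any
descendant tip does, and every retained→lost edge is one event. Each
event's age is bracketed by the crown age of the losing clade (minimum)
and its split from the nearest gene-retaining lineage (maximum); shared
lesions with identical alleles at matching coordinates place the event
on the branch above the sharing tips.

**Selection intensity.** On codon alignments the package fits a
Goldman–Yang-style model (61 sense codons, κ, F3x4 frequencies) with one
ω per branch partition and a selection-intensity parameter K linking
them:

    omega_test = omega_reference ** K

K < 1 flattens ω toward 1 (relaxed selection), K > 1 sharpens it
(intensification). The null (K = 1) and alternative (K free) are
compared by a likelihood-ratio test against χ²(1). Nei–Gojobori (1986)
counting with Jukes–Cantor correction is included as a model-free
cross-check. A fully seeded simulator generates codon cohorts with loss
events, frameshifts, nonsense mutations and deletions — with a complete
truth table — so every stage is testable without any downloads.

## Worked example

Simulate a six-species cohort in which the clade `{T3, T4, T5}` loses
the gene, then scan the tips against the simulated ancestral CDS:

```bash
genedecay simulate --seed 11 --n-tips 6 --n-codons 300 \
    --loss 'T3|T4|T5' --out sim
genedecay scan --query sim/tips_cds.fasta --ref sim/root_cds.fasta \
    --out scan
```

`scan/status.tsv`:

```
species status     coverage n_hard n_soft reason
T5      pseudogene 1.0      1      0      1 inactivating lesion(s)
T3      pseudogene 1.0      1      0      1 inactivating lesion(s)
T4      pseudogene 1.0      1      0      1 inactivating lesion(s)
T6      functional 1.0      0      0
T1      functional 1.0      0      0
T2      functional 1.0      0      0
```

The single hard lesion is a premature stop (`TGA@183`, reference bases
547–549) planted by the simulator on the ancestral loss branch
`T3|T4|T5` — the scanner recovers it at exactly the planted coordinates
in each descendant, which is the shared-lesion signature the dating
stage uses.

Counting losses on the two competing Eulipotyphla family arrangements
(bundled, transcribed from the literature) with Talpidae retaining the
gene and the other families having lost it:

```bash
genedecay date-losses \
    --tree src/genedecay/data/eulipotyphla_solenodontidae_basal.nwk \
    --tree src/genedecay/data/eulipotyphla_talpidae_soricidae.nwk \
    --states states.tsv --out losses
```

`losses/loss_counts.tsv` reports **2** independent losses with
Solenodontidae basal and **3** with Talpidae–Soricidae as sisters, and
`loss_events.tsv` brackets each event (e.g. the Soricidae+Erinaceidae
loss between 50 and 60 My under the first topology).

Other subcommands: `archaeology` (exon presence, splice integrity and
deletion breakpoints on genomic loci), `conserve` (reference-anchored
identity profile per domain), `relax` (the K test) and `run` (the whole
pipeline on a cohort FASTA).

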