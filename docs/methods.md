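# Methods

This note documents the models, conventions and numerical choices behind
`genedecay`, and what the synthetic-data experiments do and do not show.

## Reference gene model and coordinates

All coordinates are expressed against one canonical reference gene model
(for PCSK9: the 692-residue human protein; 2079 coding bp including the
stop; 12 exons). Internally coordinates are 0-based half-open;
everything read from or written to files (GFF3, report tables) is
1-based inclusive. Minus-strand loci are reverse-complemented on ingest
so all downstream logic sees plus orientation. Species positions are
mapped into the canonical frame by pairwise alignment to the reference,
the convention the comparative literature uses when it names residues
like N317 or Cys562 across species.

The bundled reference (`src/genedecay/data/pcsk9_reference_synthetic.*`)
is a **synthetic stand-in**, generated by
`scripts/build_reference_bundle.py`: the protein has the canonical key
residues at their published human positions (triad D186/H226/S386,
oxyanion N317, 25 catalytic+C-terminal cysteines of which 18 are
V-domain, including C562, C588, C600, C601, C608, C635, C654, C679), a
2079-bp CDS split over 12 exons with canonical GT/AG introns and
intergenic flanks, but the filler sequence and the per-exon base counts
are constructed, not copied from the human genome. Domain limits follow
the standard human annotation: signal peptide 1–30, prodomain 31–152,
catalytic 153–452, V-domain 453–682, C-terminal tail 683–692; the
conservation analysis region defaults to residues 31–692 (outside the
signal peptide).

## Lesion calling

Queries are aligned globally with affine gap costs (match +2, mismatch
−3, gap open −8, extend −1; configurable). Two refinements matter for
reproducible lesion coordinates:

* **Free terminal query gaps.** A query shorter than the reference is
  treated as incomplete data, not as a terminal deletion; coverage, not
  lesion lists, reflects missing sequence.
* **Slip-pair collapse.** In homopolymer-rich regions an affine-gap
  aligner sometimes explains a run of substitutions as a short deletion
  plus a nearby equal-length insertion. Such equal-length opposite gap
  pairs (each ≤3 bp, ≤15 gap-free columns apart) are re-paired base to
  base; without this, pure substitution processes would occasionally
  yield fabricated frameshift calls.

Stops and residue substitutions are read off **aligned triplets**: the
query bases aligned to the three bases of each reference codon,
including downstream of a frameshift. This is how pseudogene alignments
are read in practice (a stop codon visible in the alignment is reported
even though the shifted ribosomal frame differs), and it makes calls
robust to upstream indels; the frameshift itself is always separately
reported as a hard lesion.

Severity encodes the functional interpretation defended in the PCSK9
literature: premature stops before residue 681, frameshifts, exon-scale
and whole-gene deletions, splice disruptions, start loss, and
triad/N317 substitutions are inactivating (*hard*) because catalytically
dead PCSK9 is not secreted; truncations at 681 or later are neutral
(the extreme C-terminus is unstructured and dispensable); in-frame
indels are neutral on their own (ancient shared in-frame indels occur in
clades with fully functional, expressed genes); conserved-cysteine
substitutions are *soft* — suspicious but tolerated in lineages (e.g.
gerbils with C588 changes) that keep expressing the gene under
undiminished selection. C608 is kept soft as well; the evidence on
whether all changes there are tolerated is equivocal, and a soft call
leaves the species "uncertain" rather than forcing either conclusion.
Compensated frameshift pairs restoring the frame are annotated
`frame_restored` but stay hard, matching the treatment of overlapping
1-bp/2-bp deletions in tenrecs as inactivating.

Status thresholds: coverage <40% → excluded ("uncertain: insufficient
coverage"); lesion-free but <85% complete → uncertain; hard lesion →
pseudogene; soft-only → uncertain.

## Locus archaeology

Degraded loci are compared to the intact reference locus by seeded
gap-free alignment: exact 11-mer anchors (reference k-mers occurring >4
times are skipped) merged along diagonals, chained co-linearly by a
quadratic DP maximizing anchored reference coverage, and extended
through isolated substitutions with an x-drop rule (+1 match, −2
mismatch, stop at 6 below the running best). Near-co-diagonal neighbour
blocks (≤30 bp apart, diagonal jitter ≤15 bp) are merged so small
indels do not fragment the chain.

* **Exon presence**: an exon is *present* when ≥80% of its length is
  covered by chained blocks, *partial* between 20% and 80%, *absent*
  below; percent identity is computed over the covered positions.
  Orientation is auto-detected by chaining both strands.
* **Breakpoints**: a reference gap between adjacent chain blocks (net
  ≥30 bp after subtracting any query-side gap) is a deletion
  breakpoint. Because junctions flanked by microhomology can slide, each
  anchor carries an ambiguity interval (how far the junction can move
  left/right through identical flanking bases); two species share a
  breakpoint when their intervals overlap on both anchors. On planted
  deletions with up to 2% background divergence, anchors localize within
  ±5 bp.
* **Splice sites**: donor (GT) and acceptor (AG) dinucleotides are read
  off the query anchored at the aligned exon edge — the intron bases
  themselves are often unalignable precisely because they are mutated.
  A disrupted acceptor triggers a scan ≤100 bp upstream for a rescuing
  cryptic AG, reporting the implied 5′ exon extension (the pig-style
  39-bp extension of exon 4 is the template for this behaviour). A
  missing flank yields "unknown", never "disrupted".

## Loss phylogenetics

Tip states map from scan statuses: pseudogene → lost, functional →
retained; uncertain tips are excluded by default (they carry no signal
either way) with an option to force either state. Dollo parsimony then
gives the exact minimum: a node is retained iff any descendant tip is,
losses are retained→lost edges. If every considered tip is lost the
single event is placed on the stem above the root with both ages at the
root age — the data cannot see further back. The implementation is
checked against exhaustive enumeration over all irreversible internal
assignments on hundreds of random ≤12-tip trees.

Lesion matching across species is exact on kind and allele with ±2 bp
coordinate tolerance (absorbing alignment jitter at homopolymers); each
lesion joins at most one group, anchored to the group's first member.
Dating: min age = crown age of the evidence-sharing tips' MRCA (0 for a
singleton), max age = age of that branch's parent node. A group whose
MRCA subtends a gene-retaining tip is rejected with a homoplasy
diagnostic rather than dated.

The bundled order-level trees (`src/genedecay/data/*.nwk`) transcribe
the recently advocated Laurasiatheria arrangements at the granularity
the loss counts need (Eulipotyphla at family level, Cetartiodactyla at
sub-clade level). Node ages not pinned by a published split date
(Whippomorpha–Ruminantia ≈70 My, Ruminantia crown ≈52 My, crown
Noctilionoidea ≈49 My) are plausible interpolations; the Dollo counts
depend only on topology, and the dated windows only on the pinned nodes.
The per-clade loss-range table sums to a 7–10 total across scenarios;
the low end matches the published "at least" reasoning and the high end
is the arithmetic maximum of the per-clade ranges, which the module
reports rather than collapsing to one number.

## Conservation and selection

The reference-anchored MSA maps every species to canonical residue
columns via its pairwise codon-aware alignment; insertion columns
carried by ≤10% of species are removed and logged, more widely shared
in-frame insertions become explicit extra columns. Identity is the mean
over unordered sequence pairs of the equal-residue indicator with
pairwise deletion; columns gapped in >50% of species are excluded from
domain summaries; domain means average columns first (column-first
weighting is a documented choice; species-pair-first weighting is the
alternative). The completely-conserved fraction counts columns with a
single residue state among present sequences.

The codon model is Goldman–Yang-style on the 61 sense codons:
single-nucleotide exchanges at rate κ^[transition]·ω^[nonsynonymous]·π_j
with F3x4 frequencies estimated from the analysed alignment (floored at
1e-6 for irreducibility), normalized to one expected substitution per
codon per branch-length unit. The generator is reversible, so P(t) is
computed by symmetric eigendecomposition (verified against
`scipy.linalg.expm` to <1e-10 and against exhaustive state summation on
4-tip trees). Likelihoods use Felsenstein pruning with site-pattern
compression and per-node rescaling; codons containing gaps or N are
missing data (all-ones partials).

The relaxation test shares κ, π and one branch-length scale factor
across partitions, fits ω_ref on reference branches and ω_test =
ω_ref^K on test branches, and compares K=1 against K free by LRT with
χ²(1). Simplifications relative to the published selection-intensity
framework, made deliberately: a single ω per partition instead of a
three-category ω distribution, and input branch lengths rescaled by one
free factor instead of per-branch optimization. Exact K parity with the
published tool is therefore not expected; the direction of K and the
test's significance are the comparable outputs, and the simulation
calibration (below) shows both behave correctly under the model.

Numerical choices for the fit: κ, ω_ref and the scale are optimized in
log space with L-BFGS-B (ftol 1e-6); K is optimized in **linear** space
because its likelihood gradient in log space vanishes proportionally to
K and strands fits at the lower bound (K is clamped to [0.001, 50]). A
coarse grid scan over the branch scale (6 points) seeds the null fit —
without it, single-start fits on trees whose lengths are in different
units than substitutions can stall in distant local optima and inflate
the LRT — and a coarse K profile from the null optimum (6 points) seeds
the alternative. The default is 3 fixed restarts; replicate loops in the
validation suite use one start with these data-driven initializations,
which the type-I calibration shows is sufficient.

## Synthetic data: what it emulates

The generator evolves codon states along a tree by sampling from the
matrix exponential of the same generator used in fitting (separately
validated against its own transition probabilities at 3-standard-error
tolerance). A loss branch switches from the background model (default
ω=0.1, κ=2) to a post-loss model (default ω=1) at a time drawn uniformly
along the branch; descendant branches are fully post-loss. Decay lesions
are planted on post-loss lineage segments: frameshifting indels
(2×10⁻⁵ events/coding-bp/My; 1–2 bp with probability 0.8, else 3n
in-frame), nonsense substitutions (2×10⁻⁴ events/codon/My) and,
optionally, exon-scale deletions. Every lesion is recorded with its
originating branch, inherited by all descendants, and survives at a tip
unless overwritten by a larger deletion. The start codon is treated as
invariant. Branch lengths are My on chronograms with a substitution
scale of 0.005 substitutions/codon/My — a conservative, realistic
divergence for a constrained mammalian gene over tens of My; the decay
rates give a lost lineage a handful of hard lesions over ~30 My of
neutral time, matching the "widespread accumulation of inactivating
alterations" regime that motivates the pipeline.

Deliberate simplifications: substitutions are simulated at codon level
first and indels applied afterwards in reference coordinates (so a
planted lesion's coordinates are exact by construction); there is no
rate heterogeneity across sites, no CpG effect, no sequencing error or
assembly gaps, and locus-level background divergence is modelled as
independent substitutions. Passing the synthetic validation therefore
demonstrates correctness of the inference machinery under the model it
assumes — not robustness to alignment error, annotation error or
assembly artifacts in real data, which the thresholds (coverage bounds,
±2 bp matching tolerance, ambiguity intervals) only partially address.

## Validation summary (recomputed by `scripts/acceptance.py`)

* Dollo counts equal brute-force enumeration on 200 random ≤12-tip
  trees; the transcribed topologies give ≥3 Laurasiatheria losses under
  every arrangement and 2 vs 3 in Eulipotyphla by family arrangement.
* Pruning equals exhaustive internal-state summation on 4-tip trees to
  ~1e-13 log-likelihood units.
* Planted nonsense substitutions are recovered at exact coordinates;
  planted hard lesions are recovered at ≥95% recall (±2 bp) under the
  full decay process; planted deletion breakpoints localize within
  ±5 bp.
* The K test's empirical type-I error at nominal 0.05 stays ≤0.10 over
  50 null replicates, and K̂<1 in ≥90% of relaxed replicates simulated
  at true K=0.2 (500 codons, 12 tips), with median K̂ near the truth.

Problem sizes (500 codons, 12 tips, 50/20 replicates) are chosen to make
the full validation run in about a minute while leaving the statistical
assertions comfortably powered.

## Known limitations

* The lesion scanner works in CDS space; promoter/UTR lesions are out of
  scope except as part of whole-gene deletions seen by the archaeology
  stage.
* Inversions are only flagged as reversed-orientation hit chains, not
  fine-mapped.
* The selection test's single-ω partitions cannot represent within-
  partition ω variation; strongly heterogeneous reference sets will
  bias K.
* Identity summaries are column-first and unweighted by phylogeny;
  closely related over-sampled species inflate apparent conservation.
* Chronogram handling assumes the input tree is dated (ultrametric or
  with a node-age table); no dating is inferred.
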