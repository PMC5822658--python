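# Methods

This note documents the models, conventions and numerical choices behind
`teratornscan`, and what the synthetic-data experiments do and do not
demonstrate about real assemblies.

## The detection model

The pipeline treats an endogenous herpesvirus element as a contiguous
genomic region carrying translated-homology hits to a fixed query set: the
13 alloherpesvirus core genes (DNA polymerase `pol`, helicase `hel`,
primase `pri`, major capsid protein `mcp`, capsid triplex `tri`, membrane
glycoprotein `mem`, terminase `ter`, protease `pro`, and ORFs 37, 54, 56,
60, 64) plus two accessory ORFs (34, 44) and the *piggyBac*-like
transposase. Three thresholds define a detection: hits are significant at
E-value < 10⁻³; hits within 60 kb of one another (gap measured between hit
envelopes, boundary inclusive) belong to one locus; and an assembly is
positive when at least 8 of the 13 core genes have a significant hit. The
≥ 8 reading (rather than a strict > 8) is deliberate: it keeps assemblies
with exactly 8 detected core genes among the positives, consistent with
the published species tally. Loci are extracted with 40-kb flanks, clipped
at contig ends.

## Translated search

The search is a compact tblastn analogue. Each contig is translated in all
six frames (ambiguous codons → X; coordinates map back to forward-strand
base pairs). Seeding uses exact 4-mer amino-acid words — no neighborhood
words — followed by a vectorized ±12-residue diagonal prefilter, an exact
ungapped X-drop extension (X = 20), and finally gapped local alignment of
the full query against a window around the surviving seed (BLOSUM62, gap
open −11, extend −1, a gap of length L costing open + (L−1)·extend).
E-values use the ungapped Karlin–Altschul parameters for BLOSUM62
(λ = 0.3176, K = 0.134) applied to gapped scores — a knowing
approximation; E-values serve only for thresholding, and the threshold
behavior is what the tests pin down. Overlapping same-frame hits collapse
to the best-scoring one. On ≤ 2 kb × ≤ 100 aa instances the best hit's raw
score equals full Smith–Waterman (checked against an independent DP oracle
in the test suite); sensitivity loss from one-hit 4-mer seeding is
acceptable because the targets are planted, high-identity elements.
Exact score parity with NCBI BLAST is not attempted.

## Divergence and dN/dS

Pairwise identity and distances use pairwise deletion: a column counts
only when both rows carry an unambiguous nucleotide. The K2P distance is
d = −½·ln((1−2P−Q)·√(1−2Q)) with transition/transversion difference
fractions P and Q; arguments outside the model's domain raise a saturation
error rather than returning NaN. The modified Nei–Gojobori estimator
weights transitions R = 2 relative to transversions in synonymous-site
counting (changes producing stops count as nonsynonymous), averages
difference counts equally over minimal mutational pathways (orderings
through stop codons are discarded unless unavoidable), and Jukes–Cantor
corrects pN and pS. dS = 0 yields an explicitly flagged undefined ratio,
never infinity. Needleman–Wunsch global alignment (affine gaps) backs
gene-scale alignment; its optimal score is tie-independent and the
implementation's deterministic tie-breaking is the aligner's canonical
order. For long element copies (> 2 kb) subtype identities come from
banded edit distance (edlib), identity = 1 − distance/mean length; for the
substitution-dominated copies the simulator produces, this equals the
gap-excluded identity of a full alignment at a fraction of the cost.

## Subtypes and copy number

Copies with pairwise identity strictly above 0.90 join one subtype via
single-linkage — the weakest assumption consistent with a pairwise
threshold rule; chained triples therefore merge, which is documented
behavior. The representative is the longest ungapped member (ties broken
lexicographically). A non-fatal check warns when within-subtype pairs fall
below 0.95 identity.

Copy number assumes depth proportional to copy count. Known copies are
replaced by N-runs and one reference per subtype is appended, so reads
from all copies of a subtype collapse onto a single close target; mapping
to a single distant ancestor instead loses diverged-subtype reads and
underestimates. The internal mapper is exact-seed (21-mers at five anchor
offsets, both strands) plus full-read Hamming verification (≤ 8
mismatches), ties broken uniformly at random under the run seed. Copy
number is the pooled mean depth over all viral CDS bases divided by the
pooled mean over host CDS bases — the grand mean rather than a mean of
per-gene means, chosen as the variance-minimizing reading of "average
coverage" — summed over subtype references for a species total. A
bootstrap CI (resampling genes within each class) is an extension beyond
the point estimates the procedure originally reported.

## Annotation

ORFs are maximal ATG-to-stop spans (first ATG after the previous stop,
terminal stop required, ≥ 100 aa by default). A gene is intact when an ORF
on the hit's strand overlapping its best hit reaches ≥ 0.8 of the expected
protein length — 0.8 is a declared operationalization of "degraded", and
both midpoint premature stops and 1-bp frameshifts fall well below it.
Element verdicts: intact (all genes), degraded (none), partially degraded
otherwise. TIR detection scans all inverted-repeat pairs (10–40 bp, ≤ 1
mismatch) with the left repeat starting and the right repeat ending within
a window just beyond the outermost gene hits (spacer + maximal TIR + 20
bp); longest wins, then fewest mismatches, then leftmost. Because
revcomp(TTAA) = TTAA, a detected repeat tends to absorb the flanking
target-site duplications; the pipeline therefore probes inward boundary
shifts for the canonical TTAA duplication and, on success, trims the
reported repeat back to the TSD-delimited element boundary. Fusion calls
order hits by midpoint: a transposase inside (or within 1 kb of) the
viral-gene envelope with viral genes on both sides is fused_internal, with
the envelope boundary on one side fused_edge, within the 40-kb flank
co_localized (with distance), otherwise none. When TIRs are absent the
element "core" is just the merged hit envelope — reported as coordinates,
not as biology, since true termini may extend further.

## Phylogenetics

Distance matrices are K2P with pairwise deletion; saturated pairs abort
with the pair named (inside bootstrap replicates they are instead capped
at 5 substitutions/site so a single degenerate resample cannot kill a
run). Neighbor joining follows the Saitou–Nei Q-criterion with
lowest-index tie-breaking; negative branch-length estimates are clamped to
zero; three taxa reduce to the closed form. Bootstrap support resamples
alignment columns with replacement and reports the percentage of replicate
trees containing each split of the point tree. Congruence between the
transposase tree and the viral-gene tree (genes concatenated in the fixed
order pol, hel, ter, mcp, mem) is quantified by the Robinson–Foulds
distance over shared leaves, normalized by 2(n−3) — a minimal formal stand-
in for a visual "nearly identical topology" claim, and labeled an
extension. The RF = 0 expectation applies to the simulator's
co-inheritance regime, not to any empirical tree.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the full biology of fish genomes:

- **Host genomes** are i.i.d. nucleotides at a chosen GC (default 0.45)
  with non-overlapping single-copy CDS intervals (default 1.5 kb) that
  anchor the copy-number denominator. No repeats, isochores or real gene
  structure.
- **Elements** are random proteins back-translated with uniform synonymous
  codon choice, separated by 150-bp i.i.d. spacers, flanked by a 13-bp TIR
  pair (right = revcomp(left)); the transposase sits between ORF60 and
  ORF54 (internal), at an element end (edge), or is absent. Default gene
  lengths (150–450 aa) put a full 16-gene element at ~15 kb — a deliberate
  scale-down from the ~100–150-kb real elements that preserves every
  structural feature the pipeline keys on.
- **Divergence** follows a K2P substitution process with R = 2 (the
  generative counterpart of the distance model). Subtype structure places
  each subtype ancestor `between/2` from the template and each copy
  `within/2` from its ancestor. The paper-regime defaults are between =
  0.17 and within = 0.02 substitutions/site, giving ~0.85 between-subtype
  and ~0.98 within-subtype identity — chosen to satisfy the < 0.90 / >
  0.95 identity regime; a nominal divergence of 0.08 would *not* (identity
  ~0.92 > 0.90). Within element CDSs, copies evolve stop-free with start
  and stop codons held fixed (initiation/termination constraint), and TIRs
  are held fixed entirely (transposition requires them): maintained
  elements should not drift into apparent ORF degradation, and that
  constraint is what keeps intactness and TIR recovery meaningful.
  Explicit degradation plants a midpoint premature stop or a 1-bp
  deletion.
- **Insertion** occurs at TTAA sites (≥ 200 bp from host CDSs, minimum
  separation configurable) with target-site duplication, the canonical
  *piggyBac* signature — a simulator convention, adopted to give the
  fusion/TSD callers a testable signal.
- **Reads** are single-end, uniform-start, substitution-error-only
  (default 0.2%), fixed quality — sufficient for a depth-ratio estimator;
  no indels, GC bias or insert-size structure.

Passing tests therefore demonstrate correctness of the algorithms under
these assumptions; they do not certify performance on repeat-rich real
assemblies, fragmented contigs, intron-containing genes (not modeled — the
original annotation used HMM gene finders), or biased sequencing.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 5-Mb single-contig assemblies for detection, 60–150-kb hosts for
copy-number and fusion recovery batches (50 seeds), 10 planted copies in
two subtypes at 30× depth, 100-bp reads. Coordinates are 0-based
half-open on the forward strand everywhere; BED output is 0-based
half-open, GFF3 1-based closed, depth tables 1-based. All randomness flows
from a single integer seed through fixed-order derived seeds, making every
artifact byte-reproducible; derived seeds stay below 2³¹.

## Known limitations

- Cross-contig locus stitching is not automated (multi-contig elements are
  reported as separate loci).
- E-value calibration is approximate (ungapped parameters on gapped
  scores); absolute E-values should not be compared with BLAST's.
- The copy-number estimator inherits a small negative bias (~3–5% at
  default settings) from reads whose seed k-mers all straddle mismatches;
  five anchors keep this inside the ±15% recovery band.
- Subtype identity via edit distance slightly overstates divergence when
  indels are common; the simulator's copies are substitution-dominated.
- The dN/dS generator (acceptance-rejection thinning of nonsynonymous
  proposals) is a regime emulator, not a codon model; realized dN/dS
  approximates the thinning factor.
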