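# Methods

## Detection model

A satellite *set* is a group of co-localized homologues of the seven P4
core components. Detection proceeds in four steps.

1. **Hit filtering.** HMM profile hits are kept at e-value ≤ 10⁻⁵ and
   profile coverage ≥ 40%. "Profile coverage" is computed on the
   profile side (aligned HMM positions divided by profile length, with
   per-domain intervals merged by union); a config switch
   (`coverage_side`) exposes the target-side alternative for hit tables
   that only provide it. A protein is called an integrase from a
   tyrosine-recombinase hit alone (PF00589) or from hits to **both**
   serine-recombinase profiles (PF00239 + PF07508); the merged integrase
   hit keeps the best contributing e-value. A protein hitting profiles
   of two different components keeps the lower-e-value component, so
   every gene carries at most one label.
2. **Chaining.** Hits are ordered by gene index and swept left to
   right; a hit joins the open chain when its gap to the chain's nearest
   member is within `max_gap_orfs` (default 10), otherwise the chain
   closes. "Less than 10 genes apart" is read as fewer than 10
   intervening ORFs, i.e. a gene-index difference ≤ 10; the stricter
   index-difference reading is selectable (`gap_semantics="index"`). On
   circular replicons the first and last chains merge when they are
   within the gap across the origin.
3. **Deduplication.** When a chain carries several integrases, the one
   closest to *psu* is kept (first occurrence when *psu* is absent);
   any other duplicated component keeps its first occurrence in gene
   order.
4. **Classification.** Chains with ≥ 5 distinct components become sets;
   smaller chains are reported as fragments (the sharp drop beyond two
   missing components is itself informative, so fragments are never
   silently discarded). Types A/B/C correspond to 0/1/2 missing
   components. Type B codes number the missing component in reverse
   canonical order (#01 = α … #07 = integrase); Type C codes order the
   21 missing pairs lexicographically by those single-component codes,
   so {ε, α} is TypeC#01. The corpus this numbering reflects uses the
   same mapping inconsistently in one place (lacking-α vs lacking-ε for
   #02); the catalogue constructor therefore takes the ordering as a
   parameter rather than hard-coding it.

The sweep is provably equivalent to taking connected components of the
graph whose edges join hits within the gap; the test suite checks this
equivalence against a networkx oracle on hundreds of random instances.

## Delimitation and architecture

An element's genome runs from its integrase to the component furthest
from it in gene order (ties broken by bp distance, then protein id),
including both genes entirely; *psu* replaces the integrase as anchor
for integrase-less variants. Distances are measured in ORFs because
every co-localization rule upstream is stated in ORFs. Strand is
recorded but ignored. Sets delimited by a non-standard pair (anything
other than integrase↔α) are flagged in the size table so size
statistics can exclude them.

Organization signatures read the component order from the integrase
end; the labels `canonical`, `psu_delta_swap` and `reversed` cover the
observed organization classes, everything else is `other`. Flank
conservation scans the `window` (default 5) genes strictly outside the
delimited span on each side and flags families present in more than 25%
of elements. Chromosomal positions use the N+1 rule against an ordered
core-genome table; on circular replicons an element upstream of the
rank-1 core gene wraps to the last core family, and whether that is
reported as n+1 or 1 is a config choice (`wrap`), defaulting to n+1.

## Pangenome

Families are connected components of the similarity graph with edges at
identity ≥ 0.4 and bidirectional coverage ≥ 0.8 — single-linkage
semantics mirroring an mmseqs2 `--cluster-mode 1 --min-seq-id 0.4` run;
the coverage default is the clustering tool's, exposed in config.
Spectra count genomes containing at least one family member, optionally
after removing families that contain any core-component protein.
Rarefaction uses 100 seeded permutations by default; each permutation's
curve is nondecreasing and ends at the total family count.
Variant–accessory association uses a one-sided hypergeometric test per
(variant, family) pair with Benjamini–Hochberg correction at 0.05; the
test and the correction are both config-exposed since nothing stronger
is implied by the data model. Degenerate margins report p = 1 with a
flag.

## wGRR

wGRR(A,B) = Σᵢ id(Aᵢ,Bᵢ)/min(|A|,|B|) over bidirectional best hits.
Input hits are filtered at e-value < 10⁻⁴, identity ≥ 35% and coverage
≥ 50% of **both** proteins (the plural reading; an either-side switch
exists). Best hits are deterministic under the tie-break chain bitscore
desc → e-value asc → identity desc → lexicographic id. The matrix is
clustered by average linkage (UPGMA) on the distance 1 − wGRR — the
natural transform of a similarity in [0,1] — and cut with the maxclust
criterion (default 7 flat clusters). Self-comparisons are excluded from
histogram exports.

## Trees and pseudogenes

Patristic distances are computed with DendroPy and are invariant to
rerooting; correlations between components are plain Spearman ρ (average
ranks for ties) over element-paired distance vectors — no Mantel
permutation test, since a single correlation value is the target
statistic. Elements contributing several copies of a component are
represented by the copy retained by deduplication, giving one leaf per
element per component. Monophyly is evaluated in the unrooted sense
(some edge bipartition equals the subset).

The pseudogene scanner translates the locus in all six frames, splits
each translation at stop codons and locally aligns every stop-free
segment (≥ 8 aa) to the reference protein (match +1, mismatch −1, gap
open −2, extend −1). Segments with ≥ 30% identity over ≥ 8 aligned
reference positions qualify. The verdict is **intact** when a single
segment covers ≥ 80% of the reference *and* starts within 5% of its
N-terminus — the N-terminal condition is essential, because an early
internal stop leaves a long clean downstream ORF that would otherwise
satisfy the coverage rule alone. The verdict is **pseudogene** when the
qualifying segments jointly cover ≥ 40% of the reference and require a
frame change (frameshift evidence) or are separated by an in-frame stop
(internal-stop evidence); anything else is **absent**. The 30/40/80
thresholds are package defaults chosen to separate the three verdict
classes robustly on synthetic loci; they are parameters of
`pseudogene_scan`, not constants.

## Synthetic data

The generator emulates the detection substrate: multi-gene replicons
(default 60 ORFs each, protein lengths 80–400 aa, intergenic gaps
20–200 bp), planted satellites of chosen variant and organization with
0–3 intervening ORFs between components by default (within the 0–9
range observed between integrase and *psu* in real elements; fixed
per-interval gaps can emulate hotspots), decoy isolated components
placed more than `max_gap_orfs` from any element, and a protein universe
whose pairwise identities are asserted directly in the similarity table
(within-family 0.7–1.0, between homologous core components of different
elements 0.5–0.9, nothing across families). Protein *sequences* are
random strings emitted only where FASTA output is required — the
pipeline consumes tables, and generating identities directly keeps the
tests alignment-tool-free. Every artefact draws from its own stream
derived from the master seed, so adding replicons does not move
previously placed elements.

What the generator does **not** emulate: realistic nucleotide
composition, sequence evolution under substitution models, annotation
errors, overlapping or nested mobile elements, and noisy HMM scores near
the thresholds. Passing the planted-recovery tests therefore
demonstrates the correctness of the chaining/classification/delimitation
logic under the stated rules, not the sensitivity of the HMM profiles on
real genomes.

Tree simulation builds a random topology by recursive splitting with
exponential branch lengths; `shared_history` reuses one element
genealogy across components with lognormal branch-length jitter (noise 0
gives ρ = 1 exactly), `independent` draws unrelated topologies (mean ρ
near 0 over seeds). Pseudogene loci are deterministic back-translations
of random proteins with an optional single-base deletion or TAA
substitution at a chosen codon (mid-gene by default).

## Problem sizes and numerics

The test suite runs the oracle-equivalence check on 200 random replicons
(≤ 25 hits each), planted recovery on a 100-replicon / 100-element
simulation, the patristic oracle on 50 random 20-leaf trees, the
pseudogene scanner on 300 loci and the enrichment oracle on 1000 random
2×2 tables — sizes at which the independent oracles (graph components,
shortest paths, direct hypergeometric summation) are exact and fast.
Floating-point comparisons use absolute tolerances of 10⁻⁹ for patristic
distances and exact equality elsewhere when the arithmetic is closed
(counts, set operations). All randomness in the package goes through
`numpy.random.default_rng` with explicit seeds; identical seeds produce
byte-identical output files.

## Known limitations

- Wrapped (origin-spanning) sets on circular replicons are detected and
  flagged, but their delimited span is reported as the enclosing
  min–max interval, not a wrapped interval.
- The naive similarity model plants no cross-family noise hits below the
  clustering threshold; clustering robustness to near-threshold noise is
  exercised only via the random-graph property tests.
- The pseudogene scanner assumes a single expected gene per locus;
  tandem or nested relics yield a single merged verdict.
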