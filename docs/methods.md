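# Methods

This note records the models implemented in `orcensus`, the parameters
that matter, the numerical conventions, and the known limits — in the
spirit of a methods supplement a maintainer can check code against.

## Coordinates and conventions

All genomic coordinates are 0-based, half-open, on the forward strand;
GFF3 output converts to 1-based inclusive. Gene models on the minus
strand keep forward-strand intervals with exons ordered 5′→3′ in gene
orientation. All stochastic components take an explicit integer seed; a
master seed fans out to per-component substreams
(`numpy.random.SeedSequence`) so adding one generator never perturbs
another's stream.

## Translated homology search

A seed-and-extend search over six-frame translations stands in for an
external TBLASTN where desk-scale, self-contained operation matters.
Seeds are exact amino-acid words (default k = 4) between query and
translated frame; extensions are ungapped BLOSUM62 with an X-drop of 20;
HSP raw scores are converted to bit scores with the published ungapped
BLOSUM62 Karlin–Altschul parameters (λ = 0.3176, K = 0.134) and to
e-values with the query length in residues times the genome length in
nucleotides as the search-space product. The default reporting threshold
is E ≤ 1e-10. This engine is deliberately not a bit-exact BLAST
re-implementation: e-values are accurate to the order of magnitude,
which is all the fixed reporting threshold requires; an external search
tool can be substituted upstream by constructing `HomologyHit` records
directly.

Hit regions on the same contig and strand are widened by `extension_bp`
(default 20,000 nt, matching the largest intron the gene predictor will
consider) and unioned into candidate loci; loci are clipped to contig
bounds and processed in (contig, start, strand) order.

## Spliced gene prediction

Gene models come from a local dynamic program aligning the query protein
to the locus DNA codon-wise:

- match state: codon vs residue under BLOSUM62, with in-frame stop
  codons scored at −`stop_penalty` (default 15) rather than the BLOSUM
  '*' column;
- affine gaps: genome-side codon skips (open 11, extend 3 per codon) and
  query-side unaligned residues (open 11, extend 1 per residue);
- frameshift states: codons of 1–2 nt or 1–2 extra nt, at a flat 28;
- introns: permitted only between codons (phase 0), only with GT…AG
  terminal dinucleotides, and only with lengths in
  [`min_intron_bp`, `max_intron_bp`] = [50, 20,000]; a fixed penalty of
  40 per intron. The max-intron bound is enforced exactly with a
  monotone-deque sliding-window maximum over donor positions, so the
  kernel stays O(m·n).

Ties are broken deterministically: codon continuation over frameshifts,
non-intron predecessors over introns (hence fewer introns), and the
leftmost best-scoring end cell.

The penalty ladder is deliberate: hiding a genuine premature stop would
cost a paired genome+query gap (≥ 22), a frameshift (28), or an intron
(40), all above the stop penalty (15), so disabling mutations are
aligned through and remain visible; conversely the stop penalty is high
enough that marginal chance extensions into flanking sequence that
happen to contain a stop become net-negative and are discarded by the
optimum itself. After traceback, terminal codons are trimmed while the
outermost 10-codon window falls below 30% identity ("end polishing"):
chance extensions run at roughly the random-codon match rate (~7–20%),
while genuinely homologous ends at the divergences this pipeline targets
sit near 75% amino-acid identity, so the floor separates the two
regimes with a wide margin.

### Loss-of-function calls and status

`detect_lof` reports one `premature_stop` per aligned in-frame stop
strictly before the codon aligned to the query's last aligned residue
(the terminal stop codon downstream of the alignment is never an event),
with its 0-based query-aligned codon index; and one `frameshift` per
1–2 nt codon or insertion, with a nucleotide offset of 3 × (query
residues consumed). Status is then a strict decision ladder: any LOF
event ⇒ **pseudogene**; else a full ORF (ATG at the model start, a stop
codon immediately downstream in frame, query coverage ≥ 0.9) ⇒
**complete**; else **edge** if the genomic span lies within
`edge_distance_bp` (default 5,000 nt) of a contig end, otherwise
**truncated**. The four categories are mutually exclusive and exhaustive
by construction.

### Family assignment

Stage 1 labels a candidate by its best local BLOSUM62 alignment against
a reference panel of olfactory families plus decoys (taste receptors,
other GPCRs); decoy best-hits are rejected. Stage 2 places the candidate
in an NJ tree over global-alignment distances (1 − identity) with all
references, roots at a decoy, and retains the candidate only if its
smallest enclosing clade containing any reference contains references of
the assigned family exclusively. Reference–reference distances are
cached on the database object.

### Probe cross-reactivity

Moderately stringent in-situ hybridisation tolerates a bounded mismatch
fraction between probe and target. The probe (cDNA sense, ≥ 50 nt) is
aligned into each transcript with an infix edit-distance alignment
(edlib HW mode); mismatch fraction = edit distance / probe length; the
default tolerance is 0.24, the permissive end of the 12–24% window such
hybridisation conditions allow, with full-probe coverage by
construction. The returned set is monotone non-shrinking in the
tolerance.

## Gene trees, reconciliation, dating

The built-in tree builder is neighbor joining over p-distances (or
Poisson-corrected distances) with a nonparametric bootstrap (default 100
replicates) for internal-edge supports on a 0–100 scale; large-scale
maximum-likelihood inference with model selection is intentionally out
of scope — any external ML tree in newick drops into the same
downstream operations. NJ child order is canonicalised (smallest
descendant leaf label first) so equal topologies serialise identically.
Edges with support below the threshold (default 90) are contracted
before reconciliation; contraction is idempotent and leaf-preserving.

Reconciliation minimises duplications + losses by classical LCA mapping.
A strictly bifurcating input root is respected; a multifurcating-root
(newick-unrooted) tree triggers a search over all rootings. Polytomies
are resolved exhaustively when each has ≤ 7 children (105 resolutions
for 5 children, 945 for 6), otherwise by stepwise joining of the pair
with the deepest species-tree LCA; the first minimum-cost candidate in
canonical enumeration order wins, making output deterministic.
Duplications are charged to the species node where they occur; losses to
the species branch on which the copy died. The family is presumed
present as a single copy at the species-tree root: if the gene-tree root
maps below it, one loss is charged to each sister branch along the
descent path. Ancestral counts give the copies present at each species
node after the events at that node; leaf counts equal observed
per-species gene counts. An independent dynamic program over all
feasible gene-node→species-node mappings (with the same root-presence
charge) provides a brute-force cross-check used by the test suite and
the acceptance script; the two agree on every instance of an exhaustive
small-tree sweep.

Dating fits a strict clock by weighted least squares: minimise
Σ_b w_b (b − r·Δt_b)² with w_b = 1/(b + ε), ε = 1e-6, subject to
parent-older-than-child ordering, tips fixed at age 0, and min/max
calibration ages on MRCA nodes (SLSQP, three starts, tightest feasible
initialisation from node heights). Infeasible calibration systems
(a descendant's minimum above an ancestor's maximum after propagation)
raise `InfeasibleCalibration` naming the offending node. Note an
identifiability caveat: with only interval calibrations the objective is
exactly flat under joint rescaling of all ages and the rate, so absolute
ages are pinned only by a point (min = max) calibration or tip dates;
scaling all branch lengths by c leaves inferred ages unchanged with the
rate absorbing c. Confidence intervals on ages are out of scope.

## Expression statistics

The unit of replication for labeling density is the lamella: density is
the mean over surveyed lamellae of labeled cells per mm (zero-count
lamellae included), reported ± SEM across lamellae. Primary/secondary
proportions are percentages of total cells and sum to 100 by
construction. Normalized radial position is distance-from-apex divided
by apex-to-base lamellar length (secondary-lamella cells enter after
projection onto their primary lamella, which is how the input tables are
expected to be measured): 0 = apex, 1 = base.

The t-test defaults to Welch (unequal variances, Welch–Satterthwaite
df, two-sided), with pooled-variance Student behind a flag; two
all-identical samples return t = 0, p = 1 by convention. The two-sample
Kolmogorov–Smirnov statistic D is the sup-difference of the two ECDFs
computed with exact integer numerators; the p-value is the exact
permutation tail P(D* ≥ D) obtained by lattice-path counting over
pooled-rank arrangements (tied groups handled by binomial convolution)
whenever n1·n2 ≤ 10,000, and the asymptotic Kolmogorov distribution
otherwise. The exact p agrees with literal enumeration on small samples
and never exceeds the nominal level under the null. One discreteness
fact worth knowing: with equal sample sizes n the null distribution of D
is supported on multiples of 1/n, so only a lattice of significance
levels is attainable — at n1 = n2 = 100 the levels adjacent to 0.05 are
P(D ≥ 0.19) ≈ 0.054 and P(D ≥ 0.20) ≈ 0.036 (as given by the exact null
distribution this module computes), and the realised type-I error at
nominal α = 0.05 is therefore ≈ 0.036, not 0.05. This is a property of
the test itself, not of the implementation.

## Synthetic data: what it emulates, and what it does not

The generators exist so that every pipeline stage can be validated
against recorded ground truth without downloading genomes.

**Gene families** evolve by a linear birth–death process: each extant
copy waits an exponential time at rate λ + µ (events/lineage/Ma along a
dated species tree) and duplicates with probability λ/(λ+µ), else dies;
copies surviving to a species node speciate into all child branches.
Every event is recorded on its branch, including events inside
subsequently extinct subtrees; the emitted gene tree is pruned to extant
descendants. On a single branch the expected copy number is
root_count · e^{(λ−µ)t}, which the simulator reproduces within
Monte-Carlo error. Reconciliation of the true gene tree recovers at most
the true event count (parsimony bound); at rates giving ≲ 0.25 expected
events per branch the recovered/true ratio is ~0.95, the shortfall being
genuinely confounded event pairs (e.g. a duplication whose extra copy
dies on the same branch).

**Genomes**: one planted gene per contig (default 30 kb, i.i.d. uniform
ACGT background, random strand). Planted genes are template coding
sequences diverged by a fixed substitution fraction (default 0.15) with
a 3:1 third-codon-position bias (so amino-acid identity stays ~75% and
genes remain findable), never introducing an in-frame stop and keeping
the start codon and final two codons intact. Statuses are realised by
LOF mutagenesis (pseudogene), 3′ truncation placed mid-contig
(truncated), or 5′ truncation placed within 50–1,200 nt of a contig end
(edge); a subset of genes receives one GT…AG intron (200–1,500 nt).

The generator plants only configurations the alignment model can
resolve, and these constraints encode real identifiability limits of
spliced alignment rather than conveniences:

- LOF events ≥ 12 codons from the gene start (a frameshift closer to an
  end than the frameshift penalty is worth is indistinguishable from a
  trimmed local alignment);
- LOF events ≥ 12 codons apart (two nearby indels are cheaper to absorb
  as a short out-of-frame mismatch stretch than as two frameshift
  states);
- splice sites ≥ 8 codons from any LOF event (an intron boundary
  absorbs an adjacent frameshift, because intron length is unconstrained
  modulo 3) and terminal exons ≥ 25 codons (a shorter diverged exon can
  score below the intron-open penalty and be dropped).

Not emulated: repeats, base-composition structure, assembly gaps/errors
beyond contig fragmentation, paralogous gene clusters on one contig,
selection-aware codon substitution. Passing the plant-and-recover suite
therefore demonstrates correctness of the census machinery under clean
divergence, not robustness to repeat-rich real assemblies — on real
data, the family-assignment tree-placement step and manual curation
carry more weight.

**Labeled cells**: per receptor, n cells draw normalized radial
positions from Beta(α, β) and lamella identity from
Bernoulli(p_primary), on 100 lamellae of 0.8–2.5 mm across 5 sections.
The default receptor panel mirrors the archetypes quantified in
cartilaginous-fish olfactory epithelium: an abundant, apically skewed,
primary-lamella-biased coreceptor-like gene (n = 410, Beta(2,5),
p_primary = 0.81), a sparse apically skewed gene with even lamella use
(n = 110, Beta(2,5), p_primary = 0.47), and a uniformly distributed,
secondary-biased gene (n = 300, Beta(1,1), p_primary = 0.28). The
Beta(2,5)-vs-Beta(5,2) contrast at n = 200 is detected by the KS test at
p < 0.001 essentially always.

## Problem sizes

The shipped test and acceptance runs are sized for a single CPU:
synthetic genomes of 10 × 30 kb contigs (10–20 genomes per sweep), an
exhaustive reconciliation sweep of ~1,900 instances on ≤ 4-taxon species
trees, 10,000-replicate KS calibration at n = 100, 1,000-replicate
birth–death expectation checks, and 100 LOF plant-and-recover rounds.
These sizes were chosen as the smallest at which each statistical check
has clear resolution; all scale up by parameter.

## Known limitations

- Phase-1/2 (codon-interrupting) introns are not modelled; real
  chemoreceptor genes with such introns will be predicted with a
  1–2 nt frameshift at the splice junction instead.
- Selenocysteine recoding is not handled (standard genetic code only).
- The built-in search engine's e-values are approximate
  (order-of-magnitude); swap in a full search tool for sensitive
  full-genome screens.
- The greedy polytomy resolution is a heuristic beyond 7 children; its
  cost is an upper bound on the optimum (exhaustive resolution bounds it
  below in tests).
- WLS dating reports point estimates only, and only relative ages unless
  a point calibration or non-zero tip dates pin the scale.
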