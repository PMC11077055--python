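# Methods

This note records the models, conventions and parameter choices behind each
analysis stage, what the synthetic data does and does not emulate, and the
known limitations.

## Homolog families and the PCD metric

**Pairwise alignment.**  Protein pairs are compared by best local alignment
under BLOSUM62 with affine gap penalties (open 11, extend 1; a gap of length
L costs 11 + (L−1)·1).  Identity is defined as identical aligned residue
pairs divided by *all* alignment columns, internal gap columns included —
the usual homology-search convention; the alternative
(matches / min sequence length) is deliberately not used because it inflates
identity for short local hits.  Coverage of each sequence is the aligned
span divided by its full length.  An edge requires identity ≥ 0.3 **and**
coverage ≥ 0.7 of *both* sequences (bidirectional coverage); homolog
families are connected components of the edge graph.  The joint criterion
matters: unrelated proteins frequently produce short local hits with
identity ≥ 0.3, but never with 70% bidirectional coverage.

**Candidate generation.**  For ≤ 2,000 proteins every pair is aligned
(exact mode, the default — correctness first at desk scale).  For larger
sets a shared-5-mer prefilter restricts alignment to candidate pairs; it is
a heuristic (a homologous pair sharing no exact 5-mer would be missed) and
therefore opt-in.  At ~10% sequence divergence the chance that two ~120-aa
homologs share no 5-mer is negligible, which is why the two modes agree on
the synthetic benchmarks.

**Similarity definition.**  `sim(i, j)` counts the *proteins* of phage i
whose family contains at least one protein of phage j, normalized by the
proteome size of i.  This reading makes `sim(i, i) = 1` exactly, including
for phages with paralogs.  An alternative definition counting shared
*families* (normalized by the number of distinct families of phage i) is
available via `definition="families"` / `--sim-definition families`; the two
differ whenever paralogs exist, so comparisons against externally produced
similarity matrices should state which definition was used.  Empty proteomes
(retained so matrix dimensions match the manifest) get sim = 0 to all
others and distance 1.

**PCD.**  `dist(i, j) = 1 − (sim(i, j) + sim(j, i))/2` is symmetric with
zero diagonal and values in [0, 1], but it is *not* a metric — the triangle
inequality can fail — so no metric property is asserted or relied upon.

## UPGMA

Average-linkage agglomeration merges, at each step, the two clusters with
the smallest mean pairwise leaf-to-leaf distance; the merge height is that
mean, computed exactly from sums of original distances (no successive
averaging drift).  Average linkage is monotone; non-decreasing heights are
asserted on every constructed tree.  Ties are broken by the
lexicographically smallest pair of cluster representatives (a cluster's
representative is its smallest leaf id), and flat-cluster labels are the
smallest member id — both purely for reproducibility.  Merge heights are
stored raw; Newick export places nodes at age height/2 so branch lengths
are parent−child age differences and the tree is ultrametric.  Leaf order
is the in-order traversal with the smaller-representative subtree first; no
optimal-leaf-ordering optimization is performed (a heat map needs *an*
order, not an optimal one).

## Defense profiles

Titer uses the most dilute spot within the countable window (3–300 plaques,
configurable; standard plaque-assay practice).  If no spot is in the
window, the most dilute non-zero count is used; if every counted spot is
zero the titer is censored at 0.5 plaques over the most concentrated spot
(0.5 / (volume · 10^d_max)), i.e. half a plaque defines the detection
limit.  EOP divides the defense-host titer by the matched empty-vector
titer per replicate (a censored control is an error — the assay failed).
Protection is −log₁₀ of the *arithmetic* mean of replicate EOPs; censored
replicates contribute their bound, flagging the result as a lower bound.
A geometric-mean option exists for sensitivity analysis.  Censoring flags
are carried by type through titer → EOP → protection and are never silently
dropped.  Untested phage×system cells are NaN, distinct from protection 0.

## Product composition

Only the complementary strand of a protein-primed product is sequenceable
(the priming tyrosine blocks adaptor ligation on the original strand), so
`strand_mode="complement"` swaps A↔T and C↔G — an involution that conserves
total counts.  Headline frequencies are pooled over all bases of all reads;
per-read counts are also emitted because the pooled frequency equals the
read-length-weighted mean of per-read frequencies, and both views are
useful.  N bases are excluded from the frequency denominator (basecaller
artifacts should not dilute composition) and reported as a separate
fraction.  No length or quality filtering is applied by default;
`--min-len`/`--max-len` are available.

## Adduct quantification

The weighted mean product length Σ(Iₗ·l)/Σ(Iₗ) treats band intensity as
proportional to molecule count, which holds when each strand carries exactly
one radiolabel.  The adduct absorbance model is a two-component mixture
*per mole of protein*: at DNA occupancy f,

    ratio(f) = (f·A260_DNA + A260_prot) / (f·A280_DNA + A280_prot)

with A_DNA = mean length × composition-weighted per-base extinction.
Absorbances are additive; ratios are not, so occupancy is recovered by the
exact algebraic inversion f = (r·A280_prot − A260_prot)/(A260_DNA − r·A280_DNA),
never by linear interpolation of ratios.  The protein endpoint may be given
either as molar extinction coefficients or as a measured protein-only
A260/A280 (e.g. from a polymerase-dead variant that carries no DNA) plus
ε280.  Defaults: per-base ε260 of 15,400 (dA), 7,400 (dC), 11,500 (dG),
8,700 (dT) M⁻¹cm⁻¹ with 280/260 ratios 0.16/0.97/0.66/0.72; no
hypochromicity correction unless requested.  All coefficients are inputs —
published occupancy figures cannot be reproduced without the underlying
measured ratios, so the package validates the *procedure* by exact
round-trip (occupancy∘ratio = identity to 1e−10) and monotonicity rather
than by any fixed number.  The initial polymerization rate is the linear
two-point estimate (L̄(t₁) − L̄(t₀))/Δt in nt/min; no kinetic model beyond
that is attempted.

## Synthetic data

Generators are pure functions of (spec, seed) — byte-identical reruns — and
always emit machine-readable truth beside the data.

* **Proteomes.**  Each planted cluster owns 30 core families (default)
  carried by every member phage as mutated copies; 2 families are shared by
  all clusters; each phage adds ~20% singletons and occasional paralogs
  (p = 0.05).  Sequences evolve by i.i.d. uniform amino-acid substitution
  (rate 0.1 by default; optional indels), which keeps pairwise identity
  analytically controllable for threshold tests but does not emulate real
  phage evolution (no domain structure, no rearrangements, no HGT).  Protein
  lengths are normal (mean 120, sd 30, min 30) — short phage-protein-like
  sizes that keep exhaustive all-vs-all alignment tractable on one CPU.
  Default study size: 3 clusters × 4 phages (~500 proteins).
* **Plaque tables.**  Counts over eight 10-fold dilutions of 2.5 μl spots,
  three replicates, from titers implied by true protection values.  The
  default vector titer of 4×10⁹ PFU/ml makes every expected count an
  integer, so noiseless tables round-trip to machine precision; Poisson
  mode adds counting noise.  Spots above 400 expected plaques are emitted
  as lawns.
* **Reads.**  Primer lengths from a discretized triangular distribution on
  [10, 40] nt peaking at 18 nt, plus Gamma-distributed (shape 2) extensions
  reaching a 100-nt target mean; i.i.d. bases at the specified
  original-strand probabilities (A/C-rich 0.5/0.45/0.03/0.02 by default, or
  uniform); emission of either strand.  No sequencing-error or homopolymer
  model — passing composition-recovery tests shows the strand bookkeeping
  and estimator are correct, not that real nanopore artifacts are handled.
* **Densitometry.**  A triangular 10–40 nt profile peaked at 18 nt blended
  with a boundary point mass so the weighted mean is *exactly* the target
  (default 18.3 nt).

Because the generators define the test conditions, passing the suite
demonstrates internal correctness of the estimators and pipeline plumbing on
data matching the stated statistical structure; it does not certify family
boundaries or cluster counts on real proteomes, whose alignment statistics
differ from the i.i.d. substitution model.

## Numerical conventions

Matrices serialize at 6 decimal places (byte-stable diffs); Newick branch
lengths round at 1e−10; partition validity (disjoint + exhaustive) is
asserted on every clustering run; distance-matrix symmetry is required
exactly as constructed and to 1e−12 on ingest.  Flat cluster/family naming
is lexicographic throughout.

## Limitations

* Homolog families use single-linkage connected components; promiscuous
  multi-domain proteins can chain otherwise distinct families (no profile/HMM
  refinement).
* Cluster counts on real data depend on the cut threshold, which must be
  supplied; the package does not guess one.
* The prefilter is not guaranteed complete below ~25 aa or at high
  divergence; exact mode is the reference behavior.
* Liquid-culture MOI growth kinetics are not modelled; MOI series are
  bookkeeping only.
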