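# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish. Notation: trees are rooted and
ultrametric in relative time with the root at age 1.0 unless stated;
distances are proportions (substitutions/site), reported as percent only
at the reporting layer.

## Distance analysis

K2P distances use pairwise deletion: for each sequence pair only sites
where both sequences carry an unambiguous A/C/G/T are compared; IUPAC
ambiguity codes are treated as missing throughout (never as partial
matches), which keeps every computation deterministic. A pair whose
transition/transversion proportions make a logarithm argument nonpositive
is flagged saturated and carries an infinite distance; downstream tree
building refuses such matrices and names the offending pair.

Divergence summaries report within-group and between-group means and
medians per group, per group pair, and pooled. Because "mean
between-population divergence" is ambiguous — all pairs pooled versus the
mean of per-population-pair means — both are reported, labeled. Empty
pair classes are reported with n = 0 and NaN statistics, never as 0.

The reference-library benchmark keeps only sequences whose label matches
a plain `Genus species` binomial (regex `^[A-Z][a-z]+ [a-z][a-z-]+$`);
excluded sequences are counted and logged. The two-sample location test
is a Mann–Whitney rank-sum test (the published description "unpaired
Wilcoxon signed rank test" is internally contradictory; an unpaired
rank-sum test is the only consistent reading): exact enumeration for
combined n ≤ 12 without ties, asymptotic with tie correction otherwise,
and p = 1 by definition when all values are tied.

## Neighbor joining and rate smoothing

Neighbor joining is the standard Saitou–Nei algorithm with the
Q-criterion. Negative branch-length estimates at a join are clamped to
zero with the deficit moved to the adjacent branch of the same join, so
path lengths through the join are preserved (the convention downstream
smoothing needs, since it requires nonnegative lengths). The unrooted
result is rooted on the outgroup when one is given — the outgroup is then
dropped before smoothing and delimitation, which model only the ingroup's
branching — otherwise at the midpoint. Identical sequences can be
collapsed to unique haplotypes before tree building; delimitations are
re-expanded to all specimens afterwards.

NPRS minimizes W = Σ over internal nodes of Σ over child edges of
(r_child − r_parent)², where r = substitution length / branch duration
and the root contributes the summed squared deviation of its children's
rates from their mean. Internal node ages are parameterized as fractions
of their parent's age in (10⁻⁶, 1−10⁻⁶), optimized with L-BFGS-B
(ftol 10⁻¹⁴); this enforces age monotonicity along every path by
construction. Durations are floored at ε = 10⁻⁹ so zero-length pendant
edges cannot produce infinite rates. The deterministic start sets each
age proportional to the node's maximum path length to a tip, which makes
an already clock-like tree a fixed point (objective 0 at the start). The
fitted and starting objective values are stored on the returned tree; the
optimizer result is discarded if it is ever worse than the start.
Smoothing is invariant to uniform rescaling of the input branch lengths.

## GMYC

The single-threshold model follows the generalized mixed
Yule-coalescent likelihood. An ultrametric tree is decomposed into
waiting intervals between distinct branching ages (ties within 10⁻⁹ of
each other are merged, with a log note); the final interval runs to the
present, so waiting times telescope to the root age. Given a threshold T,
each lineage segment older than T is species-level; each segment younger
than T belongs to the within-species cluster rooted where its ancestral
lineage crosses T. The interval rate is

    b_i = λ_Y · n_{i,Y}^{p_Y} + λ_C · Σ_k (n_{i,k}(n_{i,k}−1))^{p_C}

with n_{i,Y} the species-lineage count — above T every lineage, below T
one lineage per delimited entity: the diversification process continues
beneath the threshold without observable speciations, which also keeps
every interval's rate positive. The log-likelihood is
Σ_i [ln b_i] − Σ_i b_i x_i, with the ln b_i density factor applied to
every interval except a segment cut off by the threshold itself; reading
the coalescent part in its own (tips-to-root) time direction shows this
assigns exactly one rate factor per branching event, and for the
whole-tree null it reduces to the plain product Π b_i e^{−b_i x_i},
whose rate MLE at fixed exponent is the closed-form exponential estimate
λ̂ = (#intervals)/Σ w_i x_i used as a test oracle.

Candidate thresholds are the distinct node ages below the root — the
threshold is definitionally tied to a branching event (the oldest
within-species coalescence). A scan over midpoints between node ages was
evaluated and rejected: inside inter-node gaps the likelihood is flat in
T, and gap-interior candidates produced spurious likelihood-equivalent
optima that oversplit clean three-species simulations. A degenerate
candidate just above the root (the whole tree as one cluster) is always
scanned; it coincides with the null model, making the nesting inequality
lnL_GMYC ≥ lnL_null exact. Per threshold, (log λ_Y, p_Y, log λ_C, p_C)
are optimized by L-BFGS-B with λ ∈ (10⁻⁸, 10⁸) and p ∈ [0, 10] from a
fixed four-point start grid (one start reuses the fitted null
parameters); non-converged thresholds are skipped with a warning, and
likelihood ties resolve to the deepest (fewest-entity) threshold. The
LRT uses 2·ΔlnL against χ² with 3 degrees of freedom (threshold plus one
extra rate and one extra exponent), the choice that reproduces both
published p-value examples (LR 12 → 0.007; LR 1.44 → 0.70); a negative
LR beyond 10⁻⁶ raises, as it can only be an optimizer defect.

## Diagnostic characters

Only simple (single-position) characters are extracted. For every
(position, group, state) with the state present in the group and absent
from every unambiguous base of every other group, a character is emitted:
pure when every group member carries it (confidence 1.0 — a member with
a gap at the site therefore demotes the state to private), else private
with confidence equal to the within-group frequency. Positions are
1-based. A site may diagnose several groups, so character-level counts
exceed site-level counts; a distinct-site view classes each site pure
(≥1 pure character) or private, and the site fraction is
100·(#diagnostic sites)/(alignment length) at one decimal. Query
assignment scores each group by the fraction of its pure characters
matched and assigns the argmax only when it exceeds 0.5 and beats the
runner-up by a margin (default 0.1); anything else is unassigned.

## Morphometrics

TPS blocks (`LM=`, coordinate lines, `ID=`, optional `IMAGE=`) are read
with repeated IDs interpreted as digitization replicates; writing uses
17-significant-digit floats so write∘read is the identity. Replicates are
averaged landmark-wise on the raw coordinates (replicate pairs share the
digitization frame, so no superimposition is needed first).

GPA centers each configuration, scales to unit centroid size, and
iterates proper-rotation (no reflection) alignment to the running
consensus until the consensus moves by less than 10⁻¹⁰. The arbitrary
global orientation is then canonicalized to the consensus principal axes
with a third-moment sign rule, making the output a deterministic function
of the shapes alone — this is what lets the similarity-invariance
property hold to 10⁻⁸ rather than only up to rotation.

Relative warps are computed with bending-energy exponent α = 0 — an
ordinary PCA of the aligned coordinates about their mean with the uniform
component retained, the tps-RELW default reading; component signs are
fixed by making each component's largest-magnitude loading positive.
Degenerate inputs (all shapes identical) return zero scores and zero
variance fractions rather than failing. Group tests are per-axis one-way
ANOVAs (F infinite with p = 0 when the within-group variance vanishes);
specimen clustering is Ward-linkage agglomerative clustering on the
leading warps (default 10 axes), with the linkage configurable because
the original analysis's SPSS settings are not recorded.

## Evidence integration

Every stream is reduced to a partition of the same specimens:
GMYC entities; average-linkage clusters of the K2P matrix cut at k;
morphometric Ward clusters; mating-compatibility components (populations
joined when courtship/mating was seen in either reciprocal cross,
lifted from populations to specimens via the metadata); and host
association (flagged as non-independent of the sampling design).
Agreement is the adjusted Rand index. The final delimitation is the
strict consensus — two specimens share a block iff they are co-clustered
in every stream — chosen over majority rule because corroboration by all
independent evidence is the standard demanded before breaking out of an
existing taxonomy; the consensus can therefore only split, never merge.
The pipeline records an ok/skipped/failed status per stage, degrades
gracefully when an input (e.g. landmarks) is absent, and writes a report
whose JSON is byte-identical across reruns of the same seed.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis assumes,
at the study's stated conditions:

* **Trees.** Species divergences follow a Yule process (root normalized
  to 1.0) conditioned on every split being at least `min_split = 0.4` of
  the root age — all clades deeply separated, as in the motivating
  complex; unconditioned Yule shapes place one split among the
  coalescent depths in roughly a quarter of draws, which makes
  delimitation of those replicates ill-posed rather than merely hard.
  Within-species genealogies are neutral Kingman coalescents with pair
  time-scale `coal_theta`, accepted when their depth is ≤ 0.9× the
  species' stem age (up to 100 redraws, then rescaled onto that bound).
* **Sequences.** K80 along the tree with κ = 2 (matching the distance
  metric used downstream; no GTR+Γ, no indels), branch time ×
  `subs_rate` expected substitutions/site, and an AT-rich root
  composition. Defaults (`coal_theta` 0.135, `subs_rate` 0.062,
  `at_fraction` 0.715, 631 bp, 3 species × 10 specimens) reproduce the
  study conditions: ≈1.4–1.5% mean within-population and ≈11.2% mean
  between-population K2P divergence, AT ≈ 68.8%. `n_fixed_diag` sites
  (default 73) are engineered to be pure diagnostics by, in order of
  preference, marking sites that are already naturally pure, fixing a
  majority state that other species lack, and only as a last resort
  forcing a free state — so the engineered diagnostics live inside the
  natural divergence instead of inflating it.
* **Landmarks.** Seven landmarks per wing; per group a distinct mean
  shape (offset 0.08), per specimen anisotropic Gaussian shape variation
  (scale 0.02, fixed decaying covariance spectrum), one nuisance
  rotation/translation/scale per specimen shared by its two replicates,
  and replicate digitization noise at 10% of the shape scale
  (measurement error ≪ biological variation).
* **Mating.** Compatibility true on the diagonal and false off it, each
  cell flipped independently with probability `mating_error` (default 0,
  the observed outcome), 10 replicates per cross.
* **Reference library.** Independent per-genus complexes with
  `congeneric_rate` 0.083 and expected intraspecific divergence 0.0075,
  which put the benchmark's intraspecific and congeneric distance
  medians near 0.005 and 0.155; a few `Genus sp.` labels exercise the
  exclusion rule.

What passing tests on these data show — and do not. The generator matches
the analysis's own model family (K80 sequences, Yule/coalescent trees,
Gaussian shapes), so end-to-end recovery demonstrates internal
correctness and calibration, not robustness to model violation: there is
no rate heterogeneity across sites or lineages, no saturation beyond K2P,
no alignment error, no unbalanced sampling, and host/locality metadata
are decorative. Real barcode data can and do violate all of these.

Study-regime choices for the simulation experiments: the GMYC
parameter-recovery study runs at `coal_theta = 0.02`, 12 specimens per
species (sharply separated clusters — "deep splits, shallow
coalescents"), where the modal entity count over 20 replicates is 3 and
the LRT rejects in a majority; the type-I study uses single-population
coalescents of 15 tips, where the rejection rate is consistent with the
nominal α = 0.05 within binomial error. At the pipeline's default,
paper-calibrated divergences the LRT is honestly low-powered — consistent
with the motivating study itself, where one of the two reported GMYC runs
was far from significance. Problem sizes throughout (tens of specimens,
hundreds of sites, tens of replicates) are chosen as the smallest at
which these distributional statements are stable.

## Known limitations

* NJ trees are built from K2P distances; distance estimation under
  richer models (the "optimal model" route) is out of scope, a labeled
  deviation.
* The GMYC likelihood is the standard total-rate approximation: event
  factors use the combined rate rather than per-process factors, and
  topology/combinatorial terms are ignored, as in the original method.
* Single-threshold GMYC only; no multiple thresholds, no Bayesian
  delimitation.
* Diagnostics are nucleotide-level and single-position; no compound
  characters.
* Relative warps use α = 0 (no bending-energy weighting); no
  thin-plate-spline deformation visualization, no semilandmarks.
* The strict consensus treats all streams as equally reliable; the host
  stream is flagged, not down-weighted.
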