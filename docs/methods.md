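# Methods

This note documents the models implemented in `supermhc`, the
parameter choices that matter, the numerical decisions, and the limits
of what the synthetic evaluation shows.

## Affinity normalization

Competition-assay IC50 values are informative roughly between 1 nM and
50,000 nM. They are mapped onto `[0, 1]` by
`psi(IC50) = 1 − log(IC50)/log(50000)`, clamped to 1 below 1 nM and to
0 above 50,000 nM. The ratio of logarithms makes the base irrelevant;
the implementation uses natural logs. The inverse
(`ic50_from_affinity`) uses the middle branch, `50000^(1−a)`, clamped
to `[1, 50000]`, so normalize/invert round-trips exactly. Duplicate
(allele, peptide) measurements are averaged on the normalized scale —
kernel regression needs one target per training point — and the stored
IC50 is re-derived from the mean so that written tables reload
bit-identically.

## Substitution model

The string kernel needs the BLOSUM62 *pair frequencies* `Q(x, y)` and
marginals `p(x)`, not the familiar integer log-odds matrix (which is a
rounded transform of them). The package embeds the clustered target
frequency table from the original BLOSUM construction as plain text
(`data/blosum62.qij`); its off-diagonal printed values are per ordered
cell, so mirroring without rescaling gives a symmetric matrix whose
row sums reproduce the standard background frequencies. The mirrored
matrix is renormalized to total mass exactly 1 (the printed 4-decimal
table sums to 0.9987). Two consistency checks are enforced in tests:
the marginals match an independently transcribed background vector
within 0.005 per residue, and `round(2·log2 Q/(p p))` lands on the
published integer matrix within ±1 (the slack covers 4-decimal
rounding; extremely rare pairs such as C–W are rounding-dominated and
excluded). Whether `Q` normalizes over ordered or unordered pairs only
rescales the raw kernel by a constant per sequence length, which the
correlation normalization cancels.

Per-position kernel factors `(Q(x,y)/(p(x)p(y)))^beta` are computed as
`exp(beta · log-odds)`, so products over long substrings can be
assembled in log space when needed.

## String kernel

`K3(f, g)` sums, over all pairs of equal-length contiguous substrings,
the product of per-position factors. The naive sum is quartic in
sequence length and infeasible for exon-2-scale chains (~90 residues);
the implementation uses the equivalent diagonal recursion
`D(i,j) = s(f_i, g_j)(1 + D(i+1,j+1))`, `K3 = Σ D(i,j)`, evaluated as
a sequence of vectorized diagonal-run products (O(|f||g|)). The
brute-force enumerator is kept as a reference implementation and the
two are required to agree to 1e-9 relative on exhaustive short-string
sweeps. Substring length runs to `min(|f|, |g|)` — the equal-length
constraint admits nothing longer.

Numerics: the linear-domain recursion is exact in double precision for
all realistic inputs; if a running sum exceeds 1e300 the pair is
recomputed in log domain (run products become exact sums of logs;
aggregation over anchors and lengths uses log-sum-exp), and normalized
values are then formed from log quantities. Only the
correlation-normalized kernel (unit self-similarity) is exposed to
models; the pan-allele kernel is the product of the normalized α, β,
and peptide kernels and is PSD with unit diagonal by construction.

The per-role exponents default to `beta_peptide = 0.1137`,
`beta_beta = 0.06`, `beta_alpha = 0.02` — the method's calibrated
operating point; smaller beta flattens the kernel, which suits the
nearly conserved α chains.

A `KernelEngine` memoizes every normalized evaluation per unordered
string pair and per-string self-similarities. Binding tables repeat a
modest set of distinct chains and peptides across thousands of
records, so Gram and cross-Gram construction reduces to index lookups
into small distinct-pair matrices; the same engine can be shared
across cluster models and cross-validation folds.

## Regularized least squares

Fitting minimizes `Σ (f(x_i) − y_i)² + λ ||f||²` over the RKHS of the
pan-allele kernel; by the representer theorem the solution solves
`(K + λI)c = y`. The loss is an *unscaled* sum of squares (no `1/m`),
which fixes the meaning of λ; the default `λ = e^-13` is the
calibrated value under that convention. The system is symmetric
positive definite for any λ > 0 and is solved by Cholesky
factorization — per-cluster training sizes at desk scale are a few
thousand, where a direct solve is exact and fast. Predictions
`f(x*) = Σ c_i K(x_i, x*)` are not clipped by default (they may exit
`[0, 1]` slightly); a clipping flag exists for reporting.

## Repertoire dissimilarity index

For molecules `Mi, Mj`: `d_ij` is the mean absolute normalized-affinity
difference over shared peptides (undefined, not zero, when no peptide
is shared). The RDI of a target pair is `1 − tau` where tau is
Kendall's rank correlation between the reference vectors `(d_ui)` and
`(d_uj)`. Decisions:

- **Reference set** — all molecules, including the targets themselves
  (`d_ii = 0` terms); `include_self_references=False` gives the
  alternative reading.
- **Undefined references** — a reference whose overlap with either
  target is below `min_overlap` (default 1) is dropped for that pair
  rather than imputed; tau is normalized over the usable pairs. Pairs
  left with fewer than two usable references are reported as missing
  (NA) with a warning.
- **Ties** — tau-a: tied differences contribute zero to the sum but
  remain in the normalization. Real affinity data rarely tie; the
  fully degenerate case (identical repertoires everywhere) yields
  tau = 0, hence RDI 1 off the diagonal, with the diagonal forced
  to 0.

## Supertype clustering

WPGMA linkage: after merging P′ and P″, the distance to any Q is the
plain average of the two parts' distances, independent of cluster
sizes. Because the average of two distances that are at least the
current minimum is itself at least that minimum, merge heights are
nondecreasing, and tree cutting is a single union pass. Decisions:

- **Determinism** — ties in the minimum-distance pair are broken by
  the lexicographic order of the concatenated sorted member names, so
  the tree is invariant to input ordering.
- **Cut semantics** — merges strictly below the threshold join; a
  merge exactly at the cut height does not. The default cut of 0.7 on
  the RDI scale excludes weak and negative rank correlations.
- **Height vs diameter** — the cut applies to WPGMA merge heights.
  Cutting on cluster diameters is a defensible alternative reading;
  merge heights were chosen because they are what the linkage
  construction orders monotonically.
- **Main vs diverse** — clusters with at least `min_size = 2` members
  become main supertypes, named by majority isotype with ordinal
  suffixes (size-descending) when an isotype yields several; a
  one-molecule "supertype" cannot generalize, so singletons join the
  diverse pool.

Newick export writes an ultrametric tree with leaf-to-root distance
equal to half the root merge height.

## Ensemble and routing

Training records are partitioned by their molecule's cluster label
(records of unassigned molecules fall to the diverse pool, logged) and
one RLS model is fitted per non-empty cluster. Prediction:

- a molecule that belongs to a cluster with a model uses that single
  model — membership is decided by canonical allele name, not sequence
  identity;
- an unseen molecule is scored by the unweighted mean of the models
  routed for its isotype: DR → main DR + diverse (the diverse pool is
  predominantly DR data), DP → main DP only, DQ → both main DQ
  clusters. The table is fixed at train time and user-overridable; if
  a routed cluster is empty it is dropped (an isotype with no route
  falls back to the diverse model, then to all models, with a
  warning). Per-query provenance (which models fired) is always
  reported.

## Evaluation

Binder labels use measured IC50 ≤ 500 nM (inclusive — intermediate
binders count as binders); AUC is the Mann–Whitney statistic with
midrank tie handling and is undefined for single-class molecules,
which are excluded from the AUC macro-average (and counted); RMSE is
on the normalized affinity scale. Method comparisons use the classical
paired t-test on per-molecule metrics (significant at p < 0.05), with
zero-variance nonzero differences flagged degenerate rather than
forced through the formula.

Cross-validation uses seeded random folds stratified by molecule
(externally defined benchmark folds are not reproducible here; reports
label the substitution). Per-molecule predictions are pooled across
folds before computing metrics, then macro-averaged; per-fold
averaging is a defensible alternative that is noisier for sparse
molecules.

## Synthetic worlds

The generator emulates the shape of a public class II binding table:
a few dozen molecules across DR/DP/DQ, hundreds of peptides per
molecule, IC50 confined to `[1, 50000]` nM, roughly half the
measurements above the 500 nM binder threshold. Per planted supertype
it draws ancestral α/β exon-2-like chains (90 residues by default,
locus markers at the boundaries) and mutates member alleles per site
(rate 0.05 — about the divergence of alleles within a locus); the DR α
chain is shared and unmutated, mirroring the monomorphic DRA. Each
supertype owns a 9-position residue preference profile; a peptide's
latent affinity is a logistic transform of its best 9-mer window score
(the binding-core notion without core alignment), plus an
allele-specific offset (sd 0.05) and Gaussian noise (sd 0.05), clipped
to `[0, 1]`. Peptides (9–15-mers) are drawn from a pool of twice the
per-allele count, with a shared core (min(50, half the per-allele
count)) measured by every molecule so the RDI is always defined. All
draws flow from one seeded generator; regeneration is bit-identical.

Defaults are 4 supertypes (DR, DP, DQ, DQ — so every routing rule is
exercised) × 6 alleles × 300 peptides. The test suite and acceptance
script use these sizes, with 150 peptides per allele for
cross-validation runs to keep the per-fold Gram solves small; a
compact world (4 × 3 × 40, 30-residue chains) backs the unit tests.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real HLA polymorphism structure (alleles
differing at a handful of functionally clustered sites rather than
uniformly at random), assay length- and composition-biases,
heavy-tailed per-molecule measurement counts, and — importantly —
*related* supertypes. Planted supertypes are statistically
independent, which is harsher than reality in one specific way: when
an unseen DQ molecule is scored by averaging the two main DQ models,
the wrong-supertype model contributes noise, and on most seeds the
isotype-routed ensemble trails a single pooled kernel-RLS baseline by
a few hundredths of RMSE on held-out molecules. The ensemble's
practical advantages — per-cluster Gram matrices are far smaller than
one global kernel system, and in-cluster queries match a
supertype-specific model — do not depend on that averaging. Predictions
for molecules dissimilar to all training molecules are also shrunk
toward zero (kernel regression on uncentered targets), which both the
ensemble and the pooled baseline exhibit.

## Degenerate inputs and edge cases

- Non-positive or non-finite IC50, empty sequences, residues outside
  the 20-letter alphabet, and unparseable allele names raise addressed
  errors; peptides with B/J/O/U/X/Z are rejected, not imputed, because
  `Q` is defined only on the standard alphabet.
- DP/DQ allele names must specify both chains; DR names take the fixed
  DRA*01:01 α chain.
- Exon-2 extraction takes the first occurrence of the start marker
  through the last occurrence of the end marker, inclusive of both
  3-residue markers (for loci with marker alternatives: earliest start,
  latest end); whether the markers themselves belong to the kernelized
  region is not settled by convention, and including them keeps
  extraction idempotent.
- An RDI matrix with missing entries refuses to cluster, with guidance
  to raise `min_overlap` or drop sparse molecules.
- A single-cluster ensemble behaves identically to a plain RLS model.
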