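# Methods

`cladesparse` interrogates the robustness of a single clade in a
phylogenomic dataset by supervised sparse learning. This note documents
the model, the estimators, the numerical choices, and what the synthetic
study fixtures do and do not establish.

## The clade model

Let the dataset be G gene alignments over a set of taxa, and let the
hypothesis assign y_s = +1 to every member of the clade of interest and
y_s = −1 to everyone else. Each polymorphic alignment site contributes
one 0/1 indicator column per residue character observed at that site
(gaps and ambiguity codes are "no state": they light no column). Genes
map to contiguous column blocks of the design matrix X.

A clade model is a logistic regression fit with a bi-level
sparse-group penalty,

    min over (β0, β) of
    (1/n) Σ_s w_s · log(1 + exp(−y_s (β0 + x_s·β)))
      + α_S ‖β‖₁ + α_G Σ_g √K_g ‖β_g‖₂ ,

where K_g is the number of columns in gene g and w_s are optional class
weights. The ℓ1 term prunes individual sites, the group-ℓ2 term prunes
whole genes; the intercept is never penalized. The fitted model is the
minimal genetic signature that classifies taxa into/out of the clade.

### Penalty scale

Users steer sparsity through a normalized pair (λ_S, λ_G) ∈ [0, 1]².
`compute_lambda_max` finds the critical magnitudes (α_S*, α_G*) at
which the all-zero coefficient vector becomes optimal (largest absolute
gradient coordinate, and largest group gradient norm over √K_g,
evaluated at β = 0 with the optimal weighted-log-odds intercept). Each
λ then indexes the geometric regularization path

    α(λ) = α* · ε^(1−λ),  ε = 0.01,  with α(0) = 0,

i.e. log-spaced between ε·α* and α*, the standard construction for
lasso paths (cf. glmnet's λ sequence). λ = 1 is therefore provably the
empty model and λ = 0 the unregularized limit. A linear mapping
α = λ·α* was tried first and rejected: on every fixture examined it
crowds the conventional 0.1–0.9 sweep against the empty end of the
path, so virtually all grid points carry 0–3 genes and the ensemble
summaries degenerate.

### Optimization

Monotone FISTA (accelerated proximal gradient) with backtracking line
search; 100 iterations by default with an additional stop when the
relative objective change falls below 1e−5. The penalty's proximal
operator is the exact composition: elementwise soft-threshold at
step·α_S, then per-group norm shrinkage by step·α_G·√K_g (groups whose
norm falls below the threshold are zeroed exactly). "Selected" means a
coefficient is exactly nonzero — the prox produces hard zeros, so no
epsilon thresholding is involved. A function-value restart guards the
acceleration; the objective of the reported iterate is never above the
zero-model objective. Columns are not standardized (0/1 indicators are
already on a common scale).

Accuracy: on tiny instances the solver's penalized objective matches
generic constrained optimizers (SLSQP / trust-constr on a smooth
variable-splitting reformulation) to 1e−6 relative; the test suite
verifies this on 50+ random instances.

## Class balancing

Clades are usually minorities. When S₊ < S₋ (scenario 1) the outside
class is reduced phylogeny-aware: walking rootward from the clade node,
sibling subtrees' leaves are accumulated until at least S₊ outside taxa
are kept; any surplus is removed by repeatedly locating the closest
remaining pair of outside leaves (patristic distance when branch
lengths exist, edge counts otherwise; ties broken lexicographically)
and deleting one member of it uniformly at random under the run seed.
The "next-closest pair" of the procedure is recomputed after every
removal, since each removal changes which pair is closest. When
S₊ > S₋ (scenario 2) nothing is removed; the minority −1 class gets
weight S₊/S₋ as a per-sample multiplier in the loss. The clade itself
is never reduced. A response-file-only analysis with S₊ < S₋ falls back
to random down-sampling with a warning, since no tree is available.

## Concordance and probability estimators

For one fitted model and a member species s:

* gsc(g, s) = Σ_k y_s β_k x_sk over gene g's columns — positive when
  the species' residues at selected sites support its clade membership,
  negative when they conflict, exactly 0 when the gene is unselected or
  the (species, gene) data are missing (the all-zero block).
* scp(s) = logistic(β0 + Σ_g gsc(g, s)) — identically the model's own
  classification probability; the suite asserts this identity at
  machine precision.
* Normalization: scpⁿᵒʳᵐ = (scp − 0.5)/(max scp − 0.5), clamped to 0
  for species the model misclassifies (raw scp < 0.5). Models in which
  no member exceeds 0.5 are dropped from the ensemble with a warning.

A rectangular (λ_S, λ_G) grid (default 0.1–0.9, step 0.1, i.e. 81
fits) produces the model ensemble; models with fewer than two selected
genes are discarded. Ensemble summaries: GSC(g, s) = median of gsc over
retained models (missing pairs are reported as missing, not zero);
SCP(s) = mean of normalized scp; CP = min over member species of SCP.
Normalization is applied per model before averaging (a toggleable
choice; normalizing the averaged raw values once is the alternative).
A low CP flags a fragile clade; strongly negative GSC cells identify
the gene-species sequences responsible.

The QUICK option prunes the sweep: at the lowest λ_S, λ_G is raised
until a model keeps only one gene (that bound, λ_G,max, caps all later
rows), and the λ_S loop stops after a row yields a model with at most
`min_genes` (default 3) genes. Successive fits along each row are
warm-started, which makes the sweep fast and the path stable.

## The M-grid

The report is visualized as a ranked grid: rows are the member species
with the lowest SCP (ascending, SCP printed next to the name), columns
the most influential genes — by mean |GSC| across members by default,
or mean positive GSC. Cells use a symmetric diverging colormap (green
= concordant, magenta = discordant, white ≈ 0) normalized per grid;
missing pairs carry a cross-mark. A TSV twin holds the same numbers.

## Synthetic data: what it emulates

`simulate_dataset` builds a desk-scale analogue of a phylogenomic
supermatrix study. Defaults (chosen once, to put the fixture in the
operating regime reported for real datasets of this kind):

* 20 clade members + 20 outside taxa, 30 genes × 200 sites,
  nucleotide alphabet.
* Supporting genes carry Binomial(200, p_support = 0.1) diagnostic
  sites where all clade members share a residue the outside group's
  modal residue differs from; outside taxa deviate from their modal
  residue at rate `noise` = 0.05, and such homoplasy may hit the clade
  residue — without this, every supporting gene would carry literally
  identical indicator columns and the group penalty would degenerate to
  winner-take-all single-gene models, which no real dataset shows.
* 3 discordant genes whose diagnostic partition unites a random mixed
  subset of inside and outside taxa (gene-tree discordance).
* Whole-gene missingness at mean rate 0.27, heterogeneous per gene
  (uniform on 0.1–0.44), mirroring published supermatrices where
  per-gene taxon coverage spans roughly half to all taxa; additionally
  30% of present sequences are truncated by a contiguous gap span
  (30–70% of sites). Both are what force fitted models to combine
  genes, as they do on real data.
* Contamination: `plant_swaps` exchanges (reciprocal) or copies
  (nonreciprocal) one gene's sequences between a random clade member
  and a random outsider, leaving every other gene untouched.

Everything is reproducible from the config seed, and the ground truth
(diagnostic sites, discordant genes, swap records) is written alongside
the FASTA/Newick/response files.

What the fixture does **not** emulate: branch-length-dependent
substitution processes (no GTR/LG simulation — the learner consumes
site patterns, so a pattern-level generator keeps the planted signal
exactly known), rate variation across sites, alignment error, and
codon structure. Passing tests on these fixtures therefore demonstrate
the estimators' internal correctness and their qualitative behaviour
under planted discordance and contamination — not performance
guarantees on any particular empirical dataset.

## Problem sizes used by the tests and the acceptance script

The grid sweeps in the test suite run on the 40-taxon default fixture
(~14k encoded columns; a full 81-point sweep takes a few seconds with
warm starts). The planted-swap experiment uses 50 replicates per swap
mode with the QUICK grid; the acceptance script reports the same
experiment at 20 replicates per mode, alongside the control-dataset CP
and minimum GSC computed over the full grid.

## Known limitations and observed behaviour

* Gene counts along the λ_G axis are *mostly* non-increasing, but the
  exact bi-level optimum can recruit an extra low-norm gene as the
  group penalty shrinks a dominant gene's norm, so small count
  increases (±1–2) do occur on some fixtures. The suite asserts the
  strict weak-monotonicity property on the default fixture; see the
  mechanism above when interpreting failures on other data.
* CP is sensitive to member taxa with poor data coverage: a member
  missing the genes a sparse model selected receives a normalized scp
  of 0 in that model. This is by design — missing data genuinely
  lowers confidence in a species' placement — but it means CP mixes
  "discordance" with "absence of evidence" on very incomplete taxa.
* The λ normalization is a convention. Absolute penalty levels differ
  across datasets; only within-dataset comparisons of models across the
  grid are meaningful.
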