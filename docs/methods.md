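# Methods

This note documents the models and procedures implemented in `neuralsig`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Reference-based methylation deconvolution

A bulk methylation profile is modeled as a non-negative mixture of
cell-type reference profiles on the beta-value scale. For each sample the
package solves

    min_{w >= 0} || A w - b ||_2

over the CpGs shared between bulk and atlas (intersection by CpG id;
non-shared probes are dropped with a log entry, mirroring 450k/850k array
mismatches), then rescales w to the probability simplex. The reported
residual is the norm at the *unnormalized* optimum. The **neural score**
is the proportion assigned to the single "cortical neurons" component.
An all-zero optimum (possible only for pathological inputs such as an
all-zero beta profile) raises a degenerate-fit error naming the sample.

Dichotomization: a cohort's cutoff is the median neural score; with an
even number of samples, the mean of the two central order statistics. A
sample is *high-neural* iff score >= cutoff. The tie rule (exact equality
counts as high) is a convention; nothing in the analysis depends on it
except determinism at the boundary. For 1,058 distinct scores the median
split yields exactly 529 low and 529 high.

Under least-squares theory the per-component estimation error at noise
sd sigma is sigma * sqrt[(A'A)^-1_kk]; for the default synthetic atlas
(25 disjoint 10-CpG blocks with a 0.1/0.9 methylation contrast) this is
about 0.4 sigma per component. Recovery error is therefore reported as
the mean absolute error per proportion entry, the standard recovery
metric for simplex-valued estimands.

## Differentially methylated positions and label transfer

Per CpG, a two-sample t-test with pooled variance compares beta values
between the low and high groups; two-group F-tests as used in array
pipelines are equivalent (t² = F). CpGs with zero variance in both groups
have an undefined statistic and are skipped with a log entry. P-values
receive Benjamini–Hochberg correction; CpGs with q <= alpha (default
0.05) form the DMP set, sorted by q.

The transfer classifier is an L2-regularized logistic regression
(regularization strength C = 1.0, lbfgs) of the low/high label on beta
values at the DMP sites. Applying it to a new cohort requires all model
CpGs to be present (missing features raise an error listing them); the
decision threshold is the logistic midpoint.

## Module expression score

Given a module of n genes and a cell's log-normalized, scaled expression
values x_1..x_n, the score is

    m_exp = (sum_i x_i / n) * (#{i : x_i != 0} / n)

— the mean module expression times the detection frequency, which
down-weights cells where most module genes dropped out. The score is
homogeneous of degree one in the expression values, zero when no module
gene is detected, and never decreases when a zero is replaced by a
positive value. An alternative variant, sum(x) * #nonzero / (2n), is
available via `formula="printed"`; the frequency-normalized form is the
default because only it matches the verbal definition of the score (the
two differ by a factor n/2). Gene matching is exact and case-sensitive.

## Spatial graphs and subgraphs

Spot coordinates (micrometres, continuous) give a pairwise Euclidean
distance matrix. Zero entries — the diagonal, and any duplicate-spot
pairs — are replaced by the constant 1,000 so no spot is its own
neighbor; duplicate-coordinate pairs additionally trigger a warning since
the rule conflates them with self-distances. The adjacency threshold is
the smallest nonzero distance plus one unit (one micrometre for synthetic
data; whatever the coordinate unit is otherwise). A guard refuses
coordinate systems whose smallest spot distance exceeds 999, where the
zero-replacement constant would itself fall under the threshold. On a
hexagonal lattice with 100 µm pitch this construction links every
interior spot to exactly its six direct neighbors.

Subgraphs are n-hop neighborhoods (default 3) of query spots sampled
uniformly **with replacement**; neighborhoods are computed by
breadth-first search on the unweighted graph. Subgraphs with fewer than
15 nodes are dropped and resampled, up to a bounded number of attempts.
On the interior of a hexagonal lattice a 3-hop neighborhood has
1 + 6 + 12 + 18 = 37 nodes.

Node features are per-gene standardized log1p expression of the most
variable genes (variance of log1p values; full-scale Visium analyses
use 5,000 genes, the synthetic experiments all 200 simulated genes).
Genes with zero raw expression across a subgraph's nodes are masked to
zero there. Standardization statistics default to the sample's own spots
but should be pooled over the training collection in multi-sample
experiments: per-sample statistics would subtract each sample's mean
expression — exactly the between-sample signal a score regressor needs.

## GIN regressor

Three GIN convolution layers; in each, with self-loops added to the
adjacency before the forward pass,

    combine_v = (1 + eps) * x_v + sum_{u in N(v)} ReLU(x_u)

with eps a learnable scalar (initialized 0), followed by a two-layer MLP
(affine, ReLU, affine), batch normalization, LeakyReLU with negative
slope 0.2, and dropout 0.5. The final node embeddings pass through a
Xavier-uniform-initialized affine merge into a latent space (default
width 32; hidden width 64), global mean pooling produces one vector per
subgraph, and an MLP head

    h(x) = W2 . Dropout(BatchNorm(ReLU(W1 x + b1))) + b2

emits the scalar score. Training minimizes the plain mean absolute error
(L1) over mini-batches of 32 subgraphs with Adam (lr 1e-3, decayed
exponentially to 2% of its initial value across training; MAE gradients
are sign-valued, so the late-training learning rate bounds the
oscillation floor of the predictions). Batch normalization uses batch
statistics in training and running statistics in evaluation, making
eval-mode predictions deterministic; dropout is inactive in evaluation.

The network is implemented on a small in-package reverse-mode autodiff
engine over numpy (broadcast arithmetic, matmul, fixed-sparse matmul,
rectifiers, axis reductions) with a hand-written Adam. Correctness is
enforced by tests: per-operation finite-difference gradient checks, a
whole-model loss-gradient check on a two-node graph (relative error
< 1e-4), and equivalence with an independent dense per-node
re-implementation of the forward equations on graphs of up to five nodes
(within 1e-6 over 100 random parameter draws). Batched graphs are
processed block-diagonally; mean pooling is a sparse matrix with one row
per graph.

Evaluation: R² = 1 − SS_res/SS_tot between predictions and truth scores
(undefined and reported as missing when truth is constant), and the F1
score after binarizing both predictions and truth at the 0.41 cutoff with
high-neural as the positive class.

## Cell-composition estimation

Per-spot deconvolution scores d_jk (any non-negative abundance measure)
are min-max normalized to [0, 1] **globally** over the score matrix
(per-type normalization is a configurable alternative; the global reading
keeps relative magnitudes between cell types). Integer counts are

    C_jk = round(d'_jk * N_j / sum_k d'_jk)

with rounding half away from zero (banker's rounding would silently
change counts). Row totals match the nucleus count N_j only within the
rounding bound |sum_k C_jk − N_j| <= T/2 — e.g. three equal scores and
N = 10 give (3, 3, 3), total 9. An optional largest-remainder correction
(`conserve=True`, off by default to match the formula above) enforces
exact totals. Nuclei are mapped to their nearest grid point; per grid
point a multiset with C_jk copies of each type is padded or truncated to
the local nucleus count in largest-remainder order, shuffled with the
seed, and assigned one type per nucleus.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their arguments including the seed
(bit-reproducible), and every output respects its container's invariants
(betas in [0, 1], simplex rows summing to 1 within 1e-9).

**Reference atlas** — 25 components named after a whole-body cell-type
methylome atlas with one "cortical neurons" entry. Each component owns a
disjoint block of `block_width` CpGs hypomethylated (0.1) in it and
hypermethylated (0.9) elsewhere; remaining CpGs share a uniform baseline
carrying no compositional information. The block construction forces
identifiability (every column pair differs by >= 0.5 somewhere). Not
emulated: probe-level chemistry, array normalization artifacts,
correlated CpG neighborhoods.

**Bulk cohorts** — proportions drawn from a Dirichlet whose default
concentration has total mass 10 with the neuronal component's mass chosen
so the marginal Beta median equals 0.41; simulated cohorts therefore
straddle the low/high boundary the way the dichotomized reference cohort
does. Betas are atlas-times-proportions plus Gaussian noise truncated to
[0, 1] by clipping (the simplest noise model preserving both the range
and the NNLS forward model; beta-value noise in real arrays is
heteroscedastic, which is not emulated). Default noise sd 0.005.

**Single cells** — background expression is exponential (scale 0.3) on a
log-normalized scale; module genes gain a fixed offset (1.5) in cells of
the targeted type; every entry is independently zeroed with the dropout
rate (default 0.3). Not emulated: library-size variation, gene-gene
correlation beyond the planted modules.

**Spatial samples** — spots on a hexagonal lattice (odd rows offset by
pitch/2, rows pitch·√3/2 apart; default pitch 100 µm, the Visium
geometry, which yields the maximum-six-neighbors property). Each spot has
a latent composition over seven cell types (NPC-like, AC-like, OPC-like,
oligodendrocyte, neuron, immune, MES-like). The *total* neural-lineage
abundance is exactly 0.15 + 0.7·score at every spot; long-wavelength
sinusoidal fields (8 pitches) redistribute abundance within the
neural-lineage group and within the non-neural group but never across
them. At noise_sd = 0 the expression therefore carries a noise-free
score signal while still varying smoothly from spot to spot — the
designed regime for the GIN experiment; with noise_sd > 0, Gaussian
expression noise (clipped at zero) degrades it. Expression is
composition times a gamma-distributed signature matrix with
marker-gene blocks. Nuclei (1 + Poisson(4) per spot by default) scatter
uniformly in a 27.5 µm disk around the spot centre. Not emulated:
H&E imagery, segmentation errors, spot swelling, within-spot expression
gradients.

Because the score link is exact by construction, a high held-out R² in
the GIN experiment demonstrates that the architecture, features and
training loop can extract a recoverable spatial signal — not that real
tissue is this clean. Equivalently, the DMP and deconvolution suites
show correct statistical behavior under their assumed models, not
robustness to array artifacts.

## Experiment scales and defaults

The packaged GIN experiment uses 20 samples on 12×12 lattices, 100
3-hop subgraphs each (~2,000 total), 200 genes, noise-free expression,
an 80/20 subgraph split, and 80 training epochs — sizes chosen so the
full experiment runs in a few minutes on one CPU while keeping enough
samples on both sides of the 0.41 cutoff for a meaningful F1. Sample
scores are drawn half from U[0.20, 0.38] and half from U[0.44, 0.70]:
the cohort spans the published score range, both classes are populated,
and no sample sits on the cutoff itself — by construction a cohort
dichotomized at its own median has no mass exactly at the boundary.

Known limitations: integer cell counts quantize coarsely at realistic
Visium nucleus densities (~5 per spot), capping the achievable
count-vs-truth correlation around 0.86 there (the recovery property is
demonstrated at ~13 nuclei per spot); the NNLS recovery floor is set by
the atlas's conditioning as derived above; and the GIN experiment's
per-sample score labels mean subgraphs from one sample share a target,
so its R² measures within-cohort score recovery, not generalization to
unseen patients.
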