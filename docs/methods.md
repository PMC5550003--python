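# Methods

## The model

A motif of length `l` is classically described by a position-specific
weight matrix (PSWM): independent letter probabilities per position. The
dinucleotide weight tensor (DWT) drops the independence assumption and
allows a dependency between *any* pair of positions, without choosing which
pairs in advance.

Given an aligned set `S` of `n` binding sites, each alignment column is
scored by its Dirichlet-multinomial marginal likelihood

    P(S_i) = Γ(4λ) / Γ(n + 4λ) · Π_a Γ(n_ia + λ) / Γ(λ),

and each column pair by the analogous 16-category marginal with pseudocount
λ′ = λ/4 (prior consistency between the mono- and di-nucleotide
descriptions forces exactly this ratio). The default λ = 1/2 is the
Jeffreys prior; results are insensitive over 0 < λ ≤ 1, and λ is exposed
as a parameter rather than hard-coded. The evidence for a dependency
between positions i and j is the ratio

    R_ij = P(S_i, S_j) / (P(S_i) P(S_j)),

which behaves like `exp(n·I_ij)` for large `n` (`I_ij` the empirical
mutual information) — so with hundreds of sites and a strongly coupled
pair, `log R` reaches several hundred.

Any factorization of the joint column probability into pairwise
conditionals corresponds to a spanning tree of the position graph, with
probability `Π_i P(S_i) · Π_(i,j)∈tree R_ij`. Rather than selecting one
tree, the DWT marginalizes over all `l^(l−2)` of them; by the weighted
matrix-tree theorem the sum equals any principal minor determinant `D(R)`
of the Laplacian of `R`. The predictive probability of a new segment `s`
is then

    P(s|S) = Π_i (n_i,s_i + λ)/(n + 4λ) · D(R(s,S)) / D(R(S)),

the PSWM predictive times a ratio of determinants, where `R(s,S)` augments
the counts with `s` at weight one (a single orientation; the strand
symmetry of sequence scoring below handles orientation). The predictive is
exactly normalized, and when the pair counts carry no dependency
information the ratio is identically 1 and the DWT *is* the PSWM — the
model's built-in protection against over-fitting. (Note the reduction is
exact when the augmentation increments vanish, i.e. for the empty model or
uniform columns; a model holding a single concrete site does carry
pairwise information about that site, and the predictive correctly
reflects it.)

The ADJ variant restricts dependencies to adjacent positions; the chain is
then the unique spanning tree and the predictive factorizes as a
first-order Markov chain of Dirichlet predictives. At `l = 2` ADJ and DWT
coincide. The constant `1/|π|` tree-count prefactor is dropped throughout:
only normalized predictives and likelihood ratios are ever used.

## Numerical evaluation of the tree sum

`R` entries span hundreds of orders of magnitude in realistic fits, and LU
factorization of the rescaled Laplacian minor fails there: for a strongly
coupled pair the pivot update `d_j − R_ij²/d_i` subtracts nearly equal
large numbers whose difference carries the remaining tree weights
(observed: negative determinants at condition number ~1e21). The
determinant is therefore computed by **subtraction-free graph
elimination** (star–mesh reduction): eliminating node k multiplies the
determinant by the pivot `d_k = Σ_j W_kj` (a sum of positive weights,
including the edge to the removed "ground" node) and adds `W_ki W_kj/d_k`
to each remaining weight. Every operation is a sum, product, or quotient
of positive numbers, so each pivot keeps full relative precision at any
dynamic range; in exact arithmetic the procedure is Gaussian elimination
on the minor and reproduces `D(R)` identically. A uniform rescaling
`exp(logR − c)` is applied up front and re-applied before each step
(dividing the remaining weights by `f` scales each of the `r` remaining
pivots by `1/f`, compensated exactly by `r·log f`), so nothing can
overflow. Against brute-force Prüfer enumeration over `logR ∈ [−20, 20]`
(17 orders of magnitude within one matrix) the worst observed relative
error of `log D` is ~6e−15; a numerically disconnected graph raises an
explicit instability error instead of returning garbage.

Edge posteriors `P(i,j)` — the weighted fraction of spanning trees
containing edge `(i,j)` — use the contraction identity
`P(i,j) = R_ij · D(G/ij) / D(G)`, both determinants by the same stable
elimination (`O(l^5)` total, paid once per model, not per segment). The
textbook effective-resistance route through the inverse Laplacian minor
cancels catastrophically for near-certain edges and is not used. The upper
triangle of `P` sums to `l − 1` to ~1e−12.

Per-segment DWT scoring never rebuilds counts: the augmentation only
shifts each `logR_ij` by a predictive increment
`log[(n_ab+λ′)(n+4λ) / ((n_a+λ)(n_b+λ))]` that is tabulated once per
model, so scoring m segments is one gather plus m batched `O(l³)`
eliminations (chunked for cache locality).

## Energies, EM, and the thermodynamic likelihood

The binding energy of a segment is its log-odds against a 0th-order
background fitted to the input set, `E(s) = log P(s|M) − log P(s|B)`
(units kT). A longer sequence's energy log-sum-exps `E(s)` over all
`L_S = 2(|S|−l+1)` segments on both strands; scoring is strand-symmetric
by construction. An N contributes 0 to both the model and background terms
and suppresses any pair increment it touches, keeping `E` a log-odds with
the missing letter marginalized; an all-N segment has `E = 0` and an all-N
read has `E(S) = log L_S`.

Motif inference maximizes the probability of sampling the input sequences
from a large background pool in proportion to their binding probability in
the unsaturated (low TF concentration) limit, where the concentration
cancels:

    L(M, E0) = Σ_S log[(e^{E(S)} + L_S e^{E0}) / (1 + e^{E0})] + const.

Each EM iteration: (1) score all segments; (2) re-optimize the
non-specific energy `E0` as the root of `dL/dE0` — the derivative decays
to zero (and rounds to noise) toward +∞, so the root finder scans a
201-point grid over the bracket `[−50, 50]`, polishes every genuine sign
change with Brent's method, and keeps the candidate (or bracket end) with
the highest likelihood; (3) convert energies to per-segment binding
posteriors `P_b(s) = e^{E(s)}/(e^{E(S)} + L_S e^{E0})`; (4) accumulate
posterior-weighted dinucleotide counts (reverse-strand segments contribute
their reverse-complemented letters), which define the next model. The same
loop fits PSWM, ADJ, and DWT motifs — only the segment scorer differs — so
comparisons are on equal footing. Iteration 0 scores with the initial
PSWM, which is exactly the DWT with no pair evidence, so no initial pair
tensor is needed. Convergence: relative likelihood change below `tol`
(default 1e−6) or `max_iter` (default 200); the best-likelihood state is
returned. The count update is a fixed-point heuristic rather than a
provable minorizer of this likelihood, so a candidate update that
*decreases* L (observed only as ~1e−5-relative terminal dips near the
fixed point) is rejected and treated as convergence; the iteration trace
therefore records accepted, monotone steps. An optional multi-start mode reruns EM from Dirichlet-perturbed
initial counts (seeded, deterministic), a guard against the rare poor
local optimum.

`MotifEM` wraps this as a scikit-learn estimator (`fit`, `score_samples`,
`predict_sites`, `get_params`/`set_params`, trailing-underscore
attributes), composing with sklearn model selection.

## HT-SELEX likelihoods

For round data `n_t(S)`, selection is modeled as sampling proportional to
`e^{βE(S)}`; the likelihood gain per consecutive round pair over random
resampling is `N(t+1)(β⟨E⟩_{t+1} − log⟨e^{βE}⟩_t)` with count-weighted
averages. `dL(E, β)` is concave in β (log-convexity of the moment
generating function) and is maximized by bounded Brent search on
`[0, β_max = 5]` to 1e−8; the reported performance measure is `dL/N` with
`N = Σ_{t≥2} N(t)`. At β = 1, `dL` equals `L(E) − L0` from the explicit
selection likelihood; reads absent in the earlier round get
pseudo-frequency `1/(N(t)+U)` there (`U` = distinct reads), but the
tempered form needs no such handling and is the primary metric. Reads
shorter than the motif are padded with `⌊l/2⌋` N's per side. An
energy-stratified enrichment table (`log[f_{t+1}(E)/f_t(E)]` per energy
bin) provides the slope diagnostic: ideal tempered selection gives slope β.

## Evaluation

Decoys match the source sequences' lengths and pooled dinucleotide
composition via a fitted first-order Markov chain (composition preserved
in expectation; observed transition rows are used exactly, so degenerate
sources give degenerate decoys); an exact per-sequence dinucleotide-
preserving shuffle (random Euler path) is available behind a flag.
Precision–recall sweeps all distinct score thresholds with strict
`E > E_c` tie handling (tied scores enter and leave together); average
precision integrates step-wise over recall increments, which equals the
mean precision at the positives and makes results bit-reproducible. The
randomized-dependency control marginalizes a fitted DWT to its PSWM,
resamples the same number of sites independently per position, rebuilds a
DWT, and reports its edge posteriors stratified by adjacency — a null for
the dependency detector.

## Synthetic data

`PlantedModel` realizes exactly the generative family the DWT assumes: a
forest over positions with root marginals and per-edge conditional tables,
sampled ancestrally. Embedded "peaks" place one site per background
sequence (default 200 bp, composition A/T-rich 0.3/0.2/0.2/0.3) at a
uniform offset and strand. The default fixtures are: an independent
(null) motif; one distal coupled pair; the two-edge fixture with a distal
pair (positions 2, 9) and an adjacent pair (3, 4) in an `l = 10` motif;
and a first-order chain. Coupled positions are two-letter 50/50 —
invisible to a PSWM beyond their 1-bit marginal — with parent–child
agreement 0.9 for the one-edge and chain fixtures (≈0.53 bits of mutual
information per pair) and 0.95 for the two-edge benchmark fixture
(≈0.71 bits per pair), the latter chosen so the discrimination benchmark
sits inside the strong-coupling regime, i.e. the regime in which pairwise
structure contributes a held-out average-precision gain of at least 0.05
over the PSWM rather than hovering at its edge. The remaining positions
carry a 0.85-probability consensus letter, typical of well-defined TFBS
PWM columns — chosen so the benchmark operates in the strong-motif
regime, defined by ≥80% of training sites having their true offset/strand
recovered as the top-posterior segment —
below that, alignment ambiguity (not pairwise structure) dominates what
the fitted tensor records, and site-assignment noise induces spurious
dependencies between all positions. What the generator does *not* emulate:
peak-shape/coverage structure, multiple sites per peak, sequencing error,
phylogenetic conservation, and PCR amplification bias in SELEX — so
passing benchmarks demonstrate correct and well-conditioned inference
under the model's own assumptions, not performance on real ChIP-seq data.

## Problem sizes and numerical choices

The bundled studies use: 500 training peaks of 200 bp with an `l = 10`
motif (≈191k scored segments per E-step), 200 held-out peaks against 800
decoys, EM to relative tolerance 1e−4 capped at 25 iterations (the
likelihood is flat well before the cap; recovery statistics are stable
after ~10), 20 replicate seeds for recovery rates, and SELEX simulations
of 3 rounds × 10⁴ draws from a 500-sequence pool with β₀ = 0.3. Tree-sum
exactness is gated against enumeration at `l ≤ 6` (Prüfer sequences),
`logR ∈ [−20, 20]`, 200 random matrices.

Degenerate inputs: `l = 1` motifs bypass tree algebra (`D ≡ 1`); an empty
model scores uniformly; a numerically disconnected dependency graph, a
non-finite energy, or an EM posterior collapse raise explicit errors.
Ranking of edges for recovery statistics breaks posterior ties (saturated
at 1.0 for near-certain edges) by the dependency evidence `log R`,
deterministically.

## Known limitations

Motif length is fixed by the initial PSWM (no trimming/extension); no
multiple-motif mixtures; no phylogenetic information; the dilogo's arrow
orientation (away from the highest-information position of each forest
component) is a display convention, not an inferred causal direction; ADJ
shares the DWT's machinery but its chain factorization ignores the
`1/|π|` mixture constant, which cancels in every quantity reported here.
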