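# Methods

## Network construction

Each subject contributes either an ROI×time matrix or a symmetric
connectivity matrix. Time series are reduced to Pearson correlations and
Fisher-z transformed, `w_ij = arctanh(r_ij)`, which stabilizes variance so
matrices can be averaged across subjects for the group-representative tree.
Perfect off-diagonal correlations (duplicated series) are clamped to
±(1−10⁻⁷) with a warning rather than producing infinities; zero-variance
series are a hard error naming the offending ROI.

Weights are converted to distances `d_ij = 1/w_ij`. Edges with `w_ij ≤ 0` are
removed: negative functional couplings have no natural place in a
minimum-spanning backbone of *strongest* connections, and `w = 0` would make
the reciprocal undefined, so zero joins the removal rule. If the remaining
positive graph is disconnected the default is a loud error listing the
components — positively-connected correlation graphs at this scale virtually
always connect, so a silent fix would mask data problems. An opt-in
`repair=True` adds the minimum number of largest-|z| non-positive edges back
as tiny positive weights (huge distances) so they can only be used when no
positive route exists.

## MST and global metrics

The MST minimizes total distance, i.e. keeps the strongest backbone; it is
unique when weights are unique. Extraction uses Kruskal's algorithm (Prim is
provided as a cross-check and must agree on unique weights). Edges are fed to
the sorter in lexicographic index order, which makes tie-breaking on
degenerate inputs deterministic; a warning notes that uniqueness is then not
guaranteed.

Per tree the package reports:

| symbol | definition | star (n nodes) | path |
|---|---|---|---|
| L | mean hop distance over unordered pairs | 2(n−1)/n | (n+1)/3 |
| Lf | fraction of degree-1 nodes | (n−1)/n | 2/n |
| Th | L_leaf / (2·m·BC_max) | 0.5 exactly | → 0 |
| Dmax | maximum degree | n−1 | 2 |
| r | degree assortativity | −1 | — |
| κ | ⟨k²⟩/⟨k⟩ | n/2 | → 2 |

Path length uses hop counts, not summed 1/w distances: hop-L is scale-free
across subjects and is the convention of the MST comparison literature. It is
computed in O(n) from subtree sizes (an edge splitting the tree into parts of
sizes s and n−s lies on s(n−s) paths) and verified against explicit
shortest-path enumeration in tests.

Tree hierarchy deserves a note: no closed formula is universal in the
literature. We use Th = L_leaf/(2·m·BC_max) with *pair-normalized* betweenness
(raw pair count divided by (n−1)(n−2)/2), the convention under which a star of
any size scores exactly 0.5 and a long path decays like 2/(n−1). A sometimes
repeated claim that a line scores Th = 1 is inconsistent with the star = 0.5
anchor under any standard variant we know; we keep the star anchor.
Assortativity is Newman's degree–degree Pearson correlation over both edge
orientations and is reported as NaN where undefined (e.g. n = 2); NaNs are
excluded from group tests. κ is the second moment of the degree sequence over
the first.

## Nodal roles: local importance and connector index

In a tree, two kinds of nodes carry high betweenness: hubs (centres of
star-like modules) and low-degree *bridges* between hubs. Local importance

    li(v) = |{u ∈ Adj(v) : deg(u) ≤ deg(v)}| / |Adj(v)| + 1/n

lies in [1/n, 1+1/n]: 1/n when every neighbour out-ranks v (the 1/n term is a
baseline that shrinks with network size), 1+1/n when v dominates all
neighbours. Equal degrees count toward the numerator (the set definition is
inclusive). The connector index ci(v) = BC(v)/li(v) is therefore high exactly
for nodes routing much global traffic while being locally dominated — the
bridge profile — and zero if and only if the node is a leaf. Betweenness is
pair-normalized; only relative comparisons of ci are interpreted, and those
are invariant to the normalization choice.

Roles are classified on the group-representative MST (MST of the
element-wise mean Fisher-z matrix): hub if degree > mean + 2·SD over nodes,
connector if ci > mean + 2·SD. The SD is the population SD over the fixed
node set (at n = 164 the sample/population difference is negligible). A node
passing both thresholds is reported as `hub+connector` with a warning rather
than silently collapsed — empirically the sets do not overlap, but nothing
forbids it.

## Tree similarity and its permutation test

σ(a,b) = |E_a ∩ E_b|/(n−1) is a bounded symmetric similarity kernel with
σ(a,a)=1; (n−1)·σ is an integer edge count. The test statistic is the
unweighted mean of the two within-group mean overlaps (a size-weighted option
exists; both coincide for equal groups). The null is built by shuffling group
labels with group sizes fixed, and the one-sided p-value is the fraction of
permutations whose statistic is ≥ the observed one, with the observed
arrangement *not* added to the null — the convention deliberately divides by
exactly the number of permutations. Consequently p = 0 is possible at finite
n_perm; calibration at α = .05 is verified by simulation rather than by
construction.

## Degree-distribution fitting

The representative tree's degree histogram (small integer support, no
binning) is fitted to power-law `P(k) ∝ k^(−α)`, exponential `P(k) ∝
e^(−αk)` and exponentially truncated power-law `P(k) ∝ k^(α−1)e^(−k/kc)`
forms — the truncated exponent is negative; a positive exponent would be
non-normalizable and is inconsistent with decaying empirical parameter
values (α ≈ 1.3–2.4, kc ≈ 1.3–2.3). Each family carries a free scale
constant. Fitting is least squares of log P(k): exact linear algebra for the
one-shape-parameter families, nonlinear least squares for the truncated one,
seeded from both nested solutions so it can never fit worse than the power
law it contains. R² is computed on the fitted (log) scale by default; a
linear-scale mode is available since published toolbox conventions vary and
cannot be pinned down. Model selection is argmax-R² with a parsimony
tie-break: within 10⁻⁶ of the best R², the simpler family wins (otherwise the
nesting family would win every exact tie by construction).

## Group inference

Covariate adjustment inside a permutation test is not uniquely defined; we
adopt Freedman–Lane, the standard residual-permutation scheme: regress the
outcome on the nuisance design (intercept + age, gender, head motion),
permute the residuals, add them back to the nuisance fit, re-residualize and
recompute the statistic (difference of adjusted group means). The two-sided
p uses (1 + #{|null| ≥ |obs|})/(1 + n_perm); the +1 smoothing guarantees
p > 0 and differs intentionally from the similarity test's literal /n_perm
convention — both are documented where they appear. A `scheme="raw"`
label-permutation fallback is provided. Families of tests (6 global metrics;
n regions × 2 nodal metrics) are corrected by Benjamini–Hochberg step-up FDR
as single families.

Partial correlations residualize both variables on the controls and use
t-based p with df = n − #controls − 2. Cohort matching is 1:1
minimum-total-|Δage| bipartite assignment (Hungarian algorithm) within each
gender stratum, so matched groups have identical gender ratios by
construction.

## Path models

Full structural-equation machinery is intentionally avoided: mediation is
estimated by product-of-coefficients on standardized variables — a from
m ~ x + covariates, b and c′ from y ~ m + x + covariates — with percentile
bootstrap CIs for the indirect effect a·b (subjects resampled with
replacement; batched normal-equation solves keep 5,000 resamples cheap).
Significance is the CI excluding zero, which permits asymmetric intervals;
no posterior-predictive fit index is produced. The identity c = c′ + a·b
holds exactly for OLS on standardized data and is asserted to machine
precision. Moderation is the OLS interaction test y ~ x + g + x·g +
covariates.

Four model configurations mirror the intended study design: (1) mediation
age → leaf fraction → cognition in controls; (2) the same pooled across
groups; (3) age → leaf fraction → three symptom domains in patients; (4)
moderation of the age → leaf-fraction slope by group. Head motion and gender
are covariates everywhere; medication only in the patient-only model (it is
undefined for controls). Leaf fraction is the mediator because the six
global metrics are strongly intercorrelated; an optional variant replaces it
with the first principal component of the six standardized metrics, oriented
to correlate positively with Lf.

Cognitive batteries are reduced to working-memory and executive-function
composites (standardized mean of the standardized assigned tests). An EFA
mode (maximum-likelihood extraction, oblimin rotation, regression-method
scores) is available for symptom batteries whose factor structure is not
fixed a priori.

## Synthetic cohort generator

The generator emulates the study conditions, not raw BOLD data. Defaults: two
groups of 40, 164 nodes, 150 timepoints, ages uniform on [21, 55], gender
29:11 M:F per group, log-normal head-motion with a patient-group upward shift
(means ≈ 0.40 vs 0.58), medication log-normal for patients only, and six
cognitive tests with group-specific means drawn from a typical schizophrenia
battery (shared within-domain latent, loading 0.7).

Trees grow by sequential attachment: each new node attaches to the current
maximum-degree node with probability `star_bias` and otherwise to the most
recently added node. This spans the continuum exactly — bias 0 is a pure
path, bias 1 a pure star — with expected leaf fraction monotone in between.
(A mixture with *uniform* random attachment cannot reach the path limit,
which is why path-extension is the second component.)

Subject covariance is identity plus `edge_strength` (default 0.6) on planted
tree edges and `baseline` (default 0.1) elsewhere, shrunk toward the identity
until positive definite; shrinkage scales all off-diagonals uniformly, so
tree edges keep strictly dominating and the noise-free MST recovers the
planted tree exactly. Time series are zero-mean Gaussian draws from this
covariance with no temporal autocorrelation — the pipeline consumes only
zero-lag correlations, so autocorrelation would add realism without changing
any consumed statistic. What the generator does **not** emulate: hemodynamics,
motion artifacts, spatial ROI geometry, negative-correlation structure, or
heavy-tailed noise. Passing tests therefore demonstrate correctness of the
estimators under the planted model, not robustness to fMRI artifacts.

The mediation chain is planted as star_bias_i = base + group_offset·1[patient]
+ a·z(age_i) + ε (clipped to [0, 1], clipping recorded per subject so
linearity checks can exclude clipped cases), and negative-symptom score
= b·z(Lf_i) + c′·z(age_i) + ε on the standardized scale. Defaults a = 0.10
(bias units per SD of age), b = 0.5, c′ = 0: published evidence reports a
clearly positive indirect path with a total age–symptom effect statistically
indistinguishable from zero, so the direct path defaults to zero and the
total effect is carried by the chain. Because the tree realization given
star_bias is stochastic, the a-path holds in expectation (sign and
Monte-Carlo tolerance), while b and c′ are exact OLS solutions of the
generative equation at zero symptom noise.

## Numerical and design choices

- Random streams: one `numpy` Generator per entry point; the pipeline splits
  a root seed per stage via `SeedSequence`, so reruns are bit-identical.
- Degenerate inputs: n < 3 makes betweenness/Th undefined (error); constant
  metric columns are excluded from correlation matrices as NaN; zero degree
  variance yields no hubs plus a warning.
- Test problem sizes are scaled-down study conditions chosen for tight Monte
  Carlo behaviour at desk scale: calibration suites use 400 null replicates
  at n_perm = 500; power checks use the study's 40+40 subjects with 60-node
  trees; mediation coverage uses 200 replicates of n = 2000 with 500
  bootstrap resamples; the end-to-end check uses 30+30 subjects, 80 nodes,
  400 timepoints. Production defaults remain 10,000 (similarity), 5,000
  (group tests) and 5,000 (bootstrap).

## Known limitations

- Published headline numbers from real cohorts depend on an fMRI
  preprocessing chain (realignment, normalization, nuisance regression,
  filtering) that is out of scope here; this package starts at time
  series/connectivity matrices.
- R²-based degree-fit selection always favours the nesting family up to the
  parsimony tie-break; likelihood-based selection (e.g. Clauset-style
  maximum-likelihood power-law fitting) is deliberately not implemented.
- The mediation estimator is regression-based and makes no causal claim
  beyond the planted-model semantics; latent outcomes are approximated by
  factor scores/composites rather than full SEM.
- The similarity test supports exactly two groups; exchangeability blocks
  are not supported in the permutation machinery.
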