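# Methods

## Network construction

A subject's connectome is a pair of square symmetric matrices over the
parcellation nodes: fiber numbers (FN, nonnegative integers) and FA
weights in [0, 1], both with zero diagonal and identical support.
An edge is retained iff FN **strictly** exceeds the threshold (default
3); an edge supported by exactly 3 streamlines is removed. Hemisphere
membership comes from the parcellation table, never from index parity,
so other atlases can be supplied; the packaged `aal90.tsv` follows the
AAL convention of alternating left/right regions. The k-th left and
k-th right region in parcellation order are treated as homotopic — the
parcellation validator enforces identical abbreviation sequences in the
two hemispheres, which makes the pairing explicit rather than
positional luck. Thresholding and hemisphere splitting commute (both
are entrywise/blockwise); the pipeline thresholds first.

Input matrices asymmetric beyond 1e-8 are an error, not silently
symmetrized: an asymmetric "connectome" indicates an upstream bug that
averaging would hide.

## Graph measures

Topological distance between connected regions is the reciprocal FA
weight — the standard convention for FA-weighted connectomes, under
which a strong tract is a short path. Since weights are ≤ 1, every
finite distance is ≥ 1 and all efficiency measures lie in [0, 1].

* **L_p** is the mean shortest-path distance over *connected* ordered
  pairs. Hemispheric graphs can fragment after thresholding; excluding
  unreachable pairs keeps L_p finite, the exclusion count is tracked
  (`n_connected_pairs`), and disconnection itself is captured by E_g,
  which uses 1/∞ = 0. The alternative (infinite L_p on any
  fragmentation) was rejected as uninformative.
* **E_g** and **E_nodal(i)** are means of reciprocal distances over
  all ordered pairs / over pairs involving node i. By construction
  E_g = mean_i E_nodal(i) identically; the test suite asserts this to
  1e-12 on every computed network.
* **C_p** uses the Onnela geometric-mean weighted clustering with
  weights normalized by the network-wide maximum — the convention of
  the common connectome toolboxes. Nodes of degree < 2 score 0 and
  stay in the average. The Barrat (arithmetic-mean) form was considered
  and rejected to stay consistent with toolbox behavior.
* **E_loc** is the mean over nodes of the global efficiency of the
  neighborhood subgraph (neighbors of i with their *original* weights,
  i excluded); degree < 2 contributes 0. Weights are deliberately not
  renormalized per neighborhood.

Shortest paths are computed with Dijkstra (scipy.sparse.csgraph);
correctness is checked in the tests against exhaustive simple-path
enumeration on graphs of ≤ 7 nodes and against networkx's independent
clustering implementation.

## Small-world normalization

γ = C_p/C_rand and λ = L_p/L_rand use the arithmetic mean of C_p and
L_p over an ensemble of (default 100) matched random networks; σ = γ/λ.
σ is not given a formula in most applied reports; γ/λ is the standard
definition and is adopted here explicitly.

"Matched" means: topology randomized by Maslov–Sneppen double-edge
swaps (attempts = 10 × edge count; swaps creating self-loops or
multi-edges rejected), then the observed weight multiset randomly
permuted onto the rewired edges. This preserves the degree sequence
and the weight distribution exactly — both are asserted on every
rewiring — but *not* the weight–degree correlation; strength-preserving
nulls are out of scope and the choice is stated rather than implied.
Null networks are not forced to be connected; the connected-pairs
convention for L_p handles fragmented nulls.

For the default template, hemispheric networks show γ ≈ 1.8–2.0 with
λ ≈ 1.04–1.12. A λ a few percent above 1 is intrinsic to small-world
organization (the real network's paths are slightly longer than its
rewired nulls') and matches the range typically reported for structural
connectomes; λ is statistically indistinguishable from 1 only in the
degenerate case where the input is itself a random network.

## Asymmetry score

AS(X) = 100·(X_R − X_L)/(X_R + X_L): antisymmetric under hemisphere
exchange, scale-invariant, bounded in (−100, 100) for positive inputs,
positive = rightward. L_p enters as-is, so its AS flips sign relative
to efficiency-type metrics; this is a plausibility check in reports,
not an identity, and is not asserted. Region pairs with X_R = X_L = 0
(a region isolated in both hemispheres) have undefined AS: the value
becomes missing, is logged per region, and propagates through the
statistics by pairwise deletion with per-test n reported.

## Statistical battery

The two-level within-subject factor admits an exact sum/difference
decomposition: the group effect is OLS of the subject mean (L+R)/2 on
group + covariates; the hemisphere main effect and group×hemisphere
interaction are OLS of the difference R−L on intercept + group +
covariates (intercept → hemisphere, group coefficient → interaction).
Each F is reported as the squared regression t with (1, residual) df.
This is algebraically the mixed ANOVA for two levels; the tests verify
agreement with `pingouin.mixed_anova` on balanced designs. With
unbalanced groups the implementation tests *unweighted* marginal means
(effect-coded group, SPSS Type-III style) — classical weighted-means
sums of squares differ there, which is a documented convention, not a
discrepancy.

Coding: age mean-centered; gender and group effect-coded ±1/2;
age×gender formed after centering, so the difference-regression
intercept estimates the grand hemisphere effect. Two-sample t-tests
are pooled-variance Student (df = n₁+n₂−2), not Welch, matching the
reporting convention of the field. Bonferroni corrects the regional
family (m = number of regions; significant iff p < α/m, adjusted
p = min(1, m·p)). Partial correlations residualize both variables on
the covariates and correlate the residuals; the Spearman variant
rank-transforms *first* and then residualizes, treating the two sides
symmetrically (residualize-then-rank was rejected as asymmetric between
x and y). Correlations with clinical scores are computed in patients
only and left uncorrected, reflecting their exploratory role; df =
n − 2 − #covariates.

A Pearson χ² utility (no continuity correction) is provided for
gender tables.

## Synthetic world

The generator's defaults *are* the reference study design, and are not
tuned to test outcomes:

| parameter | default | rationale |
|---|---|---|
| cohort | 49 BD / 61 NC | reference case-control sizes |
| ages / education | 21–50 / 11–19 y | reference cohort ranges |
| regions | 45 per hemisphere | AAL-90 |
| template topology | ring lattice, rewiring p = 0.1 | small-world by construction (γ > 1, λ ≈ 1 must hold in kind) |
| edge density | 0.30 | typical thresholded-connectome density |
| FA weights | Beta(4, 6) | concentrates near 0.4, typical tract FA |
| FN mean scale | 60 | streamline counts in the tens; template edges comfortably clear FN > 3 |
| subject FA noise | SD 0.03 | small relative to weight scale |
| δ_right (controls / patients) | +0.05 / 0 | modest rightward control asymmetry, symmetric patients |
| spurious edge rate | 0.05 | FN ∈ {1,2,3} noise edges the filter must remove |
| clinical link | ROL nodal-efficiency AS → YMRS, slope 2.9, intercept 11.9, noise SD 10.7 | YMRS ≈ 12 ± 11; slope set once from a pilot SD(AS) ≈ 0.9 so the implied population correlation is ≈ 0.24 |

Subject FA = clip(template × multipliers + N(0, noise_sd), 0.01, 1) on
the template support; FN ~ Poisson(60 × template FA), and an edge whose
count draw is 0 vanishes for that subject, keeping FA and FN supports
identical. Nodal multipliers act per endpoint (an edge between two
affected regions is multiplied twice). Asymmetry is injected
multiplicatively on weights, not topology, because the analyzed
networks are FA-weighted and efficiency responds monotonically to
weights. Seeding: subject i draws from `default_rng([seed, i])`,
metadata from `default_rng([seed, n_subjects])`, the template from
`default_rng([seed, 2^30])` — reproducible, independent streams.

What the generator does **not** emulate: spatial embedding and
distance-dependent connection probability, hub/rich-club structure,
realistic FA spatial covariance, medication or illness-duration
effects (recorded as placeholders only), or any property of raw
diffusion images. A green simulation test therefore establishes that
the pipeline recovers effects of the injected kind at the stated
sizes — not that any particular empirical claim about real cohorts is
reproduced.

## Numerical conventions

Metric comparisons in tests use absolute tolerance 1e-9 (1e-12 for
oracle equivalence); input symmetry tolerance 1e-8; zero-denominator
asymmetry returns NaN with a warning rather than raising, because one
isolated region should not abort a cohort run; rank-deficient designs
raise with the collinear columns named; constant-after-residualization
detection uses a relative tolerance (1e-10 of the input scale) so exact
linear dependence is caught despite floating-point rounding.

## Known limitations

* Only FA-weighted analysis; no binarized or inter-hemispheric
  networks.
* Null models preserve degree and weight distribution, not strength
  sequences.
* The repeated-measures GLM covers exactly one within-subject factor
  with two levels; it is not a general mixed-model engine.
* Calibration and power figures in the acceptance suite are properties
  of the synthetic world at its stated parameters; they transfer to
  real data only to the extent the noise model does.
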