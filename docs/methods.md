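# Methods

## The measurement problem

Nominal (discrete/attribute) assortativity summarizes how categorical
groups mix in a network.  Given the B×B mixing matrix **e**, where
`e_ij` is the fraction of edges running from group *i* to group *j*,

    r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i),

with `a_i = Σ_j e_ij` and `b_i = Σ_j e_ji`.  The coefficient is +1 when
every edge is intra-group, 0 when the diagonal matches the product of
marginals, and negative when inter-group ties dominate.

The coefficient has two blind spots that this package quantifies and
repairs:

1. **Group-size bias.**  A small group has quadratically fewer
   same-group pairs to draw from, so even a strongly homophilous
   minority contributes little diagonal mass.  With symmetric mixing
   tendency h = 0.8, r ranges from 0.6 (equal groups) down toward 0 as
   the minority fraction f₀ → 0, at *fixed* mixing.
2. **Asymmetry blindness.**  r is one number; opposite group tendencies
   can cancel.  On the locus h₀₀ = 1 − h₁₁, r = 0 exactly for every
   group split, even when the minority is strongly homophilous and the
   majority strongly heterophilous.

## Model

The random homophily network model (a two-parameter stochastic block
model in mixing-tendency form): each node belongs to group *i* with
fraction `f_i`; a group-*i* node tends to connect to group *j* with
probability `h_ij`, row-stochastic, so `h_ij = 1 − h_ii` for two
groups.  The probability mass of an i→j edge is

    p_ij = f_i f_j h_ij,      e_ij = p_ij / T,  T = Σ_ij p_ij.

The expected mixing matrix is asymmetric whenever h₀₀ ≠ h₁₁ — the
directed (formation-orientation) accounting is retained in all closed
forms because it is what makes the zero locus exact.

Closed forms implemented (`mixkit.analytic`):

* `analytic_r(f0, h00, h11)` — r of the expected matrix, written out in
  scalar form with row-sum × column-sum marginals.  Reduces to
  `h00 + h11 − 1` at f₀ = 0.5; vanishes identically on h₁₁ = 1 − h₀₀.
* `analytic_r_adj(h00, h11) = h00 + h11 − 1` — the adjusted coefficient
  is independent of f₀ (adjusting the expected matrix leaves h/2).

### A note on the marginal convention

For a symmetric mixing matrix, Σ a_i b_i equals the sum of squared row
sums, and some presentations collapse it accordingly.  The two forms
diverge for asymmetric matrices, and only the row-sum × column-sum form
makes r vanish exactly on the asymmetric zero locus.  This package uses
row × column everywhere; for undirected empirical matrices (always
symmetric) the choice is invisible.

## The adjustment

`adjust` divides each entry by `f_i f_j` and renormalizes to sum 1:

    ê_ij ∝ e_ij / (f_i f_j).

The renormalization step is required for ê to be a proper mixing matrix
(and is what makes the published empirical r_adj values reproducible
from their printed counts); the unnormalized quotients are available via
`normalize=False` for inspection.  With equal group fractions the
adjustment cancels exactly, so r_adj = r.

## The asymmetry estimator

Inverting the model's diagonal with raw intra-group edge fractions
`e₀₀ = E₀₀/E`, `e₁₁ = E₁₁/E` (note: *not* the half-weight matrix
entries) and the two-group complement rule gives a closed form for the
normalizer,

    T = 2 f₀ f₁ / (1 − e₀₀(1 − f₁/f₀) − e₁₁(1 − f₀/f₁)),

and then `h₀₀ = e₀₀ T / f₀²`, `h₁₁ = e₁₁ T / f₁²`.  The inversion is
algebraically exact on expected model fractions.  The denominator is
provably positive whenever E₀₀ + E₁₁ ≤ E, so the defensive
"inconsistent counts" error can only trigger on invalid inputs.
Estimates outside [0, 1] are flagged (`out_of_range`), never clipped:
an out-of-range value is evidence that the assumed generative topology
does not fit, and hiding it would hide the misfit.  The inversion
assumes random (ER-like) tie formation; a scale-free variant would need
a different edge-mass derivation and is not provided (`model="er"`
only).

## Generators

### ER-homophily

Proposals are drawn as (uniform source, uniform target) and accepted
with probability `h[g_src, g_tgt]`; generation stops when `m_edges`
edges are accepted.  Two deliberate implementation choices keep the
realized block composition exactly proportional to `p_ij = f_i f_j
h_ij` at any network size — the property every closed form assumes:

* **Block-level materialization.**  An accepted proposal fixes only the
  group block; the concrete edge is a uniformly drawn not-yet-used pair
  within that block.  Within a block all pairs are exchangeable under
  the model, and this removes the bias that discarding duplicate
  proposals would otherwise introduce (duplicates are more common in
  blocks whose pair pools are filling fastest, i.e. exactly the
  high-tendency blocks; at 500 nodes and 2000 edges that bias is
  already ≈ −0.02 in mean r at f₀ = 0.1, h = 0.8).
* **Self-inclusive target draw.**  The target draw includes the source
  node, with a same-node proposal counting toward the intra-group
  block.  Excluding it would give intra-block proposal mass
  n_i(n_i − 1) rather than n_i², an O(1/n) distortion of p_ij.

A proposal whose block has no unused pairs left consumes a step without
producing an edge; if the quota is unreachable (e.g. h = 1 with too few
intra-group pairs) generation fails after a bounded number of proposals
with a progress report.  Inter-group edges are stored ordered
(source, target), so ensembles can score either the symmetrized
("undirected") mixing matrix — what any observer of the bare network
sees — or the formation-orientation ("formation") matrix.  The
distinction matters on the asymmetric zero locus: formation accounting
gives mean r ≈ 0 there, while the symmetrized matrix reports a slightly
negative value (≈ −0.066 at f₀ = 0.1, h₀₀ = 0.8, h₁₁ = 0.2) because
symmetrization changes the marginals.  Both behaviors are asserted in
the test suite.

### BA-homophily

A growing scale-free variant: each group is seeded with its own
(m+1)-clique, and every arriving node connects to m distinct existing
nodes with probability ∝ `h[g_new, g_tgt] · degree(tgt)`.  Per-group
seeding (rather than one mixed clique) is chosen so that fully
homophilous parameters (h = 1) grow two disconnected homophilous
components with no inter-group edge at all.  If every
homophily-weighted degree vanishes the degree factor is dropped, and
failing that the choice is uniform.  This model is exercised
qualitatively (neutral mixing → r ≈ 0; minority imbalance →
r_adj > r); no closed forms are claimed for it.

### Ensembles and seeding

`ensemble` derives per-run seeds once from a master seed
(PCG64 stream), so results are reproducible end to end.  When several
parameter settings are compared (as in the calibration tests), each
setting gets an independently spawned child seed — reusing one stream
across settings would correlate their fluctuations and make a single
unlucky draw fail many comparisons at once.

## What the synthetic data does and does not emulate

The generators produce simple, unweighted, self-loop-free networks with
exactly the model's expected group mixing, fixed group counts ⌊n·f⌉,
and (for ER) a fixed edge budget.  They do not emulate degree
heterogeneity within groups (ER), clustering, weighted or repeated
interactions, temporal structure, or attribute noise.  Calibration
results on them validate the estimators under the model's own
assumptions; on real networks the ER inversion is only as good as the
random-mixing assumption, which should be checked against the degree
distribution before trusting ĥ.

## Numerical choices and problem sizes

* Mixing matrices are validated to sum to 1 within 1e−9 at
  construction; closed-form identities are tested at 1e−10..1e−12.
* Calibration runs use networks of 500 nodes and 2000 edges with
  60-run ensembles (300 nodes for the asymmetric-locus checks with 150
  runs) — large enough that sampling error per point is ~0.005–0.01 on
  r, small enough that the full suite runs in seconds.
* Group ordering is stable and minority-first (ties broken
  lexicographically by category name), so index 0 is always the
  minority.
* Published empirical counts are bundled with f₀ as printed (2
  decimals); the regression tolerance ±0.01 absorbs that rounding.
* Estimator edge cases: a network with no inter-group edges still
  inverts (the normalizer stays positive); B ≠ 2 is rejected.

## Known limitations

* The asymmetry estimator is two-group and ER-only by construction.
* The BA-homophily model is a best-effort qualitative companion; its
  mixing matrix has no closed form here.
* Undirected empirical data cannot reveal formation orientation, so on
  (or near) the zero locus the measured r and r_adj of a genuinely
  asymmetric process are small and negative, not exactly zero; use the
  estimator, which needs only E, E₀₀, E₁₁ and f₀, to detect the
  asymmetry itself.
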