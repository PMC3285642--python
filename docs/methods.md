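# Methods

## The analysis problem

A fixed-roster (sociometric) coalition survey yields, per wave, an n×n
binary directed matrix A with A[i,j] = 1 when member *i* reported a
connection to member *j*, plus member attributes (sector, city, tenure) and
binary outcome items.  `sectornet` computes the structural, sector-block and
member-level statistics of such data and tests whether intersectoral
connectivity predicts collaboration outcomes, using permutation inference
throughout because the n members are one interacting system, not an i.i.d.
sample.

## Definitions and conventions

* **Arc direction.** A[i,j] = 1 means *i reported* j; out-degree is the row
  sum.  Self-ties are structurally excluded.  Non-respondents are absent
  from the matrix entirely: the data model covers respondents only, and
  ties reported toward non-listed actors are out of scope.
* **Density** = arcs / n(n−1), requiring n ≥ 2.
* **Reciprocity.** Default is dyad-based — mutual dyads over dyads with at
  least one arc — matching the verbal definition "reported by both members
  of a pair"; the arc-based variant (arcs in mutual dyads over all arcs) is
  available and the choice is echoed in every report.  Undefined (NaN, with
  a warning) on an empty network.
* **Degree.** `total_degree` is union degree: the number of distinct alters
  with an arc in either direction, so a mutual dyad counts once per
  endpoint.  This is the "number of connections per member" used for node
  sizing in network maps; the in+out sum is recoverable from the degree
  table if wanted.
* **Centralization.** Freeman's statistic on out-degree with denominator
  (n−1)², which attains exactly 1 on the out-star and keeps the statistic a
  percentage on directed data; n ≥ 3 required.
* **Betweenness.** Raw (unnormalized) Freeman betweenness on directed
  geodesics, computed via networkx; unreachable ordered pairs contribute 0.
  Raw scores are reported because coalition evaluations conventionally
  print them unnormalized.
* **Block density** is computed on the union-symmetrized matrix — a tie
  between sectors counts regardless of which side reported it — with
  unordered-pair denominators: n_g(n_g−1)/2 within a sector (undefined for
  singleton sectors), n_g·n_h between.  The matrix is symmetric.
* **Block reciprocity** is directional: cell (reporting = G, target = H) is
  the share of arcs from G-members to H-members that were returned.  Cells
  with no arcs are NaN internally; the printed table renders them as 0 for
  fidelity to the conventional layout, but statistics never average the
  sentinel as a real zero — "no arcs" and "arcs, none returned" stay
  distinguishable.  The stored matrix has rows = reporting sector; the
  printed table transposes to columns = reporting sector, the layout these
  tables conventionally use.
* **Member intersectoral statistics.** Sector is a static attribute (role
  at entry).  Intersectoral and intrasectoral out-degree partition each
  member's out-degree; member reciprocity shares are arc-based by
  construction and NaN when the corresponding out-degree is 0.  NaN shares
  are excluded from means; where a regression needs a complete vector they
  are coded 0 (a member reporting no intersectoral ties has no reciprocated
  ones), and that recoding is logged.

## Permutation regression

Point estimates are ordinary least squares on a design of intercept, one
focal predictor (intersectoral out-degree *or* intersectoral reciprocity —
never both, see the screen below), city dummies (reference Boston, the
largest city), an original-member indicator, and sector dummies (reference
Researcher, the largest sector).  Reference levels were chosen for cell
stability; focal coefficients are reference-invariant.

Significance comes from Y-permutation: the outcome vector is re-ordered
across members B times (default B = 10,000), the model refit, and the
two-sided p-value for coefficient k is (1 + #{|β*ₖ| ≥ |β̂ₖ|}) / (1 + B) —
the add-one rule keeps p strictly positive.  Refits are vectorized through
a single pseudoinverse, so large B is cheap.  With `exact=True` all n!
re-orderings are enumerated (n ≤ 8) and p is a plain proportion including
the identity.  Freedman–Lane residual permutation (permute reduced-model
residuals, coefficient by coefficient) is available as an option;
Y-permutation is the default because it is the standard node-level choice
in coalition sociometry.  Full dyadic QAP/MRQAP is out of scope: the models
here are node-level.

The collinearity screen computes pairwise |Pearson r| among candidate
member-level predictors, excludes zero-variance candidates, and flags pairs
above 0.70 (the usual rule-of-thumb bound); flagged pairs are refused in a
joint specification and must be fit in separate models.  In practice the
two focal predictors are fit in two single-focal model panels of three
outcomes each — six models per run.

## Outcome indices

Unweighted sums of binary items: community activities (4 items),
grants/publications (3), policy engagement (2).  Items must be complete and
strictly 0/1; no imputation or weighting.  One reference table in the
literature prints SD = 1.29 for a 0–2 index with mean 1.11, which exceeds
the maximum possible SD (≈ 0.99) of any [0, 2] variable at that mean; the
0–2 integer sum is retained here and that printed value treated as
unverifiable.

## Synthetic-data generator

The generator emulates the study conditions end-to-end: 38 members with
sector counts (11, 14, 1, 2, 4, 6), cities (26, 5, 7), 23 original members
(largest-remainder allocation, seed-shuffled assignment).

**Network model.** For each unordered pair, a fair coin picks the potential
reporter; the reporter names the tie with probability p from the
sector-block target matrix, and a named tie is confirmed (reverse arc) with
probability r.  This gives directed density p(1+r)/2, union-tie probability
p, and dyad reciprocity exactly r.  The inception wave thins year-4 arcs
independently with retention w (inception ⊆ year 4 by construction; an
independent-waves mode exists behind a flag), giving inception density
w·p(1+r)/2 and dyad reciprocity rw/((1−r)+r(2−w)).  Defaults r = 0.54,
w = 16/35 and block targets set to the year-4 within/between-sector union
densities of the reference coalition (pair-weighted mean p ≈ 0.45) pin all
four calibration targets at once: density 16%→35% and reciprocity 19%→54%,
the last following with no free parameter left.  The reporter of each pair
is chosen by coin flip rather than by index order because an index-ordered
rule would make expected out-degree depend on roster position whenever
r < 1, an artifact with no substantive counterpart.

**Outcomes.** A latent score per member,
`β₀ + β_focal·focal + city/tenure/sector effects + N(0, σ²)` (defaults
β₀ = 1.0, β_focal = 0.15 on out-degree or 3.5 on reciprocity — the natural
scale of each predictor — σ = 1.0, modest covariate effects), is thresholded
at fixed item cutpoints, so each index is a monotone step function of the
latent score.  Cutpoints were set once so default index means sit near 2.0,
2.3 and 1.1 — calibration targets, not assertions.  The generator records
the latent score and true β for recovery tests.

**Activity heterogeneity.** `activity_dispersion` (default 0, inert) gives
members activity levels aᵢ ~ U[1−d, 1+d] scaling reporting (p·aᵢ) and
confirmation (r·aᵢ·aⱼ).  Active members then report more ties *and* have
more-reciprocated ones, coupling the two focal predictors — the regime in
which the collinearity screen must refuse a joint model.  At full strength
(d = 0.8, dense flat targets, n = 120) sample |r| exceeds 0.8.

**What the generator does not emulate.**  Members are exchangeable within
sector: there are no hubs, so out-degree centralization sits near 15–20%
rather than the 40–60% a hub-dominated coalition shows.  The confirmation
mechanism makes every confirmation arc reciprocated, so member-level
arc-based reciprocity shares average 2r/(1+r) ≈ 0.70 at year 4 — higher
than coalitions where reciprocation is closer to independent.  Regressions
on the binarised indices recover attenuated coefficients relative to the
latent-scale β (coarsening bias); unbiasedness holds on the latent scale
and is tested there.  Passing tests therefore certify the *computations*
and the method's calibration, not that real coalitions look like the
generator.

## Numerical choices

* Permutation comparisons use |β*| ≥ |β̂| − 1e−12 to make equality robust to
  refit round-off; exact-mode p-values then match exhaustive enumeration to
  machine precision.
* OLS uses `numpy.linalg.lstsq` after an explicit rank check; rank
  deficiency raises an error directing users to the collinearity screen
  rather than silently pseudo-inverting.
* Standard deviations in summaries are population SDs (ddof = 0), the
  convention of classical sociometric software.
* Rendered tables round to whole percent; `report.json` keeps full
  precision, is serialized with sorted keys, and reruns byte-identically
  for a fixed (config, seed).
* Per-model permutation seeds derive deterministically from the run seed
  (seed·31 + model index, mod 2³¹−1).

## Problem sizes used in the checks

Oracle-equivalence batches use 200 random digraphs at n ≤ 7 (exhaustive
path and pair enumeration stays exact there); permutation calibration uses
500 null replicates at n = 38 with 2,000 permutations; parameter recovery
uses 200 replicates per focal predictor, with power-versus-type-I checks at
150 replicates and 500 permutations; the acceptance script averages 20
replicate coalitions with 10,000-permutation regressions.  These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.
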