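# Methods

`dietshift` analyses a pair of pellet surveys of a predator's diet —
typically a barn-owl roost sampled before and after a land-use change —
and asks whether the diet spectrum shifted more than random reshuffling
of the same prey individuals would produce.

## Data model and normalization

The central object is a taxa × surveys matrix of integer prey counts
`n_ij` (the resource-utilization matrix), together with each survey's
pellet total `P_j`. Because pellet effort can differ several-fold
between surveys, all comparative statistics are computed on one of two
normalizations:

* **per-pellet abundance** `a_ij = n_ij / P_j` (prey individuals per
  pellet) — comparable across surveys with unequal effort; used for the
  guild tests and the ordination;
* **within-survey proportions** `p_ij = n_ij / N_j`, `N_j = Σ_i n_ij` —
  used for evenness and niche overlap, which are properties of the
  diet's relative composition.

Mixed-rank identifications are first collapsed to a single rank
(typically subfamily) through a flat item → group map, which removes
taxonomic nestedness from compositional data. Taxa unexploited in both
surveys are rejected at load: an entirely unused category carries no
information about either diet, and admitting it would make the
"unexploited categories per survey" count (a conserved quantity of the
null models) ill-defined. Guild matrices are the exception — all three
guild rows (insectivore / herbivore / omnivore) are always kept, even
when empty, so the three guild tests always exist.

## Statistics

* **Pielou's evenness** `J = H / ln(S_used)`, where `H` is Shannon
  entropy (nats) of the proportions over the `S_used` taxa with
  `n_ij > 0`. `J ∈ [0, 1]`, is invariant to rescaling counts, and is
  undefined when fewer than two taxa are used. The paired contrast is
  `ΔJ = J_later − J_earlier`.
* **Petraitis specific niche overlap**
  `O_{A|B} = exp(Σ_{p_Ai>0} p_Ai ln p_Bi − Σ p_Ai ln p_Ai) = exp(−KL(p_A‖p_B))`,
  the exponentiated mean log-likelihood ratio of A's utilization under
  B's. `O = 1` iff the distributions agree on A's support; if A uses a
  category B does not, `O = 0` (complete separation). Both directed
  values and their geometric mean are computed.
* **Guild abundance difference** `Δa_g = a_{g,later} − a_{g,earlier}`
  in per-pellet units.
* **Taxon change** is reported in both common senses — percentage-point
  change of the proportion, and percent change of per-pellet
  abundance — because the two can differ substantially when total prey
  per pellet changes between surveys.

All logarithms are natural: `J` is base-invariant, and the overlap–KL
identity is cleanest in nats.

## Null models

The permutation null randomizes the count matrix while conserving the
features not under test: every variant keeps the number of occupied
cells and the per-survey count of unexploited categories (drawing the
occupancy pattern uniformly from all binary matrices with the observed
incidence margins — exactly, by direct enumeration of the singleton
taxa, in the two-survey case; by a 2×2 checkerboard trial-swap chain,
default 10,000 attempts, with more surveys). Quantities are then placed
on the occupied cells:

* `shuffle_samp` (default): the observed multiset of non-zero cell
  values is permuted uniformly over the occupied cells. Grand total and
  value multiset conserved; per-survey totals may migrate between
  surveys.
* `shuffle_both`: the grand total is redistributed as a uniform random
  composition over the occupied cells (each ≥ 1).
* `multinomial`: each survey is redrawn independently — a uniform
  choice of which `S_used,j` taxa are occupied and a uniform
  composition of `N_j` over them — conserving per-survey totals
  exactly.

`shuffle_samp` is the default because it reproduces the stated
conservation properties while leaving per-survey totals free; whether a
given historical analysis fixed per-survey totals is often ambiguous,
so the variant is a config switch rather than a constant. The guild
tests randomize the 3 × surveys guild matrix directly by default;
randomizing the taxon matrix and aggregating each replicate post hoc is
available via `randomize_guilds_from_taxa=True`.

## Inference

Empirical p-values use the add-one convention `p = (r + 1)/(n + 1)`
with ties counted as at least as extreme, so `p ∈ [1/(n+1), 1]`. The
two-sided p compares absolute deviations from the null mean rather than
doubling a tail — under this definition the minimum attainable p equals
`1/(n+1)` for every alternative. The standardized effect size is the
signed probit of half the p-value, `SES = sign(T_obs − T̄*) × |Φ⁻¹(p/2)|`,
which depends on the null only through `p` and is therefore robust to
skewed null distributions; `|SES| > 1.96` flags two-sigma (5%)
significance. No separate p-adjustment is applied: `2Φ(−|SES|)` returns
the empirical p by construction.

Alternatives are fixed per feature: two-sided for evenness and the
three guild differences, left-sided for overlap (the question is
whether the two diets are *less* similar than randomly expected).

The pipeline's overlap statistic is, by default, the directed overlap
of the later diet on the earlier baseline. The symmetrized geometric
mean — the single-number default of `petraitis_overlap` itself — is
identically zero as soon as *either* survey has an exclusive taxon,
which would make the left-sided test vacuous on most real data; the
directed value stays finite whenever the later survey's exploited taxa
are nested within the earlier survey's, the typical situation when the
follow-up sample is smaller. Both directions and the geometric mean
remain available through `overlap_mode`.

## Ordination

Prey taxa are embedded in two dimensions by non-metric multidimensional
scaling of the Euclidean distances between their per-pellet abundance
profiles. The loss is Kruskal's stress-1,
`sqrt(Σ(D_ij − ĥ_ij)² / Σ D_ij²)`, with `ĥ` the pool-adjacent-violators
isotonic regression of the configuration distances onto the rank order
of the input distances (primary approach to ties: tied input distances
impose no mutual order). Minimization alternates isotonic fits with
Guttman-transform updates; one start comes from classical metric
scaling and the rest (default 20) are random, so the returned stress
never exceeds the metric-scaling initialization's. An update that would
increase stress terminates its start, making the per-iteration stress
history non-increasing by construction. With two surveys the abundance
profiles are literally planar points, so stress at the optimum is
numerically zero — the expected outcome for any two-survey dataset.
Axis orientation and scale are arbitrary (NMDS is invariant to
rotation, reflection and uniform scaling); only stress and the
inter-point rank structure are comparable across runs.

Note one deliberate consequence of the primary tie approach: with fully
tied dissimilarities every configuration satisfies the rank
constraints, so stress is 0 by definition.

## Synthetic data generator

`generate_dataset` emulates the study design the analysis assumes: two
surveys with strongly unequal pellet effort (defaults 535 and 159
pellets), nine subfamily-level taxa in three guilds, Poisson prey
totals at λ = 1.6 prey per pellet (pellets of this predator typically
hold one to a few small mammals), per-survey exploited-taxon sets
(expected unexploited fraction 0.15, matching one to two unused taxa
out of nine), Dirichlet taxon proportions and multinomial counts. The
`shift` parameter multiplies omnivore weights by `(1 + shift)` and
divides insectivore weights by the same factor in the later survey
only.

The baseline Dirichlet concentration is flat (all ones) by design: a
flat Dirichlet followed by a multinomial is uniform over compositions,
so conditionally on each survey's prey total and used-taxon count the
generator's law *equals* the `multinomial` null variant. Shift-free
data are therefore exactly exchangeable with null replicates, and the
two-sided permutation test has exactly nominal type-I error — the
calibration test (500 datasets × 499 permutations) checks 5% ± 2%.
The price of the flat baseline is high between-survey dispersion:
even a strong shift (2.0) leaves a small fraction of datasets with a
negative omnivore change, and test power against the highly dispersed
null variants is modest at these sample sizes.

What the generator does not emulate: temporal autocorrelation between
surveys (proportions are drawn independently), pellet-level structure,
detection or decay bias, and taxon-specific identifiability. Passing
tests on synthetic data therefore validate the inferential machinery
under the stated sampling model, not the field realism of any
particular dataset.

## Numerical choices and limitations

* Proportion vectors are validated to sum to 1 within 1e-9; count
  matrices must be integer exactly.
* NMDS defaults: 20 starts, 500 iterations, relative tolerance 1e-6 —
  ample for the ≤ 12-point, 2-coordinate configurations this analysis
  produces.
* Uniform compositions are drawn by the stars-and-bars construction
  (sorted distinct cut points), which is exact rather than approximate.
* One master seed drives a run: per-feature replicate streams and the
  NMDS starts derive from it deterministically, so repeated runs are
  byte-identical.
* The trial-swap incidence sampler for more than two surveys uses a
  fixed attempt count with no convergence diagnostic; for the
  two-survey case (the intended use) the sampler is exact.
* p-values are bounded below by `1/(n_perm + 1)`; with the default
  9,999 replicates the smallest reportable p is 0.0001.
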