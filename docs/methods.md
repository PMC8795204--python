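# Methods

## Experimental designs

**Definitive screening design.** For m cytokines the DSD is built as
[C; −C; 0] from a conference matrix C (zero diagonal, ±1 off-diagonal,
CCᵀ = (n−1)I). Conference matrices of orders 6, 8, 10, 12, 14 and 16 are
shipped as verified static data (Paley constructions and a skew-Hadamard
doubling for order 16); for odd m or m without a stored order, the next
stored even order m′ is used and the trailing m′−m columns dropped, giving
2m′+1 runs. Consequences: each retained column takes exactly the three
levels {−1, 0, +1}, non-center runs come in mirror pairs, main-effect
columns are mutually orthogonal and orthogonal to all two-factor interaction
columns, and — when no columns are dropped — each non-center run has exactly
one factor at its center level. Larger orders are rejected rather than
computed at run time.

**Central composite design.** A two-level factorial core (full for k ≤ 5, a
resolution-V half-fraction for k = 6–8, configurable), 2k axial runs at ±α,
and n_center center replicates (default 8). `alpha_mode="orthogonal"`
(default) sets α = [((√N − √F)²·F)/4]^(1/4) with F the factorial and N the
total run count, which makes the centered pure-quadratic columns orthogonal
to the linear and interaction columns, so curvature estimates do not
contaminate the linear dose effects. Rotatable (α = F^(1/4)) and
face-centered (α = 1) variants are available. Combinations yielding α ≤ 1
are rejected as degenerate.

**Coded units.** Factor coding is affine on the natural ng/ml range by
default (center = midpoint, ±1 at the stated low/high), with log10 coding
available for log-spaced dose grids. Round-trips are exact to 1e-12.

## Screening analysis

Counts are standardized per (donor, interval, population) against the
control wells of the same group: z = (count − mean_ctrl)/sd_ctrl with the
n−1 sample standard deviation, requiring ≥ 2 control replicates. Donors are
z-scored separately and pooled as independent observations (no donor random
effect).

Model selection is forward stepwise OLS from the intercept-only model,
adding at each step the move that most decreases
BIC = n·ln(RSS/n) + k·ln(n) (k counts the intercept; constants that cancel
in comparisons are dropped) and stopping when no move decreases it. Strong
effect heredity is enforced, with *bundle* moves: an interaction whose
parent main effects are absent may enter together with them (likewise a
quadratic with its main effect) when the bundle as a whole lowers BIC —
without bundles, a pure interaction effect could never enter because its
parents explain nothing on their own. RSS below (10⁻⁹·‖y‖)² is treated as
numerically zero so an exact fit terminates selection instead of inviting
float-noise terms. Candidates numerically collinear with the current model
are set aside and reported (a 13-run DSD cannot support the full quadratic
expansion; selection works within whatever subspace is estimable, while the
one-shot RSM fit raises an aliasing error naming the dependent columns).

A calibration worth knowing: at DSD sample sizes the BIC penalty ln(13) ≈
2.6 is mild, so pure-noise responses keep the intercept-only model only
about a third of the time and roughly one spurious term enters on average
even when the true effects are found (power for |β| ≥ 3σ effects is
essentially 1). The tests assert these simulation-calibrated rates; screens
of this size find what matters but should not be read as a false-positive
filter — that is what the follow-up response-surface experiment is for.

## Response-surface models

Per population and 7-day interval, OLS of √count on the full quadratic
expansion (1 + k + k(k−1)/2 + k terms) in coded units; replicate rows
(donors, center replicates) pool into one fit. The sqrt transform
variance-stabilizes flow-cytometry counts; zeros are allowed (√0 = 0, no
offset). Predictions back-transform as max(ŷ, 0)²: negative sqrt-scale
predictions are clipped to zero rather than squared (squaring would invent
cells), and no retransformation bias correction is applied — the optimizer
only needs monotone fidelity, not unbiased count forecasts. Dose sweeps pin
all other factors at coded 0. Points outside the design hull [−α, +α] raise
an error unless extrapolation is explicitly enabled.

## Desirability optimization

Each maximized population contributes a Derringer–Suich larger-is-better
desirability: d = 0 at or below L, 1 at or above T, ((ŷ−L)/(T−L))^s
between. Defaults: L = 0 cells, s = 1, equal weights. T = "auto" estimates
the attainable count maximum over the optimization box by a coarse pre-pass
(9-point sweep along each marginal axis plus the center) followed by a short
Nelder–Mead polish of the best grid point. The polish matters: with more
than one active factor the best axis-aligned point underestimates the joint
maximum, which would put a d = 1 plateau around the optimum; plateau ties
would then be broken arbitrarily in the staging search. With the polished
target, d = 1 is attained only at the true maximum.

Overall desirability is the weighted geometric mean D = (Π dᵢ^wᵢ)^(1/Σwᵢ):
monotone in every component and zero if any objective is at zero, so no
population can be traded away entirely. Maximization runs scipy's
basin-hopping on −D: a uniform random perturbation of magnitude ≤ step_size
(default 0.5 coded units) clipped to the box, a bounded Nelder–Mead local
minimization, and Metropolis acceptance at temperature 1.0 on the D scale;
default 200 iterations (smaller values suffice on the smooth synthetic
surfaces and are used in the test suite and acceptance script to keep runs
short). All randomness flows from one integer seed; per-interval seeds are
derived as seed + 1009·interval_index so intervals are decoupled but
reproducible. The k best local minima are retained verbatim (no spatial
deduplication; a deduplicated view at L∞ > 0.05 coded units is available).

## Protocol staging

Boundaries (t₁, t₂) are multiples of 7 with 7 ≤ t₁ < t₂ ≤ 35 — ten pairs,
searched exhaustively. Weeks are half-open intervals [7w, 7w+7) and belong
to the stage containing their start day. Stage concentrations are arithmetic
means of the per-interval optimal concentrations in **natural units**
(ng/ml), matching how media would actually be formulated; each interval's
desirability is then re-evaluated at its stage concentration with that
interval's own objectives (objectives change over time), and the pair
maximizing the mean of the six interval scores wins. Ties break to the
lexicographically earlier pair. The ratio of the staged average D to the
mean of the unconstrained interval optima is reported as the protocol's
desirability retention.

## Synthetic ground truth

The generator emulates: full-quadratic surfaces on the sqrt-count scale per
(population, interval); Gaussian noise on the sqrt scale (consistent with
fitting sqrt-transformed counts; a count-scale negative-binomial option
exists for robustness checks but is not the default); optional additive
per-donor sqrt-scale offsets; and control-condition replicates for
z-scoring. Counts are max(s, 0)².

Default regimes (coefficient magnitudes are package defaults, recorded in
`synthetic.py`, not measured values):

| days   | active effects |
|--------|----------------|
| 0–7    | SCF, IL-3, TNFα positive; SCF×TNFα and IL-3×TNFα synergies; IL-7 inert |
| 7–21   | SCF and IL-7 positive; IL-3 inert; TNFα small positive, small negative TNFα×CXCL12 |
| 21–42  | SCF and IL-7 positive with synergy; TNFα negative; IL-3 inert |

Flt3L is inert throughout. Every factor keeps a negative pure-quadratic
term (−0.5 for inactive factors) so all surfaces are strictly concave with
unique interior optima; "inert" therefore means no dose preference away
from the center rather than a perfectly flat axis. IL-3 is zeroed from day
21 (the real response decays between days 21 and 28); collapsing it to the
regime boundary keeps the regimes exactly piecewise-constant on
[0,7)/[7,21)/[21,42), giving the staging search a known correct answer of
(7, 21). This sharp-break structure is a test-fixture choice — real
differentiation shifts gradually — so partition-recovery results certify
the search machinery, not any claim about biological abruptness. Within an
interval all populations share one surface shape scaled by a positive
multiplier (an ancestor-progeny consistency assumption), so they agree on
the optimum's location and the desirability trade-off is non-conflicting by
construction; the machinery accepts arbitrary per-population surfaces.

Default factor ranges put IL-3 and TNFα centers at the 10 and 5 ng/ml
working concentrations and keep all natural concentrations non-negative at
the α ≈ 2.1 axial points. Default noise sd 0.5 on the sqrt scale (≈ ±25
cells at a 625-cell prediction) is comfortably inside the regime where the
52-run CCD recovers coefficients and the partition search is exact;
recovery degrades monotonically as the noise grows.

What passing tests do **not** show: robustness to donor-by-cytokine
interactions, non-Gaussian count noise, model misspecification (true
response not quadratic), or drifting (non-piecewise-constant) regimes.

## Bioassay computations

* **ED50**: responses normalized to the dose-0 vehicle control (100%);
  linear interpolation on the dose axis between the first adjacent pair
  bracketing 50%; censored at the maximum dose if never crossed;
  non-monotone curves use the first crossing and are flagged. Per-donor
  estimates are meant to be summarized as mean ± standard error.
* **Fold expansion**: product over weeks of counted/seeded with
  seeded = previous counted × fraction carried — per-cell growth, invariant
  to passage splits.
* **Coating density**: µg/ml × µl / mm² = ng/mm² (a 96-well growth area of
  32 mm² is the working default; it is why 15 µg/ml in 50 µl reads "~24"
  rather than exactly 24 ng/mm²).
* **ΔCt**: relative expression 2^(−ΔCt) against the reference gene.
* **Group comparison**: Shapiro–Wilk on every group; any p < 0.05 routes to
  Kruskal–Wallis with hand-rolled Dunn post hoc (rank-sum z statistics with
  tie correction) and Benjamini–Hochberg adjustment, otherwise one-way
  ANOVA with Tukey HSD. All-constant groups are skipped with a warning.
  The branch taken is always reported.

## Numerical choices

* OLS via `numpy.linalg.lstsq`; rank deficiency in the one-shot RSM fit is
  an error naming the aliased terms.
* R² is defined as 0 for a constant response.
* Basin-hopping iterates are clipped to the box both in the take-step and
  through Nelder–Mead bounds; increasing n_iter under a fixed seed never
  worsens the best D (the random stream is consumed sequentially).
* Stage-concentration averaging defaults to natural units; coded-unit
  averaging (`average_in="coded"`) is available for sensitivity analysis.
  Under linear factor coding the two are identical; they differ under log10
  coding (arithmetic vs geometric dose means).
* Seeds derived from the root seed stay below 2³¹.

## Known limitations

* Forward-only selection (no bidirectional stepwise); commercial stepwise
  implementations differ in their exact rules, and forward selection with
  strong heredity is the reproducible choice.
* No donor random effects, no lack-of-fit F test by default, no
  multiplicity control across populations in screening.
* The desirability bounds, weights and basin-hopping hyperparameters of the
  original campaign are not published; the defaults here are declared
  choices, and the acceptance checks exercise properties (convergence,
  recovery, retention) rather than any undisclosed constant.
* Culture-derived magnitudes (fold expansions, CFSE proportions, secretion
  frequencies, measured ED50s) are wet-lab outcomes outside what a
  simulation can certify; the suite tests the arithmetic identities and
  estimator properties underneath them instead.
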