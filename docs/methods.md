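# Methods

## Model and score

A logo summarizes, position by position, how an observed symbol
distribution **p** differs from a background **q**. We model the
relationship multiplicatively, pᵢ ∝ λᵢqᵢ; on the log scale the
enrichment parameters lᵢ = log₂λᵢ are identified only up to an additive
constant k, since lᵢ = log₂(pᵢ/qᵢ) + k fits for any k. The ED score
resolves the constant by parsimony: the choice k = −median{log₂(pᵢ/qᵢ)}
uniquely minimizes Σᵢ|lᵢ| (the total stacked-glyph height) when n is odd.
Positive scores are drawn above the axis, negative below, each glyph
scaled to |rᵢ|, stacked bottom-to-top in increasing rᵢ so the largest
glyphs sit furthest from the axis.

Two properties anchor interpretation. First, enrichment/depletion is
*relative to the median symbol*, not absolute: rᵢ can be positive with
pᵢ < qᵢ. Second, height differences are centering-free log-odds ratios:
rₐ − r_b = log₂((pₐ/p_b)/(qₐ/q_b)). Both are enforced by tests at
1e−12.

### Even alphabets and the centering rules

For even n every offset in the closed interval between the two central
order statistics of the raw ratios attains the same minimal stack
height. `centering_constant` therefore exposes three rules — `smallest`
(lower central order statistic), `conventional` (their mean),
`largest` (upper) — which coincide for odd n. `smallest` is the package
default: it favors an enrichment representation, which most users find
more natural, at the cost of the mirror property. `conventional` is the
unique rule for which swapping p and q negates every score exactly; the
suite carries both the 1000-pair mirror test and a documented even-n
counterexample for `smallest`. Ties among raw ratios are handled on the
sorted multiset, no jitter. The same centering operation applies
unchanged to externally derived score matrices such as PSSMs
(`median_center` accepts any `ScoreMatrix`).

### Comparison scorers

`standard_logo_scores` implements the classic information-content logo:
heightᵢ = pᵢ·IC with IC = log₂(n_ref) + Σpᵢlog₂pᵢ in bits and
0·log₂0 = 0; n_ref defaults to the position's alphabet size, and only
the uniform-reference form is supported (non-uniform-background standard
logos are out of scope). `wkl_scores` implements the weighted
Kullback–Leibler logo as heightᵢ = pᵢ·log₂(pᵢ/qᵢ) with 0 ↦ 0 — the
conventional signed wKL height — and is intended for comparison plots
only; significance-based heights (iceLogo-style) are out of scope.

## Stabilization

The MLE p̂ᵢ = mᵢ/m makes |r̃ᵢ| infinite for unobserved symbols and
unstable for rare ones.

**Pseudocounts.** p̂ᵢ = (mᵢ+c)/(m+nc) with c = 0.5 (half a count) by
default; for a 20-letter protein alphabet at m = 5422 this is
(mᵢ+0.5)/(m+10). The known artifact: all-zero symbols get a *common*
p̂ but *different* backgrounds, so their log ratios spread with q and
unobserved symbols can appear strongly enriched or depleted. A
background supplied as probabilities is used as-is in this mode (it
needs no zero-count repair); a count-valued background is pseudocounted
like the foreground.

**Empirical Bayes.** Shrinks the log-ratio estimates directly. Per
(position, symbol) cell: a point estimate
xᵢ = log₂((mᵢ+½)/(m+n/2)) − log₂((bᵢ+½)/(b+n/2)) from foreground and
background counts, and a delta-method standard error
sᵢ² = [(1/(mᵢ+½) − 1/(m+n/2)) + (1/(bᵢ+½) − 1/(b+n/2))]/ln²2, so
zero-count cells carry the (large) SE of a half-count cell. Deviations
dᵢ = xᵢ − μⱼ from the per-position median μⱼ are then modeled as
dᵢ ~ N(δᵢ, sᵢ²) with a unimodal prior
δ ~ π₀·δ₀ + Σₖπₖ·N(0, τₖ²) — a point mass at zero plus a geometric
variance grid from min(s)/10 to twice the data span, step √2. Mixture
weights are fitted by maximum marginal likelihood (EM, uniform
initialization, tolerance 1e−8 on the mean log-likelihood, ≤1000
iterations — fully deterministic), jointly across all cells of the
matrix (one prior, more data for its estimation; per-position fitting is
a defensible alternative we did not take). Posterior means are returned,
re-anchored at μⱼ.

Consequences, each a tested contract: estimates are finite for any input
with m ≥ 1; they converge to the MLE log ratios as counts grow (max
abs error < 0.01 at m = 10⁶ for entries ≥ 0.01, tested with expected
counts so estimator bias is isolated from sampling noise); on shallow
data (m ≤ 50) the mean |estimate| does not exceed the pseudocount
mode's; and symbols with zero foreground counts collapse onto a
near-common value whose spread is at most 10% of the pseudocount-mode
spread (observed: ≈2%). The collapse is *near*-exact, not exact — a
posterior mean retains a small O(posterior weight on wide components)
dependence on the background, in practice a few hundredths of a log₂
unit on the degenerate 20-letter test column; a scheme returning
posterior modes under a sparsity-inducing prior could make it exact but
would sacrifice the smooth consistency behavior.

Probability-valued inputs are converted to counts as round(p·effective
count) before shrinkage; the effective count (default 1000, i.e. values
trusted to ~3 decimal places) is the declared precision of such inputs.
EB shrinkage is defined for log-ratio (ED) scores only; the CLI rejects
`--stabilize eb` with the standard/wKL scorers rather than guessing a
probability-space analogue.

## Synthetic data

`SyntheticSpec`/`generate` build count matrices with known truth.
Designated symbols get pᵢ = qᵢ·2^eᵢ *exactly* (so the true uncentered
log ratio of a designated symbol equals its effect size), remaining
symbols share the leftover mass proportionally to q; effects whose mass
reaches 1 are rejected. Unspecified positions draw p from a symmetric
Dirichlet (concentration 5 by default — moderately informative noise).
Counts are multinomial at depth m per position (no overdispersion; the
binomial sampling view of frequency estimation), seeded through
`numpy.random.default_rng`. The generator emulates independent positions
with exact compositional truth; it does not emulate positional
dependence, alignment error, or overdispersed replicates, so passing
recovery tests demonstrate estimator behavior under clean multinomial
sampling, not robustness to those real-data features. Recovery tests use
depths 10²–10⁶ and 20 seeds; suite problem sizes are kept small (≤ a few
thousand cells) so the default run finishes in seconds.

## Layout and rendering

Positions occupy unit slots centered on x = 0..L−1, trimmed by a gap
fraction (default 0.05) per side; user-facing tick labels come from the
position labels (e.g. −2…+2 for mutation contexts). Scores within
1e−12 of zero are not drawn; above- and below-axis boxes tile their
half-axes without gaps or overlaps, and Σ box heights equals the stack
height to 1e−9. Ties in rᵢ are ordered by alphabet index, lower index
nearer the axis — a package convention; the original plots' tie order is
unspecified.

SVG output is a pure function of (layout, style): glyphs are filled
outlines extracted from matplotlib's bundled DejaVu fonts (so rendering
does not depend on system fonts), floats are written at fixed precision,
element order is stable and no timestamps are embedded — two runs with
the same inputs are byte-identical, and the CLI's JSON manifest replays
a run exactly. Single-character glyphs stretch non-uniformly to fill
their boxes; multi-character strings scale uniformly to the box width
and stretch vertically at most 8× that scale, beyond which they are
vertically centered (unbounded stretching makes strings unreadable;
the cap is a design choice). Below-axis glyphs keep full color by
default, with an optional reduced-opacity style flag. The y axis is
labeled "Enrichment score (log₂)" for ED/wKL modes and "bits" for
standard mode.

## Degenerate inputs and numerics

Zero probabilities reach `log_ratios` only if no stabilizer was
requested, and raise a domain error naming the (position, symbol) and
advising stabilization. A position with total count 0 cannot be
normalized and is rejected by name. Positions with a single symbol
center to exactly 0 under every rule. Closed-form invariants are tested
at 1e−12 (double precision); layout conservation at 1e−9.

## Known limitations

- The EB prior is fitted jointly across positions; matrices whose
  positions have radically different signal scales might prefer
  per-position priors.
- Only the uniform-reference information content is available for
  standard logos.
- Probability tables are renormalized per position, so compositional
  inputs are accepted, but their declared precision is only as good as
  the effective-count setting.
- Multi-panel figure composition and interactive output are out of
  scope; one logo per SVG document.
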