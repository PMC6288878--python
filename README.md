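# edlogo

Enrichment–depletion sequence logos for motif and compositional data.

Standard sequence logos scale each symbol by its frequency and are
excellent at showing *enrichment*, but they make *depletion* — a proline
that never follows a glycosylation site, a CpG missing downstream of a
mutation hotspot — nearly invisible. `edlogo` implements a logo variant
built for both directions at once, aimed at anyone who visualizes
position-wise symbol distributions: transcription-factor binding sites,
protein motifs, somatic mutational signatures, or compositional data such
as histone-mark abundances across genomic regions. Symbols may be
arbitrary strings ("C→T", "H3K4ME1"), and different positions may use
different alphabets.

## The score

At one position, let **p** = (p₁,…,pₙ) be the observed symbol
probabilities and **q** = (q₁,…,qₙ) a background. The logo height of
symbol *i* is the median-centered log₂ enrichment

  r̃ᵢ = log₂(pᵢ/qᵢ),  rᵢ = r̃ᵢ − median(r̃₁,…,r̃ₙ),

drawn above the axis if rᵢ > 0 and below if rᵢ < 0, stacked bottom-to-top
in increasing rᵢ. Subtracting the median is a parsimony choice: among all
height vectors of the form log₂(pᵢ/qᵢ) + k (the unidentifiable log scale
of the model pᵢ ∝ λᵢqᵢ), the median-centered one minimizes the total
stack height Σ|rᵢ|. Height *differences* are absolute:
rₐ − r_b = log₂((pₐ/p_b)/(qₐ/q_b)), a log-odds ratio, whatever the
centering. For an even alphabet the minimizing offset is an interval;
the `smallest`/`conventional`/`largest` rules pick its lower end
(default, favors an enrichment reading), midpoint (restores the exact
mirror symmetry under p↔q exchange), or upper end (favors depletion).

Because log ratios explode for rare or unobserved symbols, scores can be
estimated from counts with stabilization: classic pseudocounts
(p̂ᵢ = (mᵢ+c)/(m+nc), c = 0.5), or an Empirical Bayes mode that shrinks
the log-ratio estimates themselves toward each position's median using a
point-mass + normal mixture prior fitted across all cells — so symbols
with no data collapse onto the position baseline instead of inheriting
spurious structure from the background. Standard information-content
logos and weighted Kullback–Leibler (wKL) logos are included for
comparison. Rendering is deterministic SVG: glyph outlines come from a
bundled font, so identical inputs give byte-identical files.

## Worked example

The distribution p = (A: 0.33, C: 0.33, G: 0.33, T: 0.01) against a
uniform background can be read as "A, C and G are enriched" or, more
parsimoniously, "T is depleted". The ED score says the latter:

```python
>>> import edlogo as el
>>> p = el.paper_fixtures()["fig1_probs"]
>>> r = el.edlogo_scores(p, el.Background.uniform(), rule="conventional")
>>> r.values[0]
array([ 0.        ,  0.        ,  0.        , -5.04439412])
>>> el.stack_height(r, 1)
5.044394119358453
>>> el.log_odds(r, 1, "A", "T")
5.044394119358453
```

Only T gets a (large, negative) height: the logo contains a single glyph
below the axis, 5.04 log₂ units tall, and the A-vs-T height difference
equals the log-odds ratio log₂((0.33/0.01)/(0.25/0.25)). A standard logo
of the same p draws three half-size letters above the axis instead, and a
wKL logo draws all four.

From the shell:

```sh
edlogo plot --input src/edlogo/data/fixtures/fig1_probs.tsv --format probs \
    --median conventional --out logo.svg --dump-scores scores.tsv
```

writes the SVG, the score table (with a `# mode` / `# centering` header)
and a JSON manifest; `edlogo replay logo.svg.manifest.json` reproduces
the outputs byte-identically, and `edlogo simulate` generates synthetic
count matrices with known log₂ enrichments for benchmarking.

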