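# Methods

## The scoring model

A product is scored from two label surfaces only: the per-100 g nutrition
facts and the ordered ingredient list.  No per-serving values, energy,
protein or micronutrients enter the score (micronutrient declaration is
voluntary in the EU, so a micronutrient component would be unevaluable for
most packs).

**Quantitative sub-score (0–7).**  Five nutrients are scored against the
claim limits of Regulation (EC) No 1924/2006, per 100 g: total fat <3 g
(1 pt), saturated fat <1.5 g (1 pt), sodium <0.4 g (1 pt) or <0.12 g
(2 pts), fiber >3 g (1 pt), sugars <5 g (1 pt) or <0.05 g (2 pts).  A value
earns the points of the most favourable tier it satisfies.  Declared salt is
converted with the standard equivalence sodium = salt / 2.5 (0.3 g salt ↔
0.12 g sodium).  Two deliberate fidelity choices, both config-switchable:

* *Boundary semantics.*  Cut-offs are strict inequalities by default — a
  value exactly at a cut-off scores the unfavourable tier.  The regulation's
  own wording ("no more than", "at least") suggests inclusive comparison;
  `boundary="inclusive"` selects it.  Rounded label values essentially never
  sit exactly on a cut-off, so the choice is cosmetic in practice.
* *Sugar-free cut-off.*  The default top sugar tier is 0.05 g/100 g as in
  the rubric's printed table; the regulation's "sugars-free" limit is
  0.5 g/100 g and can be selected via `sugar_free_cutoff=0.5`.  The printed
  0.05 is likely a typo for 0.5, but fidelity to the rubric wins by default.

Fiber declaration is voluntary, so an undeclared fiber is accepted and
scores 0 fiber points (with a logged warning at ingestion), distinct from a
declared 0 g.

**Qualitative sub-score.**  Seven formulation features are detected by
substring matching of a bilingual (English + Italian) lexicon on normalised
text (lower-case, accent-folded, hyphens as spaces, whitespace collapsed).
Polarity: presence of wholegrain flours, sourdough, legume flours or other
alternative flours earns 1 point; absence of starch-as-first-ingredient,
fructose/corn syrup and mono-/diglyceride emulsifiers earns 1 point.
Decisions taken where the rubric was open:

* *"First or principal ingredient"* is operationalised as first-position
  only.  EU ingredient lists are weight-ordered, and "principal" is
  undecidable without quantities.
* *Sourdough* is counted by lexicon presence.  Distinguishing leavening use
  from flavouring use is impossible from an ingredient list; known
  limitation.
* *Legume terms* require a flour context ("chickpea flour", "farina di
  ceci") or an unambiguous standalone name: bare "soy"/"pea" would false-hit
  soy lecithin or peanut.
* *Other flours* cover buckwheat, quinoa, amaranth, sorghum, millet, teff
  and the non-wheat gluten cereals rye and barley.  Rice and corn are
  excluded by definition and additionally stripped from the text before
  matching, so lexicon edits can never make "corn starch" count as an
  alternative flour.  Oat is not counted (its status was unstated; the
  lexicon is editable).

**Applicability and ceilings.**  Each qualitative rule applies only to some
categories: bread gets all but fructose (6 rules), bread substitutes drop
sourdough too (5), breakfast pastries get starch-first, wholegrain, other
flours, fructose, emulsifiers (5), cookies drop wholegrain (4).  The
category ceiling is 7 + applicable rules: 13 / 12 / 12 / 11.  The source
rubric is internally ambiguous about bread substitutes (its prose implies a
ceiling of 13, its table marks sourdough "n.u." for the category); this
package resolves in favour of the table — sourdough is bread-only — and the
matrix is config-overridable for the other reading.  A `normalized` score
(total / ceiling) is provided for cross-category comparison; it is an
extension, not part of the rubric, and is excluded from rubric-replication
outputs.

## Statistics

Scores are short-range integers, so the pipeline is nonparametric
throughout.  Shapiro-Wilk (scipy) is reported but never gates the analysis.
Each category's GF-vs-GC contrast is a two-sided Mann-Whitney U test:
exact enumeration of the U null distribution when n₁ + n₂ ≤ 16 and the
pooled sample is untied, otherwise the normal approximation with midranks,
tie-corrected variance and continuity correction (scipy's implementation
behind the module surface; the test suite checks it against an independent
full-enumeration oracle).  α = 0.05; no multiple-testing correction is
applied across the four categories — the analysis mirrors the original
procedure, and the four contrasts are reported, not pooled.  A
quantitative-only mode re-runs the contrasts on the 0–7 sub-score to check
that qualitative parameters do not drive group differences.

Condition-table percentages report raw presence (a cell of 58 for
starch-first means 58 % of products list a starch first, even though
presence earns no point), computed over the (category, group) n and rounded
half-away-from-zero to whole numbers.  Non-applicable cells carry the
marker "n.u.", never 0.  Box summaries use linear-interpolation quartiles.

## Synthetic markets

No real product set is available, so the generator emulates one: per
(category, group) segments with lognormal or truncated-normal nutrient
amounts (g/100 g), saturated fat drawn as a Beta fraction of total fat
(the facts invariant saturated ≤ total holds by construction), a
probability for the voluntary fiber declaration, and Bernoulli presence of
each ingredient rule.  Ingredient lists are assembled from one exemplar
label string per rule, each verified at generation time to trigger exactly
its own rule, plus neutral fillers verified to trigger none — so detection
equals the generator's ground truth exactly, by construction, and the
round-trip is a meaningful end-to-end check of the lexicon machinery rather
than of string luck.  Each product draws from its own stream keyed by
(seed, category, group, index); adding a segment never perturbs another's
draws.

What the generator does **not** emulate: nutrient–ingredient coherence
(e.g. wholegrain presence does not raise the fiber draw), label rounding
conventions, brand clustering, or real ingredient-list phrasing
variability.  Passing tests therefore demonstrate the correctness of the
scoring and statistics machinery on label-like inputs, not calibration to
any real market.

The reference preset mirrors a published survey's per-category sample
sizes (GF 24/26/53/32, GC 34/49/43/36 — totals 135 GF, 162 GC) with
nutrient medians and presence probabilities chosen once as realistic for
each segment; the GF bread-substitute segment is formulated worse (median
fiber 2.2 vs 4.5 g/100 g, other flours 27 % vs 47 %, emulsifiers 59 % vs
8 %, starch first 77 % vs 2 %), so its scores run stochastically below the
GC segment and the pipeline detects that contrast in the majority of
seeded replicates while the other three categories stay mostly
non-significant.

## Problem sizes and numerical choices

* Brute-force ceiling enumeration: 2⁷ qualitative assignments × 108
  nutrient tier profiles (13 824 states per category); runs in seconds and
  visits every attainable total.
* Mann-Whitney oracle: every untied rank configuration with n₁ + n₂ ≤ 10
  (2 036 configurations) against full enumeration.
* Monotonicity: 10 000 seeded random fact-pairs.
* Type-I calibration: 1 000 seeded null markets of 20 + 20 products;
  observed rejection rate 0.049 at α = 0.05 (band 0.03–0.07).  Continuity
  correction plus heavy ties make the asymptotic test mildly conservative
  at smaller n.
* Generator/detector round trip: one 10 000-product market, exact equality.
* Preset power check: 25 seeded replicates of the full 297-product market.

Degenerate inputs: empty ingredient lists are an error outside
quantitative-only mode; zero-variance samples and n outside [3, 5000] are
errors for Shapiro-Wilk; a category with only one group is reported
not-comparable rather than aborting; batch scoring is lenient by default
(failures collected per product) with a strict mode that re-raises.
Comparisons are made on declared label values as given — no rounding is
applied, since labels are already rounded.
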