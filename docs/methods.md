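# Methods

## Scoring model

An estuary record holds ordinal scores in {0, 1, 2} (or MISSING) on 14
criteria: four ecological (recruitment limitation, local extinction risk,
post-settlement mortality, isolation) and ten social/logistic (hatchery
access, consumption safety, harvest legality, growth, existing bivalve
farming, management plans, community and Indigenous engagement, community
growing). An index is a weighted sum of criterion values divided by the
maximum possible weighted sum (every weighted criterion at 2), giving a
score in [0, 1]; an estuary is a priority for that index when the score is
at least the threshold (default 1/2).

Assumptions baked into the model:

* **Missing counts as zero in sums.** Scores are conservative: estuaries
  with data gaps can only gain as data accrue. Missingness is still tracked
  separately (`n_missing_weighted`, validation warnings) because it drives
  eligibility and should temper interpretation.
* **Vetoes are absolute.** Community harvest requires safe consumption and
  legal harvest; commercial production requires safe consumption. A zero —
  explicit or missing-treated-as-zero — on a veto criterion forces the
  index to exactly 0. Missing data triggering a veto is deliberate: the
  missing-as-zero rule and the veto rule compose, and the affected records
  are flagged to the user through the missing-criterion count.
* **Fixed polarity.** Higher always means better for aquaculture
  investment; no reverse-scored criteria exist in the default registry.
* **Sub-basins are independent.** Portions of large systems (Salish Sea,
  San Francisco Bay) are scored as separate records; `parent_system` is
  reporting metadata and nothing aggregates across it.
* **Certainty is metadata.** The 1–3 certainty annotation never alters a
  score; only the sensitivity module consumes it.

## Exact arithmetic

Weights are restricted to positive integers (fractional weights are
rejected at configuration load), raw sums are integers, and normalized
scores are `fractions.Fraction`. Threshold comparisons are therefore exact
rational comparisons — equivalent to integer cross-multiplication — so the
attainable boundary case 11/22 against a threshold of 1/2 classifies as
priority deterministically on every platform. Thresholds written as
decimal text (`0.50`, `0.7`) are converted to exact rationals at parse
time; floats passed through an upstream parser are interpreted via their
shortest decimal representation for the same reason. Display rounding
(two decimals in the matrix report) never feeds back into classification.

## Eligibility

Records lacking data on the three core ecological criteria are excluded
before scoring but retained for reporting. The default mode (`all_missing`)
drops a record only when *all three* are missing — the reading that
"no information on the first three criteria" most directly supports —
while `any_missing` is available by configuration for the stricter
interpretation. The two modes can only be adjudicated against a full
original scoring table, which is why the choice is a runtime switch rather
than a constant.

## Ranking and reporting

Rankings are total and deterministic: score descending, then fewer missing
weighted criteria, then estuary name. The run summary reports, per index,
priority counts and membership; the count of eligible estuaries scoring
strictly above 0.7 but below the maximum (the high band is strict because
perfect scores are reported separately); and the count at exactly 1.
Project-type threshold counts are computed over the ecological-priority
subset only, matching the framing "how many *of the priority estuaries*
suit each project type". Row order in the matrix report follows input
order, which by convention runs north to south; no geographic computation
is attempted. The matrix shows MISSING as an empty CSV cell / JSON null,
never as 0.

## Sensitivity analysis

The certainty stars carry no published numeric meaning, so the
uncertainty-propagation machinery is explicitly configuration, not a
finding; any stability claim must be reported alongside the mapping used.

* **Score resampling** flips each assigned score with a
  certainty-dependent probability (defaults 0.30 / 0.10 / 0.02 for
  certainty 1/2/3; unannotated scores use 0.30) to an ordinally adjacent
  value — one-step mis-scoring being the plausible expert error mode —
  with both directions equally likely from 1. MISSING values are never
  resampled, so eligibility is invariant across draws.
* **Weight jitter** adds an integer step in ±1 (configurable range) to
  each weight, floored at 1, keeping exact rational scoring valid.
* **Leave-one-criterion-out** is deterministic: one re-run per weighted
  criterion per index, with the maximum rescaled.

Each draw re-runs the full pipeline. Reports give per-estuary priority
frequencies, always/never-priority lists, and the mean Jaccard similarity
between each draw's priority set and the baseline (defined as 1 when both
sets are empty). All randomness flows from one `numpy` generator seeded by
the scheme, so identical inputs give identical reports.

## Synthetic data

The generator emulates the *structure* of a real range-wide scoring
exercise: ~66 records across region codes BCC/WA/OR/CA/BCM in
north-to-south order, ordinal scores from configurable per-criterion
distributions, certainty annotations on every assigned score, missingness
elevated at the range edges (defaults 0.35/0.40 for BCC/BCM against
0.06–0.10 mid-range), a configurable fraction of records (default 26/66)
lacking all three core criteria, and sub-basin records. Defaults were
chosen once as a realistic emulation of those conditions. Criterion scores
are drawn independently; real data surely carry correlations (consumption
safety with existing farming, say), and no correlation structure is
published, so passing tests demonstrate correct pipeline mechanics on
realistic marginals — not calibrated behaviour on correlated real data.

`generate_paperlike_fixture` goes further: it *constructs* a 66-record
table whose count structure under default settings matches the published
range-wide assessment — 26 excluded / 40 eligible, exactly ten ecological
priorities of which two score 1.0 and three fall strictly between 0.7
and 1, one priority pinned at exactly 11/22 to exercise the boundary, and
a 5/4/4 split of restoration/harvest/production project types among the
ten. Constrained cells are set directly from hand-derived value patterns;
unconstrained cells are drawn randomly, so every seed yields a different
table with an identical count structure. Names are overtly synthetic; no
real estuary identity or score is reproduced.

## Numerical and design choices

* Scoring uses exact rationals throughout; nothing in the pipeline
  round-trips through floats except display strings and the JSON
  sensitivity frequencies.
* The canonical on-disk format is UTF-8 CSV (diffs and versions cleanly);
  .xlsx workbooks are read-only conveniences, values only, formulas
  ignored. Certainty is accepted as stars or integers and always written
  as integers. Free-text rationale/source columns are preserved verbatim,
  never interpreted.
* Degenerate inputs: an empty record list yields a header-only table and
  an all-zero summary; a record absent a criterion scores it as MISSING;
  an index losing every criterion in leave-one-out is skipped rather than
  divided by zero.
* Test problem sizes (1000-record oracle sweeps, 2000-draw resampling
  checks, 20-seed stability comparisons on 6–8 record tables, 5000-record
  distribution checks) were chosen to make the checks statistically
  meaningful while keeping the default suite fast.

## Limitations

* The certainty-to-probability mapping is a stated convention; the
  framework cannot validate it against real elicitation error.
* Independence of criteria in the generator understates the clustering of
  real scores; count-calibrated fixtures demonstrate construction, not
  inference.
* Eligibility-mode ambiguity (`all_missing` vs `any_missing`) is resolved
  by configuration, not evidence, until an original scoring table is
  supplied.
* No geographic computation: isolation is an input score, and map
  rendering is out of scope.
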