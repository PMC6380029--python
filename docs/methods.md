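# Methods

## Input model

The tool consumes the two-level hierarchy a semantic-similarity
summarisation (REVIGO-style) produces from a GO enrichment run. Each row is
a term with a free-text `description`, a `representative` parent label, and
a log₁₀ enrichment p-value. Conventions honoured on ingestion:

- the weight is the **absolute** value of the log₁₀ p-value (exports print
  it negative); larger = more significant;
- a `null` or empty representative marks a parent term, which becomes its
  own representative and an ordinary child of its own group;
- the three columns are located by case-insensitive substring match
  (`description`, `representative`, `log10`) so full exports with extra
  columns (term_ID, frequency, uniqueness, dispensability, plot
  coordinates) parse unchanged, in any column order;
- the delimiter is sniffed by counting comma/semicolon/tab in the header
  line; ties resolve to comma (the most common export dialect);
- rows with blank or NaN weights are skipped with a logged warning rather
  than failing the run; zero weights are likewise dropped — a zero-weight
  slice would be invisible and would degenerate the colour gradient;
- UTF-8 with an optional BOM.

## Values calculation

Given n rows and a requested category count m:

1. sort by non-increasing weight; ties break alphabetically by description
   (and the sort is stable beyond that), making the pipeline a pure
   function of its input;
2. keep the first min(m, n) rows; m is bounded to [1, 60] — beyond ~60
   outer slices the labels of a circular plot lose legibility — with a
   default of 40;
3. per parent of the kept rows, sum that parent's omitted rows into one
   *additional categories* slice, placed **last** in the group even when
   its sum exceeds a sibling: its position encodes "least significant",
   not its size;
4. omitted rows whose parent kept no rows cannot attach to any inner
   wedge. They are pooled into one trailing *additional categories* group
   rather than dropped, so the hierarchy total always equals the sum of
   every parsed input weight (verified to 1e-9 relative in the invariants,
   observed at machine precision). The alternative — silently discarding
   orphan mass — would make slice proportions depend on m in a
   hard-to-explain way;
5. order groups by non-increasing total weight, ties by first appearance
   in the sorted rows; the orphan pool always comes last. Ordering by
   total weight (rather than by each group's best child rank) was a
   genuinely open choice; totals were chosen because the inner-ring wedge
   *is* the group total, so visual size and order then agree.

Slice-count law: outer slices = min(m, n) + (parents with ≥ 1 omitted
child) + (1 if the orphan pool exists). The tests assert this against an
independently hand-executed oracle over seed sweeps.

## Geometry

Angles are measured clockwise from 12 o'clock, the familiar pie-chart
convention. A child slice spans 360°·value/total; arcs are laid
contiguously in display order and each inner (parent) arc is the union of
its children's arcs, so the nesting is exact by construction. Default
radii — inner ring 0.35–0.60, outer ring 0.60–0.85, label anchors at
0.90 (fractions of the figure half-size) — were chosen so labels at the
default 7 pt clear the wedges in a 10×8-inch figure; they are conventions,
not derived quantities, and are configurable.

Labels: every child label is drawn (none is ever dropped for space), all
at one configured font size, anchored at the arc's angular midpoint and
rotated to the local radial direction. Labels whose midpoint falls in the
left half-circle (mid-angle strictly between 180° and 360°) are flipped
180° so the text still reads outward. Labels longer than 35 characters
wrap onto two lines at the space nearest the middle — wrapping, not
truncation, preserves the no-omission contract. Adjacent labels of very
thin slices may overlap; vector output lets users nudge them, and no
leader-line system is attempted.

## Colour

Parent groups draw from a fixed, embedded 20-colour qualitative palette
(curated in the spirit of Colorgorical-generated palettes; minimum pairwise
RGB distance 0.126, checked by test). Embedding a fixed palette keeps the
output reproducible offline. Beyond 20 groups the palette cycles with the
HLS lightness reduced by 0.15 per cycle.

Each group's children get a linear gradient from the base colour toward an
endpoint blended 75 % of the way to white; the first (most significant)
child is the base colour itself and lightness — measured as Rec. 601 luma,
0.299R + 0.587G + 0.114B — increases strictly along the gradient. Because
the overflow slice is always last, it is always the lightest. Every parent
wedge also carries a "GO j" tag (j = display order, 1-based) repeated in
the legend, so grouping survives greyscale printing and colour-impaired
viewing; tag text colour flips white/black on dark/light wedges by the same
luma measure.

## Determinism

The full pipeline is a pure function of (input file, configuration). SVG
output is byte-identical across runs: a fixed hash salt, no timestamp
metadata, and fonts referenced by family name (DejaVu Sans) rather than
embedded. PDF/PNG determinism is best-effort (backend-dependent) and not
contractual.

## Synthetic-data generator

`gorings.fixtures` emulates a REVIGO web export: the real header with
extra columns, parent rows with the literal `representative = null`,
children pointing at their parent, and signed (negative) log₁₀ p-values so
parsing must exercise the absolute-value rule. Weights are log-normal
(default μ = 1, σ = 0.8 on the log scale), matching the right-skew of
|log₁₀ p| in real enrichment runs: many terms near 10⁻²–10⁻³, few very
strong hits. Defaults of 5 parents with 2–6 children each give tables of
~15–35 rows; sweeps vary these from 1–9 parents and 1–6 children.

What the generator does **not** emulate: real GO term names or DAG
structure, correlated significance within a cluster, term frequencies, or
the term-ID namespace. Passing tests therefore demonstrate the structural
contracts (conservation, ordering, slice counts, determinism, label
completeness) on realistic table *shapes*, not biological plausibility of
any particular figure.

## Numerical choices

- Sums use compensated summation (`math.fsum`); conservation and group
  totals are validated at 1e-9 relative tolerance.
- Angular invariants (closure to 360°, parent/child nesting, contiguity)
  are validated at 1e-6 degrees; the closing edge is snapped onto 360°
  only within that tolerance.
- The processing file prints weights with 6 decimal places; round-trip
  identity is defined at that precision.
- Percentages in the legend are rounded to 2 decimal places; the unrounded
  values sum to 100 exactly, rounded ones to 100 ± 0.05.

## Problem sizes

The test suite sweeps 200 synthetic tables for the conservation, ordering
and slice-count suites and 100 for the round-trip suite, with tables of up
to ~60 rows and m swept over [1, 60]; the acceptance script's headline run
uses a ~70-row table (12 parents, 2–8 children) summarised to m = 40, the
default category count. These sizes exercise every branch (overflow,
orphans, ties, single-slice degenerate cases) while keeping a full run in
seconds.

## Known limitations

- No leader lines or collision avoidance for labels of very thin slices.
- One hierarchy per figure; no multi-panel or interactive output.
- The tool starts from an already-summarised two-level table: it does not
  perform GO enrichment, semantic-similarity clustering, or p-value
  computation, and does not read the GO OBO graph.
- Raster (PNG) byte-level reproducibility across matplotlib versions is
  not guaranteed; the determinism contract is SVG-only.
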