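# gorings

Two-ring circular visualisation of summarised gene-ontology (GO) enrichment
terms.

## The problem

GO enrichment analysis of a differential-expression experiment typically
returns hundreds of overlapping terms. Semantic-similarity summarisation
(e.g. the REVIGO web service) reduces them to a two-level hierarchy: each
*representative* (parent) term groups the child terms that are similar in
meaning, and every term carries a weight |log₁₀ p| — the absolute base-10
log of its enrichment p-value. Tree-maps are the usual way to draw this
structure, but at publication scale they omit labels that do not fit and
their rectangle sizes are hard to compare.

`gorings` draws the same hierarchy as a two-ring donut instead: parent
wedges on the inner ring, child wedges on the outer ring, laid out clockwise
from 12 o'clock in order of decreasing significance. Every label is drawn at
one uniform font size — nothing is ever omitted — and a legend gives each
parent's share of the total weight.

## The algorithm

For *n* input rows and a requested number of child categories *m*
(default 40, hard cap 60):

1. **Formatting** — parse the REVIGO-style export (comma/semicolon/tab
   sniffed automatically), take |log₁₀ p| as the slice weight, and treat a
   `null`/empty representative as "this term is its own parent". The sorted
   three-column table can be dumped as a tab-delimited processing file.
2. **Values calculation** — sort all rows by weight, keep the top
   min(m, n), and sum each parent's omitted children into one *additional
   categories* slice that is always placed last in its group (it stands for
   the least significant terms, whatever its summed size). Omitted rows
   whose parent kept no children are pooled into a trailing *additional
   categories* group, so total weight is conserved exactly. Groups are
   ordered by decreasing total weight.
3. **Visualisation** — each child slice spans 360°·value/total; the parent
   wedge spans the union of its children. Parents get perceptually distinct
   base colours; children get a dark-to-light gradient of their parent's
   colour (darkest = most significant, so the overflow slice is always the
   lightest). Each parent wedge carries a "GO j" tag linking it to the
   legend entry `GO j: <parent> (<percent>%)`. Output is SVG (byte-for-byte
   deterministic), PDF or PNG.

## Worked example

A five-term toy table with two parents, summarised to m = 3 categories:

```python
from gorings import summarise_records, build_style, build_legend, toy_T1

h = summarise_records(toy_T1(), m=3)
for g in h.groups:
    print(g.parent_label, g.group_total, [(c.label, c.value) for c in g.children])
print("outer slices:", h.n_outer_slices)
print(build_legend(h, build_style(h), "Biological process").formatted())
```

prints

```
A 9.0 [('a1', 5.0), ('a2', 3.0), ('additional categories', 1.0)]
B 6.0 [('b1', 4.0), ('additional categories', 2.0)]
outer slices: 5
['GO 1: A (60.00%)', 'GO 2: B (40.00%)']
```

The three most significant terms (a1 = 5, b1 = 4, a2 = 3) are kept; the two
omitted ones (b2 = 2, a3 = 1) become one overflow slice per parent, so the
outer ring has 3 + 2 = 5 slices and the total weight 15 is fully conserved.
Group A holds 9/15 = 60 % of the weight, so its inner wedge spans
0.60 · 360° = 216°, starting at 12 o'clock.

From the shell, the same run is:

```sh
gorings --input revigo_export.csv --output plot.svg \
        --num-categories 40 --legend-title "Biological process"
```

Exit codes: 0 success, 2 input parse error, 3 validation error (e.g.
`--num-categories 61`), 4 I/O error.

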