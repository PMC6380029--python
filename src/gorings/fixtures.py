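"""Synthetic REVIGO-style tables for testing every pipeline stage offline.

The generator emits the same dialect a REVIGO web export uses: a header
row with extra columns (term_ID, frequency, uniqueness, dispensability),
parent rows whose ``representative`` field is the literal string ``null``,
child rows pointing at their parent's description, and *signed* (negative)
log10 p-values — so parsing must exercise the absolute-value rule.  Weights
are drawn from a log-normal law, matching the right-skewed |log10 p|
distributions that GO enrichment analyses produce.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import GOTermRecord

_HEADER = (
    "term_ID",
    "description",
    "frequency",
    "log10pval",
    "uniqueness",
    "dispensability",
    "representative",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and law of one synthetic table.

    ``value_law`` gives the (mu, sigma) of the log-normal that weights are
    drawn from; defaults emulate a typical enrichment run where most terms
    sit at modest significance with a long tail of strong hits.
    """

    n_parents: int = 5
    children_per_parent: tuple[int, int] = (2, 6)
    value_law: tuple[float, float] = (1.0, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.children_per_parent
        if self.n_parents < 1:
            raise ValidationError(f"n_parents must be >= 1, got {self.n_parents}")
        if lo < 1 or hi < lo:
            raise ValidationError(
                f"children_per_parent must satisfy 1 <= min <= max, "
                f"got {self.children_per_parent}"
            )
        if self.value_law[1] < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.value_law[1]}")


def generate_revigo_table(
    spec: FixtureSpec, path: str | Path
) -> list[GOTermRecord]:
    """Write a synthetic REVIGO-dialect CSV and return its parsed records.

    Fully reproducible from ``spec.seed``.  The returned records are what
    :func:`gorings.io_formats.parse_revigo` yields on the written file:
    values absolute and rounded to the 6 decimals printed, parent rows
    self-representative.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sigma = spec.value_law
    lo, hi = spec.children_per_parent

    rows: list[tuple[str, str, float]] = []  # description, representative-as-written, value
    term_counter = 0
    for i in range(spec.n_parents):
        parent = f"parent process {i + 1:02d}"
        rows.append((parent, "null", float(rng.lognormal(mu, sigma))))
        n_children = int(rng.integers(lo, hi + 1))
        for j in range(n_children):
            child = f"child term {i + 1:02d}-{j + 1:02d}"
            rows.append((child, parent, float(rng.lognormal(mu, sigma))))

    records: list[GOTermRecord] = []
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_HEADER)
        for description, representative, value in rows:
            term_counter += 1
            written = f"{-value:.6f}"
            writer.writerow(
                [
                    f"GO:{term_counter:07d}",
                    description,
                    "1.000%",
                    written,
                    "0.900",
                    "0.050",
                    representative,
                ]
            )
            records.append(
                GOTermRecord(
                    description=description,
                    representative=(
                        description if representative == "null" else representative
                    ),
                    value=abs(float(written)),
                )
            )
    return records


def toy_T1() -> list[GOTermRecord]:
    """The fixed five-record toy table used throughout the test suite.

    Two parents A and B; sorting and top-3 selection interleave their
    children, so both groups gain an overflow slice — the smallest worked
    example exercising every values-calculation rule.
    """
    return [
        GOTermRecord("a1", "A", 5.0),
        GOTermRecord("a2", "A", 3.0),
        GOTermRecord("a3", "A", 1.0),
        GOTermRecord("b1", "B", 4.0),
        GOTermRecord("b2", "B", 2.0),
    ]
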