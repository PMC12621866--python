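"""Per-run and grid-level summaries of generation performance.

One run (a batch of sequences generated at fixed hyperparameters,
filtered, structure-annotated, and homology-searched) condenses to one
row: the fraction of valid sequences, the number of distinct folds
detected, the structural hit rate, and the sequence escape rate.  A
hyperparameter scan lays such rows out on a (top_k, temperature) grid.

The escape-rate denominator defaults to the structurally assigned
subset of a run; a flag switches it to all valid sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

from foldcensus.annotation import (
    FoldAnnotation,
    fold_inventory,
    structural_hit_rate,
)
from foldcensus.filters import FilterReport
from foldcensus.novelty import HomologyHit, escape_rate

logger = logging.getLogger(__name__)


def round_half_up(x: float, digits: int = 3) -> float:
    """Decimal half-up rounding as used in printed report tables."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScanSummary:
    """One grid cell of a hyperparameter scan."""

    top_k: Optional[int]
    temperature: float
    valid_fraction: float
    n_folds_detected: int
    structural_hit_rate: float
    sequence_escape_rate: float

    def __post_init__(self):
        for name in ("valid_fraction", "structural_hit_rate", "sequence_escape_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} {v} outside [0, 1]")

    def rounded(self, digits: int = 3) -> "ScanSummary":
        return ScanSummary(
            top_k=self.top_k,
            temperature=self.temperature,
            valid_fraction=round_half_up(self.valid_fraction, digits),
            n_folds_detected=self.n_folds_detected,
            structural_hit_rate=round_half_up(self.structural_hit_rate, digits),
            sequence_escape_rate=round_half_up(self.sequence_escape_rate, digits),
        )


def summarize_run(
    filter_report: FilterReport,
    annotations: Sequence[FoldAnnotation],
    homology_hits: Sequence[HomologyHit],
    top_k: Optional[int] = None,
    temperature: float = 1.0,
    evalue_max: float = 0.01,
    escape_denominator: str = "assigned",
) -> ScanSummary:
    """Condense one run's filter report, fold annotations and homology
    hits into a summary row.

    ``escape_denominator`` is ``"assigned"`` (escape among structurally
    assigned sequences, the reporting default) or ``"all"`` (escape
    among every annotated sequence).  Full precision is retained here;
    call :meth:`ScanSummary.rounded` when printing.
    """
    if escape_denominator not in ("assigned", "all"):
        raise ValueError("escape_denominator must be 'assigned' or 'all'")
    if filter_report.n_output != len(annotations):
        raise ValueError(
            f"filter output {filter_report.n_output} != "
            f"annotated batch size {len(annotations)}"
        )
    n_folds, _, _ = fold_inventory(annotations)
    hit_rate = structural_hit_rate(annotations)
    if escape_denominator == "assigned":
        universe = [a.query_id for a in annotations if a.assigned]
    else:
        universe = [a.query_id for a in annotations]
    if universe:
        esc, _ = escape_rate(universe, homology_hits, evalue_max)
    else:
        esc = 0.0
    return ScanSummary(
        top_k=top_k,
        temperature=temperature,
        valid_fraction=filter_report.valid_fraction,
        n_folds_detected=n_folds,
        structural_hit_rate=hit_rate,
        sequence_escape_rate=esc,
    )


#: The hyperparameter grid of the scan experiment: six temperatures by
#: five top-k pool sizes.
SCAN_TEMPERATURES: Tuple[float, ...] = (0.8, 1.0, 1.2, 1.5, 2.0, 5.0)
SCAN_TOP_K: Tuple[int, ...] = (600, 950, 1500, 2400, 4000)


def default_grid() -> List[Tuple[int, float]]:
    """The 30 (top_k, temperature) cells, top_k major, temperature
    minor — the deterministic row order of the scan table."""
    return [(k, t) for k in SCAN_TOP_K for t in SCAN_TEMPERATURES]


def run_scan(
    grid: Sequence[Tuple[Optional[int], float]],
    cell_inputs,
    evalue_max: float = 0.01,
    escape_denominator: str = "assigned",
) -> List[ScanSummary]:
    """Summarize every grid cell.

    ``cell_inputs`` maps ``(top_k, temperature)`` to a
    ``(FilterReport, annotations, homology_hits)`` triple — either
    precomputed from files or produced live by a generation callback
    upstream.  Cells with missing inputs are skipped with a warning,
    not aborted.
    """
    rows: List[ScanSummary] = []
    for top_k, temperature in grid:
        key = (top_k, temperature)
        if callable(cell_inputs):
            triple = cell_inputs(top_k, temperature)
        else:
            triple = cell_inputs.get(key)
        if triple is None:
            logger.warning("grid cell %s missing inputs; skipped", key)
            continue
        report, annotations, hits = triple
        rows.append(
            summarize_run(
                report,
                annotations,
                hits,
                top_k=top_k,
                temperature=temperature,
                evalue_max=evalue_max,
                escape_denominator=escape_denominator,
            )
        )
    return rows


def write_scan_table(rows: Sequence[ScanSummary], path, digits: int = 3) -> None:
    """Scan table in the (top_k, temp, valid, folds, hit, escape)
    layout, values half-up rounded to ``digits`` decimals."""
    with open(path, "w") as fh:
        fh.write("#top_k\ttemp\tvalid_seq\tn_folds\tstruct_hit\tseq_esc\n")
        for row in rows:
            r = row.rounded(digits)
            fh.write(
                f"{r.top_k}\t{r.temperature:.3f}\t{r.valid_fraction:.3f}"
                f"\t{r.n_folds_detected}\t{r.structural_hit_rate:.3f}"
                f"\t{r.sequence_escape_rate:.3f}\n"
            )


def plan_inverse_folding_batch(n_templates: int, per_template: int) -> int:
    """Job count for sampling ``per_template`` sequences from each of
    ``n_templates`` backbone templates."""
    if n_templates < 0 or per_template < 0:
        raise ValueError("counts must be non-negative")
    return n_templates * per_template
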