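"""End-to-end census over one sequence batch.

Chains the filter pipeline, consensus fold annotation and escape
statistics over a batch's records and hit tables, returning every
headline statistic in one dictionary.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence

from foldcensus.annotation import (
    AnnotationConfig,
    SCOP_FOLD_UNIVERSE,
    annotate_batch,
    fold_inventory,
    structural_hit_rate,
    topology_distribution,
)
from foldcensus.filters import FilterConfig, apply_filter_pipeline
from foldcensus.novelty import HomologyHit, escape_rate
from foldcensus.sampling import SequenceRecord


def run_census(
    records: Sequence[SequenceRecord],
    structure_hits,
    homology_hits: Sequence[HomologyHit],
    fold_map: Mapping[str, str],
    filter_config: FilterConfig = FilterConfig(),
    annotation_config: AnnotationConfig = AnnotationConfig(),
    evalue_max: float = 0.01,
    dedup: bool = False,
    reference_fold_total: int = SCOP_FOLD_UNIVERSE,
) -> Dict:
    """Filter a batch, assign consensus folds, and measure escape.

    Returns counts and rates: valid fraction, structural hit rate,
    fold inventory and coverage of the reference fold universe, escape
    among assigned queries and among all valid queries, and the class
    topology distribution.
    """
    kept, report = apply_filter_pipeline(records, filter_config, dedup=dedup)
    annotations = annotate_batch(
        structure_hits, fold_map, annotation_config,
        query_ids=[r.id for r in kept],
    )
    n_folds, fold_counts, coverage = fold_inventory(
        annotations, reference_total=reference_fold_total
    )
    assigned_ids = [a.query_id for a in annotations if a.assigned]
    all_ids = [a.query_id for a in annotations]
    esc_assigned, escaped_set = (
        escape_rate(assigned_ids, homology_hits, evalue_max)
        if assigned_ids else (0.0, set())
    )
    esc_all = (
        escape_rate(all_ids, homology_hits, evalue_max)[0] if all_ids else 0.0
    )
    return {
        "n_input": report.n_input,
        "n_valid": report.n_input - report.n_invalid,
        "n_output": report.n_output,
        "valid_fraction": report.valid_fraction,
        "n_assigned": len(assigned_ids),
        "structural_hit_rate": structural_hit_rate(annotations),
        "n_folds_detected": n_folds,
        "fold_counts": dict(fold_counts),
        "fold_coverage": coverage,
        "n_escaped_assigned": len(escaped_set),
        "escape_rate_assigned": esc_assigned,
        "escape_rate_all": esc_all,
        "topology_distribution": topology_distribution(annotations),
        "filter_report": report,
        "annotations": annotations,
    }
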