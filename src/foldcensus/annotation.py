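"""Consensus fold assignment from structure-search hit tables.

Predicted structures are annotated at the fold level of the SCOP
hierarchy by majority vote over their structure-search hits: a hit
counts when its TM-score exceeds 0.5 and the larger of its query and
target coverages exceeds 0.8 (both inequalities strict), and the fold
accounting for the most surviving hits wins.  Ties are resolved
deterministically (highest TM-score among the tied folds, then
lexicographic fold id) and flagged.

The reciprocal-hit filter used to build a joint sequence–structure
fragment database applies a stricter rule: BOTH coverages must exceed
the threshold, in both search directions.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

logger = logging.getLogger(__name__)

#: Number of fold labels in the SCOP reference classification.
SCOP_FOLD_UNIVERSE = 1579

_FOLD_ID_RE = re.compile(r"^[a-z]\.[0-9]+$")


@dataclass(frozen=True)
class StructureHit:
    """One row of a structure-search result table."""

    query_id: str
    target_id: str
    tm_score: float
    query_coverage: float
    target_coverage: float

    def __post_init__(self):
        if not self.query_id or not self.target_id:
            raise ValueError("hit ids must be non-empty")
        for name in ("tm_score", "query_coverage", "target_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} {v} outside [0, 1]")


def validate_fold_id(fold_id: str) -> str:
    if not _FOLD_ID_RE.match(fold_id):
        raise ValueError(
            f"fold id {fold_id!r} does not match the class.number pattern (e.g. 'a.4')"
        )
    return fold_id


def fold_class(fold_id: str) -> str:
    """SCOP class letter: the fold-id prefix before the first dot
    (a = all-alpha, b = all-beta, c = alpha/beta, d = alpha+beta)."""
    return fold_id.split(".", 1)[0]


class FoldMap(Mapping[str, str]):
    """Total mapping from target domain ids to SCOP fold ids."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {k: validate_fold_id(v) for k, v in mapping.items()}

    def __getitem__(self, key: str) -> str:
        return self._map[key]

    def __iter__(self):
        return iter(self._map)

    def __len__(self):
        return len(self._map)

    @classmethod
    def from_tsv(cls, path) -> "FoldMap":
        """Read a two-column (domain_id, fold_id) tab-separated file.
        '#'-prefixed lines are comments."""
        mapping = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#domain_id\tfold_id\n")
            for k, v in self._map.items():
                fh.write(f"{k}\t{v}\n")


@dataclass(frozen=True)
class AnnotationConfig:
    """Thresholds and conventions of the consensus vote."""

    tm_min: float = 0.5
    cov_min: float = 0.8
    coverage_rule: str = "max_of_two"  # or "both"
    count_unique_targets: bool = False

    def __post_init__(self):
        if not 0 < self.tm_min < 1 or not 0 < self.cov_min < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.coverage_rule not in ("max_of_two", "both"):
            raise ValueError("coverage_rule must be 'max_of_two' or 'both'")


@dataclass
class FoldAnnotation:
    """Per-query consensus outcome with the underlying vote counts."""

    query_id: str
    assigned_fold: Optional[str]
    vote_counts: Dict[str, int] = field(default_factory=dict)
    tie_broken: bool = False

    @property
    def assigned(self) -> bool:
        return self.assigned_fold is not None


# default Foldseek --format-output "query,target,alntmscore,qcov,tcov"
DEFAULT_COLUMNS: Dict[str, int] = {
    "query_id": 0,
    "target_id": 1,
    "tm_score": 2,
    "query_coverage": 3,
    "target_coverage": 4,
}


def parse_structure_hits(
    path, column_spec: Optional[Dict[str, int]] = None
) -> List[StructureHit]:
    """Parse a tab-separated structure-search result file.

    ``column_spec`` maps field names to 0-based column positions
    (default matches query, target, TM-score, query coverage, target
    coverage).  A malformed numeric field raises with its line number;
    a row with a score outside [0, 1] is rejected and logged.
    """
    cols = dict(DEFAULT_COLUMNS if column_spec is None else column_spec)
    hits: List[StructureHit] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                fields = {
                    "query_id": parts[cols["query_id"]],
                    "target_id": parts[cols["target_id"]],
                    "tm_score": float(parts[cols["tm_score"]]),
                    "query_coverage": float(parts[cols["query_coverage"]]),
                    "target_coverage": float(parts[cols["target_coverage"]]),
                }
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            try:
                hits.append(StructureHit(**fields))
            except ValueError as exc:
                n_rejected += 1
                logger.warning("%s:%d: rejected hit: %s", path, lineno, exc)
    if not hits and n_rejected == 0:
        logger.warning("%s: no hit rows found", path)
    return hits


def write_structure_hits(hits: Sequence[StructureHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("#query\ttarget\talntmscore\tqcov\ttcov\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.tm_score:.4f}"
                f"\t{h.query_coverage:.4f}\t{h.target_coverage:.4f}\n"
            )


def _hit_passes(hit: StructureHit, config: AnnotationConfig) -> bool:
    if not hit.tm_score > config.tm_min:
        return False
    if config.coverage_rule == "max_of_two":
        return max(hit.query_coverage, hit.target_coverage) > config.cov_min
    return (
        hit.query_coverage > config.cov_min
        and hit.target_coverage > config.cov_min
    )


def assign_consensus_fold(
    hits: Sequence[StructureHit],
    fold_map: Mapping[str, str],
    config: AnnotationConfig = AnnotationConfig(),
) -> FoldAnnotation:
    """Plurality fold vote over one query's surviving hits.

    Hits failing the TM-score or coverage rule are discarded (strict
    inequalities).  Surviving hits vote for the fold of their target;
    the fold with the most votes is assigned, or none when no hit
    survives.  A plurality tie is broken by the highest TM-score within
    the tied folds, then by lexicographic fold id, and flagged.
    """
    if not hits:
        return FoldAnnotation(query_id="", assigned_fold=None)
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(query_ids)}")
    query_id = hits[0].query_id

    survivors = [h for h in hits if _hit_passes(h, config)]
    missing = sorted({h.target_id for h in survivors} - set(fold_map.keys()))
    if missing:
        raise KeyError(f"targets absent from fold map: {missing}")

    if config.count_unique_targets:
        best_by_target: Dict[str, StructureHit] = {}
        for h in survivors:
            prev = best_by_target.get(h.target_id)
            if prev is None or h.tm_score > prev.tm_score:
                best_by_target[h.target_id] = h
        survivors = list(best_by_target.values())

    votes: Counter = Counter()
    best_tm: Dict[str, float] = defaultdict(float)
    for h in survivors:
        fold = fold_map[h.target_id]
        votes[fold] += 1
        best_tm[fold] = max(best_tm[fold], h.tm_score)

    if not votes:
        return FoldAnnotation(query_id=query_id, assigned_fold=None)

    top = max(votes.values())
    tied = sorted(f for f, c in votes.items() if c == top)
    if len(tied) == 1:
        return FoldAnnotation(query_id, tied[0], dict(votes), tie_broken=False)
    # break by max TM-score within tied folds, then lexicographic fold id
    winner = min(tied, key=lambda f: (-best_tm[f], f))
    return FoldAnnotation(query_id, winner, dict(votes), tie_broken=True)


def annotate_batch(
    hits: Iterable[StructureHit],
    fold_map: Mapping[str, str],
    config: AnnotationConfig = AnnotationConfig(),
    query_ids: Optional[Iterable[str]] = None,
) -> List[FoldAnnotation]:
    """Group hits by query and assign a consensus fold to each.

    ``query_ids`` optionally supplies the full query universe; queries
    with zero hit rows (search tools omit them) are annotated none.
    """
    grouped: Dict[str, List[StructureHit]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    universe = list(query_ids) if query_ids is not None else sorted(grouped)
    annotations = []
    for qid in universe:
        if qid in grouped:
            annotations.append(assign_consensus_fold(grouped[qid], fold_map, config))
        else:
            annotations.append(FoldAnnotation(query_id=qid, assigned_fold=None))
    return annotations


def structural_hit_rate(annotations: Sequence[FoldAnnotation]) -> float:
    """Fraction of queries assignable to any fold label."""
    if not annotations:
        logger.warning("structural_hit_rate over an empty batch; returning 0")
        return 0.0
    return sum(a.assigned for a in annotations) / len(annotations)


def fold_inventory(
    annotations: Sequence[FoldAnnotation],
    reference_total: int = SCOP_FOLD_UNIVERSE,
) -> Tuple[int, Counter, float]:
    """Distinct assigned folds, per-fold counts, and the coverage
    fraction of the reference fold universe."""
    counts: Counter = Counter(
        a.assigned_fold for a in annotations if a.assigned
    )
    n_detected = len(counts)
    coverage = n_detected / reference_total if reference_total else 0.0
    return n_detected, counts, coverage


def topology_distribution(
    annotations: Sequence[FoldAnnotation],
) -> Dict[str, float]:
    """Fraction of assigned queries per SCOP class letter; fractions
    sum to one over the assigned set."""
    classes = Counter(
        fold_class(a.assigned_fold) for a in annotations if a.assigned
    )
    total = sum(classes.values())
    if total == 0:
        return {}
    return {c: n / total for c, n in sorted(classes.items())}


def fold_enrichment(
    generated_counts: Mapping[str, int],
    natural_counts: Mapping[str, int],
) -> Dict[str, float]:
    """Per-fold log2 frequency ratio, generated over natural, with
    add-one pseudocounts over the shared fold universe.

    For fold f with generated count g_f (total G) and natural count n_f
    (total N) over a universe of K folds:

        log2((g_f + 1) / (G + K)) - log2((n_f + 1) / (N + K))

    Swapping the two inputs negates every value.
    """
    import math

    universe = sorted(set(generated_counts) | set(natural_counts))
    if not universe:
        raise ValueError("empty fold universe")
    K = len(universe)
    G = sum(generated_counts.values())
    N = sum(natural_counts.values())
    return {
        f: math.log2((generated_counts.get(f, 0) + 1) / (G + K))
        - math.log2((natural_counts.get(f, 0) + 1) / (N + K))
        for f in universe
    }


def reciprocal_filter(
    hits_ab: Sequence[StructureHit],
    hits_ba: Sequence[StructureHit],
    tm_min: float = 0.5,
    cov_min: float = 0.8,
) -> Set[FrozenSet[str]]:
    """Reciprocal-hit screen for the sequence–structure fragment
    database: keep unordered pairs present in both search directions,
    each direction passing TM-score > tm_min AND query coverage >
    cov_min AND target coverage > cov_min (both coverages, unlike the
    consensus vote).  Exact-duplicate pairs collapse in the set."""
    config = AnnotationConfig(tm_min=tm_min, cov_min=cov_min, coverage_rule="both")
    fwd = {
        frozenset((h.query_id, h.target_id))
        for h in hits_ab
        if _hit_passes(h, config)
    }
    rev = {
        frozenset((h.query_id, h.target_id))
        for h in hits_ba
        if _hit_passes(h, config)
    }
    return fwd & rev


def write_annotations(annotations: Sequence[FoldAnnotation], path) -> None:
    """Annotation table: query, fold, class, vote total, tie flag."""
    with open(path, "w") as fh:
        fh.write("#query_id\tfold\tclass\tvotes\ttie_broken\n")
        for a in annotations:
            fold = a.assigned_fold or "-"
            cls = fold_class(a.assigned_fold) if a.assigned else "-"
            votes = a.vote_counts.get(a.assigned_fold, 0) if a.assigned else 0
            fh.write(f"{a.query_id}\t{fold}\t{cls}\t{votes}\t{int(a.tie_broken)}\n")


def read_annotations(path) -> List[FoldAnnotation]:
    annotations = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            qid, fold, _cls, votes, tie = line.split("\t")
            assigned = None if fold == "-" else fold
            vc = {fold: int(votes)} if assigned else {}
            annotations.append(
                FoldAnnotation(qid, assigned, vc, tie_broken=bool(int(tie)))
            )
    return annotations
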