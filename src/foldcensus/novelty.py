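"""Sequence-escape statistics from homology-search hit tables.

A generated sequence "escapes" when a sensitive homology search against
a reference sequence database returns no alignment hit of any length at
the stated E-value cutoff (0.01 by default, inclusive).  Search tools
omit no-hit queries from their tabular output, so the query universe
must be supplied independently of the hit file.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from foldcensus.annotation import FoldAnnotation

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 0.01


@dataclass(frozen=True)
class HomologyHit:
    """One row of a BLAST-m8 style homology search result."""

    query_id: str
    target_id: str
    evalue: float
    extra: Tuple[str, ...] = ()  # remaining m8 columns, carried opaquely

    def __post_init__(self):
        if not self.query_id or not self.target_id:
            raise ValueError("hit ids must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")


def parse_homology_hits(path) -> List[HomologyHit]:
    """Parse a 12-column BLAST-m8 / MMseqs2 tabular file.

    Columns: query, target, identity, alnlen, mismatch, gapopen,
    qstart, qend, tstart, tend, evalue, bits.  The E-value is read from
    column 11 (1-based); other columns are carried opaquely.
    """
    hits: List[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: expected >= 11 columns")
            try:
                evalue = float(parts[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad E-value ({exc})") from exc
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value {evalue}")
            hits.append(
                HomologyHit(
                    query_id=parts[0],
                    target_id=parts[1],
                    evalue=evalue,
                    extra=tuple(parts[2:10] + parts[11:]),
                )
            )
    return hits


def write_homology_hits(hits: Sequence[HomologyHit], path) -> None:
    """Write hits back out in the 12-column m8 dialect (filler values
    for unspecified alignment columns)."""
    with open(path, "w") as fh:
        for h in hits:
            extra = h.extra if len(h.extra) == 9 else ("100.0", "100", "0", "0", "1", "100", "1", "100", "100")
            fh.write(
                "\t".join(
                    [h.query_id, h.target_id, *extra[:8], f"{h.evalue:g}", extra[8]]
                )
                + "\n"
            )


def escape_rate(
    query_ids: Iterable[str],
    hits: Sequence[HomologyHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    inclusive: bool = True,
) -> Tuple[float, Set[str]]:
    """Fraction of queries with no qualifying homology hit.

    A hit qualifies at ``evalue <= evalue_max`` (inclusive boundary by
    default; set ``inclusive=False`` for strict ``<``).  Hits for
    queries outside the supplied universe are ignored with a warning.
    Returns ``(rate, escaped_id_set)``.
    """
    universe = set(query_ids)
    if not universe:
        raise ValueError("query universe must be non-empty")
    qualifies = (
        (lambda e: e <= evalue_max) if inclusive else (lambda e: e < evalue_max)
    )
    with_hit: Set[str] = set()
    unknown: Set[str] = set()
    for h in hits:
        if h.query_id not in universe:
            unknown.add(h.query_id)
            continue
        if qualifies(h.evalue):
            with_hit.add(h.query_id)
    if unknown:
        logger.warning(
            "ignored hits for %d query ids outside the universe", len(unknown)
        )
    escaped = universe - with_hit
    return len(escaped) / len(universe), escaped


def per_fold_escape(
    annotations: Sequence[FoldAnnotation],
    hits: Sequence[HomologyHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    inclusive: bool = True,
) -> Dict[str, float]:
    """Escape rate restricted to the queries assigned each fold.

    Folds with zero assigned queries are omitted.  The weighted mean of
    the per-fold rates (weights = assigned counts) equals the overall
    escape rate among assigned queries.
    """
    by_fold: Dict[str, List[str]] = defaultdict(list)
    for a in annotations:
        if a.assigned:
            by_fold[a.assigned_fold].append(a.query_id)
    out: Dict[str, float] = {}
    for fold, qids in sorted(by_fold.items()):
        rate, _ = escape_rate(qids, hits, evalue_max, inclusive)
        out[fold] = rate
    return out


def write_escape_table(
    query_ids: Sequence[str],
    hits: Sequence[HomologyHit],
    path,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> None:
    """Per-query escape table: id, number of qualifying hits, flag."""
    n_pass: Dict[str, int] = defaultdict(int)
    universe = set(query_ids)
    for h in hits:
        if h.query_id in universe and h.evalue <= evalue_max:
            n_pass[h.query_id] += 1
    with open(path, "w") as fh:
        fh.write("#query_id\tn_hits_pass\tescaped\n")
        for qid in query_ids:
            n = n_pass.get(qid, 0)
            fh.write(f"{qid}\t{n}\t{int(n == 0)}\n")
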