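"""Validity, truncation, deduplication and composition filters.

Generated sequences are screened for rare or ambiguous amino-acid codes
(B, J, O, U, X, Z), truncated to a maximal length, and exactly
deduplicated.  A stricter variant of the rules — minimum length,
structure resolution, and a cap on single-residue composition — applies
to experimental validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Optional, Sequence, Tuple

from foldcensus.sampling import FORBIDDEN_LETTERS, SequenceRecord


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the sequence filters.

    ``max_single_aa_fraction``, ``min_length`` and
    ``max_resolution_angstrom`` belong to the validation-set rules and
    are not applied by the generation pipeline unless requested.
    """

    forbidden_letters: FrozenSet[str] = FORBIDDEN_LETTERS
    max_length: int = 100
    max_single_aa_fraction: float = 0.20
    min_length: int = 21
    max_resolution_angstrom: float = 9.0

    def __post_init__(self):
        if self.max_length < 1 or self.min_length < 1:
            raise ValueError("length thresholds must be positive")
        if not 0 < self.max_single_aa_fraction <= 1:
            raise ValueError("max_single_aa_fraction must be in (0, 1]")
        if self.max_resolution_angstrom <= 0:
            raise ValueError("max_resolution_angstrom must be positive")


def is_valid_sequence(
    seq: str, config: FilterConfig = FilterConfig()
) -> Tuple[bool, str]:
    """True iff ``seq`` is non-empty and free of forbidden letters.

    Returns ``(ok, reason)``; the reason names the first offending
    letter.  Input must already be uppercase with no whitespace —
    normalization is the caller's job.
    """
    if seq != seq.strip().upper() or any(c.isspace() for c in seq):
        raise ValueError("sequence must be pre-cleaned (uppercase, no whitespace)")
    if not seq:
        return False, "empty"
    for c in seq:
        if c in config.forbidden_letters:
            return False, c
    return True, ""


def truncate_sequence(seq: str, max_length: int) -> str:
    """Prefix of length ``min(len(seq), max_length)``."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    return seq[:max_length]


def composition_filter(seq: str, max_fraction: float = 0.20) -> bool:
    """False iff any single residue strictly exceeds ``max_fraction`` of
    the sequence.  The boundary is exclusive: exactly 20% passes."""
    if not seq:
        raise ValueError("composition_filter needs a non-empty sequence")
    n = len(seq)
    for c in set(seq):
        if seq.count(c) / n > max_fraction:
            return False
    return True


def deduplicate(
    records: Sequence[SequenceRecord],
) -> Tuple[List[SequenceRecord], int]:
    """Drop exact residue-string duplicates, keeping first occurrences
    in input order.  Returns ``(kept, removed_count)``."""
    seen = set()
    kept = []
    for rec in records:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        kept.append(rec)
    return kept, len(records) - len(kept)


@dataclass
class FilterReport:
    """Per-stage in/out/removed counts for one filtered batch."""

    n_input: int = 0
    n_truncated: int = 0
    n_invalid: int = 0
    n_duplicates: int = 0
    n_output: int = 0

    @property
    def valid_fraction(self) -> float:
        """Fraction of input sequences surviving the validity screen
        (the "valid sequences" column of a scan summary)."""
        if self.n_input == 0:
            return 0.0
        return (self.n_input - self.n_invalid) / self.n_input

    def stages(self) -> List[Tuple[str, int, int, int]]:
        """(stage, in, out, removed) rows; counts are conserved at
        every stage."""
        after_valid = self.n_input - self.n_invalid
        return [
            ("truncate", self.n_input, self.n_input, 0),
            ("validity", self.n_input, after_valid, self.n_invalid),
            ("dedup", after_valid, self.n_output, self.n_duplicates),
        ]


def apply_filter_pipeline(
    records: Sequence[SequenceRecord],
    config: FilterConfig = FilterConfig(),
    dedup: bool = True,
) -> Tuple[List[SequenceRecord], FilterReport]:
    """Truncate, then screen validity, then (optionally) deduplicate.

    Truncation precedes the validity check, so a forbidden letter
    beyond the length cap does not invalidate a sequence.  The pipeline
    is idempotent: running it on its own output changes nothing.
    """
    report = FilterReport(n_input=len(records))
    truncated: List[SequenceRecord] = []
    for rec in records:
        cut = truncate_sequence(rec.sequence, config.max_length)
        if len(cut) != len(rec.sequence):
            report.n_truncated += 1
            rec = replace_sequence(rec, cut)
        truncated.append(rec)

    valid: List[SequenceRecord] = []
    for rec in truncated:
        ok, _ = is_valid_sequence(rec.sequence, config)
        if ok:
            valid.append(rec)
        else:
            report.n_invalid += 1

    if dedup:
        kept, removed = deduplicate(valid)
    else:
        kept, removed = list(valid), 0
    report.n_duplicates = removed
    report.n_output = len(kept)
    return kept, report


def replace_sequence(rec: SequenceRecord, sequence: str) -> SequenceRecord:
    return SequenceRecord(
        id=rec.id,
        sequence=sequence,
        source=rec.source,
        description=rec.description,
        params=rec.params,
    )


def validation_set_filter(
    records: Sequence[SequenceRecord],
    resolutions: Optional[Sequence[float]] = None,
    config: FilterConfig = FilterConfig(),
) -> Tuple[List[SequenceRecord], List[str]]:
    """Experimental-structure screen: drop entries with resolution
    above the cap, length at-or-below the minimum minus one (length
    <= 20 by default), forbidden letters, or any residue above the
    composition cap.  ``resolutions`` aligns with ``records``; ``None``
    entries skip the resolution rule.  Returns kept records and a
    parallel list of drop reasons for the removed ones."""
    if resolutions is not None and len(resolutions) != len(records):
        raise ValueError("resolutions must align with records")
    kept, reasons = [], []
    for i, rec in enumerate(records):
        res = resolutions[i] if resolutions is not None else None
        if res is not None and res > config.max_resolution_angstrom:
            reasons.append(f"{rec.id}: resolution {res} A")
            continue
        if len(rec.sequence) < config.min_length:
            reasons.append(f"{rec.id}: length {len(rec.sequence)}")
            continue
        ok, why = is_valid_sequence(rec.sequence, config)
        if not ok:
            reasons.append(f"{rec.id}: forbidden letter {why}")
            continue
        if not composition_filter(rec.sequence, config.max_single_aa_fraction):
            reasons.append(f"{rec.id}: composition")
            continue
        kept.append(rec)
    return kept, reasons
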