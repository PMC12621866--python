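"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to this pipeline come from GPU-scale language models and
multi-gigabyte structure/sequence databases.  The generators here stand
in for them at desk scale:

* toy Markov token models with exactly known sequence distributions
  (oracle substrate for the decoding engines),
* hit tables with planted assignable fractions, fold compositions and
  escape sets, realized as exact counts so counts-based statistics are
  recovered exactly, with sub-threshold decoy rows to exercise the
  filters,
* toy coordinate sets (isolated residues, ideal helices, extended
  chains, compact clusters) for the surface-area code.

Everything is deterministic under a fixed seed.  None of this attempts
to simulate realistic protein structures or homology statistics beyond
the thresholds the pipeline exercises.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from foldcensus.annotation import FoldMap, StructureHit
from foldcensus.novelty import HomologyHit
from foldcensus.sampling import (
    AMINO_ACIDS,
    BackgroundModel,
    SequenceRecord,
    SWISSPROT_ABUNDANCES,
    Vocabulary,
)

STOP_TOKEN = "<stop>"


class ToyMarkovModel:
    """First-order Markov chain over a small token vocabulary.

    Implements both sides of the token-model contract: the
    autoregressive conditional depends only on the last context token,
    and the masked conditional on the filled left neighbor (the right
    context is masked and carries no information in a left-to-right
    chain), so exact sequence probabilities follow by matrix products.
    """

    def __init__(
        self,
        vocabulary: Vocabulary,
        initial: np.ndarray,
        transition: np.ndarray,
    ):
        v = len(vocabulary)
        initial = np.asarray(initial, float)
        transition = np.asarray(transition, float)
        if initial.shape != (v,) or transition.shape != (v, v):
            raise ValueError("initial/transition shapes must match vocabulary")
        if abs(initial.sum() - 1) > 1e-9 or np.any(
            np.abs(transition.sum(axis=1) - 1) > 1e-9
        ):
            raise ValueError("rows must be probability vectors")
        self.vocabulary = vocabulary
        self.initial = initial
        self.transition = transition

    def next_token_probs(self, context: Tuple[int, ...]) -> np.ndarray:
        if not context:
            return self.initial.copy()
        return self.transition[context[-1]].copy()

    def masked_probs(self, template: Tuple[Optional[int], ...], position: int) -> np.ndarray:
        if position > 0 and template[position - 1] is not None:
            return self.transition[template[position - 1]].copy()
        return self.initial.copy()


def _letters(n: int) -> List[str]:
    return [AMINO_ACIDS[i] for i in range(n)]


def make_toy_markov_model(
    n_tokens: int = 3,
    structure: str = "uniform",
    seed: int = 0,
) -> ToyMarkovModel:
    """Build a small token model (``n_tokens`` including STOP) with
    exactly known transition probabilities.

    ``uniform``: every conditional is 1/n over all tokens.
    ``chain``: a deterministic token cycle ending in STOP, so a single
    sequence carries probability 1.
    ``two_mode``: two high-probability sequence families whose mode
    masses respond visibly to temperature; minor transitions are
    jittered from the seed but remain exactly recorded in the matrix.
    """
    if not 2 <= n_tokens <= 8:
        raise ValueError("n_tokens must be in [2, 8]")
    tokens = _letters(n_tokens - 1) + [STOP_TOKEN]
    vocab = Vocabulary(tokens, stop_index=n_tokens - 1)
    v = n_tokens
    if structure == "uniform":
        initial = np.full(v, 1.0 / v)
        transition = np.full((v, v), 1.0 / v)
    elif structure == "chain":
        initial = np.zeros(v)
        initial[0] = 1.0
        transition = np.zeros((v, v))
        for i in range(v - 1):
            transition[i, i + 1] = 1.0
        transition[v - 1, v - 1] = 1.0  # STOP row (never consulted)
    elif structure == "two_mode":
        if v < 4:
            raise ValueError("two_mode needs at least 4 tokens")
        rng = np.random.default_rng(seed)
        eps = 0.02 + 0.01 * rng.random()
        initial = np.full(v, eps / v)
        initial[0] += (1 - eps) * 0.5
        initial[1] += (1 - eps) * 0.5
        initial /= initial.sum()
        transition = np.full((v, v), eps / v)
        # family A: 0 -> 2 -> STOP; family B: 1 -> 3 -> STOP
        transition[0, 2] += 1 - eps
        transition[1, 3] += 1 - eps
        transition[2, v - 1] += 1 - eps
        transition[3, v - 1] += 1 - eps
        for j in range(4, v):
            transition[j, v - 1] += 1 - eps
        transition[v - 1, v - 1] += 1 - eps
        transition /= transition.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return ToyMarkovModel(vocab, initial, transition)


# ---------------------------------------------------------------------------
# Planted hit tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedBatchSpec:
    """Recipe for a synthetic batch with exactly realized counts.

    Fractions are converted to counts by round-half-up once, then used
    exactly (no sampling noise), so counts-based statistics recovered
    by the pipeline equal the planted truth to the last digit.
    """

    n_sequences: int
    invalid_fraction: float = 0.0
    assigned_fraction: float = 0.3
    n_distinct_folds: int = 10
    fold_weights: Optional[Tuple[float, ...]] = None
    escape_fraction_among_assigned: float = 0.5
    seq_length: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        for name in (
            "invalid_fraction", "assigned_fraction", "escape_fraction_among_assigned"
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_distinct_folds < 0:
            raise ValueError("n_distinct_folds must be non-negative")
        if self.fold_weights is not None and len(self.fold_weights) != self.n_distinct_folds:
            raise ValueError("fold_weights length must equal n_distinct_folds")

    @classmethod
    def from_counts(
        cls,
        n_valid: int,
        n_assigned: int,
        n_distinct_folds: int,
        n_escaped_among_assigned: int,
        n_invalid: int = 0,
        seed: int = 0,
        seq_length: int = 100,
    ) -> "PlantedBatchSpec":
        """Spec from target counts; the realized counts equal these
        exactly (fractions are derived, then re-rounded to the same
        integers)."""
        n_total = n_valid + n_invalid
        return cls(
            n_sequences=n_total,
            invalid_fraction=n_invalid / n_total,
            assigned_fraction=n_assigned / n_valid if n_valid else 0.0,
            n_distinct_folds=n_distinct_folds,
            escape_fraction_among_assigned=(
                n_escaped_among_assigned / n_assigned if n_assigned else 0.0
            ),
            seq_length=seq_length,
            seed=seed,
        )


def _exact_count(fraction: float, total: int) -> int:
    return int(math.floor(fraction * total + 0.5))


def fold_universe(n: int) -> List[str]:
    """Deterministic fold-id universe cycling the four SCOP classes:
    a.1, b.1, c.1, d.1, a.2, ..."""
    return [f"{'abcd'[i % 4]}.{i // 4 + 1}" for i in range(n)]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by ``weights``; each positive
    weight gets at least one unit when total allows."""
    k = weights.size
    if k == 0 or total == 0:
        return np.zeros(k, dtype=int)
    if total < k:
        counts = np.zeros(k, dtype=int)
        counts[np.argsort(-weights, kind="stable")[:total]] = 1
        return counts
    # reserve one per fold so every planted fold is detected
    remaining = total - k
    quota = weights / weights.sum() * remaining
    counts = np.floor(quota).astype(int)
    short = remaining - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts + 1


@dataclass
class PlantedBatch:
    """A synthetic batch plus its planted truth."""

    records: List[SequenceRecord]
    structure_hits: List[StructureHit]
    homology_hits: List[HomologyHit]
    fold_map: FoldMap
    truth: Dict

    def write(self, outdir: str) -> None:
        from foldcensus.annotation import write_structure_hits
        from foldcensus.io import write_fasta
        from foldcensus.novelty import write_homology_hits

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.records, os.path.join(outdir, "sequences.fasta"))
        write_structure_hits(
            self.structure_hits, os.path.join(outdir, "structure_hits.tsv")
        )
        write_homology_hits(
            self.homology_hits, os.path.join(outdir, "homology_hits.m8")
        )
        self.fold_map.to_tsv(os.path.join(outdir, "fold_map.tsv"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def make_synthetic_hit_tables(
    spec: PlantedBatchSpec,
    sequences: bool = True,
) -> PlantedBatch:
    """Generate a batch with planted assignability, fold composition
    and escape structure.

    Assignable queries each receive two hits passing the consensus
    thresholds that vote their planted fold, plus one sub-threshold
    decoy; a third of unassignable queries receive only sub-threshold
    rows and the rest none.  Escaped queries get no homology hit at or
    below E = 0.01 (half receive a decoy at E = 0.5); every other valid
    query gets one hit at E = 1e-5.  ``sequences=False`` skips residue
    strings (ids only) for large count-only runs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    n_invalid = _exact_count(spec.invalid_fraction, n)
    n_valid = n - n_invalid
    n_assigned = _exact_count(spec.assigned_fraction, n_valid)
    n_escaped = _exact_count(spec.escape_fraction_among_assigned, n_assigned)
    n_folds = min(spec.n_distinct_folds, n_assigned)

    ids = [f"q{i:06d}" for i in range(n)]

    records: List[SequenceRecord] = []
    if sequences:
        letters = np.frombuffer(AMINO_ACIDS.encode(), np.uint8)
        draws = rng.choice(
            letters, size=(n, spec.seq_length), p=np.asarray(SWISSPROT_ABUNDANCES)
        )
        seqs = [draws[i].tobytes().decode() for i in range(n)]
    else:
        seqs = ["A" * spec.seq_length] * n

    invalid_idx = set(rng.choice(n, size=n_invalid, replace=False).tolist())
    for i in range(n):
        s = seqs[i]
        if i in invalid_idx:
            pos = int(rng.integers(spec.seq_length))
            s = s[:pos] + "X" + s[pos + 1:]
        records.append(SequenceRecord(id=ids[i], sequence=s, source="planted"))

    valid_ids = [ids[i] for i in range(n) if i not in invalid_idx]
    perm = rng.permutation(n_valid)
    assigned_ids = [valid_ids[j] for j in perm[:n_assigned]]
    unassigned_ids = [valid_ids[j] for j in perm[n_assigned:]]

    folds = fold_universe(n_folds)
    weights = (
        np.asarray(spec.fold_weights, float)[:n_folds]
        if spec.fold_weights is not None
        else np.exp(-0.05 * np.arange(n_folds))  # mildly skewed composition
    )
    fold_counts = _largest_remainder(weights, n_assigned)
    fold_of: Dict[str, str] = {}
    cursor = 0
    for fold, count in zip(folds, fold_counts):
        for qid in assigned_ids[cursor: cursor + count]:
            fold_of[qid] = fold
        cursor += count

    # two reference domains per fold
    fold_map = FoldMap(
        {f"d_{fold}_{j}": fold for fold in folds for j in (0, 1)}
    )
    all_targets = sorted(fold_map)

    structure_hits: List[StructureHit] = []
    for qid in assigned_ids:
        fold = fold_of[qid]
        for j in (0, 1):
            structure_hits.append(
                StructureHit(
                    query_id=qid,
                    target_id=f"d_{fold}_{j}",
                    tm_score=float(rng.uniform(0.55, 0.95)),
                    query_coverage=float(rng.uniform(0.85, 0.99)),
                    target_coverage=float(rng.uniform(0.3, 0.7)),
                )
            )
        # decoy below the TM threshold; must not flip the vote
        structure_hits.append(
            StructureHit(
                query_id=qid,
                target_id=all_targets[int(rng.integers(len(all_targets)))] if all_targets else "d_none",
                tm_score=float(rng.uniform(0.05, 0.45)),
                query_coverage=float(rng.uniform(0.85, 0.99)),
                target_coverage=float(rng.uniform(0.3, 0.7)),
            )
        )
    if all_targets:
        for k, qid in enumerate(unassigned_ids):
            if k % 3 == 0:  # a third get sub-threshold rows, the rest none
                structure_hits.append(
                    StructureHit(
                        query_id=qid,
                        target_id=all_targets[int(rng.integers(len(all_targets)))],
                        tm_score=float(rng.uniform(0.05, 0.45)),
                        query_coverage=float(rng.uniform(0.2, 0.75)),
                        target_coverage=float(rng.uniform(0.2, 0.75)),
                    )
                )

    escaped_ids = set(assigned_ids[:n_escaped])
    homology_hits: List[HomologyHit] = []
    for k, qid in enumerate(valid_ids):
        if qid in escaped_ids:
            if k % 2 == 0:  # decoy above the E-value cutoff
                homology_hits.append(
                    HomologyHit(query_id=qid, target_id="UR50_decoy", evalue=0.5)
                )
        else:
            homology_hits.append(
                HomologyHit(query_id=qid, target_id=f"UR50_{k:06d}", evalue=1e-5)
            )

    truth = {
        "n_sequences": n,
        "n_invalid": n_invalid,
        "n_valid": n_valid,
        "valid_fraction": n_valid / n,
        "n_assigned": n_assigned,
        "assigned_fraction": n_assigned / n_valid if n_valid else 0.0,
        "n_distinct_folds": n_folds,
        "fold_counts": {f: int(c) for f, c in zip(folds, fold_counts)},
        "n_escaped_among_assigned": n_escaped,
        "escape_fraction_among_assigned": (
            n_escaped / n_assigned if n_assigned else 0.0
        ),
        "escape_fraction_among_valid": n_escaped / n_valid if n_valid else 0.0,
        "seed": spec.seed,
    }
    return PlantedBatch(records, structure_hits, homology_hits, fold_map, truth)


# ---------------------------------------------------------------------------
# Toy coordinates
# ---------------------------------------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:>5d}  {name:<3s}{res:>4s} A{resi:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
)


def _pdb_text(atoms: Sequence[Tuple[int, str, str, str, float, float, float]]) -> str:
    lines = []
    for serial, (resi, res, name, element, x, y, z) in enumerate(atoms, 1):
        lines.append(
            _PDB_ATOM.format(
                serial=serial, name=name, res=res, resi=resi,
                x=x, y=y, z=z, element=element,
            )
        )
    lines.append("END\n")
    return "".join(lines)


def make_toy_coordinates(
    kind: str,
    n_residues: int = 10,
    seed: int = 0,
) -> str:
    """Minimal synthetic PDB text for surface-area fixtures.

    ``isolated_residue``: one residue whose atoms sit far apart, so its
    surface area is an exact sum of isolated spheres (a synthetic
    geometry, not a physical conformer).
    ``ideal_helix``: a C-alpha trace with canonical alpha-helix
    geometry (1.5 A rise, 100 degrees per residue, 2.3 A radius).
    ``extended_chain``: residues spaced far beyond contact, so areas
    are exactly additive.
    ``compact_cluster``: the same composition packed on a tight cubic
    grid, strictly more buried than the extended arrangement.
    """
    rng = np.random.default_rng(seed)
    atoms: List[Tuple[int, str, str, str, float, float, float]] = []
    if kind == "isolated_residue":
        names = ["N", "CA", "C", "O", "CB"]
        elements = ["N", "C", "C", "O", "C"]
        for j, (nm, el) in enumerate(zip(names, elements)):
            atoms.append((1, "ALA", nm, el, 100.0 * j, 0.0, 0.0))
    elif kind == "ideal_helix":
        rise, twist, radius = 1.5, math.radians(100.0), 2.3
        for i in range(n_residues):
            atoms.append(
                (
                    i + 1, "ALA", "CA", "C",
                    radius * math.cos(i * twist),
                    radius * math.sin(i * twist),
                    rise * i,
                )
            )
    elif kind == "extended_chain":
        for i in range(n_residues):
            atoms.append((i + 1, "ALA", "CA", "C", 100.0 * i, 0.0, 0.0))
    elif kind == "compact_cluster":
        side = max(1, math.ceil(n_residues ** (1 / 3)))
        spacing = 3.8
        placed = 0
        for ix in range(side):
            for iy in range(side):
                for iz in range(side):
                    if placed >= n_residues:
                        break
                    jitter = rng.uniform(-0.1, 0.1, size=3)
                    atoms.append(
                        (
                            placed + 1, "ALA", "CA", "C",
                            spacing * ix + jitter[0],
                            spacing * iy + jitter[1],
                            spacing * iz + jitter[2],
                        )
                    )
                    placed += 1
    else:
        raise ValueError(f"unknown coordinate kind {kind!r}")
    return _pdb_text(atoms)
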