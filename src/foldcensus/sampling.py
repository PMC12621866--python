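"""Decoding engines over pluggable token-probability models.

Three generation schemes used to sample protein sequences from language
models are reproduced here over an abstract :class:`TokenModel` seam:

* autoregressive left-to-right next-token decoding with the full
  temperature / top-k / nucleus / repetition-penalty transform chain,
* single-pass left-to-right Gibbs sampling for masked (bidirectional)
  models, filling a fixed-length masked template one position at a time,
* a position-independent background sampler weighting residues by their
  natural abundance.

Real neural models attach through the :class:`TokenModel` contract via
user-supplied adapters; nothing in this module performs inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np

#: The 20 proteinogenic amino acids (one-letter codes, alphabetical).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguous / rare one-letter codes excluded from generation alphabets.
FORBIDDEN_LETTERS = frozenset("BJOUXZ")

_PROB_ATOL = 1e-9


def _validate_probs(probs: np.ndarray, name: str = "probs") -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.all(np.isfinite(probs)) or np.any(probs < 0):
        raise ValueError(f"{name} must be finite and non-negative")
    if abs(probs.sum() - 1.0) > _PROB_ATOL:
        raise ValueError(f"{name} must sum to 1 (got {probs.sum():.12f})")
    return probs


@dataclass(frozen=True)
class Vocabulary:
    """An ordered token inventory with a distinguished STOP symbol.

    Tokens are non-empty strings over the 20-letter amino-acid alphabet;
    a token may cover several residues (a "subword"), as in models that
    decode short amino-acid subsequences rather than single residues.
    """

    tokens: Tuple[str, ...]
    stop_index: int

    def __init__(self, tokens: Sequence[str], stop_index: int):
        tokens = tuple(tokens)
        if len(tokens) < 2:
            raise ValueError("vocabulary needs at least 2 tokens")
        if len(set(tokens)) != len(tokens):
            raise ValueError("vocabulary tokens must be unique")
        if not 0 <= stop_index < len(tokens):
            raise ValueError(f"stop_index {stop_index} out of range")
        for i, tok in enumerate(tokens):
            if i == stop_index:
                continue
            if not tok or any(c not in AMINO_ACIDS for c in tok):
                raise ValueError(
                    f"token {tok!r} is not a non-empty string over {AMINO_ACIDS}"
                )
        object.__setattr__(self, "tokens", tokens)
        object.__setattr__(self, "stop_index", stop_index)

    def __len__(self) -> int:
        return len(self.tokens)

    def decode(self, indices: Sequence[int]) -> str:
        """Concatenate the residue strings of non-STOP tokens."""
        return "".join(
            self.tokens[i] for i in indices if i != self.stop_index
        )


@runtime_checkable
class TokenModel(Protocol):
    """Conditional-distribution contract between the pipeline and a model.

    ``next_token_probs`` (autoregressive mode) maps a left context — a
    tuple of token indices — to a probability vector over the
    vocabulary.  ``masked_probs`` (masked mode, optional) maps a
    fixed-length template with ``None`` at unfilled positions plus one
    designated position to the conditional distribution at that
    position.  Both must be deterministic for a fixed input and return
    vectors that are non-negative and sum to one within 1e-9.
    """

    vocabulary: Vocabulary

    def next_token_probs(self, context: Tuple[int, ...]) -> np.ndarray: ...


def supports_masked(model: object) -> bool:
    return callable(getattr(model, "masked_probs", None))


@dataclass(frozen=True)
class SamplingParams:
    """Decoding knobs.

    Defaults are the autoregressive scheme's: temperature 1, top-k pool
    of 950 tokens, nucleus mass 1.0 (off), repetition penalty 1.2,
    termination after the 40th token or the first STOP, and truncation
    of the residue string at 100 amino acids.  The Gibbs scheme uses
    temperature 1, no penalty, the full token distribution, and a
    100-position template (see :func:`gibbs_defaults`).
    """

    temperature: float = 1.0
    top_k: Optional[int] = 950
    top_p: float = 1.0
    repetition_penalty: float = 1.2
    max_tokens: int = 40
    max_residues: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (self.temperature > 0 and np.isfinite(self.temperature)):
            raise ValueError("temperature must be a positive real")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.top_p <= 1:
            raise ValueError("top_p must be in (0, 1]")
        if self.repetition_penalty < 1:
            raise ValueError("repetition_penalty must be >= 1")
        if self.max_tokens < 1 or self.max_residues < 1:
            raise ValueError("max_tokens and max_residues must be positive")


def gibbs_defaults(seed: int = 0, max_residues: int = 100) -> SamplingParams:
    """Default knobs for the masked-model Gibbs scheme: temperature 1,
    no repetition penalty, full distribution, 100-residue template."""
    return SamplingParams(
        temperature=1.0, top_k=None, top_p=1.0, repetition_penalty=1.0,
        max_tokens=max_residues, max_residues=max_residues, seed=seed,
    )


@dataclass(frozen=True)
class BackgroundModel:
    """Position-independent residue sampler at natural abundances."""

    abundances: Tuple[float, ...]
    length: int = 100

    def __init__(self, abundances: Sequence[float], length: int = 100):
        probs = _validate_probs(np.asarray(abundances, float), "abundances")
        if probs.size != len(AMINO_ACIDS):
            raise ValueError(f"abundances must have {len(AMINO_ACIDS)} entries")
        if length < 1:
            raise ValueError("length must be positive")
        object.__setattr__(self, "abundances", tuple(probs))
        object.__setattr__(self, "length", int(length))


#: SwissProt-style amino-acid relative abundances (alphabetical ACDE...),
#: normalized to 1.  Used as the default background composition.
_SWISSPROT_PCT = np.array(
    [
        8.25, 1.38, 5.46, 6.72, 3.86, 7.07, 2.27, 5.91, 5.80, 9.65,
        2.41, 4.06, 4.74, 3.93, 5.53, 6.64, 5.35, 6.86, 1.10, 2.92,
    ]
)
SWISSPROT_ABUNDANCES: Tuple[float, ...] = tuple(_SWISSPROT_PCT / _SWISSPROT_PCT.sum())


@dataclass
class SequenceRecord:
    """One generated sequence plus its provenance."""

    id: str
    sequence: str
    source: str = ""
    description: str = ""
    params: Optional[SamplingParams] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")


# ---------------------------------------------------------------------------
# The transform chain: penalty -> temperature -> top_k -> top_p -> renorm
# ---------------------------------------------------------------------------

def apply_temperature(logits: np.ndarray, temperature: float) -> np.ndarray:
    """Softmax of ``logits / temperature``.

    Raising the temperature flattens the distribution over the token
    pool; lowering it sharpens it toward the argmax.  Token ranking is
    preserved for every positive temperature.
    """
    if not (temperature > 0 and np.isfinite(temperature)):
        raise ValueError("temperature must be a positive real")
    logits = np.asarray(logits, dtype=float)
    if np.any(np.isnan(logits)) or np.any(logits == np.inf):
        raise ValueError("logits must be finite (or -inf for zero mass)")
    scaled = logits / temperature
    # max-subtraction for numerical stability; -inf rows stay -inf
    m = np.max(scaled)
    if not np.isfinite(m):
        raise ValueError("all logits are -inf; distribution undefined")
    ex = np.exp(scaled - m)
    return ex / ex.sum()


def filter_top_k(probs: np.ndarray, k: int) -> np.ndarray:
    """Zero all but the ``k`` highest-probability tokens and renormalize.

    Ties at the pool boundary are broken by token index (stable sort),
    so the operation is deterministic.
    """
    probs = _validate_probs(probs)
    if not 1 <= k <= probs.size:
        raise ValueError(f"top_k must be in [1, {probs.size}], got {k}")
    if k == probs.size:
        return probs.copy()
    order = np.argsort(-probs, kind="stable")
    out = np.zeros_like(probs)
    keep = order[:k]
    out[keep] = probs[keep]
    total = out.sum()
    if total <= 0:
        raise ValueError("top_k pool has zero mass")
    return out / total


def filter_top_p(probs: np.ndarray, p: float) -> np.ndarray:
    """Nucleus filter: keep the smallest descending-sorted prefix whose
    cumulative mass reaches ``p``, renormalized.  ``p == 1`` is the
    identity."""
    probs = _validate_probs(probs)
    if not 0 < p <= 1:
        raise ValueError(f"top_p must be in (0, 1], got {p}")
    if p == 1.0:
        return probs.copy()
    order = np.argsort(-probs, kind="stable")
    csum = np.cumsum(probs[order])
    # index of the first prefix with cumulative mass >= p
    cut = int(np.searchsorted(csum, p, side="left")) + 1
    keep = order[:cut]
    out = np.zeros_like(probs)
    out[keep] = probs[keep]
    return out / out.sum()


def apply_repetition_penalty(
    logits: np.ndarray, history: set, penalty: float
) -> np.ndarray:
    """Sign-dependent logit penalty for already-emitted tokens.

    For each token index in ``history``: a positive logit is divided by
    the penalty, a negative logit multiplied by it; tokens outside the
    history are untouched.  ``penalty == 1`` is the identity.
    """
    if penalty < 1:
        raise ValueError("repetition penalty must be >= 1")
    logits = np.asarray(logits, dtype=float).copy()
    if penalty == 1.0 or not history:
        return logits
    idx = np.fromiter(history, dtype=int)
    vals = logits[idx]
    logits[idx] = np.where(vals > 0, vals / penalty, vals * penalty)
    return logits


def transform_distribution(
    probs: np.ndarray, history: set, params: SamplingParams
) -> np.ndarray:
    """Full per-step transform: repetition penalty on log-probabilities,
    then temperature, then top-k, then nucleus, then renormalization."""
    probs = _validate_probs(probs, "model probabilities")
    with np.errstate(divide="ignore"):
        logits = np.log(probs)
    logits = apply_repetition_penalty(logits, history, params.repetition_penalty)
    out = apply_temperature(logits, params.temperature)
    k = params.top_k if params.top_k is not None else out.size
    out = filter_top_k(out, min(k, out.size))
    out = filter_top_p(out, params.top_p)
    total = out.sum()
    if total <= 0:
        raise RuntimeError("all probability mass filtered out")
    return out / total


def sample_next_token(
    model: TokenModel,
    context: Sequence[int],
    params: SamplingParams,
    rng: np.random.Generator,
) -> int:
    """Draw one token index from the post-transform conditional."""
    probs = model.next_token_probs(tuple(context))
    dist = transform_distribution(probs, set(context), params)
    return int(rng.choice(dist.size, p=dist))


# ---------------------------------------------------------------------------
# Generation engines
# ---------------------------------------------------------------------------

def _substream(seed: int, index: int) -> np.random.Generator:
    # counter-based substream derived by sequence index: n is parallelizable
    # without changing results
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


class _DistCache:
    """Memoizes post-transform cumulative distributions per context.

    Valid because the model contract is deterministic and the penalty
    history is a pure function of the context.
    """

    def __init__(self, model: TokenModel, params: SamplingParams):
        self.model = model
        self.params = params
        self._cum: Dict[Tuple[int, ...], np.ndarray] = {}

    def draw(self, context: Tuple[int, ...], rng: np.random.Generator) -> int:
        cum = self._cum.get(context)
        if cum is None:
            probs = self.model.next_token_probs(context)
            dist = transform_distribution(probs, set(context), self.params)
            cum = np.cumsum(dist)
            cum[-1] = 1.0
            self._cum[context] = cum
        return int(np.searchsorted(cum, rng.random(), side="right"))


def generate_autoregressive(
    model: TokenModel,
    params: SamplingParams,
    n: int,
    seed: Optional[int] = None,
    source: str = "ar",
) -> List[SequenceRecord]:
    """Sample ``n`` sequences token-by-token, left to right.

    Each sequence grows until the first STOP token or ``max_tokens``
    tokens, whichever comes first; STOP contributes no residues.  The
    concatenated residue string is then truncated to ``max_residues``
    (a multi-residue token is kept whole before the cut).  Output is
    bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vocab = model.vocabulary
    if params.top_k is not None and params.top_k > len(vocab):
        raise ValueError(
            f"top_k {params.top_k} exceeds vocabulary size {len(vocab)}"
        )
    base_seed = params.seed if seed is None else seed
    cache = _DistCache(model, params)
    records = []
    for i in range(n):
        rng = _substream(base_seed, i)
        context: Tuple[int, ...] = ()
        for _ in range(params.max_tokens):
            idx = cache.draw(context, rng)
            if idx == vocab.stop_index:
                break
            context = context + (idx,)
        seq = vocab.decode(context)[: params.max_residues]
        records.append(
            SequenceRecord(
                id=f"{source}_{i:06d}", sequence=seq, source=source, params=params
            )
        )
    return records


def generate_gibbs_lr(
    model: TokenModel,
    params: SamplingParams,
    n: int,
    seed: Optional[int] = None,
    source: str = "gibbs",
) -> List[SequenceRecord]:
    """Left-to-right Gibbs sampling from a masked model.

    A fixed-length template of ``max_residues`` positions starts fully
    masked and is filled one position at a time, left to right, each
    draw conditioned on the filled left context and the masked right
    context.  A single pass is made (positions are not revisited).
    STOP is sampleable at any position and cuts the sequence before it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not supports_masked(model):
        raise TypeError("model does not implement masked_probs (masked mode)")
    vocab = model.vocabulary
    base_seed = params.seed if seed is None else seed
    records = []
    for i in range(n):
        rng = _substream(base_seed, i)
        template: List[Optional[int]] = [None] * params.max_residues
        filled: List[int] = []
        for pos in range(params.max_residues):
            probs = model.masked_probs(tuple(template), pos)
            dist = transform_distribution(probs, set(filled), params)
            cum = np.cumsum(dist)
            cum[-1] = 1.0
            idx = int(np.searchsorted(cum, rng.random(), side="right"))
            if idx == vocab.stop_index:
                break
            template[pos] = idx
            filled.append(idx)
        seq = vocab.decode(filled)[: params.max_residues]
        records.append(
            SequenceRecord(
                id=f"{source}_{i:06d}", sequence=seq, source=source, params=params
            )
        )
    return records


def generate_background(
    background: BackgroundModel,
    n: int,
    seed: int = 0,
    source: str = "background",
) -> List[SequenceRecord]:
    """Draw ``n`` fixed-length sequences i.i.d. per position at the
    background abundances.  No STOP, no truncation, and no rare or
    ambiguous letters can occur by construction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    probs = np.asarray(background.abundances)
    draws = rng.choice(letters, size=(n, background.length), p=probs)
    return [
        SequenceRecord(
            id=f"{source}_{i:06d}",
            sequence=draws[i].tobytes().decode(),
            source=source,
        )
        for i in range(n)
    ]


def enumerate_sequence_distribution(
    model: TokenModel,
    params: SamplingParams,
    max_len: int,
    path_budget: int = 10**6,
) -> Dict[str, float]:
    """Exact output-sequence distribution by exhaustive path enumeration.

    Walks every token path under the same transform chain as the
    sampler, terminating at STOP or ``max_len`` tokens, and accumulates
    the probability of each terminated-or-truncated residue string
    (truncated to ``params.max_residues``).  Serves as the independent
    oracle for the stochastic engines on toy vocabularies.
    """
    vocab = model.vocabulary
    if len(vocab) ** max_len > path_budget:
        raise ValueError(
            f"|V|^max_len = {len(vocab)}^{max_len} exceeds the "
            f"{path_budget} path budget"
        )
    out: Dict[str, float] = {}

    def walk(context: Tuple[int, ...], prob: float):
        probs = model.next_token_probs(context)
        dist = transform_distribution(probs, set(context), params)
        for idx in np.flatnonzero(dist > 0):
            p = prob * dist[idx]
            if idx == vocab.stop_index or len(context) + 1 >= max_len:
                toks = context if idx == vocab.stop_index else context + (int(idx),)
                seq = vocab.decode(toks)[: params.max_residues]
                out[seq] = out.get(seq, 0.0) + p
            else:
                walk(context + (int(idx),), p)

    walk((), 1.0)
    return out


def total_variation(p: Dict[str, float], q: Dict[str, float]) -> float:
    """Total-variation distance between two sequence distributions."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def empirical_distribution(records: Sequence[SequenceRecord]) -> Dict[str, float]:
    """Relative frequency of each distinct residue string in a batch."""
    counts: Dict[str, float] = {}
    for rec in records:
        counts[rec.sequence] = counts.get(rec.sequence, 0.0) + 1.0
    n = float(len(records))
    return {k: v / n for k, v in counts.items()}
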