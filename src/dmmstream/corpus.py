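"""Core domain types and I/O for multi-stream token corpora.

An observation unit is a *segment*: one audio segment represented, per
stream (e.g. one beamforming direction), by a sequence of discrete
acoustic words.  Words are dense 0-based integer identifiers per stream;
the string<->id mapping lives only in :class:`StreamSchema`.  Segments
optionally carry an activity label and a cross-validation fold index
(0-based).

File formats
------------
* Corpus: JSON-Lines, one object per segment
  ``{"id": str, "label": str|null, "fold": int|null, "streams": {name: [word, ...]}}``
  where words are their string form.
* Code matrix: TSV, one row per frame, one integer column per codebook
  level.
* Model: a single JSON document holding every field of
  :class:`DmmModelState` with integers stored losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CorpusFormatError, IntegrityError, SchemaViolationError

_MODEL_FORMAT_VERSION = 1


@dataclass
class StreamSchema:
    """Per-stream vocabularies: ordered word strings with corpus counts.

    The order of ``vocabularies[stream]`` defines the integer id of each
    word (position = id).  Counts are total corpus occurrences and are
    bookkeeping only; they do not enter the model.
    """

    streams: list[str]
    vocabularies: dict[str, list[str]]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.streams:
            vocab = self.vocabularies[s]
            if len(set(vocab)) != len(vocab):
                raise SchemaViolationError(f"duplicate word strings in stream {s!r}")
            if s not in self.counts:
                self.counts[s] = np.zeros(len(vocab), dtype=np.int64)
            else:
                self.counts[s] = np.asarray(self.counts[s], dtype=np.int64)
                if (self.counts[s] < 0).any():
                    raise SchemaViolationError(f"negative word count in stream {s!r}")
                if len(self.counts[s]) != len(vocab):
                    raise SchemaViolationError(f"count/vocabulary length mismatch in stream {s!r}")

    def vocab_size(self, stream: str) -> int:
        return len(self.vocabularies[stream])

    def word_ids(self, stream: str) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabularies[stream])}

    def to_json_obj(self) -> dict:
        return {
            "streams": list(self.streams),
            "vocabularies": {s: list(self.vocabularies[s]) for s in self.streams},
            "counts": {s: self.counts[s].tolist() for s in self.streams},
        }

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "StreamSchema":
        return cls(
            streams=list(obj["streams"]),
            vocabularies={s: list(v) for s, v in obj["vocabularies"].items()},
            counts={s: np.asarray(c, dtype=np.int64) for s, c in obj.get("counts", {}).items()},
        )


@dataclass
class Segment:
    """One observation: per-stream word-id sequences plus optional label/fold.

    Sequence lengths may differ across streams and across segments;
    temporal order is preserved even though the mixture model is
    order-invariant (counts are sufficient statistics).
    """

    id: str
    tokens: dict[str, np.ndarray]
    label: str | None = None
    fold: int | None = None

    def __post_init__(self) -> None:
        self.tokens = {s: np.asarray(t, dtype=np.int64) for s, t in self.tokens.items()}
        if self.fold is not None and self.fold < 0:
            raise CorpusFormatError(f"segment {self.id!r}: negative fold index")


@dataclass
class Corpus:
    """Ordered collection of segments sharing one :class:`StreamSchema`."""

    schema: StreamSchema
    segments: list[Segment]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise CorpusFormatError("empty corpus")
        ids = [seg.id for seg in self.segments]
        if len(set(ids)) != len(ids):
            raise CorpusFormatError("duplicate segment ids")
        for seg in self.segments:
            for s in self.schema.streams:
                toks = seg.tokens.get(s)
                if toks is None:
                    seg.tokens[s] = np.zeros(0, dtype=np.int64)
                    continue
                v = self.schema.vocab_size(s)
                if toks.size and (toks.min() < 0 or toks.max() >= v):
                    raise SchemaViolationError(
                        f"segment {seg.id!r}, stream {s!r}: word id out of [0, {v})"
                    )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def M(self) -> int:
        return len(self.segments)

    def labels(self) -> list[str | None]:
        return [seg.label for seg in self.segments]

    def folds(self) -> list[int | None]:
        return [seg.fold for seg in self.segments]

    def segment_index(self) -> dict[str, int]:
        return {seg.id: i for i, seg in enumerate(self.segments)}


@dataclass
class CodeMatrix:
    """Integer codes of one segment: shape (frames, codebook levels)."""

    segment_id: str
    codes: np.ndarray
    codebook_sizes: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise CorpusFormatError(f"code matrix for {self.segment_id!r} is not 2-D")
        if self.codes.size and self.codes.min() < 0:
            raise CorpusFormatError(f"negative code in matrix for {self.segment_id!r}")
        if self.codebook_sizes is not None:
            sizes = np.asarray(self.codebook_sizes, dtype=np.int64)
            if sizes.shape[0] != self.codes.shape[1]:
                raise CorpusFormatError("codebook_sizes length != number of levels")
            if self.codes.size and (self.codes >= sizes[None, :]).any():
                raise CorpusFormatError(f"code out of codebook range for {self.segment_id!r}")

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_levels(self) -> int:
        return self.codes.shape[1]


# ---------------------------------------------------------------------------
# Corpus I/O


def _segment_record(seg: Segment, schema: StreamSchema) -> dict:
    return {
        "id": seg.id,
        "label": seg.label,
        "fold": seg.fold,
        "streams": {
            s: [schema.vocabularies[s][t] for t in seg.tokens[s]] for s in schema.streams
        },
    }


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Serialize a corpus as JSON-Lines; inverse of :func:`read_corpus`."""
    path = Path(path)
    with path.open("w") as fh:
        for seg in corpus.segments:
            fh.write(json.dumps(_segment_record(seg, corpus.schema), sort_keys=True))
            fh.write("\n")
    return path


def read_corpus(path: str | Path, schema: StreamSchema | None = None) -> Corpus:
    """Read a JSON-Lines corpus.

    Without an explicit ``schema`` the vocabulary of each stream is the
    union of observed word strings in first-seen order.  With an explicit
    schema, a token absent from it is a schema violation (never silently
    dropped; dropping is the tokenizer filter's documented semantics).
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                rec = (
                    str(obj["id"]),
                    obj.get("label"),
                    obj.get("fold"),
                    {str(s): [str(w) for w in words] for s, words in obj["streams"].items()},
                )
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed segment record: {exc}") from exc
            records.append(rec)
    if not records:
        raise CorpusFormatError("empty corpus")

    if schema is None:
        stream_names: list[str] = []
        vocab: dict[str, dict[str, int]] = {}
        for _, _, _, streams in records:
            for s, words in streams.items():
                if s not in vocab:
                    vocab[s] = {}
                    stream_names.append(s)
                ids = vocab[s]
                for w in words:
                    if w not in ids:
                        ids[w] = len(ids)
        schema = StreamSchema(
            streams=stream_names,
            vocabularies={s: list(vocab[s]) for s in stream_names},
        )
        word_ids = vocab
    else:
        word_ids = {s: schema.word_ids(s) for s in schema.streams}

    counts = {s: np.zeros(schema.vocab_size(s), dtype=np.int64) for s in schema.streams}
    segments = []
    for seg_id, label, fold, streams in records:
        tokens: dict[str, np.ndarray] = {}
        for s, words in streams.items():
            if s not in word_ids:
                raise SchemaViolationError(f"segment {seg_id!r}: unknown stream {s!r}")
            ids = word_ids[s]
            try:
                tok = np.array([ids[w] for w in words], dtype=np.int64)
            except KeyError as exc:
                raise SchemaViolationError(
                    f"segment {seg_id!r}, stream {s!r}: token {exc.args[0]!r} not in schema"
                ) from exc
            tokens[s] = tok
            np.add.at(counts[s], tok, 1)
        segments.append(
            Segment(id=seg_id, label=label, fold=None if fold is None else int(fold), tokens=tokens)
        )
    schema.counts = counts
    return Corpus(schema=schema, segments=segments)


def read_code_matrix(
    path: str | Path,
    segment_id: str | None = None,
    codebook_sizes: Sequence[int] | None = None,
) -> CodeMatrix:
    """Read one TSV code matrix (rows = frames, columns = codebook levels)."""
    path = Path(path)
    try:
        codes = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise CorpusFormatError(f"{path}: malformed code matrix: {exc}") from exc
    return CodeMatrix(
        segment_id=segment_id if segment_id is not None else path.stem,
        codes=codes,
        codebook_sizes=codebook_sizes,
    )


def write_code_matrix(matrix: CodeMatrix, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, matrix.codes, fmt="%d", delimiter="\t")
    return path


# ---------------------------------------------------------------------------
# Model state


@dataclass
class DmmModelState:
    """Sufficient statistics and hyperparameters of a fitted mixture.

    ``tau[k]`` counts segments currently assigned to cluster ``k``;
    ``omega[stream][k, v]`` counts occurrences of word ``v`` in segments
    of cluster ``k``.  Both are exactly recomputable from
    ``(assignments, corpus)`` and must agree; :func:`validate` checks the
    internal invariants and, given the corpus, the recomputation.
    """

    K: int
    alpha: np.ndarray
    beta: dict[str, np.ndarray]
    tau: np.ndarray
    omega: dict[str, np.ndarray]
    assignments: np.ndarray
    seed: int
    iterations_run: int = 0
    schema: StreamSchema | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.tau = np.asarray(self.tau, dtype=np.int64)
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        self.beta = {s: np.asarray(b, dtype=np.float64) for s, b in self.beta.items()}
        self.omega = {s: np.asarray(o, dtype=np.int64) for s, o in self.omega.items()}

    @property
    def streams(self) -> list[str]:
        return list(self.beta)

    def validate(self, corpus: Corpus | None = None) -> None:
        if self.alpha.shape != (self.K,) or (self.alpha <= 0).any():
            raise IntegrityError("alpha must be length-K and strictly positive")
        for s, b in self.beta.items():
            if b.shape[0] != self.K or (b <= 0).any():
                raise IntegrityError(f"beta[{s!r}] must be K x V and strictly positive")
        M = len(self.assignments)
        if self.tau.shape != (self.K,) or (self.tau < 0).any() or self.tau.sum() != M:
            raise IntegrityError("tau inconsistent: sum(tau) must equal number of segments")
        if self.assignments.size and (
            self.assignments.min() < 0 or self.assignments.max() >= self.K
        ):
            raise IntegrityError("assignment out of [0, K)")
        tau = np.bincount(self.assignments, minlength=self.K)
        if not np.array_equal(tau, self.tau):
            raise IntegrityError("tau does not match assignments")
        for s, o in self.omega.items():
            if (o < 0).any():
                raise IntegrityError(f"negative omega count in stream {s!r}")
        if corpus is not None:
            tau_r, omega_r = recompute_counts(corpus, self.assignments, self.K)
            if not np.array_equal(tau_r, self.tau):
                raise IntegrityError("tau does not match recomputation from corpus")
            for s in corpus.schema.streams:
                if not np.array_equal(omega_r[s], self.omega[s]):
                    raise IntegrityError(f"omega[{s!r}] does not match recomputation from corpus")


def recompute_counts(
    corpus: Corpus, assignments: Iterable[int], K: int
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Rebuild (tau, omega) count tables from scratch."""
    z = np.asarray(list(assignments), dtype=np.int64)
    tau = np.bincount(z, minlength=K)
    omega = {
        s: np.zeros((K, corpus.schema.vocab_size(s)), dtype=np.int64)
        for s in corpus.schema.streams
    }
    for m, seg in enumerate(corpus.segments):
        for s in corpus.schema.streams:
            np.add.at(omega[s][z[m]], seg.tokens[s], 1)
    return tau, omega


def save_model(state: DmmModelState, path: str | Path) -> Path:
    """Write the full model state as one JSON document (lossless)."""
    state.validate()
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "K": state.K,
        "alpha": state.alpha.tolist(),
        "beta": {s: b.tolist() for s, b in state.beta.items()},
        "tau": state.tau.tolist(),
        "omega": {s: o.tolist() for s, o in state.omega.items()},
        "assignments": state.assignments.tolist(),
        "seed": state.seed,
        "iterations_run": state.iterations_run,
        "schema": None if state.schema is None else state.schema.to_json_obj(),
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_model(path: str | Path) -> DmmModelState:
    """Read a model file; invariant violations raise :class:`IntegrityError`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"{path}: corrupt model file: {exc}") from exc
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise IntegrityError(f"{path}: unsupported model format version")
    try:
        state = DmmModelState(
            K=int(doc["K"]),
            alpha=np.asarray(doc["alpha"], dtype=np.float64),
            beta={s: np.asarray(b, dtype=np.float64) for s, b in doc["beta"].items()},
            tau=np.asarray(doc["tau"], dtype=np.int64),
            omega={s: np.asarray(o, dtype=np.int64) for s, o in doc["omega"].items()},
            assignments=np.asarray(doc["assignments"], dtype=np.int64),
            seed=int(doc["seed"]),
            iterations_run=int(doc["iterations_run"]),
            schema=None if doc.get("schema") is None else StreamSchema.from_json_obj(doc["schema"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise IntegrityError(f"{path}: corrupt model file: {exc}") from exc
    state.validate()
    return state
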