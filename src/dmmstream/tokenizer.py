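"""Acoustic-word construction and vocabulary filtering.

A residual-vector-quantizer codec emits a column of codes per audio
frame, coarsest stage first.  An *acoustic word* is the concatenation
of the first ``prefix`` codes of a frame (default 2), joined with an
unambiguous "_" separator — a deliberately coarse re-quantization that
is enough to tell activities apart even where it would not be for
speech.

Two vocabulary filters:

* **TFR (term frequency ratio)** — words sorted by descending corpus
  frequency are retained until the cumulative frequency relative to the
  total first exceeds the threshold r; all later words are discarded.
  Smaller vocabularies keep the sampler cheap and numerically tame.
* **Noise-word removal** — every word type occurring in designated
  noise segments (e.g. segments labeled 'absence' by a presence sensor)
  is removed from the vocabulary everywhere, and the noise segments are
  dropped.  This also removes such words' occurrences from genuine
  activity segments, where many of them are high-frequency background.

Filtering order is noise removal first, then TFR on the cleaned
vocabulary, each stream independently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import CodeMatrix, Corpus, Segment, StreamSchema, read_code_matrix
from .errors import ConfigError, CorpusFormatError

WORD_SEPARATOR = "_"


@dataclass
class TokenizerConfig:
    """How code matrices become words: number of leading codes to keep."""

    prefix: int = 2

    def __post_init__(self) -> None:
        if self.prefix < 1:
            raise ConfigError("codebook prefix length must be >= 1")


@dataclass
class StreamFilterReport:
    """Kept/discarded/noise word bookkeeping for one stream."""

    stream: str
    r: float
    words: list[str]              # pre-TFR vocabulary, sorted by descending count
    counts: np.ndarray            # aligned with words
    cumulative: np.ndarray        # cumulative frequency ratio at each rank
    kept: list[str]
    discarded: list[str]
    noise_words: list[str]        # removed by absence filtering before TFR

    @property
    def original_vocab_size(self) -> int:
        return len(self.kept) + len(self.discarded) + len(self.noise_words)


@dataclass
class VocabularyFilterReport:
    """Per-stream filter reports for one tokenization run."""

    streams: dict[str, StreamFilterReport] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["stream", "token", "count", "kept", "status"])
            for s, rep in self.streams.items():
                count_of = dict(zip(rep.words, rep.counts.tolist()))
                for word in rep.kept:
                    w.writerow([s, word, count_of[word], 1, "kept"])
                for word in rep.discarded:
                    w.writerow([s, word, count_of[word], 0, "discarded"])
                for word in rep.noise_words:
                    w.writerow([s, word, count_of.get(word, 0), 0, "noise"])
        return path


def codes_to_words(code_matrix: CodeMatrix, config: TokenizerConfig | None = None) -> list[str]:
    """One word per frame: the "_"-joined first ``prefix`` codes of that frame.

    The separator makes the mapping injective on distinct code
    prefixes (1,23 never collides with 12,3).
    """
    if config is None:
        config = TokenizerConfig()
    if config.prefix > code_matrix.n_levels:
        raise ConfigError(
            f"prefix {config.prefix} exceeds {code_matrix.n_levels} codebook levels"
        )
    prefix = code_matrix.codes[:, : config.prefix]
    return [WORD_SEPARATOR.join(str(c) for c in row) for row in prefix]


def tfr_filter(
    word_counts: Mapping[str, int], r: float
) -> tuple[list[str], "StreamFilterReport"]:
    """Retain the most frequent words up to cumulative frequency ratio r.

    Words are sorted by descending count, ties broken lexicographically.
    Every word up to and including the first at which the cumulative
    ratio exceeds r is kept; with r = 1.0 the threshold is never
    exceeded and all words survive.
    """
    if not 0.0 < r <= 1.0:
        raise ConfigError(f"TFR threshold must be in (0, 1], got {r}")
    items = [(w, int(c)) for w, c in word_counts.items() if c > 0]
    if not items:
        raise ConfigError("TFR filter requires at least one word with positive count")
    items.sort(key=lambda wc: (-wc[1], wc[0]))
    words = [w for w, _ in items]
    counts = np.array([c for _, c in items], dtype=np.int64)
    cumulative = np.cumsum(counts) / counts.sum()
    n_keep = len(words)
    for i, ratio in enumerate(cumulative):
        if ratio > r:
            n_keep = i + 1
            break
    report = StreamFilterReport(
        stream="",
        r=r,
        words=words,
        counts=counts,
        cumulative=cumulative,
        kept=words[:n_keep],
        discarded=words[n_keep:],
        noise_words=[],
    )
    return words[:n_keep], report


def remove_noise_words(
    corpus: Corpus, noise_segment_ids: Iterable[str]
) -> tuple[Corpus, dict[str, list[str]]]:
    """Remove every word type seen in any noise segment, then drop those segments.

    Removal applies corpus-wide: a word occurring both in noise and in
    genuine activity segments disappears from the activity segments
    too.  Surviving segments may end up with zero-length streams; they
    are kept.  Returns the filtered corpus and the per-stream removed
    word lists.
    """
    noise_ids = set(noise_segment_ids)
    known = {seg.id for seg in corpus.segments}
    unknown = noise_ids - known
    if unknown:
        raise CorpusFormatError(f"unknown noise segment ids: {sorted(unknown)}")
    if not noise_ids:
        return corpus, {s: [] for s in corpus.schema.streams}

    noise_word_ids: dict[str, set[int]] = {s: set() for s in corpus.schema.streams}
    for seg in corpus.segments:
        if seg.id in noise_ids:
            for s in corpus.schema.streams:
                noise_word_ids[s].update(np.unique(seg.tokens[s]).tolist())

    removed = {
        s: [corpus.schema.vocabularies[s][v] for v in sorted(noise_word_ids[s])]
        for s in corpus.schema.streams
    }
    keep_words = {
        s: [w for i, w in enumerate(corpus.schema.vocabularies[s]) if i not in noise_word_ids[s]]
        for s in corpus.schema.streams
    }
    filtered = _reindex(corpus, keep_words, drop_segment_ids=noise_ids)
    return filtered, removed


def _reindex(
    corpus: Corpus, keep_words: Mapping[str, Sequence[str]], drop_segment_ids: set[str] = frozenset()
) -> Corpus:
    """Rebuild a corpus on a reduced vocabulary (occurrences of dropped words deleted)."""
    old_to_new: dict[str, np.ndarray] = {}
    for s in corpus.schema.streams:
        keep_set = set(keep_words[s])
        mapping = np.full(corpus.schema.vocab_size(s), -1, dtype=np.int64)
        new_id = 0
        for i, w in enumerate(corpus.schema.vocabularies[s]):
            if w in keep_set:
                mapping[i] = new_id
                new_id += 1
        old_to_new[s] = mapping
    # preserve original vocabulary order among surviving words
    new_vocab = {
        s: [w for w in corpus.schema.vocabularies[s] if w in set(keep_words[s])]
        for s in corpus.schema.streams
    }
    segments = []
    counts = {s: np.zeros(len(new_vocab[s]), dtype=np.int64) for s in corpus.schema.streams}
    for seg in corpus.segments:
        if seg.id in drop_segment_ids:
            continue
        tokens = {}
        for s in corpus.schema.streams:
            mapped = old_to_new[s][seg.tokens[s]]
            tokens[s] = mapped[mapped >= 0]
            np.add.at(counts[s], tokens[s], 1)
        segments.append(Segment(id=seg.id, label=seg.label, fold=seg.fold, tokens=tokens))
    if not segments:
        raise CorpusFormatError("filtering removed every segment")
    schema = StreamSchema(streams=list(corpus.schema.streams), vocabularies=new_vocab, counts=counts)
    return Corpus(schema=schema, segments=segments)


def filter_corpus(
    corpus: Corpus, r: float, noise_segment_ids: Iterable[str] = ()
) -> tuple[Corpus, VocabularyFilterReport]:
    """Noise-word removal followed by per-stream TFR filtering.

    TFR runs on the absence-cleaned vocabulary so the threshold r
    budgets frequency mass over activity-related words only.
    """
    cleaned, removed = remove_noise_words(corpus, noise_segment_ids)
    keep_words: dict[str, list[str]] = {}
    report = VocabularyFilterReport()
    for s in cleaned.schema.streams:
        word_counts = dict(zip(cleaned.schema.vocabularies[s], cleaned.schema.counts[s].tolist()))
        kept, srep = tfr_filter(word_counts, r)
        srep.stream = s
        srep.noise_words = removed[s]
        report.streams[s] = srep
        keep_words[s] = kept
    return _reindex(cleaned, keep_words), report


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a code-matrix manifest TSV.

    Columns: ``segment_id``, ``stream``, ``path``, optional ``label``
    and ``fold``.  One row per (segment, stream) pair.
    """
    df = pd.read_csv(path, sep="\t", dtype={"segment_id": str, "stream": str, "path": str})
    for col in ("segment_id", "stream", "path"):
        if col not in df.columns:
            raise CorpusFormatError(f"manifest missing required column {col!r}")
    if "label" not in df.columns:
        df["label"] = None
    if "fold" not in df.columns:
        df["fold"] = None
    return df


def tokenize_corpus(
    manifest: str | Path | pd.DataFrame,
    config: TokenizerConfig | None = None,
    r: float = 0.6,
    noise_segment_ids: Iterable[str] = (),
) -> tuple[Corpus, VocabularyFilterReport]:
    """Code matrices -> words -> noise removal -> TFR filter, per stream.

    Each stream gets its own independent vocabulary.  Deterministic:
    identical inputs give an identical corpus.
    """
    if config is None:
        config = TokenizerConfig()
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    base = Path(manifest).parent if not isinstance(manifest, pd.DataFrame) else Path(".")

    streams: list[str] = []
    vocab: dict[str, dict[str, int]] = {}
    seg_tokens: dict[str, dict[str, np.ndarray]] = {}
    seg_meta: dict[str, tuple[str | None, int | None]] = {}
    seg_order: list[str] = []
    for row in df.itertuples(index=False):
        sid, stream = str(row.segment_id), str(row.stream)
        mpath = Path(row.path)
        if not mpath.is_absolute():
            mpath = base / mpath
        words = codes_to_words(read_code_matrix(mpath, segment_id=sid), config)
        if stream not in vocab:
            vocab[stream] = {}
            streams.append(stream)
        ids = vocab[stream]
        for w in words:
            if w not in ids:
                ids[w] = len(ids)
        if sid not in seg_tokens:
            seg_tokens[sid] = {}
            seg_order.append(sid)
            label = None if pd.isna(row.label) else str(row.label)
            fold = None if pd.isna(row.fold) else int(row.fold)
            seg_meta[sid] = (label, fold)
        seg_tokens[sid][stream] = np.array([ids[w] for w in words], dtype=np.int64)

    schema = StreamSchema(streams=streams, vocabularies={s: list(vocab[s]) for s in streams})
    segments = []
    for sid in seg_order:
        label, fold = seg_meta[sid]
        segments.append(Segment(id=sid, label=label, fold=fold, tokens=seg_tokens[sid]))
    for s in streams:
        c = np.zeros(len(vocab[s]), dtype=np.int64)
        for seg in segments:
            np.add.at(c, seg.tokens.get(s, np.zeros(0, dtype=np.int64)), 1)
        schema.counts[s] = c
    corpus = Corpus(schema=schema, segments=segments)
    return filter_corpus(corpus, r=r, noise_segment_ids=noise_segment_ids)
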