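import numpy as np
import pytest

from dmmstream import Corpus, Segment, StreamSchema


def make_corpus(stream_tokens, labels=None, folds=None, vocab_sizes=None):
    """Build a corpus from {stream: [token-id list per segment]}."""
    streams = list(stream_tokens)
    M = len(next(iter(stream_tokens.values())))
    if vocab_sizes is None:
        vocab_sizes = {
            s: int(max((max(t) for t in toks if len(t)), default=-1)) + 1
            for s, toks in stream_tokens.items()
        }
    schema = StreamSchema(
        streams=streams,
        vocabularies={s: [f"w{v}" for v in range(vocab_sizes[s])] for s in streams},
    )
    segments = []
    for m in range(M):
        segments.append(
            Segment(
                id=f"s{m}",
                label=None if labels is None else labels[m],
                fold=None if folds is None else folds[m],
                tokens={s: np.asarray(stream_tokens[s][m], dtype=np.int64) for s in streams},
            )
        )
    for s in streams:
        c = np.zeros(vocab_sizes[s], dtype=np.int64)
        for seg in segments:
            np.add.at(c, seg.tokens[s], 1)
        schema.counts[s] = c
    return Corpus(schema=schema, segments=segments)


@pytest.fixture
def two_stream_corpus():
    """M=4 segments, two streams, small vocabularies, random-ish counts."""
    rng = np.random.default_rng(7)
    return make_corpus(
        {
            "w": [rng.integers(0, 5, size=n).tolist() for n in (6, 3, 5, 4)],
            "y": [rng.integers(0, 3, size=n).tolist() for n in (2, 4, 0, 3)],
        },
        vocab_sizes={"w": 5, "y": 3},
    )


@pytest.fixture
def separable_corpus():
    """Two clusters with disjoint vocabularies; trivially recoverable."""
    rng = np.random.default_rng(5)
    toks = []
    labels = []
    for m in range(20):
        block = m % 2
        toks.append((rng.integers(0, 4, size=30) + 4 * block).tolist())
        labels.append("even" if block == 0 else "odd")
    return make_corpus({"d0": toks}, labels=labels, vocab_sizes={"d0": 8})
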