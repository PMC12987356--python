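"""Turn codec code matrices into acoustic-word streams and filter the
vocabulary.

Each audio frame of a residual-vector-quantizer codec yields a column
of codes; concatenating the first two codes of a frame gives one
acoustic word.  Here we synthesize small code matrices for three
'beamforming direction' streams, then apply the two vocabulary
filters: removal of words seen in a designated noise segment, and the
term-frequency-ratio (TFR) cutoff r=0.6.
"""

import tempfile
from pathlib import Path

import numpy as np

import dmmstream as ds
from dmmstream import CodeMatrix, TokenizerConfig, write_code_matrix
from dmmstream.tokenizer import tokenize_corpus

rng = np.random.default_rng(0)
tmp = Path(tempfile.mkdtemp())

# 8 segments x 3 streams of (200 frames x 8 codebook levels); segment
# "noise" stands in for an 'absence' recording detected by a PIR sensor.
rows = ["segment_id\tstream\tpath\tlabel\tfold"]
for m in range(8):
    sid = "noise" if m == 7 else f"seg{m}"
    for d, direction in enumerate(["d0", "d+30", "d-30"]):
        # codes cluster by segment parity so the corpus has structure
        base = 4 * (m % 2)
        codes = np.column_stack(
            [rng.integers(base, base + 4, size=200) for _ in range(8)]
        )
        path = tmp / f"{sid}_{direction}.tsv"
        write_code_matrix(CodeMatrix(sid, codes), path)
        rows.append(f"{sid}\t{direction}\t{path}\t\t")
manifest = tmp / "manifest.tsv"
manifest.write_text("\n".join(rows) + "\n")

corpus, report = tokenize_corpus(
    manifest, TokenizerConfig(prefix=2), r=0.6, noise_segment_ids=["noise"]
)

print(f"tokenized {corpus.M} segments (noise segment dropped)")
for s, rep in report.streams.items():
    print(
        f"stream {s}: {rep.original_vocab_size} words before filtering -> "
        f"{len(rep.kept)} kept, {len(rep.discarded)} cut by TFR, "
        f"{len(rep.noise_words)} noise words removed"
    )
example_word = corpus.schema.vocabularies["d0"][0]
print(f"an acoustic word looks like {example_word!r} (first two codes of a frame)")
# Words seen in the noise segment are gone from every activity segment
# too; the TFR cutoff then keeps only the words carrying the top 60% of
# the remaining frequency mass.
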