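"""k-mer and BPE tokenization of barcode sequences.

Shows the frame-shift sensitivity that motivates random-offset
augmentation, the [UNK] handling of ambiguous k-mers, and a BPE tokenizer
trained on a toy corpus.
"""

import numpy as np

from barcodelm import KmerTokenizer, train_bpe

tk = KmerTokenizer(k=4)
print(f"k=4 vocabulary: {tk.vocab_size} ids (256 k-mers + [MASK] + [UNK])")

seq = "ACGTACGTACGTACGT"
print("offset 0:", tk.tokenize(seq))            # four identical ACGT tokens
print("offset 1:", tk.tokenize(seq, offset=1))  # entirely different tokens
# A one-base frame shift changes every token - during pretraining each
# sequence is tokenized from a random offset so the model sees all frames.

print("with N:  ", tk.tokenize("ACGNACGT"), f"([UNK] id = {tk.unk_id})")

rng = np.random.default_rng(0)
corpus = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(50)]
bpe = train_bpe(corpus, v=32, max_tokens=64)
print(f"BPE v=32: first merges {bpe.merges[:4]}")
print("BPE tokens:", bpe.encode_symbols(corpus[0][:24]))
# BPE tokens are variable-length, so one substitution can re-segment the
# whole string - the main argument for k-mers on barcode data.
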