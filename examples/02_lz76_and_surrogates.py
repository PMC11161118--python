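"""Lempel-Ziv-76 parsing and shuffle-surrogate testing.

First parses the classic 21-symbol binary worked example into its 7 words,
then runs a 100-shuffle surrogate test of OP Entropy on a strongly
patterned (alternating short/long) ISI sequence and on an order-free one.
"""

import numpy as np

from spikeprofile import lz76_parse, lz_normalize, surrogate_test

parse = lz76_parse("100110111001010001011")
print("sequence 100110111001010001011")
print("words   :", " . ".join("".join(w) for w in parse.words))
print(f"c_LZ    : {parse.c_lz}")
print(f"C_LZ    : {lz_normalize(parse.c_lz, parse.length, 2):.4f} (normalized)")
print()

alternating = np.tile([0.05, 0.2], 113)[:225]
res = surrogate_test(alternating, "op_entropy", n=100, seed=0)
print(f"alternating ISIs : observed OP Entropy {res.observed:.4f}, "
      f"surrogate mean {res.surrogate_values.mean():.4f}, p = {res.p_value:.4f}")

iid = np.random.default_rng(0).exponential(0.1, 225)
res = surrogate_test(iid, "op_entropy", n=100, seed=0)
print(f"i.i.d. ISIs      : observed OP Entropy {res.observed:.4f}, "
      f"surrogate mean {res.surrogate_values.mean():.4f}, p = {res.p_value:.4f}")
print()
print("Shuffling preserves the interval distribution but destroys order, so")
print("a small p-value means the discharge carries temporal structure beyond")
print("its ISI histogram; order-free input gives an unremarkable p.")
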