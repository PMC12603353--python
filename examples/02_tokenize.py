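"""LCA tokenization: overlapping k-mers, special tokens, round-trip.

Shows how a nucleotide segment becomes a model-ready id sequence, and that
tokenization is invertible when the shift divides the sequence evenly.
"""

from phastyle import LCATokenizer, mini_c_tokenizer

tok = LCATokenizer(k=6, shift=1, max_len=512)
seq = "AATCGGTACCTT"
tokens = tok.tokenize(seq)
print(f"{seq} -> {tokens}")
# consecutive 6-mers advance by 1 base, sharing 5 bases of context

enc = tok.encode(seq)
print(f"encoded: n_real_tokens={enc.n_real_tokens} "
      f"(= {len(tokens)} k-mers + [CLS] + [SEP]), padded to {len(enc.ids)}")
print(f"roundtrip: {tok.detokenize(tokens)!r}")

char_tok = mini_c_tokenizer()
print(f"character-level variant: {char_tok.tokenize('ACGT')} "
      f"(vocabulary size {len(char_tok.vocab)})")
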