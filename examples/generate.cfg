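# Annotated corpus-generation configuration for
# `deidtext generate --config generate.cfg out/`.
# Format: one "key = value" per line; '#' starts a comment; flags win.

# Number of documents.
n = 250

# Fraction of documents per structural profile
# (headered, dept7, meddocan; fractions must sum to 1).
profile_mix = headered=0.72,dept7=0.28

# Fraction of tokens inside entity spans.
entity_density = 0.15

# Seed for byte-reproducible output.
seed = 7

# Optional train/validation/test sizes; when given, three CoNLL files are
# emitted and the dept7 documents are held out as the test set, with
# `heldout_in_train` of them kept in training.
split = 140,60,50
heldout_in_train = 20
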