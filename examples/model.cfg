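# Annotated model configuration for `deidtext train --config model.cfg`.
# Format: one "key = value" per line; '#' starts a comment.
# Flags given on the command line override values from this file.

# Architecture: lstm-crf (word-only), lstm-lstm-crf (character BiLSTM),
# or conv-lstm-crf (character CNN).
architecture = lstm-lstm-crf

# Embedding and hidden sizes (per direction for the BiLSTMs).
word_dim = 100
char_dim = 25
char_hidden = 25
word_hidden = 100

# Inverted dropout on the encoder input and output; 0 disables.
dropout = 0.5

# Exponential moving average of the weights, used for prediction.
use_ema = true
ema_decay = 0.999

# Optimization: Adam, minibatches of line sequences, early stopping on
# validation global de-identification F1.
epochs = 20
batch_size = 16
learning_rate = 0.001
patience = 5

# Single seed driving initialization, shuffling and dropout.
seed = 0

# Optional GloVe-style text embeddings ("word v1 ... vd" per line);
# leave unset for random initialization.
# embeddings_path = vectors/es-100d.txt
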