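"""Word, character and tag vocabularies for the sequence taggers.

Words are lowercased for the word channel (capitalization is a key person-
name cue, but it survives through the character channel, which sees the
original case).  Digits are not normalized: numeric and date surfaces are
themselves the signal for NUM and FECHA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from ..corpus_io import ENTITY_LABELS, TaggedSequence

PAD, UNK = "<pad>", "<unk>"

#: Fixed tag inventory: O first, then B-/I- per label in canonical order.
TAG_INVENTORY = tuple(
    ["O"] + [f"{p}-{lab}" for lab in ENTITY_LABELS for p in ("B", "I")]
)


@dataclass
class Vocabulary:
    """Dense word/char/tag index maps with reserved PAD and UNK entries."""

    words: dict[str, int] = field(default_factory=dict)
    chars: dict[str, int] = field(default_factory=dict)
    tags: dict[str, int] = field(
        default_factory=lambda: {t: i for i, t in enumerate(TAG_INVENTORY)}
    )

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_chars(self) -> int:
        return len(self.chars)

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @property
    def tag_names(self) -> list[str]:
        return sorted(self.tags, key=self.tags.get)

    def word_id(self, word: str) -> int:
        return self.words.get(word.lower(), self.words[UNK])

    def char_ids(self, word: str) -> list[int]:
        unk = self.chars[UNK]
        return [self.chars.get(c, unk) for c in word]

    @classmethod
    def build(cls, sequences: Iterable[TaggedSequence]) -> "Vocabulary":
        words = {PAD: 0, UNK: 1}
        chars = {PAD: 0, UNK: 1}
        for seq in sequences:
            for tok in seq.tokens:
                w = tok.text.lower()
                if w not in words:
                    words[w] = len(words)
                for c in tok.text:
                    if c not in chars:
                        chars[c] = len(chars)
        return cls(words=words, chars=chars)
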