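"""Tokenization and sentence splitting for clinical report text.

The historical corpus this pipeline was designed around is Chinese; the
synthetic fixtures are English.  Both are handled by one pluggable scheme:

* sentence delimiters cover ASCII and CJK punctuation (configurable);
* the default tokenizer lowercases and extracts word-like runs, emitting
  CJK text one character at a time (the standard segmenter-free fallback).

A period flanked by digits on both sides ("1.26 Mb") is a decimal point,
not a sentence delimiter.
"""

from __future__ import annotations

import re
from typing import Callable

from .models import Sentence

#: ASCII + CJK clause/sentence punctuation.
DEFAULT_DELIMITERS = (",", ".", ";", "，", "。", "；")

Tokenizer = Callable[[str], list[str]]

_TOKEN_RE = re.compile(
    r"[A-Za-z]+|\d+(?:\.\d+)?|[一-鿿]",
)


def default_tokenizer(text: str) -> list[str]:
    """Lowercased word / number / single-CJK-character tokens."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def _split_regex(delimiters: tuple[str, ...]) -> re.Pattern[str]:
    parts = []
    for d in delimiters:
        if d == ".":
            # keep decimal points intact
            parts.append(r"(?<!\d)\.|\.(?!\d)")
        else:
            parts.append(re.escape(d))
    return re.compile("|".join(parts))


def split_sentences(
    paragraph: str, delimiters: tuple[str, ...] = DEFAULT_DELIMITERS
) -> list[Sentence]:
    """Split a paragraph into sentences on comma/period-class punctuation.

    Delimiters are consumed; empty fragments are dropped; indices are
    contiguous from 0.
    """
    if not paragraph:
        return []
    pieces = _split_regex(delimiters).split(paragraph)
    sentences = []
    for piece in pieces:
        stripped = piece.strip()
        if stripped:
            sentences.append(Sentence(text=stripped, index=len(sentences)))
    return sentences
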