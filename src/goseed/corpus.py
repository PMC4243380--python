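"""Turn raw documents plus a gene lexicon into classification examples.

The unit of annotation is the sentence.  A classification *example* is a
sentence containing at least one gene from the lexicon; it is positive
when a gold evidence annotation marks it, negative when a gold set is
supplied but does not mark it, and unknown when no gold set is given
(the unlabeled stream used for semi-supervised training).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_UNKNOWN = "unknown"

REFERENCES_SECTION = "References"


@dataclass(frozen=True)
class Sentence:
    """One sentence of a document, with its provenance.

    ``char_start``/``char_end`` are offsets into the paragraph the
    sentence was split from; they back the relaxed (span-overlap)
    evaluation mode.
    """

    doc_id: str
    section: str
    index: int
    text: str
    paragraph_id: int = 0
    char_start: int = 0
    char_end: int = 0

    def __post_init__(self):
        if not self.text:
            raise ValueError("Sentence text must be non-empty")


@dataclass(frozen=True)
class Example:
    """A gene-bearing sentence ready for classification."""

    sentence: Sentence
    gene_ids: frozenset
    label: str = LABEL_UNKNOWN
    paragraph_text: str = ""

    def __post_init__(self):
        if self.label not in (LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_UNKNOWN):
            raise ValueError(f"bad label: {self.label!r}")


class GeneLexicon:
    """Exact-string (case-normalized) surface form -> gene ID lookup.

    Many surface forms may map to one gene ID.  Matching is whole-token:
    a surface form matches only where it is not flanked by alphanumeric
    characters, so ``BRCA1`` does not fire inside ``BRCA10``.
    """

    def __init__(self, entries: dict[str, str] | Iterable[tuple[str, str]]):
        items = entries.items() if isinstance(entries, dict) else entries
        self._entries: dict[str, str] = {}
        for surface, gene_id in items:
            if not surface:
                raise ValueError("empty surface form in lexicon")
            self._entries[surface.lower()] = str(gene_id)
        self._pattern = self._compile()

    def _compile(self) -> Optional[re.Pattern]:
        if not self._entries:
            return None
        # Longest-first alternation so multi-word forms win over prefixes.
        alts = sorted(self._entries, key=len, reverse=True)
        body = "|".join(re.escape(s) for s in alts)
        return re.compile(
            r"(?<![A-Za-z0-9])(?:" + body + r")(?![A-Za-z0-9])", re.IGNORECASE
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self._entries

    def lookup(self, surface: str) -> Optional[str]:
        return self._entries.get(surface.lower())

    def find(self, text: str) -> set[str]:
        """All gene IDs whose surface forms occur in ``text`` as whole tokens."""
        if self._pattern is None:
            return set()
        return {self._entries[m.group(0).lower()] for m in self._pattern.finditer(text)}

    @classmethod
    def from_tsv(cls, path) -> "GeneLexicon":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                surface, gene_id = line.split("\t")[:2]
                entries.append((surface, gene_id))
        return cls(entries)


def _split_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences under the token-terminal-period rule.

    A boundary is placed after a whitespace-delimited token when the
    token ends with ``.``, it is followed by whitespace, and the first
    character after that whitespace is not a lowercase letter.  The rule
    keeps abbreviations such as ``e.g. the`` intact while splitting at
    ordinary sentence ends.
    """
    spans: list[tuple[int, int]] = []
    tokens = [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]
    if not tokens:
        return spans
    sent_start = tokens[0][0]
    for i, (start, end) in enumerate(tokens):
        last = i == len(tokens) - 1
        if last:
            spans.append((sent_start, end))
            break
        if text[end - 1] == ".":
            next_char = text[tokens[i + 1][0]]
            if not next_char.islower():
                spans.append((sent_start, end))
                sent_start = tokens[i + 1][0]
    return spans


def split_sentences(
    text: str,
    doc_id: str = "",
    section: str = "",
    paragraph_id: int = 0,
    index_start: int = 0,
) -> list[Sentence]:
    """Split plain text into :class:`Sentence` objects.

    Empty input yields an empty list.  The concatenation of the returned
    sentence texts, modulo the whitespace at boundaries, equals the
    input.
    """
    sentences = []
    for offset, (start, end) in enumerate(_split_spans(text)):
        sentences.append(
            Sentence(
                doc_id=doc_id,
                section=section,
                index=index_start + offset,
                text=text[start:end],
                paragraph_id=paragraph_id,
                char_start=start,
                char_end=end,
            )
        )
    return sentences


def drop_references(sentences: Sequence[Sentence]) -> list[Sentence]:
    """Remove every sentence in the 'References' section, preserving order."""
    return [s for s in sentences if s.section != REFERENCES_SECTION]


def match_genes(sentence: Sentence | str, lexicon: GeneLexicon) -> set[str]:
    """Gene IDs of all lexicon surface forms occurring as whole tokens."""
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    return lexicon.find(text)


def build_examples(
    sentences: Sequence[Sentence],
    lexicon: GeneLexicon,
    gold: Optional[Iterable[tuple]] = None,
    paragraphs: Optional[dict] = None,
) -> list[Example]:
    """One :class:`Example` per sentence with at least one gene match.

    ``gold`` is an iterable of gold evidence records whose first two
    fields are ``(doc_id, sentence_index)`` (extra fields such as
    gene/GO IDs are ignored here).  With a gold set, matched sentences
    become positive and the remaining gene sentences negative; without
    one, every gene sentence is labeled unknown.

    ``paragraphs`` optionally maps ``(doc_id, paragraph_id)`` to the
    paragraph text used for sentence+paragraph feature scopes.

    Raises ``KeyError`` if a gold record refers to a sentence absent
    from ``sentences``.
    """
    known = {(s.doc_id, s.index) for s in sentences}
    gold_keys: Optional[set] = None
    if gold is not None:
        gold_keys = set()
        for record in gold:
            key = (record[0], int(record[1]))
            if key not in known:
                raise KeyError(f"gold annotation refers to unknown sentence {key}")
            gold_keys.add(key)

    examples = []
    for s in sentences:
        genes = match_genes(s, lexicon)
        if not genes:
            continue
        if gold_keys is None:
            label = LABEL_UNKNOWN
        elif (s.doc_id, s.index) in gold_keys:
            label = LABEL_POSITIVE
        else:
            label = LABEL_NEGATIVE
        para = ""
        if paragraphs is not None:
            para = paragraphs.get((s.doc_id, s.paragraph_id), "")
        examples.append(
            Example(sentence=s, gene_ids=frozenset(genes), label=label,
                    paragraph_text=para)
        )
    return examples


# ---------------------------------------------------------------------------
# I/O


def read_documents_jsonl(path) -> tuple[list[Sentence], dict]:
    """Read documents from JSONL and split them into sentences.

    Each line is ``{"doc_id": ..., "sections": [{"name": ...,
    "paragraphs": [text, ...]}, ...]}``.  Returns the sentence list and
    a ``(doc_id, paragraph_id) -> paragraph text`` map.
    """
    sentences: list[Sentence] = []
    paragraphs: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            doc_id = doc["doc_id"]
            index = 0
            paragraph_id = 0
            for section in doc.get("sections", []):
                name = section.get("name", "")
                for text in section.get("paragraphs", []):
                    split = split_sentences(
                        text, doc_id=doc_id, section=name,
                        paragraph_id=paragraph_id, index_start=index,
                    )
                    sentences.extend(split)
                    index += len(split)
                    paragraphs[(doc_id, paragraph_id)] = text
                    paragraph_id += 1
    return sentences, paragraphs


def read_sentences_tsv(path) -> list[Sentence]:
    """Read pre-split sentences: doc_id, section, paragraph_id, index, text."""
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            doc_id, section, paragraph_id, index, text = line.split("\t")[:5]
            sentences.append(
                Sentence(doc_id=doc_id, section=section, index=int(index),
                         text=text, paragraph_id=int(paragraph_id),
                         char_start=0, char_end=len(text))
            )
    return sentences


def read_gold_tsv(path) -> list[tuple]:
    """Gold evidence records: doc_id, sentence_index, gene_id, go_id."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            records.append((fields[0], int(fields[1]), fields[2], fields[3]))
    return records


def write_examples_jsonl(examples: Sequence[Example], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in examples:
            s = e.sentence
            fh.write(json.dumps({
                "doc_id": s.doc_id, "section": s.section, "index": s.index,
                "paragraph_id": s.paragraph_id, "char_start": s.char_start,
                "char_end": s.char_end, "text": s.text,
                "gene_ids": sorted(e.gene_ids), "label": e.label,
                "paragraph_text": e.paragraph_text,
            }) + "\n")


def read_examples_jsonl(path) -> list[Example]:
    examples = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            sentence = Sentence(
                doc_id=d["doc_id"], section=d["section"], index=d["index"],
                text=d["text"], paragraph_id=d.get("paragraph_id", 0),
                char_start=d.get("char_start", 0), char_end=d.get("char_end", 0),
            )
            examples.append(Example(
                sentence=sentence, gene_ids=frozenset(d["gene_ids"]),
                label=d.get("label", LABEL_UNKNOWN),
                paragraph_text=d.get("paragraph_text", ""),
            ))
    return examples
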