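"""Readers and writers for tab-separated relation corpora, CoNLL-U parses and predictions.

The corpus dialect follows the BioCreative convention of three parallel
tab-separated files (abstracts, entity mentions, gold relations).  Character
offsets of entity mentions are 0-based half-open over the joint
``title + "\\t" + abstract`` axis.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

ENTITY_TYPES = {"CHEMICAL", "GENE_PROTEIN", "DISEASE", "PROTEIN"}


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the expected dialect."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract_text: str

    @property
    def text(self) -> str:
        """Joint character axis: title and abstract share one offset space."""
        return self.title + "\t" + self.abstract_text


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    mention_id: str
    entity_type: str
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class RelationAnnotation:
    doc_id: str
    relation_class: str
    arg1: str
    arg2: str
    evaluated: bool = True


@dataclass
class Corpus:
    documents: List[Document] = field(default_factory=list)
    entities: List[EntityMention] = field(default_factory=list)
    relations: List[RelationAnnotation] = field(default_factory=list)

    def document(self, doc_id: str) -> Document:
        for doc in self.documents:
            if doc.doc_id == doc_id:
                return doc
        raise KeyError(doc_id)

    def entities_of(self, doc_id: str) -> List[EntityMention]:
        return [e for e in self.entities if e.doc_id == doc_id]

    def relations_of(self, doc_id: str) -> List[RelationAnnotation]:
        return [r for r in self.relations if r.doc_id == doc_id]

    def validate(self) -> None:
        seen = set()
        for doc in self.documents:
            if not doc.doc_id:
                raise CorpusFormatError("empty doc_id")
            if doc.doc_id in seen:
                raise CorpusFormatError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
        docs = {d.doc_id: d for d in self.documents}
        mention_ids = set()
        for ent in self.entities:
            if ent.doc_id not in docs:
                raise CorpusFormatError(
                    f"mention {ent.mention_id} references unknown doc {ent.doc_id}")
            text = docs[ent.doc_id].text
            if not (0 <= ent.start < ent.end <= len(text)):
                raise CorpusFormatError(
                    f"mention {ent.mention_id} in {ent.doc_id}: offsets "
                    f"[{ent.start}, {ent.end}) outside document of length {len(text)}")
            if text[ent.start:ent.end] != ent.surface:
                raise CorpusFormatError(
                    f"mention {ent.mention_id} in {ent.doc_id}: surface "
                    f"{ent.surface!r} does not match slice "
                    f"{text[ent.start:ent.end]!r}")
            mention_ids.add((ent.doc_id, ent.mention_id))
        for rel in self.relations:
            for arg in (rel.arg1, rel.arg2):
                if (rel.doc_id, arg) not in mention_ids:
                    raise CorpusFormatError(
                        f"relation in {rel.doc_id} references unknown mention {arg}")


def _read_lines(path: os.PathLike) -> Iterable[Tuple[int, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line:
                yield lineno, line


def _strip_arg(value: str) -> str:
    # tolerate the "Arg1:T12" dialect of the raw shared-task files
    if value.startswith(("Arg1:", "Arg2:")):
        return value.split(":", 1)[1]
    return value


def read_corpus(abstracts_path, entities_path, relations_path=None) -> Corpus:
    """Read a corpus from the tab-separated three-file dialect.

    ``relations_path`` may be ``None`` (test mode): the relation list is left
    empty.  All invariants are checked; a malformed line raises
    :class:`CorpusFormatError` naming the file and line number.
    """
    documents = []
    for lineno, line in _read_lines(abstracts_path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise CorpusFormatError(
                f"{abstracts_path}:{lineno}: expected 3 tab-separated fields, "
                f"got {len(parts)}")
        documents.append(Document(parts[0], parts[1], parts[2]))

    entities = []
    for lineno, line in _read_lines(entities_path):
        parts = line.split("\t")
        if len(parts) != 6:
            raise CorpusFormatError(
                f"{entities_path}:{lineno}: expected 6 tab-separated fields, "
                f"got {len(parts)}")
        doc_id, mention_id, etype, start, end, surface = parts
        if etype not in ENTITY_TYPES:
            raise CorpusFormatError(
                f"{entities_path}:{lineno}: unknown entity type {etype!r}")
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise CorpusFormatError(
                f"{entities_path}:{lineno}: non-integer offsets") from None
        entities.append(EntityMention(doc_id, mention_id, etype, start_i, end_i, surface))

    relations = []
    if relations_path is not None:
        for lineno, line in _read_lines(relations_path):
            parts = line.split("\t")
            if len(parts) != 5:
                raise CorpusFormatError(
                    f"{relations_path}:{lineno}: expected 5 tab-separated "
                    f"fields, got {len(parts)}")
            doc_id, rel_class, evaluated, arg1, arg2 = parts
            relations.append(RelationAnnotation(
                doc_id, rel_class, _strip_arg(arg1), _strip_arg(arg2),
                evaluated=evaluated.strip().upper() != "N"))

    corpus = Corpus(documents, entities, relations)
    corpus.validate()
    return corpus


def write_corpus(corpus: Corpus, abstracts_path, entities_path,
                 relations_path=None) -> None:
    """Write a corpus back out in the same dialect (UTF-8, LF endings)."""
    with open(abstracts_path, "w", encoding="utf-8", newline="\n") as fh:
        for doc in corpus.documents:
            fh.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract_text}\n")
    with open(entities_path, "w", encoding="utf-8", newline="\n") as fh:
        for ent in corpus.entities:
            fh.write(f"{ent.doc_id}\t{ent.mention_id}\t{ent.entity_type}\t"
                     f"{ent.start}\t{ent.end}\t{ent.surface}\n")
    if relations_path is not None:
        with open(relations_path, "w", encoding="utf-8", newline="\n") as fh:
            for rel in corpus.relations:
                flag = "Y" if rel.evaluated else "N"
                fh.write(f"{rel.doc_id}\t{rel.relation_class}\t{flag}\t"
                         f"{rel.arg1}\t{rel.arg2}\n")


# ---------------------------------------------------------------------------
# Dependency parses (CoNLL-U)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependencyParse:
    """One parsed sentence: parallel token / PoS / head / deprel arrays.

    Heads are 1-based token indices with 0 denoting the root.
    """
    tokens: Tuple[str, ...]
    pos: Tuple[str, ...]
    heads: Tuple[int, ...]
    deprels: Tuple[str, ...]

    def __post_init__(self):
        n = len(self.tokens)
        if not (len(self.pos) == len(self.heads) == len(self.deprels) == n):
            raise ValueError("parse arrays must be parallel")
        roots = [i for i, h in enumerate(self.heads) if h == 0]
        if len(roots) != 1:
            raise ValueError(f"parse must have exactly one root, found {len(roots)}")
        for i, h in enumerate(self.heads):
            if not (0 <= h <= n):
                raise ValueError(f"head index {h} out of range at token {i + 1}")
        # cycle check: walk each token to the root
        for i in range(n):
            seen = set()
            j = i
            while self.heads[j] != 0:
                if j in seen:
                    raise ValueError(f"cyclic head assignment at token {i + 1}")
                seen.add(j)
                j = self.heads[j] - 1

    @property
    def root_index(self) -> int:
        """0-based index of the root token."""
        return self.heads.index(0)

    def dependents(self, index: int) -> List[int]:
        """0-based indices of the tokens headed by ``index`` (0-based)."""
        return [i for i, h in enumerate(self.heads) if h == index + 1]


def read_parses(conllu_path) -> Dict[Tuple[str, int], DependencyParse]:
    """Read CoNLL-U parses keyed by (doc_id, sentence_index) metadata."""
    parses: Dict[Tuple[str, int], DependencyParse] = {}
    meta: Dict[str, str] = {}
    rows: List[Tuple[str, str, int, str]] = []

    def flush(lineno):
        if not rows:
            return
        if "doc_id" not in meta or "sentence_index" not in meta:
            raise CorpusFormatError(
                f"{conllu_path}:{lineno}: sentence missing doc_id/sentence_index metadata")
        key = (meta["doc_id"], int(meta["sentence_index"]))
        tokens, pos, heads, deprels = zip(*rows)
        try:
            parses[key] = DependencyParse(tokens, pos, heads, deprels)
        except ValueError as exc:
            raise CorpusFormatError(f"{conllu_path}:{lineno}: {exc}") from exc
        meta.clear()
        rows.clear()

    with open(conllu_path, encoding="utf-8", newline="") as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                flush(lineno)
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise CorpusFormatError(
                    f"{conllu_path}:{lineno}: expected 10 columns, got {len(cols)}")
            if "-" in cols[0] or "." in cols[0]:
                continue  # multiword/empty nodes are not produced here
            try:
                head = int(cols[6])
            except ValueError:
                raise CorpusFormatError(
                    f"{conllu_path}:{lineno}: non-integer head {cols[6]!r}") from None
            rows.append((cols[1], cols[4], head, cols[7]))
        flush(lineno + 1)
    return parses


def write_parses(parses: Dict[Tuple[str, int], DependencyParse], conllu_path) -> None:
    with open(conllu_path, "w", encoding="utf-8", newline="\n") as fh:
        for (doc_id, sent_idx) in sorted(parses):
            parse = parses[(doc_id, sent_idx)]
            fh.write(f"# doc_id = {doc_id}\n")
            fh.write(f"# sentence_index = {sent_idx}\n")
            for i, (tok, pos, head, rel) in enumerate(
                    zip(parse.tokens, parse.pos, parse.heads, parse.deprels), start=1):
                fh.write(f"{i}\t{tok}\t_\t_\t{pos}\t_\t{head}\t{rel}\t_\t_\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(results: Sequence, path) -> None:
    """Write prediction rows sorted by (doc_id, arg1, arg2).

    Each result must expose doc_id, arg1, arg2, label and score attributes.
    """
    rows = sorted(results, key=lambda r: (r.doc_id, r.arg1, r.arg2))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in rows:
            fh.write(f"{r.doc_id}\t{r.arg1}\t{r.arg2}\t{r.label}\t{r.score:.6f}\n")


def read_predictions(path) -> List[Tuple[str, str, str, str, float]]:
    out = []
    for lineno, line in _read_lines(path):
        parts = line.split("\t")
        if len(parts) != 5:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}")
        out.append((parts[0], parts[1], parts[2], parts[3], float(parts[4])))
    return out
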