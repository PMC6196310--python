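"""Candidate instance generation.

A document is segmented into sentences, each sentence is decomposed into one
candidate instance per co-located heterogeneous entity pair, and each
instance is a rewritten copy of the sentence: the focal pair is replaced by
role-tagged normalized symbols, every other entity mention is replaced by a
generic type symbol, and (for interacting pairs) the proximal verb is
replaced by a relation tag.  The parallel PoS sequence mirrors the rewrite,
with CHEMICAL / GENEPRO / DISEASE / RELATION participating as ordinary tag
symbols.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .corpus_io import Corpus, Document, EntityMention, RelationAnnotation
from .tagging import INFLECTED_VERB_TAGS, VERB_TAGS, RuleTagger, TaggerInterface

logger = logging.getLogger(__name__)

NEGATIVE_CLASS = "NEG"

#: PoS-level symbol used both for focal anchors and genericized mentions.
ROLE_SYMBOL = {
    "CHEMICAL": "CHEMICAL",
    "GENE_PROTEIN": "GENEPRO",
    "PROTEIN": "GENEPRO",
    "DISEASE": "DISEASE",
}

RELATION_SYMBOL = "RELATION"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


@dataclass
class Sentence:
    doc_id: str
    sentence_index: int
    text: str
    char_span: Tuple[int, int]
    tokens: List[str]
    pos_tags: List[str]
    lemmas: List[str]
    mention_spans: List[Tuple[str, int, int]]  # (mention_id, first_tok, last_tok)
    mention_types: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.tokens) != len(self.pos_tags):
            raise ValueError("tokens and pos_tags must be parallel")
        for mid, first, last in self.mention_spans:
            if not (0 <= first <= last < len(self.tokens)):
                raise ValueError(f"mention {mid} token span out of range")


@dataclass
class CandidateInstance:
    """One entity-pair-focused, normalization-rewritten copy of a sentence."""
    instance_id: str
    doc_id: str
    sentence: Sentence
    relation_class: str
    entity1: Tuple[str, int, str]  # (mention_id, norm token index, norm tag)
    entity2: Tuple[str, int, str]
    proximal_verb: Optional[Tuple[int, str]]  # (norm token index, norm tag)
    proximal_verb_lemma: Optional[str]
    norm_tokens: List[str]
    norm_pos: List[str]
    orig_token_map: List[Tuple[int, int]]  # norm index -> original token range

    @property
    def e1_index(self) -> int:
        return self.entity1[1]

    @property
    def e2_index(self) -> int:
        return self.entity2[1]

    @property
    def rel_index(self) -> Optional[int]:
        return self.proximal_verb[0] if self.proximal_verb else None

    def original_tokens(self, norm_index: int) -> List[str]:
        """Recover the original surface tokens behind a normalized token."""
        first, last = self.orig_token_map[norm_index]
        return self.sentence.tokens[first:last + 1]


def _class_number(relation_class: str) -> int:
    digits = re.sub(r"\D", "", relation_class)
    return int(digits) if digits else 0


def _tokenize(text: str) -> List[Tuple[str, int, int]]:
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def segment_and_tag(document: Document, entities: Sequence[EntityMention],
                    tagger: TaggerInterface) -> List[Sentence]:
    """Split a document into tagged sentences, assigning every mention to
    exactly one sentence (boundaries crossing a mention are repaired)."""
    text = document.text
    # candidate boundaries: the title/abstract tab, then sentence enders
    spans: List[Tuple[int, int]] = []
    tab = text.index("\t")
    spans.append((0, tab))
    cursor = tab + 1
    abstract = text[cursor:]
    start = 0
    for match in _SENT_SPLIT_RE.finditer(abstract):
        spans.append((cursor + start, cursor + match.start()))
        start = match.end()
    spans.append((cursor + start, len(text)))
    spans = [(a, b) for a, b in spans if text[a:b].strip()]

    # boundary repair: merge spans until no mention crosses a boundary
    changed = True
    while changed:
        changed = False
        for i in range(len(spans) - 1):
            boundary = spans[i][1]
            if any(e.start < boundary < e.end for e in entities):
                spans[i] = (spans[i][0], spans[i + 1][1])
                del spans[i + 1]
                changed = True
                break

    sentences: List[Sentence] = []
    for idx, (s_start, s_end) in enumerate(spans):
        stext = text[s_start:s_end]
        toks = _tokenize(stext)
        tokens = [t for t, _, _ in toks]
        pos = list(tagger.tag(tokens))
        if len(pos) != len(tokens):
            raise ValueError("tagger returned a PoS sequence of wrong length")
        lemmas = list(tagger.lemmatize(tokens))
        mention_spans = []
        mention_types: Dict[str, str] = {}
        for ent in entities:
            if not (s_start <= ent.start and ent.end <= s_end):
                continue
            rel_s, rel_e = ent.start - s_start, ent.end - s_start
            covering = [i for i, (_, ts, te) in enumerate(toks)
                        if ts < rel_e and te > rel_s]
            if not covering:
                raise ValueError(f"mention {ent.mention_id} matches no token")
            mention_spans.append((ent.mention_id, covering[0], covering[-1]))
            mention_types[ent.mention_id] = ent.entity_type
        sentences.append(Sentence(document.doc_id, idx, stext, (s_start, s_end),
                                  tokens, pos, lemmas, mention_spans, mention_types))

    assigned = {mid for s in sentences for mid, _, _ in s.mention_spans}
    missing = {e.mention_id for e in entities} - assigned
    if missing:
        raise ValueError(f"mentions not assigned to any sentence: {sorted(missing)}")
    return sentences


def select_proximal_verb(pos_tags: Sequence[str], e1_span: Tuple[int, int],
                         e2_span: Tuple[int, int]) -> Optional[int]:
    """Pick the verb token minimizing summed distance to the two entity spans.

    Inflected forms (VBD/VBZ/VBP/VBN/VBG) are preferred over base VB on
    distance ties; remaining ties go to the leftmost verb.  Returns ``None``
    when the sentence has no verb.
    """
    if hasattr(pos_tags, "pos_tags"):  # accept a Sentence as well
        pos_tags = pos_tags.pos_tags

    def span_dist(i: int, span: Tuple[int, int]) -> int:
        first, last = span
        if first <= i <= last:
            return 0
        return min(abs(i - first), abs(i - last))

    best = None
    for i, tag in enumerate(pos_tags):
        if tag not in VERB_TAGS:
            continue
        key = (span_dist(i, e1_span) + span_dist(i, e2_span),
               0 if tag in INFLECTED_VERB_TAGS else 1, i)
        if best is None or key < best[0]:
            best = (key, i)
    return None if best is None else best[1]


def _pair_roles(sentence: Sentence) -> List[Tuple[str, str]]:
    """Enumerate focal pairs: heterogeneous (chemical, other-type) pairs, or
    protein-protein pairs when the sentence carries only proteins."""
    chems = [mid for mid, _, _ in sentence.mention_spans
             if sentence.mention_types[mid] == "CHEMICAL"]
    others = [mid for mid, _, _ in sentence.mention_spans
              if sentence.mention_types[mid] in ("GENE_PROTEIN", "PROTEIN", "DISEASE")]
    if chems:
        return [(c, o) for c in chems for o in others]
    proteins = [mid for mid in others
                if sentence.mention_types[mid] in ("GENE_PROTEIN", "PROTEIN")]
    return [(proteins[i], proteins[j])
            for i in range(len(proteins)) for j in range(i + 1, len(proteins))]


def _role_name(entity_type: str) -> str:
    return ROLE_SYMBOL[entity_type].capitalize()


def _build_instance(sentence: Sentence, pair: Tuple[str, str],
                    relation_class: str, pair_counter: int,
                    normalize_relation: bool) -> CandidateInstance:
    spans = {mid: (first, last) for mid, first, last in sentence.mention_spans}
    e1_id, e2_id = pair
    cnum = _class_number(relation_class)

    replacements = []  # (first, last, surface, pos, which)
    for mid, (first, last) in spans.items():
        etype = sentence.mention_types[mid]
        symbol = ROLE_SYMBOL[etype]
        if mid == e1_id:
            replacements.append((first, last,
                                 f"{_role_name(etype)}R{pair_counter}T{cnum}",
                                 symbol, "e1"))
        elif mid == e2_id:
            replacements.append((first, last,
                                 f"{_role_name(etype)}R{pair_counter}T{cnum}",
                                 symbol, "e2"))
        else:
            replacements.append((first, last, symbol, symbol, None))
    replacements.sort()

    norm_tokens: List[str] = []
    norm_pos: List[str] = []
    orig_map: List[Tuple[int, int]] = []
    e1_idx = e2_idx = -1
    i = 0
    rep_iter = iter(replacements)
    rep = next(rep_iter, None)
    while i < len(sentence.tokens):
        if rep is not None and i == rep[0]:
            first, last, surface, pos, which = rep
            if which == "e1":
                e1_idx = len(norm_tokens)
            elif which == "e2":
                e2_idx = len(norm_tokens)
            norm_tokens.append(surface)
            norm_pos.append(pos)
            orig_map.append((first, last))
            i = last + 1
            rep = next(rep_iter, None)
        else:
            norm_tokens.append(sentence.tokens[i])
            norm_pos.append(sentence.pos_tags[i])
            orig_map.append((i, i))
            i += 1

    proximal = None
    verb_lemma = None
    if normalize_relation:
        vi = select_proximal_verb(norm_pos, (e1_idx, e1_idx), (e2_idx, e2_idx))
        if vi is not None:
            orig_first, _ = orig_map[vi]
            verb_lemma = sentence.lemmas[orig_first]
            norm_tokens[vi] = f"Relation{cnum}"
            norm_pos[vi] = RELATION_SYMBOL
            proximal = (vi, RELATION_SYMBOL)

    cls_tag = relation_class.replace(":", "")
    instance_id = (f"{sentence.doc_id}.s{sentence.sentence_index}"
                   f".{e1_id}-{e2_id}.{cls_tag}")
    e1_type = sentence.mention_types[e1_id]
    e2_type = sentence.mention_types[e2_id]
    return CandidateInstance(
        instance_id=instance_id,
        doc_id=sentence.doc_id,
        sentence=sentence,
        relation_class=relation_class,
        entity1=(e1_id, e1_idx, ROLE_SYMBOL[e1_type]),
        entity2=(e2_id, e2_idx, ROLE_SYMBOL[e2_type]),
        proximal_verb=proximal,
        proximal_verb_lemma=verb_lemma,
        norm_tokens=norm_tokens,
        norm_pos=norm_pos,
        orig_token_map=orig_map,
    )


def generate_candidate_instances(
        sentence: Sentence,
        relations: Sequence[RelationAnnotation],
        mode: str = "TRAIN",
        class_inventory: Optional[Sequence[str]] = None) -> List[CandidateInstance]:
    """Emit candidate instances for every focal entity pair of a sentence.

    TRAIN mode labels pairs from the gold relations (one instance per gold
    annotation on the pair; non-gold pairs get the negative class and no
    relation normalization).  TEST mode replicates each pair once per class
    in ``class_inventory``.
    """
    if mode not in ("TRAIN", "TEST"):
        raise ValueError(f"unknown mode {mode!r}")
    gold: Dict[frozenset, List[str]] = {}
    for rel in relations:
        if rel.doc_id != sentence.doc_id:
            continue
        gold.setdefault(frozenset((rel.arg1, rel.arg2)), []).append(rel.relation_class)

    instances = []
    for counter, pair in enumerate(_pair_roles(sentence), start=1):
        if mode == "TEST":
            for cls in (class_inventory or [NEGATIVE_CLASS]):
                instances.append(_build_instance(
                    sentence, pair, cls, counter,
                    normalize_relation=cls != NEGATIVE_CLASS))
        else:
            classes = gold.get(frozenset(pair))
            if classes:
                for cls in classes:
                    instances.append(_build_instance(sentence, pair, cls,
                                                     counter, normalize_relation=True))
            else:
                instances.append(_build_instance(sentence, pair, NEGATIVE_CLASS,
                                                 counter, normalize_relation=False))
    return instances


def sample_negative_instances(corpus: Corpus, seed: int,
                              tagger: Optional[TaggerInterface] = None,
                              ratio: float = 1.0) -> List[CandidateInstance]:
    """Cross-group negative sampling: co-sentential pairs absent from the
    gold set, capped per abstract at ``ratio`` times the positive count."""
    tagger = tagger or RuleTagger()
    negatives: List[CandidateInstance] = []
    for doc in corpus.documents:
        doc_neg = []
        doc_pos = 0
        for sentence in segment_and_tag(doc, corpus.entities_of(doc.doc_id), tagger):
            for inst in generate_candidate_instances(sentence, corpus.relations, "TRAIN"):
                if inst.relation_class == NEGATIVE_CLASS:
                    doc_neg.append(inst)
                else:
                    doc_pos += 1
        cap = int(ratio * doc_pos)
        if cap < len(doc_neg):
            rng = random.Random(f"{seed}:{doc.doc_id}")
            doc_neg = rng.sample(sorted(doc_neg, key=lambda i: i.instance_id), cap)
        negatives.extend(doc_neg)
    return negatives


def collect_keywords(instances: Sequence[CandidateInstance]) -> Set[str]:
    """Interaction keywords: lemmatized proximal verbs of training positives."""
    return {inst.proximal_verb_lemma for inst in instances
            if inst.relation_class != NEGATIVE_CLASS and inst.proximal_verb_lemma}


def filter_test_instances(instances: Sequence[CandidateInstance],
                          keywords: Set[str]) -> List[CandidateInstance]:
    """Keep test instances whose sentence contains at least one keyword lemma."""
    if not keywords:
        logger.warning("empty keyword set: keyword filter passes everything")
        return list(instances)
    return [inst for inst in instances
            if keywords.intersection(inst.sentence.lemmas)]
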