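"""Deterministic synthetic corpora in the BioCreative three-file dialect.

Each relation class owns a template: a planted PoS skeleton with one
chemical anchor, one relation-verb anchor and one gene/protein anchor, plus
a class-specific surface vocabulary.  Sentences realize a template with
entity mentions and filler words; noise tokens are inserted outside the
planted context windows (padding mode) or anywhere (corrupting mode).  The
generator output is the no-download test surface for the whole pipeline.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .corpus_io import (Corpus, DependencyParse, Document, EntityMention,
                        RelationAnnotation)
from .grct import fallback_parse
from .patterns import AlignmentConfig, LinguisticPattern, align_pair
from .tagging import RuleTagger

CHEM_SLOT = "CHEMICAL"
GENE_SLOT = "GENEPRO"
REL_SLOT = "RELATION"


@dataclass(frozen=True)
class TemplateSpec:
    """Planted sentence skeleton for one relation class.

    ``core_pos`` is the PoS sequence with role slots; it must keep at least
    ``margin`` non-slot tags on both sides of every slot so that context
    frames extracted from realized sentences never leave the core.
    """
    class_label: str
    core_pos: Tuple[str, ...]
    vocab: Dict[str, Tuple[str, ...]]          # PoS tag -> filler words
    chemicals: Tuple[str, ...]
    genes: Tuple[str, ...]
    verbs: Tuple[str, ...] = ()                 # inflected surface forms
    margin: int = 3

    def slot_index(self, slot: str) -> Optional[int]:
        return self.core_pos.index(slot) if slot in self.core_pos else None

    def context(self, role_slot: str, n: int) -> Tuple[str, ...]:
        """Planted context for a role: the anchor-first window of size n+1
        over the normalized core PoS sequence."""
        idx = self.slot_index(role_slot)
        if idx is None:
            return ()
        return self.core_pos[idx:idx + n + 1]

    def validate(self) -> None:
        for slot in (CHEM_SLOT, GENE_SLOT):
            if slot not in self.core_pos:
                raise ValueError(f"template {self.class_label} lacks {slot}")
        for slot in (CHEM_SLOT, GENE_SLOT, REL_SLOT):
            idx = self.slot_index(slot)
            if idx is None:
                continue
            if idx < self.margin or idx > len(self.core_pos) - 1 - self.margin:
                raise ValueError(
                    f"template {self.class_label}: slot {slot} closer than "
                    f"{self.margin} tags to the core boundary")
        if REL_SLOT in self.core_pos and not self.verbs:
            raise ValueError(f"template {self.class_label} needs verb surfaces")


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    n_abstracts: int = 50
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: {"CPR:3": 0.5, "CPR:4": 0.5})
    negatives_fraction: float = 0.25
    noise_token_rate: float = 0.0
    corrupting_noise: bool = False
    multi_pair_sentence_rate: float = 0.0
    max_sentences_per_abstract: int = 3
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for cls, frac in self.class_proportions.items():
            if frac * self.n_abstracts < 1:
                raise ValueError(
                    f"class {cls}: fraction {frac} infeasible for "
                    f"{self.n_abstracts} abstracts")


_NOISE_WORDS = ("sample", "cohort", "assay", "baseline", "control", "group",
                "marker", "profile", "panel", "subset")


def default_templates() -> List[TemplateSpec]:
    """Two positive classes plus a verb-free negative template, with
    pairwise disjoint vocabularies and distinct PoS context structure."""
    return [
        TemplateSpec(
            class_label="CPR:3",
            core_pos=("DT", "JJ", "NN", CHEM_SLOT, "RB", REL_SLOT,
                      "DT", GENE_SLOT, "NN", "NN", "NN"),
            vocab={"DT": ("The", "the"), "JJ": ("selective", "potent"),
                   "NN": ("agonist", "receptor", "pathway", "response",
                          "cascade", "sequence"),
                   "RB": ("rapidly", "strongly")},
            chemicals=("alprexate", "vemodrine", "cortaxel"),
            genes=("kinoralin", "fosbeta", "mapkor"),
            verbs=("activates", "stimulates", "induces")),
        TemplateSpec(
            class_label="CPR:4",
            core_pos=("IN", "NN", "NN", CHEM_SLOT, REL_SLOT, "JJ",
                      GENE_SLOT, "NN", "IN", "NN", "NN"),
            vocab={"IN": ("In", "of", "within"), "JJ": ("active", "native"),
                   "NN": ("culture", "extract", "kinase", "domain",
                          "fraction", "lysate")},
            chemicals=("zaltropin", "nexavirol", "quibrafen"),
            genes=("tyralon", "gactamol", "hepsarin"),
            verbs=("inhibits", "blocks", "suppresses")),
        TemplateSpec(
            class_label="NEG",
            core_pos=("DT", "NN", "IN", CHEM_SLOT, "NN", "IN",
                      "DT", GENE_SLOT, "NN", "NN", "NN"),
            vocab={"DT": ("The", "the"), "IN": ("of", "near"),
                   "NN": ("amount", "trace", "record", "tissue",
                          "section", "aliquot")},
            chemicals=("placebrol", "aquasol"),
            genes=("histonel", "lamusol")),
    ]


def _realize(template: TemplateSpec, rng: random.Random
             ) -> Tuple[List[str], Dict[str, int]]:
    """Instantiate one core as a token list; returns the tokens and the
    token index of each role slot."""
    tokens: List[str] = []
    slots: Dict[str, int] = {}
    for pos in template.core_pos:
        if pos == CHEM_SLOT:
            slots[CHEM_SLOT] = len(tokens)
            tokens.append(rng.choice(template.chemicals))
        elif pos == GENE_SLOT:
            slots[GENE_SLOT] = len(tokens)
            tokens.append(rng.choice(template.genes))
        elif pos == REL_SLOT:
            slots[REL_SLOT] = len(tokens)
            tokens.append(rng.choice(template.verbs))
        else:
            tokens.append(rng.choice(template.vocab[pos]))
    tokens[0] = tokens[0][0].upper() + tokens[0][1:]  # sentence-splitter cue
    return tokens, slots


def _insert_noise(tokens: List[str], slots: Dict[str, int],
                  rate: float, corrupting: bool, rng: random.Random) -> List[str]:
    if rate <= 0:
        return tokens
    count = sum(1 for _ in tokens if rng.random() < rate)
    out = list(tokens)
    for _ in range(count):
        word = rng.choice(_NOISE_WORDS)
        if corrupting:
            pos = rng.randrange(len(out) + 1)
            out.insert(pos, word)
            for slot, idx in slots.items():
                if idx >= pos:
                    slots[slot] = idx + 1
        else:
            # padding mode: append after the core so planted windows stay intact
            out.append(word)
    return out


def generate_corpus(templates: Sequence[TemplateSpec],
                    config: SyntheticCorpusConfig
                    ) -> Tuple[Corpus, Dict[Tuple[str, int], DependencyParse], dict]:
    """Generate (corpus, gold parses, manifest); byte-identical under a
    fixed seed."""
    config.validate()
    for template in templates:
        template.validate()
    positive = [t for t in templates if t.class_label != "NEG"
                and t.class_label in config.class_proportions]
    negative = next((t for t in templates if t.class_label == "NEG"), None)
    if not positive:
        raise ValueError("need at least one positive-class template")
    weights = [config.class_proportions[t.class_label] for t in positive]

    rng = random.Random(config.seed)
    tagger = RuleTagger()
    documents: List[Document] = []
    entities: List[EntityMention] = []
    relations: List[RelationAnnotation] = []
    parses: Dict[Tuple[str, int], DependencyParse] = {}
    planted: Dict[str, List[dict]] = {}

    for a in range(config.n_abstracts):
        doc_id = f"D{a:04d}"
        title = f"Synthetic record {a:04d} ."
        n_sent = rng.randint(1, config.max_sentences_per_abstract)
        sent_texts: List[str] = []
        doc_entities: List[Tuple[str, str, int, int, str]] = []
        doc_relations: List[Tuple[str, str, str]] = []
        doc_planted: List[dict] = []
        mention_counter = 0
        # title occupies sentence index 0 on the document axis
        offset = len(title) + 1  # past the title + tab separator

        for s in range(n_sent):
            if negative is not None and rng.random() < config.negatives_fraction:
                template = negative
            else:
                template = rng.choices(positive, weights=weights, k=1)[0]
            tokens, slots = _realize(template, rng)
            tokens = _insert_noise(tokens, slots, config.noise_token_rate,
                                   config.corrupting_noise, rng)
            if rng.random() < config.multi_pair_sentence_rate:
                extra_template = rng.choice(positive)
                tokens.extend(["and", rng.choice(extra_template.chemicals)])
                slots["EXTRA_CHEM"] = len(tokens) - 1
            tokens.append(".")

            text = " ".join(tokens)
            char_starts = []
            pos_cursor = 0
            for tok in tokens:
                char_starts.append(pos_cursor)
                pos_cursor += len(tok) + 1

            sent_offset = offset + sum(len(t) + 1 for t in sent_texts)
            mention_ids = {}
            for slot in (CHEM_SLOT, GENE_SLOT, "EXTRA_CHEM"):
                if slot not in slots:
                    continue
                mention_counter += 1
                mid = f"T{mention_counter}"
                idx = slots[slot]
                start = sent_offset + char_starts[idx]
                surface = tokens[idx]
                etype = "GENE_PROTEIN" if slot == GENE_SLOT else "CHEMICAL"
                doc_entities.append((mid, etype, start, start + len(surface), surface))
                mention_ids[slot] = mid
            if template.class_label != "NEG":
                doc_relations.append((template.class_label,
                                      mention_ids[CHEM_SLOT],
                                      mention_ids[GENE_SLOT]))
            doc_planted.append({
                "sentence_index": s + 1,
                "class": template.class_label,
                "mentions": mention_ids,
            })
            sent_texts.append(text)

        abstract = " ".join(sent_texts)
        documents.append(Document(doc_id, title, abstract))
        for mid, etype, start, end, surface in doc_entities:
            entities.append(EntityMention(doc_id, mid, etype, start, end, surface))
        for cls, arg1, arg2 in doc_relations:
            relations.append(RelationAnnotation(doc_id, cls, arg1, arg2))
        planted[doc_id] = doc_planted

        # gold parses from the fallback parser, title included as sentence 0
        title_tokens = title.split(" ")
        parses[(doc_id, 0)] = fallback_parse(title_tokens,
                                             tagger.tag(title_tokens))
        for s, text in enumerate(sent_texts, start=1):
            toks = text.split(" ")
            parses[(doc_id, s)] = fallback_parse(toks, tagger.tag(toks))

    corpus = Corpus(documents, entities, relations)
    corpus.validate()
    manifest = {
        "config": {
            "n_abstracts": config.n_abstracts,
            "class_proportions": dict(config.class_proportions),
            "negatives_fraction": config.negatives_fraction,
            "noise_token_rate": config.noise_token_rate,
            "corrupting_noise": config.corrupting_noise,
            "multi_pair_sentence_rate": config.multi_pair_sentence_rate,
            "seed": config.seed,
        },
        "templates": [
            {"class": t.class_label, "core_pos": list(t.core_pos)}
            for t in templates
        ],
        "planted": planted,
    }
    return corpus, parses, manifest


# ---------------------------------------------------------------------------
# Recovery statistics
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    per_template: Dict[str, float]   # class label -> best normalized score
    fraction_recovered: float


def recovery_report(learned: Dict[str, List[LinguisticPattern]],
                    templates: Sequence[TemplateSpec],
                    n: int = 3,
                    threshold: float = 0.5,
                    align_config: AlignmentConfig = AlignmentConfig()
                    ) -> RecoveryReport:
    """Best alignment of each planted template against the learned patterns
    of its class, normalized by the perfect self-alignment score; a template
    is recovered when the normalized score reaches ``threshold``."""
    role_slots = {CHEM_SLOT: "entity1", REL_SLOT: "relation", GENE_SLOT: "entity2"}
    scores: Dict[str, float] = {}
    recovered = 0
    total = 0
    for template in templates:
        contexts = {slot: template.context(slot, n) for slot in role_slots}
        perfect = sum(2.0 * len(ctx) for ctx in contexts.values() if ctx)
        if perfect == 0:
            continue
        total += 1
        best = 0.0
        for pattern in learned.get(template.class_label, []):
            pattern_contexts = {CHEM_SLOT: pattern.entity1_context,
                                REL_SLOT: pattern.relation_context,
                                GENE_SLOT: pattern.entity2_context}
            score = 0.0
            for slot, ctx in contexts.items():
                pctx = pattern_contexts[slot]
                if ctx and pctx:
                    score += align_pair(ctx, pctx, align_config)[0]
            best = max(best, score / perfect)
        scores[template.class_label] = best
        if best >= threshold:
            recovered += 1
    return RecoveryReport(scores, recovered / total if total else 0.0)
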