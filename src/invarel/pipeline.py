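"""End-to-end orchestration: corpus -> candidates -> patterns -> trees ->
kernel -> SVM -> predictions.

Task-mode presets follow the per-corpus setups: the chemical-protein mode
uses frame size n=3 with score cutoffs (>0, -0.3), the chemical-disease
mode uses n=5, and the protein-protein mode uses n=3 with the in-range
[0, 1] decision rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import classification, grct, patterns as pat
from .candidates import (NEGATIVE_CLASS, CandidateInstance, collect_keywords,
                         filter_test_instances, generate_candidate_instances,
                         sample_negative_instances, segment_and_tag)
from .classification import (CUTOFF_RULE, RANGE_RULE, PredictionResult,
                             TrainedModel, binary_decision)
from .corpus_io import Corpus
from .grct import GRCTTree
from .sptk import KernelParams, kernel_matrix
from .tagging import RuleTagger, TaggerInterface

logger = logging.getLogger(__name__)

MODE_PRESETS = {
    "CPI": {"n": 3, "rule": CUTOFF_RULE},
    "CDR": {"n": 5, "rule": CUTOFF_RULE},
    "PPI": {"n": 3, "rule": RANGE_RULE},
}


@dataclass
class PipelineConfig:
    task_mode: str = "CPI"
    invariance: pat.InvarianceConfig = field(default_factory=pat.InvarianceConfig)
    alignment: pat.AlignmentConfig = field(default_factory=pat.AlignmentConfig)
    kernel: KernelParams = field(default_factory=KernelParams)
    C: float = 1.0
    pos_cut: float = 0.0
    neg_cut: float = -0.3
    negative_ratio: float = 1.0
    min_match_score: float = 0.0
    use_keyword_filter: bool = True
    seed: int = 0

    @classmethod
    def for_mode(cls, task_mode: str, **overrides) -> "PipelineConfig":
        if task_mode not in MODE_PRESETS:
            raise ValueError(f"unknown task mode {task_mode!r}")
        preset = MODE_PRESETS[task_mode]
        config = cls(task_mode=task_mode,
                     invariance=pat.InvarianceConfig(n=preset["n"]))
        for key, value in overrides.items():
            setattr(config, key, value)
        return config

    @property
    def decision_rule(self) -> str:
        return MODE_PRESETS[self.task_mode]["rule"]


@dataclass
class PipelineModel:
    config: PipelineConfig
    patterns: Dict[str, List[pat.LinguisticPattern]]
    keywords: set
    class_inventory: List[str]
    training_trees: Dict[str, GRCTTree]
    training_ids: List[str]
    binary_model: TrainedModel
    ova_models: Dict[str, TrainedModel]


def training_instances(corpus: Corpus, config: PipelineConfig,
                       tagger: Optional[TaggerInterface] = None
                       ) -> List[CandidateInstance]:
    """Gold-labeled positives plus capped sampled negatives."""
    tagger = tagger or RuleTagger()
    positives: List[CandidateInstance] = []
    for doc in corpus.documents:
        for sentence in segment_and_tag(doc, corpus.entities_of(doc.doc_id), tagger):
            for inst in generate_candidate_instances(sentence, corpus.relations,
                                                     "TRAIN"):
                if inst.relation_class != NEGATIVE_CLASS:
                    positives.append(inst)
    negatives = sample_negative_instances(corpus, config.seed, tagger,
                                          config.negative_ratio)
    return positives + negatives


def instance_tree(instance: CandidateInstance,
                  pattern_set: Sequence[pat.LinguisticPattern],
                  config: PipelineConfig,
                  decoration: Optional[str] = None) -> GRCTTree:
    """Parse, build the relation-centered tree, prune by the best matching
    pattern (if any clears the threshold) and decorate with the class."""
    parse = grct.fallback_parse(instance.norm_tokens, instance.norm_pos)
    tree = grct.build_grct(parse)
    match = grct.match_pattern(instance, pattern_set, config.alignment,
                               config.min_match_score)
    if match is not None:
        tree = grct.prune_tree(tree, match)
    label = decoration if decoration is not None else instance.relation_class
    return grct.decorate_tree(tree, label)


def train_pipeline(corpus: Corpus, config: Optional[PipelineConfig] = None,
                   tagger: Optional[TaggerInterface] = None) -> PipelineModel:
    config = config or PipelineConfig()
    instances = training_instances(corpus, config, tagger)
    if not instances:
        raise ValueError("corpus yields no training instances")
    learned = pat.learn_patterns(instances, config.invariance, config.alignment)
    all_patterns = [p for plist in learned.values() for p in plist]
    keywords = collect_keywords(instances)
    inventory = sorted({i.relation_class for i in instances
                        if i.relation_class != NEGATIVE_CLASS})

    trees: Dict[str, GRCTTree] = {}
    labels: Dict[str, str] = {}
    for instance in instances:
        trees[instance.instance_id] = instance_tree(instance, all_patterns, config)
        labels[instance.instance_id] = instance.relation_class
    ids = sorted(trees)
    gram = kernel_matrix([(i, trees[i]) for i in ids], None, config.kernel)

    y_binary = [1 if labels[i] != NEGATIVE_CLASS else -1 for i in ids]
    binary_model = classification.train_binary(
        gram.values, y_binary, config.C, ids, positive_label="INTERACTING")
    ova_models = classification.train_multiclass_ova(
        gram.values, [labels[i] for i in ids], config.C, ids,
        positive_classes=inventory)
    return PipelineModel(config, learned, keywords, inventory, trees, ids,
                         binary_model, ova_models)


def predict_pipeline(model: PipelineModel, corpus: Corpus,
                     tagger: Optional[TaggerInterface] = None
                     ) -> List[PredictionResult]:
    """Score every co-sentential candidate pair of a (test) corpus.

    Each pair is replicated once per class in the inventory; the binary
    score is the best replica score, and the assigned class is the best
    one-vs-all score among the replicas.
    """
    tagger = tagger or RuleTagger()
    config = model.config
    all_patterns = [p for plist in model.patterns.values() for p in plist]

    replicas: List[CandidateInstance] = []
    for doc in corpus.documents:
        for sentence in segment_and_tag(doc, corpus.entities_of(doc.doc_id), tagger):
            replicas.extend(generate_candidate_instances(
                sentence, [], "TEST", class_inventory=model.class_inventory))

    pair_of = {}
    for inst in replicas:
        pair_of[inst.instance_id] = (inst.doc_id, inst.entity1[0], inst.entity2[0])
    all_pairs = sorted(set(pair_of.values()))

    if config.use_keyword_filter:
        replicas = filter_test_instances(replicas, model.keywords)

    results: List[PredictionResult] = []
    if replicas:
        trees = [(inst.instance_id,
                  instance_tree(inst, all_patterns, config,
                                decoration=inst.relation_class))
                 for inst in replicas]
        train_items = [(i, model.training_trees[i]) for i in model.training_ids]
        test_gram = kernel_matrix(trees, train_items, config.kernel)

        by_pair: Dict[Tuple[str, str, str], List[Tuple[str, np.ndarray]]] = {}
        for (iid, _), row in zip(trees, test_gram.values):
            by_pair.setdefault(pair_of[iid], []).append((iid, row))

        for pair_key in sorted(by_pair):
            rows = by_pair[pair_key]
            binary_scores = {iid: model.binary_model.decision(row)
                             for iid, row in rows}
            best_iid = max(sorted(binary_scores), key=lambda i: binary_scores[i])
            score = binary_scores[best_iid]
            doc_id, arg1, arg2 = pair_key
            if binary_decision(score, config.pos_cut, config.neg_cut,
                               config.decision_rule) and model.ova_models:
                class_scores = {}
                for iid, row in rows:
                    cls = _replica_class(iid, model.class_inventory)
                    if cls in model.ova_models:
                        class_scores[cls] = model.ova_models[cls].decision(row)
                if class_scores:
                    label = max(sorted(class_scores),
                                key=lambda c: class_scores[c])
                else:
                    label = NEGATIVE_CLASS
            else:
                class_scores = {}
                label = NEGATIVE_CLASS
            results.append(PredictionResult(best_iid, doc_id, arg1, arg2,
                                            label, score, class_scores))

    scored_pairs = {(r.doc_id, r.arg1, r.arg2) for r in results}
    for doc_id, arg1, arg2 in all_pairs:
        if (doc_id, arg1, arg2) not in scored_pairs:
            # filtered out by the keyword gate: defaults to non-interacting
            results.append(PredictionResult(
                f"{doc_id}.{arg1}-{arg2}.filtered", doc_id, arg1, arg2,
                NEGATIVE_CLASS, float(config.neg_cut)))
    return sorted(results, key=lambda r: (r.doc_id, r.arg1, r.arg2))


def _replica_class(instance_id: str, inventory: Sequence[str]) -> str:
    tag = instance_id.rsplit(".", 1)[-1]
    for cls in inventory:
        if cls.replace(":", "") == tag:
            return cls
    return NEGATIVE_CLASS


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

def save_model(model: PipelineModel, path) -> None:
    payload = {
        "task_mode": model.config.task_mode,
        "config": {
            "n": model.config.invariance.n,
            "ratio_tolerance": model.config.invariance.ratio_tolerance,
            "fringe": model.config.invariance.fringe,
            "mu": model.config.kernel.mu,
            "lam": model.config.kernel.lam,
            "normalize": model.config.kernel.normalize,
            "C": model.config.C,
            "pos_cut": model.config.pos_cut,
            "neg_cut": model.config.neg_cut,
            "negative_ratio": model.config.negative_ratio,
            "min_match_score": model.config.min_match_score,
            "use_keyword_filter": model.config.use_keyword_filter,
            "seed": model.config.seed,
        },
        "patterns": {
            cls: [{"e1": list(p.entity1_context), "rel": list(p.relation_context),
                   "e2": list(p.entity2_context), "support": p.support}
                  for p in plist]
            for cls, plist in model.patterns.items()
        },
        "keywords": sorted(model.keywords),
        "class_inventory": model.class_inventory,
        "training_trees": {iid: grct.serialize_tree(tree)
                           for iid, tree in model.training_trees.items()},
        "training_ids": model.training_ids,
        "binary_model": classification.model_to_dict(model.binary_model),
        "ova_models": {cls: classification.model_to_dict(m)
                       for cls, m in model.ova_models.items()},
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> PipelineModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    config = PipelineConfig(
        task_mode=payload["task_mode"],
        invariance=pat.InvarianceConfig(
            n=cfg["n"], ratio_tolerance=cfg["ratio_tolerance"],
            fringe=cfg["fringe"]),
        kernel=KernelParams(mu=cfg["mu"], lam=cfg["lam"],
                            normalize=cfg["normalize"]),
        C=cfg["C"], pos_cut=cfg["pos_cut"], neg_cut=cfg["neg_cut"],
        negative_ratio=cfg["negative_ratio"],
        min_match_score=cfg["min_match_score"],
        use_keyword_filter=cfg["use_keyword_filter"], seed=cfg["seed"])
    learned = {
        cls: [pat.LinguisticPattern(cls, tuple(p["e1"]), tuple(p["rel"]),
                                    tuple(p["e2"]), p["support"])
              for p in plist]
        for cls, plist in payload["patterns"].items()
    }
    trees = {iid: grct.parse_tree(text)
             for iid, text in payload["training_trees"].items()}
    for tree in trees.values():
        tree.decorated = True
    return PipelineModel(
        config=config,
        patterns=learned,
        keywords=set(payload["keywords"]),
        class_inventory=list(payload["class_inventory"]),
        training_trees=trees,
        training_ids=list(payload["training_ids"]),
        binary_model=classification.model_from_dict(payload["binary_model"]),
        ova_models={cls: classification.model_from_dict(m)
                    for cls, m in payload["ova_models"].items()})


def evaluate_predictions(results: Sequence[PredictionResult],
                         corpus: Corpus) -> dict:
    """Binary and per-class reports against a gold-annotated corpus."""
    def canonical(doc_id, a, b):
        return (doc_id, *sorted((a, b)))

    gold_canonical = {canonical(r.doc_id, r.arg1, r.arg2): r.relation_class
                      for r in corpus.relations}
    predicted = {canonical(r.doc_id, r.arg1, r.arg2): r.label for r in results}
    binary = classification.evaluate_binary(
        {k for k, v in predicted.items() if v != NEGATIVE_CLASS},
        set(gold_canonical))
    report = classification.evaluate(predicted, gold_canonical)
    return {
        "binary": {"precision": binary.precision, "recall": binary.recall,
                   "f1": binary.f1, "tp": binary.tp, "fp": binary.fp,
                   "fn": binary.fn},
        "per_class": {
            cls: {"precision": m.precision, "recall": m.recall, "f1": m.f1,
                  "tp": m.tp, "fp": m.fp, "fn": m.fn}
            for cls, m in report.per_class.items()},
        "micro_f1": report.micro_f1,
    }
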