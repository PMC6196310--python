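"""Grammatical-relation-centered trees: construction, pattern-guided pruning,
class decoration and bracketed serialization.

A GRCT re-expresses a dependency parse as a three-layer tree: one SYNT node
per dependency relation, a POS node per token underneath its relation node,
and the lexical token as a LEX leaf under its POS node.  Children are
ordered by token position so the left-to-right leaf sequence equals the
token sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .candidates import CandidateInstance
from .corpus_io import DependencyParse
from .patterns import (GAP, ENTITY1, ENTITY2, RELATION, AlignmentConfig,
                       LinguisticPattern, align_pair)
from .tagging import VERB_TAGS

SYNT = "SYNT"
POS = "POS"
LEX = "LEX"

DECORATION_RELATION = "class"


@dataclass
class TreeNode:
    label: str
    kind: str
    children: List["TreeNode"] = field(default_factory=list)
    token_index: Optional[int] = None

    def leaves(self) -> List["TreeNode"]:
        if not self.children:
            return [self]
        out: List[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def nodes(self) -> List["TreeNode"]:
        out = [self]
        for child in self.children:
            out.extend(child.nodes())
        return out


@dataclass
class GRCTTree:
    root: TreeNode
    decorated: bool = False

    def leaves(self) -> List[TreeNode]:
        return self.root.leaves()

    def validate(self) -> None:
        def walk(node: TreeNode, parent: Optional[TreeNode]) -> None:
            if node.kind == LEX:
                if node.children:
                    raise ValueError("LEX nodes must be leaves")
                if parent is None or parent.kind != POS:
                    raise ValueError("every LEX leaf needs a POS parent")
            elif node.kind == POS:
                if parent is not None and parent.kind not in (SYNT,):
                    raise ValueError("POS nodes attach under SYNT nodes")
                if len(node.children) != 1 or node.children[0].kind != LEX:
                    raise ValueError("POS nodes carry exactly one LEX child")
            elif node.kind == SYNT:
                if not node.children:
                    raise ValueError("SYNT nodes cannot be empty")
            else:
                raise ValueError(f"unknown node kind {node.kind!r}")
            for child in node.children:
                walk(child, node)
        walk(self.root, None)
        for leaf in self.leaves():
            if leaf.kind != LEX:
                raise ValueError("all leaves must be LEX nodes")


def build_grct(parse: DependencyParse) -> GRCTTree:
    """Build the GRCT for a dependency parse.

    Each token contributes a SYNT(deprel) node whose children are the
    subtrees of its dependents plus its own POS -> LEX chain, all ordered
    by token position.
    """
    def subtree(index: int) -> TreeNode:
        pos_chain = TreeNode(parse.pos[index], POS, [
            TreeNode(parse.tokens[index], LEX, token_index=index)],
            token_index=index)
        items: List[Tuple[int, TreeNode]] = [(index, pos_chain)]
        for dep in parse.dependents(index):
            items.append((dep, subtree(dep)))
        items.sort(key=lambda t: t[0])
        return TreeNode(parse.deprels[index], SYNT, [n for _, n in items])

    tree = GRCTTree(subtree(parse.root_index))
    tree.validate()
    return tree


def fallback_parse(tokens: Sequence[str], pos: Sequence[str]) -> DependencyParse:
    """Deterministic heuristic parse: every token attaches to the nearest
    verb (ties leftward); extra verbs attach to the first verb, which roots
    the sentence.  Verbless sentences are rooted at the first token."""
    n = len(tokens)
    verbs = [i for i, t in enumerate(pos) if t in VERB_TAGS or t == "RELATION"]
    heads = [0] * n
    deprels = ["dep"] * n
    if verbs:
        root = verbs[0]
        for i in range(n):
            if i == root:
                continue
            if i in verbs:
                heads[i] = root + 1
                deprels[i] = "conj"
            else:
                nearest = min(verbs, key=lambda v: (abs(v - i), v))
                heads[i] = nearest + 1
    else:
        root = 0
        for i in range(1, n):
            heads[i] = 1
    heads[root] = 0
    deprels[root] = "root"
    return DependencyParse(tuple(tokens), tuple(pos), tuple(heads), tuple(deprels))


# ---------------------------------------------------------------------------
# Pattern matching against the instance PoS sequence
# ---------------------------------------------------------------------------

@dataclass
class PatternMatch:
    pattern: LinguisticPattern
    covered_tokens: Set[int]
    score: float


def _role_anchor_indices(instance: CandidateInstance) -> Dict[str, int]:
    anchors = {ENTITY1: instance.e1_index, ENTITY2: instance.e2_index}
    if instance.rel_index is not None:
        anchors[RELATION] = instance.rel_index
    return anchors


def _anchor_offset(context: Tuple[str, ...], symbol: str) -> Optional[int]:
    try:
        return context.index(symbol)
    except ValueError:
        return None


def _score_one(instance: CandidateInstance, pattern: LinguisticPattern,
               align_config: AlignmentConfig) -> Optional[Tuple[float, Set[int]]]:
    pos = instance.norm_pos
    anchors = _role_anchor_indices(instance)
    role_symbols = {ENTITY1: instance.entity1[2], ENTITY2: instance.entity2[2],
                    RELATION: "RELATION"}
    total = 0.0
    covered: Set[int] = set(anchors.values())
    for role in (ENTITY1, RELATION, ENTITY2):
        context = pattern.context(role)
        if not context:
            continue  # pattern has no context for this role (negative class)
        if role not in anchors:
            if role == RELATION:
                continue  # instance carries no relation anchor
            return None
        offset = _anchor_offset(context, role_symbols[role])
        if offset is None:
            if role == RELATION:
                continue
            return None  # entity contexts must stay anchored
        start = anchors[role] - offset
        window = pos[max(0, start):max(0, start) + len(context)]
        if not window:
            continue
        score, (actx, awin) = align_pair(context, window, align_config)
        total += score
        wi = max(0, start)
        for ca, cb in zip(actx, awin):
            if cb != GAP:
                if ca != GAP:
                    covered.add(wi)
                wi += 1
    return total, covered


def match_pattern(instance: CandidateInstance,
                  patterns: Sequence[LinguisticPattern],
                  align_config: AlignmentConfig = AlignmentConfig(),
                  min_score: float = 0.0) -> Optional[PatternMatch]:
    """Align every pattern's contexts against the instance PoS sequence,
    anchored at the role positions, and return the best-scoring match above
    ``min_score`` (or ``None``)."""
    best: Optional[PatternMatch] = None
    for pattern in patterns:
        result = _score_one(instance, pattern, align_config)
        if result is None:
            continue
        score, covered = result
        if score <= min_score:
            continue
        if best is None or score > best.score:
            best = PatternMatch(pattern, covered, score)
    return best


# ---------------------------------------------------------------------------
# Pruning and decoration
# ---------------------------------------------------------------------------

def prune_tree(tree: GRCTTree, match: PatternMatch) -> GRCTTree:
    """Drop LEX leaves for tokens outside the match, then every POS/SYNT
    ancestor left without a LEX descendant."""
    if not match.covered_tokens:
        raise ValueError("pattern match covers no tokens")

    def keep(node: TreeNode) -> Optional[TreeNode]:
        if node.kind == LEX:
            if node.token_index in match.covered_tokens:
                return TreeNode(node.label, LEX, token_index=node.token_index)
            return None
        children = [c for c in (keep(child) for child in node.children)
                    if c is not None]
        if not children:
            return None
        return TreeNode(node.label, node.kind, children, node.token_index)

    root = keep(tree.root)
    if root is None:
        raise ValueError("pattern match covers no tokens of this tree")
    pruned = GRCTTree(root, decorated=tree.decorated)
    pruned.validate()
    return pruned


def decorate_tree(tree: GRCTTree, class_label: str) -> GRCTTree:
    """Prefix the class node: a fresh super-root whose leftmost child names
    the interaction class of the instance."""
    if tree.decorated:
        raise ValueError("tree is already decorated")
    label = "Class" + class_label.replace(":", "").replace(" ", "")
    class_node = TreeNode(DECORATION_RELATION, SYNT, [
        TreeNode(label, POS, [TreeNode(label, LEX)])])
    return GRCTTree(TreeNode("TOP", SYNT, [class_node, tree.root]),
                    decorated=True)


# ---------------------------------------------------------------------------
# Bracketed serialization
# ---------------------------------------------------------------------------

def serialize_tree(tree: GRCTTree, lexical_compat: bool = False) -> str:
    """Render the bracketed form; ``lexical_compat`` renders LEX leaves in
    the ``token::p`` style (lowercased token, PoS initial)."""
    def render(node: TreeNode, parent: Optional[TreeNode] = None) -> str:
        if not node.children:
            label = node.label
            if lexical_compat and node.kind == LEX and parent is not None:
                label = f"{label.lower()}::{parent.label[:1].lower()}"
            return f"({label})"
        inner = " ".join(render(c, node) for c in node.children)
        return f"({node.label} {inner})"
    return render(tree.root)


class TreeParseError(ValueError):
    pass


def parse_tree(text: str) -> GRCTTree:
    """Parse a bracketed tree; node kinds are recovered structurally
    (leaf -> LEX, parent of a lone LEX -> POS, else SYNT)."""
    pos = 0

    def skip_ws():
        nonlocal pos
        while pos < len(text) and text[pos].isspace():
            pos += 1

    def parse_node() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos >= len(text) or text[pos] != "(":
            raise TreeParseError(f"expected '(' at position {pos}")
        pos += 1
        skip_ws()
        start = pos
        while pos < len(text) and text[pos] not in "() \t\n":
            pos += 1
        label = text[start:pos]
        if not label:
            raise TreeParseError(f"empty node label at position {start}")
        children = []
        skip_ws()
        while pos < len(text) and text[pos] == "(":
            children.append(parse_node())
            skip_ws()
        if pos >= len(text) or text[pos] != ")":
            raise TreeParseError(f"expected ')' at position {pos}")
        pos += 1
        return TreeNode(label, SYNT, children)

    root = parse_node()
    skip_ws()
    if pos != len(text):
        raise TreeParseError(f"trailing characters at position {pos}")

    def assign_kinds(node: TreeNode) -> None:
        if not node.children:
            node.kind = LEX
        elif len(node.children) == 1 and not node.children[0].children:
            node.kind = POS
            node.children[0].kind = LEX
        else:
            node.kind = SYNT
        for child in node.children:
            if child.children:
                assign_kinds(child)
            # leaf kinds are set by their parent above
    assign_kinds(root)
    for leaf in root.leaves():
        leaf.kind = LEX
    return GRCTTree(root)


def write_trees(trees: Dict[str, GRCTTree], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for instance_id in sorted(trees):
            fh.write(f"{instance_id}\t{serialize_tree(trees[instance_id])}\n")


def read_trees(path) -> Dict[str, GRCTTree]:
    trees: Dict[str, GRCTTree] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line:
                continue
            instance_id, _, bracketed = line.partition("\t")
            trees[instance_id] = parse_tree(bracketed)
    return trees
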