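"""Invariance-based linguistic pattern mining.

The pipeline implemented here:

1. extract PoS context frames around each referential-group anchor
   (entity1 / relation / entity2) for every window offset ``e_c`` in 0..n;
2. score each frame against the corpus-wide frame-prefix counts (a joint
   conditional probability with a fringe addend for self-conditioned frames);
3. consolidate per-role cumulative scores into conic coefficients
   (p20, p11, p02) and reduce them to the rotation-invariant scalar
   ``I = p20^2 + p11^2/2 + p02^2``;
4. pick the best-scoring window per instance, cluster instances whose
   invariant ratio is 1 (within tolerance), and consolidate each cluster
   into a triple-context consensus pattern by progressive global alignment.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .candidates import CandidateInstance, NEGATIVE_CLASS

logger = logging.getLogger(__name__)

ENTITY1 = "ENTITY1"
RELATION = "RELATION"
ENTITY2 = "ENTITY2"
ROLES = (ENTITY1, RELATION, ENTITY2)

GAP = "-"


@dataclass(frozen=True)
class InvarianceConfig:
    n: int = 3                      # context frame size (window spans n+1 tags)
    delta: float = 1.00             # determinant of the assumed transformation
    weight: float = 1.0             # invariant weight W
    ratio_tolerance: float = 1e-6   # epsilon around the unit invariance ratio
    fringe: float = 1e-8            # delta_v for self-conditioned frames

    def __post_init__(self):
        if not (3 <= self.n <= 7):
            raise ValueError(f"frame size n must lie in [3, 7], got {self.n}")


@dataclass(frozen=True)
class AlignmentConfig:
    match: float = 2.0
    mismatch: float = -2.0
    gap: float = -2.0


@dataclass(frozen=True)
class ContextFrame:
    rfg_role: str                 # ENTITY1 / RELATION / ENTITY2
    e_c: int                      # iteration index requested (0..n)
    anchor_offset: int            # actual anchor position m inside the frame
    tags: Tuple[str, ...]
    instance_id: str


@dataclass(frozen=True)
class FrameScore:
    rho: float
    frame: ContextFrame


@dataclass(frozen=True)
class PolynomialRepr:
    p20: float
    p11: float
    p02: float
    instance_id: str


@dataclass(frozen=True)
class InvariantScore:
    value: float
    e_c: int
    instance_id: str


@dataclass
class InstanceRepresentation:
    """Best-scoring conic representation of one instance."""
    poly: PolynomialRepr
    score: InvariantScore
    frames: Dict[str, ContextFrame]


@dataclass
class InstanceCluster:
    members: List[str]
    representative: float
    class_label: str


@dataclass(frozen=True)
class LinguisticPattern:
    class_label: str
    entity1_context: Tuple[str, ...]
    relation_context: Tuple[str, ...]
    entity2_context: Tuple[str, ...]
    support: int

    def context(self, role: str) -> Tuple[str, ...]:
        return {ENTITY1: self.entity1_context,
                RELATION: self.relation_context,
                ENTITY2: self.entity2_context}[role]


# ---------------------------------------------------------------------------
# Frame extraction and scoring
# ---------------------------------------------------------------------------

def _anchors(instance: CandidateInstance) -> Dict[str, int]:
    anchors = {ENTITY1: instance.e1_index, ENTITY2: instance.e2_index}
    if instance.rel_index is not None:
        anchors[RELATION] = instance.rel_index
    return anchors


def extract_context_frames(instance: CandidateInstance, n: int) -> List[ContextFrame]:
    """Emit, for each referential-group role present, one frame per window
    offset e_c in 0..n.  Frames are truncated (never padded) at sentence
    boundaries; negative instances contribute entity frames only."""
    pos = instance.norm_pos
    frames = []
    for role, anchor in _anchors(instance).items():
        if not (0 <= anchor < len(pos)):
            raise ValueError(f"anchor for role {role} out of range in "
                             f"{instance.instance_id}")
        for e_c in range(n + 1):
            start = max(0, anchor - e_c)
            end = min(len(pos) - 1, start + n)
            frames.append(ContextFrame(
                rfg_role=role, e_c=e_c, anchor_offset=anchor - start,
                tags=tuple(pos[start:end + 1]),
                instance_id=instance.instance_id))
    return frames


def build_frame_counts(instances: Sequence[CandidateInstance],
                       n: int) -> Counter:
    """Count every frame prefix across all frames of all instances.

    The counts back the frame score: ``counts[t]`` is the number of frames
    in the inventory whose leading tags equal the tuple ``t``.
    """
    counts: Counter = Counter()
    for instance in instances:
        for frame in extract_context_frames(instance, n):
            for j in range(1, len(frame.tags) + 1):
                counts[frame.tags[:j]] += 1
    return counts


def score_frame(frame: ContextFrame, counts: Counter,
                fringe: float = 1e-8) -> FrameScore:
    """Score one context frame against the corpus prefix counts.

    For anchor offset m with 0 < m <= n the score is the product of two
    count ratios ``(c(x0..xm)/c(x0..x_{m-1})) * (c(x0..xn)/c(x0..xm))``;
    for m = 0 the frame is conditioned on itself and scores ``1 + fringe``.
    """
    tags = frame.tags
    full = counts.get(tags)
    if not full:
        raise ValueError(f"frame {tags} absent from the counts table; counts "
                         "must be built over the same instance set")
    m = frame.anchor_offset
    if m == 0:
        return FrameScore(full / full + fringe, frame)
    num1 = counts.get(tags[:m + 1])
    den1 = counts.get(tags[:m])
    if not num1 or not den1:
        raise ValueError(f"prefix of frame {tags} absent from the counts table")
    rho = (num1 / den1) * (full / num1)
    return FrameScore(rho, frame)


# ---------------------------------------------------------------------------
# Coefficients and the invariant
# ---------------------------------------------------------------------------

def consolidate_coefficients(scores_by_role: Dict[str, Sequence[FrameScore]],
                             instance_id: str) -> PolynomialRepr:
    """Club per-role cumulative frame scores into the conic coefficients.

    ``x`` couples Entity1 with Relation and ``y`` couples Entity2 with
    Relation; when the Relation group is absent (negative instances) the
    entity score passes through unchanged.  The cross coefficient is the
    product of the two paired scores.
    """
    for role in (ENTITY1, ENTITY2):
        if role not in scores_by_role or not scores_by_role[role]:
            raise ValueError(f"no frames for mandatory role {role}")
    cumulative = {role: sum(s.rho for s in scores)
                  for role, scores in scores_by_role.items() if scores}
    rel = cumulative.get(RELATION)
    alpha_x = cumulative[ENTITY1] * rel if rel is not None else cumulative[ENTITY1]
    alpha_y = cumulative[ENTITY2] * rel if rel is not None else cumulative[ENTITY2]
    return PolynomialRepr(p20=alpha_x, p11=alpha_x * alpha_y, p02=alpha_y,
                          instance_id=instance_id)


def invariant_score(poly: PolynomialRepr, e_c: int = 0) -> InvariantScore:
    """Rotation invariant of the conic: ``p20^2 + p11^2/2 + p02^2``."""
    value = poly.p20 ** 2 + poly.p11 ** 2 / 2.0 + poly.p02 ** 2
    return InvariantScore(value=value, e_c=e_c, instance_id=poly.instance_id)


def best_instance_representation(instance: CandidateInstance, counts: Counter,
                                 config: InvarianceConfig) -> InstanceRepresentation:
    """Evaluate all n+1 window offsets and keep the representation with the
    highest invariant score (ties resolved toward the smallest e_c)."""
    frames = extract_context_frames(instance, config.n)
    by_ec: Dict[int, Dict[str, ContextFrame]] = {}
    for frame in frames:
        by_ec.setdefault(frame.e_c, {})[frame.rfg_role] = frame
    best: Optional[InstanceRepresentation] = None
    for e_c in sorted(by_ec):
        role_frames = by_ec[e_c]
        scores = {role: [score_frame(f, counts, config.fringe)]
                  for role, f in role_frames.items()}
        poly = consolidate_coefficients(scores, instance.instance_id)
        inv = invariant_score(poly, e_c)
        if best is None or inv.value > best.score.value:
            best = InstanceRepresentation(poly, inv, role_frames)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_by_invariance(scored: Sequence[Tuple[str, float]],
                          config: InvarianceConfig,
                          class_label: str = "") -> List[InstanceCluster]:
    """Chain instances, sorted by descending invariant score, into clusters
    of unit invariance ratio.

    An instance joins the open cluster iff the ratio of the cluster
    representative's score to its own lies within ``ratio_tolerance`` of
    ``delta ** weight`` (= 1 for the preset no-rotation transformation);
    otherwise it opens a new cluster.
    """
    for iid, value in scored:
        if not (value > 0):
            raise ValueError(f"non-positive invariant score for {iid}")
    target = config.delta ** config.weight
    ordered = sorted(scored, key=lambda t: (-t[1], t[0]))
    clusters: List[InstanceCluster] = []
    for iid, value in ordered:
        if clusters:
            ratio = clusters[-1].representative / value
            if abs(ratio - target) <= config.ratio_tolerance:
                clusters[-1].members.append(iid)
                continue
        clusters.append(InstanceCluster([iid], value, class_label))
    return clusters


# ---------------------------------------------------------------------------
# Alignment and pattern consolidation
# ---------------------------------------------------------------------------

def align_pair(a: Sequence[str], b: Sequence[str],
               config: AlignmentConfig = AlignmentConfig()
               ) -> Tuple[float, Tuple[Tuple[str, ...], Tuple[str, ...]]]:
    """Global alignment by the three-way recurrence (match +2, mismatch -2,
    gap -2).  Traceback ties prefer diagonal, then up (gap in ``b``), then
    left (gap in ``a``).  Returns the optimal score and one alignment."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    la, lb = len(a), len(b)
    score = [[0.0] * (lb + 1) for _ in range(la + 1)]
    move = [[""] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        score[i][0] = i * config.gap
        move[i][0] = "U"
    for j in range(1, lb + 1):
        score[0][j] = j * config.gap
        move[0][j] = "L"
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = config.match if a[i - 1] == b[j - 1] else config.mismatch
            diag = score[i - 1][j - 1] + sub
            up = score[i - 1][j] + config.gap
            left = score[i][j - 1] + config.gap
            best = max(diag, up, left)
            score[i][j] = best
            move[i][j] = "D" if diag == best else ("U" if up == best else "L")
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        m = move[i][j]
        if m == "D":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif m == "U":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return score[la][lb], (tuple(reversed(out_a)), tuple(reversed(out_b)))


def _consensus(rows: List[Tuple[str, ...]]) -> Tuple[str, ...]:
    """Column-majority consensus; labels win ties over gaps, label ties go
    to the earliest-processed row; gap-majority columns are dropped."""
    out = []
    for col in zip(*rows):
        tally = Counter(col)
        labels = {k: v for k, v in tally.items() if k != GAP}
        if not labels:
            continue
        best_count = max(labels.values())
        if tally.get(GAP, 0) > best_count:
            continue
        winner = next(s for s in col if s != GAP and labels[s] == best_count)
        out.append(winner)
    return tuple(out)


def _column_guide(rows: List[List[str]]) -> Tuple[str, ...]:
    """Full-width guide: the first non-gap symbol of every column."""
    return tuple(next((s for s in col if s != GAP), GAP) for col in zip(*rows))


def _progressive_align(sequences: List[Tuple[str, ...]],
                       config: AlignmentConfig) -> Tuple[str, ...]:
    rows: List[List[str]] = [list(sequences[0])]
    for seq in sequences[1:]:
        guide = _column_guide(rows)
        _, (ag, anew) = align_pair(guide, seq, config)
        # re-expand gaps introduced into the guide across all stored rows
        expanded: List[List[str]] = [[] for _ in rows]
        gi = 0
        for sym in ag:
            if sym == GAP:
                for row in expanded:
                    row.append(GAP)
            else:
                for ri, row in enumerate(expanded):
                    row.append(rows[ri][gi])
                gi += 1
        rows = expanded
        rows.append(list(anew))
    return _consensus([tuple(r) for r in rows])


def consolidate_pattern(cluster: InstanceCluster,
                        representations: Dict[str, InstanceRepresentation],
                        config: AlignmentConfig = AlignmentConfig()
                        ) -> LinguisticPattern:
    """Consolidate one invariance cluster into a triple-context pattern by
    progressive alignment (most frequent frame first) and column-majority
    consensus."""
    if not cluster.members:
        raise ValueError("cannot consolidate an empty cluster")
    contexts: Dict[str, Tuple[str, ...]] = {}
    for role in ROLES:
        member_frames = [(iid, representations[iid].frames[role].tags)
                         for iid in cluster.members
                         if role in representations[iid].frames]
        if not member_frames:
            contexts[role] = ()
            continue
        freq = Counter(tags for _, tags in member_frames)
        ordered = sorted(member_frames, key=lambda t: (-freq[t[1]], t[0]))
        contexts[role] = _progressive_align([tags for _, tags in ordered], config)
    return LinguisticPattern(
        class_label=cluster.class_label,
        entity1_context=contexts[ENTITY1],
        relation_context=contexts[RELATION],
        entity2_context=contexts[ENTITY2],
        support=len(cluster.members))


def learn_patterns(instances: Sequence[CandidateInstance],
                   config: InvarianceConfig = InvarianceConfig(),
                   align_config: AlignmentConfig = AlignmentConfig()
                   ) -> Dict[str, List[LinguisticPattern]]:
    """Full mining pass: frames -> scores -> invariants -> per-class
    clustering -> consensus patterns, keyed by relation class."""
    if not instances:
        return {}
    counts = build_frame_counts(instances, config.n)
    by_class: Dict[str, List[CandidateInstance]] = {}
    for inst in instances:
        by_class.setdefault(inst.relation_class, []).append(inst)

    patterns: Dict[str, List[LinguisticPattern]] = {}
    for cls in sorted(by_class):
        members = by_class[cls]
        if not members:
            logger.warning("class %s has no instances; skipped", cls)
            continue
        reps = {inst.instance_id: best_instance_representation(inst, counts, config)
                for inst in members}
        scored = [(iid, rep.score.value) for iid, rep in reps.items()]
        clusters = cluster_by_invariance(scored, config, cls)
        patterns[cls] = sorted(
            (consolidate_pattern(c, reps, align_config) for c in clusters),
            key=lambda p: (-p.support, p.entity1_context))
    return patterns


# ---------------------------------------------------------------------------
# Pattern serialization
# ---------------------------------------------------------------------------

def write_patterns(patterns: Dict[str, List[LinguisticPattern]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for cls in sorted(patterns):
            for p in patterns[cls]:
                fh.write("\t".join([
                    cls,
                    " ".join(p.entity1_context),
                    " ".join(p.relation_context),
                    " ".join(p.entity2_context),
                    str(p.support)]) + "\n")


def read_patterns(path) -> Dict[str, List[LinguisticPattern]]:
    patterns: Dict[str, List[LinguisticPattern]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            cls, e1, rel, e2, support = parts
            patterns.setdefault(cls, []).append(LinguisticPattern(
                class_label=cls,
                entity1_context=tuple(e1.split()) if e1 else (),
                relation_context=tuple(rel.split()) if rel else (),
                entity2_context=tuple(e2.split()) if e2 else (),
                support=int(support)))
    return patterns
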