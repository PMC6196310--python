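"""Part-of-speech tagging plug-in contract and a deterministic fallback tagger.

External taggers can be plugged in through :class:`TaggerInterface`; the
built-in :class:`RuleTagger` is a lexicon + suffix tagger over the Penn
Treebank tagset.  It is deliberately simple: deterministic, dependency-free
and accurate on the constrained vocabulary of the synthetic corpora.
"""

from __future__ import annotations

from typing import List, Protocol, Sequence

VERB_TAGS = frozenset({"VB", "VBD", "VBZ", "VBP", "VBN", "VBG"})
INFLECTED_VERB_TAGS = frozenset({"VBD", "VBZ", "VBP", "VBN", "VBG"})


class TaggerInterface(Protocol):
    def tag(self, tokens: Sequence[str]) -> List[str]:
        """Return PoS labels parallel to ``tokens``."""

    def lemmatize(self, tokens: Sequence[str]) -> List[str]:
        """Return lemmas parallel to ``tokens``."""


# closed-class lexicon
_CLOSED = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "IN", "of": "IN", "in": "IN", "on": "IN", "by": "IN",
    "with": "IN", "for": "IN", "to": "TO", "at": "IN", "from": "IN",
    "via": "IN", "through": "IN", "within": "IN", "near": "IN",
    "and": "CC", "or": "CC", "but": "CC",
    "not": "RB", "also": "RB", "is": "VBZ", "are": "VBP", "was": "VBD",
    "were": "VBD", "be": "VB", "been": "VBN", "it": "PRP", "its": "PRP$",
    "which": "WDT", "we": "PRP", ",": ",", ".": ".", ";": ":", ":": ":",
    "(": "-LRB-", ")": "-RRB-", "-": "HYPH", "%": "NN",
}

# verb lemmas known to the fallback tagger; inflections are derived
_VERB_LEMMAS = frozenset({
    "inhibit", "induce", "activate", "stimulate", "block", "bind", "reduce",
    "enhance", "suppress", "increase", "decrease", "regulate", "mediate",
    "modulate", "antagonize", "promote", "attenuate", "trigger", "cause",
    "phosphorylate", "upregulate", "downregulate", "target", "abolish",
    "potentiate", "elevate", "diminish", "show", "contain", "remain",
    "appear", "exist",
})

_IRREGULAR_LEMMAS = {
    "bound": "bind", "binds": "bind", "binding": "bind",
    "caused": "cause", "causes": "cause", "causing": "cause",
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
}


def _verb_lemma(word: str) -> str:
    """Map an inflected verb form to its lemma, or return '' if unknown."""
    low = word.lower()
    if low in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[low]
    if low in _VERB_LEMMAS:
        return low
    for suffix, restore in (("ies", "y"), ("ing", ""), ("ing", "e"),
                            ("ed", ""), ("ed", "e"), ("es", ""), ("s", "")):
        if low.endswith(suffix):
            stem = low[: len(low) - len(suffix)] + restore
            if stem in _VERB_LEMMAS:
                return stem
    return ""


class RuleTagger:
    """Deterministic Penn-Treebank tagger: closed-class lexicon, verb
    inflection analysis, then orthographic suffix rules, default NN."""

    def tag(self, tokens: Sequence[str]) -> List[str]:
        return [self._tag_one(t) for t in tokens]

    @staticmethod
    def _tag_one(word: str) -> str:
        low = word.lower()
        if low in _CLOSED:
            return _CLOSED[low]
        lemma = _verb_lemma(word)
        if lemma:
            if low == lemma:
                return "VB"
            if low.endswith("ing"):
                return "VBG"
            if low.endswith("ed") or low in ("bound",):
                return "VBD"
            return "VBZ"
        if word[:1].isdigit():
            return "CD"
        if low.endswith("ly"):
            return "RB"
        if low.endswith(("ive", "ous", "ent", "ant", "able", "ic", "al")):
            return "JJ"
        if low.endswith("s") and len(low) > 3:
            return "NNS"
        return "NN"

    def lemmatize(self, tokens: Sequence[str]) -> List[str]:
        out = []
        for word in tokens:
            low = word.lower()
            lemma = _verb_lemma(word)
            if lemma:
                out.append(lemma)
            elif low.endswith("s") and len(low) > 3 and low not in _CLOSED:
                out.append(low[:-1])
            else:
                out.append(low)
        return out
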