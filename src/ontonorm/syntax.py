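"""Constituency parses, head-word extraction and possessive-PP stripping.

The most informative word of an entity mention is taken to be the head of
its noun phrase: the top-level rightmost noun of the constituency parse.
Parses are supplied pre-computed in Penn Treebank bracketed notation (e.g.
from an off-the-shelf parser); when no parse is available a degenerate
flat-NP tree is synthesized so the head falls back to the last token.

Possessive prepositional phrases ("throats of two healthy children") carry
their information entirely in the left noun phrase; :func:`strip_possessive_pp`
drops the "of ..." remainder when the parse has the NP-PP(of)-NP shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ParseNode",
    "HeadResult",
    "ParseError",
    "parse_bracketed",
    "serialize",
    "find_head",
    "strip_possessive_pp",
    "synthesize_parse",
]

NOUN_TAGS = frozenset({"NN", "NNS", "NNP", "NNPS"})

# tags whose nodes are ignored when matching the NP-PP-NP shape
_PUNCT_LABELS = frozenset({",", ".", ":", "``", "''", "-LRB-", "-RRB-"})


class ParseError(ValueError):
    """Malformed bracketed parse string."""


@dataclass
class ParseNode:
    """A node of a constituency parse: internal nodes carry a phrase or POS
    label and children; leaves carry a token."""

    label: str
    children: list["ParseNode"] = field(default_factory=list)
    token: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.token]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def last_leaf(self) -> str:
        node = self
        while not node.is_leaf:
            node = node.children[-1]
        return node.token


@dataclass
class HeadResult:
    """The head token of a phrase and how it was found."""

    token: str
    source: str  # "parse" | "fallback_last_token"


def _tokenize(s: str) -> list[str]:
    out: list[str] = []
    buf: list[str] = []
    for ch in s:
        if ch in "()":
            if buf:
                out.append("".join(buf))
                buf.clear()
            out.append(ch)
        elif ch.isspace():
            if buf:
                out.append("".join(buf))
                buf.clear()
        else:
            buf.append(ch)
    if buf:
        out.append("".join(buf))
    return out


def parse_bracketed(s: str) -> ParseNode:
    """Parse a Penn Treebank bracketed string into a :class:`ParseNode`.

    Whitespace-insensitive.  An outer wrapper with an empty label (the
    ``( (NP ...) )`` ROOT dialect) is stripped.  Raises :class:`ParseError`
    on unbalanced parentheses or empty nodes.
    """
    tokens = _tokenize(s)
    if not tokens:
        raise ParseError("empty parse string")
    pos = 0

    def parse_node() -> ParseNode:
        nonlocal pos
        if tokens[pos] != "(":
            raise ParseError(f"expected '(' at token {pos}: {tokens[pos]!r}")
        pos += 1
        if pos >= len(tokens):
            raise ParseError("unbalanced parentheses")
        label = ""
        if tokens[pos] not in "()":
            label = tokens[pos]
            pos += 1
        children: list[ParseNode] = []
        token = ""
        while pos < len(tokens) and tokens[pos] != ")":
            if tokens[pos] == "(":
                children.append(parse_node())
            else:
                token = tokens[pos]
                pos += 1
        if pos >= len(tokens):
            raise ParseError("unbalanced parentheses")
        pos += 1  # consume ')'
        if children and token:
            raise ParseError(f"node {label!r} mixes children and a token")
        if not children and not token:
            raise ParseError(f"empty node {label!r}")
        if not label and len(children) == 1:
            return children[0]  # strip anonymous ROOT wrapper
        if not label:
            raise ParseError("internal node without label")
        if token and not label:
            raise ParseError(f"leaf {token!r} without POS label")
        return ParseNode(label=label, children=children, token=token)

    node = parse_node()
    if pos != len(tokens):
        raise ParseError("trailing content after parse")
    return node


def serialize(node: ParseNode) -> str:
    """Inverse of :func:`parse_bracketed`."""
    if node.is_leaf:
        return f"({node.label} {node.token})"
    return "(" + node.label + " " + " ".join(serialize(c) for c in node.children) + ")"


def _descend_to_np(tree: ParseNode) -> ParseNode | None:
    """Descend through unary wrappers to the outermost NP, if any."""
    node = tree
    while True:
        if node.label == "NP":
            return node
        if len(node.children) == 1 and not node.is_leaf:
            node = node.children[0]
            continue
        return None


def find_head(tree: ParseNode) -> HeadResult:
    """Head word of a mention or concept-name parse.

    The top-level rightmost noun: descend through unary wrappers to the
    outermost NP and scan its immediate children right to left for a leaf
    tagged NN/NNS/NNP/NNPS; failing that, recurse into the rightmost NP
    child; failing that, take the NP's last token.  A tree with no NP at
    all yields its last token, flagged ``fallback_last_token``.
    """
    np_node = _descend_to_np(tree)
    if np_node is None:
        return HeadResult(token=tree.last_leaf(), source="fallback_last_token")
    node = np_node
    while True:
        for child in reversed(node.children):
            if child.is_leaf and child.label in NOUN_TAGS:
                return HeadResult(token=child.token, source="parse")
        np_children = [c for c in node.children if c.label == "NP"]
        if np_children:
            node = np_children[-1]
            continue
        return HeadResult(token=node.last_leaf(), source="fallback_last_token")


def strip_possessive_pp(tree: ParseNode) -> list[str]:
    """Drop the "of ..." remainder of a possessive prepositional phrase.

    When the outermost NP (through unary wrappers) has the shape
    ``NP -> [NP, PP(IN='of', ...)]`` (punctuation ignored), only the left
    NP's tokens are informative and are returned; any other shape returns
    all leaf tokens unchanged.  Never returns an empty list; idempotent.
    """
    np_node = _descend_to_np(tree)
    if np_node is None:
        return tree.leaves()
    content = [c for c in np_node.children if c.label not in _PUNCT_LABELS]
    if (
        len(content) == 2
        and content[0].label == "NP"
        and content[1].label == "PP"
        and _pp_is_of(content[1])
    ):
        left = content[0].leaves()
        if left:
            return left
    return tree.leaves()


def _pp_is_of(pp: ParseNode) -> bool:
    for child in pp.children:
        if child.is_leaf and child.label == "IN":
            return child.token.lower() == "of"
    return False


def synthesize_parse(tokens: Sequence[str]) -> ParseNode:
    """Degenerate flat NP over the tokens (every leaf tagged NN).

    Used when no external parse is available; :func:`find_head` then
    returns the last token, keeping the pipeline total.
    """
    if not tokens:
        raise ValueError("cannot synthesize a parse over zero tokens")
    return ParseNode(
        label="NP",
        children=[ParseNode(label="NN", token=t) for t in tokens],
    )
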