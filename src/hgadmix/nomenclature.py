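"""Hierarchical haplogroup label handling.

Mitochondrial haplogroup names (``H``, ``H1``, ``H13a``, ``K1a1b1a``) encode a
position in the mtDNA phylogeny as an alternating sequence of letter and digit
runs.  This module decomposes such labels into tokens, measures their
phylogenetic depth (the number of tokens), truncates them, and assigns an
observed label to a fixed common basis of haplogroups by either of two rules:

``cumulating``
    a deep subclade is attributed to its nearest ancestor present in the
    basis, i.e. the longest *token-level* prefix (``A2a1`` falls under ``A``
    when only ``A`` is in the basis; ``H13a`` never falls under ``H1``
    because the token ``13`` is not the token ``1``).
``cutting``
    only labels literally present in the basis survive; everything deeper is
    discarded.

Assignment failures are reported with the explicit :data:`UNASSIGNED`
sentinel; deciding what to do with unassigned individuals (drop, renormalize)
belongs to the frequency layer, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Union

__all__ = [
    "MalformedLabelError",
    "HgLabel",
    "HgBasis",
    "UNASSIGNED",
    "tokenize_label",
    "label_depth",
    "truncate_label",
    "assign_to_basis",
]


class MalformedLabelError(ValueError):
    """Raised when a string cannot be parsed as a haplogroup label."""


@dataclass(frozen=True)
class HgLabel:
    """A haplogroup label decomposed into alternating letter/digit tokens.

    The first token is the maximal leading alphabetic run (so ``HV`` and
    ``JT`` are single depth-1 tokens); subsequent tokens alternate between
    maximal digit runs and maximal alphabetic runs.  Case is canonical: the
    leading run is upper-cased, later alphabetic runs lower-cased.
    """

    tokens: tuple[str, ...]

    @property
    def raw(self) -> str:
        return "".join(self.tokens)

    @property
    def depth(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return self.raw

    def is_token_prefix_of(self, other: "HgLabel") -> bool:
        """True if this label's tokens are a prefix of ``other``'s tokens."""
        return self.tokens == other.tokens[: len(self.tokens)]

    def sort_key(self) -> tuple:
        # digit tokens compare numerically so H2 sorts before H13
        return tuple(int(t) if t.isdigit() else t for t in self.tokens)


class _UnassignedType:
    """Sentinel for a label with no match in the basis."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNASSIGNED"

    def __bool__(self) -> bool:
        return False


UNASSIGNED = _UnassignedType()


def tokenize_label(raw: str) -> HgLabel:
    """Parse ``raw`` into an :class:`HgLabel`.

    Parameters
    ----------
    raw
        Non-empty label starting with a letter and containing only ASCII
        letters and digits.

    Raises
    ------
    MalformedLabelError
        If the string is empty, starts with a digit, or contains a character
        that is neither a letter nor a digit.
    """
    if not isinstance(raw, str) or raw == "":
        raise MalformedLabelError(f"empty or non-string haplogroup label: {raw!r}")
    if not raw[0].isalpha() or not raw[0].isascii():
        raise MalformedLabelError(
            f"haplogroup label must start with a letter: {raw!r}"
        )
    tokens: list[str] = []
    current = raw[0]
    current_is_alpha = True
    for ch in raw[1:]:
        if ch.isascii() and ch.isalpha():
            ch_alpha = True
        elif ch.isascii() and ch.isdigit():
            ch_alpha = False
        else:
            raise MalformedLabelError(
                f"illegal character {ch!r} in haplogroup label {raw!r}"
            )
        if ch_alpha == current_is_alpha:
            current += ch
        else:
            tokens.append(current)
            current = ch
            current_is_alpha = ch_alpha
    tokens.append(current)
    # canonical case: leading run upper, later alphabetic runs lower
    canon = [tokens[0].upper()] + [
        t.lower() if t[0].isalpha() else t for t in tokens[1:]
    ]
    return HgLabel(tuple(canon))


def label_depth(raw: str) -> int:
    """Phylogenetic depth of a label: its token count (``HV0a`` -> 3)."""
    return tokenize_label(raw).depth


def _as_label(label: Union[str, HgLabel]) -> HgLabel:
    return label if isinstance(label, HgLabel) else tokenize_label(label)


def truncate_label(label: Union[str, HgLabel], max_depth: int) -> HgLabel:
    """Keep at most the first ``max_depth`` tokens of ``label``.

    Idempotent; a label already at or below ``max_depth`` is returned
    unchanged.
    """
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    lab = _as_label(label)
    if lab.depth <= max_depth:
        return lab
    return HgLabel(lab.tokens[:max_depth])


class HgBasis:
    """An ordered, duplicate-free set of haplogroup labels.

    The order is significant: it defines the coordinate axes of every
    frequency vector built over the basis.
    """

    def __init__(self, labels: Iterable[Union[str, HgLabel]]):
        parsed = [_as_label(x) for x in labels]
        seen: dict[tuple[str, ...], int] = {}
        for lab in parsed:
            if lab.tokens in seen:
                raise ValueError(f"duplicate label in basis: {lab.raw}")
            seen[lab.tokens] = len(seen)
        self._labels: tuple[HgLabel, ...] = tuple(parsed)
        self._index: dict[tuple[str, ...], int] = seen

    @classmethod
    def sorted_from(cls, labels: Iterable[Union[str, HgLabel]]) -> "HgBasis":
        """Build a basis in canonical sorted order (deduplicated)."""
        parsed = {_as_label(x).tokens: _as_label(x) for x in labels}
        return cls(sorted(parsed.values(), key=HgLabel.sort_key))

    @property
    def labels(self) -> tuple[HgLabel, ...]:
        return self._labels

    @property
    def raw_labels(self) -> list[str]:
        return [lab.raw for lab in self._labels]

    def index_of(self, label: Union[str, HgLabel]) -> int:
        return self._index[_as_label(label).tokens]

    def __contains__(self, label: object) -> bool:
        if isinstance(label, (str, HgLabel)):
            return _as_label(label).tokens in self._index
        return False

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[HgLabel]:
        return iter(self._labels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HgBasis) and self._labels == other._labels

    def __repr__(self) -> str:
        preview = ", ".join(self.raw_labels[:6])
        more = "..." if len(self) > 6 else ""
        return f"HgBasis({len(self)} labels: {preview}{more})"


def assign_to_basis(
    label: Union[str, HgLabel],
    basis: HgBasis,
    mode: str = "cumulating",
) -> Union[HgLabel, _UnassignedType]:
    """Assign an observed label to a basis member, or :data:`UNASSIGNED`.

    ``cumulating`` returns the basis label that is the longest token-level
    prefix of the query; ``cutting`` returns the query itself only when it is
    literally a basis member.
    """
    if len(basis) == 0:
        raise ValueError("basis is empty")
    lab = _as_label(label)
    if mode == "cutting":
        if lab.tokens in basis._index:
            return basis.labels[basis._index[lab.tokens]]
        return UNASSIGNED
    if mode != "cumulating":
        raise ValueError(f"unknown assignment mode: {mode!r}")
    for k in range(lab.depth, 0, -1):
        prefix = lab.tokens[:k]
        if prefix in basis._index:
            return basis.labels[basis._index[prefix]]
    return UNASSIGNED
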