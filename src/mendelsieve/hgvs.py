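"""A small HGVS cDNA (c.) name parser.

Supports the subset of the nomenclature that annotated panel variant tables
actually use: substitutions, deletions, duplications, deletion-insertions and
insertions, at single positions or underscore ranges, with optional signed
intronic offsets (``c.4773+1G>T``, ``c.161-2A>G``).  Positions are
transcript-relative and are never converted to genomic coordinates.

``parse_hgvs_c`` / ``format_hgvs_c`` round-trip exactly for every supported
name.  Anything outside the grammar raises :class:`HgvsParseError` naming the
offending token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["CdnaChange", "HgvsParseError", "parse_hgvs_c", "format_hgvs_c", "is_canonical_splice"]

CHANGE_KINDS = frozenset({"substitution", "deletion", "duplication", "delins", "indel_range"})

_POSITION = r"(?P<{p}pos>\d+)(?P<{p}off>[+-]\d+)?"
_SEQ = r"[ACGTN]*"

_SUBSTITUTION_RE = re.compile(
    rf"^{_POSITION.format(p='')}(?P<ref>[ACGTN])>(?P<alt>[ACGTN])$"
)
_INDEL_RE = re.compile(
    rf"^{_POSITION.format(p='')}(?:_{_POSITION.format(p='end')})?"
    rf"(?P<op>delins|del|dup|ins)(?P<seq>{_SEQ})$"
)

_OP_TO_KIND = {
    "del": "deletion",
    "dup": "duplication",
    "delins": "delins",
    "ins": "indel_range",
}
_KIND_TO_OP = {v: k for k, v in _OP_TO_KIND.items()}


class HgvsParseError(ValueError):
    """The name is outside the supported cDNA grammar."""


@dataclass(frozen=True)
class CdnaChange:
    """Structured form of a supported HGVS c. name.

    ``coding_position`` / ``intron_offset`` describe the (start of the)
    change; ``intron_offset`` is 0 for exonic positions and carries the sign
    of the ``+``/``-`` suffix otherwise.  Range changes also carry
    ``end_position`` / ``end_offset``; ``ref``/``alt`` hold whatever explicit
    sequence the name spells out (possibly empty for e.g. ``c.101_106del``).
    """

    coding_position: int
    intron_offset: int = 0
    change_kind: str = "substitution"
    end_position: int | None = None
    end_offset: int = 0
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.change_kind not in CHANGE_KINDS:
            raise ValueError(f"unknown change kind {self.change_kind!r}")
        if self.coding_position < 1:
            raise ValueError("coding_position must be >= 1")

    @property
    def exonic(self) -> bool:
        return self.intron_offset == 0 and self.end_offset == 0


def _fmt_pos(pos: int, offset: int) -> str:
    if offset == 0:
        return str(pos)
    return f"{pos}{offset:+d}"


def format_hgvs_c(change: CdnaChange) -> str:
    """Inverse of :func:`parse_hgvs_c` for supported names."""
    start = _fmt_pos(change.coding_position, change.intron_offset)
    if change.change_kind == "substitution":
        return f"c.{start}{change.ref}>{change.alt}"
    span = start
    if change.end_position is not None:
        span += "_" + _fmt_pos(change.end_position, change.end_offset)
    op = _KIND_TO_OP[change.change_kind]
    seq = change.alt if change.change_kind in ("delins", "indel_range") else change.ref
    return f"c.{span}{op}{seq}"


def parse_hgvs_c(name: str) -> CdnaChange:
    """Parse a supported HGVS c. name into a :class:`CdnaChange`.

    >>> parse_hgvs_c("c.4773+1G>T")
    CdnaChange(coding_position=4773, intron_offset=1, ...)
    """
    if not isinstance(name, str) or not name.startswith("c."):
        raise HgvsParseError(f"not a cDNA name (missing 'c.' prefix): {name!r}")
    body = name[2:]

    m = _SUBSTITUTION_RE.match(body)
    if m:
        return CdnaChange(
            coding_position=int(m.group("pos")),
            intron_offset=int(m.group("off") or 0),
            change_kind="substitution",
            ref=m.group("ref"),
            alt=m.group("alt"),
        )

    m = _INDEL_RE.match(body)
    if m:
        kind = _OP_TO_KIND[m.group("op")]
        seq = m.group("seq")
        if kind == "indel_range" and not seq:
            raise HgvsParseError(f"insertion without inserted sequence: {name!r}")
        end_pos = m.group("endpos")
        return CdnaChange(
            coding_position=int(m.group("pos")),
            intron_offset=int(m.group("off") or 0),
            change_kind=kind,
            end_position=int(end_pos) if end_pos else None,
            end_offset=int(m.group("endoff") or 0),
            ref="" if kind in ("delins", "indel_range") else seq,
            alt=seq if kind in ("delins", "indel_range") else "",
        )

    token = body.split("_")[0] if body else name
    raise HgvsParseError(f"unsupported cDNA grammar near {token!r} in {name!r}")


def is_canonical_splice(change: CdnaChange) -> bool:
    """True iff the change touches the invariant splice dinucleotides.

    Donor sites are the first two intronic bases (+1/+2), acceptor sites the
    last two (-1/-2); a change at any of these offsets abolishes splicing.
    """
    return any(1 <= abs(off) <= 2 for off in (change.intron_offset, change.end_offset))
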