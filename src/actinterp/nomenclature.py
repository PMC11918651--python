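"""Lightweight HGVS parsing for cDNA and protein change strings.

Covers the subset of HGVS nomenclature that actually occurs in actin
variant databases — substitutions, deletions, duplications, insertions,
frameshifts, stop-loss/start-loss, synonymous changes — plus the
one-letter legacy labels (``R256H``) used by older publications, which
are numbered on the mature protein and must be shifted by +2 to HGVS.
A full HGVS implementation is deliberately out of scope: variant strings
are normalized to one canonical spelling so that records from different
sources collate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

from .gene_model import (
    CdnaPosition,
    GeneModelError,
    legacy_to_hgvs,
    parse_cdna_position,
)

__all__ = [
    "CdnaChange",
    "ProteinChange",
    "HgvsParseError",
    "parse_cdna_change",
    "parse_protein_change",
    "CONSEQUENCE_KINDS",
]

CONSEQUENCE_KINDS = (
    "missense",
    "nonsense",
    "frameshift",
    "stop_loss",
    "start_loss",
    "inframe_del",
    "inframe_dup",
    "synonymous",
    "splice_donor",
    "splice_acceptor",
    "splice_region",
    "intronic",
    "UTR5",
    "UTR3",
)

_1TO3 = {k.upper(): v for k, v in protein_letters_1to3.items()}
_1TO3["*"] = "Ter"
_1TO3["X"] = "Ter"
_3TO1 = {v: k for k, v in protein_letters_1to3.items()}
_3TO1["Ter"] = "*"


class HgvsParseError(ValueError):
    """Raised when a variant string cannot be interpreted."""


def _aa3(token: str) -> str:
    """Normalize an amino-acid token to its three-letter code."""
    if token in ("*", "X"):
        return "Ter"
    t = token.capitalize()
    if t in _3TO1:
        return t
    if len(token) == 1 and token.upper() in _1TO3:
        return _1TO3[token.upper()]
    raise HgvsParseError(f"unknown amino-acid code {token!r}")


@dataclass(frozen=True)
class CdnaChange:
    """A parsed HGVS ``c.`` description."""

    start: CdnaPosition
    end: CdnaPosition | None  # for ranged changes (del/dup/ins)
    op: str  # sub | del | dup | ins | delins
    ref: str = ""
    alt: str = ""

    def __str__(self) -> str:
        s = str(self.start)[2:]
        span = s if self.end is None else f"{s}_{str(self.end)[2:]}"
        if self.op == "sub":
            return f"c.{span}{self.ref}>{self.alt}"
        if self.op in ("del", "dup"):
            return f"c.{span}{self.op}{self.ref}"
        if self.op == "ins":
            return f"c.{span}ins{self.alt}"
        return f"c.{span}delins{self.alt}"

    @property
    def is_snv(self) -> bool:
        return self.op == "sub" and len(self.ref) == 1 and len(self.alt) == 1

    @property
    def intronic(self) -> bool:
        return self.start.offset != 0 or (self.end is not None and self.end.offset != 0)


@dataclass(frozen=True)
class ProteinChange:
    """A parsed protein-level change in HGVS (Met1-anchored) numbering."""

    ref_aa: str  # three-letter code
    hgvs_residue: int
    alt_aa: str  # three-letter code, "=" for synonymous, "" for del
    kind: str
    end_ref_aa: str = ""
    end_residue: int = 0
    fs_ter: int = 0  # frameshift: new stop offset, 0 if unknown

    def __str__(self) -> str:
        pos = f"{self.ref_aa}{self.hgvs_residue}"
        if self.kind == "synonymous":
            return f"p.{pos}="
        if self.kind == "frameshift":
            ter = f"Ter{self.fs_ter}" if self.fs_ter else ""
            return f"p.{pos}{self.alt_aa}fs{ter}"
        if self.kind in ("inframe_del", "inframe_dup"):
            op = "del" if self.kind == "inframe_del" else "dup"
            if self.end_residue:
                return f"p.{pos}_{self.end_ref_aa}{self.end_residue}{op}"
            return f"p.{pos}{op}"
        if self.kind == "start_loss":
            return f"p.{pos}?"
        if self.kind == "stop_loss":
            ext = f"extTer{self.fs_ter}" if self.fs_ter else "ext"
            return f"p.{pos}{self.alt_aa}{ext}"
        return f"p.{pos}{self.alt_aa}"

    @property
    def residue_key(self) -> int:
        return self.hgvs_residue


_PC_PATTERNS: list[tuple[re.Pattern, str]] = [
    # p.Gly344AlafsTer77 / p.Gly344fs / G344fs*77
    (
        re.compile(
            r"^(?P<ref>[A-Za-z\*]{1,3})(?P<pos>\d+)(?P<alt>[A-Za-z]{1,3})?"
            r"fs(?:(?:Ter|\*)(?P<ter>\d+)?)?$"
        ),
        "frameshift",
    ),
    # p.Ala146_Ser147dup / p.Phe92del / p.Phe92_Gly94del
    (
        re.compile(
            r"^(?P<ref>[A-Za-z]{1,3})(?P<pos>\d+)"
            r"(?:_(?P<ref2>[A-Za-z]{1,3})(?P<pos2>\d+))?(?P<op>del|dup)$"
        ),
        "indel",
    ),
    # p.Met1? (start loss)
    (re.compile(r"^(?P<ref>[A-Za-z]{1,3})(?P<pos>\d+)\?$"), "start_loss"),
    # p.Lys70= (synonymous)
    (re.compile(r"^(?P<ref>[A-Za-z]{1,3})(?P<pos>\d+)=$"), "synonymous"),
    # p.Ter378GlnextTer47 (stop loss)
    (
        re.compile(
            r"^(?:Ter|\*)(?P<pos>\d+)(?P<alt>[A-Za-z]{1,3})?ext(?:Ter|\*)?(?P<ext>\d+)?$"
        ),
        "stop_loss",
    ),
    # p.Arg258His / R256H / p.Trp358Ter
    (
        re.compile(r"^(?P<ref>[A-Za-z]{1,3})(?P<pos>\d+)(?P<alt>[A-Za-z]{1,3}|\*)$"),
        "subst",
    ),
]

_LEGACY_TAG = re.compile(r"\s*\(\s*legacy\s*\)\s*$", re.IGNORECASE)


def parse_protein_change(text: str, legacy: bool | None = None) -> ProteinChange:
    """Parse a protein change string, normalizing to HGVS numbering.

    A trailing ``(legacy)`` tag, or ``legacy=True``, marks mature-protein
    numbering; the residue number is then shifted by +2.  Numbering
    schemes are never inferred from the amino acids themselves.
    """
    s = text.strip()
    if _LEGACY_TAG.search(s):
        s = _LEGACY_TAG.sub("", s)
        legacy = True
    s = re.sub(r"^p\.", "", s).strip("()")

    for pattern, tag in _PC_PATTERNS:
        m = pattern.match(s)
        if not m:
            continue
        pos = int(m.group("pos"))
        if legacy:
            pos = legacy_to_hgvs(pos)
        if tag == "stop_loss":
            alt = _aa3(m.group("alt")) if m.group("alt") else ""
            ext = int(m.group("ext") or 0)
            return ProteinChange("Ter", pos, alt, "stop_loss", fs_ter=ext)
        ref = _aa3(m.group("ref"))
        if tag == "frameshift":
            alt = _aa3(m.group("alt")) if m.group("alt") else ""
            return ProteinChange(ref, pos, alt, "frameshift", fs_ter=int(m.group("ter") or 0))
        if tag == "indel":
            kind = "inframe_del" if m.group("op") == "del" else "inframe_dup"
            end_ref, end_pos = "", 0
            if m.group("ref2"):
                end_ref = _aa3(m.group("ref2"))
                end_pos = int(m.group("pos2"))
                if legacy:
                    end_pos = legacy_to_hgvs(end_pos)
            return ProteinChange(ref, pos, "", kind, end_ref_aa=end_ref, end_residue=end_pos)
        if tag == "start_loss":
            return ProteinChange(ref, pos, "?", "start_loss")
        if tag == "synonymous":
            return ProteinChange(ref, pos, "=", "synonymous")
        alt = _aa3(m.group("alt"))
        if ref == "Ter":
            return ProteinChange(ref, pos, alt, "stop_loss")
        kind = "nonsense" if alt == "Ter" else "missense"
        return ProteinChange(ref, pos, alt, kind)
    raise HgvsParseError(f"cannot parse protein change {text!r}")


_CC_RE = re.compile(
    r"^c\.(?P<p1>\d+(?:[+-]\d+)?)"
    r"(?:_(?P<p2>\d+(?:[+-]\d+)?))?"
    r"(?P<tail>.*)$"
)
_SUB_RE = re.compile(r"^(?P<ref>[ACGT]+)>(?P<alt>[ACGT]+)$")
_OP_RE = re.compile(r"^(?P<op>del|dup|ins|delins)(?P<seq>[ACGT]*)$")


def parse_cdna_change(text: str) -> CdnaChange:
    """Parse an HGVS ``c.`` change string (substitution, del, dup, ins)."""
    s = text.strip().replace(" ", "")
    m = _CC_RE.match(s)
    if not m or not m.group("tail"):
        raise HgvsParseError(f"cannot parse cDNA change {text!r}")
    try:
        start = parse_cdna_position(m.group("p1"))
        end = parse_cdna_position(m.group("p2")) if m.group("p2") else None
    except GeneModelError as exc:
        raise HgvsParseError(str(exc)) from exc
    tail = m.group("tail")
    sub = _SUB_RE.match(tail)
    if sub:
        if end is not None:
            raise HgvsParseError(f"ranged substitution not supported: {text!r}")
        return CdnaChange(start, None, "sub", sub.group("ref"), sub.group("alt"))
    op = _OP_RE.match(tail)
    if not op:
        raise HgvsParseError(f"cannot parse cDNA change {text!r}")
    kind = op.group("op")
    seq = op.group("seq")
    if kind in ("del", "dup"):
        return CdnaChange(start, end, kind, ref=seq)
    return CdnaChange(start, end, kind if kind == "delins" else "ins", alt=seq)
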