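"""ACTA1 transcript/protein architecture and coordinate arithmetic.

The skeletal-muscle alpha-actin gene has seven exons of which exons 2-7
are coding; the encoded protein is 377 residues long (initiator Met
included).  Two protein numbering schemes circulate in the literature:

* **HGVS numbering** counts from the initiator methionine (Met1 = 1).
* **Legacy (mature-protein) numbering** counts from the first residue of
  the mature protein, i.e. after post-translational cleavage of the
  first two residues, so it is offset by exactly -2 from HGVS.

This module converts between the two schemes, locates cDNA (HGVS ``c.``)
positions within the exon/intron architecture, decides whether a
premature termination codon escapes nonsense-mediated decay (NMD), and
computes the length of the C-terminal extension produced by stop-loss
variants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ExonModel",
    "CdnaPosition",
    "ProteinPosition",
    "GeneModelError",
    "LEGACY_OFFSET",
    "load_exon_model",
    "legacy_to_hgvs",
    "hgvs_to_legacy",
    "parse_cdna_position",
    "exon_of",
    "nmd_escape",
    "stop_loss_extension",
]

#: residues cleaved from the N-terminus of the nascent protein
LEGACY_OFFSET = 2

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GeneModelError(ValueError):
    """Raised for coordinates or sequences outside the gene model."""


@dataclass(frozen=True)
class CdnaPosition:
    """An HGVS ``c.`` coordinate: 1-based base, signed intronic offset.

    ``offset == 0`` means the position is exonic; ``c.455-2`` is
    ``CdnaPosition(455, -2)`` and ``c.616+4`` is ``CdnaPosition(616, 4)``.
    """

    base: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset == 0:
            return f"c.{self.base}"
        return f"c.{self.base}{self.offset:+d}"


@dataclass(frozen=True)
class ProteinPosition:
    """A protein residue under both numbering schemes."""

    hgvs_residue: int

    @property
    def legacy_residue(self) -> int:
        return hgvs_to_legacy(self.hgvs_residue)


class ExonModel:
    """Exon/intron lengths and derived coding-coordinate boundaries."""

    def __init__(self, config: dict):
        self.gene: str = config["gene"]
        self.protein_length: int = int(config["protein_length"])
        self.coding_length: int = int(config["coding_length"])
        self.coding_start_offset: int = int(config["coding_start_offset_in_exon2"])
        self.exon_lengths: dict[int, int] = {int(k): int(v) for k, v in config["exons"].items()}
        self.intron_lengths: dict[int, int] = {int(k): int(v) for k, v in config["introns"].items()}
        self.coding_nt: dict[int, int] = {int(k): int(v) for k, v in config["coding_nt"].items()}
        self.nmd_window: int = int(config.get("nmd_escape_window_nt", 50))

        if sum(self.coding_nt.values()) != self.coding_length:
            raise GeneModelError(
                f"coding nt per exon sum to {sum(self.coding_nt.values())}, "
                f"expected {self.coding_length}"
            )
        if self.coding_length != self.protein_length * 3 + 3:
            raise GeneModelError("coding length inconsistent with protein length")

        # c. span of each coding exon, derived cumulatively
        self.exon_spans: dict[int, tuple[int, int]] = {}
        start = 1
        for exon in sorted(self.coding_nt):
            end = start + self.coding_nt[exon] - 1
            self.exon_spans[exon] = (start, end)
            start = end + 1

    @property
    def coding_exons(self) -> list[int]:
        return sorted(self.exon_spans)

    def coded_aa(self, exon: int) -> float:
        """Amino acids encoded by *exon* (fractional at split codons; the
        stop codon in the last exon codes none)."""
        nt = self.coding_nt.get(exon, 0)
        if exon == self.last_exon:
            nt -= 3
        return nt / 3

    @property
    def last_exon(self) -> int:
        return max(self.exon_spans)

    @property
    def penultimate_exon(self) -> int:
        return sorted(self.exon_spans)[-2]

    def nmd_escape_start(self) -> int:
        """First c. base of the NMD-escape window (3' end of exon 6)."""
        _, end = self.exon_spans[self.penultimate_exon]
        return end - self.nmd_window + 1


def load_exon_model(path: str | Path | None = None) -> ExonModel:
    """Load the exon model from *path*, or the packaged ACTA1 config."""
    if path is None:
        text = (
            resources.files("actinterp.data")
            .joinpath("acta1_exon_model.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return ExonModel(yaml.safe_load(text))


_DEFAULT_MODEL: ExonModel | None = None


def default_model() -> ExonModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_exon_model()
    return _DEFAULT_MODEL


def legacy_to_hgvs(pos: int, protein_length: int = 377) -> int:
    """Convert a mature-protein (legacy) residue number to HGVS numbering.

    The mature protein lacks the first two cleaved residues, so HGVS
    residue = legacy residue + 2 (e.g. legacy Arg256 is HGVS Arg258).
    """
    if pos < 1 or pos + LEGACY_OFFSET > protein_length:
        raise GeneModelError(
            f"legacy residue {pos} outside the mature protein "
            f"(protein length {protein_length}, mature length "
            f"{protein_length - LEGACY_OFFSET})"
        )
    return pos + LEGACY_OFFSET


def hgvs_to_legacy(pos: int, protein_length: int = 377) -> int:
    """Inverse of :func:`legacy_to_hgvs`."""
    if pos <= LEGACY_OFFSET or pos > protein_length:
        raise GeneModelError(
            f"HGVS residue {pos} has no mature-protein equivalent "
            f"(protein length {protein_length}; residues 1-{LEGACY_OFFSET} are cleaved)"
        )
    return pos - LEGACY_OFFSET


_CPOS_RE = re.compile(r"^(?:c\.)?(\d+)([+-]\d+)?$")


def parse_cdna_position(text: str) -> CdnaPosition:
    """Parse ``c.455-2`` / ``617-5`` / ``c.1031`` into a :class:`CdnaPosition`."""
    m = _CPOS_RE.match(text.strip())
    if not m:
        raise GeneModelError(f"cannot parse cDNA position {text!r}")
    return CdnaPosition(int(m.group(1)), int(m.group(2) or 0))


def exon_of(pos: CdnaPosition | str, model: ExonModel | None = None) -> str:
    """Name the exon or intron containing *pos*.

    Exonic positions (offset 0) return ``"Exon2"`` .. ``"Exon7"``.
    Offset positions must anchor to an exon boundary: a negative offset on
    the first base of exon *k* or a positive offset on the last base of
    exon *k* both land in the intervening intron.
    """
    if isinstance(pos, str):
        pos = parse_cdna_position(pos)
    model = model or default_model()
    containing = None
    for exon, (start, end) in model.exon_spans.items():
        if start <= pos.base <= end:
            containing = exon
            break
    if containing is None:
        raise GeneModelError(
            f"c.{pos.base} is beyond the coding region (c.1-c.{model.coding_length}); "
            "no 3'UTR model is configured"
        )
    if pos.offset == 0:
        return f"Exon{containing}"
    start, end = model.exon_spans[containing]
    if pos.offset < 0:
        if pos.base != start:
            raise GeneModelError(
                f"{pos}: negative offsets are only valid at the first base of an exon"
            )
        return f"Intron{containing - 1}"
    if pos.base != end:
        raise GeneModelError(
            f"{pos}: positive offsets are only valid at the last base of an exon"
        )
    return f"Intron{containing}"


def nmd_escape(ptc_position: CdnaPosition | str, model: ExonModel | None = None) -> bool:
    """Whether a premature termination codon at *ptc_position* escapes NMD.

    Termination within the 3'-most ``nmd_window`` nucleotides of the
    penultimate exon (by default the last 50 nt of exon 6, c.941-990) or
    anywhere in the last exon evades nonsense-mediated decay, so the
    truncated protein is produced and can act dominantly.

    *ptc_position* is the first base of the premature stop codon.
    """
    if isinstance(ptc_position, str):
        ptc_position = parse_cdna_position(ptc_position)
    model = model or default_model()
    if ptc_position.offset != 0:
        raise GeneModelError(
            f"{ptc_position} is intronic; a termination codon must be exonic"
        )
    exon_of(ptc_position, model)  # range check
    return ptc_position.base >= model.nmd_escape_start()


def stop_loss_extension(utr3_sequence: str) -> int:
    """Count residues appended by a stop-loss variant.

    *utr3_sequence* must start at the first base after the reference stop
    codon.  Translation reads through the mutated stop and continues
    in-frame into the 3' UTR; the return value is the number of codons
    translated before the next in-frame stop codon.
    """
    seq = utr3_sequence.strip().upper()
    if not seq or set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise GeneModelError(f"3'UTR sequence contains non-ACGT characters: {bad}")
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOP_CODONS:
            return i // 3
    raise GeneModelError("no in-frame stop codon found in the supplied 3'UTR")
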