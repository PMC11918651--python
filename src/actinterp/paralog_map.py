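"""Cross-paralog residue mapping over the six human actins.

The human actin family (ACTA1, ACTC1, ACTA2, ACTG2, ACTB, ACTG1) is
extraordinarily conserved — no pair of isoforms is less than ~93%
identical — which makes pathogenicity evidence transferable between
homologous residues.  This module builds a deterministic multiple
alignment of the paralogs (star alignment of global pairwise alignments
anchored on the first sequence, BLOSUM62, affine gaps open 10 / extend
1), maps residue numbers between isoforms through alignment columns,
classifies column conservation with the Clustal strong/weak substitution
groups, and aggregates prior reports per column into the confidence
tiers used by the evidence rules: cardiac (ACTC1, the closest paralog to
ACTA1), smooth muscle (ACTA2/ACTG2), and cytoplasmic (ACTB/ACTG1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .knowledgebase import PriorReport

__all__ = [
    "IsoformAlignment",
    "ColumnEvidence",
    "TIER_OF",
    "TIERS",
    "align_isoforms",
    "read_fasta",
    "load_paralog_reports",
    "column_evidence",
]

GAP = "-"

#: confidence tier of each paralog when transferring evidence to ACTA1
TIER_OF = {
    "ACTC1": "cardiac",
    "ACTA2": "smooth",
    "ACTG2": "smooth",
    "ACTB": "cytoplasmic",
    "ACTG1": "cytoplasmic",
}
TIERS = ("cardiac", "smooth", "cytoplasmic")

# Clustal-style conservation groups
_STRONG_GROUPS = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"]
_WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
    "NDEQHK", "NEQHRK", "FVLIM", "HFY",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class AlignmentError(ValueError):
    pass


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


class IsoformAlignment:
    """Column-indexed multiple alignment with per-isoform residue maps."""

    def __init__(self, aligned: dict[str, str]):
        lengths = {len(s) for s in aligned.values()}
        if len(lengths) != 1:
            raise AlignmentError("aligned rows have differing lengths")
        self.aligned = dict(aligned)
        self.names = list(aligned)
        self.n_columns = lengths.pop()
        # residue number (1-based) per column, None at gaps
        self._col_to_res: dict[str, list[int | None]] = {}
        self._res_to_col: dict[str, dict[int, int]] = {}
        for name, row in self.aligned.items():
            col_map: list[int | None] = []
            res_map: dict[int, int] = {}
            res = 0
            for col, ch in enumerate(row):
                if ch == GAP:
                    col_map.append(None)
                else:
                    res += 1
                    col_map.append(res)
                    res_map[res] = col
            self._col_to_res[name] = col_map
            self._res_to_col[name] = res_map

    # ------------------------------------------------------------- accessors

    def sequence(self, name: str) -> str:
        return self.aligned[name].replace(GAP, "")

    def length(self, name: str) -> int:
        return len(self._res_to_col[name])

    def column_of(self, name: str, hgvs_residue: int) -> int:
        try:
            return self._res_to_col[name][hgvs_residue]
        except KeyError:
            raise AlignmentError(
                f"residue {hgvs_residue} outside {name} (length {self.length(name)})"
            ) from None

    def residue_at(self, name: str, column: int) -> int | None:
        return self._col_to_res[name][column]

    def map_residue(self, from_isoform: str, hgvs_residue: int, to_isoform: str) -> int | None:
        """Residue number of *to_isoform* in the column of *from_isoform*'s
        residue, or ``None`` when the target is gapped there."""
        col = self.column_of(from_isoform, hgvs_residue)
        return self.residue_at(to_isoform, col)

    # ---------------------------------------------------------- conservation

    def conservation(self, column: int) -> str:
        """Clustal-style class of a column: ``identical`` (*),
        ``conserved_substitution`` (:), ``semiconserved`` (.) or
        ``variable``."""
        residues = [row[column] for row in self.aligned.values()]
        if GAP in residues:
            return "variable"
        if len(set(residues)) == 1:
            return "identical"
        rset = set(residues)
        if any(rset <= set(g) for g in _STRONG_GROUPS):
            return "conserved_substitution"
        if any(rset <= set(g) for g in _WEAK_GROUPS):
            return "semiconserved"
        return "variable"

    def conservation_string(self) -> str:
        symbols = {"identical": "*", "conserved_substitution": ":", "semiconserved": ".", "variable": " "}
        return "".join(symbols[self.conservation(c)] for c in range(self.n_columns))

    # --------------------------------------------------------------- metrics

    def percent_identity(self, a: str, b: str) -> float:
        """100 x identical columns / gapless columns of the (a, b) pair."""
        row_a, row_b = self.aligned[a], self.aligned[b]
        total = same = 0
        for x, y in zip(row_a, row_b):
            if x == GAP or y == GAP:
                continue
            total += 1
            if x == y:
                same += 1
        if total == 0:
            raise AlignmentError(f"no gapless columns between {a} and {b}")
        return 100.0 * same / total

    def n_differences(self, a: str, b: str) -> int:
        """Mismatched gapless columns between two rows."""
        return sum(
            1
            for x, y in zip(self.aligned[a], self.aligned[b])
            if x != GAP and y != GAP and x != y
        )

    def to_json(self) -> str:
        return json.dumps(
            {"aligned": self.aligned, "conservation": self.conservation_string()},
            indent=1,
            sort_keys=True,
        )


def align_isoforms(sequences: dict[str, str]) -> IsoformAlignment:
    """Globally align 2-6 paralog protein sequences.

    The first sequence anchors a star alignment: every other sequence is
    aligned to it pairwise and the pairwise alignments are merged on the
    anchor's coordinates.  For sequences this similar the result matches
    a full progressive MSA, and it is deterministic for fixed inputs.
    """
    if len(sequences) < 2:
        raise AlignmentError("need at least two sequences to align")
    for name, seq in sequences.items():
        if not seq:
            raise AlignmentError(f"{name}: empty sequence")
        bad = set(seq.upper()) - _AA
        if bad:
            raise AlignmentError(f"{name}: non-amino-acid characters {sorted(bad)}")

    names = list(sequences)
    anchor_name = names[0]
    anchor = sequences[anchor_name].upper()
    aligner = _make_aligner()

    # pairwise alignments against the anchor, as (anchor_row, other_row)
    pairs: dict[str, tuple[str, str]] = {}
    for name in names[1:]:
        aln = aligner.align(anchor, sequences[name].upper())[0]
        pairs[name] = (str(aln[0]), str(aln[1]))

    # insertion slots: gaps in the anchor before anchor residue j+1
    n = len(anchor)
    ins = [0] * (n + 1)
    for a_row, _ in pairs.values():
        j = 0
        run = 0
        local = [0] * (n + 1)
        for ch in a_row:
            if ch == GAP:
                run += 1
            else:
                local[j] = run
                run = 0
                j += 1
        local[n] = run
        for k in range(n + 1):
            ins[k] = max(ins[k], local[k])

    def project(a_row: str, s_row: str) -> str:
        # rebuild s_row on the master coordinate frame
        out = []
        j = 0  # anchor residues consumed
        i = 0
        while j <= n:
            # consume the insertion block before anchor residue j+1
            block = []
            while i < len(a_row) and a_row[i] == GAP:
                block.append(s_row[i])
                i += 1
            block.extend(GAP * (ins[j] - len(block)))
            out.extend(block)
            if j == n:
                break
            out.append(s_row[i])
            i += 1
            j += 1
        return "".join(out)

    aligned: dict[str, str] = {}
    anchor_row = []
    for j in range(n):
        anchor_row.append(GAP * ins[j])
        anchor_row.append(anchor[j])
    anchor_row.append(GAP * ins[n])
    aligned[anchor_name] = "".join(anchor_row)
    for name in names[1:]:
        aligned[name] = project(*pairs[name])
    return IsoformAlignment(aligned)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by gene symbol (first token of the id)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.split("|")[0].split()[0]
        out[name] = str(rec.seq).upper()
    if not out:
        raise AlignmentError(f"no sequences found in {path}")
    return out


# --------------------------------------------------------------------- reports


def load_paralog_reports(path: str | Path) -> list[PriorReport]:
    """Read a paralog-report snapshot TSV: isoform, protein_change,
    classification (plus optional source)."""
    import pandas as pd

    from .nomenclature import parse_protein_change

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            PriorReport(
                source=row.get("source") or "literature",
                classification=row["classification"],
                isoform=row["isoform"],
                protein_change=parse_protein_change(row["protein_change"]),
            )
        )
    return out


@dataclass
class ColumnEvidence:
    """Prior-report evidence projected onto one alignment column."""

    isoform: str
    hgvs_residue: int
    column: int
    conservation: str
    same_change: dict[str, list[PriorReport]] = field(default_factory=dict)
    same_residue: dict[str, list[PriorReport]] = field(default_factory=dict)
    distinct_plp_changes: set[tuple[str, str, str]] = field(default_factory=set)
    benign_at_column: bool = False

    def tier_reports(self, which: str, tier: str) -> list[PriorReport]:
        table = self.same_change if which == "same_change" else self.same_residue
        return table.get(tier, [])


def column_evidence(
    isoform: str,
    hgvs_residue: int,
    all_paralog_reports: list[PriorReport],
    alignment: IsoformAlignment,
    alt_aa: str | None = None,
) -> ColumnEvidence:
    """Bucket paralog prior reports for the alignment column of
    ``isoform:hgvs_residue``.

    ``same_change`` holds P/LP reports in *other* isoforms whose
    homologous residue carries the same substitution (``alt_aa``);
    ``same_residue`` holds P/LP reports of any other change at the
    homologous residue.  Buckets are keyed by confidence tier.
    ``distinct_plp_changes`` collects the distinct P/LP substitutions at
    the column across *all* isoforms (the query isoform included), and
    ``benign_at_column`` flags any B/LB report there.
    """
    col = alignment.column_of(isoform, hgvs_residue)
    ev = ColumnEvidence(
        isoform=isoform,
        hgvs_residue=hgvs_residue,
        column=col,
        conservation=alignment.conservation(col),
        same_change={t: [] for t in TIERS},
        same_residue={t: [] for t in TIERS},
    )
    for rep in all_paralog_reports:
        pc = rep.protein_change
        if pc is None or pc.kind != "missense":
            continue
        if rep.isoform not in alignment.aligned:
            continue
        try:
            rep_col = alignment.column_of(rep.isoform, pc.hgvs_residue)
        except AlignmentError:
            continue
        if rep_col != col:
            continue
        if rep.is_benign:
            ev.benign_at_column = True
            continue
        if not rep.is_pathogenic:
            continue
        ev.distinct_plp_changes.add((pc.ref_aa, pc.alt_aa, ""))
        if rep.isoform == isoform:
            continue
        tier = TIER_OF.get(rep.isoform)
        if tier is None:  # querying from a non-ACTA1 isoform: treat by symbol
            tier = TIER_OF.get(rep.isoform, "cytoplasmic")
        if alt_aa is not None and pc.alt_aa == alt_aa:
            ev.same_change[tier].append(rep)
        else:
            ev.same_residue[tier].append(rep)
    return ev
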