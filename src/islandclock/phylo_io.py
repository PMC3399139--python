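"""Alignment, tree, and calibration-table I/O plus the sequence de-duplication
filter applied before dating.

Alignments are concatenated DNA supermatrices; gaps and ambiguity codes are
retained throughout (they enter the likelihood as partially missing data).
Trees are rooted binary newick.  Calibration tables are tab-separated with
columns ``taxonA  taxonB  island_name  island_age_Ma  prior_kind  param1
param2`` where ``prior_kind`` is ``none`` (island age only), ``normal``
(param1=mean, param2=sd) or ``hard_uniform`` (param1=lower, param2=upper).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .calibration import CalibrationEntry, CalibrationPrior, CalibrationTable
from .trees import RootedTimeTree, TreeStructureError

IUPAC_DNA = set("ACGTU-NRYSWKMBDHV?")

#: IUPAC symbol -> tuple of compatible bases (A,C,G,T); gaps/unknowns match all.
IUPAC_STATES: dict[str, tuple[int, ...]] = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,), "U": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}

_FORMATS = {"fasta": "fasta", "phylip-relaxed": "phylip-relaxed"}


class AlignmentFormatError(ValueError):
    """Malformed or empty alignment file."""


class AlignmentValidationError(ValueError):
    """Alignment violates the supermatrix invariants."""


@dataclass
class SequenceAlignment:
    """Concatenated supermatrix of homologous DNA sequences.

    ``sites`` is an (n_taxa, n_sites) array of single uppercase IUPAC
    characters; ``partition_bounds`` optionally records the half-open column
    interval of each concatenated locus.
    """

    taxon_ids: list[str]
    sites: np.ndarray
    partition_bounds: Optional[list[tuple[int, int]]] = None

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype="U1")
        if self.sites.ndim != 2:
            raise AlignmentValidationError("sites must be a 2-D matrix")
        if len(self.taxon_ids) != self.sites.shape[0]:
            raise AlignmentValidationError("one row per taxon required")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dupes = sorted({t for t in self.taxon_ids if self.taxon_ids.count(t) > 1})
            raise AlignmentValidationError(f"duplicate taxon ids: {dupes}")
        if self.n_taxa < 1:
            raise AlignmentValidationError("alignment needs at least one sequence")
        bad = set(np.unique(self.sites)) - IUPAC_DNA
        if bad:
            raise AlignmentValidationError(f"non-IUPAC symbols in alignment: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.sites.shape[0]

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.sites[self.taxon_ids.index(taxon)]

    def subset(self, keep: Sequence[int]) -> "SequenceAlignment":
        keep = list(keep)
        return SequenceAlignment(
            [self.taxon_ids[i] for i in keep], self.sites[keep], self.partition_bounds
        )


def read_alignment(path: str | Path, format: str = "fasta") -> SequenceAlignment:
    """Read a FASTA or relaxed-PHYLIP alignment into a supermatrix."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
            if not records:
                raise AlignmentFormatError(f"no sequences in {path}")
            lengths = {len(r.seq) for r in records}
            if len(lengths) > 1:
                raise AlignmentFormatError(
                    f"ragged alignment in {path}: row lengths {sorted(lengths)}"
                )
            ids = [r.id for r in records]
            mat = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
        else:
            aln = AlignIO.read(str(path), _FORMATS[format])
            ids = [r.id for r in aln]
            mat = np.array([list(str(r.seq).upper()) for r in aln], dtype="U1")
    except AlignmentFormatError:
        raise
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return SequenceAlignment(ids, mat)


def write_alignment(aln: SequenceAlignment, path: str | Path, format: str = "fasta") -> None:
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    records = [
        SeqRecord(Seq("".join(row)), id=tid, description="")
        for tid, row in zip(aln.taxon_ids, aln.sites)
    ]
    msa = MultipleSeqAlignment(records)
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, _FORMATS[format])


# --------------------------------------------------------------- de-duplication

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def p_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Uncorrected p-distance over columns where both rows are unambiguous.

    Gap/ambiguity columns are excluded from the denominator; a pair with no
    comparable columns is reported as ``inf`` (treated as maximally distant).
    """
    a = _encode_unambiguous(row_a)
    b = _encode_unambiguous(row_b)
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n == 0:
        return float("inf")
    return float((a[both] != b[both]).sum()) / n


def _encode_unambiguous(row: np.ndarray) -> np.ndarray:
    out = np.full(row.shape, -1, dtype=np.int8)
    for sym, code in _BASE_CODE.items():
        out[row == sym] = code
    return out


def dedupe_alignment(aln: SequenceAlignment, threshold: float = 0.003) -> SequenceAlignment:
    """Drop near-identical sequences: of any pair with p-distance < threshold,
    only the first in input order is kept.

    Greedy single pass in input order, so the result is deterministic, never
    removes the first sequence, and is idempotent.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    coded = np.stack([_encode_unambiguous(r) for r in aln.sites])
    kept: list[int] = []
    for i in range(aln.n_taxa):
        drop = False
        for j in kept:
            a, b = coded[i], coded[j]
            both = (a >= 0) & (b >= 0)
            n = int(both.sum())
            if n and float((a[both] != b[both]).sum()) / n < threshold:
                drop = True
                break
        if not drop:
            kept.append(i)
    if len(kept) == aln.n_taxa:
        return aln
    return aln.subset(kept)


# ----------------------------------------------------------------------- trees

def read_tree(path: str | Path, ages_from_lengths: bool = False) -> RootedTimeTree:
    """Read a rooted binary newick tree; polytomies are rejected."""
    text = Path(path).read_text().strip()
    if not text:
        raise TreeStructureError(f"empty tree file {path}")
    return RootedTimeTree.from_newick(text, ages_from_lengths=ages_from_lengths)


def write_tree(tree: RootedTimeTree, path: str | Path, lengths: str = "auto") -> None:
    Path(path).write_text(tree.to_newick(lengths=lengths) + "\n")


def resolve_mrca(tree: RootedTimeTree, taxon_pair: tuple[str, str]) -> int:
    """Internal node index of the MRCA of a pair of tips."""
    return tree.mrca(taxon_pair[0], taxon_pair[1])


# ---------------------------------------------------------- calibration tables

_TABLE_HEADER = ["taxonA", "taxonB", "island_name", "island_age_Ma",
                 "prior_kind", "param1", "param2"]


def read_calibration_table(path: str | Path) -> CalibrationTable:
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty calibration table {path}")
    header = lines[0].split("\t")
    if header != _TABLE_HEADER:
        raise ValueError(
            f"calibration table header must be {_TABLE_HEADER}, got {header}"
        )
    entries = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        ta, tb, island, age, kind, p1, p2 = fields
        prior: Optional[CalibrationPrior]
        if kind == "none":
            prior = None
        elif kind == "normal":
            prior = CalibrationPrior("normal", mean=float(p1), sd=float(p2))
        elif kind == "hard_uniform":
            prior = CalibrationPrior("hard_uniform", lower=float(p1), upper=float(p2))
        else:
            raise ValueError(f"unknown prior_kind {kind!r}")
        entries.append(CalibrationEntry(ta, tb, island, float(age), prior))
    return CalibrationTable(tuple(entries))


def write_calibration_table(table: CalibrationTable, path: str | Path) -> None:
    rows = ["\t".join(_TABLE_HEADER)]
    for e in table:
        if e.prior is None:
            kind, p1, p2 = "none", "", ""
        elif e.prior.kind == "normal":
            kind, p1, p2 = "normal", f"{e.prior.mean:g}", f"{e.prior.sd:g}"
        else:
            kind, p1, p2 = "hard_uniform", f"{e.prior.lower:g}", f"{e.prior.upper:g}"
        rows.append("\t".join(
            [e.taxon_a, e.taxon_b, e.island_name, f"{e.island_age:g}", kind, p1, p2]
        ))
    Path(path).write_text("\n".join(rows) + "\n")
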