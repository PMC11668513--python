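"""Sequence and quantification I/O, and rule-based protein dataset construction.

The pull-down experiment yields log2 label-free quantification (LFQ)
intensity matrices with structured missingness.  Downstream sequence
analyses operate on named protein datasets built from quantification
evidence in nuclear and cytosolic fractions: a protein belongs to a
fraction if it was quantifiable in at least ``min_reps`` replicates of
that fraction, and specificity is defined by failing the same criterion
in the other fraction.  The RNA-dependent PIP2-associated (RDPA) set is
always folded into the nuclear-side datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids plus X (unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Cell contents treated as missing in quantification tables.
NA_TOKENS = ("", "NA", "NaN", "nan")


@dataclass(frozen=True)
class ProteinRecord:
    """One canonical protein sequence keyed by its accession."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        for pos, letter in enumerate(self.sequence, start=1):
            if letter not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"illegal residue {letter!r} at position {pos} "
                    f"in protein {self.protein_id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class QuantMatrix:
    """Protein groups x samples of log2 intensities with explicit missingness.

    Parameters
    ----------
    data
        DataFrame indexed by protein-group id, one column per sample.
        ``NaN`` marks a missing (not quantified) value.
    groups
        Mapping sample -> group label (e.g. ``WT``, ``R40A``); every
        column must carry exactly one label.
    """

    def __init__(self, data: pd.DataFrame, groups: dict[str, str]):
        missing = [c for c in data.columns if c not in groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.data = data.astype(float)
        self.groups = {c: groups[c] for c in data.columns}
        present = self.data.to_numpy()
        if not np.isfinite(present[~np.isnan(present)]).all():
            raise ValueError("non-finite intensity present in matrix")

    # -- introspection -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def group_columns(self, label: str) -> list[str]:
        cols = [c for c, g in self.groups.items() if g == label]
        if not cols:
            raise KeyError(f"no samples with group label {label!r}")
        return cols

    def n_valid(self, label: str | None = None) -> pd.Series:
        """Number of observed values per row, in one group or overall."""
        cols = self.group_columns(label) if label else list(self.data.columns)
        return self.data[cols].notna().sum(axis=1)

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    # -- manipulation --------------------------------------------------
    def subset_rows(self, ids) -> "QuantMatrix":
        keep = [i for i in self.data.index if i in set(ids)]
        return QuantMatrix(self.data.loc[keep].copy(), self.groups)

    def subset_groups(self, labels) -> "QuantMatrix":
        cols = [c for c in self.data.columns if self.groups[c] in set(labels)]
        return QuantMatrix(self.data[cols].copy(), self.groups)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy(), dict(self.groups))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"QuantMatrix({self.data.shape[0]} proteins x "
            f"{self.data.shape[1]} samples, groups={self.group_labels})"
        )


@dataclass
class DatasetDefinition:
    """A named protein set used as a unit of downstream analysis."""

    name: str
    members: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.members


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a proteome FASTA; the header token before the first whitespace
    is the protein id, sequences are uppercased and validated."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(pid, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records, path, wrap: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def read_id_list(path) -> set[str]:
    """Plain-text protein id list, one accession per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(ids):
            fh.write(f"{pid}\n")


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------

def read_quant_table(path, group_map: dict[str, str]) -> QuantMatrix:
    """Read a TSV of log2 intensities (column 1 = protein group id).

    ``group_map`` assigns each sample column a group label; every sample
    it names must exist in the header.  Blank cells and the tokens
    ``NA``/``NaN`` denote missing values; any other non-numeric cell is
    an error.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        keep_default_na=False, na_values=list(NA_TOKENS),
    )
    absent = [s for s in group_map if s not in df.columns]
    if absent:
        raise ValueError(f"samples {absent} in group_map absent from {path}")
    df = df[list(group_map)]
    numeric = {}
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col!r}: {exc}") from exc
    return QuantMatrix(pd.DataFrame(numeric, index=df.index), dict(group_map))


def write_quant_table(matrix: QuantMatrix, path, params: dict | None = None) -> None:
    """Write a QuantMatrix as TSV with a JSON sidecar logging parameters."""
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="protein_id")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"groups": matrix.groups, **(params or {})}, indent=1))


# ---------------------------------------------------------------------------
# Dataset construction from fraction evidence
# ---------------------------------------------------------------------------

def build_fraction_datasets(
    nuclear: QuantMatrix,
    cytosolic: QuantMatrix,
    rdpa_members: set[str],
    min_reps: int = 2,
    strict_absence: bool = False,
) -> dict[str, DatasetDefinition]:
    """Build the named fraction datasets from quantifiability evidence.

    A protein is *quantifiable* in a fraction if it has >= ``min_reps``
    observed values across that fraction's replicates.  "Absent from" the
    other fraction means not quantifiable there (mirror rule); with
    ``strict_absence=True`` it instead means zero observed values.  The
    RDPA set is added to the nuclear-side and total datasets.
    """
    for name, mat in (("nuclear", nuclear), ("cytosolic", cytosolic)):
        if min_reps > mat.data.shape[1]:
            raise ValueError(
                f"min_reps={min_reps} exceeds the {name} replicate count "
                f"({mat.data.shape[1]})"
            )
    nuc_valid = nuclear.n_valid()
    cyt_valid = cytosolic.n_valid()
    universe = set(nuc_valid.index) | set(cyt_valid.index)
    quant_nuc = set(nuc_valid.index[nuc_valid >= min_reps])
    quant_cyt = set(cyt_valid.index[cyt_valid >= min_reps])
    if strict_absence:
        absent_nuc = universe - set(nuc_valid.index[nuc_valid > 0])
        absent_cyt = universe - set(cyt_valid.index[cyt_valid > 0])
    else:
        absent_nuc = universe - quant_nuc
        absent_cyt = universe - quant_cyt

    rdpa = set(rdpa_members)
    nucleo_specific = (quant_nuc & absent_cyt) | rdpa
    nuclear_fraction = quant_nuc | rdpa
    cytosol_specific = quant_cyt & absent_nuc
    cytosolic_fraction = quant_cyt
    total_cell = nuclear_fraction | cytosolic_fraction | rdpa

    sets = {
        "RDPA": DatasetDefinition("RDPA", rdpa),
        "Nucleo-specific": DatasetDefinition("Nucleo-specific", nucleo_specific),
        "Nuclear-fraction": DatasetDefinition("Nuclear-fraction", nuclear_fraction),
        "Cytosol-specific": DatasetDefinition("Cytosol-specific", cytosol_specific),
        "Cytosolic-fraction": DatasetDefinition("Cytosolic-fraction", cytosolic_fraction),
        "Total-cell": DatasetDefinition("Total-cell", total_cell),
    }
    # structural invariants of the rule system
    assert sets["Nucleo-specific"].members <= sets["Nuclear-fraction"].members
    assert sets["Nuclear-fraction"].members <= sets["Total-cell"].members
    assert sets["Cytosol-specific"].members <= sets["Cytosolic-fraction"].members
    assert sets["Cytosolic-fraction"].members <= sets["Total-cell"].members
    for s in sets.values():
        if not s.members:
            warnings.warn(f"dataset {s.name!r} is empty", stacklevel=2)
    return sets
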