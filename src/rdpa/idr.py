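"""Intrinsically disordered region (IDR) annotation from predictor intervals.

Disorder predictions arrive as per-protein, per-predictor 1-based
inclusive residue intervals (the D2P2-style export).  This module
normalizes them (sort + merge touching/overlapping intervals within one
predictor), answers the "has an IDR of >= min_len residues" question,
builds >=k-predictor residue-coverage consensus regions, and computes
per-protein disorder fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class DisorderInterval:
    """One predictor's disorder call: 1-based inclusive [start, end]."""

    protein_id: str
    predictor: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] for "
                f"{self.protein_id}/{self.predictor}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusIdr:
    """Maximal region whose every residue is covered by >= support predictors."""

    protein_id: str
    start: int
    end: int
    support: int

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


class DisorderAnnotation:
    """Normalized per-protein, per-predictor disorder intervals."""

    def __init__(self, intervals: list[DisorderInterval]):
        by_protein: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for iv in intervals:
            by_protein.setdefault(iv.protein_id, {}).setdefault(
                iv.predictor, []
            ).append((iv.start, iv.end))
        self._data = {
            pid: {pred: merge_intervals(ivs) for pred, ivs in preds.items()}
            for pid, preds in by_protein.items()
        }

    @property
    def protein_ids(self) -> list[str]:
        return list(self._data)

    def predictors(self, protein_id: str) -> dict[str, list[tuple[int, int]]]:
        return self._data.get(protein_id, {})

    def intervals(self, protein_id: str) -> list[DisorderInterval]:
        out = []
        for pred, ivs in sorted(self.predictors(protein_id).items()):
            out.extend(DisorderInterval(protein_id, pred, s, e) for s, e in ivs)
        return out


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge touching or overlapping 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def load_disorder_table(path, proteome: dict[str, str] | None = None) -> DisorderAnnotation:
    """Read a TSV with columns protein_id, predictor, start, end.

    When ``proteome`` (id -> sequence) is given, intervals exceeding the
    sequence length are rejected.  An empty table is allowed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "predictor": str})
    required = {"protein_id", "predictor", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"disorder table must have columns {sorted(required)}")
    intervals = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        if row.end < row.start or row.start < 1:
            raise ValueError(
                f"row {row_number}: invalid interval [{row.start}, {row.end}]"
            )
        if proteome is not None:
            if row.protein_id not in proteome:
                raise ValueError(f"row {row_number}: unknown protein {row.protein_id!r}")
            if row.end > len(proteome[row.protein_id]):
                raise ValueError(
                    f"row {row_number}: interval end {row.end} exceeds length "
                    f"of {row.protein_id} ({len(proteome[row.protein_id])})"
                )
        intervals.append(
            DisorderInterval(row.protein_id, row.predictor, int(row.start), int(row.end))
        )
    return DisorderAnnotation(intervals)


def write_disorder_table(annotation: DisorderAnnotation, path) -> None:
    rows = [
        (iv.protein_id, iv.predictor, iv.start, iv.end)
        for pid in sorted(annotation.protein_ids)
        for iv in annotation.intervals(pid)
    ]
    pd.DataFrame(rows, columns=["protein_id", "predictor", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def protein_has_idr(
    annotation: DisorderAnnotation, protein_id: str, min_len: int = 20
) -> bool:
    """True iff any single-predictor interval spans >= min_len residues."""
    return any(
        e - s + 1 >= min_len
        for ivs in annotation.predictors(protein_id).values()
        for s, e in ivs
    )


def consensus_regions(
    annotation: DisorderAnnotation,
    protein_id: str,
    k: int = 3,
    min_len: int = 20,
) -> list[ConsensusIdr]:
    """Maximal runs of residues covered by >= k distinct predictors.

    Runs shorter than ``min_len`` are dropped.  ``support`` is the
    minimum predictor coverage over the run (every residue is covered by
    at least that many predictors).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    events: dict[int, int] = {}
    for ivs in annotation.predictors(protein_id).values():
        for s, e in ivs:
            events[s] = events.get(s, 0) + 1
            events[e + 1] = events.get(e + 1, 0) - 1
    regions: list[ConsensusIdr] = []
    coverage = 0
    run_start = None
    run_support = 0
    for pos in sorted(events):
        prev = coverage
        coverage += events[pos]
        if prev < k <= coverage and run_start is None:
            run_start = pos
            run_support = coverage
        elif run_start is not None:
            if coverage < k:
                regions.append(ConsensusIdr(protein_id, run_start, pos - 1, run_support))
                run_start = None
            else:
                run_support = min(run_support, coverage)
    # events always close every interval, so a run cannot remain open
    return [r for r in regions if len(r) >= min_len]


def all_consensus_regions(
    annotation: DisorderAnnotation, k: int = 3, min_len: int = 20
) -> list[ConsensusIdr]:
    out: list[ConsensusIdr] = []
    for pid in sorted(annotation.protein_ids):
        out.extend(consensus_regions(annotation, pid, k=k, min_len=min_len))
    return out


def disorder_fraction(
    protein_length: int, intervals: list[tuple[int, int]]
) -> float:
    """Percentage of residues covered by one predictor's intervals."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    covered = sum(e - s + 1 for s, e in merge_intervals(list(intervals)))
    return 100.0 * covered / protein_length


def to_zero_based_half_open(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span to 0-based half-open (BED-like)."""
    return start - 1, end


def from_zero_based_half_open(start: int, end: int) -> tuple[int, int]:
    return start + 1, end
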