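"""PTM sites inside K/R-motif-containing IDRs.

Post-translational modification (PTM) sites — acetylation, methylation,
phosphorylation, sumoylation, ubiquitination — are intersected with
consensus IDRs that contain at least one hit of a chosen K/R pattern.
The summary is per IDR (one protein can contribute several IDRs): for
each dataset, the number of qualifying IDRs and, per PTM type, the
percentage of those IDRs containing at least one site of that type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .idr import ConsensusIdr
from .motifs import MotifHit

PTM_TYPES = (
    "acetylation",
    "methylation",
    "phosphorylation",
    "sumoylation",
    "ubiquitination",
)


@dataclass(frozen=True)
class PtmSite:
    protein_id: str
    position: int
    ptm_type: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"non-positive PTM position {self.position}")
        if self.ptm_type not in PTM_TYPES:
            raise ValueError(f"unknown ptm_type {self.ptm_type!r}")


def load_ptm_table(path, proteome: dict[str, str] | None = None) -> list[PtmSite]:
    """Read a PhosphoSitePlus-style TSV (protein_id, position, ptm_type).

    Rows with a ptm_type outside the closed set are skipped with a
    warning; duplicates on (protein, position, type) are collapsed;
    non-positive positions are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ptm_type": str})
    required = {"protein_id", "position", "ptm_type"}
    if not required <= set(df.columns):
        raise ValueError(f"PTM table must have columns {sorted(required)}")
    sites: list[PtmSite] = []
    seen: set[tuple[str, int, str]] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        if row.ptm_type not in PTM_TYPES:
            warnings.warn(
                f"row {row_number}: skipping unknown ptm_type {row.ptm_type!r}",
                stacklevel=2,
            )
            continue
        position = int(row.position)
        if position < 1:
            raise ValueError(f"row {row_number}: non-positive position {position}")
        if proteome is not None and row.protein_id in proteome:
            if position > len(proteome[row.protein_id]):
                raise ValueError(
                    f"row {row_number}: position {position} exceeds length of "
                    f"{row.protein_id}"
                )
        key = (row.protein_id, position, row.ptm_type)
        if key in seen:
            continue
        seen.add(key)
        sites.append(PtmSite(row.protein_id, position, row.ptm_type))
    return sites


def write_ptm_table(sites: list[PtmSite], path) -> None:
    pd.DataFrame(
        [(s.protein_id, s.position, s.ptm_type) for s in sites],
        columns=["protein_id", "position", "ptm_type"],
    ).to_csv(path, sep="\t", index=False)


def motif_containing_idrs(
    idrs: list[ConsensusIdr], hits: list[MotifHit]
) -> list[ConsensusIdr]:
    """IDRs containing at least one motif hit (full span containment)."""
    by_protein: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return [
        idr
        for idr in idrs
        if any(
            idr.contains(h.start, h.end) for h in by_protein.get(idr.protein_id, [])
        )
    ]


def ptm_in_motif_idrs(
    sites: list[PtmSite], motif_idrs: list[ConsensusIdr]
) -> pd.DataFrame:
    """Per-IDR presence flags by PTM type.

    An IDR is flagged for a type iff >= 1 site of that type lies within
    [start, end]; multiple sites flag once (presence, not count).
    """
    by_protein: dict[str, list[PtmSite]] = {}
    for s in sites:
        by_protein.setdefault(s.protein_id, []).append(s)
    rows = []
    for idr in motif_idrs:
        flags = {t: False for t in PTM_TYPES}
        for site in by_protein.get(idr.protein_id, []):
            if idr.start <= site.position <= idr.end:
                flags[site.ptm_type] = True
        rows.append(
            {"protein_id": idr.protein_id, "start": idr.start, "end": idr.end, **flags}
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "start", "end", *PTM_TYPES]
    )


def ptm_frequency_table(
    datasets: dict[str, set[str]],
    idrs: list[ConsensusIdr],
    hits: list[MotifHit],
    sites: list[PtmSite],
) -> pd.DataFrame:
    """Frequency table of PTMs in K/R-motif-containing IDRs per dataset.

    For each dataset: n_idrs = number of consensus IDRs (on that
    dataset's proteins) containing >= 1 hit of the chosen pattern, and
    per PTM type the percentage of those IDRs containing >= 1 site of
    the type (NA when n_idrs = 0).
    """
    qualifying = motif_containing_idrs(idrs, hits)
    rows = []
    for name, members in datasets.items():
        ds_idrs = [i for i in qualifying if i.protein_id in members]
        flags = ptm_in_motif_idrs(sites, ds_idrs)
        n = len(ds_idrs)
        row = {"dataset": name, "n_idrs": n}
        for t in PTM_TYPES:
            row[t] = 100.0 * flags[t].sum() / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=["dataset", "n_idrs", *PTM_TYPES])
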