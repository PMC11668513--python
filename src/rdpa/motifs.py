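"""Polybasic K/R motif scanning (PROSITE semantics) and IDR assignment.

Three lysine/arginine-rich patterns implicated in PIP2 binding are
scanned with ScanProsite's "greedy, no overlaps" semantics: the scan
moves left to right, at each position the longest feasible x(3,7) run
wins, and after a hit is accepted scanning resumes immediately after its
end.  A hit counts as inside an IDR only when at least ``k`` predictors
each report a disordered interval of >= ``min_len`` residues fully
containing the motif span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import pandas as pd

from .idr import DisorderAnnotation

#: Residues matched by the PROSITE wildcard x (20 canonical letters + X).
X_RESIDUES = "ACDEFGHIKLMNPQRSTVWYX"
_X = f"[{X_RESIDUES}]"

#: The three polybasic patterns, longest to shortest suffix.
PROSITE_PATTERNS = {
    "long": "[KR]-x(3,7)-K-x-[KR]-[KR]",
    "mid": "[KR]-x(3,7)-K-x-[KR]",
    "short": "[KR]-x(3,7)-K-x-K",
}

#: Inclusive match-length bounds per pattern.
MATCH_LENGTH_BOUNDS = {"long": (8, 12), "mid": (7, 11), "short": (7, 11)}


def prosite_to_regex(pattern: str) -> str:
    """Translate a PROSITE pattern string to a Python regex.

    Supports the subset used here: residue letters, [..] classes,
    x wildcards, and (n)/(n,m) repetition.
    """
    out = []
    for element in pattern.split("-"):
        m = re.fullmatch(r"(\[[A-Z]+\]|[A-Zx])(?:\((\d+)(?:,(\d+))?\))?", element)
        if not m:
            raise ValueError(f"unsupported PROSITE element {element!r}")
        token, lo, hi = m.groups()
        if token == "x":
            token = _X
        out.append(token)
        if lo and hi:
            out.append(f"{{{lo},{hi}}}")
        elif lo:
            out.append(f"{{{lo}}}")
    return "".join(out)


@dataclass(frozen=True)
class KrPattern:
    """A compiled polybasic motif pattern."""

    pattern_id: str
    prosite: str

    @property
    def regex(self) -> re.Pattern:
        return re.compile(prosite_to_regex(self.prosite))


KR_PATTERNS = {
    pid: KrPattern(pid, prosite) for pid, prosite in PROSITE_PATTERNS.items()
}


@dataclass(frozen=True)
class MotifHit:
    """One accepted motif occurrence; 1-based inclusive span."""

    protein_id: str
    pattern_id: str
    start: int
    end: int
    matched: str
    in_idr: bool | None = None


def scan_sequence(
    sequence: str, pattern: KrPattern, protein_id: str = ""
) -> list[MotifHit]:
    """Greedy, non-overlapping left-to-right scan of one sequence.

    Python's regex engine implements exactly the required semantics:
    ``finditer`` yields leftmost matches, a greedy ``{3,7}`` takes the
    longest feasible x-run at each start, and iteration resumes after
    each match's end.
    """
    hits = []
    for m in pattern.regex.finditer(sequence):
        hit = MotifHit(
            protein_id=protein_id,
            pattern_id=pattern.pattern_id,
            start=m.start() + 1,
            end=m.end(),
            matched=m.group(0),
        )
        lo, hi = MATCH_LENGTH_BOUNDS.get(pattern.pattern_id, (1, len(sequence)))
        assert lo <= len(hit.matched) <= hi
        assert sequence[hit.start - 1 : hit.end] == hit.matched
        hits.append(hit)
    return hits


def scan_proteome(
    proteome: dict[str, str], patterns=None
) -> dict[str, list[MotifHit]]:
    """Scan every protein with every pattern; hits keyed by pattern id."""
    patterns = patterns or KR_PATTERNS
    out: dict[str, list[MotifHit]] = {pid: [] for pid in patterns}
    for protein_id in sorted(proteome):
        for pid, pat in patterns.items():
            out[pid].extend(scan_sequence(proteome[protein_id], pat, protein_id))
    return out


def assign_hits_to_idrs(
    hits: list[MotifHit],
    annotation: DisorderAnnotation,
    k: int = 3,
    min_len: int = 20,
    proteome_ids=None,
    mode: str = "containment",
) -> list[MotifHit]:
    """Set ``in_idr`` on each hit.

    Default rule ("containment"): true iff >= k distinct predictors each
    have an interval of length >= min_len fully containing the hit span.
    ``mode="overlap"`` relaxes full containment to any overlap with a
    qualifying interval.
    """
    if mode not in ("containment", "overlap"):
        raise ValueError("mode must be 'containment' or 'overlap'")
    known = set(proteome_ids) if proteome_ids is not None else None
    out = []
    for hit in hits:
        if known is not None and hit.protein_id not in known:
            raise KeyError(f"hit protein {hit.protein_id!r} absent from proteome")
        n_support = 0
        for ivs in annotation.predictors(hit.protein_id).values():
            for s, e in ivs:
                if e - s + 1 < min_len:
                    continue
                if mode == "containment":
                    ok = s <= hit.start and hit.end <= e
                else:
                    ok = s <= hit.end and hit.start <= e
                if ok:
                    n_support += 1
                    break  # one qualifying interval per predictor suffices
        out.append(replace(hit, in_idr=n_support >= k))
    return out


def motif_site_stats(
    hits_by_dataset: dict[str, dict[str, list[MotifHit]]]
) -> pd.DataFrame:
    """Per-dataset, per-pattern site counts and % of sites inside IDRs.

    ``hits_by_dataset`` maps dataset name -> pattern id -> annotated
    hits.  A dataset/pattern with zero sites reports NA, not 0%.
    """
    rows = []
    for dataset, by_pattern in hits_by_dataset.items():
        for pattern_id, hits in by_pattern.items():
            n_sites = len(hits)
            n_in = sum(1 for h in hits if h.in_idr)
            percent = 100.0 * n_in / n_sites if n_sites else float("nan")
            rows.append(
                {
                    "dataset": dataset,
                    "pattern_id": pattern_id,
                    "n_sites": n_sites,
                    "n_in_idr": n_in,
                    "percent_in_idr": percent,
                }
            )
    return pd.DataFrame(rows)


def hits_to_table(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "pattern_id": h.pattern_id,
                "start": h.start,
                "end": h.end,
                "matched": h.matched,
                "in_idr": h.in_idr,
            }
            for h in hits
        ],
        columns=["protein_id", "pattern_id", "start", "end", "matched", "in_idr"],
    )
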