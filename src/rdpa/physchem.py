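"""Sequence physicochemistry: isoelectric point, GRAVY, charge composition.

IDRs of PIP2-interacting proteins fall into two charge classes — an
acidic population enriched in D/E and a basic, K/R-rich population —
separated here at pI 7.  The isoelectric point is the pH at which the
Henderson-Hasselbalch net charge crosses zero; hydropathy is the
Kyte-Doolittle grand average (GRAVY), with lower values more
hydrophilic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PkaSet:
    """Ionizable-group pKa constants (default: the EMBOSS set)."""

    n_term: float = 8.6
    c_term: float = 3.6
    C: float = 8.5
    D: float = 3.9
    E: float = 4.1
    H: float = 6.5
    K: float = 10.8
    R: float = 12.5
    Y: float = 10.1

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {name}={v} outside (0, 14)")


EMBOSS_PKA = PkaSet()

_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("D", "E", "C", "Y")


def net_charge(sequence: str, ph: float, pka: PkaSet = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Positive terms: the free N-terminus plus H/K/R side chains, each
    contributing 1/(1 + 10^(pH - pKa)); negative terms: the C-terminus
    plus D/E/C/Y, each contributing 1/(1 + 10^(pKa - pH)).
    """
    if not sequence:
        raise ValueError("empty sequence")
    q = 1.0 / (1.0 + 10.0 ** (ph - pka.n_term))
    q -= 1.0 / (1.0 + 10.0 ** (pka.c_term - ph))
    for aa in _POSITIVE:
        n = sequence.count(aa)
        if n:
            q += n / (1.0 + 10.0 ** (ph - getattr(pka, aa)))
    for aa in _NEGATIVE:
        n = sequence.count(aa)
        if n:
            q -= n / (1.0 + 10.0 ** (getattr(pka, aa) - ph))
    return q


def isoelectric_point(
    sequence: str, pka: PkaSet = EMBOSS_PKA, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Net charge is monotone decreasing in pH, positive at pH 0 (free
    N-terminus) and negative at pH 14 (free C-terminus), so a root
    always exists and is unique.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value.

    X (and any non-canonical letter) is excluded from both the sum and
    the length; a sequence with no scorable residue is an error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    values = [KYTE_DOOLITTLE[aa] for aa in sequence if aa in KYTE_DOOLITTLE]
    if not values:
        raise ValueError("no canonical residues to score")
    return sum(values) / len(values)


def charged_residue_counts(sequence: str) -> tuple[int, int]:
    """(n_DE, n_KR): counts of acidic and basic residues."""
    if not sequence:
        raise ValueError("empty sequence")
    n_de = sequence.count("D") + sequence.count("E")
    n_kr = sequence.count("K") + sequence.count("R")
    return n_de, n_kr


def classify_idr_charge(pi: float) -> str:
    """'acidic' if pI < 7, else 'basic' (pI == 7 counts as basic)."""
    if not 0.0 < pi < 14.0:
        raise ValueError("pI outside (0, 14)")
    return "acidic" if pi < 7.0 else "basic"


def idr_physchem_table(
    proteome: dict[str, str],
    idrs,
    pka: PkaSet = EMBOSS_PKA,
) -> pd.DataFrame:
    """Per-IDR physicochemical summary.

    ``idrs`` is an iterable of objects with protein_id/start/end (1-based
    inclusive), typically ConsensusIdr.  Returns one row per IDR with
    length, pI, GRAVY, D/E and K/R counts and the acidic/basic class.
    """
    rows = []
    for region in idrs:
        seq = proteome[region.protein_id][region.start - 1 : region.end]
        pi = isoelectric_point(seq, pka)
        n_de, n_kr = charged_residue_counts(seq)
        rows.append(
            {
                "protein_id": region.protein_id,
                "start": region.start,
                "end": region.end,
                "length": len(seq),
                "pI": pi,
                "gravy": gravy(seq),
                "n_DE": n_de,
                "n_KR": n_kr,
                "charge_class": classify_idr_charge(pi),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "end", "length", "pI", "gravy",
            "n_DE", "n_KR", "charge_class",
        ],
    )
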