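"""Independent brute-force oracles used to cross-check the implementation.

Each oracle restates the contract from first principles (enumeration,
per-residue counting, grid search) without sharing code with the library
path it validates.
"""

from itertools import combinations
from math import comb

import numpy as np

KR = set("KR")
X_SET = set("ACDEFGHIKLMNPQRSTVWYX")

# pattern suffix after the common [KR]-x(3,7)-K-x core
SUFFIXES = {"long": ("KR", "KR"), "mid": ("KR",), "short": ("K",)}


def candidate_matches(sequence: str, pattern_id: str):
    """Every (start, length) realization of the pattern, 1-based inclusive.

    Explicit positional checks: first residue K/R, an x-run of 3..7
    residues, K, one x, then the pattern-specific suffix.
    """
    suffix = SUFFIXES[pattern_id]
    n = len(sequence)
    out = []
    for start in range(n):  # 0-based here
        if sequence[start] not in KR:
            continue
        for xlen in range(3, 8):
            pos = start + 1 + xlen
            length = 1 + xlen + 2 + len(suffix)
            if start + length > n:
                continue
            if any(sequence[start + 1 + i] not in X_SET for i in range(xlen)):
                continue
            if sequence[pos] != "K":
                continue
            if sequence[pos + 1] not in X_SET:
                continue
            ok = True
            for j, allowed in enumerate(suffix):
                if sequence[pos + 2 + j] not in set(allowed):
                    ok = False
                    break
            if ok:
                out.append((start + 1, length))
    return out


def greedy_scan_oracle(sequence: str, pattern_id: str):
    """Greedy no-overlap acceptance: sort candidates by (start, -length),
    accept each candidate not overlapping an accepted one.

    Returns 1-based inclusive (start, end) spans.
    """
    candidates = sorted(
        candidate_matches(sequence, pattern_id), key=lambda c: (c[0], -c[1])
    )
    accepted = []
    for start, length in candidates:
        end = start + length - 1
        if all(end < s or start > e for s, e in accepted):
            accepted.append((start, end))
    return sorted(accepted)


def coverage_consensus_oracle(intervals_by_predictor, k, min_len, max_pos):
    """Per-residue coverage counting for consensus IDRs.

    Returns (start, end, support) runs where >= k predictors cover every
    residue; support is the minimum coverage over the run.
    """
    cover = np.zeros(max_pos + 2, dtype=int)
    for ivs in intervals_by_predictor.values():
        seen = np.zeros(max_pos + 2, dtype=bool)
        for s, e in ivs:
            seen[s : e + 1] = True
        cover += seen
    runs = []
    pos = 1
    while pos <= max_pos:
        if cover[pos] >= k:
            start = pos
            while pos <= max_pos and cover[pos] >= k:
                pos += 1
            end = pos - 1
            if end - start + 1 >= min_len:
                runs.append((start, end, int(cover[start : end + 1].min())))
        else:
            pos += 1
    return runs


def grid_search_pi(sequence: str, pka, step: float = 1e-4) -> float:
    """pH grid minimizing |net charge|, via vectorized Henderson-Hasselbalch."""
    ph = np.arange(0.0, 14.0 + step, step)
    q = 1.0 / (1.0 + 10.0 ** (ph - pka.n_term))
    q -= 1.0 / (1.0 + 10.0 ** (pka.c_term - ph))
    for aa in "HKR":
        n = sequence.count(aa)
        if n:
            q += n / (1.0 + 10.0 ** (ph - getattr(pka, aa)))
    for aa in "DECY":
        n = sequence.count(aa)
        if n:
            q -= n / (1.0 + 10.0 ** (getattr(pka, aa) - ph))
    return float(ph[np.argmin(np.abs(q))])


def hypergeom_enumeration(k, K, n, N, tail):
    """Exact tail probability by enumerating all C(N, n) draws.

    Population 0..N-1 with carriers 0..K-1; count draws whose carrier
    overlap satisfies the tail condition.  Feasible for N <= 12.
    """
    carriers = set(range(K))
    hits = 0
    total = comb(N, n)
    for draw in combinations(range(N), n):
        x = len(carriers & set(draw))
        if (tail == "upper" and x >= k) or (tail == "lower" and x <= k):
            hits += 1
    return hits / total


def ptm_frequency_oracle(datasets, idrs, hits, sites, ptm_types):
    """Nested-loop recomputation of the PTM frequency table.

    Returns {dataset: (n_idrs, {ptm_type: percent-or-nan})}.
    """
    out = {}
    for name, members in datasets.items():
        qualifying = []
        for idr in idrs:
            if idr.protein_id not in members:
                continue
            has_motif = False
            for h in hits:
                if (
                    h.protein_id == idr.protein_id
                    and idr.start <= h.start
                    and h.end <= idr.end
                ):
                    has_motif = True
            if has_motif:
                qualifying.append(idr)
        n = len(qualifying)
        percents = {}
        for t in ptm_types:
            flagged = 0
            for idr in qualifying:
                found = False
                for s in sites:
                    if (
                        s.protein_id == idr.protein_id
                        and s.ptm_type == t
                        and idr.start <= s.position <= idr.end
                    ):
                        found = True
                if found:
                    flagged += 1
            percents[t] = 100.0 * flagged / n if n else float("nan")
        out[name] = (n, percents)
    return out


def pooled_t_oracle(a, b):
    """Classical equal-variance two-sample t statistic, textbook form."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
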