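"""Ground-truth synthetic data for every stage of the pipeline.

Three generators, each a pure function of (config, seed):

* :func:`generate_proteome` — protein sequences with planted IDRs of
  controlled charge composition, a multi-predictor disorder panel with
  boundary jitter and dropout, planted K/R motifs (inside and outside
  IDRs, verified by the scanner before emission) and planted PTM sites.
* :func:`generate_pulldown_experiment` — a three-condition pull-down
  LFQ experiment (WT PH domain, R40A mutant, WT + RNase III; three
  replicates each) with planted enrichment/depletion effects and
  intensity-dependent (MNAR) plus uniform (MCAR) missingness.
* :func:`generate_image_stack` — 3D nuclei (ellipsoids, DAPI-like
  channel) with planted Gaussian-profile foci and an optional partially
  co-located second channel.

The generators emulate the statistical structure of the real inputs —
not their scale: default sizes are desk-scale so the full pipeline runs
in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .idr import DisorderAnnotation, DisorderInterval
from .motifs import KR_PATTERNS, scan_sequence
from .proteome_io import AMINO_ACIDS, ProteinRecord, QuantMatrix, write_fasta
from .ptm import PTM_TYPES, PtmSite, write_ptm_table

# Approximate vertebrate proteome residue frequencies (background draw).
BACKGROUND_FREQS = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.011, "Y": 0.027, "V": 0.060,
}

_NON_KR = [aa for aa in AMINO_ACIDS if aa not in "KR"]


def _composition(de: float, kr: float) -> dict[str, float]:
    """Composition vector with fixed total D/E and K/R frequencies; the
    remaining mass follows the background distribution."""
    rest = {a: f for a, f in BACKGROUND_FREQS.items() if a not in "DEKR"}
    scale = (1.0 - de - kr) / sum(rest.values())
    comp = {a: f * scale for a, f in rest.items()}
    comp.update({"D": de / 2, "E": de / 2, "K": kr / 2, "R": kr / 2})
    return comp


#: Charge-class compositions for planted IDRs.
DE_RICH = _composition(de=0.30, kr=0.05)
KR_RICH = _composition(de=0.05, kr=0.30)


@dataclass
class ProteomeConfig:
    n_proteins: int = 150
    length_range: tuple[int, int] = (200, 600)
    mean_idrs_per_protein: float = 1.2
    idr_length_range: tuple[int, int] = (40, 90)
    frac_acidic_idrs: float = 0.5
    n_predictors: int = 9
    boundary_jitter: int = 3
    predictor_drop_rate: float = 0.1
    #: planted motif counts per pattern: inside truth IDRs / outside them
    motifs_in_idr: dict = field(default_factory=lambda: {"long": 20, "mid": 10, "short": 10})
    motifs_outside: dict = field(default_factory=lambda: {"long": 10, "mid": 5, "short": 5})
    #: per-IDR planting probability of >= 1 site per PTM type
    ptm_rates: dict = field(default_factory=lambda: {
        "phosphorylation": 0.4, "acetylation": 0.2, "ubiquitination": 0.15,
        "methylation": 0.1, "sumoylation": 0.05,
    })
    background_ptms_per_protein: float = 0.5
    strict_no_accidental: bool = False


@dataclass(frozen=True)
class TruthIdr:
    protein_id: str
    start: int
    end: int
    charge_class: str  # acidic | basic


@dataclass
class SynthProteomeTruth:
    records: list[ProteinRecord]
    annotation: DisorderAnnotation
    idr_truth: list[TruthIdr]
    motif_truth: dict[str, list[tuple[str, int, int, bool]]]
    ptm_truth: list[PtmSite]
    config: ProteomeConfig

    @property
    def proteome(self) -> dict[str, str]:
        return {r.protein_id: r.sequence for r in self.records}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "proteome.fasta")
        from .idr import write_disorder_table
        write_disorder_table(self.annotation, outdir / "disorder.tsv")
        write_ptm_table(self.ptm_truth, outdir / "ptm_sites.tsv")
        pd.DataFrame(
            [(t.protein_id, t.start, t.end, t.charge_class) for t in self.idr_truth],
            columns=["protein_id", "start", "end", "charge_class"],
        ).to_csv(outdir / "idr_truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (pat, pid, s, e, in_idr)
                for pat, spans in self.motif_truth.items()
                for pid, s, e, in_idr in spans
            ],
            columns=["pattern_id", "protein_id", "start", "end", "in_idr"],
        ).to_csv(outdir / "motif_truth.tsv", sep="\t", index=False)


def sample_sequence(rng: np.random.Generator, length: int,
                    composition: dict[str, float] | None = None) -> np.ndarray:
    comp = composition or BACKGROUND_FREQS
    letters = np.array(list(comp))
    probs = np.array(list(comp.values()))
    probs = probs / probs.sum()
    return rng.choice(letters, size=length, p=probs)


def _motif_string(rng: np.random.Generator, pattern_id: str) -> str:
    """A sequence realizing one pattern; x positions avoid K/R so the
    planted span is exactly what the greedy scanner should accept."""
    kr = lambda: rng.choice(["K", "R"])
    x = lambda n: "".join(rng.choice(_NON_KR, size=n))
    body = kr() + x(int(rng.integers(3, 8))) + "K" + x(1)
    if pattern_id == "long":
        return body + kr() + kr()
    if pattern_id == "mid":
        return body + kr()
    if pattern_id == "short":
        return body + "K"
    raise ValueError(f"unknown pattern {pattern_id!r}")


def generate_proteome(config: ProteomeConfig | None = None, seed: int = 0) -> SynthProteomeTruth:
    """Generate a proteome with planted IDRs, motifs and PTM sites."""
    cfg = config or ProteomeConfig()
    rng = np.random.default_rng(seed)
    max_motif_len = 12
    # inner margin keeping any scan hit that touches a planted in-IDR
    # motif (greedy hits reach at most 11 residues left / 5 right of the
    # planted span) inside every jittered predictor interval
    margin = 13 + cfg.boundary_jitter
    if cfg.idr_length_range[0] < 20:
        raise ValueError("IDRs must be at least 20 residues")

    sequences: dict[str, np.ndarray] = {}
    idr_truth: list[TruthIdr] = []
    idrs_by_protein: dict[str, list[tuple[int, int]]] = {}
    for i in range(cfg.n_proteins):
        pid = f"SYN{i + 1:04d}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = sample_sequence(rng, length)
        placed: list[tuple[int, int]] = []
        for _ in range(rng.poisson(cfg.mean_idrs_per_protein)):
            ilen = int(rng.integers(cfg.idr_length_range[0], cfg.idr_length_range[1] + 1))
            if ilen + 10 >= length:
                continue
            for _attempt in range(20):
                start = int(rng.integers(5, length - ilen - 4))
                end = start + ilen - 1
                if all(end < s - 5 or start > e + 5 for s, e in placed):
                    placed.append((start, end))
                    charge = "acidic" if rng.random() < cfg.frac_acidic_idrs else "basic"
                    comp = DE_RICH if charge == "acidic" else KR_RICH
                    seq[start - 1 : end] = sample_sequence(rng, ilen, comp)
                    idr_truth.append(TruthIdr(pid, start, end, charge))
                    break
        sequences[pid] = seq
        idrs_by_protein[pid] = sorted(placed)

    # ---- plant motifs -------------------------------------------------
    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in sequences}

    def _free(pid: str, start: int, end: int) -> bool:
        # keep planted spans > max_motif_len apart so no scan hit can
        # bridge two of them
        return all(
            end < s - max_motif_len - 1 or start > e + max_motif_len + 1
            for s, e in occupied[pid]
        )

    motif_truth: dict[str, list[tuple[str, int, int, bool]]] = {
        p: [] for p in KR_PATTERNS
    }

    def _plant(pattern_id: str, inside: bool, count: int) -> None:
        if inside:
            slots = [
                (pid, s, e)
                for pid, ivs in idrs_by_protein.items()
                for s, e in ivs
                if e - s + 1 >= max_motif_len + 2 * margin
            ]
        else:
            slots = [(pid, 1, len(sequences[pid])) for pid in sequences]
        if not slots and count > 0:
            raise ValueError(
                f"infeasible config: no slot can hold a planted {pattern_id} motif"
                + (" inside an IDR" if inside else "")
            )
        planted = 0
        for _attempt in range(200 * max(count, 1)):
            if planted >= count:
                break
            pid, lo, hi = slots[rng.integers(len(slots))]
            motif = _motif_string(rng, pattern_id)
            mlen = len(motif)
            if inside:
                lo_pos, hi_pos = lo + margin, hi - margin - mlen + 1
            else:
                lo_pos, hi_pos = max(1, lo + 12), hi - mlen - 11
            if hi_pos <= lo_pos:
                continue
            start = int(rng.integers(lo_pos, hi_pos + 1))
            end = start + mlen - 1
            if not inside:
                # stay clear of every truth IDR so the motif is truly outside
                near_idr = any(
                    start <= e + 12 and end >= s - 12
                    for s, e in idrs_by_protein[pid]
                )
                if near_idr:
                    continue
            if not _free(pid, start, end):
                continue
            sequences[pid][start - 1 : end] = list(motif)
            occupied[pid].append((start, end))
            motif_truth[pattern_id].append((pid, start, end, inside))
            planted += 1
        if planted < count:
            raise ValueError(
                f"could not plant {count} {pattern_id} motifs "
                f"({'inside' if inside else 'outside'} IDRs); config infeasible"
            )

    for pattern_id, count in cfg.motifs_in_idr.items():
        _plant(pattern_id, True, count)
    for pattern_id, count in cfg.motifs_outside.items():
        _plant(pattern_id, False, count)

    # ---- optional removal of accidental motifs ------------------------
    if cfg.strict_no_accidental:
        planted_spans = {
            pid: [
                (s, e)
                for spans in motif_truth.values()
                for p, s, e, _ in spans
                if p == pid
            ]
            for pid in sequences
        }
        for pid, seq in sequences.items():
            for _round in range(50):
                dirty = False
                text = "".join(seq)
                for pat in KR_PATTERNS.values():
                    for h in scan_sequence(text, pat, pid):
                        accidental = all(
                            h.end < s or h.start > e for s, e in planted_spans[pid]
                        )
                        if accidental:
                            seq[h.start - 1] = rng.choice(_NON_KR)
                            dirty = True
                if not dirty:
                    break

    # ---- scanner verification of planted motifs -----------------------
    for pattern_id, spans in motif_truth.items():
        pat = KR_PATTERNS[pattern_id]
        by_protein: dict[str, list[tuple[int, int]]] = {}
        for pid, s, e, _ in spans:
            by_protein.setdefault(pid, []).append((s, e))
        for pid, wanted in by_protein.items():
            hits = scan_sequence("".join(sequences[pid]), pat, pid)
            for s, e in wanted:
                if not any(h.start <= e and s <= h.end for h in hits):
                    raise RuntimeError(
                        f"planted {pattern_id} motif at {pid}:{s}-{e} "
                        "not recovered by the scanner"
                    )

    # ---- predictor panel ----------------------------------------------
    intervals: list[DisorderInterval] = []
    for t in idr_truth:
        length = len(sequences[t.protein_id])
        for p in range(cfg.n_predictors):
            if rng.random() < cfg.predictor_drop_rate:
                continue
            js = int(rng.integers(0, cfg.boundary_jitter + 1))
            je = int(rng.integers(0, cfg.boundary_jitter + 1))
            s = max(1, t.start + int(rng.choice([-1, 1])) * js)
            e = min(length, t.end + int(rng.choice([-1, 1])) * je)
            if e - s + 1 >= 1:
                intervals.append(
                    DisorderInterval(t.protein_id, f"pred{p + 1}", s, min(max(s, e), length))
                )
    annotation = DisorderAnnotation(intervals)

    # ---- PTM sites ----------------------------------------------------
    ptm_truth: list[PtmSite] = []
    seen_ptm: set[tuple[str, int, str]] = set()
    for t in idr_truth:
        for ptm_type, rate in cfg.ptm_rates.items():
            if rng.random() < rate:
                pos = int(rng.integers(t.start, t.end + 1))
                key = (t.protein_id, pos, ptm_type)
                if key not in seen_ptm:
                    seen_ptm.add(key)
                    ptm_truth.append(PtmSite(*key))
    for pid, seq in sequences.items():
        for _ in range(rng.poisson(cfg.background_ptms_per_protein)):
            pos = int(rng.integers(1, len(seq) + 1))
            ptm_type = str(rng.choice(list(PTM_TYPES)))
            key = (pid, pos, ptm_type)
            if key not in seen_ptm:
                seen_ptm.add(key)
                ptm_truth.append(PtmSite(*key))

    records = [ProteinRecord(pid, "".join(seq)) for pid, seq in sequences.items()]
    return SynthProteomeTruth(records, annotation, idr_truth, motif_truth, ptm_truth, cfg)


# ---------------------------------------------------------------------------
# Pull-down experiment
# ---------------------------------------------------------------------------

@dataclass
class PulldownConfig:
    """Three-condition pull-down design (WT / R40A / WT+RNaseIII, 3+3+3).

    Defaults follow the experimental design being emulated: ~2,000
    quantified background protein groups, 195 PIP2-associated proteins
    of which 150 lose association after RNase III (dsRNA+) and 15 gain
    it (dsRNA-), log2 effect sizes of +/-2.0, replicate noise SD 0.3,
    and abundance-dependent missingness.
    """

    n_proteins: int = 2000
    n_pip2: int = 195
    n_dsrna_plus: int = 150
    n_dsrna_minus: int = 15
    effect_pip2: float = 2.0
    effect_rnase: float = 2.0
    noise_sd: float = 0.3
    n_reps: int = 3
    base_mean: float = 25.0
    base_sd: float = 2.0
    mnar_midpoint: float = 19.0
    mnar_scale: float = 0.8
    mcar_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_dsrna_plus + self.n_dsrna_minus > self.n_pip2:
            raise ValueError("dsRNA subsets exceed the PIP2-associated set")
        if self.n_pip2 > self.n_proteins:
            raise ValueError("n_pip2 exceeds n_proteins")


@dataclass
class SynthExperimentTruth:
    pip2_associated: set[str]
    dsrna_plus: set[str]
    dsrna_minus: set[str]


def generate_pulldown_experiment(
    config: PulldownConfig | None = None, seed: int = 0
) -> tuple[QuantMatrix, SynthExperimentTruth]:
    """Simulate the pull-down LFQ matrix (9 samples, 3 groups).

    Background rows share one latent abundance across groups; PIP2-
    associated rows are shifted up in WT relative to R40A; dsRNA+ rows
    are additionally shifted down (and dsRNA- up) in WT+RNaseIII.
    Missingness is logistic in the noisy intensity (MNAR) plus a small
    uniform MCAR rate, applied after the shifts.
    """
    cfg = config or PulldownConfig()
    if cfg.n_proteins < 100:
        import warnings
        warnings.warn("fewer than 100 background proteins: FDR estimates unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    ids = np.array([f"PG{i + 1:05d}" for i in range(cfg.n_proteins)])
    pip2_idx = rng.choice(cfg.n_proteins, size=cfg.n_pip2, replace=False)
    plus_idx = pip2_idx[: cfg.n_dsrna_plus]
    minus_idx = pip2_idx[cfg.n_dsrna_plus : cfg.n_dsrna_plus + cfg.n_dsrna_minus]

    mu = rng.normal(cfg.base_mean, cfg.base_sd, cfg.n_proteins)
    wt = np.tile(mu[:, None], (1, cfg.n_reps))
    r40a = wt.copy()
    r40a[pip2_idx] -= cfg.effect_pip2
    rnase = wt.copy()
    rnase[plus_idx] -= cfg.effect_rnase
    rnase[minus_idx] += cfg.effect_rnase

    X = np.concatenate([wt, r40a, rnase], axis=1)
    X = X + rng.normal(0.0, cfg.noise_sd, X.shape)
    # missing-not-at-random: low intensities drop out preferentially
    p_mnar = 1.0 / (1.0 + np.exp((X - cfg.mnar_midpoint) / cfg.mnar_scale))
    missing = rng.random(X.shape) < (cfg.mcar_rate + (1 - cfg.mcar_rate) * p_mnar)
    X = np.where(missing, np.nan, X)

    columns = (
        [f"WT_{r + 1}" for r in range(cfg.n_reps)]
        + [f"R40A_{r + 1}" for r in range(cfg.n_reps)]
        + [f"RNaseIII_{r + 1}" for r in range(cfg.n_reps)]
    )
    groups = {c: c.rsplit("_", 1)[0] for c in columns}
    groups = {c: ("WT_RNaseIII" if g == "RNaseIII" else g) for c, g in groups.items()}
    matrix = QuantMatrix(pd.DataFrame(X, index=ids, columns=columns), groups)
    truth = SynthExperimentTruth(
        set(ids[pip2_idx]), set(ids[plus_idx]), set(ids[minus_idx])
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass
class ImageConfig:
    shape: tuple[int, int, int] = (50, 100, 100)
    n_foci: int = 5
    focus_sigma: float = 1.5      # Gaussian profile SD, voxels (radius ~ 3)
    peak_to_background: float = 10.0
    background: float = 1.0
    noise_sd: float = 0.2
    nucleus_semiaxes: tuple[float, float, float] = (18.0, 34.0, 34.0)
    dapi_intensity: float = 5.0
    min_focus_separation: float = 10.5
    coloc_fraction: float | None = None  # second channel sharing this focus fraction


@dataclass
class SynthNucleus:
    dapi: np.ndarray
    target: np.ndarray
    mask: np.ndarray          # ground-truth nuclear mask
    foci_centers: np.ndarray  # (n, 3) voxel coordinates
    second: np.ndarray | None = None


def generate_image_stack(
    config: ImageConfig | None = None, seed: int = 0
) -> SynthNucleus:
    """One synthetic nucleus: ellipsoidal DAPI channel plus a target
    channel with ``n_foci`` planted Gaussian-profile foci (and an
    optional second channel sharing ``coloc_fraction`` of them)."""
    cfg = config or ImageConfig()
    rng = np.random.default_rng(seed)
    nz, ny, nx = cfg.shape
    center = np.array([nz / 2, ny / 2, nx / 2])
    semi = np.array(cfg.nucleus_semiaxes)
    if (2 * semi >= np.array(cfg.shape)).any():
        raise ValueError("nucleus does not fit in the volume")
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)
    norm = (((coords - center) / semi) ** 2).sum(axis=-1)
    mask = norm <= 1.0

    centers = _place_foci(rng, cfg, center, semi)
    target = np.full(cfg.shape, cfg.background)
    amp = cfg.background * (cfg.peak_to_background - 1.0)
    for c in centers:
        target += amp * np.exp(-((coords - c) ** 2).sum(axis=-1) / (2 * cfg.focus_sigma**2))
    target = np.where(mask, target, 0.05 * cfg.background)
    target = np.clip(target + rng.normal(0, cfg.noise_sd, cfg.shape), 0, None)

    dapi = np.where(mask, cfg.dapi_intensity, 0.0)
    dapi = np.clip(dapi + rng.normal(0, cfg.dapi_intensity / 5.0, cfg.shape), 0, None)

    second = None
    if cfg.coloc_fraction is not None:
        n_shared = int(round(cfg.coloc_fraction * len(centers)))
        shared = centers[:n_shared]
        own = _place_foci(
            rng, replace(cfg, n_foci=cfg.n_foci - n_shared), center, semi,
            avoid=centers,
        ) if cfg.n_foci - n_shared > 0 else np.empty((0, 3))
        second = np.full(cfg.shape, cfg.background)
        for c in [*shared, *own]:
            second += amp * np.exp(
                -((coords - c) ** 2).sum(axis=-1) / (2 * cfg.focus_sigma**2)
            )
        second = np.where(mask, second, 0.05 * cfg.background)
        second = np.clip(second + rng.normal(0, cfg.noise_sd, cfg.shape), 0, None)

    return SynthNucleus(dapi, target, mask, np.asarray(centers, dtype=float), second)


def _place_foci(rng, cfg: ImageConfig, center, semi, avoid=None) -> np.ndarray:
    """Rejection-sample focus centers well inside the nucleus with a
    minimum pairwise separation (so planted counts stay resolvable)."""
    placed: list[np.ndarray] = []
    existing = [np.asarray(a) for a in (avoid if avoid is not None else [])]
    for _ in range(4000):
        if len(placed) >= cfg.n_foci:
            break
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = 0.75 * rng.random() ** (1 / 3)
        cand = center + u * r * semi
        if all(
            np.linalg.norm(cand - p) >= cfg.min_focus_separation
            for p in [*placed, *existing]
        ):
            placed.append(cand)
    if len(placed) < cfg.n_foci:
        raise ValueError(
            f"could not place {cfg.n_foci} foci with separation "
            f"{cfg.min_focus_separation} inside the nucleus"
        )
    return np.array(placed) if placed else np.empty((0, 3))
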