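import numpy as np
import pytest

from rdpa import (
    KR_PATTERNS,
    assign_hits_to_idrs,
    call_rdpa,
    classify_idr_charge,
    count_foci,
    filter_valid_values,
    isoelectric_point,
    load_disorder_table,
    load_ptm_table,
    read_fasta,
    scan_sequence,
)
from rdpa.simulate import (
    ImageConfig,
    ProteomeConfig,
    PulldownConfig,
    generate_image_stack,
    generate_proteome,
    generate_pulldown_experiment,
)


class TestGenerateProteome:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a = generate_proteome(seed=11)
        b = generate_proteome(seed=11)
        da, db = tmp_path / "a", tmp_path / "b"
        a.write(da)
        b.write(db)
        for name in ("proteome.fasta", "disorder.tsv", "ptm_sites.tsv",
                     "idr_truth.tsv", "motif_truth.tsv"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_truth_tables_roundtrip_through_io(self, tmp_path):
        truth = generate_proteome(seed=3)
        truth.write(tmp_path)
        records = read_fasta(tmp_path / "proteome.fasta")
        assert {r.protein_id: r.sequence for r in records} == truth.proteome
        ann = load_disorder_table(tmp_path / "disorder.tsv", truth.proteome)
        for pid in truth.annotation.protein_ids:
            assert ann.predictors(pid) == truth.annotation.predictors(pid)
        sites = load_ptm_table(tmp_path / "ptm_sites.tsv", truth.proteome)
        assert set(sites) == set(truth.ptm_truth)

    def test_planted_motifs_recovered_by_scanner(self):
        cfg = ProteomeConfig(
            motifs_in_idr={"long": 50}, motifs_outside={},
            predictor_drop_rate=0.0, boundary_jitter=0,
        )
        truth = generate_proteome(cfg, seed=5)
        proteome = truth.proteome
        hits = []
        for pid in proteome:
            hits.extend(scan_sequence(proteome[pid], KR_PATTERNS["long"], pid))
        assert len(hits) >= 50
        annotated = assign_hits_to_idrs(hits, truth.annotation,
                                        k=cfg.n_predictors, min_len=20)
        planted = truth.motif_truth["long"]
        n_in = 0
        for pid, s, e, inside in planted:
            assert inside
            overlapping = [
                h for h in annotated
                if h.protein_id == pid and h.start <= e and s <= h.end
            ]
            assert overlapping
            n_in += any(h.in_idr for h in overlapping)
        assert n_in >= 50

    def test_planted_outside_motifs_not_in_idr(self):
        cfg = ProteomeConfig(motifs_in_idr={}, motifs_outside={"mid": 20})
        truth = generate_proteome(cfg, seed=6)
        for pid, s, e, inside in truth.motif_truth["mid"]:
            assert not inside
            for t in truth.idr_truth:
                if t.protein_id == pid:
                    assert e < t.start or s > t.end

    def test_charge_composition_controls_class(self, rng):
        truth = generate_proteome(ProteomeConfig(n_proteins=120,
                                                 motifs_in_idr={},
                                                 motifs_outside={}), seed=7)
        ok = total = 0
        for t in truth.idr_truth:
            seq = truth.proteome[t.protein_id][t.start - 1 : t.end]
            got = classify_idr_charge(isoelectric_point(seq))
            ok += got == t.charge_class
            total += 1
        assert total > 50
        assert ok / total >= 0.95

    def test_infeasible_motif_config_rejected(self):
        cfg = ProteomeConfig(idr_length_range=(20, 25),  # too short for margin
                             motifs_in_idr={"long": 5})
        with pytest.raises(ValueError, match="infeasible|could not plant"):
            generate_proteome(cfg, seed=0)

    def test_strict_mode_leaves_only_planted_hits(self):
        cfg = ProteomeConfig(n_proteins=40, motifs_in_idr={"long": 5},
                             motifs_outside={"long": 5},
                             strict_no_accidental=True)
        truth = generate_proteome(cfg, seed=8)
        spans = {
            (pid, s, e) for pat in truth.motif_truth.values() for pid, s, e, _ in pat
        }
        for pid, seq in truth.proteome.items():
            for pat_id, pat in KR_PATTERNS.items():
                for h in scan_sequence(seq, pat, pid):
                    assert any(
                        p == pid and h.start <= e and s <= h.end
                        for p, s, e in spans
                    )


class TestGeneratePulldown:
    def test_determinism(self):
        m1, t1 = generate_pulldown_experiment(seed=9)
        m2, t2 = generate_pulldown_experiment(seed=9)
        assert m1.data.equals(m2.data)
        assert t1.dsrna_plus == t2.dsrna_plus

    def test_truth_sets_disjoint_and_nested(self):
        _, truth = generate_pulldown_experiment(seed=1)
        assert truth.dsrna_plus <= truth.pip2_associated
        assert truth.dsrna_minus <= truth.pip2_associated
        assert not truth.dsrna_plus & truth.dsrna_minus

    def test_zero_effects_yield_null_calls(self):
        cfg = PulldownConfig(n_proteins=500, n_pip2=50, n_dsrna_plus=30,
                             n_dsrna_minus=5, effect_pip2=0.0, effect_rnase=0.0)
        m, _ = generate_pulldown_experiment(cfg, seed=10)
        call = call_rdpa(m, m, seed=10)
        assert len(call.pip2_associated) <= 10
        assert len(call.dsrna_plus) + len(call.dsrna_minus) <= 2

    def test_no_missingness_keeps_planted_rows(self):
        cfg = PulldownConfig(n_proteins=300, n_pip2=40, n_dsrna_plus=20,
                             n_dsrna_minus=5, mcar_rate=0.0,
                             mnar_midpoint=-100.0)  # logistic never fires
        m, truth = generate_pulldown_experiment(cfg, seed=11)
        assert m.n_missing() == 0
        kept = set(filter_valid_values(m).protein_ids)
        assert truth.pip2_associated <= kept


class TestGenerateImageStack:
    def test_determinism(self):
        a = generate_image_stack(seed=12)
        b = generate_image_stack(seed=12)
        assert np.array_equal(a.target, b.target)
        assert np.array_equal(a.foci_centers, b.foci_centers)

    def test_end_to_end_count_recovery(self):
        nuc = generate_image_stack(ImageConfig(n_foci=5), seed=13)
        count, _ = count_foci(nuc.target, nuc.mask)
        assert count == 5

    def test_centers_inside_mask(self):
        nuc = generate_image_stack(ImageConfig(n_foci=10), seed=14)
        for c in nuc.foci_centers:
            z, y, x = np.round(c).astype(int)
            assert nuc.mask[z, y, x]

    def test_infeasible_packing_rejected(self):
        cfg = ImageConfig(n_foci=500)
        with pytest.raises(ValueError, match="could not place"):
            generate_image_stack(cfg, seed=0)
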