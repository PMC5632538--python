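import numpy as np
import pytest

from cernet.core import Config, SequenceRecord
from cernet.targets import (
    correlation_matrix,
    extract_scan_region,
    pearson_r,
    scan_mirna_sites,
    screen_max_scores,
    trans_targets,
)

from _oracles import naive_scan
from conftest import make_matrix, make_record

RC_RNA_TO_DNA = str.maketrans("ACGU", "TGCA")


def random_mirna(rng, length=22, name="mir"):
    return SequenceRecord(name, "".join("ACGU"[i] for i in rng.integers(0, 4, length)), "RNA")


def random_region(rng, length=300, name="reg"):
    return SequenceRecord(name, "".join("ACGT"[i] for i in rng.integers(0, 4, length)), "DNA")


def plant(region_seq, mirna, pos):
    site = mirna.seq.translate(RC_RNA_TO_DNA)[::-1]
    return region_seq[:pos] + site + region_seq[pos + len(site):]


class TestPearson:
    def test_perfect_positive(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # sum(dx*dy)=102/9, sum(dx^2)=42/9, sum(dy^2)=258/9 -> 102/sqrt(10836)
        assert pearson_r([1, 2, 4], [2, 3, 9]) == pytest.approx(0.9799, abs=1e-4)

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson_r(x, y) == pytest.approx(pearson_r(y, x))
        assert pearson_r(2.5 * x + 1, y) == pytest.approx(pearson_r(x, y))
        assert pearson_r(-x, y) == pytest.approx(-pearson_r(x, y))

    def test_zero_variance_nan(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


class TestTransTargets:
    def test_identical_profile(self, cfg, rng):
        prof = rng.normal(size=12)
        lnc = make_matrix([prof], feature_ids=["lnc1"], kind="transformed")
        mrna = make_matrix([prof, rng.normal(size=12)], feature_ids=["g1", "g2"], kind="transformed")
        edges, _ = trans_targets(lnc, mrna, cfg)
        assert any(e.a_id == "lnc1" and e.b_id == "g1" and e.r == pytest.approx(1.0) for e in edges)

    def test_constant_feature_skipped(self, cfg):
        lnc = make_matrix([np.ones(12)], feature_ids=["lnc1"], kind="transformed")
        mrna = make_matrix([np.arange(12.0)], feature_ids=["g1"], kind="transformed")
        edges, skipped = trans_targets(lnc, mrna, cfg)
        assert edges == [] and skipped >= 1

    def test_matches_all_pairs_oracle(self, cfg, rng):
        lnc = make_matrix(rng.normal(size=(15, 12)), feature_ids=[f"l{i}" for i in range(15)], kind="transformed")
        mrna = make_matrix(rng.normal(size=(40, 12)), feature_ids=[f"g{i}" for i in range(40)], kind="transformed")
        relaxed = cfg.replace(r_trans=0.5)  # random data rarely hits 0.95
        edges, _ = trans_targets(lnc, mrna, relaxed)
        got = {(e.a_id, e.b_id): e.r for e in edges}
        expected = {}
        for i, l_id in enumerate(lnc.feature_ids):
            for j, g_id in enumerate(mrna.feature_ids):
                r = pearson_r(lnc.to_numpy()[i], mrna.to_numpy()[j])
                if r >= 0.5 or r <= -0.5:
                    expected[(l_id, g_id)] = r
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_too_few_samples(self, cfg):
        a = make_matrix([[1.0, 2.0]], sample_ids=["V1", "V2"], kind="transformed")
        with pytest.raises(ValueError, match="3"):
            trans_targets(a, a, cfg)


class TestScanRegion:
    def test_annotated_utr_returned(self, cfg):
        rec = make_record("t1")
        utr = {"t1": SequenceRecord("t1", "ACGT" * 60)}
        out = extract_scan_region(rec, utr, None, cfg)
        assert out.seq == "ACGT" * 60

    def test_plus_strand_fallback(self, cfg):
        chrom_seq = "".join("ACGT"[i % 4] for i in range(3000))
        genome = {"chr1": SequenceRecord("chr1", chrom_seq)}
        rec = make_record("t1", exon_spans=((100, 400),), attrs={"stop_pos": "400"})
        out = extract_scan_region(rec, {}, genome, cfg)
        assert out.seq == chrom_seq[400:1400]

    def test_minus_strand_reverse_complement(self, cfg, rng):
        chrom_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        genome = {"chr1": SequenceRecord("chr1", chrom_seq)}
        rec = make_record("t1", exon_spans=((1500, 1800),), strand="-", attrs={"stop_pos": "1500"})
        out = extract_scan_region(rec, {}, genome, cfg)
        expected = SequenceRecord("x", chrom_seq[500:1500]).reverse_complement().seq
        assert out.seq == expected

    def test_truncated_at_chrom_end_warns(self, cfg):
        genome = {"chr1": SequenceRecord("chr1", "ACGT" * 100)}
        rec = make_record("t1", exon_spans=((0, 100),), attrs={"stop_pos": "100"})
        with pytest.warns(UserWarning, match="truncated"):
            out = extract_scan_region(rec, {}, genome, cfg)
        assert len(out.seq) == 300

    def test_no_utr_no_stop_skipped(self, cfg):
        rec = make_record("t1")
        with pytest.warns(UserWarning, match="skipped"):
            assert extract_scan_region(rec, {}, {}, cfg) is None


class TestScanner:
    def test_planted_full_complement_found(self, cfg, rng):
        mir = random_mirna(rng, 22)
        region = SequenceRecord("r", plant(random_region(rng, 400).seq, mir, 150))
        sites = scan_mirna_sites(mir, region, cfg)
        hits = [s for s in sites if s.target_start == 150]
        assert hits, "planted site not recovered"
        assert hits[0].align_score == 22 * 5 + 7 * 5  # seed columns doubled
        assert hits[0].energy < -10

    def test_no_complementary_stretch(self, cfg):
        mir = SequenceRecord("m", "A" * 22, "RNA")  # binds poly-T only
        region = SequenceRecord("r", "A" * 300, "DNA")
        assert scan_mirna_sites(mir, region, cfg) == []

    def test_mirna_length_bounds(self, cfg, rng):
        with pytest.raises(ValueError, match="length"):
            scan_mirna_sites(random_mirna(rng, 10), random_region(rng), cfg)
        with pytest.raises(ValueError, match="length"):
            scan_mirna_sites(random_mirna(rng, 30), random_region(rng), cfg)

    def test_sites_never_overlap_and_pass_thresholds(self, cfg, rng):
        mir = random_mirna(rng, 22)
        seq = random_region(rng, 500).seq
        for pos in (10, 60, 200):  # several planted copies
            seq = plant(seq, mir, pos)
        sites = scan_mirna_sites(mir, SequenceRecord("r", seq), cfg)
        assert len(sites) >= 3
        spans = sorted((s.target_start, s.target_end) for s in sites)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 <= a2
        for s in sites:
            assert s.align_score > cfg.site_score_min
            assert s.energy < cfg.site_energy_max

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle_random(self, cfg, seed):
        rng = np.random.default_rng(seed)
        mir = random_mirna(rng, int(rng.integers(18, 27)))
        region = random_region(rng, int(rng.integers(100, 400)))
        got = [
            (s.target_start, s.target_end, s.align_score, round(s.energy, 9))
            for s in scan_mirna_sites(mir, region, cfg)
        ]
        expected = [
            (a, b, sc, round(e, 9))
            for a, b, sc, e in naive_scan(
                mir.seq, region.seq, cfg.site_score_min, cfg.site_energy_max
            )
        ]
        assert got == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_oracle_planted(self, cfg, seed):
        rng = np.random.default_rng(1000 + seed)
        mir = random_mirna(rng, int(rng.integers(22, 25)))
        seq = random_region(rng, 350).seq
        seq = plant(seq, mir, int(rng.integers(0, 300)))
        got = [
            (s.target_start, s.target_end, s.align_score, round(s.energy, 9))
            for s in scan_mirna_sites(mir, SequenceRecord("r", seq), cfg)
        ]
        expected = [
            (a, b, sc, round(e, 9))
            for a, b, sc, e in naive_scan(mir.seq, seq, cfg.site_score_min, cfg.site_energy_max)
        ]
        assert got == expected
        assert got  # at least the planted site

    def test_monotone_in_thresholds(self, cfg, rng):
        mir = random_mirna(rng, 23)
        seq = plant(random_region(rng, 400).seq, mir, 100)
        region = SequenceRecord("r", seq)
        base = {(s.target_start, s.target_end) for s in scan_mirna_sites(mir, region, cfg)}
        stricter_score = {
            (s.target_start, s.target_end)
            for s in scan_mirna_sites(mir, region, cfg.replace(site_score_min=150))
        }
        stricter_energy = {
            (s.target_start, s.target_end)
            for s in scan_mirna_sites(mir, region, cfg.replace(site_energy_max=-30))
        }
        assert stricter_score <= base
        assert stricter_energy <= base

    def test_screen_equals_per_pair_best(self, cfg, rng):
        mir = random_mirna(rng, 22)
        regions = [random_region(rng, int(rng.integers(50, 500)), f"r{i}") for i in range(30)]
        regions[7] = SequenceRecord("r7", plant(regions[7].seq, mir, 20))
        best = screen_max_scores(mir, regions)
        for k, reg in enumerate(regions):
            oracle = naive_scan(mir.seq, reg.seq, -1e9, 1e9)
            exp = max((s[2] for s in oracle), default=None)
            if exp is not None and exp > 0:
                assert best[k] == exp, reg.id

    def test_correlation_matrix_requires_shared_samples(self, rng):
        a = make_matrix(rng.normal(size=(2, 12)), kind="transformed")
        b = make_matrix(
            rng.normal(size=(2, 6)),
            sample_ids=["V1", "V2", "V3", "Q1", "Q2", "Q3"],
            kind="transformed",
        )
        with pytest.raises(ValueError, match="sample"):
            correlation_matrix(a, b)
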