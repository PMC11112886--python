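import math

import numpy as np
import pytest

import superbarcode as sb
from superbarcode.distances import matrix_from_codes

from conftest import (
    make_aln,
    oracle_gap_verdicts,
    oracle_k2p,
    oracle_raw_diff,
    random_aln,
    related_aln,
)


class TestK2P:
    def test_identical_is_zero(self):
        assert sb.k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_transition_closed_form(self):
        # one A->G change among 10 columns: P = 0.1, Q = 0
        d = sb.k2p_distance("AAAAAAAAAA", "GAAAAAAAAA")
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_matches_counting_oracle(self, rng):
        chars = np.array(list("ACGT"))
        for _ in range(50):
            a = "".join(chars[rng.integers(0, 4, 100)])
            # perturb a little so saturation cannot occur
            b = list(a)
            for i in rng.choice(100, size=8, replace=False):
                b[i] = chars[rng.integers(0, 4)]
            b = "".join(b)
            assert sb.k2p_distance(a, b) == pytest.approx(oracle_k2p(a, b), abs=1e-12)

    def test_complement_invariance(self):
        comp = str.maketrans("ACGT", "TGCA")
        a, b = "ACGTTGCAAC", "ACGTTGCAGC"
        assert sb.k2p_distance(a, b) == pytest.approx(
            sb.k2p_distance(a.translate(comp), b.translate(comp)), abs=1e-15
        )

    def test_exceeds_raw_p_distance(self, rng):
        # Jensen: the log correction can only inflate the observed proportion
        chars = np.array(list("ACGT"))
        a = "".join(chars[rng.integers(0, 4, 200)])
        b = list(a)
        for i in rng.choice(200, size=30, replace=False):
            b[i] = chars[rng.integers(0, 4)]
        b = "".join(b)
        p_dist = oracle_raw_diff(a, b) / 200
        assert sb.k2p_distance(a, b) > p_dist

    def test_saturation_raises(self):
        with pytest.raises(sb.SaturationError):
            sb.k2p_distance("AAAA", "GGGG")  # P = 1

    def test_no_comparable_columns_raises(self):
        with pytest.raises(sb.SaturationError):
            sb.k2p_distance("--NN", "AC--")


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        aln = make_aln(["ACGT", "ACGT", "ACGT"])
        dm = sb.distance_matrix(aln, "K2P")
        assert np.all(dm.values == 0.0)

    def test_raw_difference_single(self):
        aln = make_aln(["AAT", "AAC"])
        dm = sb.distance_matrix(aln, "raw_differences")
        assert dm.values[0, 1] == 1

    def test_matches_pairwise_loop_oracle(self, rng):
        aln = related_aln(rng, 6, 150, mut=0.1, gap_frac=0.03)
        rows = ["".join(r) for r in aln.matrix]
        dm_raw = sb.distance_matrix(aln, "raw_differences")
        dm_k2p = sb.distance_matrix(aln, "K2P")
        for i in range(6):
            for j in range(6):
                assert dm_raw.values[i, j] == oracle_raw_diff(rows[i], rows[j])
                if i != j:
                    assert dm_k2p.values[i, j] == pytest.approx(
                        oracle_k2p(rows[i], rows[j]), abs=1e-12
                    )
        assert np.array_equal(dm_raw.values, dm_raw.values.T)

    def test_saturated_pair_named(self):
        aln = make_aln(["AAAA", "GGGG", "AAAA"], ids=["u", "v", "w"])
        with pytest.raises(sb.SaturationError) as exc:
            sb.distance_matrix(aln, "K2P")
        assert exc.value.pair == ("u", "v")

    def test_complete_deletion_drops_gap_columns(self):
        aln = make_aln(["AC-T", "ACGT", "ACGA"])
        dm = sb.distance_matrix(aln, "raw_differences", deletion="complete")
        # column 2 (gap) removed; only the final column differs for row 2
        assert dm.values[0, 1] == 0
        assert dm.values[1, 2] == 1

    def test_weighted_counts_equal_materialized_resample(self, rng):
        aln = random_aln(rng, 5, 60, gap_frac=0.05)
        idx = rng.integers(0, 60, size=60)
        w = np.bincount(idx, minlength=60).astype(float)
        dm_w = matrix_from_codes(aln.codes, aln.sample_ids, "raw_differences", weights=w)
        resampled = make_aln(["".join(r) for r in aln.matrix[:, idx]])
        dm_m = sb.distance_matrix(resampled, "raw_differences")
        assert np.allclose(dm_w.values, dm_m.values)


class TestBarcodingGaps:
    def _clustered(self):
        # species A: two near-identical rows; B: two rows; C: singleton neighbor
        rows = [
            "AAAAAAAAAA" "AAAAAAAAAA",
            "AAAAAAAAAC" "AAAAAAAAAA",
            "GGGAAAAAAA" "AAAAAAAAAA",
            "GGGAAAAAAC" "AAAAAAAAAA",
            "GGGGGAAAAA" "AAAAAAAAAA",
        ]
        return make_aln(rows, ["A", "A", "B", "B", "C"])

    def test_gap_rule(self):
        aln = self._clustered()
        dm = sb.distance_matrix(aln, "K2P")
        out = {g.species: g for g in sb.barcoding_gaps(dm, aln.samples)}
        assert set(out) == {"A", "B"}  # singleton C not evaluated
        assert out["A"].has_gap and out["B"].has_gap
        assert out["A"].nearest_other == "B"

    def test_tie_is_failure(self):
        # intra and inter distances both exactly one difference in 10 sites
        rows = ["AAAAAAAAAA", "CAAAAAAAAA", "GAAAAAAAAA"]
        aln = make_aln(rows, ["X", "X", "Y"])
        dm = sb.distance_matrix(aln, "raw_differences")
        (g,) = sb.barcoding_gaps(dm, aln.samples)
        assert g.max_intra == g.min_inter == 1
        assert not g.has_gap

    def test_matches_exhaustive_oracle(self, rng):
        species = ["A", "A", "A", "B", "B", "C", "C", "D"]
        aln = related_aln(rng, 8, 120, mut=0.08, species=species)
        dm = sb.distance_matrix(aln, "K2P")
        dist = {
            (aln.sample_ids[i], aln.sample_ids[j]): dm.values[i, j]
            for i in range(8)
            for j in range(i + 1, 8)
        }
        species_of = {s.sample_id: s.species for s in aln.samples}
        expect = oracle_gap_verdicts(dist, species_of)
        got = {g.species: g.has_gap for g in sb.barcoding_gaps(dm, aln.samples)}
        assert got == expect

    def test_no_multi_species_warns_empty(self):
        aln = make_aln(["ACGT", "AGGT"], ["A", "B"])
        dm = sb.distance_matrix(aln, "K2P")
        with pytest.warns(UserWarning):
            assert sb.barcoding_gaps(dm, aln.samples) == []

    def test_relabeling_invariance(self, rng):
        aln = related_aln(rng, 6, 100, mut=0.08, species=["A", "A", "B", "B", "C", "C"])
        renamed = make_aln(
            ["".join(r) for r in aln.matrix],
            ["A", "A", "B", "B", "C", "C"],
            ids=[f"z{i}" for i in range(6)],
        )
        v1 = [(g.species, g.has_gap) for g in sb.barcoding_gaps(sb.distance_matrix(aln), aln.samples)]
        v2 = [(g.species, g.has_gap) for g in sb.barcoding_gaps(sb.distance_matrix(renamed), renamed.samples)]
        assert v1 == v2


class TestZeroK2PAndAMID:
    def test_well_separated_all_zero_counts(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAC", "GGGAAAAAAA", "GGGAAAAAAC"]
        aln = make_aln(rows, ["A", "A", "B", "B"])
        dm = sb.distance_matrix(aln, "K2P")
        assert sb.zero_k2p_stats(dm, aln.samples) == (0, 0)

    def test_shared_haplotype_counted_once(self):
        # A and B share one identical haplotype: 1 pair, both species zero-min
        rows = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAA", "CCCCAAAAAA"]
        aln = make_aln(rows, ["A", "A", "B", "B"])
        dm = sb.distance_matrix(aln, "K2P")
        zero_multi, zero_pairs = sb.zero_k2p_stats(dm, aln.samples)
        assert zero_pairs == 1
        assert zero_multi == 2  # both A and B have a zero interspecific minimum

    def test_singletons_participate_in_pairs(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAA"]
        aln = make_aln(rows, ["A", "B"])  # two singletons, identical
        dm = sb.distance_matrix(aln, "K2P")
        assert sb.zero_k2p_stats(dm, aln.samples) == (0, 1)

    def test_matches_bruteforce_pair_enumeration(self, rng):
        species = ["A", "A", "B", "B", "C", "D", "D", "E"]
        aln = related_aln(rng, 8, 30, mut=0.1)
        mat = aln.matrix.copy()
        mat[2] = mat[0]  # plant shared haplotype A~B
        mat[7] = mat[4]  # plant shared haplotype C~E
        aln = make_aln(["".join(r) for r in mat], species)
        dm = sb.distance_matrix(aln, "K2P")
        sp_names = sorted(set(species))
        pairs = 0
        for i, a in enumerate(sp_names):
            for b in sp_names[i + 1 :]:
                ra = [k for k, s in enumerate(species) if s == a]
                rb = [k for k, s in enumerate(species) if s == b]
                if min(dm.values[x, y] for x in ra for y in rb) == 0.0:
                    pairs += 1
        assert sb.zero_k2p_stats(dm, aln.samples)[1] == pairs

    def test_amid_uniform(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAA", "CCCCCAAAAA", "CCCCCAAAAA"]
        aln = make_aln(rows, ["A", "A", "B", "B"])
        dm = sb.distance_matrix(aln, "raw_differences")
        assert sb.amid(dm, aln.samples) == (5.0, 5.0, 5.0)

    def test_amid_mean_and_range(self):
        # A's minimum interspecific difference is 2 (to singleton C),
        # B's is 5 (to A): mean 3.5, range (2, 5)
        rows = [
            "AAAAAAAAAA",
            "AAAAAAAAAA",
            "GGGGGAAAAA",
            "GGGGGAAAAA",
            "CCAAAAAAAA",
        ]
        aln = make_aln(rows, ["A", "A", "B", "B", "C"])
        dm = sb.distance_matrix(aln, "raw_differences")
        assert sb.amid(dm, aln.samples) == (3.5, 2.0, 5.0)

    def test_amid_requires_raw_model(self):
        aln = make_aln(["ACGT", "ACGT"], ["A", "A"])
        dm = sb.distance_matrix(aln, "K2P")
        with pytest.raises(sb.AlignmentError):
            sb.amid(dm, aln.samples)


class TestRegression:
    def test_perfect_anticorrelation(self):
        pts = [(100.0, 0), (90.0, 1), (80.0, 2), (70.0, 3)]
        slope, r, p = sb.resolution_vs_zero_k2p(pts)
        assert r == pytest.approx(-1.0)
        assert slope == pytest.approx(-10.0)

    def test_constant_resolution(self):
        slope, r, p = sb.resolution_vs_zero_k2p([(80.0, 0), (80.0, 2), (80.0, 5)])
        assert slope == 0.0 and r == 0.0

    def test_zero_predictor_variance_errors(self):
        with pytest.raises(sb.AlignmentError):
            sb.resolution_vs_zero_k2p([(90.0, 1), (80.0, 1), (70.0, 1)])

    def test_planted_negative_trend_recovered(self, rng):
        zk = np.arange(10)
        res = 95 - 4 * zk + rng.normal(0, 2, size=10)
        slope, r, p = sb.resolution_vs_zero_k2p(list(zip(res, zk)))
        assert slope < 0 and r < -0.9 and p < 0.01


def test_phylip_export_lower_triangle(tmp_path):
    aln = make_aln(["AAT", "AAC", "ACC"], ids=["u", "v", "w"])
    dm = sb.distance_matrix(aln, "raw_differences")
    p = tmp_path / "dm.phy"
    dm.write_phylip(p)
    lines = p.read_text().splitlines()
    assert lines[0] == "3"
    assert lines[1] == "u"
    assert lines[2].split("\t") == ["v", "1"]
    assert lines[3].split("\t") == ["w", "2", "1"]
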