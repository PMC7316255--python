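"""Similarity, clustering, ordination, diversity, AMOVA and Mantel —
each checked against an independent brute-force or library oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average as scipy_average, cophenet
from scipy.spatial.distance import squareform

from msaptools.diversity import (
    amova,
    diversity_indices,
    mantel,
    pcoa,
    sm_similarity,
    similarity_to_distance,
    upgma,
    upgma_tree,
)
from msaptools.io import MISSING
from msaptools.states import BinaryRecodedMatrix


def _brm(values, tag="MSL-methylation"):
    arr = np.asarray(values, dtype=np.int8)
    return BinaryRecodedMatrix(
        [f"S{i}" for i in range(arr.shape[0])],
        [f"L{j}" for j in range(arr.shape[1])],
        arr,
        tag,
    )


# ---------------------------------------------------------------------------
# Simple matching
# ---------------------------------------------------------------------------

class TestSimilarity:
    def test_identical_samples_similarity_one(self):
        m = _brm([[1, 0, 1], [1, 0, 1]])
        assert sm_similarity(m).iloc[0, 1] == pytest.approx(1.0)

    def test_half_matching(self):
        m = _brm([[1, 1, 0, 0], [1, 0, 0, 1]])
        assert sm_similarity(m).iloc[0, 1] == pytest.approx(0.5)

    def test_complementary_vectors_zero(self):
        m = _brm([[1, 0, 1], [0, 1, 0]])
        assert sm_similarity(m).iloc[0, 1] == pytest.approx(0.0)

    def test_missing_excluded_pairwise_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.integers(0, 2, (6, 30)).astype(np.int8)
        v[rng.random(v.shape) < 0.2] = MISSING
        m = _brm(v)
        sim = sm_similarity(m)
        for i in range(6):
            for j in range(6):
                both = (v[i] != MISSING) & (v[j] != MISSING)
                if both.sum() == 0:
                    assert np.isnan(sim.iloc[i, j])
                else:
                    expected = (v[i][both] == v[j][both]).mean()
                    assert sim.iloc[i, j] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def _sim_from_dist(d, ids):
    return pd.DataFrame(1.0 - d, index=ids, columns=ids)


class TestUPGMA:
    def test_three_leaf_hand_case(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]]) / 10.0
        nwk = upgma(_sim_from_dist(d, list("ABC")))
        tree = upgma_tree(_sim_from_dist(d, list("ABC")))
        # A and B merge at height 0.1, C joins at 0.2
        tips = {t.name: t for t in tree.tips()}
        assert tree.find("A").length == pytest.approx(0.1)
        assert nwk.count("(") == 2
        assert tips["A"].distance(tips["B"]) == pytest.approx(0.2)
        assert tips["A"].distance(tips["C"]) == pytest.approx(0.4)

    def test_two_samples_cherry_at_half_distance(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        tree = upgma_tree(_sim_from_dist(d, ["A", "B"]))
        assert tree.find("A").length == pytest.approx(0.15)

    @pytest.mark.parametrize("seed", range(30))
    def test_cophenetic_distances_match_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        coords = rng.normal(size=(n, 3))
        d = np.round(np.linalg.norm(coords[:, None] - coords[None], axis=2), 6)
        d = d / (d.max() + 1.0)  # keep 1-d a valid similarity
        ids = [f"S{i}" for i in range(n)]
        tree = upgma_tree(_sim_from_dist(d, ids))
        tips = {t.name: t for t in tree.tips()}
        coph = squareform(cophenet(scipy_average(squareform(d))))
        for i in range(n):
            for j in range(i + 1, n):
                assert tips[ids[i]].distance(tips[ids[j]]) == pytest.approx(
                    coph[i, j], abs=1e-6
                )

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(99)
        n = 10
        d = squareform(rng.uniform(0.1, 0.9, n * (n - 1) // 2))
        tree = upgma_tree(_sim_from_dist(d, [f"S{i}" for i in range(n)]))
        # depth of every internal node >= depth of its children's subtrees
        def height(node):
            return max((t.distance(node) for t in node.tips()), default=0.0)

        for node in tree.non_tips(include_self=True):
            for child in node.children:
                assert height(node) >= height(child) - 1e-9

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[1.0, 0.2], [0.6, 1.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            upgma(bad)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPCoA:
    def test_equidistant_triplet_two_equal_eigenvalues(self):
        d = np.full((3, 3), 0.4)
        np.fill_diagonal(d, 0.0)
        res = pcoa(_sim_from_dist(d, list("ABC")))
        ev = np.sort(res.eigvals.to_numpy())[::-1]
        assert ev[0] == pytest.approx(ev[1])

    def test_coordinates_reproduce_euclidean_distances(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(6, 4))
        d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        d = d / (2 * d.max())
        res = pcoa(_sim_from_dist(d, [f"S{i}" for i in range(6)]))
        emb = res.samples.to_numpy()
        d_emb = np.linalg.norm(emb[:, None] - emb[None], axis=2)
        assert np.allclose(d_emb, d, atol=1e-8)

    def test_explained_fractions_bounded(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 2, (8, 40)).astype(np.int8)
        res = pcoa(sm_similarity(_brm(v)))
        assert res.proportion_explained.sum() <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

class TestDiversity:
    @pytest.mark.parametrize(
        "p,ne,he,i",
        [
            (0.5, 2.0, 0.5, np.log(2)),
            (1.0, 1.0, 0.0, 0.0),
            (0.2, 1 / 0.68, 0.32, -(0.2 * np.log(0.2) + 0.8 * np.log(0.8))),
        ],
    )
    def test_closed_forms_single_locus(self, p, ne, he, i):
        n = 10
        ones = int(round(p * n))
        col = np.array([[1]] * ones + [[0]] * (n - ones), dtype=np.int8)
        m = _brm(col)
        t = diversity_indices(m, dict.fromkeys(m.sample_ids, "G"))
        assert t.loc["G", "ne"] == pytest.approx(ne)
        assert t.loc["G", "he"] == pytest.approx(he)
        assert t.loc["G", "i"] == pytest.approx(i)

    def test_he_equals_one_minus_inverse_ne_per_locus(self):
        rng = np.random.default_rng(11)
        v = rng.integers(0, 2, (8, 50)).astype(np.int8)
        p = v.mean(axis=0)
        ne = 1 / (p**2 + (1 - p) ** 2)
        he = 1 - p**2 - (1 - p) ** 2
        assert np.allclose(he, 1 - 1 / ne)

    def test_monomorphic_group(self):
        m = _brm(np.ones((3, 5), dtype=np.int8))
        t = diversity_indices(m, dict.fromkeys(m.sample_ids, "G"))
        row = t.loc["G"]
        assert (row["ppl"], row["ne"], row["i"], row["he"]) == (0.0, 1.0, 0.0, 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(21)
        v = rng.integers(0, 2, (10, 40)).astype(np.int8)
        groups = {f"S{i}": ("A" if i < 5 else "B") for i in range(10)}
        t = diversity_indices(_brm(v), groups)
        for grp, sl in (("A", slice(0, 5)), ("B", slice(5, 10))):
            sub = v[sl]
            nes, hes, shs, poly = [], [], [], 0
            for j in range(40):
                p = sub[:, j].mean()
                q = 1 - p
                nes.append(1 / (p * p + q * q))
                hes.append(1 - p * p - q * q)
                shs.append(-(p * np.log(p) if p > 0 else 0) - (q * np.log(q) if q > 0 else 0))
                poly += 0 < p < 1
            assert t.loc[grp, "ne"] == pytest.approx(np.mean(nes))
            assert t.loc[grp, "he"] == pytest.approx(np.mean(hes))
            assert t.loc[grp, "i"] == pytest.approx(np.mean(shs))
            assert t.loc[grp, "ppl"] == pytest.approx(100 * poly / 40)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_oracle(x, labels):
    """Independent AMOVA from raw vectors via centroid sums of squares."""
    n = len(labels)
    groups = sorted(set(labels))
    grand = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_within = 0.0
    sizes = []
    for g in groups:
        sub = x[[i for i, l in enumerate(labels) if l == g]]
        sizes.append(len(sub))
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    ss_among = ss_total - ss_within
    g = len(groups)
    ms_a, ms_w = ss_among / (g - 1), ss_within / (n - g)
    n0 = (n - sum(s * s for s in sizes) / n) / (g - 1)
    va, vw = (ms_a - ms_w) / n0, ms_w
    return ss_among, ss_within, va, vw, va / (va + vw)


class TestAMOVA:
    def test_disjoint_profiles_phi_one(self):
        x = np.vstack([np.tile([1, 0], (4, 5)), np.tile([0, 1], (4, 5))]).astype(np.int8)
        groups = {f"S{i}": ("A" if i < 4 else "B") for i in range(8)}
        res = amova(_brm(x), groups, n_permutations=99, seed=0)
        assert res.phi_pt == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.p_value <= 0.05

    def test_random_labels_phi_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, (20, 60)).astype(np.int8)
        groups = {f"S{i}": ("A" if i % 2 else "B") for i in range(20)}
        res = amova(_brm(x), groups, n_permutations=199, seed=1)
        assert abs(res.phi_pt) < 0.1
        assert res.p_value > 0.05

    @pytest.mark.parametrize("seed", range(20))
    def test_components_match_centroid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        x = rng.integers(0, 2, (n, 25)).astype(np.int8)
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        groups = {f"S{i}": labels[i] for i in range(n)}
        res = amova(_brm(x), groups, n_permutations=0, seed=0)
        ss_a, ss_w, va, vw, phi = _amova_oracle(x.astype(float), labels)
        assert res.ss_among == pytest.approx(ss_a)
        assert res.ss_within == pytest.approx(ss_w)
        assert res.var_among == pytest.approx(va)
        assert res.var_within == pytest.approx(vw)
        assert res.phi_pt == pytest.approx(phi)

    def test_percentages_sum_to_100(self, small_dataset):
        from msaptools.states import build_state_matrix, partition_loci, recode_msl

        _, pair, meta, _ = small_dataset
        states = build_state_matrix(pair)
        msl, _ = recode_msl(states, partition_loci(states))
        groups = {m.sample_id: m.group for m in meta if not m.is_reference}
        keep = [i for i, s in enumerate(msl.sample_ids) if s in groups]
        sub = BinaryRecodedMatrix(
            [msl.sample_ids[i] for i in keep], msl.locus_ids, msl.values[keep],
            msl.semantics_tag,
        )
        res = amova(sub, groups, n_permutations=49, seed=0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_p_invariant_to_distance_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, (12, 30)).astype(np.int8)
        groups = {f"S{i}": ("A" if i < 6 else "B") for i in range(12)}
        res1 = amova(_brm(x), groups, n_permutations=99, seed=3)
        # duplicating every locus doubles all squared distances
        res2 = amova(_brm(np.hstack([x, x])), groups, n_permutations=99, seed=3)
        assert res1.p_value == res2.p_value
        assert res1.phi_pt == pytest.approx(res2.phi_pt)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _rand_dist(rng, n):
    d = squareform(rng.uniform(0.1, 1.0, n * (n - 1) // 2))
    ids = [f"S{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestMantel:
    def test_self_correlation_one(self):
        d = _rand_dist(np.random.default_rng(0), 8)
        res = mantel(d, d, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_affine_invariance(self):
        d = _rand_dist(np.random.default_rng(1), 8)
        res = mantel(d, 3.0 * d + 0.2, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_null_r_small_and_p_roughly_uniform(self):
        rng = np.random.default_rng(2)
        rs, ps = [], []
        for k in range(15):
            d1, d2 = _rand_dist(rng, 20), _rand_dist(rng, 20)
            res = mantel(d1, d2, n_permutations=99, seed=k)
            rs.append(res.r)
            ps.append(res.p_value)
        assert np.mean(np.abs(rs)) < 0.15
        assert 0.2 < np.mean(ps) < 0.8

    def test_size_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            mantel(_rand_dist(rng, 5), _rand_dist(rng, 6))
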