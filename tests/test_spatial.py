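import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from assemblage.distance import DistanceMatrix
from assemblage.metadata import SampleMetadata
from assemblage.spatial import (
    EARTH_RADIUS_KM,
    distance_decay,
    env_distance,
    geographic_distance,
    mantel,
    partial_mantel,
    pcnm,
)


def meta_from_coords(lons, lats, **env):
    n = len(lons)
    frame = pd.DataFrame({
        "habitat": ["x"] * n,
        "longitude": lons,
        "latitude": lats,
        **env,
    }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    return SampleMetadata(frame)


class TestGeographicDistance:
    def test_identical_coordinates_zero(self):
        m = meta_from_coords([10.0, 10.0], [20.0, 20.0])
        assert geographic_distance(m).values[0, 1] == pytest.approx(0.0)

    def test_one_degree_at_equator(self):
        m = meta_from_coords([0.0, 1.0], [0.0, 0.0])
        expected = 2 * EARTH_RADIUS_KM * math.asin(math.sin(math.radians(0.5)))
        d = geographic_distance(m).values[0, 1]
        assert d == pytest.approx(expected, rel=1e-12)
        assert d == pytest.approx(111.195, abs=1e-3)

    def test_antipodal(self):
        m = meta_from_coords([0.0, 180.0], [0.0, 0.0])
        assert geographic_distance(m).values[0, 1] == pytest.approx(
            math.pi * EARTH_RADIUS_KM, rel=1e-9)


class TestEnvDistance:
    def test_identical_rows_zero(self):
        m = meta_from_coords([0, 1], [0, 0], TN=[2.0, 2.0], pH=[8.0, 8.0])
        assert env_distance(m).values[0, 1] == pytest.approx(0.0)

    def test_ph_not_sqrted(self):
        m = meta_from_coords([0, 1], [0, 0], pH=[7.0, 9.0])
        d = env_distance(m, variables=["pH"], standardize=False)
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_tn_sqrted(self):
        m = meta_from_coords([0, 1], [0, 0], TN=[1.0, 4.0])
        d = env_distance(m, variables=["TN"], standardize=False)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_negative_value_error(self):
        m = meta_from_coords([0, 1], [0, 0], TN=[-1.0, 4.0])
        with pytest.raises(ValueError, match="TN"):
            env_distance(m, variables=["TN"])

    def test_missing_value_error(self):
        m = meta_from_coords([0, 1], [0, 0], TN=[np.nan, 4.0])
        with pytest.raises(ValueError):
            env_distance(m, variables=["TN"])


def rand_dm(rng, n, labels=None):
    vals = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
    return DistanceMatrix(vals, labels or [f"s{i}" for i in range(n)])


def mantel_oracle_exact(a_vals, b_vals, method="spearman", tail="upper"):
    """Full-enumeration Mantel p, written independently of the module."""
    n = a_vals.shape[0]
    a = squareform(a_vals, checks=False)
    b_sq = b_vals

    def corr(x, y):
        if method == "spearman":
            x, y = rankdata(x), rankdata(y)
        return np.corrcoef(x, y)[0, 1]

    r_obs = corr(a, squareform(b_sq, checks=False))
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        p = list(perm)
        r_p = corr(a, squareform(b_sq[np.ix_(p, p)], checks=False))
        if tail == "upper" and r_p >= r_obs - 1e-12:
            hits += 1
        elif tail == "lower" and r_p <= r_obs + 1e-12:
            hits += 1
        elif tail == "two" and abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, hits / total


class TestMantel:
    def test_self_correlation_one(self):
        dm = rand_dm(np.random.default_rng(0), 6)
        res = mantel(dm, dm, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_rank_reversed_minus_one(self):
        rng = np.random.default_rng(1)
        dm = rand_dm(rng, 6)
        flipped = DistanceMatrix(
            np.where(np.eye(6, dtype=bool), 0.0, 2.0 - dm.values), list(dm.labels))
        res = mantel(dm, flipped, n_permutations=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    @pytest.mark.parametrize("tail", ["upper", "lower", "two"])
    def test_exact_enumeration_matches_oracle(self, method, tail):
        rng = np.random.default_rng(2)
        dmA = rand_dm(rng, 5)
        dmB = rand_dm(rng, 5)
        res = mantel(dmA, dmB, method=method, tail=tail, exact=True)
        r_oracle, p_oracle = mantel_oracle_exact(dmA.values, dmB.values, method, tail)
        assert res.n_permutations == 120
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-15)

    def test_symmetry_of_r(self):
        rng = np.random.default_rng(3)
        dmA, dmB = rand_dm(rng, 7), rand_dm(rng, 7)
        assert mantel(dmA, dmB, n_permutations=0 + 9, seed=0).r == pytest.approx(
            mantel(dmB, dmA, n_permutations=9, seed=0).r)

    def test_label_mismatch_error(self):
        rng = np.random.default_rng(4)
        dmA = rand_dm(rng, 5)
        dmB = rand_dm(rng, 5, labels=[f"t{i}" for i in range(5)])
        with pytest.raises(ValueError, match="label"):
            mantel(dmA, dmB)

    def test_label_order_irrelevant(self):
        rng = np.random.default_rng(5)
        dmA, dmB = rand_dm(rng, 6), rand_dm(rng, 6)
        shuffled = dmB.reorder(["s3", "s0", "s5", "s1", "s4", "s2"])
        assert mantel(dmA, dmB, n_permutations=9, seed=0).r == pytest.approx(
            mantel(dmA, shuffled, n_permutations=9, seed=0).r)


class TestPartialMantel:
    def test_self_conditioning_zero(self):
        rng = np.random.default_rng(0)
        dmA = rand_dm(rng, 8)
        dmB = rand_dm(rng, 8)
        res = partial_mantel(dmA, dmB, dmA, method="pearson", n_permutations=49, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-10)

    def test_uncorrelated_conditioner_near_marginal(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 3))
        dmA = DistanceMatrix(squareform(pdist(base)), [f"s{i}" for i in range(30)])
        dmB = DistanceMatrix(squareform(pdist(base + rng.normal(scale=0.2, size=base.shape))),
                             list(dmA.labels))
        dmC = rand_dm(rng, 30, labels=list(dmA.labels))
        r_ab = mantel(dmA, dmB, n_permutations=9, seed=0).r
        r_partial = partial_mantel(dmA, dmB, dmC, n_permutations=9, seed=0).r
        assert abs(r_partial - r_ab) < 0.1

    def test_closed_form_four_sites(self):
        rng = np.random.default_rng(2)
        dmA, dmB, dmC = (rand_dm(rng, 4) for _ in range(3))
        res = partial_mantel(dmA, dmB, dmC, method="pearson",
                             n_permutations=9, seed=0)
        a = squareform(dmA.values, checks=False)
        b = squareform(dmB.values, checks=False)
        c = squareform(dmC.values, checks=False)
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        expected = (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_conditioning_on_b_itself_is_zero(self):
        # |r_BC| = 1 forces the numerator to vanish as well (b affine in c
        # implies r_AC = r_AB), so the partial r is 0 by construction
        rng = np.random.default_rng(3)
        dmA = rand_dm(rng, 5)
        dmB = rand_dm(rng, 5)
        res = partial_mantel(dmA, dmB, dmB, method="pearson")
        assert res.r == pytest.approx(0.0)
        assert res.p_value == 1.0


class TestDistanceDecay:
    def test_constant_similarity_warns(self):
        n = 6
        comm = DistanceMatrix(0.5 * (np.ones((n, n)) - np.eye(n)),
                              [f"s{i}" for i in range(n)])
        geo = rand_dm(np.random.default_rng(0), n)
        with pytest.warns(UserWarning, match="zero variance"):
            res = distance_decay(comm, geo)
        assert math.isnan(res.mantel.r)

    def test_exponential_decay_detected(self):
        rng = np.random.default_rng(1)
        n = 12
        x = np.sort(rng.uniform(0, 50, n))
        geo_vals = np.abs(x[:, None] - x[None, :])
        sim = np.exp(-geo_vals / 20) + rng.normal(scale=0.01, size=(n, n))
        sim = (sim + sim.T) / 2
        dis = np.clip(1 - sim, 0, 1)
        np.fill_diagonal(dis, 0)
        labels = [f"s{i}" for i in range(n)]
        res = distance_decay(DistanceMatrix(dis, labels),
                             DistanceMatrix(geo_vals, labels),
                             n_permutations=999, seed=0)
        assert res.mantel.r < 0
        assert res.mantel.p_value < 0.05
        assert res.slope < 0


class TestPcnm:
    def make_transect(self, n=10):
        x = np.arange(float(n))
        d = np.abs(x[:, None] - x[None, :])
        return DistanceMatrix(d, [f"s{i}" for i in range(n)])

    def test_truncation_is_largest_nn_gap(self):
        dm = self.make_transect()
        assert pcnm(dm).truncation_distance == pytest.approx(1.0)
        # irregular transect: MST edge = largest nearest-neighbour gap
        x = np.array([0.0, 1.0, 2.0, 5.5, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        dm2 = DistanceMatrix(d, list("abcde"))
        assert pcnm(dm2).truncation_distance == pytest.approx(3.5)

    def test_orthonormal_eigenvectors(self):
        basis = pcnm(self.make_transect())
        gram = basis.eigenvectors.T @ basis.eigenvectors
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_positive_descending_eigenvalues(self):
        basis = pcnm(self.make_transect())
        assert (basis.eigenvalues > 0).all()
        assert (np.diff(basis.eigenvalues) <= 1e-12).all()

    def test_leading_eigenvector_sinusoidal(self):
        # on a regular transect the leading eigenvector follows one full
        # sine period over site order (verified against vegan::pcnm)
        n = 10
        basis = pcnm(self.make_transect(n))
        x = np.arange(n)
        wave = np.sin(2 * np.pi * (x + 0.5) / n)
        r = np.corrcoef(basis.eigenvectors[:, 0], wave)[0, 1]
        assert abs(r) > 0.95

    def test_relabel_invariance_up_to_sign(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(9, 2))
        d = squareform(pdist(pts))
        labels = [f"s{i}" for i in range(9)]
        basis = pcnm(DistanceMatrix(d, labels))
        perm = rng.permutation(9)
        basis_p = pcnm(DistanceMatrix(d[np.ix_(perm, perm)],
                                      [labels[i] for i in perm]))
        assert np.allclose(basis.eigenvalues, basis_p.eigenvalues, atol=1e-9)
        for k in range(basis.eigenvectors.shape[1]):
            v = basis.eigenvectors[perm, k]
            w = basis_p.eigenvectors[:, k]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-6

    def test_all_zero_distances_error(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        with pytest.raises(ValueError):
            pcnm(dm)
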