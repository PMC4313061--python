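import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domainflux.correlation import (
    CorrelationResult,
    apply_filters,
    block_summary,
    compute_rmsf,
    generalized_matrix,
    generalized_pair,
    knn_mutual_information,
    map_to_structure,
    pearson_matrix,
)
from domainflux.model_io import StructureModel, SubdomainPartition, Trajectory, read_bfactors
from domainflux.synthetic import (
    CorrelationBlock,
    PlantedMotion,
    TrimerSpec,
    build_trimer,
    generate_fluctuation_trajectory,
)


def brute_force_rmsf(coords):
    """Two-pass per-bead RMSF oracle."""
    mean = coords.mean(axis=0)
    out = np.zeros(coords.shape[1])
    for i in range(coords.shape[1]):
        acc = 0.0
        for f in range(coords.shape[0]):
            d = coords[f, i] - mean[i]
            acc += d @ d
        out[i] = np.sqrt(acc / coords.shape[0])
    return out


def brute_force_pearson(coords):
    """Double-loop displacement-vector Pearson oracle."""
    d = coords - coords.mean(axis=0)
    n = coords.shape[1]
    mat = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = np.mean([d[f, i] @ d[f, j] for f in range(coords.shape[0])])
            vi = np.mean([d[f, i] @ d[f, i] for f in range(coords.shape[0])])
            vj = np.mean([d[f, j] @ d[f, j] for f in range(coords.shape[0])])
            mat[i, j] = num / np.sqrt(vi * vj)
    return mat


def make_traj(coords):
    return Trajectory(np.asarray(coords, float), dt=1.0)


class TestRmsf:
    def test_static_zero(self):
        traj = make_traj(np.zeros((5, 4, 3)))
        np.testing.assert_allclose(compute_rmsf(traj, align=False), 0.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            compute_rmsf(make_traj(np.zeros((1, 4, 3))))

    def test_isotropic_gaussian_closed_form(self):
        # sigma = 1 per axis -> RMSF = sqrt(3)
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5000, 6, 3))
        rmsf = compute_rmsf(make_traj(coords), align=False)
        np.testing.assert_allclose(rmsf, np.sqrt(3.0), atol=0.05)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=2.0, size=(50, 10, 3))
        rmsf = compute_rmsf(make_traj(coords), align=False)
        np.testing.assert_allclose(rmsf, brute_force_rmsf(coords), atol=1e-10)


class TestPearson:
    def test_identical_beads(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(100, 1, 3))
        coords = np.concatenate([base, base, rng.normal(size=(100, 1, 3))], axis=1)
        res = pearson_matrix(make_traj(coords), align=False)
        assert res.matrix[0, 1] == pytest.approx(1.0)

    def test_mirror_bead(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(100, 1, 3))
        coords = np.concatenate([base, -base], axis=1)
        res = pearson_matrix(make_traj(coords), align=False)
        assert res.matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_bruteforce_500_frames(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(500, 20, 3)).cumsum(axis=0) * 0.1
        res = pearson_matrix(make_traj(coords), align=False)
        expect = brute_force_pearson(coords)
        assert np.abs(res.matrix - expect).max() < 1e-10

    def test_zero_variance_bead_flagged(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(50, 3, 3))
        coords[:, 1, :] = 1.0
        res = pearson_matrix(make_traj(coords), align=False)
        assert np.isnan(res.matrix[1, :]).all()
        assert np.isfinite(res.matrix[0, 2])

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(200, 12, 3))
        res = pearson_matrix(make_traj(coords), align=False)
        np.testing.assert_allclose(res.matrix, res.matrix.T, atol=1e-14)
        assert np.nanmax(np.abs(res.matrix)) <= 1.0 + 1e-12
        np.testing.assert_allclose(np.diag(res.matrix), 1.0)


class TestGeneralized:
    def test_identical_beads_saturate(self):
        # the KSG estimate saturates at psi(k) + psi(n) - 2 psi(k+1),
        # which crosses rho_gen = 0.99 around n = 3000 for k = 6
        rng = np.random.default_rng(7)
        base = rng.normal(size=(4000, 1, 3))
        coords = np.concatenate([base, base.copy()], axis=1)
        res = generalized_matrix(make_traj(coords), align=False, seed=0)
        assert res.matrix[0, 1] >= 0.99

    def test_independent_beads_near_zero(self):
        # I = 0 limit; averaged over seeds the estimate stays small
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(2000, 3))
            y = rng.normal(size=(2000, 3))
            vals.append(generalized_pair(x, y, k=6, rng=rng))
        assert np.mean(vals) < 0.1

    @pytest.mark.parametrize("r", [0.3, 0.6, 0.9])
    def test_gaussian_recovery(self, r):
        # closed form: I = -(3/2) ln(1 - r^2)  =>  rho_gen = |r|
        vals = []
        for seed in range(8):
            rng = np.random.default_rng(1000 + seed)
            g = rng.normal(size=(2000, 3))
            x = g
            y = r * g + np.sqrt(1 - r * r) * rng.normal(size=(2000, 3))
            vals.append(generalized_pair(x, y, k=6, rng=rng))
        assert abs(np.mean(vals) - r) < 0.05

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(300, 4, 3))
        r1 = generalized_matrix(make_traj(coords), align=False, seed=42)
        r2 = generalized_matrix(make_traj(coords), align=False, seed=42)
        np.testing.assert_array_equal(r1.matrix, r2.matrix)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            generalized_matrix(make_traj(np.zeros((5, 3, 3))), knn_k=6)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(200, 6, 3))
        res = generalized_matrix(make_traj(coords), align=False, seed=0)
        assert res.matrix.min() >= 0.0
        assert res.matrix.max() <= 1.0
        np.testing.assert_allclose(res.matrix, res.matrix.T, atol=1e-14)

    def test_mi_value_on_correlated_gaussian(self):
        # KSG vs analytic bivariate-Gaussian MI: I = -(1/2) ln(1 - r^2)
        r = 0.8
        rng = np.random.default_rng(10)
        g = rng.normal(size=5000)
        x = g[:, None]
        y = (r * g + np.sqrt(1 - r * r) * rng.normal(size=5000))[:, None]
        mi = knn_mutual_information(x + rng.normal(0, 1e-10, x.shape),
                                    y + rng.normal(0, 1e-10, y.shape), k=6)
        assert mi == pytest.approx(-0.5 * np.log(1 - r * r), abs=0.05)


class TestFilters:
    def _result(self, matrix, rmsf):
        n = len(rmsf)
        return CorrelationResult(np.asarray(matrix, float), "pearson",
                                 np.asarray(rmsf, float), np.arange(n))

    def test_all_below_cutoff_empty(self):
        m = np.eye(4) + 0.3 - 0.3 * np.eye(4)
        res = self._result(np.eye(4) * 0.7 + 0.3, rmsf=[2.0] * 4)
        res.matrix[0, 1] = res.matrix[1, 0] = 0.4
        res.matrix[2, 3] = res.matrix[3, 2] = -0.45
        pairs = apply_filters(res, corr_threshold=0.5)
        assert len(pairs) == 0

    def test_low_rmsf_member_excluded(self):
        # one member at 1.4 A RMSF: pair dropped under the both-members rule
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        res = self._result(m, rmsf=[1.4, 2.0, 2.0])
        assert len(apply_filters(res, rmsf_threshold=1.5)) == 0
        either = apply_filters(res, rmsf_threshold=1.5, rmsf_rule="either")
        assert len(either) == 1

    def test_rmsf_threshold_is_strict(self):
        m = np.eye(2)
        m[0, 1] = m[1, 0] = 0.9
        res = self._result(m, rmsf=[1.5, 2.0])
        assert len(apply_filters(res, rmsf_threshold=1.5)) == 0

    def test_negative_values_pass_by_magnitude(self):
        m = np.eye(2)
        m[0, 1] = m[1, 0] = -0.8
        res = self._result(m, rmsf=[2.0, 2.0])
        pairs = apply_filters(res)
        assert len(pairs) == 1
        assert pairs.iloc[0]["value"] == pytest.approx(-0.8)

    def test_monotonicity_in_corr_threshold(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(-1, 1, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        res = self._result(m, rmsf=rng.uniform(0, 3, size=10))
        loose = apply_filters(res, corr_threshold=0.5)
        strict = apply_filters(res, corr_threshold=0.7)
        loose_set = set(zip(loose["i"], loose["j"]))
        strict_set = set(zip(strict["i"], strict["j"]))
        assert strict_set <= loose_set

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotonicity_property(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        m = rng.uniform(-1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        rmsf = rng.uniform(0.0, 3.0, size=n)
        res = self._result(m, rmsf)
        t1, t2 = sorted(rng.uniform(0.0, 1.0, size=2))
        r1, r2 = sorted(rng.uniform(0.0, 3.0, size=2))
        base = set(zip(*apply_filters(res, r1, t1)[["i", "j"]].to_numpy().T)) if len(
            apply_filters(res, r1, t1)) else set()
        for rt, ct in ((r1, t2), (r2, t1), (r2, t2)):
            sub = apply_filters(res, rt, ct)
            sub_set = set(zip(sub["i"], sub["j"])) if len(sub) else set()
            assert sub_set <= base


@pytest.fixture(scope="module")
def trimer_mod():
    return build_trimer(TrimerSpec(seed=1))


class TestBlockSummary:
    def test_identity_duplicate_group(self, trimer_mod):
        model, part = trimer_mod
        # two beads moving identically in two groups -> block mean = max = 1
        rng = np.random.default_rng(12)
        base = rng.normal(size=(300, 1, 3))
        sel = part.indices(model, "A/TM")[:2]
        coords = np.repeat(model.coords[None], 300, axis=0)
        coords[:, sel[0]] += base[:, 0]
        coords[:, sel[1]] += base[:, 0]
        res = pearson_matrix(make_traj(coords), selection=sel, align=False)
        sub = SubdomainPartition({
            "g1": (("A", int(model.residue_index[sel[0]]), int(model.residue_index[sel[0]])),),
            "g2": (("A", int(model.residue_index[sel[1]]), int(model.residue_index[sel[1]])),),
        })
        table = block_summary(res, model, sub, include_monomers=False)
        row = table[(table.group_a == "g1") & (table.group_b == "g2")].iloc[0]
        assert row["mean"] == pytest.approx(1.0)
        assert row["max"] == pytest.approx(1.0)

    def test_planted_block_recovered(self, trimer_mod):
        model, part = trimer_mod
        ia = part.indices(model, "B/PN2")
        ib = part.indices(model, "B/PC2")
        blk = CorrelationBlock(tuple(ia), tuple(ib), 0.9, name="planted")
        motion = PlantedMotion(correlation_blocks=(blk,), sigma=1.0,
                               n_frames=2000, seed=13)
        traj = generate_fluctuation_trajectory(model, part, motion)
        sel = np.concatenate([ia, ib, part.indices(model, "B/PN1")])
        res = pearson_matrix(traj, selection=np.sort(sel), align=False)
        table = block_summary(res, model, part, include_monomers=False)
        planted = table[(table.group_a == "B/PN2") & (table.group_b == "B/PC2")].iloc[0]
        assert planted["mean"] >= 0.8
        unplanted = table[(table.group_a == "B/PN1") & (table.group_b == "B/PC2")].iloc[0]
        assert unplanted["count_above_threshold"] == 0

    def test_empty_group_rejected(self, trimer_mod):
        model, part = trimer_mod
        sel = part.indices(model, "A/TM")
        rng = np.random.default_rng(14)
        coords = np.repeat(model.coords[None], 50, axis=0) + rng.normal(
            scale=0.5, size=(50, model.n_atoms, 3))
        res = pearson_matrix(make_traj(coords), selection=sel, align=False)
        with pytest.raises(ValueError, match="empty"):
            block_summary(res, model, part, groups=["A/TM", "B/PC2"],
                          include_monomers=False)


class TestMapToStructure:
    def test_empty_pairs_all_zero(self, trimer_mod, tmp_path):
        model, part = trimer_mod
        res = CorrelationResult(np.eye(4), "pearson", np.zeros(4), np.arange(4))
        pairs = apply_filters(res)
        path = tmp_path / "ann.pdb"
        values = map_to_structure(res, model, path, pairs=pairs)
        assert (values == 0).all()
        assert (read_bfactors(path) == 0).all()

    def test_single_pair_counts(self, trimer_mod, tmp_path):
        model, part = trimer_mod
        m = np.eye(3)
        m[0, 2] = m[2, 0] = 0.9
        res = CorrelationResult(m, "pearson", np.array([2.0, 2.0, 2.0]),
                                np.array([5, 6, 7]))
        path = tmp_path / "ann.pdb"
        values = map_to_structure(res, model, path, mode="count")
        assert values[5] == 1 and values[7] == 1
        assert values.sum() == 2

    def test_planted_block_jaccard(self, trimer_mod, tmp_path):
        model, part = trimer_mod
        ia = part.indices(model, "A/DN")
        ib = part.indices(model, "A/DC")
        blk = CorrelationBlock(tuple(ia), tuple(ib), 0.9, name="planted")
        motion = PlantedMotion(correlation_blocks=(blk,), sigma=1.0,
                               n_frames=2000, seed=15)
        traj = generate_fluctuation_trajectory(model, part, motion)
        sel = np.sort(np.concatenate([ia, ib, part.indices(model, "A/PC1")]))
        res = pearson_matrix(traj, selection=sel, align=False)
        values = map_to_structure(res, model, tmp_path / "ann.pdb", mode="count")
        annotated = set(np.flatnonzero(values > 0))
        planted = set(ia) | set(ib)
        jaccard = len(annotated & planted) / len(annotated | planted)
        assert jaccard >= 0.9


class TestSubsetAndNonlinearity:
    def test_pearson_subset_of_generalized(self, trimer_mod):
        model, part = trimer_mod
        ia = part.indices(model, "C/PN1")
        ib = part.indices(model, "C/PN2")
        blocks = (CorrelationBlock(tuple(ia[:6]), tuple(ib[:6]), 0.85, name="hi"),)
        motion = PlantedMotion(correlation_blocks=blocks, sigma=1.0,
                               n_frames=1500, seed=16)
        traj = generate_fluctuation_trajectory(model, part, motion)
        sel = np.sort(np.concatenate([ia[:6], ib[:6], ia[6:10]]))
        pres = pearson_matrix(traj, selection=sel, align=False)
        gres = generalized_matrix(traj, selection=sel, align=False, seed=0)
        strong = np.abs(pres.matrix) >= 0.5
        np.fill_diagonal(strong, False)
        assert strong.sum() > 0
        agree = (gres.matrix[strong] >= 0.45).mean()
        assert agree >= 0.95

    def test_phase_coupled_pair_detected_only_by_generalized(self, trimer_mod):
        model, part = trimer_mod
        motion = PlantedMotion(nonlinear_pairs=((3, 50),), sigma=1.0,
                               n_frames=2000, seed=17)
        traj = generate_fluctuation_trajectory(model, part, motion)
        sel = np.array([3, 50])
        pres = pearson_matrix(traj, selection=sel, align=False)
        gres = generalized_matrix(traj, selection=sel, align=False, seed=0)
        assert abs(pres.matrix[0, 1]) < 0.2
        assert gres.matrix[0, 1] > 0.6
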