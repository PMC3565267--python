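"""CCE norm: perfect-crystal zeros, discrimination, invariances, ordering."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chainpack.cce import (
    EPS_THRES,
    cce,
    cce_from_vectors,
    classify_frame,
    neighbor_shells,
    norm_distribution,
)
from chainpack.core import ChainSystem, SimulationBox
from chainpack.lattices import make_fcc, make_hcp, make_template

TEMPLATES = {n: make_template(n) for n in ("hcp", "fcc", "fivefold")}


class TestPerfectCrystals:
    def test_self_norm_zero(self, fcc_crystal, hcp_crystal):
        assert cce(0, fcc_crystal, TEMPLATES["fcc"]) < 1e-10
        assert cce(17, hcp_crystal, TEMPLATES["hcp"]) < 1e-10

    def test_cross_norm_above_threshold(self, fcc_crystal, hcp_crystal):
        assert cce(0, fcc_crystal, TEMPLATES["hcp"]) > EPS_THRES
        assert cce(17, hcp_crystal, TEMPLATES["fcc"]) > EPS_THRES

    def test_template_cross_table(self):
        for a in TEMPLATES:
            for b in TEMPLATES:
                eps = cce_from_vectors(TEMPLATES[a].unit_vectors, TEMPLATES[b])
                if a == b:
                    assert eps < 1e-10
                else:
                    assert eps > EPS_THRES

    def test_fivefold_exclusivity(self):
        # icosahedral cluster: central site's shell matches only fivefold
        shell = TEMPLATES["fivefold"].unit_vectors
        assert cce_from_vectors(shell, TEMPLATES["fivefold"]) < 1e-10
        assert cce_from_vectors(shell, TEMPLATES["hcp"]) > EPS_THRES
        assert cce_from_vectors(shell, TEMPLATES["fcc"]) > EPS_THRES


class TestInvariances:
    def test_rigid_motion_leaves_norms_unchanged(self, fcc_crystal):
        vec, _ = neighbor_shells(fcc_crystal)
        R = Rotation.from_euler("xyz", [17, 121, -49], degrees=True).as_matrix()
        for i in (0, 5, 30):
            for t in TEMPLATES.values():
                e0 = cce_from_vectors(vec[i], t)
                e1 = cce_from_vectors(vec[i] @ R.T, t)
                assert e1 == pytest.approx(e0, abs=1e-8)

    def test_dilation_invariance(self, hcp_crystal):
        vec, _ = neighbor_shells(hcp_crystal)
        e0 = cce_from_vectors(vec[17], TEMPLATES["hcp"])
        e1 = cce_from_vectors(3.7 * vec[17], TEMPLATES["hcp"])
        assert e1 == pytest.approx(e0, abs=1e-10)

    def test_noise_ramp_monotone(self, fcc_crystal):
        rng = np.random.default_rng(4)
        vec, _ = neighbor_shells(fcc_crystal)
        base = vec[:12]
        noise = rng.uniform(-1, 1, base.shape)
        means = []
        for amp in (0.0, 0.01, 0.03, 0.08):
            es = [
                cce_from_vectors(base[i] + amp * noise[i], TEMPLATES["fcc"])
                for i in range(12)
            ]
            means.append(np.mean(es))
        assert means[0] < 1e-10
        assert all(a < b for a, b in zip(means, means[1:]))
        assert means[1] < EPS_THRES  # 0.01 sigma noise stays clearly ordered

    def test_matches_rotation_grid_search(self):
        # independent oracle: dense random rotation scan + local polish of
        # the matching term for a template whose norm has no closure terms
        from scipy.optimize import linear_sum_assignment, minimize

        rng = np.random.default_rng(8)
        shell = TEMPLATES["fcc"].unit_vectors

        def matching(u, Rm):
            ru = shell @ Rm.T
            cost = np.sum((u[:, None, :] - ru[None, :, :]) ** 2, axis=-1)
            rows, cols = linear_sum_assignment(cost)
            return cost[rows, cols].sum() / 12.0

        for _ in range(3):
            u = shell + rng.uniform(-0.15, 0.15, shell.shape)
            # package result (matching term only, via the polished minimum)
            from chainpack.cce import _minimize_norm

            ms_pkg, _ = _minimize_norm(u, shell)
            best = math.inf
            for Rm in Rotation.random(4000, random_state=rng).as_matrix():
                best = min(best, matching(u, Rm))

            def f(rv):
                return matching(u, Rotation.from_rotvec(rv).as_matrix())

            for Rm in Rotation.random(40, random_state=rng).as_matrix():
                res = minimize(f, Rotation.from_matrix(Rm).as_rotvec(),
                               method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-12})
                best = min(best, res.fun)
            assert ms_pkg <= best + 1e-6


class TestClassification:
    def test_all_hcp_frame_saturates(self, hcp_crystal):
        results, order = classify_frame(hcp_crystal, structures=("hcp", "fcc"))
        assert order.S_hcp == 1.0
        assert order.S_fcc == 0.0
        assert order.tau_c == 1.0
        assert all(r.label == "hcp" for r in results)

    def test_discrimination_no_double_assignment(self, fcc_crystal, random_fluid):
        for sys_ in (fcc_crystal, random_fluid):
            results, _ = classify_frame(sys_, structures=("hcp", "fcc"))
            for r in results:
                assert not (r.eps_hcp < EPS_THRES and r.eps_fcc < EPS_THRES)

    def test_dilute_fluid_mostly_amorphous(self):
        rng = np.random.default_rng(12)
        n, L = 200, 10.0  # phi ~ 0.1
        sys_ = ChainSystem(
            rng.random((n, 3)) * L, [np.array([i]) for i in range(n)],
            SimulationBox(L),
        )
        _, order = classify_frame(sys_, structures=("hcp", "fcc"))
        assert order.tau_c < 0.05

    def test_threshold_monotonicity(self, random_fluid):
        results, _ = classify_frame(random_fluid, structures=("hcp",))
        eps = np.array([r.eps_hcp for r in results])
        fractions = [(eps < th).mean() for th in (0.15, 0.245, 0.35, 0.5)]
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_too_few_neighbors_sentinel(self):
        pos = np.array([[2.5, 2.5, 2.5], [3.5, 2.5, 2.5], [2.5, 3.5, 2.5]])
        sys_ = ChainSystem(pos, [np.array([i]) for i in range(3)], SimulationBox(5.0))
        results, order = classify_frame(sys_, structures=("hcp", "fcc"))
        assert all(math.isinf(r.eps_hcp) for r in results)
        assert all(r.label == "amorphous" for r in results)
        assert order.tau_c == 0.0


class TestNormDistribution:
    def test_mixture_fractions(self):
        seq_hcp, seq_fcc = make_hcp(4), make_fcc(3)
        res_h, _ = classify_frame(seq_hcp, structures=("hcp", "fcc"))
        res_f, _ = classify_frame(seq_fcc, structures=("hcp", "fcc"))
        # constructed 30/70 site mixture
        n_h = int(round(0.3 * 100))
        mixed = res_h[:n_h] + res_f[: 100 - n_h]
        hcp_frac = sum(r.eps_hcp < EPS_THRES for r in mixed) / len(mixed)
        fcc_frac = sum(r.eps_fcc < EPS_THRES for r in mixed) / len(mixed)
        assert hcp_frac == pytest.approx(0.30, abs=1e-12)
        assert fcc_frac == pytest.approx(0.70, abs=1e-12)

    def test_bidisperse_separation_and_integral(self, fcc_crystal):
        results, order = classify_frame(fcc_crystal, structures=("hcp", "fcc"))
        edges, dens = norm_distribution(results, "fcc", bins=40)
        widths = np.diff(edges)
        below = edges[1:] <= EPS_THRES
        s_fcc_hist = float(np.sum(dens[below] * widths[below]))
        assert s_fcc_hist == pytest.approx(order.S_fcc, abs=1.0 / 40)
        edges_h, dens_h = norm_distribution(results, "hcp", bins=40)
        mass_below = np.sum(dens_h[edges_h[1:] <= EPS_THRES])
        assert mass_below == 0.0  # hcp histogram entirely above threshold

    def test_empty_histogram_warns(self):
        from chainpack.cce import CCEResult

        results = [CCEResult(0, math.inf, math.inf, math.inf, "amorphous")]
        with pytest.warns(UserWarning):
            norm_distribution(results, "hcp")
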