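"""Monte Carlo engine: moves, conservation laws, compression, splitting."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from chainpack.core import (
    ChainSystem,
    ConfigurationError,
    EnsembleSpec,
    SimulationBox,
    packing_fraction,
    validate,
)
from chainpack.lattices import make_dilute_chains
from chainpack.mc import (
    CBSchedule,
    CompressionError,
    MoveMix,
    RunSpec,
    compress,
    monomer_fluid,
    run_mc,
    split_chains,
)


class TestMoveMix:
    def test_default_sums_to_one(self):
        assert MoveMix().probabilities().sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_bad_sum(self):
        with pytest.raises(ConfigurationError):
            MoveMix(reptation=0.5)

    def test_cb_schedule_monotone(self):
        cbs = CBSchedule()
        assert cbs.k(0.3) == 10 and cbs.k(0.5) == 30 and cbs.k(0.60) == 50
        with pytest.raises(ConfigurationError):
            CBSchedule(trials=(30, 10, 5))


class TestRunMC:
    def test_free_space_reptation_accepts_everything(self):
        # a single dimer in a huge box: no overlap is ever possible
        pos = np.array([[25.0, 25, 25], [26.0, 25, 25]])
        sys_ = ChainSystem(pos, [np.array([0, 1])], SimulationBox(50.0))
        mix = MoveMix(1.0, 0, 0, 0, 0, 0, 0)
        res = run_mc(sys_, RunSpec(n_steps=3000, seed=1, record_every=3000, movemix=mix))
        assert res.accepted["reptation"] == res.attempted["reptation"]

    def test_hard_core_rule_blocks_overlap(self):
        # end rotation of a capped trimer: every non-identity position of
        # the rotated end collides with the blocking wall of spheres
        rng = np.random.default_rng(0)
        center = np.array([10.0, 10, 10])
        wall = [center + [2.0, y, z] for y in (-1, 0, 1) for z in (-1, 0, 1)]
        pos = np.vstack([center, center + [1.0, 0, 0]] + wall)
        chains = [np.array([0, 1])] + [np.array([i]) for i in range(2, 11)]
        sys_ = ChainSystem(pos, chains, SimulationBox(20.0))
        assert validate(sys_).ok
        res = run_mc(
            sys_,
            RunSpec(
                n_steps=500,
                seed=3,
                record_every=500,
                movemix=MoveMix(0, 1.0, 0, 0, 0, 0, 0),
            ),
        )
        assert validate(res.frames[-1]).ok

    def test_conservation_and_validity(self, dilute_chains):
        mix = MoveMix(0.1, 0.1, 0.2, 0.25, 0.25, 0.05, 0.05)
        ens = EnsembleSpec("uniform", 12, 0.5)
        spec = RunSpec(
            n_steps=15_000, seed=5, record_every=3000, movemix=mix, ensemble=ens,
            cb_schedule=CBSchedule(trials=(4, 30, 50)),
        )
        res = run_mc(dilute_chains, spec)
        for fr in res.frames:
            assert fr.n_at == dilute_chains.n_at
            assert fr.n_ch == dilute_chains.n_ch
            assert fr.chain_lengths().sum() == fr.n_at
            assert validate(fr).ok
            lo, hi = ens.length_range()
            assert all(lo <= l <= hi for l in fr.chain_lengths())

    def test_lengths_conserved_without_bridging_moves(self, dilute_chains):
        mix = MoveMix(0.2, 0.2, 0.2, 0.0, 0.4, 0.0, 0.0)
        spec = RunSpec(n_steps=8000, seed=7, record_every=8000, movemix=mix)
        res = run_mc(dilute_chains, spec)
        assert np.array_equal(
            np.sort(res.frames[-1].chain_lengths()),
            np.sort(dilute_chains.chain_lengths()),
        )

    def test_libration_angle_uniform(self):
        # free 3-sphere rotor with only internal libration: the sampled
        # dihedral angle about the end-to-end axis must be uniform — the
        # hard-sphere-only acceptance must not bias the free rotor
        a, b = np.array([10.0, 10, 10]), np.array([11.6, 10, 10])
        mid = np.array([10.8, 10 + math.sqrt(1 - 0.8**2), 10])
        sys_ = ChainSystem(np.vstack([a, mid, b]), [np.arange(3)], SimulationBox(30.0))
        mix = MoveMix(0, 0, 0, 0, 1.0, 0, 0)
        spec = RunSpec(
            n_steps=40_000, seed=11, record_every=100, movemix=mix,
            libration_delta=math.radians(60.0),
        )
        res = run_mc(sys_, spec)
        angles = []
        axis = (b - a) / np.linalg.norm(b - a)
        e1 = np.array([0.0, 1, 0])
        e2 = np.cross(axis, e1)
        for fr in res.frames:
            v = fr.positions[1] - fr.positions[0]
            angles.append(math.atan2(v @ e2, v @ e1) % (2 * math.pi))
        stat, p = kstest(np.array(angles) / (2 * math.pi), "uniform")
        assert p > 0.01

    def test_invalid_start_rejected(self):
        pos = np.array([[5.0, 5, 5], [5.5, 5, 5]])
        bad = ChainSystem(pos, [np.array([0]), np.array([1])], SimulationBox(10.0))
        with pytest.raises(ConfigurationError):
            run_mc(bad, RunSpec(n_steps=10, seed=0))

    def test_hard_constraint_safety_dense(self):
        # sustained run at phi = 0.45: no frame may ever violate a constraint
        sys_ = monomer_fluid(150, 0.45, seed=21)
        chains_sys = make_dilute_chains(8, EnsembleSpec("uniform", 10, 0.4), 0.05, seed=2)
        spec = RunSpec(n_steps=0, seed=3)
        dense = compress(chains_sys, 0.45, spec, attempt_every=400)
        assert packing_fraction(dense) == pytest.approx(0.45, abs=1e-4)
        mix = MoveMix(0.1, 0.1, 0.2, 0.25, 0.25, 0.05, 0.05)
        run = RunSpec(
            n_steps=40_000, seed=9, record_every=8000, movemix=mix,
            ensemble=EnsembleSpec("uniform", 10, 0.4),
        )
        res = run_mc(dense, run)
        assert sum(res.accepted.values()) > 5000
        for fr in res.frames:
            assert validate(fr).ok


class TestCompress:
    def test_single_chain_rigid_affine(self):
        sys_ = make_dilute_chains(1, EnsembleSpec("uniform", 8, 0.0), 0.01, seed=1)
        spec = RunSpec(n_steps=0, seed=2)
        out = compress(sys_, 0.05, spec, attempt_every=200)
        assert 0.05 <= packing_fraction(out) <= 0.05 + 1e-4
        # intra-chain geometry untouched by the affine repositioning
        steps = np.linalg.norm(np.diff(out.unwrapped_chain(0), axis=0), axis=1)
        assert np.allclose(steps, 1.0, atol=1e-12)

    def test_monomer_compression_reaches_target(self):
        out = monomer_fluid(200, 0.50, seed=4)
        assert 0.50 <= packing_fraction(out) <= 0.50 + 1e-4
        assert validate(out).ok

    def test_large_requested_step_recovers_via_smaller_ones(self):
        sys_ = make_dilute_chains(6, EnsembleSpec("uniform", 8, 0.0), 0.05, seed=6)
        spec = RunSpec(n_steps=0, seed=7)
        # shrink_factor so aggressive that single-step overlap is certain;
        # the protocol must back off and still reach the target
        out = compress(sys_, 0.2, spec, shrink_factor=0.5, attempt_every=300)
        assert 0.2 <= packing_fraction(out) <= 0.2 + 1e-4

    def test_unreachable_target_raises_with_partial_state(self):
        sys_ = monomer_fluid(60, 0.30, seed=8)
        spec = RunSpec(n_steps=0, seed=9)
        with pytest.raises(CompressionError) as exc:
            compress(sys_, 0.72, spec, attempt_every=50, max_attempts=60)
        assert exc.value.phi < 0.72
        assert validate(exc.value.system).ok


class TestSplitChains:
    def test_split_doubles_chain_count(self):
        sys_ = make_dilute_chains(6, EnsembleSpec("uniform", 24, 0.0), 0.03, seed=3)
        out = split_chains(sys_)
        assert out.n_ch == 12
        assert all(l == 12 for l in out.chain_lengths())
        assert np.array_equal(out.positions, sys_.positions)
        assert validate(out).ok
        assert packing_fraction(out) == packing_fraction(sys_)

    def test_split_then_merge_restores_bonds(self):
        sys_ = make_dilute_chains(4, EnsembleSpec("uniform", 24, 0.0), 0.03, seed=5)
        before = {tuple(sorted(b)) for b in sys_.bonds.tolist()}
        out = split_chains(sys_)
        after = {tuple(sorted(b)) for b in out.bonds.tolist()}
        removed = before - after
        assert len(removed) == 4 and after | removed == before

    def test_odd_length_rejected(self):
        sys_ = make_dilute_chains(2, EnsembleSpec("uniform", 7, 0.0), 0.02, seed=6)
        with pytest.raises(ConfigurationError, match="chain 0"):
            split_chains(sys_)
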