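"""Crystal fixtures, stacking ground truth, templates, dilute generators."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from chainpack.core import ConfigurationError, EnsembleSpec, packing_fraction, validate
from chainpack.lattices import (
    InsertionError,
    StackingSequence,
    make_dilute_chains,
    make_fcc,
    make_stacking,
    make_template,
    random_stacking,
    stacking_ground_truth,
    template_table,
)
from chainpack.cce import neighbor_shells


class TestStacking:
    def test_rejects_repeated_letters(self):
        with pytest.raises(ConfigurationError):
            StackingSequence("AAB")

    def test_contact_coordination(self):
        sys_ = make_stacking(StackingSequence("ABCABC"))
        _, dist = neighbor_shells(sys_)
        # wrap-valid sequence: every site has an exact 12-shell at contact
        assert np.allclose(dist, 1.0, atol=1e-9)

    def test_close_packed_density_when_commensurate(self):
        sys_ = make_stacking(StackingSequence("ABCABC"))
        assert packing_fraction(sys_) == pytest.approx(math.pi / math.sqrt(18), abs=1e-6)
        assert packing_fraction(make_fcc(3)) == pytest.approx(
            math.pi / math.sqrt(18), abs=1e-6
        )

    def test_nonwrapping_sequence_gets_vacuum_gap(self):
        sys_ = make_stacking(StackingSequence("ABA"))
        assert validate(sys_).ok

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ABA", ["boundary", "hcp", "boundary"]),
            ("ABC", ["boundary", "fcc", "boundary"]),
            (
                "ABCBCA",
                ["boundary", "fcc", "hcp", "hcp", "fcc", "boundary"],
            ),
        ],
    )
    def test_ground_truth_rule(self, seq, expected):
        assert stacking_ground_truth(StackingSequence(seq)) == expected

    def test_random_stacking_is_admissible(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = random_stacking(8, rng)
            assert all(a != b for a, b in zip(seq.layers, seq.layers[1:]))


class TestTemplates:
    def test_shells_are_unit_and_closed_under_ops(self):
        for name in ("hcp", "fcc", "fivefold"):
            t = make_template(name)
            assert t.unit_vectors.shape == (12, 3)
            assert np.allclose(np.linalg.norm(t.unit_vectors, axis=1), 1.0, atol=1e-12)
            for g in t.symmetry_ops:
                gv = t.unit_vectors @ g.T
                d = np.min(
                    np.linalg.norm(gv[:, None] - t.unit_vectors[None], axis=-1), axis=1
                )
                assert np.max(d) < 1e-10

    def test_icosahedral_nearest_angles_equal(self):
        t = make_template("fivefold")
        cos = t.unit_vectors @ t.unit_vectors.T
        np.fill_diagonal(cos, -2.0)
        nearest = np.max(cos, axis=1)
        assert np.allclose(nearest, nearest[0], atol=1e-12)

    def test_fcc_hcp_differ_in_three_directions(self):
        # brute-force scan over all two-vector correspondence alignments:
        # the maximum number of exactly matched directions is 9 of 12
        from scipy.optimize import linear_sum_assignment

        a = make_template("fcc").unit_vectors
        b = make_template("hcp").unit_vectors

        def frame(u, v):
            e1 = u / np.linalg.norm(u)
            w = v - (v @ e1) * e1
            if np.linalg.norm(w) < 1e-9:
                return None
            e2 = w / np.linalg.norm(w)
            return np.column_stack([e1, e2, np.cross(e1, e2)])

        best = 0
        Fa = frame(a[0], a[1])
        for k in range(12):
            for l in range(12):
                if k == l:
                    continue
                Fb = frame(b[k], b[l])
                if Fb is None:
                    continue
                R = Fa @ Fb.T
                rb = b @ R.T
                cost = np.linalg.norm(a[:, None] - rb[None], axis=-1)
                rows, cols = linear_sum_assignment(cost)
                best = max(best, int(np.sum(cost[rows, cols] < 1e-9)))
        assert best == 9  # 12 - 3 matched

    def test_pentagonal_bipyramid_variant(self):
        t = make_template("fivefold7")
        assert t.unit_vectors.shape == (7, 3)

    def test_unknown_name(self):
        with pytest.raises(ConfigurationError):
            make_template("bcc")

    def test_plain_text_serialization(self):
        text = template_table(make_template("fcc"))
        rows = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(rows) == 12


class TestDiluteChains:
    def test_uniform_lengths_in_interval(self, dilute_chains):
        assert all(6 <= l <= 18 for l in dilute_chains.chain_lengths())
        assert validate(dilute_chains).ok

    def test_flory_respects_minimum(self):
        ens = EnsembleSpec("flory", 12, n_min=3)
        sys_ = make_dilute_chains(30, ens, 0.03, seed=2)
        assert sys_.chain_lengths().min() >= 3

    def test_seeded_determinism(self):
        ens = EnsembleSpec("uniform", 12, 0.5)
        a = make_dilute_chains(20, ens, 0.05, seed=7)
        b = make_dilute_chains(20, ens, 0.05, seed=7)
        assert np.array_equal(a.positions, b.positions)

    def test_exact_total_pins_mean_length(self):
        ens = EnsembleSpec("uniform", 12, 0.5)
        sys_ = make_dilute_chains(25, ens, 0.05, seed=9)
        assert sys_.n_at == 25 * 12

    def test_validates_across_seeds(self):
        ens = EnsembleSpec("uniform", 8, 0.5)
        for seed in range(6):
            assert validate(make_dilute_chains(8, ens, 0.06, seed=seed)).ok

    def test_length_sampler_matches_distribution(self):
        ens = EnsembleSpec("uniform", 12, 0.5)
        sys_ = make_dilute_chains(
            200, ens, 0.02, seed=13, exact_total=False
        )
        lengths, probs = ens.target_pmf()
        counts = np.array(
            [(sys_.chain_lengths() == l).sum() for l in lengths], dtype=float
        )
        _, p = chisquare(counts, probs * counts.sum())
        assert p > 0.01

    def test_impossible_density_raises(self):
        ens = EnsembleSpec("uniform", 12, 0.5)
        with pytest.raises(ConfigurationError):
            make_dilute_chains(10, ens, 0.4, seed=0)
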