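"""Petri-net compilation, firing semantics, and the batch kernel."""

from __future__ import annotations

import numpy as np
import pytest

from epinet import ModelSpec, SimConfig, simulate
from epinet import model_space as ms
from epinet import petri
from epinet._batch import simulate_batch
from tests.conftest import INVERSION_MOTIF


class TestCompile:
    def test_provisioning_wild_type(self, inversion_spec, config):
        net = petri.compile(inversion_spec, frozenset(), config)
        # R1 unregulated and R2 only inhibited: both keep their provision
        assert net.initial_marking.tolist() == [200, 200, 0, 0]
        assert net.silencers[1] == 0  # R1 silences R2

    def test_fed_regulator_starts_empty(self, config):
        m = np.zeros((4, 4), int)
        m[0, 1] = 1  # R1 activates R2
        m[0, 2] = 1
        m[1, 2] = 5
        spec = ms.expand_logic(m)[0]
        net = petri.compile(spec, frozenset(), config)
        assert net.initial_marking.tolist() == [200, 0, 0, 0]

    def test_deletion_clears_marking_and_output_arcs(self, inversion_spec, config):
        net = petri.compile(inversion_spec, frozenset({0}), config)
        assert net.initial_marking[0] == 0
        for t in net.transitions:
            assert t.target != 0 or t.target is None

    def test_gene_deletion_rejected(self, inversion_spec, config):
        with pytest.raises(ValueError, match="regulators"):
            petri.compile(inversion_spec, frozenset({2}), config)

    def test_inhibitor_only_gene_gets_basal_source(self, config):
        m = np.zeros((4, 4), int)
        m[0, 2] = -1  # G1 repressed by R1, no activating input
        m[0, 3] = 1
        m[1, 3] = 1  # condition 3 satisfied through G2
        spec = ms.expand_logic(m)[0]
        net = petri.compile(spec, frozenset(), config)
        sources = [t for t in net.transitions if t.sources == () and t.target == 2]
        assert len(sources) == 1
        assert sources[0].delta == config.source_rate


class TestStep:
    def test_single_transition_consumes_and_produces(self, config):
        m = np.zeros((4, 4), int)
        m[0, 2] = 1
        m[0, 3] = 1
        spec = ms.expand_logic(m)[0]
        net = petri.compile(spec, frozenset(), config)
        rng = np.random.default_rng(0)
        after = petri.step(net, net.initial_marking.copy(), rng)
        # R1 funds both firings; the idle R2 keeps its provision
        assert after.tolist() == [198, 200, 1, 1]

    def test_marking_stays_non_negative(self, random_specs, config):
        rng = np.random.default_rng(1)
        for spec in random_specs[:60]:
            net = petri.compile(spec, frozenset(), config)
            marking = net.initial_marking.copy()
            for _ in range(50):
                marking = petri.step(net, marking, rng)
                assert (marking >= 0).all()

    def test_conflict_free_net_is_seed_independent(self, inversion_spec, config):
        # total per-step demand on any place is at most 1 token here
        results = {simulate(inversion_spec, config,
                            np.random.default_rng(s)).tokens.tobytes()
                   for s in range(5)}
        assert len(results) == 1


class TestMValue:
    @pytest.mark.parametrize(
        "mut, wt, expected",
        [(50, 50, 0.0), (0, 50, -5.672425), (245, 50, 2.270089)],
    )
    def test_formula(self, mut, wt, expected):
        assert petri.m_value(mut, wt, 1) == pytest.approx(expected, abs=1e-5)

    def test_negative_tokens_rejected(self):
        with pytest.raises(ValueError):
            petri.m_value(-1, 50)


class TestSimulate:
    def test_inversion_motif_trajectory(self, inversion_spec, config):
        res = simulate(inversion_spec, config)
        assert res.tokens[:, 0].tolist() == [50, 250, 50, 0]
        m1, m2, mo = res.m_for(0)
        assert m1 > 0 and abs(m2) < 1e-9 and mo < 0

    def test_weak_and_strong_inhibition_agree(self, config):
        # the two minimal inversion motifs differ only in the silencing
        # edge weight, which carries no output arc
        strong = INVERSION_MOTIF.copy()
        strong[0, 1] = -5
        res_w = simulate(ModelSpec(INVERSION_MOTIF, (0, 0, 1, 0)), config)
        res_s = simulate(ModelSpec(strong, (0, 0, 1, 0)), config)
        assert np.array_equal(res_w.tokens, res_s.tokens)

    def test_gene_without_producers_stays_silent(self, inversion_spec, config):
        res = simulate(inversion_spec, config)
        assert res.tokens[:, 1].tolist() == [0, 0, 0, 0]
        assert res.m_for(1) == (0.0, 0.0, 0.0)

    def test_same_seed_reproduces(self, random_specs, config):
        for spec in random_specs[:20]:
            a = simulate(spec, config, np.random.default_rng(3))
            b = simulate(spec, config, np.random.default_rng(3))
            assert np.array_equal(a.tokens, b.tokens)


class TestBatchKernel:
    def test_matches_reference_on_deterministic_models(self, random_specs, config):
        specs = random_specs[:300]
        mats = np.stack([s.matrix.reshape(16) for s in specs])
        logics = np.array([[int(l) for l in s.logic] for s in specs], dtype=np.int8)
        tokens = simulate_batch(mats, logics, config)
        kernel_stable = (tokens == tokens[:, :1]).all(axis=(1, 2, 3))
        checked = 0
        for i, spec in enumerate(specs):
            if not kernel_stable[i]:
                continue
            refs = {simulate(spec, config, np.random.default_rng(s)).tokens.tobytes()
                    for s in range(4)}
            if len(refs) > 1:
                continue  # stochastic model that happened to look stable
            ref = simulate(spec, config, np.random.default_rng(0))
            assert np.array_equal(ref.tokens, tokens[i, 0]), spec.id
            checked += 1
        assert checked > 200  # the comparison actually exercised most models

    def test_mirror_symmetry_of_pattern_calls(self, random_specs, config):
        from epinet.patterns import classify_simulated_arrays, m_values_from_tokens

        specs = random_specs[:400]
        mats = np.stack([s.matrix.reshape(16) for s in specs])
        logics = np.array([[int(l) for l in s.logic] for s in specs], dtype=np.int8)

        def patterns(mats_, logics_):
            tokens = simulate_batch(mats_, logics_, config)
            codes = classify_simulated_arrays(m_values_from_tokens(tokens))
            stable = (codes == codes[:, :1]).all(axis=(1, 2))
            return codes[:, 0], stable

        base, base_stable = patterns(mats, logics)

        # regulator swap: relabel nodes, pattern calls per gene unchanged
        perm = (1, 0, 2, 3)
        r_mats = np.stack(
            [ms.apply_mirror(m.reshape(4, 4), perm).reshape(16) for m in mats]
        )
        r_logics = logics[:, list(perm)]
        swapped, swap_stable = patterns(r_mats, r_logics)
        both = base_stable & swap_stable
        assert both.sum() > 300
        assert np.array_equal(base[both], swapped[both])

        # gene swap: G1 and G2 outputs exchange
        perm = (0, 1, 3, 2)
        g_mats = np.stack(
            [ms.apply_mirror(m.reshape(4, 4), perm).reshape(16) for m in mats]
        )
        g_logics = logics[:, list(perm)]
        gswapped, g_stable = patterns(g_mats, g_logics)
        both = base_stable & g_stable
        assert np.array_equal(base[both], gswapped[both][:, ::-1])
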