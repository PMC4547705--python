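"""Offspring law, type-space bookkeeping, and parameter validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tcellnet as tc
from tcellnet.model import ConfigurationError, ParameterError

THREE_STAGE = tc.NetworkTopology(transfer_stages=("TR1", "TR2", "TR3"))


def branch_map(cell_type, params, topology):
    """{frozenset(offspring items): prob} for easy assertions."""
    return {
        frozenset(off.items()): p
        for p, off in tc.offspring_distribution(cell_type, params, topology)
    }


# ---------------------------------------------------------------------------
# type space
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "topology, p, expected_D",
    [
        (THREE_STAGE, 7, 56),  # 7 compartments x 8 generations
        (tc.NetworkTopology(transfer_stages=(), sinks=()), 2, 3),
        (tc.default_topology(), 7, 48),
    ],
)
def test_type_space_size(topology, p, expected_D):
    assert tc.build_type_space(topology, p).size == expected_D


def test_type_space_is_deterministic_bijection(topo):
    a = tc.build_type_space(topo, 7)
    b = tc.build_type_space(topo, 7)
    assert a == b and a.types == b.types
    assert len(set(a.types)) == a.size
    for k, (comp, gen) in enumerate(a.types):
        assert a.index(comp, gen) == k
    # compartments in network order, generations ascending within compartment
    assert a.types[0] == (topo.source, 0)
    assert a.types[7] == (topo.source, 7)
    assert a.types[8] == (topo.transfer_stages[0], 0)


def test_type_space_rejects_bad_inputs(topo):
    with pytest.raises(ConfigurationError):
        tc.build_type_space(topo, 1)
    with pytest.raises(ConfigurationError):
        tc.NetworkTopology(source="")


def test_transit_builder_discretizes_transit_time():
    topo = tc.NetworkTopology.from_transit_time(12.0, 4.0)
    assert topo.n_transit_steps == 3
    with pytest.raises(ConfigurationError):
        tc.NetworkTopology.from_transit_time(1.0, 4.0)


# ---------------------------------------------------------------------------
# offspring distribution
# ---------------------------------------------------------------------------

def test_source_generation0_fates(params, topo):
    bm = branch_map(("DR", 0), params, topo)
    assert bm[frozenset({(("DR", 1), 2)})] == pytest.approx(0.06)
    assert bm[frozenset({(("DR", 0), 1)})] == pytest.approx(0.43)
    assert bm[frozenset()] == pytest.approx(0.51)
    # generation 0 does not migrate: no transfer branch at all
    assert all(
        all(dest[0] == "DR" for dest, _ in key) for key in bm if key
    )


def test_transfer_stage_is_pure_delay(params):
    bm = branch_map(("TR2", 1), params, THREE_STAGE)
    assert bm == {frozenset({(("TR3", 1), 1)}): pytest.approx(1.0)}


def test_last_transfer_stage_splits_by_rho(params):
    bm = branch_map(("TR3", 2), params, THREE_STAGE)
    assert bm[frozenset({(("SPL", 2), 1)})] == pytest.approx(0.95)
    assert bm[frozenset({(("ILN", 2), 1)})] == pytest.approx(0.01)
    assert bm[frozenset({(("MLN", 2), 1)})] == pytest.approx(0.04)


def test_sink_cells_do_not_migrate(params, topo):
    bm = branch_map(("SPL", 1), params, topo)
    dests = {dest for key in bm for dest, _ in key}
    assert all(comp == "SPL" for comp, _ in dests)
    # divide / quiesce / die with the generation-1 probabilities
    assert bm[frozenset({(("SPL", 2), 2)})] == pytest.approx(0.29)
    assert bm[frozenset({(("SPL", 1), 1)})] == pytest.approx(0.31)
    assert bm[frozenset()] == pytest.approx(1 - 0.29 - 0.31)


def test_generation_cap_pools_divisions(params, topo):
    # dye-saturated pool: division from generation p yields two gen-p cells
    bm = branch_map(("DR", 7), params, topo)
    assert bm[frozenset({(("DR", 7), 2)})] == pytest.approx(0.24)
    nocap = tc.reference_parameters(divide_at_cap=False)
    bm2 = branch_map(("DR", 7), nocap, topo)
    assert frozenset({(("DR", 7), 2)}) not in bm2
    assert bm2[frozenset()] == pytest.approx(1 - 0.23)  # death absorbs gamma_p


def test_overfull_simplex_raises_naming_generation(topo):
    bad = tc.reference_parameters(gamma=(0.06, 0.9, 0.24), delta=(0.43, 0.3, 0.23))
    with pytest.raises(ParameterError, match="generation 1"):
        tc.offspring_distribution(("DR", 1), bad, topo)


@pytest.mark.parametrize("topology", [tc.default_topology(), THREE_STAGE])
def test_fate_probabilities_sum_to_one_for_every_type(params, topology):
    ts = tc.build_type_space(topology, params.p)
    for t in ts.types:
        probs = [p for p, _ in tc.offspring_distribution(t, params, topology)]
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in probs)


@settings(max_examples=25, deadline=None)
@given(
    g=st.lists(st.floats(0, 0.4), min_size=3, max_size=3),
    d=st.lists(st.floats(0, 0.4), min_size=3, max_size=3),
    m=st.floats(0, 0.2),
    r=st.floats(0.05, 0.9),
)
def test_fate_probabilities_sum_to_one_random_params(g, d, m, r):
    params = tc.reference_parameters(
        gamma=tuple(g), delta=tuple(d), m=m,
        rho={"SPL": r, "ILN": (1 - r) / 2, "MLN": (1 - r) / 2},
    )
    topo = tc.default_topology()
    ts = tc.build_type_space(topo, params.p)
    for t in ts.types:
        total = sum(p for p, _ in tc.offspring_distribution(t, params, topo))
        assert total == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# mean matrix and covariances
# ---------------------------------------------------------------------------

def test_mean_matrix_row_for_generation1_source(params, topo, ts):
    M = tc.offspring_mean_matrix(params, topo, ts)
    row = M[ts.index("DR", 1)]
    expected = np.zeros(ts.size)
    expected[ts.index("DR", 2)] = 0.58   # 2 * gamma_1
    expected[ts.index("DR", 1)] = 0.31   # delta_1
    expected[ts.index("TR1", 1)] = 0.14  # m
    np.testing.assert_allclose(row, expected, atol=1e-12)


def test_mean_matrix_all_zero_parameters_means_certain_death(topo, ts):
    """With gamma = delta = m = 0 every source and sink row is zero (the
    delay-line advance entries are parameter-free), so the expected population
    vanishes after one step from any source-supported initial state."""
    dead = tc.reference_parameters(gamma=(0, 0, 0), delta=(0, 0, 0), m=0.0)
    M = tc.offspring_mean_matrix(dead, topo, ts)
    for j, (comp, _) in enumerate(ts.types):
        if comp == topo.source or comp in topo.sinks:
            assert np.all(M[j] == 0)
    mu0 = np.zeros(ts.size)
    mu0[ts.indices_of([topo.source])] = 100.0
    assert np.all(M.T @ mu0 == 0)


def test_mean_matrix_delay_row(params, ts, topo):
    row = tc.offspring_mean_matrix(params, topo, ts)[ts.index("TR1", 3)]
    expected = np.zeros(ts.size)
    expected[ts.index("TR2", 3)] = 1.0
    np.testing.assert_allclose(row, expected, atol=1e-15)


def test_mean_matrix_equals_distribution_expectation(params, topo, ts):
    """Oracle: expectation of the enumerated fate law, row by row."""
    M = tc.offspring_mean_matrix(params, topo, ts)
    for j, t in enumerate(ts.types):
        mu = np.zeros(ts.size)
        for p, off in tc.offspring_distribution(t, params, topo):
            for dest, cnt in off.items():
                mu[ts.index(*dest)] += p * cnt
        np.testing.assert_allclose(M[j], mu, atol=1e-14)


def test_offspring_covariance_examples(params, topo, ts):
    V = tc.offspring_covariance(("DR", 1), params, topo, ts)
    i2 = ts.index("DR", 2)
    # Var of 2*Bernoulli(gamma_1): 4*0.29 - (2*0.29)^2
    assert V[i2, i2] == pytest.approx(0.8236)
    # delay line is deterministic
    assert np.all(tc.offspring_covariance(("TR1", 4), params, topo, ts) == 0)
    # splitting stage: Bernoulli variance rho_spl (1 - rho_spl)
    Vs = tc.offspring_covariance((topo.transfer_stages[-1], 2), params, topo, ts)
    ispl = ts.index("SPL", 2)
    assert Vs[ispl, ispl] == pytest.approx(0.95 * 0.05)


def test_offspring_covariance_is_symmetric_psd(params, topo, ts):
    for t in ts.types:
        V = tc.offspring_covariance(t, params, topo, ts)
        np.testing.assert_allclose(V, V.T, atol=1e-14)
        w = np.linalg.eigvalsh(V)
        assert w.min() >= -1e-10


def test_mean_matrix_is_feedforward(params, topo, ts):
    """Nonzero entries only move forward: same compartment with generation not
    decreasing, or a later compartment (no recirculation)."""
    M = tc.offspring_mean_matrix(params, topo, ts)
    order = {c: k for k, c in enumerate(topo.compartments)}
    for j, (cj, gj) in enumerate(ts.types):
        for k in np.nonzero(M[j])[0]:
            ck, gk = ts.types[k]
            assert order[ck] > order[cj] or (ck == cj and gk >= gj)


def test_source_expected_offspring_at_most_two(params, topo, ts):
    M = tc.offspring_mean_matrix(params, topo, ts)
    for i in range(params.p + 1):
        j = ts.index("DR", i)
        total = M[j].sum()
        expected = 2 * params.gamma_of(i) + params.delta_of(i) + params.m_of(i)
        assert total == pytest.approx(expected)
        assert total <= 2.0


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_reference_parameters_are_valid(params, topo):
    assert tc.validate_parameters(params, topo) == []


def test_validate_reports_simplex_violation(topo):
    bad = tc.reference_parameters(gamma=(0.06, 0.9, 0.24), delta=(0.43, 0.3, 0.23))
    msgs = tc.validate_parameters(bad, topo)
    assert any("gamma_1+delta_1" in m for m in msgs)


def test_validate_reports_rho_sum_violation(topo):
    bad = tc.reference_parameters(rho={"SPL": 0.5, "ILN": 0.2, "MLN": 0.2})
    msgs = tc.validate_parameters(bad, topo)
    assert any("splitting" in m for m in msgs)


def test_validate_rejects_migrating_edge_generations(topo):
    bad = tc.reference_parameters(migrating_generations=frozenset({0, 1, 7}))
    msgs = tc.validate_parameters(bad, topo)
    assert any("generation 0" in m for m in msgs)
    assert any("p = 7" in m for m in msgs)


# ---------------------------------------------------------------------------
# config round trip
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ext", ["yaml", "json"])
def test_config_roundtrip_is_bit_exact(tmp_path, params, topo, ext):
    from tcellnet.io import load_config, save_config

    p1 = tmp_path / f"model.{ext}"
    p2 = tmp_path / f"model2.{ext}"
    save_config(params, topo, p1)
    loaded, topo2 = load_config(p1)
    save_config(loaded, topo2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert loaded == params
    assert topo2 == topo
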