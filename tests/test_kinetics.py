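"""Unit tests for the molecular state machines and their rate tables."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from boutonsim import kinetics as kin
from boutonsim.kinetics import (BUILDERS, N_A, FARADAY, analytic_steady_state,
                                build_calbindin, build_ip3r, build_pmca,
                                build_release_sensor, build_ryr, build_serca,
                                build_vdcc_gating, generator_matrix,
                                merge_rates, vdcc_flux_rate,
                                MarkovChannelScheme, TransitionSpec)


def rate_of(scheme, a, b):
    """Sum of rate constants of transitions a -> b."""
    return sum(tr.rate_constant for tr in scheme.transitions
               if tr.from_state == a and tr.to_state == b)


# --------------------------------------------------------------------------
# Tabulated rate constants


@pytest.mark.parametrize("a,b,forward,backward", [
    ("C1L", "C2L", 1.24e6, 13.6),
    ("C2L", "C3L", 2.98e7, 3867.0),
    ("C2L", "C5L", 1.81, 3.63),
    ("C3L", "O1L", 731.2, 4183.0),
    ("C4L", "O3L", 43.3, 253.3),
    ("C1H", "C2H", 3.26e6, 116.0),
    ("C2H", "O1H", 7.86e6, 1480.0),
    ("C4H", "O2H", 2390.0, 298.0),
    ("C1L", "C2H", 6.6e2, 0.083),
    ("C3L", "C4H", 6.6e2, 0.083),
])
def test_ryr_table_rates(a, b, forward, backward):
    ryr = build_ryr()
    assert rate_of(ryr, a, b) == pytest.approx(forward)
    assert rate_of(ryr, b, a) == pytest.approx(backward)


def test_ryr_structure():
    ryr = build_ryr()
    assert set(ryr.conducting_states) == {"O1L", "O2L", "O3L", "O1H", "O2H"}
    assert ryr.flux_rate_constant == pytest.approx(1.09e9)
    assert ryr.n_states == 14


def test_ryr_settles_closed_without_calcium():
    """With no cytosolic calcium every binding propensity vanishes and the
    stationary law carries no mass on open states."""
    ryr = build_ryr()
    for tr in ryr.transitions:
        if tr.order == "calcium_cytosolic":
            assert tr.rate_at(ca_cyt=0.0) == 0.0
    with pytest.warns(UserWarning):
        pi = analytic_steady_state(ryr, ca_cyt=0.0)
    assert sum(pi[s] for s in ryr.conducting_states) < 1e-12


def test_ip3r_unbinding_rates_and_open_state():
    ip3r = build_ip3r()
    # b1..b5 appear as the unbinding partners of their sites
    assert rate_of(ip3r, "S100", "S000") == pytest.approx(52.0)
    assert rate_of(ip3r, "S101", "S100") == pytest.approx(0.21)
    assert rate_of(ip3r, "S101", "S001") == pytest.approx(377.2)
    assert rate_of(ip3r, "S001", "S000") == pytest.approx(0.029)
    assert rate_of(ip3r, "S010", "S000") == pytest.approx(1.64)
    assert ip3r.conducting_states == ("S110",)
    assert ip3r.flux_rate_constant == pytest.approx(1.19e8)


def test_ip3r_open_state_unreachable_without_ip3():
    """S110 requires IP3; with [IP3]=0 no positive-rate path reaches it."""
    ip3r = build_ip3r()
    idx = ip3r.state_index()
    adj = {s: [] for s in ip3r.states}
    for tr in ip3r.transitions:
        if tr.rate_at(ca_cyt=1e-6, ca_lum=0, ip3=0.0) > 0:
            adj[tr.from_state].append(tr.to_state)
    seen, stack = {"S000"}, ["S000"]
    while stack:
        for nxt in adj[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    assert "S110" not in seen


def test_ip3r_stationary_matches_matrix_exponential():
    """Stationary law equals the long-time propagator row (independent
    oracle via expm rather than the null-space solve)."""
    from scipy.linalg import expm

    ip3r = build_ip3r()
    Q = generator_matrix(ip3r, ca_cyt=0.5e-6, ip3=1e-6)
    pi = analytic_steady_state(ip3r, ca_cyt=0.5e-6, ip3=1e-6)
    P = expm(Q * 5000.0)
    long_run = P[0]
    vec = np.array([pi[s] for s in ip3r.states])
    np.testing.assert_allclose(long_run, vec, atol=1e-9)


def test_serca_table_rates():
    serca = build_serca()
    assert rate_of(serca, "X2", "Y2") == pytest.approx(10.8)
    assert rate_of(serca, "Y2", "X2") == pytest.approx(75.08)
    assert rate_of(serca, "X1", "X2") == pytest.approx(1e8)
    assert rate_of(serca, "Y1", "Y2") == pytest.approx(1e5)
    assert rate_of(serca, "X0", "Y0") == pytest.approx(0.022)
    assert rate_of(serca, "Y0", "X0") == pytest.approx(7.2)
    assert rate_of(serca, "X1", "X0") == pytest.approx(83.67)
    assert rate_of(serca, "Y1", "Y0") == pytest.approx(30.012)


def test_serca_cycle_moves_two_ions():
    """One forward cycle X0->X1->X2->Y2->Y1->Y0->X0 takes 2 ions from the
    cytosolic ledger and deposits 2 in the ER ledger."""
    serca = build_serca()
    path = [("X0", "X1"), ("X1", "X2"), ("X2", "Y2"),
            ("Y2", "Y1"), ("Y1", "Y0"), ("Y0", "X0")]
    d_cyt = d_lum = 0
    for a, b in path:
        tr = next(t for t in serca.transitions
                  if t.from_state == a and t.to_state == b)
        d_cyt += tr.dca_cyt
        d_lum += tr.dca_lum
    assert d_cyt == -2 and d_lum == +2
    content = serca.calcium_content()
    assert content[serca.states.index("X2")] == 2
    assert content[serca.states.index("Y2")] == 2


def test_pmca_rates_and_extrusion():
    pmca = build_pmca()
    assert rate_of(pmca, "P1", "P2") == pytest.approx(100.0)
    assert rate_of(pmca, "P2", "P0") == pytest.approx(1.0e5)
    assert rate_of(pmca, "P0", "P1") == pytest.approx(1.5e8)
    assert rate_of(pmca, "P1", "P0") == pytest.approx(20.0)
    tr = next(t for t in pmca.transitions if t.from_state == "P1"
              and t.to_state == "P2")
    assert tr.dca_ext == 1
    assert merge_rates()["pmca.kpmleak"] == pytest.approx(12.5)


def test_calbindin_rates_and_multiplicity():
    cb = build_calbindin()
    assert rate_of(cb, "H0M0", "H1M0") == pytest.approx(2 * 0.55e7)
    assert rate_of(cb, "H0M0", "H0M1") == pytest.approx(2 * 4.35e7)
    assert rate_of(cb, "H2M0", "H1M0") == pytest.approx(2 * 2.6)
    assert rate_of(cb, "H0M2", "H0M1") == pytest.approx(2 * 35.8)


@pytest.mark.parametrize("ca", [0.1e-6, 0.5e-6, 2e-6])
def test_calbindin_equilibrium_matches_isotherm(ca):
    """Mean ions bound per molecule equals the closed-form independent
    two-site isotherm 2 c/(c+Kd_h) + 2 c/(c+Kd_m)."""
    cb = build_calbindin()
    pi = analytic_steady_state(cb, ca_cyt=ca)
    content = cb.calcium_content()
    mean_bound = sum(pi[s] * content[i] for i, s in enumerate(cb.states))
    kd_h = 2.6 / 0.55e7
    kd_m = 35.8 / 4.35e7
    expected = 2 * ca / (ca + kd_h) + 2 * ca / (ca + kd_m)
    assert mean_bound == pytest.approx(expected, rel=1e-9)


def test_vdcc_voltage_dependence():
    vdcc = build_vdcc_gating()
    a1 = next(t for t in vdcc.transitions
              if t.from_state == "C0" and t.to_state == "C1")
    # a1 at 0 mV is the tabulated 4.04 ms^-1; at V = V1 it gains a factor e
    assert a1.rate_at(voltage_mV=0.0) == pytest.approx(4040.0)
    assert a1.rate_at(voltage_mV=49.14) == pytest.approx(4040.0 * math.e)
    b4 = next(t for t in vdcc.transitions
              if t.from_state == "O" and t.to_state == "C3")
    assert b4.rate_at(voltage_mV=0.0) == pytest.approx(1840.0)
    assert b4.rate_at(voltage_mV=26.55) == pytest.approx(1840.0 / math.e)
    assert vdcc.conducting_states == ("O",)
    assert len(vdcc.conducting_states) == 1


def test_vdcc_flux_zero_voltage_limit():
    """At V=0 the flux equals the analytic series limit, matched numerically
    by evaluation at V = +-1e-6 mV."""
    limit = 3.72e-12 * N_A * 80.36e-3 * (1 - 0.3933) / (2 * FARADAY)
    assert vdcc_flux_rate(0.0) == pytest.approx(limit)
    assert vdcc_flux_rate(1e-6) == pytest.approx(limit, rel=1e-6)
    assert vdcc_flux_rate(-1e-6) == pytest.approx(limit, rel=1e-6)


def test_vdcc_flux_formula_and_scaling():
    # direct evaluation of the printed expression at -40 mV
    V, A, B, C = -40e-3, 3.72e-12, 0.3933, 80.36e-3
    expected = A * V * N_A * (B - math.exp(-V / C)) / \
        (2 * FARADAY * (1 - math.exp(V / C)))
    assert vdcc_flux_rate(-40.0) == pytest.approx(expected)
    # linear scaling with extracellular calcium (4 mM protocol support)
    assert vdcc_flux_rate(-40.0, ca_out=4e-3) == \
        pytest.approx(2 * vdcc_flux_rate(-40.0))


def test_vdcc_flux_continuous_nonnegative():
    v = np.linspace(-80, 60, 4001)
    f = np.array([vdcc_flux_rate(float(x)) for x in v])
    assert np.all(f >= 0)
    assert np.all(np.abs(np.diff(f)) < 0.01 * f.max())  # no jumps on the grid
    with pytest.raises(ValueError):
        vdcc_flux_rate(float("nan"))


def test_sensor_fusion_propensities():
    sensor = build_release_sensor()
    # fully synchronous-bound: gamma; fully asynchronous-bound: a*gamma = 50
    assert rate_of(sensor, "S5A0", "R") == pytest.approx(2e3 + 0.417e-3)
    assert rate_of(sensor, "S0A2", "R") == pytest.approx(50.0 + 0.417e-3)
    # unbound vesicle: only the spontaneous pathway
    assert rate_of(sensor, "S0A0", "R") == pytest.approx(0.417e-3)
    spont = [t for t in sensor.transitions if t.event == "spontaneous"]
    assert len(spont) == 18 and all(t.rate_constant == 0.417e-3 for t in spont)
    # refractory dead time 1/epsilon, then an empty site refills
    assert rate_of(sensor, "R", "E") == pytest.approx(1 / 6.34e-3)
    assert rate_of(sensor, "E", "S0A0") == pytest.approx(0.34)


def test_sensor_cooperativity_scaling():
    sensor = build_release_sensor()
    # off-rate from S{j} is j * ks- * b^(j-1)
    for j in (1, 3, 5):
        assert rate_of(sensor, f"S{j}A0", f"S{j - 1}A0") == \
            pytest.approx(j * 2.32e3 * 0.25 ** (j - 1))
    # on-rate multiplicity (5 - j) * ks+
    assert rate_of(sensor, "S0A0", "S1A0") == pytest.approx(5 * 0.612e8)
    assert rate_of(sensor, "S4A0", "S5A0") == pytest.approx(1 * 0.612e8)


def test_two_state_toy_steady_state():
    toy = MarkovChannelScheme(
        "toy", ("C", "O"),
        (TransitionSpec("C", "O", 1e6, "calcium_cytosolic", dca_cyt=-1),
         TransitionSpec("O", "C", 3.0, dca_cyt=+1)),
        conducting_states=("O",))
    pi = analytic_steady_state(toy, ca_cyt=1e-6)  # k_on*ca = 1 /s vs 3 /s
    assert pi["O"] == pytest.approx(0.25)


@pytest.mark.parametrize("name", sorted(BUILDERS))
def test_generator_rows_sum_to_zero(name):
    scheme = BUILDERS[name]()
    Q = generator_matrix(scheme, ca_cyt=1e-6, ca_lum=1e-4, ip3=1e-6,
                         voltage_mV=-30.0)
    np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-9)


@given(ca=st.floats(0, 1e-3), lum=st.floats(0, 1e-3),
       ip3=st.floats(0, 1e-5), v=st.floats(-90, 60))
def test_propensities_nonnegative_and_normalized(ca, lum, ip3, v):
    """For any non-negative ligand values every transition rate is >= 0 and
    the stationary occupancies sum to one."""
    for name in ("ryr", "serca", "vdcc", "calbindin"):
        scheme = BUILDERS[name]()
        for tr in scheme.transitions:
            assert tr.rate_at(ca_cyt=ca, ca_lum=lum, ip3=ip3,
                              voltage_mV=v) >= 0
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi = analytic_steady_state(scheme, ca_cyt=ca, ca_lum=lum,
                                       ip3=ip3, voltage_mV=v)
        assert sum(pi.values()) == pytest.approx(1.0, abs=1e-12)


def test_rate_table_overrides():
    table = merge_rates({"sensor.gamma": 1234.0})
    assert table["sensor.gamma"] == 1234.0
    assert table["sensor.delta"] == 0.417e-3
    with pytest.raises(KeyError):
        merge_rates({"not.a.symbol": 1.0})
    with pytest.raises(ValueError):
        merge_rates({"sensor.gamma": -1.0})
    sensor = build_release_sensor(rates={"sensor.gamma": 1000.0})
    assert rate_of(sensor, "S5A1", "R") == pytest.approx(1000.0 + 0.417e-3)


def test_scheme_invariants_rejected():
    with pytest.raises(ValueError):
        MarkovChannelScheme("bad", ("A", "A"), ())
    with pytest.raises(ValueError):
        MarkovChannelScheme("bad", ("A", "B"),
                            (TransitionSpec("A", "C", 1.0),))
    with pytest.raises(ValueError):  # disconnected
        MarkovChannelScheme("bad", ("A", "B", "C"),
                            (TransitionSpec("A", "B", 1.0),))
    with pytest.raises(ValueError):  # voltage params mismatch
        TransitionSpec("A", "B", 1.0, "voltage_dependent")
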