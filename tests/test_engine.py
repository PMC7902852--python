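"""Tests for the stochastic engine: determinism, conservation, oracles."""

import numpy as np
import pytest

from boutonsim import kinetics
from boutonsim.analysis import ReleaseEventLog
from boutonsim.engine import (compile_model, integrate_mean_field, run_ensemble,
                              run_trial, trial_schedule)
from boutonsim.stimulus import APWaveform, ProtocolSpec, make_protocol

from conftest import make_clamped_config, make_reduced_config


def clamped_protocol(total_time, voltage=-70.0):
    wf = APWaveform((), rest_voltage=voltage)
    return ProtocolSpec("none", (), total_time, waveform=wf)


def test_same_seed_identical_results(reduced_config):
    p = make_protocol("single", total_time=0.030)
    a = run_trial(reduced_config, p, seed=7)
    b = run_trial(reduced_config, p, seed=7)
    np.testing.assert_array_equal(a.trace, b.trace)
    np.testing.assert_array_equal(a.event_times, b.event_times)
    assert list(a.event_pathways) == list(b.event_pathways)
    c = run_trial(reduced_config, p, seed=8)
    assert not np.array_equal(a.trace, c.trace)


def test_ledger_conservation_every_sample(control_config):
    """Free + bound + extruded - influx is an exact integer constant along
    the whole trajectory of a stimulated trial."""
    p = make_protocol("single", total_time=0.030)
    tr = run_trial(control_config, p, seed=3, trace_dt=1e-4,
                   trace_species="all")
    cm = tr.compiled
    vals = {cm.conserved_calcium(row) for row in tr.trace}
    assert len(vals) == 1
    assert tr.ledger_balanced()


def test_no_vdcc_release_is_baseline_only(control_config):
    """Without VDCCs an AP evokes nothing: no synchronous release, only the
    rare baseline activity of the sensor at resting calcium (the
    calcium-independent delta pathway plus occasional asynchronous fusions
    from the ~3% resting occupancy of the high-affinity async sites)."""
    import copy
    cfg = copy.deepcopy(control_config)
    cfg.population("vdcc").count = 0
    cfg.name = "no_vdcc"
    p = make_protocol("single")
    trials = run_ensemble(cfg, p, 100, base_seed=50)
    paths = [pw for t in trials for pw in t.event_pathways]
    assert "synchronous" not in paths
    # baseline rate ~ 0.04/s per vesicle (async) + delta: a handful at most
    # across 100 trials x 50 ms
    assert len(paths) <= 8


def test_ensemble_trivia(reduced_config):
    p = make_protocol("single", total_time=0.030)
    ens = run_ensemble(reduced_config, p, 1, base_seed=11)
    solo = run_trial(reduced_config, p, seed=11)
    assert len(ens) == 1
    np.testing.assert_array_equal(ens[0].trace, solo.trace)
    with pytest.raises(ValueError):
        run_ensemble(reduced_config, p, 0, base_seed=1)


def test_trial_schedule_presets():
    assert trial_schedule(40) == 5000
    assert trial_schedule(60) == 5000
    assert trial_schedule(80) == 2000
    assert trial_schedule(100) == 1000
    assert trial_schedule(160) == 1000


@pytest.mark.parametrize("scheme,count,ligands,voltage,T", [
    ("vdcc", 60, dict(ca_cyt=100e-9), -30.0, 1.0),
    ("serca", 60, dict(ca_cyt=0.3e-6, ca_lum=100e-6), -70.0, 4.0),
    ("calbindin", 60, dict(ca_cyt=0.5e-6), -70.0, 4.0),
])
def test_ssa_occupancy_matches_analytic(scheme, count, ligands, voltage, T):
    """Long-run SSA occupancy at clamped ligands equals the stationary law
    of the generator within 3 SE (SE across independent replicates)."""
    cfg = make_clamped_config(scheme, count, ligands.get("ca_cyt", 0.0),
                              ligands.get("ca_lum", 0.0))
    sch = kinetics.BUILDERS[scheme]()
    pi = kinetics.analytic_steady_state(sch, voltage_mV=voltage, **ligands)
    # pick the most informative states: occupancy in (0.05, 0.95)
    targets = [s for s in sch.states if 0.05 < pi[s] < 0.95]
    assert targets
    occ = {s: [] for s in targets}
    for rep in range(8):
        tr = run_trial(cfg, clamped_protocol(T, voltage), seed=100 + rep,
                       trace_dt=0.25, trace_species="all", mode="ssa")
        for s in targets:
            j = tr.compiled.species_index(f"pop.{s}")
            occ[s].append(tr.integrals[j] / (T * count))
    for s in targets:
        m = np.mean(occ[s])
        se = np.std(occ[s], ddof=1) / np.sqrt(len(occ[s]))
        assert abs(m - pi[s]) < 3 * se + 0.005, \
            f"{scheme}.{s}: {m:.4f} vs analytic {pi[s]:.4f} (se {se:.4f})"


def test_tau_leap_matches_ssa_on_reduced_model():
    """Release statistics from tau-leaping and exact SSA agree on a reduced
    terminal (10 VDCCs, no ER machinery)."""
    from scipy.stats import mannwhitneyu

    cfg = make_reduced_config(n_vdcc=25)
    p = make_protocol("single", total_time=0.025)
    counts = {}
    for mode in ("tau", "ssa"):
        ens = run_ensemble(cfg, p, 400, base_seed=500, mode=mode)
        counts[mode] = np.array([len(t.event_times) for t in ens])
    res = mannwhitneyu(counts["tau"], counts["ssa"])
    assert res.pvalue > 0.01, (counts["tau"].mean(), counts["ssa"].mean())


def test_mean_field_rest_stability(control_config):
    p = make_protocol("none", total_time=1.0)
    mf = integrate_mean_field(control_config, p)
    cyt = mf.mean_free_ca(["bulk", "az", "vdcc"])
    assert cyt == pytest.approx(100e-9, rel=0.05)
    er = mf.mean_free_ca(["er"])
    assert er == pytest.approx(250e-6, rel=0.05)


def test_mean_field_matches_ensemble_mean(reduced_config):
    """Law of large numbers: the ensemble-mean bulk calcium trace agrees
    with the mean-field trace within 3 SE at sampled times."""
    p = make_protocol("single", total_time=0.030)
    ens = run_ensemble(reduced_config, p, 300, base_seed=900, trace_dt=2e-3)
    stack = np.stack([t.column("ca.bulk") for t in ens]).astype(float)
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    mf = integrate_mean_field(reduced_config, p, t_eval=ens[0].trace_times)
    ref = mf.species("ca.bulk")
    for k in range(0, len(ref), 3):
        assert abs(mean[k] - ref[k]) < 3 * se[k] + 2.0, \
            f"t={ens[0].trace_times[k]}: {mean[k]} vs {ref[k]}"


def test_event_times_within_bounds(control_config):
    p = make_protocol("single")
    trials = run_ensemble(control_config, p, 30, base_seed=77)
    for tr in trials:
        if len(tr.event_times):
            assert tr.event_times.min() > 0
            assert tr.event_times.max() <= p.total_time + 1e-12


def test_stores_blocked_er_flux_zero(blocked_config):
    p = make_protocol("single", total_time=0.030)
    tr = run_trial(blocked_config, p, seed=5, trace_species="all")
    cm = tr.compiled
    er_idx = cm.pool_species[cm.pool_index("er")]
    assert tr.final_state.species_counts[er_idx] == 0
    assert tr.trace[:, er_idx].max() == 0
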