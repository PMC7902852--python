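import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from boutonsim import assembly, engine, kinetics, stimulus  # noqa: E402
from boutonsim.assembly import (CompartmentSpec, ExchangeSpec, ModelConfig,
                                PopulationSpec, build_canonical_model,
                                calibrate_leak_sites)


@pytest.fixture(scope="session")
def control_config():
    return build_canonical_model(80)


@pytest.fixture(scope="session")
def blocked_config():
    return build_canonical_model(80, stores_blocked=True)


def make_reduced_config(n_vdcc=10, with_er=False, seed_label="reduced"):
    """A small, fast configuration: few molecules, no ER machinery unless
    requested.  Used for exact-SSA comparisons and conservation tests."""
    cfg = build_canonical_model(max(n_vdcc, 1))
    cfg.name = seed_label
    for p in cfg.populations:
        if p.label == "vdcc":
            p.count = n_vdcc
        elif p.scheme_name == "serca":
            p.count = 300 if with_er else 0
        elif p.scheme_name in ("ryr", "ip3r"):
            p.count = 5 if with_er else 0
        elif p.scheme_name == "pmca":
            p.count = 100
        elif p.scheme_name == "calbindin":
            p.count = min(p.count, 200)
    if not with_er:
        cfg.compartment("er").initial_free_ca_M = 0.0
    cfg.leak_site_count = calibrate_leak_sites(cfg)
    return cfg


def make_clamped_config(scheme_name, count, ca_cyt, ca_lum=0.0, ip3=0.0):
    """One population in effectively infinite calcium pools so ligand
    concentrations stay clamped while the scheme gates stochastically."""
    def vol_for(conc, n_ions=10**8):
        if conc <= 0:
            return 1.0
        return n_ions / (kinetics.N_A * conc * 1e-15)

    comps = [
        CompartmentSpec("bulk", vol_for(ca_cyt), ca_cyt),
        CompartmentSpec("az", 1.0, ca_cyt),
        CompartmentSpec("vdcc", 1.0, ca_cyt),
        CompartmentSpec("er", vol_for(ca_lum), ca_lum),
        CompartmentSpec("ext", 1.0, 2e-3, is_reservoir=True),
    ]
    pop = PopulationSpec("pop", scheme_name, count,
                         sensed_compartment="bulk",
                         luminal_compartment="er" if scheme_name in
                         ("serca", "ryr", "ip3r") else None,
                         flux_target="bulk" if scheme_name in
                         ("ryr", "ip3r", "vdcc") else None)
    return ModelConfig(compartments=comps, populations=[pop], exchange=[],
                       ip3_M=ip3, leak_site_count=0, name=f"clamp_{scheme_name}")


@pytest.fixture(scope="session")
def reduced_config():
    return make_reduced_config()
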