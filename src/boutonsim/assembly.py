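"""Compartmentalized bouton assembly.

The spatial bouton is approximated by well-mixed pools: a cytosolic bulk, a
small shell over the active zone (AZ) where docked vesicles sense calcium, a
subdomain around the VDCC cluster (the channels sit at an effective distance
of ~350 nm from the active zone, so their calcium reaches the sensors only
after dilution), the ER lumen, and a clamped extracellular reservoir.
Pairwise first-order exchange between the cytosolic pools stands in for
diffusion; the three conductances are calibration parameters and ship with
values tuned so that a single action potential produces a sharp ~1 ms AZ
calcium transient and a single-AP release probability of 0.10-0.20 at the
80-VDCC reference configuration.

Geometry follows a canonical CA3 terminal: a 0.5 x 0.5 x 4 um cuboid
(surface area 8.5 um^2) containing a 0.1 x 0.1 x 3.9 um ER rod.  Resting
free calcium is 100 nM in the cytosolic pools, 250 uM in the ER and 2 mM
outside.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import List, Optional

from .kinetics import N_A, analytic_steady_state, merge_rates

# canonical geometry (um, um^2, um^3)
BOUTON_DIMS = (0.5, 0.5, 4.0)
ER_DIMS = (0.1, 0.1, 3.9)
BOUTON_VOLUME = BOUTON_DIMS[0] * BOUTON_DIMS[1] * BOUTON_DIMS[2]        # 1.0
ER_VOLUME = ER_DIMS[0] * ER_DIMS[1] * ER_DIMS[2]                        # 0.039
CYTOSOL_VOLUME = BOUTON_VOLUME - ER_VOLUME                              # 0.961
PM_AREA = 8.5
ER_AREA = 2 * ER_DIMS[0] * ER_DIMS[1] + 4 * ER_DIMS[0] * ER_DIMS[2]    # 1.58
AZ_VOLUME = 0.005
VDCC_VOLUME = 0.02

# resting conditions
CA_REST_CYT = 100e-9   # M
CA_REST_ER = 250e-6    # M
CA_OUT_DEFAULT = 2e-3  # M

# molecule placement defaults; SERCA density is the only printed one, the
# others are exposed for sensitivity sweeps
SERCA_DENSITY = 5500.0   # um^-2 on the ER membrane
PMCA_DENSITY = 180.0     # um^-2 on the plasma membrane
RYR_COUNT = 40
IP3R_COUNT = 20
CALBINDIN_CONC = 45e-6   # M, literature-typical (not printed in the source data)

# calibrated inter-pool exchange conductances, um^3/s (see docs/methods.md)
EXCHANGE_DEFAULTS = {
    ("vdcc", "bulk"): 25.0,
    ("vdcc", "az"): 1.1,
    ("az", "bulk"): 16.0,
}

# fraction of the ER membrane (SERCA pumps) exposed to the VDCC subdomain:
# the ER lies ~50 nm from the channel cluster, so part of the pump
# population samples the local transient rather than the bulk
SERCA_VDCC_FRACTION = 0.3

RRP_SIZE = 7
RRP_REFILL_RATE = 0.34  # s^-1 per empty release site


@dataclass
class CompartmentSpec:
    """A well-mixed calcium pool.  Reservoirs hold a clamped concentration."""

    name: str
    volume_um3: float
    initial_free_ca_M: float
    is_reservoir: bool = False

    def __post_init__(self):
        if self.volume_um3 <= 0:
            raise ValueError(f"compartment {self.name!r}: volume must be > 0")
        if self.initial_free_ca_M < 0:
            raise ValueError(f"compartment {self.name!r}: calcium must be >= 0")

    @property
    def volume_L(self) -> float:
        return self.volume_um3 * 1e-15


@dataclass
class PopulationSpec:
    """A population of identical molecules of one kinetic scheme.

    ``sensed_compartment`` supplies the cytosolic-facing calcium that drives
    binding; ``luminal_compartment`` (pumps and ER channels only) the ER-side
    calcium; ``flux_target`` is the pool that receives channel flux.
    """

    label: str
    scheme_name: str
    count: int
    sensed_compartment: str
    luminal_compartment: Optional[str] = None
    flux_target: Optional[str] = None

    def __post_init__(self):
        if self.count < 0:
            raise ValueError(f"population {self.label!r}: count must be >= 0")


@dataclass
class ExchangeSpec:
    """Diffusive exchange between two pools: flux a->b = g * [Ca]_a (ions/s
    with concentration in ions/um^3), symmetric in the conductance g."""

    comp_a: str
    comp_b: str
    conductance_um3_per_s: float

    def __post_init__(self):
        if self.conductance_um3_per_s < 0:
            raise ValueError("exchange conductance must be >= 0")


@dataclass
class ModelConfig:
    """Complete specification of one synaptic configuration."""

    compartments: List[CompartmentSpec]
    populations: List[PopulationSpec]
    exchange: List[ExchangeSpec]
    ca_out_M: float = CA_OUT_DEFAULT
    rrp_size: int = RRP_SIZE
    rrp_refill_rate_per_s: float = RRP_REFILL_RATE
    ip3_M: float = 0.0
    stores_blocked: bool = False
    leak_site_count: int = 0
    rate_overrides: dict = field(default_factory=dict)
    rng_seed: int = 0
    name: str = "model"

    def __post_init__(self):
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("compartment names must be unique")
        known = set(names)
        for p in self.populations:
            for ref in (p.sensed_compartment, p.luminal_compartment, p.flux_target):
                if ref is not None and ref not in known:
                    raise ValueError(
                        f"population {p.label!r} references unknown compartment {ref!r}")
        for ex in self.exchange:
            if ex.comp_a not in known or ex.comp_b not in known:
                raise ValueError("exchange references unknown compartment")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("population labels must be unique")
        merge_rates(self.rate_overrides)  # validates symbols

    # -- access helpers -----------------------------------------------------
    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def population(self, label: str) -> PopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    def cytosolic_volume(self) -> float:
        return sum(c.volume_um3 for c in self.compartments
                   if not c.is_reservoir and c.name != "er")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "compartments": [asdict(c) for c in self.compartments],
            "populations": [asdict(p) for p in self.populations],
            "exchange": [asdict(e) for e in self.exchange],
            "ca_out_M": self.ca_out_M,
            "rrp_size": self.rrp_size,
            "rrp_refill_rate_per_s": self.rrp_refill_rate_per_s,
            "ip3_M": self.ip3_M,
            "stores_blocked": self.stores_blocked,
            "leak_site_count": self.leak_site_count,
            "rate_overrides": dict(self.rate_overrides),
            "rng_seed": self.rng_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        allowed = {"name", "compartments", "populations", "exchange", "ca_out_M",
                   "rrp_size", "rrp_refill_rate_per_s", "ip3_M", "stores_blocked",
                   "leak_site_count", "rate_overrides", "rng_seed"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)} "
                             "(keys carry explicit units, e.g. 'ca_out_M')")
        comps = [CompartmentSpec(**c) for c in d.pop("compartments")]
        pops = [PopulationSpec(**p) for p in d.pop("populations")]
        exch = [ExchangeSpec(**e) for e in d.pop("exchange")]
        return cls(compartments=comps, populations=pops, exchange=exch, **d)


def concentration_to_count(molar: float, volume_um3: float) -> int:
    """Integer ion count for a molar concentration in a volume (um^3)."""
    if molar < 0 or volume_um3 <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    return int(round(N_A * molar * volume_um3 * 1e-15))


def count_to_concentration(count: float, volume_um3: float) -> float:
    """Molar concentration of a number of ions in a volume (um^3)."""
    if count < 0 or volume_um3 <= 0:
        raise ValueError("count must be >= 0 and volume > 0")
    return count / (N_A * volume_um3 * 1e-15)


def calibrate_leak_sites(config: "ModelConfig") -> int:
    """Number of plasma-membrane leak sites pinning the resting fixed point.

    Each leak site injects calcium at kpmleak (scaled by extracellular
    calcium relative to 2 mM).  The count is chosen so that at the resting
    concentrations the mean-field net calcium flux into the cytosol is zero:
    the leak balances PMCA extrusion minus the (small) resting influx through
    VDCCs at -70 mV and the net ER release through RyR/IP3R/SERCA.
    """
    import warnings as _w

    from .kinetics import BUILDERS, vdcc_flux_rate
    from .stimulus import REST_VOLTAGE

    r = merge_rates(config.rate_overrides)
    net = 0.0  # non-leak influx to the cytosol at rest, ions/s
    for pop in config.populations:
        if pop.count == 0:
            continue
        c_sens = config.compartment(pop.sensed_compartment).initial_free_ca_M
        c_lum = (config.compartment(pop.luminal_compartment).initial_free_ca_M
                 if pop.luminal_compartment else 0.0)
        if pop.scheme_name == "sensor":
            continue
        scheme = BUILDERS[pop.scheme_name](rates=config.rate_overrides)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            pi = analytic_steady_state(scheme, ca_cyt=c_sens, ca_lum=c_lum,
                                       ip3=config.ip3_M,
                                       voltage_mV=REST_VOLTAGE)
        if pop.scheme_name == "pmca":
            net -= pop.count * r["pmca.kpm3"] * pi["P1"]
        elif pop.scheme_name == "vdcc":
            net += (pop.count * pi["O"]
                    * vdcc_flux_rate(REST_VOLTAGE, config.ca_out_M,
                                     config.rate_overrides))
        elif pop.scheme_name == "serca":
            transloc = 2.0 * (pi["X2"] * r["serca.X2Y2"]
                              - pi["Y2"] * r["serca.Y2X2"])
            net -= pop.count * transloc
        elif pop.scheme_name in ("ryr", "ip3r"):
            po = sum(pi[s] for s in scheme.conducting_states)
            net += pop.count * po * float(scheme.flux_rate_constant) * c_lum
    scale = config.ca_out_M / 2e-3
    n_leak = -net / (r["pmca.kpmleak"] * scale)
    return max(0, int(round(n_leak)))


def _assemble(total_volume: float, pm_area: float, er_area: float,
              az_volume: float, vdcc_volume: float, er_volume: float,
              n_vdcc: int, stores_blocked: bool, ca_out: float,
              exchange_scale: float, name: str,
              rate_overrides: Optional[dict] = None) -> ModelConfig:
    cyt_volume = total_volume - er_volume
    bulk_volume = cyt_volume - az_volume - vdcc_volume
    if bulk_volume <= 0:
        raise ValueError("bulk volume must remain positive")
    er_ca = 0.0 if stores_blocked else CA_REST_ER
    comps = [
        CompartmentSpec("bulk", bulk_volume, CA_REST_CYT),
        CompartmentSpec("az", az_volume, CA_REST_CYT),
        CompartmentSpec("vdcc", vdcc_volume, CA_REST_CYT),
        CompartmentSpec("er", er_volume, er_ca),
        CompartmentSpec("ext", 1.0, ca_out, is_reservoir=True),
    ]
    n_serca = 0 if stores_blocked else int(round(SERCA_DENSITY * er_area))
    n_serca_vdcc = int(round(n_serca * SERCA_VDCC_FRACTION))
    n_pmca = int(round(PMCA_DENSITY * pm_area))
    pops = [
        PopulationSpec("vdcc", "vdcc", n_vdcc, sensed_compartment="vdcc",
                       flux_target="vdcc"),
        # the RyRs sit ~50 nm from the channel cluster and sense (and feed)
        # the VDCC subdomain
        PopulationSpec("ryr", "ryr", RYR_COUNT, sensed_compartment="vdcc",
                       luminal_compartment="er", flux_target="vdcc"),
        PopulationSpec("ip3r", "ip3r", IP3R_COUNT, sensed_compartment="bulk",
                       luminal_compartment="er", flux_target="bulk"),
        PopulationSpec("serca", "serca", n_serca - n_serca_vdcc,
                       sensed_compartment="bulk", luminal_compartment="er"),
        PopulationSpec("serca@vdcc", "serca", n_serca_vdcc,
                       sensed_compartment="vdcc", luminal_compartment="er"),
        PopulationSpec("pmca", "pmca", n_pmca, sensed_compartment="bulk"),
        PopulationSpec("sensor", "sensor", RRP_SIZE, sensed_compartment="az"),
    ]
    for comp in ("bulk", "az", "vdcc"):
        vol = next(c for c in comps if c.name == comp).volume_um3
        pops.append(PopulationSpec(f"calbindin@{comp}", "calbindin",
                                   concentration_to_count(CALBINDIN_CONC, vol),
                                   sensed_compartment=comp))
    exch = [ExchangeSpec(a, b, g * exchange_scale)
            for (a, b), g in EXCHANGE_DEFAULTS.items()]
    cfg = ModelConfig(
        compartments=comps, populations=pops, exchange=exch,
        ca_out_M=ca_out, stores_blocked=stores_blocked,
        rate_overrides=rate_overrides or {}, name=name,
    )
    cfg.leak_site_count = calibrate_leak_sites(cfg)
    return cfg


def build_canonical_model(n_vdcc: int = 80, stores_blocked: bool = False,
                          ca_out: float = CA_OUT_DEFAULT,
                          rate_overrides: Optional[dict] = None) -> ModelConfig:
    """Canonical CA3 terminal: 0.5 x 0.5 x 4 um bouton with a 0.1 x 0.1 x 3.9
    um ER rod; SERCA from the 5500 um^-2 density on the 1.58 um^2 ER
    membrane, an RRP of 7 docked vesicles sensing the AZ shell, VDCCs
    injecting into their subdomain, RyR/IP3R facing the bulk and PMCA plus a
    calibrated leak on the plasma membrane."""
    if not (1 <= n_vdcc <= 10_000):
        raise ValueError("n_vdcc must be in [1, 10000]")
    name = "stores_blocked_canonical" if stores_blocked else "control_canonical"
    if ca_out != CA_OUT_DEFAULT:
        name = f"{name}_{ca_out * 1e3:g}mM"
    return _assemble(BOUTON_VOLUME, PM_AREA, ER_AREA, AZ_VOLUME, VDCC_VOLUME,
                     ER_VOLUME, n_vdcc, stores_blocked, ca_out, 1.0, name,
                     rate_overrides)


def build_reconstructed_like_model(n_vdcc: int = 80, stores_blocked: bool = False,
                                   ca_out: float = CA_OUT_DEFAULT,
                                   rate_overrides: Optional[dict] = None
                                   ) -> ModelConfig:
    """Same assembly scaled to the 0.39 um^3 volume measured for a terminal
    reconstructed from EM data (ER-to-membrane spacing mode ~120 nm).  All
    per-area and per-volume molecule densities equal the canonical model's;
    linear dimensions scale by 0.39^(1/3), areas by 0.39^(2/3), and the
    exchange conductances by the volume ratio so per-ion hop rates match."""
    if not (1 <= n_vdcc <= 10_000):
        raise ValueError("n_vdcc must be in [1, 10000]")
    s = 0.39 / BOUTON_VOLUME
    a = s ** (2.0 / 3.0)
    name = "reconstructed_like"
    if stores_blocked:
        name += "_stores_blocked"
    return _assemble(BOUTON_VOLUME * s, PM_AREA * a, ER_AREA * a,
                     AZ_VOLUME * s, VDCC_VOLUME * s, ER_VOLUME * s,
                     n_vdcc, stores_blocked, ca_out, s, name, rate_overrides)


def apply_stores_blocked(config: ModelConfig) -> ModelConfig:
    """Thapsigargin-like condition: zero SERCA and an empty ER.

    With no luminal calcium the RyR/IP3R flux carries zero ions, so the ER
    release channels become redundant; everything else is untouched.
    """
    cfg = copy.deepcopy(config)
    cfg.stores_blocked = True
    for p in cfg.populations:
        if p.scheme_name == "serca":
            p.count = 0
    for c in cfg.compartments:
        if c.name == "er":
            c.initial_free_ca_M = 0.0
    if not cfg.name.endswith("stores_blocked"):
        cfg.name = cfg.name.replace("control", "stores_blocked") \
            if "control" in cfg.name else cfg.name + "_stores_blocked"
    return cfg
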