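"""Markov state machines for the molecules of the presynaptic terminal.

Every molecular species in the bouton model — the voltage-dependent calcium
channel (VDCC), the two ER release channels (ryanodine receptor and IP3
receptor), the SERCA and PMCA pumps, the calbindin-D28k buffer and the
dual-sensor release machinery on docked vesicles — is described by a finite
Markov scheme: a set of named states connected by transitions whose rates are
constant, proportional to a ligand concentration (cytosolic or luminal free
calcium, IP3), or exponentially dependent on membrane voltage.

The rate constants ship as a flat table keyed by the conventional symbol
names (``a10``, ``X2Y2``, ``ks+`` ...) so that overrides in configuration
files remain auditable.  All second-order rates are in M^-1 s^-1, first-order
rates in s^-1 unless noted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

N_A = 6.02214076e23  # Avogadro, mol^-1
FARADAY = 96485.33212  # C mol^-1

ORDERS = (
    "constant",
    "calcium_cytosolic",
    "calcium_luminal",
    "ip3",
    "voltage_dependent",
)


@dataclass(frozen=True)
class VoltageParams:
    """Exponential voltage dependence k(V) = base * exp(sign * V / efold).

    ``base_per_ms`` is the rate at 0 mV in ms^-1, ``efold_mV`` the e-fold
    voltage in mV, ``sign`` +1 for opening (forward) and -1 for closing.
    """

    base_per_ms: float
    efold_mV: float
    sign: int


@dataclass(frozen=True)
class TransitionSpec:
    """One directed transition of a Markov scheme.

    ``rate_constant`` is in s^-1 for first-order transitions and M^-1 s^-1
    for ligand-driven ones.  ``dca_cyt``/``dca_lum``/``dca_ext`` give the
    number of free calcium ions the transition adds to the sensed cytosolic
    pool, the luminal (ER) pool and the extracellular space; bindings are -1,
    unbindings +1, vesicle fusion returns all sensor-bound ions.  ``event``
    tags fusion transitions with their release pathway.
    """

    from_state: str
    to_state: str
    rate_constant: float
    order: str = "constant"
    voltage_params: Optional[VoltageParams] = None
    dca_cyt: int = 0
    dca_lum: int = 0
    dca_ext: int = 0
    event: Optional[str] = None

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValueError(f"unknown transition order {self.order!r}")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        if (self.order == "voltage_dependent") != (self.voltage_params is not None):
            raise ValueError("voltage_params present iff order='voltage_dependent'")

    def rate_at(self, ca_cyt: float = 0.0, ca_lum: float = 0.0,
                ip3: float = 0.0, voltage_mV: float = 0.0) -> float:
        """Evaluate the transition rate (s^-1) at clamped ligand/voltage."""
        if self.order == "constant":
            return self.rate_constant
        if self.order == "calcium_cytosolic":
            return self.rate_constant * ca_cyt
        if self.order == "calcium_luminal":
            return self.rate_constant * ca_lum
        if self.order == "ip3":
            return self.rate_constant * ip3
        vp = self.voltage_params
        return 1e3 * vp.base_per_ms * math.exp(vp.sign * voltage_mV / vp.efold_mV)


@dataclass(frozen=True)
class MarkovChannelScheme:
    """A named finite-state scheme with its transitions and special states.

    ``conducting_states`` are the states that carry calcium flux (open
    channel states); ``flux_rate_constant`` is the per-open-channel flux
    constant in M^-1 s^-1 applied to the driving free-calcium concentration
    (ER calcium for RyR/IP3R), or the tag ``"vdcc"`` for the voltage-dependent
    single-channel flux.  ``release_states`` (sensor only) are the states
    from which calcium-driven fusion can proceed.
    """

    name: str
    states: tuple
    transitions: tuple
    conducting_states: tuple = ()
    flux_rate_constant: object = None
    release_states: tuple = ()

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("states must be unique")
        sset = set(self.states)
        for tr in self.transitions:
            if tr.from_state not in sset or tr.to_state not in sset:
                raise ValueError(
                    f"transition {tr.from_state}->{tr.to_state} uses unknown state")
        if not set(self.conducting_states) <= sset:
            raise ValueError("conducting_states must be a subset of states")
        if not set(self.release_states) <= sset:
            raise ValueError("release_states must be a subset of states")
        if not self._connected():
            raise ValueError(f"scheme {self.name!r}: state graph is not connected")

    def _connected(self) -> bool:
        adj = {s: set() for s in self.states}
        for tr in self.transitions:
            adj[tr.from_state].add(tr.to_state)
            adj[tr.to_state].add(tr.from_state)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self) -> dict:
        return {s: i for i, s in enumerate(self.states)}

    def calcium_content(self) -> np.ndarray:
        """Ions of calcium bound per molecule in each state.

        Computed by propagating the per-transition calcium stoichiometry from
        the first state (content 0); used by the engine's conservation ledger.
        Raises if the stoichiometry is inconsistent around any cycle.
        """
        idx = self.state_index()
        content = np.full(self.n_states, -10**9, dtype=np.int64)
        content[0] = 0
        # a fusion event resets the site; its calcium return is handled by the
        # explicit dca terms, so the bound content of the target state is what
        # the propagation below assigns it.
        pending = [0]
        edges = {}
        for tr in self.transitions:
            a, b = idx[tr.from_state], idx[tr.to_state]
            d = -(tr.dca_cyt + tr.dca_lum + tr.dca_ext)
            edges.setdefault(a, []).append((b, d))
            edges.setdefault(b, []).append((a, -d))
        while pending:
            a = pending.pop()
            for b, d in edges.get(a, ()):
                want = content[a] + d
                if content[b] == -10**9:
                    content[b] = want
                    pending.append(b)
                elif content[b] != want:
                    raise ValueError(
                        f"scheme {self.name!r}: inconsistent calcium "
                        f"stoichiometry at state {self.states[b]!r}")
        return content


@dataclass(frozen=True)
class SensorReleaseSpec:
    """Parameters of the dual-sensor release machinery on a docked vesicle."""

    n_sync_sites: int = 5
    n_async_sites: int = 2
    k_sync_on: float = 0.612e8
    k_sync_off: float = 2.32e3
    k_async_on: float = 3.82e6
    k_async_off: float = 13.0
    coop_b: float = 0.25
    async_scale_a: float = 0.025
    gamma: float = 2e3
    delta: float = 0.417e-3
    refractory_eps: float = 6.34e-3

    def __post_init__(self) -> None:
        if self.n_sync_sites != 5 or self.n_async_sites != 2:
            raise ValueError("dual sensor has 5 synchronous and 2 asynchronous sites")
        if not (0 < self.coop_b <= 1):
            raise ValueError("cooperativity b must be in (0, 1]")
        for r in (self.k_sync_on, self.k_sync_off, self.k_async_on,
                  self.k_async_off, self.gamma, self.delta, self.refractory_eps):
            if r < 0:
                raise ValueError("rates must be >= 0")


# --------------------------------------------------------------------------
# Rate table (symbols follow the conventional kinetic-scheme notation)

_DEFAULT_RATES = {
    # Ryanodine receptor, low/high activity modes
    "ryr.C1L_C2L": 1.24e6, "ryr.C2L_C1L": 13.6,
    "ryr.C2L_C3L": 2.98e7, "ryr.C3L_C2L": 3867.0,
    "ryr.C2L_C5L": 1.81, "ryr.C5L_C2L": 3.63,
    "ryr.C3L_O1L": 731.2, "ryr.O1L_C3L": 4183.0,
    "ryr.C3L_O2L": 24.5, "ryr.O2L_C3L": 156.5,
    "ryr.C3L_O3L": 8.5, "ryr.O3L_C3L": 111.7,
    "ryr.C4L_O2L": 415.3, "ryr.O2L_C4L": 1995.0,
    "ryr.C4L_O3L": 43.3, "ryr.O3L_C4L": 253.3,
    "ryr.C1H_C2H": 3.26e6, "ryr.C2H_C1H": 116.0,
    "ryr.C2H_C3H": 6.6e5, "ryr.C3H_C2H": 163.0,
    "ryr.C2H_O1H": 7.86e6, "ryr.O1H_C2H": 1480.0,
    "ryr.C3H_O2H": 7.77e6, "ryr.O2H_C3H": 330.0,
    "ryr.C4H_O2H": 2390.0, "ryr.O2H_C4H": 298.0,
    "ryr.LH": 6.6e2, "ryr.HL": 0.083,
    "ryr.kFlux": 1.09e9,
    # IP3 receptor (eight-state ligand-binding model)
    "ip3r.a1": 4e8, "ip3r.a2": 2e5, "ip3r.a3": 4e8, "ip3r.a4": 2e5, "ip3r.a5": 2e7,
    "ip3r.b1": 52.0, "ip3r.b2": 0.21, "ip3r.b3": 377.2, "ip3r.b4": 0.029, "ip3r.b5": 1.64,
    "ip3r.kFlux": 1.19e8,
    # SERCA (six-state, explicit sequential binding; first-binding rates are
    # not tabulated and default to the printed second-binding rates)
    "serca.X0Y0": 0.022, "serca.Y0X0": 7.2,
    "serca.X2Y2": 10.8, "serca.Y2X2": 75.08,
    "serca.X10": 83.67, "serca.Y10": 30.012,
    "serca.X12": 1e8, "serca.Y12": 1e5,
    "serca.X01": 1e8, "serca.Y01": 1e5,
    "serca.X21": 83.67, "serca.Y21": 30.012,
    # PMCA pump + plasma-membrane leak
    "pmca.kpm1": 1.5e8, "pmca.kpm2": 20.0, "pmca.kpm3": 100.0, "pmca.kpm4": 1.0e5,
    "pmca.kpmleak": 12.5,
    # VDCC (P/Q-type), four closed states and one open state
    "vdcc.a10": 4.04, "vdcc.a20": 6.70, "vdcc.a30": 4.39, "vdcc.a40": 17.33,  # ms^-1
    "vdcc.b10": 2.88, "vdcc.b20": 6.30, "vdcc.b30": 8.16, "vdcc.b40": 1.84,  # ms^-1
    "vdcc.V1": 49.14, "vdcc.V2": 42.08, "vdcc.V3": 55.31, "vdcc.V4": 26.55,  # mV
    "vdcc.A_pS": 3.72, "vdcc.B": 0.3933, "vdcc.C_mV": 80.36,
    # Calbindin-D28k: one high-affinity and one medium-affinity pair of sites
    "calbindin.kh+": 0.55e7, "calbindin.kh-": 2.6,
    "calbindin.km+": 4.35e7, "calbindin.km-": 35.8,
    # Dual calcium sensor for vesicle release
    "sensor.ks+": 0.612e8, "sensor.ks-": 2.32e3,
    "sensor.ka+": 3.82e6, "sensor.ka-": 13.0,
    "sensor.a": 0.025, "sensor.b": 0.25,
    "sensor.gamma": 2e3, "sensor.delta": 0.417e-3, "sensor.epsilon": 6.34e-3,
}


def default_rate_table() -> dict:
    """A fresh copy of the full rate table (symbol -> value)."""
    return dict(_DEFAULT_RATES)


def merge_rates(overrides: Optional[Mapping] = None) -> dict:
    """Merge user overrides into the default rate table, rejecting unknown keys."""
    table = default_rate_table()
    if overrides:
        for key, val in overrides.items():
            if key not in table:
                raise KeyError(f"unknown rate symbol {key!r}")
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"rate {key!r} must be finite and >= 0")
            table[key] = float(val)
    return table


# --------------------------------------------------------------------------
# Scheme builders


def build_vdcc_gating(rates: Optional[Mapping] = None) -> MarkovChannelScheme:
    """Five-state voltage-gated calcium channel: C0-C1-C2-C3-O chain.

    Forward rates a_i(V) = a_i0 exp(V/V_i), backward b_i(V) = b_i0 exp(-V/V_i);
    only the terminal state O conducts calcium.
    """
    r = merge_rates(rates)
    states = ("C0", "C1", "C2", "C3", "O")
    trs = []
    for i in range(4):
        a0 = r[f"vdcc.a{i + 1}0"]
        b0 = r[f"vdcc.b{i + 1}0"]
        vi = r[f"vdcc.V{i + 1}"]
        trs.append(TransitionSpec(states[i], states[i + 1], 1e3 * a0,
                                  "voltage_dependent", VoltageParams(a0, vi, +1)))
        trs.append(TransitionSpec(states[i + 1], states[i], 1e3 * b0,
                                  "voltage_dependent", VoltageParams(b0, vi, -1)))
    return MarkovChannelScheme("vdcc", states, tuple(trs),
                               conducting_states=("O",), flux_rate_constant="vdcc")


def vdcc_flux_rate(voltage_mV: float, ca_out: float = 2e-3,
                   rates: Optional[Mapping] = None) -> float:
    """Calcium flux through one open VDCC, in ions per second.

    Evaluates A V N_A [B - exp(-V/C)] / (2F [1 - exp(V/C)]) (Goldman-type
    single-channel flux with conductance A, rectification B and voltage scale
    C), with the analytic limit at V = 0.  The result is scaled linearly by
    the extracellular calcium concentration relative to the 2 mM reference.
    """
    if not np.isfinite(voltage_mV):
        raise ValueError("voltage must be finite")
    if ca_out <= 0:
        raise ValueError("ca_out must be > 0")
    r = merge_rates(rates)
    A = r["vdcc.A_pS"] * 1e-12  # S
    B = r["vdcc.B"]
    C = r["vdcc.C_mV"] * 1e-3  # V
    V = voltage_mV * 1e-3
    scale = ca_out / 2e-3
    if abs(V) < 1e-12:
        return scale * A * N_A * C * (1.0 - B) / (2.0 * FARADAY)
    flux = A * V * N_A * (B - math.exp(-V / C)) / (2.0 * FARADAY * (1.0 - math.exp(V / C)))
    return scale * flux


def build_ryr(rates: Optional[Mapping] = None) -> MarkovChannelScheme:
    """Ryanodine receptor with low- and high-activity gating modes.

    Fourteen states; five open states conduct ER calcium into the cytosol at
    kFlux (M^-1 s^-1) applied to ER free calcium.  The three printed
    mode-switch transitions couple the L and H branches.
    """
    r = merge_rates(rates)
    states = ("C1L", "C2L", "C3L", "C4L", "C5L", "O1L", "O2L", "O3L",
              "C1H", "C2H", "C3H", "C4H", "O1H", "O2H")
    ca_edges = [("C1L", "C2L"), ("C2L", "C3L"),
                ("C1H", "C2H"), ("C2H", "C3H"), ("C2H", "O1H"), ("C3H", "O2H")]
    const_edges = [("C2L", "C5L"), ("C3L", "O1L"), ("C3L", "O2L"), ("C3L", "O3L"),
                   ("C4L", "O2L"), ("C4L", "O3L"), ("C4H", "O2H")]
    trs = []
    for a, b in ca_edges:
        trs.append(TransitionSpec(a, b, r[f"ryr.{a}_{b}"], "calcium_cytosolic",
                                  dca_cyt=-1))
        trs.append(TransitionSpec(b, a, r[f"ryr.{b}_{a}"], dca_cyt=+1))
    for a, b in const_edges:
        trs.append(TransitionSpec(a, b, r[f"ryr.{a}_{b}"]))
        trs.append(TransitionSpec(b, a, r[f"ryr.{b}_{a}"]))
    for a, b in [("C1L", "C2H"), ("C2L", "C3H"), ("C3L", "C4H")]:
        # mode switches pair an L state with the H state one calcium ahead;
        # treating them as calcium-neutral keeps the printed rates as-is, so
        # the per-state bound-calcium ledger counts gating calcium along the
        # binding edges only.
        trs.append(TransitionSpec(a, b, r["ryr.LH"]))
        trs.append(TransitionSpec(b, a, r["ryr.HL"]))
    return MarkovChannelScheme("ryr", states, tuple(trs),
                               conducting_states=("O1L", "O2L", "O3L", "O1H", "O2H"),
                               flux_rate_constant=r["ryr.kFlux"])


def build_ip3r(rates: Optional[Mapping] = None) -> MarkovChannelScheme:
    """Eight-state IP3 receptor (ligand-binding model with states S_ijk).

    i = IP3 site, j = activating calcium site, k = inactivating calcium site.
    S110 (IP3 + activating calcium bound, inhibitory site free) conducts.
    """
    r = merge_rates(rates)
    states = tuple(f"S{i}{j}{k}" for i in (0, 1) for j in (0, 1) for k in (0, 1))
    trs = []
    for i in (0, 1):
        for j in (0, 1):
            for k in (0, 1):
                s = f"S{i}{j}{k}"
                if i == 0:  # IP3 binding: a1 if inhibitory site free, a3 if occupied
                    kon, koff = (r["ip3r.a1"], r["ip3r.b1"]) if k == 0 else \
                                (r["ip3r.a3"], r["ip3r.b3"])
                    trs.append(TransitionSpec(s, f"S1{j}{k}", kon, "ip3"))
                    trs.append(TransitionSpec(f"S1{j}{k}", s, koff))
                if k == 0:  # calcium inactivation: a2 if IP3 bound, a4 otherwise
                    kon, koff = (r["ip3r.a2"], r["ip3r.b2"]) if i == 1 else \
                                (r["ip3r.a4"], r["ip3r.b4"])
                    trs.append(TransitionSpec(s, f"S{i}{j}1", kon, "calcium_cytosolic",
                                              dca_cyt=-1))
                    trs.append(TransitionSpec(f"S{i}{j}1", s, koff, dca_cyt=+1))
                if j == 0:  # calcium activation
                    trs.append(TransitionSpec(s, f"S{i}1{k}", r["ip3r.a5"],
                                              "calcium_cytosolic", dca_cyt=-1))
                    trs.append(TransitionSpec(f"S{i}1{k}", s, r["ip3r.b5"], dca_cyt=+1))
    return MarkovChannelScheme("ip3r", states, tuple(trs),
                               conducting_states=("S110",),
                               flux_rate_constant=r["ip3r.kFlux"])


def build_serca(rates: Optional[Mapping] = None) -> MarkovChannelScheme:
    """Six-state SERCA cycle with explicit sequential calcium binding.

    X states face the cytosol, Y states the ER lumen; the X2<->Y2
    translocation carries the two bound ions across the membrane, so one full
    forward cycle moves exactly two calcium ions cytosol -> ER.
    """
    r = merge_rates(rates)
    states = ("X0", "X1", "X2", "Y2", "Y1", "Y0")
    trs = (
        TransitionSpec("X0", "X1", r["serca.X01"], "calcium_cytosolic", dca_cyt=-1),
        TransitionSpec("X1", "X0", r["serca.X10"], dca_cyt=+1),
        TransitionSpec("X1", "X2", r["serca.X12"], "calcium_cytosolic", dca_cyt=-1),
        TransitionSpec("X2", "X1", r["serca.X21"], dca_cyt=+1),
        TransitionSpec("X2", "Y2", r["serca.X2Y2"]),
        TransitionSpec("Y2", "X2", r["serca.Y2X2"]),
        TransitionSpec("Y2", "Y1", r["serca.Y21"], dca_lum=+1),
        TransitionSpec("Y1", "Y2", r["serca.Y12"], "calcium_luminal", dca_lum=-1),
        TransitionSpec("Y1", "Y0", r["serca.Y10"], dca_lum=+1),
        TransitionSpec("Y0", "Y1", r["serca.Y01"], "calcium_luminal", dca_lum=-1),
        TransitionSpec("Y0", "X0", r["serca.Y0X0"]),
        TransitionSpec("X0", "Y0", r["serca.X0Y0"]),
    )
    return MarkovChannelScheme("serca", states, trs)


def build_pmca(rates: Optional[Mapping] = None) -> MarkovChannelScheme:
    """PMCA extrusion cycle: unbound <-> calcium-bound -> transported -> unbound.

    Binding at kpm1 (reversible via kpm2); the kpm3 step carries the bound ion
    across the plasma membrane (one ion extruded per cycle) and kpm4 resets
    the pump.  The accompanying plasma-membrane calcium leak (kpmleak, applied
    to the clamped extracellular pool) is attached at model-assembly level.
    """
    r = merge_rates(rates)
    states = ("P0", "P1", "P2")
    trs = (
        TransitionSpec("P0", "P1", r["pmca.kpm1"], "calcium_cytosolic", dca_cyt=-1),
        TransitionSpec("P1", "P0", r["pmca.kpm2"], dca_cyt=+1),
        TransitionSpec("P1", "P2", r["pmca.kpm3"], dca_ext=+1),
        TransitionSpec("P2", "P0", r["pmca.kpm4"]),
    )
    return MarkovChannelScheme("pmca", states, trs)


def build_calbindin(rates: Optional[Mapping] = None) -> MarkovChannelScheme:
    """Calbindin-D28k with an independent high- and medium-affinity site pair.

    States H{h}M{m} with h, m in {0,1,2} ions bound per pair; sequential
    binding within a pair carries combinatorial multiplicity (2 k_on for the
    first ion, 2 k_off from the doubly occupied pair).
    """
    r = merge_rates(rates)
    states = tuple(f"H{h}M{m}" for h in range(3) for m in range(3))
    trs = []
    for h in range(3):
        for m in range(3):
            s = f"H{h}M{m}"
            if h < 2:
                trs.append(TransitionSpec(s, f"H{h + 1}M{m}", (2 - h) * r["calbindin.kh+"],
                                          "calcium_cytosolic", dca_cyt=-1))
                trs.append(TransitionSpec(f"H{h + 1}M{m}", s, (h + 1) * r["calbindin.kh-"],
                                          dca_cyt=+1))
            if m < 2:
                trs.append(TransitionSpec(s, f"H{h}M{m + 1}", (2 - m) * r["calbindin.km+"],
                                          "calcium_cytosolic", dca_cyt=-1))
                trs.append(TransitionSpec(f"H{h}M{m + 1}", s, (m + 1) * r["calbindin.km-"],
                                          dca_cyt=+1))
    return MarkovChannelScheme("calbindin", states, tuple(trs))


def build_release_sensor(refill_rate: float = 0.34,
                         rates: Optional[Mapping] = None) -> MarkovChannelScheme:
    """Dual-sensor release machinery of one release site.

    Docked states S{s}A{a} (s synchronous ions bound of 5, a asynchronous of
    2); fusion fires at gamma from s = 5 (synchronous), at a*gamma from a = 2
    (asynchronous) and at delta from any docked state (spontaneous), returning
    all sensor-bound ions to the sensed pool.  A fused site passes through a
    refractory state (exponential dead time epsilon) to an empty state from
    which a reserve vesicle docks at ``refill_rate`` (s^-1).
    """
    r = merge_rates(rates)
    ks_on, ks_off = r["sensor.ks+"], r["sensor.ks-"]
    ka_on, ka_off = r["sensor.ka+"], r["sensor.ka-"]
    b, a_scale = r["sensor.b"], r["sensor.a"]
    gamma, delta, eps = r["sensor.gamma"], r["sensor.delta"], r["sensor.epsilon"]
    docked = [f"S{s}A{a}" for s in range(6) for a in range(3)]
    states = tuple(docked) + ("R", "E")
    trs = []
    for s in range(6):
        for a in range(3):
            st = f"S{s}A{a}"
            if s < 5:
                trs.append(TransitionSpec(st, f"S{s + 1}A{a}", (5 - s) * ks_on,
                                          "calcium_cytosolic", dca_cyt=-1))
            if s > 0:
                trs.append(TransitionSpec(st, f"S{s - 1}A{a}",
                                          s * ks_off * b ** (s - 1), dca_cyt=+1))
            if a < 2:
                trs.append(TransitionSpec(st, f"S{s}A{a + 1}", (2 - a) * ka_on,
                                          "calcium_cytosolic", dca_cyt=-1))
            if a > 0:
                trs.append(TransitionSpec(st, f"S{s}A{a - 1}", a * ka_off, dca_cyt=+1))
            if s == 5:
                trs.append(TransitionSpec(st, "R", gamma, dca_cyt=s + a,
                                          event="synchronous"))
            if a == 2:
                trs.append(TransitionSpec(st, "R", a_scale * gamma, dca_cyt=s + a,
                                          event="asynchronous"))
            trs.append(TransitionSpec(st, "R", delta, dca_cyt=s + a,
                                      event="spontaneous"))
    trs.append(TransitionSpec("R", "E", 1.0 / eps))
    trs.append(TransitionSpec("E", "S0A0", refill_rate))
    release = tuple(f"S5A{a}" for a in range(3)) + tuple(f"S{s}A2" for s in range(5))
    return MarkovChannelScheme("sensor", states, tuple(trs), release_states=release)


BUILDERS = {
    "vdcc": build_vdcc_gating,
    "ryr": build_ryr,
    "ip3r": build_ip3r,
    "serca": build_serca,
    "pmca": build_pmca,
    "calbindin": build_calbindin,
    "sensor": build_release_sensor,
}


# --------------------------------------------------------------------------
# Generator matrix and stationary distribution


def generator_matrix(scheme: MarkovChannelScheme, ca_cyt: float = 0.0,
                     ca_lum: float = 0.0, ip3: float = 0.0,
                     voltage_mV: float = 0.0) -> np.ndarray:
    """Infinitesimal generator Q (rows sum to zero) at clamped ligands."""
    idx = scheme.state_index()
    Q = np.zeros((scheme.n_states, scheme.n_states))
    for tr in scheme.transitions:
        Q[idx[tr.from_state], idx[tr.to_state]] += tr.rate_at(
            ca_cyt=ca_cyt, ca_lum=ca_lum, ip3=ip3, voltage_mV=voltage_mV)
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def analytic_steady_state(scheme: MarkovChannelScheme, ca_cyt: float = 0.0,
                          ca_lum: float = 0.0, ip3: float = 0.0,
                          voltage_mV: float = 0.0) -> dict:
    """Stationary occupancy of the scheme at clamped ligand/voltage values.

    Solves pi Q = 0 with sum(pi) = 1.  If the chain is not irreducible at
    these inputs (some states unreachable or transient), a warning is issued
    and the distribution over the terminal communicating class is returned.
    """
    from scipy.sparse.csgraph import connected_components

    Q = generator_matrix(scheme, ca_cyt, ca_lum, ip3, voltage_mV)
    n = Q.shape[0]
    ncomp, labels = connected_components(Q > 0, directed=True, connection="strong")
    if ncomp > 1:
        warnings.warn(f"scheme {scheme.name!r} is reducible at these ligand values; "
                      "returning the stationary law of the terminal class",
                      stacklevel=2)
    A = np.vstack([Q.T, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return {s: float(pi[i]) for i, s in enumerate(scheme.states)}


def open_probability(scheme: MarkovChannelScheme, **ligands) -> float:
    """Stationary probability mass of the conducting states."""
    pi = analytic_steady_state(scheme, **ligands)
    return sum(pi[s] for s in scheme.conducting_states)
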