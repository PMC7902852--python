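"""Stochastic simulation engine for the coupled bouton model.

A ``ModelConfig`` is compiled into a flat reaction network: one integer
species per Markov state of every molecule population, one per free-calcium
pool, plus two ledger counters (cumulative influx through VDCCs and the
plasma-membrane leak, cumulative efflux through PMCA).  Channels are
first-order in their source species with rates that are constant, linear in
a pool's free-calcium concentration, or exponential in membrane voltage;
open-channel calcium flux, the membrane leak and inter-pool exchange are
additional channels in the same representation.

Two stochastic integrators share this network:

* an adaptive tau-leaping kernel (production), with steps capped at 1 us
  while the membrane is depolarized (|V - rest| > 1 mV) and 0.25 ms
  otherwise, plus a per-pool stability bound ``tau <= 0.8 N / C`` (C the
  pool's total consumption propensity).  Three exact sub-schemes keep the
  leap unbiased and stable: calcium-pool outflows are drawn jointly as
  Binomial(N, min(1, C tau/N)) and partitioned multinomially over the
  consuming channels (a pool can never be overdrawn); the voltage-gated
  channel population is propagated exactly at rest with cached matrix
  exponentials over a tau ladder (removing its fast subthreshold flicker
  from the step-size restriction); sole-outflow calcium-neutral channels
  use exact-decay binomials.  Everything else draws Poisson counts, and a
  step that would still drive a state count negative is halved and redrawn
  (hard failure below 10 ns);
* an exact SSA kernel (validation): Gillespie's direct method, exact for
  propensities held piecewise-constant on a 1 us grid during action
  potentials.

A deterministic mean-field integrator for the expected-value rate equations
of the identical network (scipy BDF) serves as the law-of-large-numbers
oracle and for calibration runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from numba import njit
from scipy import sparse

from .kinetics import (BUILDERS, N_A, MarkovChannelScheme,
                       analytic_steady_state, merge_rates)
from .assembly import ModelConfig
from .stimulus import ProtocolSpec, REST_VOLTAGE, voltage_at

PATHWAYS = {1: "synchronous", 2: "asynchronous", 3: "spontaneous"}
_PATH_CODES = {"synchronous": 1, "asynchronous": 2, "spontaneous": 3}

TAU_CAP_ACTIVE = 1e-6   # s, leap cap while depolarized (matches the 1 us step)
TAU_CAP_QUIET = 2.5e-4  # s, leap cap at rest
TAU_COEF = 0.8          # per-pool stability bound: tau <= coef * N / C where
                        # C is the pool's total consumption propensity
TAU_FLOOR = 1e-8        # s, hard-failure threshold after step halving


# --------------------------------------------------------------------------
# Compilation


@dataclass
class CompiledModel:
    """Flat array representation of a ModelConfig (see module docstring)."""

    config: ModelConfig
    species_names: List[str]
    x0: np.ndarray            # int64 initial counts
    x0_float: np.ndarray      # unrounded initial state for the mean field
    ca_content: np.ndarray    # ions bound per molecule, per species
    pool_names: List[str]
    pool_species: np.ndarray  # species index of each free-calcium pool
    inv_na_vol: np.ndarray    # 1/(N_A * V_L) per pool: count -> molar
    idx_influx: int
    idx_efflux: int
    # channels
    csrc: np.ndarray
    ckind: np.ndarray
    ck: np.ndarray
    clig: np.ndarray
    cv0: np.ndarray
    cevent: np.ndarray
    cons_pool: np.ndarray
    cons_n: np.ndarray
    cons_ptr: np.ndarray
    cons_idx: np.ndarray
    chan_mode: np.ndarray
    vd_species: np.ndarray
    vd_scheme: object
    sp_ptr: np.ndarray
    sp_idx: np.ndarray
    sp_val: np.ndarray
    flux_A: float
    flux_B: float
    flux_C: float
    ca_scale: float
    groups: Dict[str, np.ndarray]

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def pool_index(self, comp: str) -> int:
        return self.pool_names.index(comp)

    def conserved_calcium(self, x: np.ndarray) -> int:
        """The exact ledger invariant: free + bound + extruded - influx."""
        free = int(sum(x[self.pool_species]))
        bound = int(np.dot(self.ca_content, np.asarray(x, dtype=np.int64)))
        return free + bound + int(x[self.idx_efflux]) - int(x[self.idx_influx])


def _largest_remainder(probs: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` items proportional to `probs`."""
    raw = probs * total
    base = np.floor(raw).astype(np.int64)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


_COMPILE_CACHE: dict = {}


def compile_model(config: ModelConfig) -> CompiledModel:
    """Compile a configuration into the flat network (cached)."""
    import yaml

    key = yaml.safe_dump(config.to_dict(), sort_keys=True)
    hit = _COMPILE_CACHE.get(key)
    if hit is not None:
        return hit
    cm = _compile(config)
    _COMPILE_CACHE[key] = cm
    return cm


def _compile(config: ModelConfig) -> CompiledModel:
    rates = merge_rates(config.rate_overrides)
    pools = [c for c in config.compartments if not c.is_reservoir]
    pool_names = [c.name for c in pools]

    species: List[str] = []
    content: List[int] = []
    x0f: List[float] = []
    x0i: List[int] = []

    schemes: Dict[str, MarkovChannelScheme] = {}
    pop_offset: Dict[str, int] = {}

    def scheme_for(pop) -> MarkovChannelScheme:
        if pop.scheme_name not in schemes:
            builder = BUILDERS[pop.scheme_name]
            if pop.scheme_name == "sensor":
                schemes[pop.scheme_name] = builder(
                    refill_rate=config.rrp_refill_rate_per_s,
                    rates=config.rate_overrides)
            else:
                schemes[pop.scheme_name] = builder(rates=config.rate_overrides)
        return schemes[pop.scheme_name]

    pops = [p for p in config.populations if p.count > 0]
    for pop in pops:
        sch = scheme_for(pop)
        pop_offset[pop.label] = len(species)
        c_sens = config.compartment(pop.sensed_compartment).initial_free_ca_M
        c_lum = (config.compartment(pop.luminal_compartment).initial_free_ca_M
                 if pop.luminal_compartment else 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi = analytic_steady_state(sch, ca_cyt=c_sens, ca_lum=c_lum,
                                       ip3=config.ip3_M, voltage_mV=REST_VOLTAGE)
        pvec = np.array([pi[s] for s in sch.states])
        counts = _largest_remainder(pvec, pop.count)
        cont = sch.calcium_content()
        for i, st in enumerate(sch.states):
            species.append(f"{pop.label}.{st}")
            content.append(int(cont[i]))
            x0i.append(int(counts[i]))
            x0f.append(float(pvec[i] * pop.count))

    pool_species = np.zeros(len(pools), dtype=np.int64)
    inv_na_vol = np.zeros(len(pools))
    for j, c in enumerate(pools):
        pool_species[j] = len(species)
        inv_na_vol[j] = 1.0 / (N_A * c.volume_L)
        species.append(f"ca.{c.name}")
        content.append(0)
        n0 = int(round(N_A * c.initial_free_ca_M * c.volume_L))
        x0i.append(n0)
        x0f.append(N_A * c.initial_free_ca_M * c.volume_L)

    idx_influx = len(species)
    species.append("ledger.influx")
    content.append(0)
    x0i.append(0)
    x0f.append(0.0)
    idx_efflux = len(species)
    species.append("ledger.efflux")
    content.append(0)
    x0i.append(0)
    x0f.append(0.0)

    sidx = {s: i for i, s in enumerate(species)}
    pidx = {name: j for j, name in enumerate(pool_names)}

    # -- channels -----------------------------------------------------------
    csrc, ckind, ck, clig, cv0, cevent = [], [], [], [], [], []
    cons_pool, cons_n = [], []
    stoich: List[List[tuple]] = []

    def add_channel(src, kind, k, lig=-1, v0=1.0, event=0, entries=()):
        csrc.append(src)
        ckind.append(kind)
        ck.append(k)
        clig.append(lig)
        cv0.append(v0)
        cevent.append(event)
        ent: Dict[int, int] = {}
        cons = (-1, 0)
        for sp, dv in entries:
            ent[sp] = ent.get(sp, 0) + dv
        for j, spid in enumerate(pool_species):
            dv = ent.get(int(spid), 0)
            if dv < 0:
                cons = (j, -dv)
        cons_pool.append(cons[0])
        cons_n.append(cons[1])
        stoich.append(sorted(ent.items()))

    vd_species_list: List[int] = []
    vd_scheme = None
    gating_channels: List[int] = []
    for pop in pops:
        sch = schemes[pop.scheme_name]
        off = pop_offset[pop.label]
        st_id = {s: off + i for i, s in enumerate(sch.states)}
        expm_able = all(tr.dca_cyt == 0 and tr.dca_lum == 0 and
                        tr.dca_ext == 0 and tr.event is None and
                        tr.order in ("constant", "voltage_dependent")
                        for tr in sch.transitions)
        if expm_able and vd_scheme is None:
            vd_scheme = sch
            vd_species_list = [off + i for i in range(sch.n_states)]
            ch_start = len(csrc)
        sens_pool = pidx[pop.sensed_compartment]
        sens_sp = int(pool_species[sens_pool])
        lum_pool = pidx[pop.luminal_compartment] if pop.luminal_compartment else -1
        lum_sp = int(pool_species[lum_pool]) if lum_pool >= 0 else -1
        for tr in sch.transitions:
            entries = [(st_id[tr.from_state], -1), (st_id[tr.to_state], +1)]
            if tr.dca_cyt:
                entries.append((sens_sp, tr.dca_cyt))
            if tr.dca_lum:
                if lum_sp < 0:
                    raise ValueError(
                        f"population {pop.label!r} needs a luminal compartment")
                entries.append((lum_sp, tr.dca_lum))
            if tr.dca_ext:
                entries.append((idx_efflux, tr.dca_ext))
            ev = _PATH_CODES.get(tr.event, 0)
            if tr.order == "constant":
                add_channel(st_id[tr.from_state], 0, tr.rate_constant,
                            event=ev, entries=entries)
            elif tr.order == "calcium_cytosolic":
                add_channel(st_id[tr.from_state], 1, tr.rate_constant,
                            lig=sens_pool, event=ev, entries=entries)
            elif tr.order == "calcium_luminal":
                add_channel(st_id[tr.from_state], 1, tr.rate_constant,
                            lig=lum_pool, event=ev, entries=entries)
            elif tr.order == "ip3":
                add_channel(st_id[tr.from_state], 0,
                            tr.rate_constant * config.ip3_M,
                            event=ev, entries=entries)
            else:  # voltage_dependent
                vp = tr.voltage_params
                add_channel(st_id[tr.from_state], 2, 1e3 * vp.base_per_ms,
                            v0=vp.sign * vp.efold_mV, event=ev, entries=entries)
        if expm_able and vd_scheme is sch and pop_offset[pop.label] == \
                vd_species_list[0]:
            gating_channels.extend(range(ch_start, len(csrc)))
        # open-channel flux
        if sch.flux_rate_constant == "vdcc":
            tgt = int(pool_species[pidx[pop.flux_target]])
            for st in sch.conducting_states:
                add_channel(st_id[st], 3, 0.0,
                            entries=[(tgt, +1), (idx_influx, +1)])
        elif sch.flux_rate_constant is not None:
            tgt = int(pool_species[pidx[pop.flux_target]])
            for st in sch.conducting_states:
                add_channel(st_id[st], 1, float(sch.flux_rate_constant),
                            lig=lum_pool, entries=[(lum_sp, -1), (tgt, +1)])

    # plasma-membrane leak: fixed-rate source, first-order in the clamped
    # extracellular concentration
    if config.leak_site_count > 0:
        leak_rate = (rates["pmca.kpmleak"] * config.leak_site_count
                     * config.ca_out_M / 2e-3)
        add_channel(-1, 0, leak_rate,
                    entries=[(int(pool_species[pidx["bulk"]]), +1),
                             (idx_influx, +1)])

    # inter-pool diffusive exchange
    for ex in config.exchange:
        for a, b in ((ex.comp_a, ex.comp_b), (ex.comp_b, ex.comp_a)):
            if config.compartment(a).is_reservoir or \
               config.compartment(b).is_reservoir:
                raise ValueError("exchange with a reservoir is not supported")
            sp_a = int(pool_species[pidx[a]])
            sp_b = int(pool_species[pidx[b]])
            k = ex.conductance_um3_per_s / config.compartment(a).volume_um3
            add_channel(sp_a, 0, k, entries=[(sp_a, -1), (sp_b, +1)])

    cons_pool_arr = np.array(cons_pool, dtype=np.int64)
    if not np.all(np.isin(np.array(cons_n)[cons_pool_arr >= 0], [1])):
        raise AssertionError("pool-consuming channels must take exactly 1 ion")
    # channel draw modes: 1 = pool-partition, 3 = exact-propagator gating,
    # 2 = sole-outflow exact-decay binomial, 0 = Poisson
    nch_total = len(csrc)
    chan_mode = np.zeros(nch_total, dtype=np.int64)
    chan_mode[cons_pool_arr >= 0] = 1
    for i in gating_channels:
        if chan_mode[i] == 0:
            chan_mode[i] = 3
    src_arr = np.array(csrc, dtype=np.int64)
    for i in range(nch_total):
        if chan_mode[i] == 0 and src_arr[i] >= 0 and \
                int(np.sum(src_arr == src_arr[i])) == 1:
            chan_mode[i] = 2
    cptr = [0]
    cidx = []
    for p in range(len(pool_names)):
        members = np.where(cons_pool_arr == p)[0]
        cidx.extend(int(i) for i in members)
        cptr.append(len(cidx))

    ptr = [0]
    flat_idx, flat_val = [], []
    for ent in stoich:
        for sp, dv in ent:
            flat_idx.append(sp)
            flat_val.append(dv)
        ptr.append(len(flat_idx))

    return CompiledModel(
        config=config,
        species_names=species,
        x0=np.array(x0i, dtype=np.int64),
        x0_float=np.array(x0f),
        ca_content=np.array(content, dtype=np.int64),
        pool_names=pool_names,
        pool_species=pool_species,
        inv_na_vol=inv_na_vol,
        idx_influx=idx_influx,
        idx_efflux=idx_efflux,
        csrc=np.array(csrc, dtype=np.int64),
        ckind=np.array(ckind, dtype=np.int64),
        ck=np.array(ck),
        clig=np.array(clig, dtype=np.int64),
        cv0=np.array(cv0),
        cevent=np.array(cevent, dtype=np.int64),
        cons_pool=cons_pool_arr,
        cons_n=np.array(cons_n, dtype=np.int64),
        cons_ptr=np.array(cptr, dtype=np.int64),
        cons_idx=np.array(cidx, dtype=np.int64),
        chan_mode=chan_mode,
        vd_species=np.array(vd_species_list, dtype=np.int64),
        vd_scheme=vd_scheme,
        sp_ptr=np.array(ptr, dtype=np.int64),
        sp_idx=np.array(flat_idx, dtype=np.int64),
        sp_val=np.array(flat_val, dtype=np.int64),
        flux_A=rates["vdcc.A_pS"] * 1e-12,
        flux_B=rates["vdcc.B"],
        flux_C=rates["vdcc.C_mV"] * 1e-3,
        ca_scale=config.ca_out_M / 2e-3,
        groups=_make_groups(species),
    )


def _make_groups(species: List[str]) -> Dict[str, np.ndarray]:
    groups: Dict[str, List[int]] = {"docked": [], "refractory": [], "empty": [],
                                    "vdcc_open": [], "ryr_open": [], "ip3r_open": []}
    ryr_open = {"O1L", "O2L", "O3L", "O1H", "O2H"}
    for i, s in enumerate(species):
        label, _, state = s.partition(".")
        if label == "sensor":
            if state == "R":
                groups["refractory"].append(i)
            elif state == "E":
                groups["empty"].append(i)
            else:
                groups["docked"].append(i)
        elif label == "vdcc" and state == "O":
            groups["vdcc_open"].append(i)
        elif label == "ryr" and state in ryr_open:
            groups["ryr_open"].append(i)
        elif label == "ip3r" and state == "S110":
            groups["ip3r_open"].append(i)
    return {k: np.array(v, dtype=np.int64) for k, v in groups.items() if v}


# --------------------------------------------------------------------------
# Numba kernels


@njit(cache=True, inline="always")
def _voltage_nb(t, onsets, vrest, vamp, sig_r, sig_d, tpk):
    v = vrest
    for i in range(onsets.size):
        dt = t - (onsets[i] + tpk)
        if -8.0 * sig_r < dt < 8.0 * sig_d:
            s = sig_r if dt < 0.0 else sig_d
            v += vamp * math.exp(-0.5 * (dt / s) ** 2)
    return v


@njit(cache=True, inline="always")
def _vdcc_flux_nb(v_mV, A, B, C):
    # A in siemens, C in volts; returns ions/s per open channel at 2 mM
    V = v_mV * 1e-3
    if abs(V) < 1e-9:
        return A * 6.02214076e23 * C * (1.0 - B) / (2.0 * 96485.33212)
    return (A * V * 6.02214076e23 * (B - math.exp(-V / C))
            / (2.0 * 96485.33212 * (1.0 - math.exp(V / C))))


@njit(cache=True)
def _fill_propensities(x, V, csrc, ckind, ck, clig, cv0, pool_sp, inv_na_vol,
                       fA, fB, fC, ca_scale, a):
    total = 0.0
    for i in range(csrc.size):
        src = csrc[i]
        mult = 1.0
        if src >= 0:
            m = x[src]
            if m == 0:
                a[i] = 0.0
                continue
            mult = float(m)
        kind = ckind[i]
        if kind == 0:
            r = ck[i]
        elif kind == 1:
            lig = clig[i]
            r = ck[i] * x[pool_sp[lig]] * inv_na_vol[lig]
        elif kind == 2:
            r = ck[i] * math.exp(V / cv0[i])
        else:
            r = _vdcc_flux_nb(V, fA, fB, fC) * ca_scale
        ai = r * mult
        a[i] = ai
        total += ai
    return total


@njit(cache=True)
def _tau_kernel(x0, total_time, seed,
                csrc, ckind, ck, clig, cv0, cevent, cons_pool, chan_mode,
                cons_ptr, cons_idx,
                sp_ptr, sp_idx, sp_val, pool_sp, inv_na_vol,
                onsets, vrest, vamp, sig_r, sig_d, tpk,
                fA, fB, fC, ca_scale,
                cap_active, cap_quiet, tau_coef,
                vd_species, P_ladder, ladder_taus,
                trace_dt, tcol_ptr, tcol_idx, max_events):
    np.random.seed(seed)
    x = x0.copy()
    nsp = x.size
    nch = csrc.size
    npool = pool_sp.size
    ncol = tcol_ptr.size - 1
    nvd = vd_species.size
    nladder = ladder_taus.size
    a = np.zeros(nch)
    nd = np.zeros(nch, np.int64)
    dx = np.zeros(nsp, np.int64)
    cons = np.zeros(npool)
    integ = np.zeros(nsp)
    n_rows = int(total_time / trace_dt + 1e-9) + 1
    trace = np.zeros((n_rows, ncol), np.int64)
    for c in range(ncol):
        ssum = 0
        for j in range(tcol_ptr[c], tcol_ptr[c + 1]):
            ssum += x[tcol_idx[j]]
        trace[0, c] = ssum
    row = 1
    ev_t = np.zeros(max_events)
    ev_p = np.zeros(max_events, np.int8)
    nev = 0
    t = 0.0
    status = 0
    steps = 0
    while t < total_time - 1e-12:
        V = _voltage_nb(t, onsets, vrest, vamp, sig_r, sig_d, tpk)
        active = abs(V - vrest) > 1.0
        _fill_propensities(x, V, csrc, ckind, ck, clig, cv0, pool_sp,
                           inv_na_vol, fA, fB, fC, ca_scale, a)
        for p in range(npool):
            cons[p] = 0.0
        for i in range(nch):
            cp = cons_pool[i]
            if cp >= 0 and a[i] > 0.0:
                cons[cp] += a[i]
        tau = cap_active if active else cap_quiet
        for p in range(npool):
            if cons[p] > 0.0:
                n_p = x[pool_sp[p]]
                lim = tau_coef * (n_p if n_p > 1 else 1.0) / cons[p]
                if lim < tau:
                    tau = lim
        # quiet steps propagate the voltage-gated population exactly with a
        # cached matrix exponential; snap tau down to the propagator ladder
        kq = 0
        use_vd_exact = (not active) and nvd > 0
        if use_vd_exact:
            while kq < nladder - 1 and ladder_taus[kq] > tau:
                kq += 1
            tau = ladder_taus[kq]
        if t + tau > total_time:
            tau = total_time - t
            if use_vd_exact:
                while kq < nladder - 1 and ladder_taus[kq] > tau:
                    kq += 1
        # re-evaluate voltage-dependent channels at the step midpoint
        if active:
            Vm = _voltage_nb(t + 0.5 * tau, onsets, vrest, vamp,
                             sig_r, sig_d, tpk)
            for i in range(nch):
                if ckind[i] >= 2:
                    src = csrc[i]
                    if src >= 0 and x[src] == 0:
                        continue
                    mult = 1.0 if src < 0 else float(x[src])
                    if ckind[i] == 2:
                        a[i] = ck[i] * math.exp(Vm / cv0[i]) * mult
                    else:
                        a[i] = _vdcc_flux_nb(Vm, fA, fB, fC) * ca_scale * mult
        ok = False
        for _attempt in range(80):
            for i in range(nsp):
                dx[i] = 0
            # exact propagation of the voltage-gated channel states while
            # the membrane is at rest (calcium-neutral, so end-state
            # multinomial sampling is exact)
            if use_vd_exact:
                for si in range(nvd):
                    n_here = x[vd_species[si]]
                    if n_here > 0:
                        draws = np.random.multinomial(n_here, P_ladder[kq, si])
                        dx[vd_species[si]] -= n_here
                        for sj in range(nvd):
                            dx[vd_species[sj]] += draws[sj]
            # calcium-pool outflows: every consuming channel is first-order
            # in its pool, so the joint loss is Binomial(N, min(1, C tau/N))
            # (unbiased mean, never overdraws), partitioned multinomially
            for p in range(npool):
                i0, i1 = cons_ptr[p], cons_ptr[p + 1]
                if i1 == i0:
                    continue
                Np = x[pool_sp[p]]
                Cp = cons[p]
                if Np <= 0 or Cp <= 0.0:
                    for j in range(i0, i1):
                        nd[cons_idx[j]] = 0
                    continue
                q = Cp * tau / Np
                if q > 1.0:
                    q = 1.0
                rem = np.random.binomial(Np, q)
                wrem = Cp
                for j in range(i0, i1):
                    i = cons_idx[j]
                    ai = a[i]
                    if rem <= 0 or ai <= 0.0:
                        nd[i] = 0
                        wrem -= ai
                        continue
                    if j == i1 - 1 or ai >= wrem:
                        ni = rem
                    else:
                        ni = np.random.binomial(rem, ai / wrem)
                    nd[i] = ni
                    rem -= ni
                    wrem -= ai
                for j in range(i0, i1):
                    i = cons_idx[j]
                    n = nd[i]
                    if n > 0:
                        for jj in range(sp_ptr[i], sp_ptr[i + 1]):
                            dx[sp_idx[jj]] += sp_val[jj] * n
            # remaining channels: exact-decay binomial for sole outflows,
            # Poisson otherwise
            for i in range(nch):
                mode = chan_mode[i]
                if mode == 1 or (mode == 3 and use_vd_exact):
                    continue
                m = a[i] * tau
                if m <= 0.0:
                    nd[i] = 0
                    continue
                if mode == 2:
                    src_n = x[csrc[i]]
                    n = np.random.binomial(
                        src_n, 1.0 - math.exp(-a[i] * tau / src_n))
                elif m < 0.02:
                    # inversion, first three terms (P(>=3) < 1.4e-6)
                    u = np.random.random()
                    q0 = math.exp(-m)
                    if u < q0:
                        nd[i] = 0
                        continue
                    n = 1 if u < q0 * (1.0 + m) else 2
                else:
                    n = np.random.poisson(m)
                nd[i] = n
                if n > 0:
                    for j in range(sp_ptr[i], sp_ptr[i + 1]):
                        dx[sp_idx[j]] += sp_val[j] * n
            ok = True
            for i in range(nsp):
                if x[i] + dx[i] < 0:
                    ok = False
                    break
            if ok:
                break
            tau *= 0.5
            if use_vd_exact:
                if kq < nladder - 1:
                    kq += 1
            if tau < 1e-8:
                status = 1
                break
        if not ok:
            break
        for i in range(nch):
            if cevent[i] > 0 and nd[i] > 0:
                if chan_mode[i] == 1 or a[i] > 0.0:
                    for _k in range(nd[i]):
                        if nev < max_events:
                            ev_t[nev] = t + tau
                            ev_p[nev] = cevent[i]
                            nev += 1
                        else:
                            status = 2
        for i in range(nsp):
            integ[i] += x[i] * tau
            x[i] += dx[i]
        t += tau
        steps += 1
        while row < n_rows and row * trace_dt <= t + 1e-12:
            for c in range(ncol):
                ssum = 0
                for j in range(tcol_ptr[c], tcol_ptr[c + 1]):
                    ssum += x[tcol_idx[j]]
                trace[row, c] = ssum
            row += 1
    while row < n_rows:
        for c in range(ncol):
            ssum = 0
            for j in range(tcol_ptr[c], tcol_ptr[c + 1]):
                ssum += x[tcol_idx[j]]
            trace[row, c] = ssum
        row += 1
    return x, trace, integ, ev_t[:nev], ev_p[:nev], status, steps


@njit(cache=True)
def _ssa_kernel(x0, total_time, seed,
                csrc, ckind, ck, clig, cv0, cevent,
                sp_ptr, sp_idx, sp_val, pool_sp, inv_na_vol,
                onsets, vrest, vamp, sig_r, sig_d, tpk,
                fA, fB, fC, ca_scale,
                dt_grid, trace_dt, tcol_ptr, tcol_idx, max_events):
    np.random.seed(seed)
    x = x0.copy()
    nsp = x.size
    nch = csrc.size
    ncol = tcol_ptr.size - 1
    a = np.zeros(nch)
    integ = np.zeros(nsp)
    n_rows = int(total_time / trace_dt + 1e-9) + 1
    trace = np.zeros((n_rows, ncol), np.int64)
    for c in range(ncol):
        s = 0
        for j in range(tcol_ptr[c], tcol_ptr[c + 1]):
            s += x[tcol_idx[j]]
        trace[0, c] = s
    row = 1
    ev_t = np.zeros(max_events)
    ev_p = np.zeros(max_events, np.int8)
    nev = 0
    winlen = tpk + 8.0 * sig_d
    t = 0.0
    status = 0
    steps = 0
    while t < total_time - 1e-12:
        V = _voltage_nb(t, onsets, vrest, vamp, sig_r, sig_d, tpk)
        total = _fill_propensities(x, V, csrc, ckind, ck, clig, cv0, pool_sp,
                                   inv_na_vol, fA, fB, fC, ca_scale, a)
        inwin = False
        nxt = total_time
        for k in range(onsets.size):
            if onsets[k] - 1e-12 <= t < onsets[k] + winlen:
                inwin = True
            if onsets[k] > t + 1e-12 and onsets[k] < nxt:
                nxt = onsets[k]
        dtm = dt_grid if inwin else nxt - t
        if t + dtm > total_time:
            dtm = total_time - t
        event = -1
        if total > 0.0:
            wait = -math.log(np.random.random()) / total
            if wait <= dtm:
                dtm = wait
                r = np.random.random() * total
                acc = 0.0
                event = nch - 1
                for i in range(nch):
                    acc += a[i]
                    if r <= acc:
                        event = i
                        break
        for i in range(nsp):
            integ[i] += x[i] * dtm
        t += dtm
        if event >= 0:
            for j in range(sp_ptr[event], sp_ptr[event + 1]):
                x[sp_idx[j]] += sp_val[j]
            if cevent[event] > 0:
                if nev < max_events:
                    ev_t[nev] = t
                    ev_p[nev] = cevent[event]
                    nev += 1
                else:
                    status = 2
            steps += 1
        while row < n_rows and row * trace_dt <= t + 1e-12:
            for c in range(ncol):
                s = 0
                for j in range(tcol_ptr[c], tcol_ptr[c + 1]):
                    s += x[tcol_idx[j]]
                trace[row, c] = s
            row += 1
    while row < n_rows:
        for c in range(ncol):
            s = 0
            for j in range(tcol_ptr[c], tcol_ptr[c + 1]):
                s += x[tcol_idx[j]]
            trace[row, c] = s
        row += 1
    return x, trace, integ, ev_t[:nev], ev_p[:nev], status, steps


# --------------------------------------------------------------------------
# Results


@dataclass
class SimState:
    """Snapshot of the integer state with the simulation clock."""

    species_counts: np.ndarray
    clock: float


@dataclass
class TrialResult:
    """One stochastic trial: release events, sampled traces, flux ledger."""

    compiled: CompiledModel
    protocol: ProtocolSpec
    seed: int
    trace_times: np.ndarray
    trace_columns: List[str]
    trace: np.ndarray
    event_times: np.ndarray
    event_pathways: np.ndarray  # strings
    integrals: np.ndarray       # per-species time integral of counts (count*s)
    final_state: SimState
    n_steps: int
    rng_algorithm: str = "numpy-MT19937 (numba), seeded per trial"

    def column(self, name: str) -> np.ndarray:
        return self.trace[:, self.trace_columns.index(name)]

    def ca_concentration(self, pool: str) -> np.ndarray:
        """Free-calcium trace of a pool, molar."""
        j = self.compiled.pool_index(pool)
        return self.column(f"ca.{pool}") * self.compiled.inv_na_vol[j]

    def mean_free_ca(self, pools: Sequence[str]) -> float:
        """Exact time-averaged free-calcium concentration (molar) over pools,
        computed from the per-step time integrals."""
        cm = self.compiled
        tot_ions = 0.0
        tot_vol = 0.0
        for p in pools:
            j = cm.pool_index(p)
            tot_ions += self.integrals[cm.pool_species[j]]
            tot_vol += 1.0 / cm.inv_na_vol[j]
        T = self.protocol.total_time
        return (tot_ions / T) / tot_vol

    def docked_trace(self) -> np.ndarray:
        return self.column("docked")

    def ledger_balanced(self) -> bool:
        x_end = self.final_state.species_counts
        return (self.compiled.conserved_calcium(self.compiled.x0)
                == self.compiled.conserved_calcium(x_end))


def _default_trace_columns(cm: CompiledModel):
    cols: List[str] = [f"ca.{p}" for p in cm.pool_names]
    idx: List[np.ndarray] = [np.array([cm.pool_species[j]], dtype=np.int64)
                             for j in range(len(cm.pool_names))]
    for gname, gidx in cm.groups.items():
        cols.append(gname)
        idx.append(gidx)
    cols += ["ledger.influx", "ledger.efflux"]
    idx += [np.array([cm.idx_influx], dtype=np.int64),
            np.array([cm.idx_efflux], dtype=np.int64)]
    return cols, idx


def _trace_layout(cm: CompiledModel, trace_species):
    if trace_species == "standard" or trace_species is None:
        cols, idx = _default_trace_columns(cm)
    elif trace_species == "all":
        cols = list(cm.species_names)
        idx = [np.array([i], dtype=np.int64) for i in range(cm.n_species)]
    else:
        cols, idx = [], []
        for name in trace_species:
            if name in cm.groups:
                cols.append(name)
                idx.append(cm.groups[name])
            else:
                cols.append(name)
                idx.append(np.array([cm.species_index(name)], dtype=np.int64))
    ptr = np.zeros(len(cols) + 1, dtype=np.int64)
    for i, arr in enumerate(idx):
        ptr[i + 1] = ptr[i] + arr.size
    flat = np.concatenate(idx) if idx else np.zeros(0, dtype=np.int64)
    return cols, ptr, flat


_LADDER_CACHE: dict = {}


def _propagator_ladder(cm: CompiledModel, rest_voltage: float, depth: int = 16):
    """Cached transition matrices expm(Q tau_k) of the voltage-gated scheme
    at the resting voltage, for the tau ladder cap/2^k."""
    from scipy.linalg import expm

    from .kinetics import generator_matrix

    key = (id(cm), float(rest_voltage), depth)
    hit = _LADDER_CACHE.get(key)
    if hit is not None:
        return hit
    taus = TAU_CAP_QUIET / (2.0 ** np.arange(depth))
    if cm.vd_species.size:
        Q = generator_matrix(cm.vd_scheme, voltage_mV=rest_voltage)
        mats = []
        for tau in taus:
            P = expm(Q * tau)
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            mats.append(P)
        ladder = np.ascontiguousarray(np.stack(mats))
    else:
        ladder = np.zeros((depth, 1, 1))
    _LADDER_CACHE[key] = (taus, ladder)
    return taus, ladder


def run_trial(config: ModelConfig, protocol: ProtocolSpec, seed: int,
              trace_dt: float = 1e-3, trace_species="standard",
              mode: str = "tau", max_events: int = 20000) -> TrialResult:
    """Advance one stochastic trial; identical inputs give identical output.

    ``mode`` selects the adaptive tau-leaping kernel (``"tau"``, production)
    or the exact SSA kernel (``"ssa"``, for validation on reduced models).
    """
    cm = compile_model(config)
    wf = protocol.waveform
    cols, ptr, flat = _trace_layout(cm, trace_species)
    onsets = np.asarray(protocol.onsets, dtype=np.float64)
    args = (cm.x0, float(protocol.total_time), int(seed),
            cm.csrc, cm.ckind, cm.ck, cm.clig, cm.cv0, cm.cevent)
    if mode == "tau":
        ladder_taus, P_ladder = _propagator_ladder(cm, wf.rest_voltage)
        out = _tau_kernel(*args, cm.cons_pool, cm.chan_mode,
                          cm.cons_ptr, cm.cons_idx,
                          cm.sp_ptr, cm.sp_idx, cm.sp_val,
                          cm.pool_species, cm.inv_na_vol,
                          onsets, wf.rest_voltage, wf.amplitude,
                          wf.sigma_rise, wf.sigma_decay, wf.peak_delay,
                          cm.flux_A, cm.flux_B, cm.flux_C, cm.ca_scale,
                          TAU_CAP_ACTIVE, TAU_CAP_QUIET, TAU_COEF,
                          cm.vd_species, P_ladder, ladder_taus,
                          float(trace_dt), ptr, flat, int(max_events))
    elif mode == "ssa":
        out = _ssa_kernel(*args,
                          cm.sp_ptr, cm.sp_idx, cm.sp_val,
                          cm.pool_species, cm.inv_na_vol,
                          onsets, wf.rest_voltage, wf.amplitude,
                          wf.sigma_rise, wf.sigma_decay, wf.peak_delay,
                          cm.flux_A, cm.flux_B, cm.flux_C, cm.ca_scale,
                          1e-6, float(trace_dt), ptr, flat, int(max_events))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    x, trace, integ, ev_t, ev_p, status, steps = out
    if status == 1:
        raise RuntimeError(
            "tau-leap step fell below 10 ns without resolving a negative "
            f"count (t around {steps} steps in, seed {seed}); the "
            "configuration is likely inconsistent (e.g. an empty pool with "
            "a large constant influx)")
    if status == 2:
        warnings.warn("event buffer full; excess release events dropped")
    n_rows = trace.shape[0]
    times = np.arange(n_rows) * trace_dt
    pathways = np.array([PATHWAYS[int(p)] for p in ev_p], dtype=object)
    return TrialResult(
        compiled=cm, protocol=protocol, seed=int(seed),
        trace_times=times, trace_columns=cols, trace=trace,
        event_times=ev_t, event_pathways=pathways,
        integrals=integ, final_state=SimState(x, protocol.total_time),
        n_steps=int(steps),
    )


def run_ensemble(config: ModelConfig, protocol: ProtocolSpec, n_trials: int,
                 base_seed: int, **kwargs) -> List[TrialResult]:
    """Independent trials with seeds base_seed + i (order-independent)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return [run_trial(config, protocol, base_seed + i, **kwargs)
            for i in range(n_trials)]


def trial_schedule(n_vdcc: int) -> int:
    """Per-VDCC trial-count schedule used for the paired-pulse ensembles:
    5000 trials up to 60 channels, 2000 for 70-90, 1000 above."""
    if n_vdcc <= 60:
        return 5000
    if n_vdcc <= 90:
        return 2000
    return 1000


# --------------------------------------------------------------------------
# Mean field


@dataclass
class MeanFieldResult:
    """Deterministic expected-value trajectories of the same network."""

    compiled: CompiledModel
    protocol: ProtocolSpec
    t: np.ndarray
    y: np.ndarray  # (n_species, n_times)

    def species(self, name: str) -> np.ndarray:
        return self.y[self.compiled.species_index(name)]

    def ca_concentration(self, pool: str) -> np.ndarray:
        j = self.compiled.pool_index(pool)
        return self.species(f"ca.{pool}") * self.compiled.inv_na_vol[j]

    def mean_free_ca(self, pools: Sequence[str]) -> float:
        cm = self.compiled
        ions = np.zeros_like(self.t)
        vol = 0.0
        for p in pools:
            j = cm.pool_index(p)
            ions = ions + self.y[cm.pool_species[j]]
            vol += 1.0 / cm.inv_na_vol[j]
        avg_ions = np.trapezoid(ions, self.t) / (self.t[-1] - self.t[0])
        return avg_ions / vol

    def docked_trace(self) -> np.ndarray:
        return self.y[self.compiled.groups["docked"]].sum(axis=0)


def integrate_mean_field(config: ModelConfig, protocol: ProtocolSpec,
                         t_eval: Optional[np.ndarray] = None,
                         clamp_pools: Sequence[str] = (),
                         rtol: float = 1e-8, atol: float = 1e-8
                         ) -> MeanFieldResult:
    """Integrate the expected-value rate equations of the compiled network.

    ``clamp_pools`` holds the listed free-calcium pools at their initial
    value (used e.g. to study ER refilling at fixed cytosolic conditions).
    Stiff BDF integration; raises if the solver fails, reporting the solver
    message so tolerances can be adjusted.
    """
    from scipy.integrate import solve_ivp

    cm = compile_model(config)
    wf = protocol.waveform
    nch = cm.csrc.size
    S = sparse.csr_matrix(
        (cm.sp_val.astype(float), cm.sp_idx,
         cm.sp_ptr), shape=(nch, cm.n_species)).T.tocsr()
    k0 = cm.ckind == 0
    k1 = cm.ckind == 1
    k2 = cm.ckind == 2
    k3 = cm.ckind == 3
    src = np.maximum(cm.csrc, 0)
    has_src = cm.csrc >= 0
    clamp_idx = np.array([cm.pool_species[cm.pool_index(p)]
                          for p in clamp_pools], dtype=np.int64)

    def rhs(t, y):
        V = voltage_at(wf, t)
        r = np.empty(nch)
        r[k0] = cm.ck[k0]
        conc = y[cm.pool_species] * cm.inv_na_vol
        r[k1] = cm.ck[k1] * conc[cm.clig[k1]]
        r[k2] = cm.ck[k2] * np.exp(V / cm.cv0[k2])
        if k3.any():
            r[k3] = _vdcc_flux_nb(V, cm.flux_A, cm.flux_B, cm.flux_C) * cm.ca_scale
        a = r * np.where(has_src, y[src], 1.0)
        dy = S @ a
        if clamp_idx.size:
            dy[clamp_idx] = 0.0
        return dy

    y0 = cm.x0_float.copy()
    if t_eval is None:
        t_eval = np.linspace(0.0, protocol.total_time, 501)
    max_step = 1e-4 if len(protocol.onsets) else np.inf
    sol = solve_ivp(rhs, (0.0, protocol.total_time), y0, method="BDF",
                    t_eval=t_eval, rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}; "
                           "consider loosening rtol/atol")
    return MeanFieldResult(compiled=cm, protocol=protocol, t=sol.t, y=sol.y)
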