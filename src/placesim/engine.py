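"""Inner integration loop for the compartmental model.

One fused, numba-compiled kernel advances the whole coupled system:
exponential-Euler gating updates, event-driven AMPA/NMDA conductances with
Mg block, plateau/step current injections, a fully implicit backward-Euler
cable solve on the tree (Hines elimination), online dendritic/somatic
spike detection with the single-excursion rule, and event-driven STDP
(pre events delivered before the voltage step, post events detected after
it, so a pre and a post falling in the same step pair as pre-before-post).

Gating-variable voltage dependences are fixed Boltzmann forms with constant
time constants (canonical reduced CA1 formulations); peak densities and
their distance gradients live in :class:`placesim.config.ChannelConfig`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# gate index layout in the (N_GATES, n_comp) state array
GATE_NAMES = ("m", "h", "n", "ap", "bp", "ad", "bd", "q", "u", "s")
N_GATES = 10

# (v_half mV, slope mV, tau ms); negative slope = inactivation/closing with V
DEFAULT_KIN = np.array([
    (-38.0,  6.0, 0.10),   # m  Na activation
    (-60.0, -6.0, 1.50),   # h  Na fast inactivation
    (-32.0,  8.0, 2.50),   # n  K_DR activation
    (-24.0, 11.0, 0.50),   # ap K_A proximal activation
    (-58.0, -8.0, 20.0),   # bp K_A proximal inactivation
    (-25.0, 11.0, 0.50),   # ad K_A distal activation
    (-55.0, -8.0, 20.0),   # bd K_A distal inactivation
    (-82.0, -7.0, 40.0),   # q  I_h activation (opens with hyperpolarization)
    (-35.0,  9.0, 35.0),   # u  K_M activation
    (-72.0, -5.0, 80.0),   # s  Na slow inactivation
], dtype=np.float64)

_BIG_NEG = -1.0e18


@njit(cache=True, inline="always")
def _ginf(v, vh, k):
    return 1.0 / (1.0 + math.exp(-(v - vh) / k))


@njit(cache=True)
def _steady_gates(v, kin):
    n = v.size
    g = np.empty((N_GATES, n))
    for j in range(N_GATES):
        for i in range(n):
            g[j, i] = _ginf(v[i], kin[j, 0], kin[j, 1])
    return g


def gates_at_steady_state(v: np.ndarray, kin=None) -> np.ndarray:
    if kin is None:
        kin = DEFAULT_KIN
    return _steady_gates(np.asarray(v, dtype=np.float64), kin)


def kin_array(overrides: dict | None = None) -> np.ndarray:
    """Gate kinetics table; ``overrides`` maps gate name → (v_half, k, tau)."""
    kin = DEFAULT_KIN.copy()
    for name, row in (overrides or {}).items():
        kin[GATE_NAMES.index(name)] = row
    return kin


@njit(cache=True)
def _kernel(n_steps, dt, t0, kin,
            parent, cap, gl, el, gax,
            gna, gkdr, gkap, gkad, gh, gkm, s_mask,
            ena, ek, eh,
            gates, v,
            syn_comp, ra, da, rn, dn,
            g0, A, gmax,
            norm_a, norm_n, ratio_n, nmda_sat,
            mg_eta_eff, mg_gamma, e_syn,
            tau_ra, tau_da, tau_rn, tau_dn,
            ev_t, ev_syn,
            plast_on, M_, V_, tau_, d_, p_, thr_dend,
            dend_above, last_pre, last_post,
            soma_i, thr_soma, soma_above,
            inj_comp, inj_on, inj_off, inj_amp, inj_ramp,
            probe_idx, rec_stride,
            probe_out, w_out,
            soma_sp, dend_sp_t, dend_sp_syn,
            counts):
    ncomp = v.size
    nsyn = syn_comp.size
    nprobe = probe_idx.size
    ninj = inj_comp.size

    # per-gate exponential-Euler factors (constant taus)
    efac = np.empty(N_GATES)
    for j in range(N_GATES):
        efac[j] = 1.0 - math.exp(-dt / kin[j, 2])
    dec_ra = math.exp(-dt / tau_ra)
    dec_da = math.exp(-dt / tau_da)
    dec_rn = math.exp(-dt / tau_rn)
    dec_dn = math.exp(-dt / tau_dn)

    G = np.empty(ncomp)
    b = np.empty(ncomp)
    diag = np.empty(ncomp)
    sqrt2pi = math.sqrt(2.0 * math.pi)

    ev_ptr = 0
    n_ev = ev_t.size
    rec_row = 0
    n_soma = counts[0]
    n_dend = counts[1]

    for step in range(n_steps):
        t = t0 + step * dt

        # --- presynaptic event delivery (and depression pairing) ---
        while ev_ptr < n_ev and ev_t[ev_ptr] < t + dt:
            s = ev_syn[ev_ptr]
            w = g0[s] + A[s]
            ra[s] += w * norm_a
            da[s] += w * norm_a
            # NMDA charges in fractional steps: one volley contributes
            # 1/n_sat of the full NMDA weight, so the slow component only
            # reaches its ceiling after ~n_sat volleys within its decay time
            rn[s] += w * ratio_n * norm_n / nmda_sat
            dn[s] += w * ratio_n * norm_n / nmda_sat
            if plast_on:
                tp = ev_t[ev_ptr]
                if last_post[s] > _BIG_NEG / 2:
                    dlt = last_post[s] - tp
                    if dlt < 0.0:
                        gw = math.exp(-((dlt - M_) ** 2) / (2.0 * V_ * V_)) / (V_ * sqrt2pi)
                        A[s] *= (1.0 - d_ * gw)
                        if A[s] < 0.0:
                            A[s] = 0.0
                last_pre[s] = tp
            ev_ptr += 1

        # --- gating update + intrinsic conductances ---
        for i in range(ncomp):
            vi = v[i]
            for j in range(N_GATES):
                gates[j, i] += (_ginf(vi, kin[j, 0], kin[j, 1])
                                - gates[j, i]) * efac[j]
            m = gates[0, i]
            h = gates[1, i]
            nk = gates[2, i]
            ap = gates[3, i]
            bp = gates[4, i]
            ad = gates[5, i]
            bd = gates[6, i]
            q = gates[7, i]
            u = gates[8, i]
            sg = gates[9, i]

            # slow Na inactivation acts on dendritic channels only
            g_na = gna[i] * m * m * m * h * (1.0 - s_mask[i] * (1.0 - sg))
            g_k = gkdr[i] * nk * nk + gkap[i] * ap * bp + gkad[i] * ad * bd \
                + gkm[i] * u
            g_h = gh[i] * q
            G[i] = gl[i] + g_na + g_k + g_h
            b[i] = gl[i] * el[i] + g_na * ena + g_k * ek + g_h * eh

        # --- synaptic conductances ---
        for s in range(nsyn):
            ra[s] *= dec_ra
            da[s] *= dec_da
            rn[s] *= dec_rn
            dn[s] *= dec_dn
            ci = syn_comp[s]
            # receptor saturation: each synapse stands for one synchronously
            # active input group, so its open-channel conductance cannot
            # exceed the single-volley peak (g0 + A per component)
            w = g0[s] + A[s]
            ga = da[s] - ra[s]
            if ga > w:
                ga = w
            gn = dn[s] - rn[s]
            wn = w * ratio_n
            if gn > wn:
                gn = wn
            blk = 1.0 / (1.0 + mg_eta_eff * math.exp(-mg_gamma * v[ci]))
            gs = ga + gn * blk
            G[ci] += gs
            b[ci] += gs * e_syn

        # --- injected currents (exponential onset ramp) ---
        for j in range(ninj):
            if inj_on[j] <= t and t < inj_off[j]:
                amp = inj_amp[j]
                if inj_ramp > 0.0:
                    amp *= 1.0 - math.exp(-(t - inj_on[j]) / inj_ramp)
                b[inj_comp[j]] += amp

        # --- implicit cable solve (Hines) ---
        for i in range(ncomp):
            diag[i] = cap[i] / dt + G[i]
            b[i] += cap[i] / dt * v[i]
        for i in range(1, ncomp):
            p = parent[i]
            diag[i] += gax[i]
            diag[p] += gax[i]
        for i in range(ncomp - 1, 0, -1):
            p = parent[i]
            f = gax[i] / diag[i]            # off-diagonal is -gax
            diag[p] -= f * gax[i]
            b[p] += f * b[i]
        v[0] = b[0] / diag[0]
        for i in range(1, ncomp):
            v[i] = (b[i] + gax[i] * v[parent[i]]) / diag[i]

        t_next = t + dt

        # --- somatic spike detection ---
        vs = v[soma_i]
        if soma_above[0] == 0:
            if vs >= thr_soma:
                if n_soma < soma_sp.size:
                    soma_sp[n_soma] = t_next
                n_soma += 1
                soma_above[0] = 1
        elif vs < thr_soma:
            soma_above[0] = 0

        # --- dendritic spike detection + potentiation pairing ---
        for s in range(nsyn):
            vloc = v[syn_comp[s]]
            if dend_above[s] == 0:
                if vloc >= thr_dend:
                    if n_dend < dend_sp_t.size:
                        dend_sp_t[n_dend] = t_next
                        dend_sp_syn[n_dend] = s
                    n_dend += 1
                    dend_above[s] = 1
                    if plast_on and last_pre[s] > _BIG_NEG / 2:
                        dlt = t_next - last_pre[s]
                        if dlt > 0.0:
                            head = gmax[s] - g0[s] - A[s]
                            A[s] += head * p_ * math.exp(-dlt / tau_)
                            hi = gmax[s] - g0[s]
                            if A[s] > hi:
                                A[s] = hi
                            elif A[s] < 0.0:
                                A[s] = 0.0
                    if plast_on:
                        last_post[s] = t_next
            elif vloc < thr_dend:
                dend_above[s] = 0

        # --- recording ---
        if rec_stride > 0 and step % rec_stride == 0:
            if rec_row < probe_out.shape[0]:
                for k in range(nprobe):
                    probe_out[rec_row, k] = v[probe_idx[k]]
                for s in range(w_out.shape[1]):
                    w_out[rec_row, s] = g0[s] + A[s]
                rec_row += 1

        # --- divergence guard ---
        if step % 200 == 0 or step == n_steps - 1:
            for i in range(ncomp):
                if not math.isfinite(v[i]):
                    counts[0] = n_soma
                    counts[1] = n_dend
                    counts[2] = 1
                    counts[3] = i
                    counts[4] = step
                    return

    counts[0] = n_soma
    counts[1] = n_dend
    counts[2] = 0


_EMPTY_F = np.empty(0, dtype=np.float64)
_EMPTY_I = np.empty(0, dtype=np.int64)


class SynapseArrays:
    """Flat per-synapse state passed through the kernel (mutated in place)."""

    def __init__(self, comp_idx, g0, gmax, params):
        nsyn = len(comp_idx)
        self.comp_idx = np.asarray(comp_idx, dtype=np.int64)
        self.g0 = np.asarray(g0, dtype=np.float64)
        self.gmax = np.asarray(gmax, dtype=np.float64)
        self.A = np.zeros(nsyn)
        self.ra = np.zeros(nsyn)
        self.da = np.zeros(nsyn)
        self.rn = np.zeros(nsyn)
        self.dn = np.zeros(nsyn)
        self.dend_above = np.zeros(nsyn, dtype=np.int64)
        self.last_pre = np.full(nsyn, _BIG_NEG)
        self.last_post = np.full(nsyn, _BIG_NEG)
        self.params = params

    @property
    def n(self):
        return self.comp_idx.size


def dual_exp_norm(rise: float, decay: float) -> float:
    """Scale factor making max_t (e^(-t/decay) − e^(-t/rise)) equal 1."""
    tp = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)
    return 1.0 / peak


def run_segment(model, duration_ms, *, t0=0.0, syn=None,
                events=(None, None), stdp=None, plasticity_on=False,
                injections=None, injection_ramp_ms=0.0, probes=(),
                rec_stride_ms=1.0,
                soma_threshold=0.0, soma_above=None,
                max_soma_spikes=None, max_dend_spikes=None):
    """Advance the model ``duration_ms`` with full event handling.

    Returns a dict with somatic/dendritic spike times, probe traces and
    weight samples.  ``model`` and ``syn`` states are mutated in place so
    consecutive segments chain seamlessly.
    """
    dt = model.integration_dt
    n_steps = max(1, int(round(duration_ms / dt)))
    rec_stride = max(1, int(round(rec_stride_ms / dt))) if rec_stride_ms else 0

    if syn is None:
        syn_comp = _EMPTY_I
        ra = da = rn = dn = g0 = A = gmax = _EMPTY_F
        dend_above = _EMPTY_I
        last_pre = last_post = _EMPTY_F
        sp = _default_syn_params()
    else:
        syn_comp = syn.comp_idx
        ra, da, rn, dn = syn.ra, syn.da, syn.rn, syn.dn
        g0, A, gmax = syn.g0, syn.A, syn.gmax
        dend_above = syn.dend_above
        last_pre, last_post = syn.last_pre, syn.last_post
        sp = syn.params

    ev_t, ev_syn = events
    if ev_t is None:
        ev_t, ev_syn = _EMPTY_F, _EMPTY_I
    else:
        ev_t = np.asarray(ev_t, dtype=np.float64)
        ev_syn = np.asarray(ev_syn, dtype=np.int64)

    if stdp is None:
        M_, V_, tau_, d_, p_, thr_dend = -24.0, 6.32, 2.0, 0.3, 1.0, -10.0
    else:
        M_, V_, tau_ = stdp.M_ms, stdp.V_ms, stdp.tau_ms
        d_, p_, thr_dend = stdp.d, stdp.p, stdp.dendritic_threshold_mV

    if injections is None:
        inj_comp, inj_on, inj_off, inj_amp = _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F
    else:
        inj_comp = np.asarray(injections[0], dtype=np.int64)
        inj_on = np.asarray(injections[1], dtype=np.float64)
        inj_off = np.asarray(injections[2], dtype=np.float64)
        inj_amp = np.asarray(injections[3], dtype=np.float64)

    probe_idx = np.asarray(probes, dtype=np.int64)
    n_rec = (n_steps + rec_stride - 1) // rec_stride if rec_stride else 0
    probe_out = np.empty((n_rec, probe_idx.size))
    w_out = np.empty((n_rec, syn_comp.size))

    if max_soma_spikes is None:
        max_soma_spikes = n_steps // 10 + 64
    if max_dend_spikes is None:
        max_dend_spikes = n_steps // 4 + 256
    soma_sp = np.empty(max_soma_spikes)
    dend_sp_t = np.empty(max_dend_spikes)
    dend_sp_syn = np.empty(max_dend_spikes, dtype=np.int64)
    counts = np.zeros(8, dtype=np.int64)
    if soma_above is None:
        soma_above = np.zeros(1, dtype=np.int64)

    _kernel(n_steps, dt, t0, model.kin,
            model.parent_idx, model.cap_nF, model.g_leak_uS, model.e_leak,
            model.g_axial_uS,
            model.gbar_uS["Na"], model.gbar_uS["K_DR"],
            model.gbar_uS["K_A_proximal"], model.gbar_uS["K_A_distal"],
            model.gbar_uS["I_h"], model.gbar_uS["K_M"], model.s_mask,
            model.e_rev["Na"], model.e_rev["K"], model.e_rev["H"],
            model.gates, model.v,
            syn_comp, ra, da, rn, dn, g0, A, gmax,
            sp["norm_a"], sp["norm_n"], sp["ratio_n"], sp["nmda_sat"],
            sp["mg_eta_eff"], sp["mg_gamma"], sp["e_syn"],
            sp["tau_ra"], sp["tau_da"], sp["tau_rn"], sp["tau_dn"],
            ev_t, ev_syn,
            plasticity_on, M_, V_, tau_, d_, p_, thr_dend,
            dend_above, last_pre, last_post,
            np.int64(0), soma_threshold, soma_above,
            inj_comp, inj_on, inj_off, inj_amp, injection_ramp_ms,
            probe_idx, rec_stride,
            probe_out, w_out,
            soma_sp, dend_sp_t, dend_sp_syn,
            counts)

    if counts[2] != 0:
        bad = model.compartments[int(counts[3])].id
        t_bad = t0 + counts[4] * dt
        raise FloatingPointError(
            f"state diverged in compartment {bad} at t = {t_bad:.3f} ms")
    n_soma = min(int(counts[0]), max_soma_spikes)
    n_dend = min(int(counts[1]), max_dend_spikes)
    if int(counts[0]) > max_soma_spikes or int(counts[1]) > max_dend_spikes:
        raise RuntimeError("spike record buffers overflowed")
    rec_t = t0 + np.arange(n_rec) * rec_stride * dt if rec_stride else _EMPTY_F
    return {
        "soma_spikes": soma_sp[:n_soma].copy(),
        "dend_spike_t": dend_sp_t[:n_dend].copy(),
        "dend_spike_syn": dend_sp_syn[:n_dend].copy(),
        "probe_t": rec_t,
        "probe_v": probe_out,
        "weights": w_out,
        "t_end": t0 + n_steps * dt,
    }


def _default_syn_params():
    return {"norm_a": 1.0, "norm_n": 1.0, "ratio_n": 0.0, "nmda_sat": 1.0,
            "mg_eta_eff": 0.28, "mg_gamma": 0.062, "e_syn": 0.0,
            "tau_ra": 0.5, "tau_da": 1.0, "tau_rn": 5.0, "tau_dn": 50.0}


def syn_param_pack(syn_cfg):
    """Kernel parameter dict from a :class:`SynapseConfig`."""
    return {
        "norm_a": dual_exp_norm(syn_cfg.ampa_rise_ms, syn_cfg.ampa_decay_ms),
        "norm_n": dual_exp_norm(syn_cfg.nmda_rise_ms, syn_cfg.nmda_decay_ms),
        "ratio_n": syn_cfg.nmda_to_ampa_ratio,
        "nmda_sat": float(syn_cfg.nmda_saturation_volleys),
        "mg_eta_eff": syn_cfg.mg_eta_per_mM * syn_cfg.mg_mM,
        "mg_gamma": syn_cfg.mg_gamma_per_mV,
        "e_syn": syn_cfg.reversal_mV,
        "tau_ra": syn_cfg.ampa_rise_ms,
        "tau_da": syn_cfg.ampa_decay_ms,
        "tau_rn": syn_cfg.nmda_rise_ms,
        "tau_dn": syn_cfg.nmda_decay_ms,
    }


def single_step(model, synaptic_currents, injected_currents, dt):
    """One explicit-input integration step (used by ``advance_state``)."""
    old_dt = model.integration_dt
    model.integration_dt = dt
    try:
        total = np.asarray(synaptic_currents, dtype=float) + \
            np.asarray(injected_currents, dtype=float)
        comp = np.flatnonzero(total != 0).astype(np.int64)
        inj = (comp, np.full(comp.size, -1.0), np.full(comp.size, dt + 1.0),
               total[comp])
        run_segment(model, dt, injections=inj, rec_stride_ms=0.0)
    finally:
        model.integration_dt = old_dt


def integrate_passive_segment(model, duration_ms, injected_nA):
    """Settle / stimulate without synapses; constant injection throughout."""
    inj = np.asarray(injected_nA, dtype=float)
    comp = np.flatnonzero(inj != 0).astype(np.int64)
    injections = (comp, np.full(comp.size, -1.0),
                  np.full(comp.size, duration_ms + 1.0), inj[comp])
    return run_segment(model, duration_ms, injections=injections,
                       rec_stride_ms=0.0)
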