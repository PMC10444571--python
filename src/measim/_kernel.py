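"""Numba-compiled inner integration loop of the network simulator.

The kernel advances all neurons, synapses and delayed spike deliveries one
timestep at a time:

* gates by exponential Euler (steady-state/decay factors pre-tabulated on a
  fine voltage grid and linearly interpolated),
* the membrane potential by forward Euler plus the Euler-Maruyama noise term
  (normal deviates pre-generated per chunk by the caller),
* AMPA drive aggregated per postsynaptic neuron (its ODE is linear, so the
  weighted sum over presynaptic sources can be integrated directly),
* NMDA gating kept per edge because its saturating ODE does not aggregate;
  the per-edge update is written branch-free so it vectorizes, and is skipped
  wholesale while every synapse is silent,
* spike events delivered through per-timestep event lists after per-edge
  conduction delays, carrying the STD-depressed transmitted weight captured
  at emission.

The engine calls the kernel in chunks; all dynamical state lives in arrays
owned by the caller so integration resumes seamlessly.  Everything here is
plain arrays and scalars; the public API lives in ``measim.engine``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATE_TOL = 1e-9  # summed synaptic state below this is treated as silent

# indices into the persistent int64 scratch vector
FLAG_ACTIVE = 0     # nonzero while some NMDA synapse is non-silent
FLAG_PENDING = 1    # scheduled spike deliveries not yet consumed
FLAG_BLOWUP = 2     # first step index with |Vm| > 200 mV, else -1


@njit(cache=True)
def _integrate_chunk(
    t_start,
    n_chunk,
    dt,
    record_start,
    rec_stride,
    # per-area membrane parameters
    Cm,
    gK,
    gNa,
    gl,
    EK,
    ENa,
    El,
    conv,          # pA -> µA/cm²
    I_app,
    alphaCa,
    ahp_decay,     # exp(-dt/tauAHP)
    v_spk,
    refrac_steps,
    # neuron state (persistent, modified in place)
    V,
    m,
    h,
    n,
    gAHP,
    I_bias,
    noise,         # (n_chunk, N) pre-scaled voltage increments, mV
    # gate lookup tables on a uniform voltage grid
    v_lo,
    inv_dv,
    n_tab,
    minf_t,
    mfac_t,
    hinf_t,
    hfac_t,
    ninf_t,
    nfac_t,
    # synapse parameters
    gA,
    gN,
    EA,
    EN,
    aN,
    inv_tauNd,
    ampa_decay,    # exp(-dt/tauAMPA)
    xr_decay,      # exp(-dt/tauNMDA_rise)
    mg_over_b,
    a_mg,
    std_rec,       # exp(-dt/tauD)
    U,
    # network: edges sorted by source (CSR); Sw = S * weight per edge
    src_ptr,
    edge_tgt,
    edge_Sw,
    edge_dsteps,
    # synaptic state (persistent)
    A,
    nm_sum,
    s_nm,
    x_nm,
    cw,
    x_std,
    last_spk,
    # delivery machinery (persistent)
    bufA,          # (ring_len, N) AMPA jump accumulator
    ev_cnt,        # (ring_len,) NMDA arrival counts
    ev_edge,       # (ring_len, E)
    ev_val,        # (ring_len, E) transmitted STD factor
    flags,         # int64[3]: active / pending / blowup
    # electrodes (CSR over electrodes) and output
    elec_ptr,
    elec_nidx,
    elec_wv,
    rec,           # (n_elec, n_rec) float32, filled at absolute indices
    spk_n,         # (cap,) int32 scratch for spike sources
    spk_t,         # (cap,) int64 scratch for spike steps
):
    N = V.shape[0]
    E = edge_tgt.shape[0]
    ring_len = bufA.shape[0]
    n_elec = elec_ptr.shape[0] - 1
    n_rec = rec.shape[1]
    n_spk = 0

    for tl in range(n_chunk):
        t = t_start + tl
        cur = t % ring_len

        # deliver AMPA arrivals scheduled for this step
        for i in range(N):
            a = bufA[cur, i]
            if a != 0.0:
                A[i] += a
                bufA[cur, i] = 0.0
            nm_sum[i] = 0.0

        # deliver NMDA arrivals (sparse event list per slot)
        nev = ev_cnt[cur]
        if nev > 0:
            for k in range(nev):
                e = ev_edge[cur, k]
                x_nm[e] += 1.0
                cw[e] = edge_Sw[e] * ev_val[cur, k]
            ev_cnt[cur] = 0
            flags[FLAG_PENDING] -= nev
            flags[FLAG_ACTIVE] = 1

        # per-edge NMDA gating: branch-free saturating update + rise decay,
        # skipped wholesale while every synapse is silent
        if flags[FLAG_ACTIVE] != 0:
            tot = 0.0
            for e in range(E):
                s = s_nm[e]
                x = x_nm[e]
                if s == 0.0 and x == 0.0:
                    continue
                s = s + dt * (aN * x - s * (inv_tauNd + aN * x))
                x = x * xr_decay
                # flush tiny values to zero (avoids denormal slow paths)
                if s < 1e-15:
                    s = 0.0
                if x < 1e-15:
                    x = 0.0
                s_nm[e] = s
                x_nm[e] = x
                if s != 0.0:
                    nm_sum[edge_tgt[e]] += cw[e] * s
                    tot += s + x
            if tot < STATE_TOL:
                flags[FLAG_ACTIVE] = 0

        for i in range(N):
            v = V[i]
            # synaptic current (pA, depolarizing positive; reversals at EA/EN)
            u = 1.0 / (1.0 + np.exp(-a_mg * v) * mg_over_b)
            i_syn = gA * (EA - v) * A[i] + gN * u * (EN - v) * nm_sum[i]
            # ionic currents (µA/cm²)
            n2 = n[i] * n[i]
            m1 = m[i]
            i_ion = (
                -gK * n2 * n2 * (v - EK)
                - gNa * m1 * m1 * m1 * h[i] * (v - ENa)
                - gl * (v - El)
            )
            i_abs = I_bias[i] + I_app - gAHP[i] * (v - EK) + i_syn
            v_new = v + dt * (i_ion + conv * i_abs) / Cm + noise[tl, i]

            # exponential-Euler gate update, tables evaluated at the start voltage
            pos = (v - v_lo) * inv_dv
            if pos < 0.0:
                pos = 0.0
            elif pos > n_tab - 1.000001:
                pos = n_tab - 1.000001
            k = int(pos)
            f = pos - k
            minf = minf_t[k] + f * (minf_t[k + 1] - minf_t[k])
            mfac = mfac_t[k] + f * (mfac_t[k + 1] - mfac_t[k])
            hinf = hinf_t[k] + f * (hinf_t[k + 1] - hinf_t[k])
            hfac = hfac_t[k] + f * (hfac_t[k + 1] - hfac_t[k])
            ninf = ninf_t[k] + f * (ninf_t[k + 1] - ninf_t[k])
            nfac = nfac_t[k] + f * (nfac_t[k + 1] - nfac_t[k])
            m[i] = minf + (m[i] - minf) * mfac
            h[i] = hinf + (h[i] - hinf) * hfac
            n[i] = ninf + (n[i] - ninf) * nfac

            # slow conductances: sAHP decay, STD recovery, AMPA decay
            gAHP[i] *= ahp_decay
            x_std[i] = 1.0 - (1.0 - x_std[i]) * std_rec
            A[i] *= ampa_decay
            if A[i] < 1e-15:
                A[i] = 0.0

            # spike registration: upward threshold crossing with lockout
            if v < v_spk and v_new >= v_spk and t - last_spk[i] > refrac_steps:
                last_spk[i] = t
                gAHP[i] += alphaCa
                x_emit = x_std[i]
                x_std[i] = x_emit * (1.0 - U)
                for ke in range(src_ptr[i], src_ptr[i + 1]):
                    slot = (t + edge_dsteps[ke]) % ring_len
                    bufA[slot, edge_tgt[ke]] += edge_Sw[ke] * x_emit
                    kk = ev_cnt[slot]
                    ev_edge[slot, kk] = ke
                    ev_val[slot, kk] = x_emit
                    ev_cnt[slot] = kk + 1
                    flags[FLAG_PENDING] += 1
                spk_n[n_spk] = i
                spk_t[n_spk] = t
                n_spk += 1

            if v_new > 200.0 or v_new < -200.0 or not np.isfinite(v_new):
                if flags[FLAG_BLOWUP] < 0:
                    flags[FLAG_BLOWUP] = t
            V[i] = v_new

        if flags[FLAG_BLOWUP] >= 0:
            return n_spk

        # virtual electrodes: weighted sums of nearby membrane potentials
        if t >= record_start and (t - record_start) % rec_stride == 0:
            r = (t - record_start) // rec_stride
            if r < n_rec:
                for el in range(n_elec):
                    acc = 0.0
                    for ke in range(elec_ptr[el], elec_ptr[el + 1]):
                        acc += elec_wv[ke] * V[elec_nidx[ke]]
                    rec[el, r] = np.float32(acc)

    return n_spk
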