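"""Compiled numerical core.

Everything here operates on plain float64 arrays so numba can compile it;
the public modules (`soil`, `plants`, `engine`) wrap these functions with
typed containers.  There is exactly one implementation of the daily
water-balance step — the Python-facing `soil.step_day` and the multi-year
driver `_run_days` both call `_step_day_arrays`.

Leakage forms (``leak_form``):
  0 : L(S) = K_s * S**tau for S > S_f, else 0
      (field capacity gates drainage; above it, a soil-conductivity power law)
  1 : L(S) = K_s * ((S - S_f)/(1 - S_f))**tau for S > S_f, else 0
      (normalized alternate: zero at field capacity, K_s at saturation)
  2 : L(S) = K_s * S**tau at any S (ungated power law)
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_FLUX = 5  # rain, runoff, evap, drainage, storage_change (per-profile T separate)


@njit(cache=True)
def _leakage_rate(s, k_s, tau, s_f, leak_form):
    if leak_form == 0:
        if s <= s_f:
            return 0.0
        return k_s * s**tau
    if leak_form == 1:
        if s <= s_f:
            return 0.0
        return k_s * ((s - s_f) / (1.0 - s_f)) ** tau
    return k_s * s**tau


@njit(cache=True)
def _drain_amount(s, dt, cap, k_s, tau, s_f, leak_form):
    """Water (mm) leaving a layer over dt by its own drainage ODE.

    Exact integral of dS/dt = -L(S)/cap for the power-law forms, which
    removes the stiffness of explicit stepping at sand-like K_s.
    """
    if leak_form == 1:
        u0 = (s - s_f) / (1.0 - s_f)
        if u0 <= 0.0:
            return 0.0
        k = k_s / (cap * (1.0 - s_f))
        if abs(tau - 1.0) < 1e-12:
            u1 = u0 * np.exp(-k * dt)
        else:
            base = u0 ** (1.0 - tau) + (tau - 1.0) * k * dt
            u1 = base ** (1.0 / (1.0 - tau)) if base > 0.0 else 0.0
        if u1 < 0.0:
            u1 = 0.0
        return (u0 - u1) * (1.0 - s_f) * cap
    # forms 0 and 2: L = K_s * S**tau, gated at S_f for form 0
    floor = s_f if leak_form == 0 else 0.0
    if s <= floor:
        return 0.0
    k = k_s / cap
    if abs(tau - 1.0) < 1e-12:
        s1 = s * np.exp(-k * dt)
    else:
        base = s ** (1.0 - tau) + (tau - 1.0) * k * dt
        s1 = base ** (1.0 / (1.0 - tau)) if base > 0.0 else 0.0
    if s1 < floor:
        s1 = floor
    return (s - s1) * cap


@njit(cache=True)
def _evaporation_rate(s1, e_max, s_star, s_w):
    if s1 >= s_star:
        return e_max
    if s1 <= s_w:
        return 0.0
    return e_max * (s1 - s_w) / (s_star - s_w)


@njit(cache=True)
def _stress_factor(s, s_star, s_w):
    if s >= s_star:
        return 1.0
    if s <= s_w:
        return 0.0
    return (s - s_w) / (s_star - s_w)


@njit(cache=True)
def _demand_matrix(
    S, B, R, rmr, b_hsat, t_atm, s_star, s_w, uptake_code, out
):
    """Stress-adjusted per-layer, per-profile demands (mm/d), before the cap.

    S: (n_layers,), B: (K,), R: (K, n_layers), out: (n_layers, K).
    uptake_code: 0 Michaelis-Menten in per-layer root biomass r;
    1 the B_hsat -> 0 limit (t_atm wherever r > 0); 2 proportional to r
    (t_atm * r / b_hsat, uncapped per layer — the joint rescale caps it).
    """
    n_layers = S.shape[0]
    K = B.shape[0]
    for i in range(n_layers):
        f = _stress_factor(S[i], s_star, s_w)
        for k in range(K):
            r = B[k] * rmr * R[k, i]
            if r <= 0.0:
                t_max = 0.0
            elif uptake_code == 1:
                t_max = t_atm
            elif uptake_code == 2:
                t_max = t_atm * r / b_hsat
            else:
                t_max = t_atm * r / (b_hsat + r)
            out[i, k] = t_max * f


@njit(cache=True)
def _rescale_to_atm(demands, t_atm):
    total = 0.0
    for i in range(demands.shape[0]):
        for k in range(demands.shape[1]):
            total += demands[i, k]
    if total > t_atm:
        scale = t_atm / total
        for i in range(demands.shape[0]):
            for k in range(demands.shape[1]):
                demands[i, k] *= scale


@njit(cache=True)
def _step_day_arrays(
    S, rain, demands, caps,
    s_f, s_w, s_star, k_s, tau, e_max,
    n_substeps, leak_form,
    transp_out, fluxes_out,
):
    """Advance the soil column one day, mutating S in place.

    demands: (n_layers, K) stress-adjusted, capped demands in mm/d.
    transp_out: (K,) realized transpiration per profile (mm), filled.
    fluxes_out: (5,) rain, runoff, evap, drainage, storage_change (mm).
    Within each substep: rain/saturation-excess cascade, then sinks
    (evaporation from layer 1, then root uptake), then leakage top-down.
    """
    n_layers = S.shape[0]
    K = demands.shape[1]
    dt = 1.0 / n_substeps
    rain_sub = rain * dt

    storage0 = 0.0
    for i in range(n_layers):
        storage0 += S[i] * caps[i]

    runoff = 0.0
    evap = 0.0
    drain = 0.0
    for k in range(K):
        transp_out[k] = 0.0

    # demands are fixed for the day, so per-layer totals and the realized
    # per-layer withdrawals can be tracked as scalars and split across
    # profiles once at the end of the day
    d_tot = np.empty(n_layers)
    taken = np.zeros(n_layers)
    for i in range(n_layers):
        t = 0.0
        for k in range(K):
            t += demands[i, k]
        d_tot[i] = t

    for _ in range(n_substeps):
        # (i) rain input; excess above saturation cascades downward and,
        # once the whole column is full, leaves as surface runoff
        excess = rain_sub
        for i in range(n_layers):
            if excess <= 0.0:
                break
            room = (1.0 - S[i]) * caps[i]
            if excess < room:
                S[i] += excess / caps[i]
                if S[i] > 1.0:
                    S[i] = 1.0
                excess = 0.0
            else:
                S[i] = 1.0
                excess -= room
        if excess > 0.0:
            runoff += excess

        # (ii)+(iii) sinks and leakage, alternated on an adaptive inner
        # step: per cycle, evaporation (layer 1) first, then root uptake,
        # both floored at the water present, then drainage top-down using
        # the closed-form integral of each layer's leakage ODE (the bottom
        # layer's outflow is deep drainage).  The inner step is capped so
        # no layer drains more than ~0.4% of saturation per cycle, which
        # keeps the sequential splitting error far below the daily budget;
        # when nothing is draining a single cycle covers the substep.
        t_left = dt
        while t_left > 1e-15:
            rmax = 0.0
            for i in range(n_layers):
                r = _leakage_rate(S[i], k_s, tau, s_f, leak_form) / caps[i]
                if r > rmax:
                    rmax = r
            h = t_left
            if rmax * h > 0.004:
                h = 0.004 / rmax

            e = _evaporation_rate(S[0], e_max, s_star, s_w) * h
            avail0 = S[0] * caps[0]
            if e > avail0:
                e = avail0
            if e > 0.0:
                S[0] -= e / caps[0]
                if S[0] < 0.0:
                    S[0] = 0.0
                evap += e

            for i in range(n_layers):
                want = d_tot[i] * h
                if want <= 0.0:
                    continue
                avail = S[i] * caps[i]
                take = want if want <= avail else avail
                if take <= 0.0:
                    continue
                S[i] -= take / caps[i]
                if S[i] < 0.0:
                    S[i] = 0.0
                taken[i] += take

            for i in range(n_layers):
                flux = _drain_amount(S[i], h, caps[i], k_s, tau, s_f,
                                     leak_form)
                if flux <= 0.0:
                    continue
                if i < n_layers - 1:
                    room = (1.0 - S[i + 1]) * caps[i + 1]
                    if flux > room:
                        flux = room
                    if flux <= 0.0:
                        continue
                    S[i] -= flux / caps[i]
                    S[i + 1] += flux / caps[i + 1]
                    if S[i + 1] > 1.0:
                        S[i + 1] = 1.0
                else:
                    S[i] -= flux / caps[i]
                    drain += flux
                if S[i] < 0.0:
                    S[i] = 0.0
            t_left -= h

    for i in range(n_layers):
        if taken[i] > 0.0:
            for k in range(K):
                transp_out[k] += taken[i] * demands[i, k] / d_tot[i]

    storage1 = 0.0
    for i in range(n_layers):
        storage1 += S[i] * caps[i]

    fluxes_out[0] = rain
    fluxes_out[1] = runoff
    fluxes_out[2] = evap
    fluxes_out[3] = drain
    fluxes_out[4] = storage1 - storage0


@njit(cache=True)
def _run_days(
    rain, R, caps, B0, S0, wue,
    s_f, s_w, s_star, k_s, tau, e_max, t_atm,
    rmr, resp, b_hsat,
    n_substeps, leak_form, uptake_code,
    rec_idx,
):
    """Full daily loop: demand -> cap -> soil step -> biomass update.

    rain: (n_days,) mm; R: (K, n_layers) root fractions; B0: (K,) g/m2;
    S0: (n_layers,) initial saturations; wue: (K,) g/m2 per mm.
    rec_idx: sorted day indices at which to record state.

    Returns (S_rec, B_rec, T_rec, flux_rec, S_final, B_final) where
    T_rec[(j, k)] is realized transpiration of profile k on recorded day j
    and flux_rec[(j, :)] is (rain, runoff, evap, drainage, storage_change).
    """
    n_days = rain.shape[0]
    n_layers = S0.shape[0]
    K = B0.shape[0]
    n_rec = rec_idx.shape[0]

    S = S0.copy()
    B = B0.copy()
    demands = np.empty((n_layers, K))
    transp = np.empty(K)
    fluxes = np.empty(N_FLUX)

    S_rec = np.empty((n_rec, n_layers))
    B_rec = np.empty((n_rec, K))
    T_rec = np.empty((n_rec, K))
    flux_rec = np.empty((n_rec, N_FLUX))

    j = 0
    for day in range(n_days):
        _demand_matrix(S, B, R, rmr, b_hsat, t_atm, s_star, s_w,
                       uptake_code, demands)
        _rescale_to_atm(demands, t_atm)
        _step_day_arrays(S, rain[day], demands, caps,
                         s_f, s_w, s_star, k_s, tau, e_max,
                         n_substeps, leak_form, transp, fluxes)
        for k in range(K):
            B[k] += wue[k] * transp[k] - resp * B[k]
            if B[k] < 0.0:
                B[k] = 0.0
        if j < n_rec and day == rec_idx[j]:
            for i in range(n_layers):
                S_rec[j, i] = S[i]
            for k in range(K):
                B_rec[j, k] = B[k]
                T_rec[j, k] = transp[k]
            for m in range(N_FLUX):
                flux_rec[j, m] = fluxes[m]
            j += 1

    return S_rec, B_rec, T_rec, flux_rec, S, B
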