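"""Numba-compiled inner loops for the diffusion solver and the agent update.

These kernels exist purely for speed; the numerical behavior they implement
is specified and unit-tested through the public module APIs (``pde`` and
``cells``), including pure-numpy reference paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Cell state codes, mirrored from world.CellState (numba needs plain ints).
VESSEL = 0
NORMAL = 1
TUM_NORMOXIC = 2
TUM_HYPOXIC = 3
TUM_NECROTIC = 4


@njit(cache=True)
def ftcs_relax(conc, alpha, dt, vmax_px, km, vessel, c_vessel, n_steps):
    """Run ``n_steps`` explicit FTCS diffusion steps with consumption.

    conc      : concentration lattice, modified in place
    alpha     : unitless diffusion number D·dt/dx²
    vmax_px   : per-pixel maximum sink rate, concentration units per second
    km        : Michaelis constant in concentration units; km <= 0 means the
                sink is concentration-independent (zero-order kinetics)
    vessel    : uint8 mask of Dirichlet source pixels clamped to c_vessel
    Returns the max absolute change of the final step.
    """
    rows, cols = conc.shape
    buf = np.empty_like(conc)
    maxdiff = 0.0
    for step in range(n_steps):
        maxdiff = 0.0
        for r in range(rows):
            rm = r - 1 if r > 0 else rows - 1
            rp = r + 1 if r < rows - 1 else 0
            for c in range(cols):
                cm = c - 1 if c > 0 else cols - 1
                cp = c + 1 if c < cols - 1 else 0
                v = conc[r, c]
                lap = conc[rm, c] + conc[rp, c] + conc[r, cm] + conc[r, cp] - 4.0 * v
                if km > 0.0:
                    sink = vmax_px[r, c] * v / (km + v)
                else:
                    sink = vmax_px[r, c]
                new = v + alpha * lap - dt * sink
                if new < 0.0:
                    new = 0.0
                if vessel[r, c] == 1:
                    new = c_vessel
                buf[r, c] = new
        for r in range(rows):
            for c in range(cols):
                d = buf[r, c] - conc[r, c]
                if d < 0.0:
                    d = -d
                if d > maxdiff:
                    maxdiff = d
                conc[r, c] = buf[r, c]
    return maxdiff


@njit(cache=True)
def update_agents_pass(
    states,
    o2,
    glucose,
    order_r,
    order_c,
    u_death_o2,
    u_death_atp,
    u_div,
    u_pick,
    u_vessel,
    o2_death_thr,
    hyp_lo,
    hyp_hi,
    atp_thr,
    atp_exp,
    vessel_removal_p,
    p_div_max,
    normoxia_ref,
    vmax_g_normox,
    vmax_g_hypox,
    km_g,
    vmax_o_normox,
    vmax_o_hypox,
    atp_per_g,
    atp_per_o,
):
    """One 1-hour agent update: survival → oxygenation → division.

    Cells are visited in the supplied (pre-permuted) order; all uniform draws
    are supplied as arrays so the caller's generator controls determinism.
    Returns (n_necrosed, n_divided).
    """
    rows, cols = states.shape
    n = order_r.shape[0]
    n_necro = 0
    n_div = 0
    for k in range(n):
        r = order_r[k]
        c = order_c[k]
        s = states[r, c]
        if s != TUM_NORMOXIC and s != TUM_HYPOXIC:
            continue
        po2 = o2[r, c]
        glu = glucose[r, c]
        if s == TUM_NORMOXIC:
            f_o = vmax_o_normox
            f_g = vmax_g_normox * glu / (km_g + glu)
        else:
            f_o = vmax_o_hypox
            f_g = vmax_g_hypox * glu / (km_g + glu)
        f_atp = atp_per_g * f_g + atp_per_o * f_o

        # Survival: two independent stochastic necrosis criteria per hour.
        if po2 < o2_death_thr:
            p = 1.0 - po2 / o2_death_thr  # oxygen exponent fixed at 1
            if u_death_o2[k] < p:
                states[r, c] = TUM_NECROTIC
                n_necro += 1
                continue
        if f_atp < atp_thr:
            ratio = f_atp / atp_thr
            p = 1.0 - ratio**atp_exp
            if u_death_atp[k] < p:
                states[r, c] = TUM_NECROTIC
                n_necro += 1
                continue

        # Oxygenation state, bidirectional within the hypoxia band.
        if hyp_lo <= po2 <= hyp_hi:
            s = TUM_HYPOXIC
        elif po2 > hyp_hi:
            s = TUM_NORMOXIC
        states[r, c] = s

        # Division requires both quantities at/above the necrosis thresholds.
        if po2 < o2_death_thr or f_atp < atp_thr:
            continue
        scale = po2 / normoxia_ref
        if scale > 1.0:
            scale = 1.0
        if u_div[k] >= p_div_max * scale:
            continue

        # Daughter placement in the Moore neighborhood: a NORMAL pixel if any,
        # else a VESSEL pixel with probability vessel_removal_p.
        n_normal = 0
        n_vessel = 0
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                nr = (r + dr) % rows
                nc = (c + dc) % cols
                t = states[nr, nc]
                if t == NORMAL:
                    n_normal += 1
                elif t == VESSEL:
                    n_vessel += 1
        if n_normal > 0:
            pick = int(u_pick[k] * n_normal)
            if pick >= n_normal:
                pick = n_normal - 1
            want = NORMAL
        elif n_vessel > 0 and u_vessel[k] < vessel_removal_p:
            pick = int(u_pick[k] * n_vessel)
            if pick >= n_vessel:
                pick = n_vessel - 1
            want = VESSEL
        else:
            continue
        idx = 0
        for dr in range(-1, 2):
            done = False
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                nr = (r + dr) % rows
                nc = (c + dc) % cols
                if states[nr, nc] == want:
                    if idx == pick:
                        states[nr, nc] = s  # daughter inherits parent state
                        n_div += 1
                        done = True
                        break
                    idx += 1
            if done:
                break
    return n_necro, n_div


@njit(cache=True)
def sor_sweep(conc, beta, vmax_px, km, vessel, c_vessel, omega, n_sweeps):
    """Red-black SOR sweeps of the steady diffusion-consumption equation.

    Solves 0 = ∇²C·D/dx² − s(C) with Dirichlet vessels: identical fixed point
    to the FTCS iteration.  beta = dx²/D (seconds).  Michaelis–Menten sinks
    (km > 0) are handled semi-implicitly, zero-order sinks (km <= 0) with a
    floor at zero.  Returns the max absolute update of the final sweep.
    """
    rows, cols = conc.shape
    maxdiff = 0.0
    for sweep in range(n_sweeps):
        maxdiff = 0.0
        for parity in range(2):
            for r in range(rows):
                rm = r - 1 if r > 0 else rows - 1
                rp = r + 1 if r < rows - 1 else 0
                cstart = (r + parity) % 2
                for c in range(cstart, cols, 2):
                    if vessel[r, c] == 1:
                        conc[r, c] = c_vessel
                        continue
                    cm = c - 1 if c > 0 else cols - 1
                    cp = c + 1 if c < cols - 1 else 0
                    nb = conc[rm, c] + conc[rp, c] + conc[r, cm] + conc[r, cp]
                    old = conc[r, c]
                    if km > 0.0:
                        gs = nb / (4.0 + beta * vmax_px[r, c] / (km + old))
                    else:
                        gs = (nb - beta * vmax_px[r, c]) / 4.0
                    new = old + omega * (gs - old)
                    if new < 0.0:
                        new = 0.0
                    conc[r, c] = new
                    d = new - old
                    if d < 0.0:
                        d = -d
                    if d > maxdiff:
                        maxdiff = d
    return maxdiff
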