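"""Fused numba time-stepping kernel.

One compiled function advances the full coupled system (populations in
(t*, x), synapses, ions, volume, representative neurons, observables)
by a chunk of steps. Transcendental-heavy per-bin quantities (gating
steady states and decay factors, the hazard terms, the NMDA block, the
depolarization-block sigmoid, exp(-x)) are evaluated from densely
sampled lookup tables with linear interpolation (grid steps of
1/64-1/256 per unit, relative error < 1e-5); the slow per-node ion
arithmetic uses libm directly. Empty t* cohorts (zero density outside
the frozen spike window) are skipped exactly: a cohort can only gain
mass at t* = 0, so skipping does not alter the dynamics.

The engine module owns the parameter-vector layout (index constants
below) and the table construction; this module must stay importable
without compilation side effects beyond numba caching.
"""

import numpy as np
from numba import njit

# --- parameter vector indices -------------------------------------------
P_DT = 0; P_NF = 1; P_GL_E = 2; P_GL_I = 3; P_VTH0_E = 4; P_VTH0_I = 5
P_VRESET = 6; P_NDR_RESET = 7; P_VDB = 8; P_DBSLOPE = 9; P_DBSHIFT = 10
P_FUINF = 11; P_SIGMA0 = 12; P_SIG_LINEAR = 13; P_GABA_LITERAL = 14
P_GDR_E = 15; P_GM_E = 16; P_GKCA_E = 17; P_GDR_I = 18
P_AKCA = 19; P_BKCA = 20; P_CAP = 21
P_GA_I = 22; P_GN_E = 23; P_GN_I = 24; P_GG_E = 25; P_GG_I = 26
P_UGLU = 27; P_UGABA = 28; P_TAUGLU = 29; P_TAUGABA = 30
P_FOU = 31; P_SOU = 32; P_VHOLD = 33; P_FNMDA_HOLD = 34
P_GAMMA = 35; P_BETAR = 36; P_ALPHAI = 37; P_IPUMPMAX = 38
P_KCC2_E = 39; P_KCC2_I = 40; P_NKCC1_E = 41; P_NKCC1_I = 42
P_GKL = 43; P_GCLL = 44; P_GNAL = 45; P_QNA = 46; P_DBATH = 47
P_KBATH = 48; P_FRKGLU = 49; P_FRNAGLU = 50; P_TAUCA = 51; P_CHI = 52
P_VCA = 53; P_GLIA = 54; P_K1 = 55; P_BMAX = 56; P_VOLDYN = 57
P_FVOL = 58; P_VOLFAC = 59; P_OSM = 60; P_DPI0 = 61; P_HCO3I = 62
P_HCO3O = 63; P_DDX2 = 64; P_ALLFRAC = 65; P_PUMPKIN = 66
P_KCC2PRINT = 67; P_NERNST = 68; P_GNA_REP = 69; P_VNA_REP = 70
P_REPSUB = 71; P_S1 = 72; P_S2 = 73; P_TRSTR = 74; P_FLSTR = 75
P_NB = 76; P_NX = 77; P_SIGOU = 78; P_TAUN = 79; P_GABACL = 80
P_IPREST_E = 81; P_IPREST_I = 82; P_PUMPV = 83
P_LEN = 84

# ION row indices
I_KIE = 0; I_KII = 1; I_CLIE = 2; I_CLII = 3; I_NAIE = 4; I_NAII = 5
I_KO = 6; I_CLO = 7; I_NAO = 8; I_CA = 9; I_B = 10; I_V = 11

# table-grid constants (GRID vector)
G_U0 = 0; G_IDU = 1; G_NU = 2        # U-grid tables
G_E0 = 3; G_IDE = 4; G_NE = 5        # exp(-x) table
G_T0 = 6; G_IDT = 7; G_NT = 8        # T-grid tables (A, G)
G_Q_G0 = 9; G_Q_IDG = 10; G_Q_NG = 11  # Q-table conductance axis
G_LEN = 12

SQ2PI = np.sqrt(2.0 / np.pi)
RT2 = np.sqrt(2.0)
SQPI = np.sqrt(np.pi)


@njit(cache=True, inline="always")
def _lerp(tab, x, x0, inv_dx, n):
    u = (x - x0) * inv_dx
    if u <= 0.0:
        return tab[0]
    if u >= n - 1:
        return tab[n - 1]
    i = int(u)
    f = u - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True, inline="always")
def _expn(x, T_EXPN, GRID):
    # exp(-x) for x >= 0 (clamped); large x -> 0
    if x >= GRID[G_E0] + (GRID[G_NE] - 1.0) / GRID[G_IDE]:
        return 0.0
    return _lerp(T_EXPN, x, GRID[G_E0], GRID[G_IDE], int(GRID[G_NE]))


@njit(cache=True)
def run_chunk(s0, n_steps, P, W, gA_E_prof, OFFS,
              rho, U, Uinf, Tprev, nDR, nM, nKCa, nu,
              syn_m, syn_md, prop, syn_src, xglu, xgaba,
              ION, Inoise, PUMP, REP, normals,
              TU, T_EXPN, T_G, T_A, T_Q, GRID,
              trace, fields):
    dt = P[P_DT]
    nf = int(P[P_NF])
    nb = int(P[P_NB])
    nx = int(P[P_NX])
    s1 = int(P[P_S1]); s2 = int(P[P_S2])
    tr_str = int(P[P_TRSTR]); fl_str = int(P[P_FLSTR])
    nU = int(GRID[G_NU]); u0 = GRID[G_U0]; idu = GRID[G_IDU]
    nT = int(GRID[G_NT]); t0 = GRID[G_T0]; idt = GRID[G_IDT]
    q_g0 = GRID[G_Q_G0]; q_idg = GRID[G_Q_IDG]; q_ng = int(GRID[G_Q_NG])
    nTq = T_Q.shape[0]

    surv = np.empty(nb)
    phi = np.empty((2, nx))
    ubar = np.empty((2, nx))
    ikact = np.empty((2, nx))
    g_glu = np.empty((2, nx))
    g_gaba = np.empty((2, nx))
    vK = np.empty((2, nx)); vCl = np.empty((2, nx)); vNa = np.empty((2, nx))
    vGABA = np.empty((2, nx)); vL = np.empty((2, nx))
    dKi = np.empty((2, nx)); dCli = np.empty((2, nx)); dNai = np.empty((2, nx))
    lap = np.empty(nx)

    gl_sum = P[P_GKL] + P[P_GCLL] + P[P_GNAL]

    for s in range(n_steps):
        step = s0 + s
        # --- 1. OU noise (interneurons only), exact update ---------------
        for x in range(nx):
            Inoise[x] = Inoise[x] * P[P_FOU] + P[P_SOU] * normals[s, x]

        # --- 2. reversal potentials and leak mixture ---------------------
        for x in range(nx):
            Ko = ION[I_KO, x]; Clo = ION[I_CLO, x]; Nao = ION[I_NAO, x]
            for p in range(2):
                Ki = ION[I_KIE + p, x]
                Cli = ION[I_CLIE + p, x]
                Nai = ION[I_NAIE + p, x]
                vK[p, x] = P[P_NERNST] * np.log(Ko / Ki)
                vCl[p, x] = P[P_NERNST] * np.log(Cli / Clo)
                vNa[p, x] = P[P_NERNST] * np.log(Nao / Nai)
                vGABA[p, x] = P[P_NERNST] * np.log(
                    (4.0 * Cli + P[P_HCO3I]) / (4.0 * Clo + P[P_HCO3O]))
                vL[p, x] = (P[P_GKL] * vK[p, x] + P[P_GCLL] * vCl[p, x]
                            + P[P_GNAL] * vNa[p, x]) / gl_sum

        # --- 3. spatial kernels ------------------------------------------
        for p in range(2):
            mean_nu = 0.0
            for x in range(nx):
                mean_nu += nu[p, x]
            mean_nu /= nx
            for x in range(nx):
                acc = 0.0
                for xp in range(nx):
                    acc += W[x, xp] * nu[p, xp]
                phi[p, x] = (1.0 - P[P_ALLFRAC]) * acc + P[P_ALLFRAC] * mean_nu

        # --- 4. synapses (second-order kinetics) and depression ----------
        for k in range(6):
            src = 0 if k < 4 else 1   # AMPA/NMDA from E, GABA from I
            a00 = prop[k, 0, 0]; a01 = prop[k, 0, 1]
            a10 = prop[k, 1, 0]; a11 = prop[k, 1, 1]
            for x in range(nx):
                m = syn_m[k, x]; md = syn_md[k, x]
                f = phi[src, x]
                m_new = a00 * m + a01 * md
                md_new = a10 * m + a11 * md + syn_src[k] * (1.0 - m) * f * dt
                syn_m[k, x] = m_new if m_new > 0.0 else 0.0
                syn_md[k, x] = md_new
        for x in range(nx):
            rg = 1.0 / P[P_TAUGLU] + P[P_UGLU] * phi[0, x]
            xi = (1.0 / P[P_TAUGLU]) / rg
            xglu[x] = xi + (xglu[x] - xi) * _expn(rg * dt, T_EXPN, GRID)
            rb = 1.0 / P[P_TAUGABA] + P[P_UGABA] * phi[1, x]
            xib = (1.0 / P[P_TAUGABA]) / rb
            xgaba[x] = xib + (xgaba[x] - xib) * _expn(rb * dt, T_EXPN, GRID)

        # --- 5. populations ----------------------------------------------
        for p in range(2):
            gL = P[P_GL_E] if p == 0 else P[P_GL_I]
            vth0 = P[P_VTH0_E] if p == 0 else P[P_VTH0_I]
            gDR = P[P_GDR_E] if p == 0 else P[P_GDR_I]
            gM = P[P_GM_E] if p == 0 else 0.0
            gKCa = P[P_GKCA_E] if p == 0 else 0.0
            gN_max = P[P_GN_E] if p == 0 else P[P_GN_I]
            gG_max = P[P_GG_E] if p == 0 else P[P_GG_I]
            for x in range(nx):
                gA_max = gA_E_prof[x] if p == 0 else P[P_GA_I]
                gA = gA_max * syn_m[0 + p, x] * xglu[x]
                gNb = gN_max * syn_m[2 + p, x] * xglu[x]
                gG = gG_max * syn_m[4 + p, x] * xgaba[x]
                v_gaba_drive = vK[p, x] if P[P_GABA_LITERAL] != 0.0 \
                    else vGABA[p, x]
                In = Inoise[x] if p == 1 else 0.0
                if P[P_PUMPV] != 0.0:
                    # electrogenic pump: net one charge out per cycle;
                    # only the deviation from the resting pump acts
                    ip0 = P[P_IPREST_E] if p == 0 else P[P_IPREST_I]
                    In -= PUMP[p, x] - ip0
                Ca = ION[I_CA, x]
                akca = P[P_AKCA] * Ca * Ca

                acc_ubar = 0.0
                acc_ik = 0.0
                acc_mass = 0.0
                fired = 0.0
                pk_val = -1.0
                pk_idx = nb - 1
                for i in range(nb):
                    ri = rho[p, x, i]
                    if i < nf:
                        surv[i] = ri
                        # frozen spike window: state clamped, no hazard
                        uu = Uinf[p, x, i]
                        uin = P[P_VRESET] + (uu - P[P_VRESET]) * P[P_FUINF]
                        Uinf[p, x, i] = uin
                        acc_ubar += ri * U[p, x, i]
                        acc_mass += ri
                        continue
                    if ri < 1e-14 and i != nb - 1:
                        surv[i] = ri
                        continue
                    u = U[p, x, i]
                    fn = _lerp(TU[0], u, u0, idu, nU)
                    gN = gNb * fn
                    gsyn = gA + gN + gG
                    ndr = nDR[p, x, i]
                    n2 = ndr * ndr
                    gv = gDR * n2 * n2
                    if p == 0:
                        gv += gM * nM[x, i] + gKCa * nKCa[x, i] * nKCa[x, i]
                    gtot = gL + gsyn + gv
                    ik = gv * (u - vK[p, x])
                    # dynamic threshold
                    uin = u + (Uinf[p, x, i] - u) * P[P_FUINF]
                    Uinf[p, x, i] = uin
                    vth = vth0 + P[P_DBSHIFT] * _lerp(TU[5], uin, u0, idu, nU)
                    # hazard
                    if P[P_SIG_LINEAR] != 0.0:
                        sig = P[P_SIGMA0] * (1.0 + gsyn / gL)
                    else:
                        sig = P[P_SIGMA0] * np.sqrt(1.0 + gsyn / gL)
                    if p == 1 and P[P_SIGOU] > 0.0:
                        tau_m = P[P_CAP] / gtot
                        s_ou = (P[P_SIGOU] / gtot) * np.sqrt(
                            P[P_TAUN] / (P[P_TAUN] + tau_m))
                        sig = np.sqrt(sig * sig + s_ou * s_ou)
                    T = (vth - u) / (RT2 * sig)
                    # A-term: exp(poly(T)) * Q(T, gtot) * gtot / C
                    Apoly = _lerp(T_A, T, t0, idt, nT)
                    gq = gtot
                    if gq < q_g0:
                        gq = q_g0
                    uq = (gq - q_g0) * q_idg
                    if uq >= q_ng - 1:
                        uq = q_ng - 1.000001
                    tq = (T - t0) * idt * (nTq - 1.0) / (nT - 1.0)
                    if tq <= 0.0:
                        tq = 0.0
                    if tq >= nTq - 1:
                        tq = nTq - 1.000001
                    it = int(tq); ft = tq - it
                    ig = int(uq); fg = uq - ig
                    Q = (T_Q[it, ig] * (1.0 - ft) * (1.0 - fg)
                         + T_Q[it + 1, ig] * ft * (1.0 - fg)
                         + T_Q[it, ig + 1] * (1.0 - ft) * fg
                         + T_Q[it + 1, ig + 1] * ft * fg)
                    H = Apoly * Q * gtot / P[P_CAP]
                    # B-term (drift); suppressed on the first unfrozen bin
                    if i > nf:
                        drift = (Tprev[p, x, i] - T) / dt
                        if drift > 0.0:
                            if T < -12.0:
                                Gv = SQPI * (-T)
                            else:
                                Gv = _lerp(T_G, T, t0, idt, nT)
                            H += 2.0 * SQ2PI * drift * Gv
                    Tprev[p, x, i] = T
                    hdt = H * dt
                    sv = ri * _expn(hdt, T_EXPN, GRID)
                    surv[i] = sv
                    rel = ri - sv
                    fired += rel
                    relH = ri * H
                    if relH > pk_val:
                        pk_val = relH
                        pk_idx = i
                    # voltage update (exponential Euler)
                    uss = (gL * vL[p, x] + gG * v_gaba_drive + gv * vK[p, x]
                           + In) / gtot
                    u_new = uss + (u - uss) * _expn(gtot * dt / P[P_CAP],
                                                    T_EXPN, GRID)
                    U[p, x, i] = u_new
                    # gating
                    ninf = _lerp(TU[1], u, u0, idu, nU)
                    dec = _lerp(TU[2], u, u0, idu, nU)
                    nDR[p, x, i] = ninf + (ndr - ninf) * dec
                    if p == 0:
                        ninfm = _lerp(TU[3], u, u0, idu, nU)
                        decm = _lerp(TU[4], u, u0, idu, nU)
                        nM[x, i] = ninfm + (nM[x, i] - ninfm) * decm
                        rk = akca + P[P_BKCA]
                        nki = akca / rk
                        nKCa[x, i] = nki + (nKCa[x, i] - nki) \
                            * _expn(rk * dt, T_EXPN, GRID)
                    acc_ubar += ri * u
                    acc_ik += ri * ik
                    acc_mass += ri

                if acc_mass > 0.0:
                    ubar[p, x] = acc_ubar / acc_mass
                else:
                    ubar[p, x] = vL[p, x]
                ikact[p, x] = acc_ik
                nu[p, x] = fired / dt
                g_glu[p, x] = gA + gNb * _lerp(TU[0], ubar[p, x], u0, idu, nU)
                g_gaba[p, x] = gG

                # slow-gate injection values from the spike-release peak
                inj_nM = nM[x, pk_idx] if p == 0 else 0.0
                inj_nK = nKCa[x, pk_idx] if p == 0 else 0.0

                # transport: shift one bin, absorbing merge at the end
                w_old = surv[nb - 1]
                w_new = surv[nb - 2]
                w_sum = w_old + w_new
                mM = 0.0
                mK = 0.0
                if w_sum > 0.0:
                    fo = w_old / w_sum
                    fn_ = 1.0 - fo
                    mU = fo * U[p, x, nb - 1] + fn_ * U[p, x, nb - 2]
                    mUi = fo * Uinf[p, x, nb - 1] + fn_ * Uinf[p, x, nb - 2]
                    mT = fo * Tprev[p, x, nb - 1] + fn_ * Tprev[p, x, nb - 2]
                    mD = fo * nDR[p, x, nb - 1] + fn_ * nDR[p, x, nb - 2]
                    if p == 0:
                        mM = fo * nM[x, nb - 1] + fn_ * nM[x, nb - 2]
                        mK = fo * nKCa[x, nb - 1] + fn_ * nKCa[x, nb - 2]
                else:
                    mU = U[p, x, nb - 1]; mUi = Uinf[p, x, nb - 1]
                    mT = Tprev[p, x, nb - 1]; mD = nDR[p, x, nb - 1]
                    if p == 0:
                        mM = nM[x, nb - 1]; mK = nKCa[x, nb - 1]
                for i in range(nb - 1, 0, -1):
                    rho[p, x, i] = surv[i - 1]
                    U[p, x, i] = U[p, x, i - 1]
                    Uinf[p, x, i] = Uinf[p, x, i - 1]
                    Tprev[p, x, i] = Tprev[p, x, i - 1]
                    nDR[p, x, i] = nDR[p, x, i - 1]
                if p == 0:
                    for i in range(nb - 1, 0, -1):
                        nM[x, i] = nM[x, i - 1]
                        nKCa[x, i] = nKCa[x, i - 1]
                rho[p, x, nb - 1] += w_old
                U[p, x, nb - 1] = mU
                Uinf[p, x, nb - 1] = mUi
                Tprev[p, x, nb - 1] = mT
                nDR[p, x, nb - 1] = mD
                if p == 0:
                    nM[x, nb - 1] = mM
                    nKCa[x, nb - 1] = mK
                # injection at t* = 0 (the spike boundary)
                rho[p, x, 0] = fired
                U[p, x, 0] = P[P_VRESET]
                nDR[p, x, 0] = P[P_NDR_RESET]
                Tprev[p, x, 0] = 10.0
                if p == 0 and fired > 0.0:
                    nM[x, 0] = inj_nM
                    nKCa[x, 0] = inj_nK

        # --- 6. representative neurons at the electrode sites ------------
        nsub = int(P[P_REPSUB])
        hdt_r = dt / nsub
        for r in range(4):
            p = 0 if r < 2 else 1
            x = s1 if (r % 2 == 0) else s2
            gL = P[P_GL_E] if p == 0 else P[P_GL_I]
            vth0 = P[P_VTH0_E] if p == 0 else P[P_VTH0_I]
            gDRr = P[P_GDR_E] if p == 0 else P[P_GDR_I]
            gMr = P[P_GM_E] if p == 0 else 0.0
            gKCar = P[P_GKCA_E] if p == 0 else 0.0
            gA_max = gA_E_prof[x] if p == 0 else P[P_GA_I]
            gA = gA_max * syn_m[0 + p, x] * xglu[x]
            gNb = (P[P_GN_E] if p == 0 else P[P_GN_I]) * syn_m[2 + p, x] * xglu[x]
            gG = (P[P_GG_E] if p == 0 else P[P_GG_I]) * syn_m[4 + p, x] * xgaba[x]
            In = Inoise[x] if p == 1 else 0.0
            if P[P_PUMPV] != 0.0:
                ip0 = P[P_IPREST_E] if p == 0 else P[P_IPREST_I]
                In -= PUMP[p, x] - ip0
            Ca = ION[I_CA, x]
            V = REP[r, 0]; m = REP[r, 1]; h = REP[r, 2]
            ndr = REP[r, 3]; nm = REP[r, 4]; nk = REP[r, 5]
            uin = REP[r, 6]; froz = REP[r, 7]
            spiked = 0.0
            for _ in range(nsub):
                if froz > 0.0:
                    froz -= hdt_r
                    V = P[P_VRESET]
                    ndr = P[P_NDR_RESET]
                else:
                    # sodium rates (removable singularities guarded)
                    xm = -(V + 50.0)
                    if abs(xm) < 1e-6:
                        am = 0.32 * 4.0
                    else:
                        am = 0.32 * xm / (np.exp(xm / 4.0) - 1.0)
                    xbm = V + 23.0
                    if abs(xbm) < 1e-6:
                        bm = 0.28 * 5.0
                    else:
                        bm = 0.28 * xbm / (np.exp(xbm / 5.0) - 1.0)
                    ah = 0.128 * np.exp(-(V + 46.0) / 18.0)
                    bh = 4.0 / (1.0 + np.exp(-(V + 23.0) / 5.0))
                    fn = _lerp(TU[0], V, u0, idu, nU)
                    INa = P[P_GNA_REP] * m * m * m * h * (V - P[P_VNA_REP])
                    IK = (gDRr * ndr ** 4 + gMr * nm + gKCar * nk * nk) \
                        * (V - vK[p, x])
                    dV = (-gL * (V - vL[p, x]) - INa - IK + In
                          + gG * (vGABA[p, x] - V) - gA * V - gNb * fn * V) \
                        / P[P_CAP]
                    V += hdt_r * dV
                    m += hdt_r * (am * (1.0 - m) - bm * m)
                    h += hdt_r * (ah * (1.0 - h) - bh * h)
                    ninf = _lerp(TU[1], V, u0, idu, nU)
                    ndr = ninf + (ndr - ninf) * _lerp(TU[2], V, u0, idu, nU)
                    ninfm = _lerp(TU[3], V, u0, idu, nU)
                    nm = ninfm + (nm - ninfm) * _lerp(TU[4], V, u0, idu, nU)
                    rk = P[P_AKCA] * Ca * Ca + P[P_BKCA]
                    nki = P[P_AKCA] * Ca * Ca / rk
                    nk = nki + (nk - nki) * _expn(rk * hdt_r, T_EXPN, GRID)
                uin += hdt_r * (V - uin) / 100.0
                vth = vth0 + P[P_DBSHIFT] * _lerp(TU[5], uin, u0, idu, nU)
                if froz <= 0.0 and V >= vth:
                    spiked = 1.0
                    V = P[P_VRESET]
                    ndr = P[P_NDR_RESET]
                    froz = 1.5
            REP[r, 0] = V; REP[r, 1] = m; REP[r, 2] = h
            REP[r, 3] = ndr; REP[r, 4] = nm; REP[r, 5] = nk
            REP[r, 6] = uin; REP[r, 7] = froz
            REP[r, 8] = 30.0 if spiked > 0.0 else V   # recorded sample

        # --- 7. ion, glia, volume dynamics -------------------------------
        # diffusion operator on K_o (Neumann ends), before the update
        for x in range(nx):
            if x == 0:
                lap[x] = ION[I_KO, 1] - ION[I_KO, 0]
            elif x == nx - 1:
                lap[x] = ION[I_KO, nx - 2] - ION[I_KO, nx - 1]
            else:
                lap[x] = ION[I_KO, x + 1] - 2.0 * ION[I_KO, x] \
                    + ION[I_KO, x - 1]
            lap[x] *= P[P_DDX2]

        for x in range(nx):
            Ko = ION[I_KO, x]; Clo = ION[I_CLO, x]; Nao = ION[I_NAO, x]
            Ca = ION[I_CA, x]
            for p in range(2):
                Ki = ION[I_KIE + p, x]
                Cli = ION[I_CLIE + p, x]
                Nai = ION[I_NAIE + p, x]
                ub = ubar[p, x]
                # pump current
                if P[P_PUMPKIN] != 0.0:
                    Uv = ub * 1e-3
                    nai_t = Nai / (2.49 * np.exp(-0.386 * Uv))
                    nae_t = Nao / (15.5 * np.exp(12.1 * Uv))
                    ki_t = Ki / 0.5
                    ke_t = Ko / 0.213
                    Pi = 4.2 / (1.0 + Ki / 292.0 + 1e-4 / 6.77 + Nai / 224.0)
                    den_i = (1.0 + nai_t) ** 3 + (1.0 + ki_t) ** 2 - 1.0
                    den_e = (1.0 + nae_t) ** 3 + (1.0 + ke_t) ** 2 - 1.0
                    a1p = 1050.0 * nai_t ** 3 / den_i
                    a2p = 481.0
                    a3p = 2000.0 * ke_t ** 2 / den_e
                    a4p = 320.0 * 3.904 / 4.904
                    a1m = 8.605
                    a2m = 40.0 * nae_t ** 3 / den_e
                    a3m = 79300.0 * Pi * 1e-4 / 4.904
                    a4m = 40.0 * ki_t ** 2 / den_i
                    S = (a2p * a3p * a4p + a1m * a3p * a4p
                         + a1m * a2m * a4p + a1m * a2m * a3m
                         + a3p * a4p * a1p + a2m * a4p * a1p
                         + a2m * a3m * a1p + a2m * a3m * a4m
                         + a4p * a1p * a2p + a3m * a1p * a2p
                         + a3m * a4m * a2p + a3m * a4m * a1m
                         + a1p * a2p * a3p + a4m * a2p * a3p
                         + a4m * a1m * a3p + a4m * a1m * a2m)
                    Ip = P[P_IPUMPMAX] * (a1p * a2p * a3p * a4p
                                          - a1m * a2m * a3m * a4m) / (16.8 * S)
                else:
                    Ip = P[P_IPUMPMAX] / ((1.0 + np.exp(3.5 - Ko))
                                          * (1.0 + np.exp((25.0 - Nai) / 3.0)))
                PUMP[p, x] = Ip
                # transporters (positive = influx)
                d = vCl[p, x] - vK[p, x]
                den = d + 40.0
                if den < 1.0 and den > -1.0:
                    den = 1.0 if den >= 0.0 else -1.0
                if P[P_KCC2PRINT] != 0.0:
                    kcc2 = (P[P_KCC2_E] if p == 0 else P[P_KCC2_I]) * d / den
                else:
                    kcc2 = -(P[P_KCC2_E] if p == 0 else P[P_KCC2_I]) * d / den
                nkmax = P[P_NKCC1_E] if p == 0 else P[P_NKCC1_I]
                nkcc1 = nkmax * (vNa[p, x] + vK[p, x] - 2.0 * vCl[p, x]) \
                    / P[P_NERNST]
                if nkcc1 > nkmax:
                    nkcc1 = nkmax
                elif nkcc1 < -nkmax:
                    nkcc1 = -nkmax
                # channel currents at the population-mean voltage
                IKleak = P[P_GKL] * (ub - vK[p, x])
                IClleak = P[P_GCLL] * (ub - vCl[p, x])
                INaleak = P[P_GNAL] * (ub - vNa[p, x])
                IKglu = P[P_FRKGLU] * g_glu[p, x] * (ub - vK[p, x])
                INaglu = P[P_FRNAGLU] * g_glu[p, x] * (ub - vNa[p, x])
                if P[P_GABACL] != 0.0:
                    IGABA = g_gaba[p, x] * 0.8 * (ub - vCl[p, x])
                else:
                    IGABA = g_gaba[p, x] * (ub - vGABA[p, x])
                INCX = Ca / (P[P_GAMMA] * P[P_TAUCA]) if p == 0 else 0.0
                dKi[p, x] = P[P_GAMMA] * (-IKleak - ikact[p, x] - IKglu
                                          + 2.0 * Ip + kcc2 + nkcc1) \
                    - OFFS[p, 0]
                dCli[p, x] = P[P_GAMMA] * (IClleak + IGABA + kcc2
                                           + 2.0 * nkcc1) - OFFS[p, 1]
                dNai[p, x] = P[P_GAMMA] * (-INaleak - INaglu
                                           + P[P_QNA] * nu[p, x]
                                           - 3.0 * Ip + nkcc1 + INCX) \
                    - OFFS[p, 2]

        for x in range(nx):
            # intracellular update (floored)
            for p in range(2):
                ki = ION[I_KIE + p, x] + dt * dKi[p, x]
                cli = ION[I_CLIE + p, x] + dt * dCli[p, x]
                nai = ION[I_NAIE + p, x] + dt * dNai[p, x]
                ION[I_KIE + p, x] = ki if ki > 1e-6 else 1e-6
                ION[I_CLIE + p, x] = cli if cli > 1e-6 else 1e-6
                ION[I_NAIE + p, x] = nai if nai > 1e-6 else 1e-6
            # calcium (E cells)
            gn_e = P[P_GN_E] * syn_m[2, x] * xglu[x] \
                * _lerp(TU[0], ubar[0, x], u0, idu, nU)
            ca = ION[I_CA, x] + dt * (-ION[I_CA, x] / P[P_TAUCA]
                                      + P[P_CHI] * gn_e
                                      * (P[P_VCA] - ubar[0, x]))
            ION[I_CA, x] = ca if ca > 0.0 else 0.0
            # glia
            G = 0.0
            if P[P_GLIA] != 0.0:
                k2 = P[P_K1] / (1.0 + np.exp(-(ION[I_KO, x] - 15.0) / 1.15))
                dB = P[P_K1] * (P[P_BMAX] - ION[I_B, x]) - k2 * ION[I_B, x]
                ION[I_B, x] += dt * dB
                G = dB
            # extracellular products
            wE = 1.0 - P[P_ALPHAI]
            wI = P[P_ALPHAI]
            v = ION[I_V, x]
            pK = v * ION[I_KO, x] + dt * (
                -P[P_BETAR] * (wE * dKi[0, x] + wI * dKi[1, x]) + G
                + P[P_DBATH] * (P[P_KBATH] - ION[I_KO, x]) + lap[x])
            pCl = v * ION[I_CLO, x] + dt * (
                -P[P_BETAR] * (wE * dCli[0, x] + wI * dCli[1, x]))
            pNa = v * ION[I_NAO, x] + dt * (
                -P[P_BETAR] * (wE * dNai[0, x] + wI * dNai[1, x]))
            # volume
            if P[P_VOLDYN] != 0.0:
                s_in = (wE * (ION[I_KIE, x] + ION[I_CLIE, x] + ION[I_NAIE, x])
                        + wI * (ION[I_KII, x] + ION[I_CLII, x]
                                + ION[I_NAII, x]))
                s_out = ION[I_KO, x] + ION[I_CLO, x] + ION[I_NAO, x]
                dpi = (s_out - s_in) - P[P_DPI0]
                tgt = 1.0 + P[P_VOLFAC] * (np.exp(dpi / P[P_OSM]) - 1.0)
                if tgt < 0.05:
                    tgt = 0.05
                v = v + (tgt - v) * P[P_FVOL]
                ION[I_V, x] = v
            ko = pK / v
            clo = pCl / v
            nao = pNa / v
            ION[I_KO, x] = ko if ko > 1e-6 else 1e-6
            ION[I_CLO, x] = clo if clo > 1e-6 else 1e-6
            ION[I_NAO, x] = nao if nao > 1e-6 else 1e-6

        # --- 8. observables ----------------------------------------------
        if step % tr_str == 0:
            row = step // tr_str
            if row < trace.shape[0]:
                for si in range(2):
                    x = s1 if si == 0 else s2
                    base = si * 15
                    gA = gA_E_prof[x] * syn_m[0, x] * xglu[x]
                    gN = P[P_GN_E] * syn_m[2, x] * xglu[x]
                    gG = P[P_GG_E] * syn_m[4, x] * xgaba[x]
                    ih = (gG * (P[P_VHOLD] - vGABA[0, x])
                          + gA * P[P_VHOLD]
                          + gN * P[P_FNMDA_HOLD] * P[P_VHOLD])
                    trace[row, base + 0] = ION[I_KO, x]
                    trace[row, base + 1] = ubar[0, x]
                    trace[row, base + 2] = ubar[1, x]
                    trace[row, base + 3] = nu[0, x]
                    trace[row, base + 4] = nu[1, x]
                    trace[row, base + 5] = REP[0 + si, 8]
                    trace[row, base + 6] = REP[2 + si, 8]
                    trace[row, base + 7] = ih
                    trace[row, base + 8] = vGABA[0, x]
                    trace[row, base + 9] = vGABA[1, x]
                    trace[row, base + 10] = ION[I_NAIE, x]
                    trace[row, base + 11] = ION[I_CLIE, x]
                    trace[row, base + 12] = ION[I_CLII, x]
                    trace[row, base + 13] = ION[I_V, x]
                    trace[row, base + 14] = ION[I_CA, x]
                mE = 0.0
                mI = 0.0
                for i in range(nb):
                    mE += rho[0, s1, i]
                    mI += rho[1, s1, i]
                trace[row, 30] = mE
                trace[row, 31] = mI
                trace[row, 32] = xglu[s1]
                trace[row, 33] = xgaba[s1]
        if step % fl_str == 0:
            row = step // fl_str
            if row < fields.shape[0]:
                for x in range(nx):
                    fields[row, 0, x] = ubar[0, x]
                    fields[row, 1, x] = ION[I_KO, x]
                    fields[row, 2, x] = ION[I_CLIE, x]
                    fields[row, 3, x] = ION[I_NAIE, x]
                    fields[row, 4, x] = ION[I_V, x]
    return 0
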