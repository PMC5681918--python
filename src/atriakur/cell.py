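"""Human atrial cardiomyocyte electrophysiology and Ca2+ handling.

ODE system of the Grandi-Pandit-Voigt human atrial cardiomyocyte (nSR and
cAF variants) with the six-state Markov Kv1.5 model of :mod:`.markov`
substituted for the Hodgkin-Huxley I_Kur.  Membrane currents: INa, INaB,
INaK, Ito, IKr, IKs, IK1, IKp, IKur (Markov), IClCa, IClB, ICaL (GHK, with
Ca/K/Na components), INCX, IpCa, ICaB.  Ca2+ handling: junctional cleft,
subsarcolemmal and bulk cytosolic compartments, SR with SERCA uptake, RyR
release (4-state) and passive leak, and the full complement of cytosolic,
sarcolemmal and SR Ca2+ buffers.  [K+]i is held constant, as in the source
formulation.

Integration uses LSODA (stiff) beat-by-beat with the stimulus as a piecewise
constant, rtol 1e-6 and per-state absolute tolerances; recorded output is
resampled at 0.1 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .markov import N_STATES as N_MARKOV
from .markov import NO_DRUG, DrugSpec, _fill_generator, steady_occupancy
from .params import ModelParameters

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "v", "m", "h", "j", "d", "f", "fcabj", "fcabsl", "xtof", "ytof",
    "xkr", "xks", "ryrr", "ryro", "ryri", "nabj", "nabsl",
    "tncl", "tnchc", "tnchm", "cam", "myoc", "myom", "srb",
    "sllj", "sllsl", "slhj", "slhsl", "csqnb",
    "casr", "naj", "nasl", "nai", "ki", "caj", "casl", "cai",
) + tuple(f"mk_{s}" for s in (
    "c1", "c2", "c3", "c4", "o", "i", "od", "id", "c1d", "c2d", "c3d", "c4d"))

N_STATE = len(STATE_NAMES)          # 49
IDX_V = 0
IDX_CAI = STATE_NAMES.index("cai")
MK0 = STATE_NAMES.index("mk_c1")    # first Markov occupancy
IDX_MK_O = MK0 + 4

# fixed physical constants
R_GAS = 8314.0       # J kmol^-1 K^-1
FRDY = 96485.0       # C mol^-1
TEMP = 310.0         # K
FORT = FRDY / R_GAS / TEMP  # mV^-1
KO = 5.4             # mM
E_K_FIXED_KI = 120.0  # mM, for reporting-only E_K


class SimulationError(RuntimeError):
    """Solver failure or invalid state during a protocol."""


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------
@njit(cache=False)
def _rhs(y, t, p, istim):
    """Time derivative of the full state.

    ``p``: [0:18] scalable parameters (see params.PARAM_NAMES),
    [18] RyR koCa (uM^-2 ms^-1), [19:26] Markov binding vector
    (bon_o, boff_o, bon_i, boff_i, bon_c, boff_c, bridged) in ms^-1.
    ``istim``: depolarizing stimulus current (A/F).
    """
    dy = np.zeros(y.shape[0])

    g_na = p[0]
    g_nab = p[1]
    g_to = p[2]
    g_kr = p[3]
    g_ks = p[4]
    g_k1 = p[5]
    g_kp = p[6]
    g_kur = p[7]
    g_clca = p[8]
    g_clb = p[9]
    p_ca = p[10]
    g_cab = p[11]
    ibar_nak = p[12]
    ibar_ncx = p[13]
    ibar_pmca = p[14]
    vmax_serca = p[15]
    ks_ryr = p[16]
    k_sr_leak = p[17]
    ko_ca = p[18]

    v = y[0]
    m, h, jg = y[1], y[2], y[3]
    d, f = y[4], y[5]
    fcabj, fcabsl = y[6], y[7]
    xtof, ytof = y[8], y[9]
    xkr, xks = y[10], y[11]
    ryrr, ryro, ryri = y[12], y[13], y[14]
    nabj, nabsl = y[15], y[16]
    tncl, tnchc, tnchm = y[17], y[18], y[19]
    cam, myoc, myom, srb = y[20], y[21], y[22], y[23]
    sllj, sllsl, slhj, slhsl = y[24], y[25], y[26], y[27]
    csqnb = y[28]
    casr = y[29]
    naj, nasl, nai = y[30], y[31], y[32]
    ki = y[33]
    caj, casl, cai = y[34], y[35], y[36]

    # geometry
    cmem = 1.10e-10           # F
    cell_length = 100.0       # um
    cell_radius = 10.25       # um
    vcell = math.pi * cell_radius ** 2 * cell_length * 1e-15  # L
    vmyo = 0.65 * vcell
    vsr = 0.035 * vcell
    vsl = 0.02 * vcell
    vjunc = 0.0539 * 0.01 * vcell
    j_ca_juncsl = 8.2413e-13  # L/ms
    j_ca_slmyo = 3.7243e-12
    j_na_juncsl = 1.8313e-14
    j_na_slmyo = 1.6386e-12
    fjunc = 0.11
    fsl = 1.0 - fjunc
    fjunc_cal = 0.9
    fsl_cal = 0.1

    nao = 140.0
    cao = 1.8
    cli = 15.0
    clo = 150.0
    mgi = 1.0
    pnak = 0.01833

    # reversal potentials
    ena_junc = (1.0 / FORT) * math.log(nao / naj)
    ena_sl = (1.0 / FORT) * math.log(nao / nasl)
    ek = (1.0 / FORT) * math.log(KO / ki)
    eca_junc = (0.5 / FORT) * math.log(cao / caj)
    eca_sl = (0.5 / FORT) * math.log(cao / casl)
    ecl = (1.0 / FORT) * math.log(cli / clo)

    # ---- fast Na+ current -------------------------------------------------
    mss = 1.0 / (1.0 + math.exp(-(56.86 + v) / 9.03)) ** 2
    taum = (0.1292 * math.exp(-((v + 45.79) / 15.54) ** 2)
            + 0.06487 * math.exp(-((v - 4.823) / 51.12) ** 2))
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = (0.6 * math.exp(0.057 * v)
              / (1.0 + math.exp(-0.1 * (v + 32.0))))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = (2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v))
        aj = ((-2.5428e4 * math.exp(0.2444 * v)
               - 6.948e-6 * math.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = (0.02424 * math.exp(-0.01052 * v)
              / (1.0 + math.exp(-0.1378 * (v + 40.14))))
    hss = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    jss = hss
    dy[1] = (mss - m) / taum
    dy[2] = (hss - h) * (ah + bh)
    dy[3] = (jss - jg) * (aj + bj)

    i_na_junc = fjunc * g_na * m ** 3 * h * jg * (v - ena_junc)
    i_na_sl = fsl * g_na * m ** 3 * h * jg * (v - ena_sl)

    i_nabk_junc = fjunc * g_nab * (v - ena_junc)
    i_nabk_sl = fsl * g_nab * (v - ena_sl)

    # ---- Na+/K+ pump ------------------------------------------------------
    km_naip = 11.0
    km_ko = 1.5
    sigma = (math.exp(nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v * FORT)
                  + 0.0365 * sigma * math.exp(-v * FORT))
    i_nak_junc = (fjunc * ibar_nak * fnak * KO
                  / (1.0 + (km_naip / naj) ** 4) / (KO + km_ko))
    i_nak_sl = (fsl * ibar_nak * fnak * KO
                / (1.0 + (km_naip / nasl) ** 4) / (KO + km_ko))
    i_nak = i_nak_junc + i_nak_sl

    # ---- rapid delayed rectifier -----------------------------------------
    gkr = g_kr * math.sqrt(KO / 5.4)
    xrss = 1.0 / (1.0 + math.exp(-(v + 10.0) / 5.0))
    tauxr = (550.0 / (1.0 + math.exp((-22.0 - v) / 9.0))
             * 6.0 / (1.0 + math.exp((v + 11.0) / 9.0))
             + 230.0 / (1.0 + math.exp((v + 40.0) / 20.0)))
    dy[10] = (xrss - xkr) / tauxr
    rkr = 1.0 / (1.0 + math.exp((v + 74.0) / 24.0))
    i_kr = gkr * xkr * rkr * (v - ek)

    # ---- slow delayed rectifier ------------------------------------------
    eks = (1.0 / FORT) * math.log((KO + pnak * nao) / (ki + pnak * nai))
    xsss = 1.0 / (1.0 + math.exp(-(v + 3.8) / 14.25))
    tauxs = 990.1 / (1.0 + math.exp(-(v + 2.436) / 14.12))
    dy[11] = (xsss - xks) / tauxs
    i_ks = g_ks * xks ** 2 * (v - eks)

    # ---- plateau K+ -------------------------------------------------------
    kp_kp = 1.0 / (1.0 + math.exp(7.488 - v / 5.98))
    i_kp = g_kp * kp_kp * (v - ek)

    # ---- transient outward (fast, atrial) --------------------------------
    xtoss = 1.0 / (1.0 + math.exp(-(v + 1.0) / 11.0))
    tauxtof = 3.5 * math.exp(-((v / 30.0) ** 2)) + 1.5
    ytoss = 1.0 / (1.0 + math.exp((v + 40.5) / 11.5))
    tauytof = 25.635 * math.exp(-(((v + 52.45) / 15.8827) ** 2)) + 24.14
    dy[8] = (xtoss - xtof) / tauxtof
    dy[9] = (ytoss - ytof) / tauytof
    i_to = g_to * xtof * ytof * (v - ek)

    # ---- inward rectifier -------------------------------------------------
    aki = 1.02 / (1.0 + math.exp(0.2385 * (v - ek - 59.215)))
    bki = ((0.49124 * math.exp(0.08032 * (v + 5.476 - ek))
            + math.exp(0.06175 * (v - ek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (v - ek + 4.753))))
    kiss = aki / (aki + bki)
    i_ki = g_k1 * math.sqrt(KO / 5.4) * kiss * (v - ek)

    # ---- Markov Kv1.5 / I_Kur --------------------------------------------
    q = np.zeros((N_MARKOV, N_MARKOV))
    _fill_generator(q, v, p[19], p[20], p[21], p[22], p[23], p[24], p[25])
    occ = y[MK0:MK0 + N_MARKOV]
    docc = q @ occ
    for k in range(N_MARKOV):
        dy[MK0 + k] = docc[k]
    i_kur = g_kur * occ[4] * (v - ek)

    # ---- Ca2+-activated and background Cl- -------------------------------
    kd_clca = 100e-3
    i_clca = (g_clca * (fjunc / (1.0 + kd_clca / caj)
                        + fsl / (1.0 + kd_clca / casl)) * (v - ecl))
    i_clbk = g_clb * (v - ecl)

    # ---- L-type Ca2+ current (GHK) ---------------------------------------
    dss = 1.0 / (1.0 + math.exp(-(v + 9.0) / 6.0))
    vd = v + 9.0
    if abs(vd) < 1e-6:
        vd = 1e-6
    taud = dss * (1.0 - math.exp(-vd / 6.0)) / (0.035 * vd)
    fss = (1.0 / (1.0 + math.exp((v + 30.0) / 7.0))
           + 0.2 / (1.0 + math.exp((50.0 - v) / 20.0)))
    tauf = 1.0 / (0.0197 * math.exp(-(0.0337 * (v + 25.0)) ** 2) + 0.02)
    dy[4] = (dss - d) / taud
    dy[5] = (fss - f) / tauf
    dy[6] = 1.7 * caj * (1.0 - fcabj) - 11.9e-3 * fcabj
    dy[7] = 1.7 * casl * (1.0 - fcabsl) - 11.9e-3 * fcabsl

    vv = v
    if abs(vv) < 1e-6:
        vv = 1e-6
    p_k = p_ca / 2.7e-4 * 1.35e-7   # pK, pNa co-scaled with pCa
    p_na = p_ca / 2.7e-4 * 0.75e-8
    e2v = math.exp(2.0 * vv * FORT)
    e1v = math.exp(vv * FORT)
    ibarca_j = (p_ca * 4.0 * vv * FRDY * FORT
                * (0.341 * caj * e2v - 0.341 * cao) / (e2v - 1.0))
    ibarca_sl = (p_ca * 4.0 * vv * FRDY * FORT
                 * (0.341 * casl * e2v - 0.341 * cao) / (e2v - 1.0))
    ibark = (p_k * vv * FRDY * FORT
             * (0.75 * ki * e1v - 0.75 * KO) / (e1v - 1.0))
    ibarna_j = (p_na * vv * FRDY * FORT
                * (0.75 * naj * e1v - 0.75 * nao) / (e1v - 1.0))
    ibarna_sl = (p_na * vv * FRDY * FORT
                 * (0.75 * nasl * e1v - 0.75 * nao) / (e1v - 1.0))
    df_gate = d * f
    i_ca_junc = fjunc_cal * ibarca_j * df_gate * (1.0 - fcabj) * 0.45
    i_ca_sl = fsl_cal * ibarca_sl * df_gate * (1.0 - fcabsl) * 0.45
    i_cak = (ibark * df_gate
             * (fjunc_cal * (1.0 - fcabj) + fsl_cal * (1.0 - fcabsl)) * 0.45)
    i_cana_junc = fjunc_cal * ibarna_j * df_gate * (1.0 - fcabj) * 0.45
    i_cana_sl = fsl_cal * ibarna_sl * df_gate * (1.0 - fcabsl) * 0.45

    # ---- Na+/Ca2+ exchanger ----------------------------------------------
    km_cai = 3.59e-3
    km_cao = 1.3
    km_nai = 12.29
    km_nao = 87.5
    ksat = 0.27
    nu = 0.35
    kdact = 0.384e-3
    ka_junc = 1.0 / (1.0 + (kdact / caj) ** 2)
    ka_sl = 1.0 / (1.0 + (kdact / casl) ** 2)
    s1_j = math.exp(nu * v * FORT) * naj ** 3 * cao
    s2_j = math.exp((nu - 1.0) * v * FORT) * nao ** 3 * caj
    s3_j = (km_cai * nao ** 3 * (1.0 + (naj / km_nai) ** 3)
            + km_nao ** 3 * caj * (1.0 + caj / km_cai)
            + km_cao * naj ** 3 + naj ** 3 * cao + nao ** 3 * caj)
    s1_sl = math.exp(nu * v * FORT) * nasl ** 3 * cao
    s2_sl = math.exp((nu - 1.0) * v * FORT) * nao ** 3 * casl
    s3_sl = (km_cai * nao ** 3 * (1.0 + (nasl / km_nai) ** 3)
             + km_nao ** 3 * casl * (1.0 + casl / km_cai)
             + km_cao * nasl ** 3 + nasl ** 3 * cao + nao ** 3 * casl)
    denom_j = 1.0 + ksat * math.exp((nu - 1.0) * v * FORT)
    i_ncx_junc = fjunc * ibar_ncx * ka_junc * (s1_j - s2_j) / s3_j / denom_j
    i_ncx_sl = fsl * ibar_ncx * ka_sl * (s1_sl - s2_sl) / s3_sl / denom_j

    # ---- sarcolemmal Ca2+ pump and background Ca2+ -----------------------
    km_pca = 0.5e-3
    caj16 = caj ** 1.6
    casl16 = casl ** 1.6
    i_pca_junc = fjunc * ibar_pmca * caj16 / (km_pca ** 1.6 + caj16)
    i_pca_sl = fsl * ibar_pmca * casl16 / (km_pca ** 1.6 + casl16)
    i_cabk_junc = fjunc * g_cab * (v - eca_junc)
    i_cabk_sl = fsl * g_cab * (v - eca_sl)

    # ---- SR fluxes --------------------------------------------------------
    kmf = 6.15e-4   # atrial: 2.5x the ventricular forward affinity
    kmr = 1.7
    hill = 1.787
    max_sr = 15.0
    min_sr = 1.0
    ec50_sr = 0.45
    kom = 0.06
    ki_ca = 0.5
    kim = 0.005
    k_ca_sr = max_sr - (max_sr - min_sr) / (1.0 + (ec50_sr / casr) ** 2.5)
    ko_sr_ca = ko_ca / k_ca_sr
    ki_sr_ca = ki_ca * k_ca_sr
    ri = 1.0 - ryrr - ryro - ryri
    dy[12] = (kim * ri - ki_sr_ca * caj * ryrr
              - (ko_sr_ca * caj ** 2 * ryrr - kom * ryro))
    dy[13] = (ko_sr_ca * caj ** 2 * ryrr - kom * ryro
              - (ki_sr_ca * caj * ryro - kim * ryri))
    dy[14] = (ki_sr_ca * caj * ryro - kim * ryri
              - (kom * ryri - ko_sr_ca * caj ** 2 * ri))
    j_sr_rel = ks_ryr * ryro * (casr - caj)
    cf = (cai / kmf) ** hill
    cr = (casr / kmr) ** hill
    j_serca = vmax_serca * (cf - cr) / (1.0 + cf + cr)
    j_sr_leak = k_sr_leak * (casr - caj)

    # ---- buffering --------------------------------------------------------
    # Na+
    dy[15] = 0.1e-3 * naj * (7.561 - nabj) - 1e-3 * nabj
    dy[16] = 0.1e-3 * nasl * (1.65 - nabsl) - 1e-3 * nabsl
    # cytosolic Ca2+
    dy[17] = 32.7 * cai * (70e-3 - tncl) - 19.6e-3 * tncl
    dy[18] = 2.37 * cai * (140e-3 - tnchc - tnchm) - 0.032e-3 * tnchc
    dy[19] = 3e-3 * mgi * (140e-3 - tnchc - tnchm) - 3.33e-3 * tnchm
    dy[20] = 34.0 * cai * (24e-3 - cam) - 238e-3 * cam
    dy[21] = 13.8 * cai * (140e-3 - myoc - myom) - 0.46e-3 * myoc
    dy[22] = 0.0157 * mgi * (140e-3 - myoc - myom) - 0.057e-3 * myom
    dy[23] = 100.0 * cai * (19.0 * 0.9e-3 - srb) - 60e-3 * srb
    j_cab_cytosol = (dy[17] + dy[18] + dy[19] + dy[20] + dy[21] + dy[22]
                     + dy[23])
    # junctional and SL Ca2+
    bmax_sllj = 4.6e-3 * vmyo / vjunc * 0.1
    bmax_sllsl = 37.4e-3 * vmyo / vsl
    bmax_slhj = 1.65e-3 * vmyo / vjunc * 0.1
    bmax_slhsl = 13.4e-3 * vmyo / vsl
    dy[24] = 100.0 * caj * (bmax_sllj - sllj) - 1300e-3 * sllj
    dy[25] = 100.0 * casl * (bmax_sllsl - sllsl) - 1300e-3 * sllsl
    dy[26] = 100.0 * caj * (bmax_slhj - slhj) - 30e-3 * slhj
    dy[27] = 100.0 * casl * (bmax_slhsl - slhsl) - 30e-3 * slhsl
    j_cab_junc = dy[24] + dy[26]
    j_cab_sl = dy[25] + dy[27]
    # SR Ca2+ (calsequestrin)
    bmax_csqn = 140e-3 * vmyo / vsr
    dy[28] = 100.0 * casr * (bmax_csqn - csqnb) - 65.0 * csqnb

    # ---- ionic balances ---------------------------------------------------
    i_na_tot_junc = (i_na_junc + i_nabk_junc + 3.0 * i_ncx_junc
                     + 3.0 * i_nak_junc + i_cana_junc)
    i_na_tot_sl = (i_na_sl + i_nabk_sl + 3.0 * i_ncx_sl
                   + 3.0 * i_nak_sl + i_cana_sl)
    dy[30] = (-i_na_tot_junc * cmem / (vjunc * FRDY)
              + j_na_juncsl / vjunc * (nasl - naj) - dy[15])
    dy[31] = (-i_na_tot_sl * cmem / (vsl * FRDY)
              + j_na_juncsl / vsl * (naj - nasl)
              + j_na_slmyo / vsl * (nai - nasl) - dy[16])
    dy[32] = j_na_slmyo / vmyo * (nasl - nai)

    dy[33] = 0.0  # [K+]i clamped

    i_ca_tot_junc = (i_ca_junc + i_cabk_junc + i_pca_junc
                     - 2.0 * i_ncx_junc)
    i_ca_tot_sl = i_ca_sl + i_cabk_sl + i_pca_sl - 2.0 * i_ncx_sl
    dy[29] = (j_serca - (j_sr_leak * vmyo / vsr + j_sr_rel) - dy[28])
    dy[34] = (-i_ca_tot_junc * cmem / (vjunc * 2.0 * FRDY)
              + j_ca_juncsl / vjunc * (casl - caj) - j_cab_junc
              + j_sr_rel * vsr / vjunc + j_sr_leak * vmyo / vjunc)
    dy[35] = (-i_ca_tot_sl * cmem / (vsl * 2.0 * FRDY)
              + j_ca_juncsl / vsl * (caj - casl)
              + j_ca_slmyo / vsl * (cai - casl) - j_cab_sl)
    dy[36] = (-j_serca * vsr / vmyo - j_cab_cytosol
              + j_ca_slmyo / vmyo * (casl - cai))

    # ---- membrane potential ----------------------------------------------
    i_na_tot = i_na_tot_junc + i_na_tot_sl
    i_cl_tot = i_clca + i_clbk
    i_ca_tot = i_ca_tot_junc + i_ca_tot_sl
    i_k_tot = (i_to + i_kr + i_ks + i_ki - 2.0 * i_nak + i_cak + i_kp
               + i_kur)
    dy[0] = -(i_na_tot + i_cl_tot + i_ca_tot + i_k_tot) + istim
    return dy


@njit(cache=False)
def _ikur_of(y, g_kur):
    v = y[0]
    ki = y[33]
    ek = (1.0 / FORT) * math.log(KO / ki)
    return g_kur * y[IDX_MK_O] * (v - ek)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class CellState:
    """Full ODE state with invariant checks."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_STATE,):
            raise ValueError(f"state must have length {N_STATE}")

    @property
    def v(self) -> float:
        return float(self.y[IDX_V])

    @property
    def cai(self) -> float:
        return float(self.y[IDX_CAI])

    @property
    def occupancies(self) -> np.ndarray:
        return self.y[MK0:MK0 + N_MARKOV]

    def validate(self):
        if not np.all(np.isfinite(self.y)):
            raise SimulationError(f"non-finite state: {self.y!r}")
        occ = self.occupancies
        if abs(occ.sum() - 1.0) > 1e-6 or np.any(occ < -1e-9):
            raise SimulationError(
                f"Markov occupancies invalid (sum={occ.sum()!r})")
        conc = self.y[29:37]
        if np.any(conc <= 0):
            raise SimulationError("non-positive ion concentration")


@dataclass
class Trace:
    """Uniformly sampled simulation output (final recorded beats)."""

    t: np.ndarray            # ms, strictly increasing
    v: np.ndarray            # mV
    cai: np.ndarray          # mM
    i_kur: np.ndarray        # A/F
    occupancies: np.ndarray  # (n, 12)
    beat_bounds: np.ndarray = field(default_factory=lambda: np.array([0]))
    stim_times: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    final_state: np.ndarray | None = None

    @property
    def cai_nm(self) -> np.ndarray:
        return self.cai * 1e6

    def to_frame(self):
        import pandas as pd
        cols = {"time_ms": self.t, "v_mv": self.v, "cai_mm": self.cai,
                "i_kur": self.i_kur}
        from .markov import STATE_NAMES as MK_NAMES
        for k, name in enumerate(MK_NAMES):
            cols[f"occ_{name}"] = self.occupancies[:, k]
        return pd.DataFrame(cols)


# default initial conditions (near the 1-Hz nSR diastolic state)
_Y0 = np.zeros(N_STATE)
_Y0[0] = -80.0
_Y0[1:4] = (1.4e-3, 0.976, 0.983)          # m h j
_Y0[4:6] = (7e-6, 1.0)                     # d f
_Y0[6:8] = (0.025, 0.015)                  # fcaB
_Y0[8:10] = (4e-3, 0.94)                   # Ito gates
_Y0[10:12] = (0.02, 8e-3)                  # xkr xks
_Y0[12:15] = (0.89, 8e-7, 1e-7)            # RyR
_Y0[15:17] = (3.54, 0.77)                  # Na buffers
_Y0[17:24] = (8.9e-3, 0.117, 0.011, 3e-4, 1.9e-3, 0.135, 2.1e-3)
_Y0[24:28] = (7e-3, 9e-3, 7e-2, 0.11)
_Y0[28] = 1.25                             # Csqn
_Y0[29] = 0.55                             # Ca_sr
_Y0[30:33] = (9.14, 9.14, 9.14)            # Na
_Y0[33] = 120.0                            # Ki
_Y0[34:37] = (1.7e-4, 1.1e-4, 9e-5)        # Ca

_ATOL = np.full(N_STATE, 1e-8)
_ATOL[0] = 1e-4
_ATOL[29:34] = 1e-6
_ATOL[34:37] = 1e-10


def initial_state(drug: DrugSpec = NO_DRUG, v0: float = -80.0) -> np.ndarray:
    """Default initial state with Markov occupancies at their stationary
    distribution for the scheme at ``v0``."""
    y = _Y0.copy()
    y[0] = v0
    # drug-free stationary occupancy with zero bound mass: the drug is
    # applied to an equilibrated cell and binds during the simulation
    occ = np.zeros(N_MARKOV)
    from .markov import DRUG_FREE
    occ[:6] = steady_occupancy(DRUG_FREE, v0)
    y[MK0:MK0 + N_MARKOV] = occ
    return y


def _param_vector(params: ModelParameters, drug: DrugSpec) -> np.ndarray:
    p = np.zeros(26)
    p[:18] = params.values
    p[18] = params.ryr_ko_ca
    p[19:26] = drug.scheme.binding_vector(drug.concentration)
    return p


def derivatives(state, params: ModelParameters, stimulus_current: float = 0.0,
                drug: DrugSpec = NO_DRUG) -> np.ndarray:
    """d(state)/dt at one instant (A/F stimulus, depolarizing positive)."""
    y = state.y if isinstance(state, CellState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state passed to derivatives: {y!r}")
    return _rhs(y, 0.0, _param_vector(params, drug), stimulus_current)


class CellSim:
    """Low-level stepping interface used by all protocols."""

    def __init__(self, params: ModelParameters, drug: DrugSpec = NO_DRUG,
                 y0: np.ndarray | None = None, rtol: float = 1e-6):
        self.params = params
        self.drug = drug
        self.p = _param_vector(params, drug)
        self.y = initial_state(drug).copy() if y0 is None else y0.copy()
        self.t = 0.0
        self.rtol = rtol

    def copy(self) -> "CellSim":
        sim = CellSim(self.params, self.drug, y0=self.y, rtol=self.rtol)
        sim.t = self.t
        return sim

    def _integrate(self, duration: float, istim: float,
                   tgrid: np.ndarray | None = None) -> np.ndarray:
        if tgrid is None:
            tgrid = np.array([0.0, duration])
        out = odeint(_rhs, self.y, tgrid, args=(self.p, istim),
                     rtol=self.rtol, atol=_ATOL, mxstep=200000,
                     tfirst=False)
        self.y = out[-1].copy()
        self.t += duration
        return out

    def step(self, duration: float, istim: float = 0.0):
        """Advance without recording."""
        self._integrate(duration, istim)

    def step_record(self, duration: float, istim: float = 0.0,
                    dt: float = 0.1):
        """Advance, returning (t_local, states) sampled every ``dt`` ms."""
        n = max(int(round(duration / dt)), 1)
        tgrid = np.linspace(0.0, duration, n + 1)
        out = self._integrate(duration, istim, tgrid)
        return tgrid, out

    def stim_beat(self, cl: float, record: bool = False, dt: float = 0.1,
                  amplitude: float | None = None,
                  duration: float | None = None):
        """One stimulated beat: 5-ms pulse then diastole, total ``cl`` ms."""
        amp = self.params.stim_amplitude if amplitude is None else amplitude
        dur = self.params.stim_duration if duration is None else duration
        if record:
            t1, y1 = self.step_record(dur, istim=amp, dt=dt)
            t2, y2 = self.step_record(cl - dur, istim=0.0, dt=dt)
            t = np.concatenate([t1, t2[1:] + dur])
            y = np.concatenate([y1, y2[1:]], axis=0)
            return t, y
        self.step(dur, istim=amp)
        self.step(cl - dur, istim=0.0)
        return None

    def check(self, beat: int):
        if not np.all(np.isfinite(self.y)):
            raise SimulationError(
                f"solver failure at beat {beat}: non-finite state "
                f"(|y|={np.abs(self.y[np.isfinite(self.y)]).max():.3g})")


def run_paced(params: ModelParameters, drug: DrugSpec = NO_DRUG,
              rate_hz: float = 1.0, n_beats: int = 300,
              record_beats: int = 1, dt: float = 0.1,
              rtol: float = 1e-6, y0: np.ndarray | None = None,
              stim_amplitude: float | None = None) -> Trace:
    """Regular pacing: ``n_beats`` beats at ``rate_hz``, recording the final
    ``record_beats`` at ``dt`` ms resolution.

    Default beat counts follow the fixed equilibration convention: 300 beats
    at 1 Hz, 900 at 3 Hz.
    """
    cl = 1000.0 / rate_hz
    sim = CellSim(params, drug, y0=y0, rtol=rtol)
    record_beats = min(record_beats, n_beats)
    t_parts, y_parts, bounds, stim_times = [], [], [], []
    t_acc = 0.0
    for beat in range(n_beats):
        rec = beat >= n_beats - record_beats
        if rec:
            bounds.append(sum(len(tp) for tp in t_parts))
            stim_times.append(t_acc)
            t, y = sim.stim_beat(cl, record=True, dt=dt,
                                 amplitude=stim_amplitude)
            if t_parts:
                t, y = t[1:], y[1:]
            t_parts.append(t + t_acc)
            y_parts.append(y)
        else:
            sim.stim_beat(cl, amplitude=stim_amplitude)
        t_acc += cl
        if beat % 25 == 0 or rec:
            sim.check(beat)
    t = np.concatenate(t_parts)
    y = np.concatenate(y_parts, axis=0)
    g_kur = params["g_kur"]
    ek = (1.0 / FORT) * np.log(KO / y[:, 33])
    i_kur = g_kur * y[:, IDX_MK_O] * (y[:, 0] - ek)
    return Trace(t=t, v=y[:, 0], cai=y[:, IDX_CAI], i_kur=i_kur,
                 occupancies=y[:, MK0:MK0 + N_MARKOV],
                 beat_bounds=np.asarray(bounds),
                 stim_times=np.asarray(stim_times),
                 final_state=sim.y.copy())


def equilibrated_state(params: ModelParameters, drug: DrugSpec = NO_DRUG,
                       rate_hz: float = 1.0, n_beats: int = 300,
                       rtol: float = 1e-6,
                       y0: np.ndarray | None = None) -> np.ndarray:
    """State vector after ``n_beats`` of regular pacing (no recording)."""
    cl = 1000.0 / rate_hz
    sim = CellSim(params, drug, y0=y0, rtol=rtol)
    for beat in range(n_beats):
        sim.stim_beat(cl)
        if beat % 25 == 0:
            sim.check(beat)
    sim.check(n_beats - 1)
    return sim.y.copy()


def default_beats(rate_hz: float) -> int:
    """Fixed equilibration beat counts: 300 at 1 Hz, 900 at 3 Hz; other
    rates scale to 300 s of pacing."""
    if abs(rate_hz - 1.0) < 1e-9:
        return 300
    if abs(rate_hz - 3.0) < 1e-9:
        return 900
    return max(int(round(300.0 * rate_hz)), 1)
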