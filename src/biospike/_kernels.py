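"""Numba-compiled numerical kernels.

Everything here operates on plain float64 arrays; the public modules own the
typed containers and unpack them into the packed layouts below.

Sensor parameter vector ``sp`` (length 10)::

    0 koff_ca_N   1 Ka_N   2 H_N   3 kon_pep_N   4 koff_pep_N
    5 koff_ca_C   6 Ka_C   7 H_C   8 kon_pep_C   9 koff_pep_C

Cell parameter vector ``cp`` (length 14)::

    0 g_total  1 a_ca     2 kappa_b  3 pump_vmax  4 pump_km
    5 store_in_vmax  6 store_in_km  7 store_out_vmax  8 store_out_km
    9 slow_frac  10 slow_k  11 ca_basal  12 leak  13 n_ca_per_lobe

Cell state vector ``x`` (length 12)::

    0 ca_free  1 ca_slow  2 ca_store  3..11 sensor occupancy P (row-major,
    row = N-lobe state, col = C-lobe state; per-lobe states 0 apo,
    1 Ca-bound, 2 Ca+peptide).
"""

import numpy as np
from numba import njit

# cp indices
GT, ACA, KB, PV, PK, SIV, SIK, SOV, SOK, SF, SK, CAB, LEAK, NCA = range(14)


@njit(cache=True)
def lobe_on_rate(koff_ca, Ka, H, ca):
    if ca <= 0.0:
        return 0.0
    return koff_ca * (ca / Ka) ** H


@njit(cache=True)
def lobe_generator(kon, koff_ca, kon_pep, koff_pep):
    """3x3 column-generator of one lobe's apo <-> Ca <-> Ca+pep chain."""
    G = np.zeros((3, 3))
    G[0, 0] = -kon
    G[0, 1] = koff_ca
    G[1, 0] = kon
    G[1, 1] = -(koff_ca + kon_pep)
    G[1, 2] = koff_pep
    G[2, 1] = kon_pep
    G[2, 2] = -koff_pep
    return G


@njit(cache=True)
def expm3(G, h):
    """exp(G*h) for a 3x3 matrix via scaling-and-squaring Taylor."""
    nrm = 0.0
    for i in range(3):
        s = 0.0
        for j in range(3):
            s += abs(G[i, j]) * h
        if s > nrm:
            nrm = s
    n_sq = 0
    while nrm > 0.125:
        nrm *= 0.5
        n_sq += 1
    A = G * (h / 2.0 ** n_sq)
    E = np.eye(3)
    term = np.eye(3)
    for k in range(1, 13):
        term = (term @ A) / k
        E = E + term
    for _ in range(n_sq):
        E = E @ E
    return E


@njit(cache=True)
def lobe_propagators(sp, ca, h):
    konN = lobe_on_rate(sp[0], sp[1], sp[2], ca)
    konC = lobe_on_rate(sp[5], sp[6], sp[7], ca)
    AN = expm3(lobe_generator(konN, sp[0], sp[3], sp[4]), h)
    AC = expm3(lobe_generator(konC, sp[5], sp[8], sp[9]), h)
    return AN, AC


@njit(cache=True, inline="always")
def bound_lobes(P):
    """Mean number of calcium-bound lobe events per sensor."""
    b = 0.0
    for j in range(3):
        b += P[1, j] + P[2, j]          # N lobe bound (states 1, 2)
        b += P[j, 1] + P[j, 2]          # C lobe bound
    return b


@njit(cache=True, inline="always")
def fluorescent_frac(P):
    """Occupancy of states with at least one lobe in Ca+peptide."""
    return P[2, 0] + P[2, 1] + P[2, 2] + P[0, 2] + P[1, 2]


@njit(cache=True, inline="always")
def _scalar_rates(ca, ca_slow, ca_store, cp):
    pump = cp[PV] * ca / (cp[PK] + ca)
    si = cp[SIV] * ca / (cp[SIK] + ca)
    so = cp[SOV] * ca_store / (cp[SOK] + ca_store)
    jslow = cp[SK] * (ca - ca_slow)
    r = cp[SF] / (1.0 - cp[SF])
    beta = 1.0 + cp[KB]
    dca = (-pump + cp[LEAK] - si + so - r * jslow) / beta
    return dca, jslow, si - so


@njit(cache=True)
def cell_substep(x, h, sp, cp):
    """One split step: sensor master equation at frozen ca, then scalar ODE.

    Returns 1 if a negative concentration had to be clipped.
    """
    clipped = 0
    ca = x[0]
    AN, AC = lobe_propagators(sp, ca, h)
    P = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            P[i, j] = x[3 + 3 * i + j]
    b0 = bound_lobes(P)
    P2 = AN @ P @ AC.T
    b1 = bound_lobes(P2)
    beta = 1.0 + cp[KB]
    ca = ca - cp[GT] * cp[NCA] * (b1 - b0) / beta
    if ca < 0.0:
        ca = 0.0
        clipped = 1
    d1 = _scalar_rates(ca, x[1], x[2], cp)
    cam = ca + 0.5 * h * d1[0]
    if cam < 0.0:
        cam = 0.0
    d2 = _scalar_rates(cam, x[1] + 0.5 * h * d1[1], x[2] + 0.5 * h * d1[2], cp)
    ca = ca + h * d2[0]
    x[1] = x[1] + h * d2[1]
    x[2] = x[2] + h * d2[2]
    if ca < 0.0:
        ca = 0.0
        clipped = 1
    if x[2] < 0.0:
        x[2] = 0.0
        clipped = 1
    x[0] = ca
    for i in range(3):
        for j in range(3):
            x[3 + 3 * i + j] = P2[i, j]
    return clipped


@njit(cache=True)
def simulate_core(x0, spike_sub, n_samples, n_sub, h, sp, cp,
                  phi0, phisat, Rf, Fbasal):
    """Deterministic bouton simulation sampled every ``n_sub`` substeps.

    ``spike_sub`` holds substep indices (sorted) at which a_ca is injected.
    Sample i reports the state at t = i * n_sub * h, before any spike whose
    snapped index equals that substep.
    """
    dff = np.empty(n_samples)
    lat = np.empty((n_samples, 12))
    x = x0.copy()
    k = 0
    isub = 0
    clipped = 0
    for i in range(n_samples):
        phi = x[3 + 3 * 2 + 0] + x[3 + 3 * 2 + 1] + x[3 + 3 * 2 + 2] \
            + x[3 + 2] + x[3 + 3 + 2]
        F = 1.0 + (Rf - 1.0) * (phi - phi0) / (phisat - phi0)
        dff[i] = (F - Fbasal) / Fbasal
        for j in range(12):
            lat[i, j] = x[j]
        for _ in range(n_sub):
            while k < spike_sub.size and spike_sub[k] == isub:
                x[0] += cp[ACA] / (1.0 + cp[KB])
                k += 1
            clipped += cell_substep(x, h, sp, cp)
            isub += 1
    return dff, lat, clipped


@njit(cache=True)
def propagate_core(P0, ca_traj, dt, h_max, sp):
    """Master-equation propagation of the sensor alone along a clamped
    calcium trajectory (piecewise constant per sample interval)."""
    n = ca_traj.size
    out = np.empty((n, 3, 3))
    P = P0.copy()
    for i in range(3):
        for j in range(3):
            out[0, i, j] = P[i, j]
    for t in range(1, n):
        ca = ca_traj[t - 1]
        n_sub = int(np.ceil(dt / h_max))
        h = dt / n_sub
        AN, AC = lobe_propagators(sp, ca, h)
        for _ in range(n_sub):
            P = AN @ P @ AC.T
        for i in range(3):
            for j in range(3):
                out[t, i, j] = P[i, j]
    return out


# ---------------------------------------------------------------------------
# SMC kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _interp_AB(ca, log_ca0, dlog, tab, out):
    """Linear interpolation of a tabulated 3x3 propagator in log-ca."""
    lc = np.log(ca) if ca > 1e-12 else np.log(1e-12)
    f = (lc - log_ca0) / dlog
    n = tab.shape[0]
    if f <= 0.0:
        i0, w = 0, 0.0
    elif f >= n - 1:
        i0, w = n - 2, 1.0
    else:
        i0 = int(f)
        w = f - i0
    for i in range(3):
        for j in range(3):
            out[i, j] = (1.0 - w) * tab[i0, i, j] + w * tab[i0 + 1, i, j]


@njit(cache=True, inline="always")
def _advance_bio(ca_mid, afree, inject_at, csl, cst, P, h, nsub, cp,
                 log_ca0, dlog, AN_tab, AC_tab, AN, AC, Pn, Ptmp):
    """Within-bin advance used inside SMC (tabulated propagator + RK2).

    ``nsub`` substeps of length ``h``; the propagator table must be built
    for step ``h``.  The input occupancy ``P`` is left untouched; the
    result lands in ``Pn``.  A spike's free-calcium increment ``afree``
    is injected at the start of substep ``inject_at`` — the bin midpoint
    by convention, since true spike times are uniform within a bin —
    and the substeps resolve the fast post-spike relaxation.
    """
    ca = ca_mid
    beta = 1.0 + cp[KB]
    src = P
    for k in range(nsub):
        if k == inject_at:
            ca = ca + afree
        _interp_AB(ca, log_ca0, dlog, AN_tab, AN)
        _interp_AB(ca, log_ca0, dlog, AC_tab, AC)
        b0 = bound_lobes(src)
        for a in range(3):
            for b in range(3):
                s = 0.0
                for c in range(3):
                    for d in range(3):
                        s += AN[a, c] * src[c, d] * AC[b, d]
                Pn[a, b] = s
        b1 = bound_lobes(Pn)
        ca = ca - cp[GT] * cp[NCA] * (b1 - b0) / beta
        if ca < 0.0:
            ca = 0.0
        d1 = _scalar_rates(ca, csl, cst, cp)
        cam = ca + 0.5 * h * d1[0]
        if cam < 0.0:
            cam = 0.0
        d2 = _scalar_rates(cam, csl + 0.5 * h * d1[1],
                           cst + 0.5 * h * d1[2], cp)
        ca = max(ca + h * d2[0], 0.0)
        csl = csl + h * d2[1]
        cst = max(cst + h * d2[2], 0.0)
        if k < nsub - 1:
            for i in range(3):
                for j in range(3):
                    Ptmp[i, j] = Pn[i, j]
            src = Ptmp
    return ca, csl, cst


@njit(cache=True, inline="always")
def _dff_from_phi(phi, phi0, phisat, Rf, Fbasal):
    F = 1.0 + (Rf - 1.0) * (phi - phi0) / (phisat - phi0)
    return (F - Fbasal) / Fbasal


@njit(cache=True)
def path_predict_bio(s, xi, cp, n_spike_sub, dt, sig_ca,
                     log_ca0, dlog, AN_tab, AC_tab, ANs_tab, ACs_tab,
                     x_init, phi0, phisat, Rf, Fbasal):
    """Deterministic ΔF/F prediction for a stored innovation path.

    Spike bins are advanced in ``n_spike_sub`` substeps with the matching
    fine propagator table; quiet bins in a single step.
    """
    n = s.size
    pred = np.empty(n)
    ca = x_init[0]
    csl = x_init[1]
    cst = x_init[2]
    P = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            P[i, j] = x_init[3 + 3 * i + j]
    AN = np.empty((3, 3))
    AC = np.empty((3, 3))
    Pn = np.empty((3, 3))
    Ptmp = np.empty((3, 3))
    afree = cp[ACA] / (1.0 + cp[KB])
    for t in range(n):
        ca_noisy = ca + sig_ca * xi[t]
        if ca_noisy < 0.0:
            ca_noisy = -ca_noisy
        if s[t] == 1:
            ca, csl, cst = _advance_bio(
                ca_noisy, afree, n_spike_sub // 2, csl, cst, P,
                dt / n_spike_sub, n_spike_sub, cp, log_ca0, dlog,
                ANs_tab, ACs_tab, AN, AC, Pn, Ptmp)
        else:
            ca, csl, cst = _advance_bio(
                ca_noisy, 0.0, -1, csl, cst, P, dt, 1, cp, log_ca0,
                dlog, AN_tab, AC_tab, AN, AC, Pn, Ptmp)
        for i in range(3):
            for j in range(3):
                P[i, j] = Pn[i, j]
        pred[t] = _dff_from_phi(fluorescent_frac(P), phi0, phisat, Rf, Fbasal)
    return pred


@njit(cache=True)
def _systematic(w, u, out):
    """Systematic resampling: fill ``out`` with len(out) ancestor indices."""
    n = out.size
    m = w.size
    c = w[0]
    i = 0
    for k in range(n):
        p = (k + u) / n
        while p > c and i < m - 1:
            i += 1
            c += w[i]
        out[k] = i


@njit(cache=True)
def _categorical(logw, u):
    m = logw[0]
    for i in range(logw.size):
        if logw[i] > m:
            m = logw[i]
    tot = 0.0
    for i in range(logw.size):
        tot += np.exp(logw[i] - m)
    target = u * tot
    c = 0.0
    for i in range(logw.size):
        c += np.exp(logw[i] - m)
        if c >= target:
            return i
    return logw.size - 1


@njit(cache=True)
def backtrack(anc_out, s_out, xi_out, zb_out, path):
    n = anc_out.shape[0]
    s = np.empty(n, s_out.dtype)
    xi = np.empty(n, xi_out.dtype)
    zb = np.empty(n, zb_out.dtype)
    idx = path
    for t in range(n - 1, -1, -1):
        s[t] = s_out[t, idx]
        xi[t] = xi_out[t, idx]
        zb[t] = zb_out[t, idx]
        idx = anc_out[t, idx]
    return s, xi, zb


# --- linear AR(2) generative model -----------------------------------------

@njit(cache=True)
def path_predict_lin(s, xi, g1, g2, amp, sig_c):
    n = s.size
    pred = np.empty(n)
    c1 = 0.0
    c2 = 0.0
    for t in range(n):
        c = g1 * c1 + g2 * c2 + amp * s[t] + sig_c * xi[t]
        pred[t] = c
        c2 = c1
        c1 = c
    return pred




@njit(cache=True, inline="always")
def _ess(logW, w):
    """Normalize accumulated log-weights into w; return effective size."""
    npart = logW.size
    m = logW[0]
    for p in range(npart):
        if logW[p] > m:
            m = logW[p]
    tot = 0.0
    for p in range(npart):
        w[p] = np.exp(logW[p] - m)
        tot += w[p]
    s2 = 0.0
    for p in range(npart):
        w[p] /= tot
        s2 += w[p] * w[p]
    return 1.0 / s2


@njit(cache=True)
def pgas_sweep_bio(y, dt, cp, sigma, p_spike, refr_bins, sig_b, a_b,
                   sig_ca, log_ca0, dlog, AN_tab, AC_tab,
                   ANs_tab, ACs_tab, n_spike_sub,
                   x_init, phi0, phisat, Rf, Fbasal,
                   ref_s, ref_xi, ref_zb, has_ref,
                   u_spike, z_ca, z_b, u_res, u_anc, u_final,
                   s_out, xi_out, zb_out, anc_out):
    """Conditional-SMC sweep with locally optimal spike proposals.

    Per bin and particle the spike indicator is proposed from its one-step
    conditional posterior (prior times current-bin likelihood of the
    advanced state, with and without the spike) and the particle is
    weighted by the predictive marginal; resampling is ESS-adaptive
    (threshold npart/2).  Particle 0 carries the reference path when
    ``has_ref``; its ancestor is drawn from ancestor-sampling weights
    built from the stochastic-innovation densities.  Returns (status, bin,
    path): status != 0 flags weight degeneracy at ``bin``; ``path`` is the
    particle index sampled at the final bin.
    """
    n = y.size
    npart = u_spike.shape[1]
    ca = np.full(npart, x_init[0])
    csl = np.full(npart, x_init[1])
    cst = np.full(npart, x_init[2])
    b = np.zeros(npart)
    P = np.empty((npart, 3, 3))
    for p in range(npart):
        for i in range(3):
            for j in range(3):
                P[p, i, j] = x_init[3 + 3 * i + j]
    logW = np.zeros(npart)
    w = np.full(npart, 1.0 / npart)
    anc = np.empty(npart, np.int64)
    last_s = np.full(npart, -2 * refr_bins - 10, np.int64)
    last_s_s = np.empty(npart, np.int64)
    ref_last = -2 * refr_bins - 10
    AN = np.empty((3, 3))
    AC = np.empty((3, 3))
    P0s = np.empty((3, 3))
    P1s = np.empty((3, 3))
    Ptmp = np.empty((3, 3))
    ca_s = np.empty(npart)
    csl_s = np.empty(npart)
    cst_s = np.empty(npart)
    b_s = np.empty(npart)
    P_s = np.empty((npart, 3, 3))
    logas = np.empty(npart)
    afree = cp[ACA] / (1.0 + cp[KB])
    ref_ca = x_init[0]
    ref_csl = x_init[1]
    ref_cst = x_init[2]
    ref_b = 0.0
    refP = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            refP[i, j] = x_init[3 + 3 * i + j]
    log_p1 = np.log(p_spike)
    log_p0 = np.log(1.0 - p_spike)

    for t in range(n):
        resampled = False
        if t > 0:
            ess = _ess(logW, w)
            if not np.isfinite(ess):
                return 1, t, 0
            if ess < 0.5 * npart:
                _systematic(w, u_res[t], anc)
                resampled = True
            else:
                for p in range(npart):
                    anc[p] = p
            if has_ref:
                ref_b_next = a_b * ref_b + sig_b * ref_zb[t]
                ca_noisy_ref = ref_ca + sig_ca * ref_xi[t]
                if ca_noisy_ref < 0.0:
                    ca_noisy_ref = -ca_noisy_ref
                for p in range(npart):
                    db = ref_b_next - a_b * b[p]
                    dca = ca_noisy_ref - ca[p]
                    logas[p] = logW[p] \
                        - 0.5 * (db / sig_b) ** 2 \
                        - 0.5 * (dca / sig_ca) ** 2
                    if ref_s[t] == 1 and t - last_s[p] < refr_bins:
                        logas[p] = -np.inf
                anc[0] = _categorical(logas, u_anc[t])
        else:
            for p in range(npart):
                anc[p] = p
        # gather parent states (and parent weights if no resampling)
        for p in range(npart):
            a = anc[p]
            ca_s[p] = ca[a]
            csl_s[p] = csl[a]
            cst_s[p] = cst[a]
            b_s[p] = b[a]
            last_s_s[p] = last_s[a]
            for i in range(3):
                for j in range(3):
                    P_s[p, i, j] = P[a, i, j]
        if resampled:
            base = np.zeros(npart)
        else:
            base = np.empty(npart)
            for p in range(npart):
                base[p] = logW[anc[p]]
        for p in range(npart):
            is_ref = has_ref and p == 0
            if is_ref:
                xi = ref_xi[t]
                zb = ref_zb[t]
                pca = ref_ca
                pcsl = ref_csl
                pcst = ref_cst
                pb = ref_b
                Pp = refP
            else:
                xi = z_ca[t, p]
                zb = z_b[t, p]
                pca = ca_s[p]
                pcsl = csl_s[p]
                pcst = cst_s[p]
                pb = b_s[p]
                Pp = P_s[p]
            b_new = a_b * pb + sig_b * zb
            ca_noisy = pca + sig_ca * xi
            if ca_noisy < 0.0:
                ca_noisy = -ca_noisy
            # no-spike branch
            ca0, csl0, cst0 = _advance_bio(
                ca_noisy, 0.0, -1, pcsl, pcst, Pp, dt, 1, cp,
                log_ca0, dlog, AN_tab, AC_tab, AN, AC, P0s, Ptmp)
            pred0 = _dff_from_phi(fluorescent_frac(P0s),
                                  phi0, phisat, Rf, Fbasal)
            lp0 = log_p0 - 0.5 * ((y[t] - b_new - pred0) / sigma) ** 2
            # spike branch: substepped to resolve the fast post-spike
            # relaxation
            ca1, csl1, cst1 = _advance_bio(
                ca_noisy, afree, n_spike_sub // 2, pcsl, pcst, Pp,
                dt / n_spike_sub, n_spike_sub, cp, log_ca0, dlog,
                ANs_tab, ACs_tab, AN, AC, P1s, Ptmp)
            pred1 = _dff_from_phi(fluorescent_frac(P1s),
                                  phi0, phisat, Rf, Fbasal)
            lp1 = log_p1 - 0.5 * ((y[t] - b_new - pred1) / sigma) ** 2
            allowed = (t - (ref_last if is_ref else last_s_s[p])) \
                >= refr_bins
            if allowed:
                mx = lp0 if lp0 > lp1 else lp1
                marg = np.exp(lp0 - mx) + np.exp(lp1 - mx)
                q1 = np.exp(lp1 - mx) / marg
            else:
                # refractory: the spike branch has zero prior mass and
                # the no-spike prior probability is 1
                mx = lp0 - log_p0
                marg = 1.0
                q1 = 0.0
            if is_ref:
                s = ref_s[t]
            else:
                s = 1 if u_spike[t, p] < q1 else 0
            if s == 1:
                if is_ref:
                    ref_last = t
                else:
                    last_s_s[p] = t
                ca[p] = ca1
                csl[p] = csl1
                cst[p] = cst1
                for i in range(3):
                    for j in range(3):
                        P[p, i, j] = P1s[i, j]
            else:
                ca[p] = ca0
                csl[p] = csl0
                cst[p] = cst0
                for i in range(3):
                    for j in range(3):
                        P[p, i, j] = P0s[i, j]
            b[p] = b_new
            if is_ref:
                ref_ca = ca[p]
                ref_csl = csl[p]
                ref_cst = cst[p]
                ref_b = b_new
                for i in range(3):
                    for j in range(3):
                        refP[i, j] = P[p, i, j]
            last_s[p] = ref_last if is_ref else last_s_s[p]
            last_s[p] = ref_last if is_ref else last_s_s[p]
            s_out[t, p] = s
            xi_out[t, p] = xi
            zb_out[t, p] = zb
            anc_out[t, p] = anc[p]
            logW[p] = base[p] + mx + np.log(marg)
    ess = _ess(logW, w)
    if not np.isfinite(ess):
        return 1, n - 1, 0
    path = _categorical(np.log(w + 1e-300), u_final)
    return 0, -1, path


@njit(cache=True)
def pgas_sweep_lin(y, g1, g2, amp, sigma, p_spike, refr_bins, sig_b, a_b,
                   sig_c,
                   ref_s, ref_xi, ref_zb, has_ref,
                   u_spike, z_ca, z_b, u_res, u_anc, u_final,
                   s_out, xi_out, zb_out, anc_out):
    """Conditional-SMC sweep for the linear AR(2) kernel model.

    Same proposal/resampling scheme as the biophysical sweep.
    """
    n = y.size
    npart = u_spike.shape[1]
    c1 = np.zeros(npart)
    c2 = np.zeros(npart)
    b = np.zeros(npart)
    logW = np.zeros(npart)
    w = np.full(npart, 1.0 / npart)
    anc = np.empty(npart, np.int64)
    last_s = np.full(npart, -2 * refr_bins - 10, np.int64)
    last_s_s = np.empty(npart, np.int64)
    ref_last = -2 * refr_bins - 10
    c1_s = np.empty(npart)
    c2_s = np.empty(npart)
    b_s = np.empty(npart)
    logas = np.empty(npart)
    rc1 = 0.0
    rc2 = 0.0
    rb = 0.0
    log_p1 = np.log(p_spike)
    log_p0 = np.log(1.0 - p_spike)
    for t in range(n):
        resampled = False
        if t > 0:
            ess = _ess(logW, w)
            if not np.isfinite(ess):
                return 1, t, 0
            if ess < 0.5 * npart:
                _systematic(w, u_res[t], anc)
                resampled = True
            else:
                for p in range(npart):
                    anc[p] = p
            if has_ref:
                rb_next = a_b * rb + sig_b * ref_zb[t]
                rc_base = g1 * rc1 + g2 * rc2 + sig_c * ref_xi[t]
                for p in range(npart):
                    db = rb_next - a_b * b[p]
                    dc = rc_base - (g1 * c1[p] + g2 * c2[p]
                                    + sig_c * ref_xi[t])
                    logas[p] = logW[p] \
                        - 0.5 * (db / sig_b) ** 2 \
                        - 0.5 * (dc / sig_c) ** 2
                    if ref_s[t] == 1 and t - last_s[p] < refr_bins:
                        logas[p] = -np.inf
                anc[0] = _categorical(logas, u_anc[t])
        else:
            for p in range(npart):
                anc[p] = p
        for p in range(npart):
            a = anc[p]
            c1_s[p] = c1[a]
            c2_s[p] = c2[a]
            b_s[p] = b[a]
            last_s_s[p] = last_s[a]
        if resampled:
            base = np.zeros(npart)
        else:
            base = np.empty(npart)
            for p in range(npart):
                base[p] = logW[anc[p]]
        for p in range(npart):
            is_ref = has_ref and p == 0
            if is_ref:
                xi = ref_xi[t]
                zb = ref_zb[t]
                pc1 = rc1
                pc2 = rc2
                pb = rb
            else:
                xi = z_ca[t, p]
                zb = z_b[t, p]
                pc1 = c1_s[p]
                pc2 = c2_s[p]
                pb = b_s[p]
            b_new = a_b * pb + sig_b * zb
            c_base = g1 * pc1 + g2 * pc2 + sig_c * xi
            lp0 = log_p0 - 0.5 * ((y[t] - b_new - c_base) / sigma) ** 2
            lp1 = log_p1 - 0.5 * ((y[t] - b_new - c_base - amp)
                                  / sigma) ** 2
            allowed = (t - (ref_last if is_ref else last_s_s[p])) \
                >= refr_bins
            if allowed:
                mx = lp0 if lp0 > lp1 else lp1
                marg = np.exp(lp0 - mx) + np.exp(lp1 - mx)
                q1 = np.exp(lp1 - mx) / marg
            else:
                mx = lp0 - log_p0
                marg = 1.0
                q1 = 0.0
            if is_ref:
                s = ref_s[t]
            else:
                s = 1 if u_spike[t, p] < q1 else 0
            if s == 1:
                if is_ref:
                    ref_last = t
                else:
                    last_s_s[p] = t
            c_new = c_base + amp * s
            c2[p] = pc1
            c1[p] = c_new
            b[p] = b_new
            if is_ref:
                rc2 = pc1
                rc1 = c_new
                rb = b_new
            s_out[t, p] = s
            xi_out[t, p] = xi
            zb_out[t, p] = zb
            anc_out[t, p] = anc[p]
            logW[p] = base[p] + mx + np.log(marg)
    ess = _ess(logW, w)
    if not np.isfinite(ess):
        return 1, n - 1, 0
    path = _categorical(np.log(w + 1e-300), u_final)
    return 0, -1, path
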