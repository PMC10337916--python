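"""Numba kernels for single-site Gibbs sampling of the animal model.

Location effects (contemporary groups, covariates, breeding values,
permanent environment) are updated one equation at a time from their full
conditionals, Gauss–Seidel style, against a running residual vector; this
keeps each update O(records at that level + pedigree row) and makes the
30k-iteration desk chains tractable on one CPU.  Variance components are
drawn from their conjugate conditionals: scaled inverse chi-square for the
scalar components, inverse-Wishart (via a 2x2 Bartlett draw in closed form)
for the between-stratum genetic covariance G0.

Both kernels return -1 on success or the iteration index at which a
non-finite variance draw was detected.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _logf_scale(s, power, A, B, C, E):
    # log density of s = log c for a group scale move (Haar measure and
    # Jacobian already folded into `power`; slice sampling adds +s for the
    # change of variables c -> s)
    c = np.exp(s)
    return (power + 1.0) * s - A * c * c + B * c - C / (c * c) - E / c


@njit(cache=True)
def _sample_scale(power, A, B, C, E):
    """Slice-sample c from f(c) ∝ c^power exp(-A c^2 + B c - C/c^2 - E/c).

    Used by the generalized-Gibbs scale moves that jointly rescale a block
    of random effects and its variance (Liu–Sabatti group move); leaves the
    posterior invariant, and lets the chain traverse the variance scale in
    one move instead of a random walk.
    """
    s0 = 0.0
    ly = _logf_scale(s0, power, A, B, C, E) + np.log(np.random.random())
    w = 0.5
    left = s0 - w * np.random.random()
    right = left + w
    for _ in range(50):
        if left <= -6.0 or _logf_scale(left, power, A, B, C, E) <= ly:
            break
        left -= w
    for _ in range(50):
        if right >= 6.0 or _logf_scale(right, power, A, B, C, E) <= ly:
            break
        right += w
    if left < -6.0:
        left = -6.0
    if right > 6.0:
        right = 6.0
    for _ in range(100):
        s1 = left + (right - left) * np.random.random()
        if _logf_scale(s1, power, A, B, C, E) >= ly:
            return np.exp(s1)
        if s1 < s0:
            left = s1
        else:
            right = s1
    return 1.0


@njit(cache=True)
def run_single(
    y,
    cov,
    cgptr,
    cgrec,
    anptr,
    anrec,
    an_of_rec,
    peptr,
    perec,
    pe_of_rec,
    aiptr,
    aiidx,
    aidat,
    n_iter,
    burn_in,
    thin,
    seed,
    nu_a,
    sa0,
    nu_p,
    sp0,
    nu_e,
    se0,
    init_a,
    init_p,
    init_e,
    sample_variances,
    use_group_moves,
    out_vc,
    out_a,
    out_b,
    out_p,
):
    np.random.seed(seed)
    n = y.shape[0]
    n_cg = cgptr.shape[0] - 1
    n_an = anptr.shape[0] - 1
    n_pe = peptr.shape[0] - 1
    ncov = cov.shape[1]

    e = y.copy()
    b_cg = np.zeros(n_cg)
    b_cov = np.zeros(ncov)
    a = np.zeros(n_an)
    p = np.zeros(n_pe)

    cc = np.zeros(ncov)
    for j in range(ncov):
        s = 0.0
        for i in range(n):
            s += cov[i, j] * cov[i, j]
        cc[j] = s

    s2a, s2p, s2e = init_a, init_p, init_e
    kept = 0
    for it in range(n_iter):
        # contemporary groups (fixed, flat prior)
        for g in range(n_cg):
            lo, hi = cgptr[g], cgptr[g + 1]
            cnt = hi - lo
            if cnt == 0:
                continue
            r = cnt * b_cg[g]
            for k in range(lo, hi):
                r += e[cgrec[k]]
            new = r / cnt + np.random.normal() * np.sqrt(s2e / cnt)
            d = new - b_cg[g]
            b_cg[g] = new
            for k in range(lo, hi):
                e[cgrec[k]] -= d
        # covariates (flat prior)
        for j in range(ncov):
            if cc[j] <= 0.0:
                continue
            r = cc[j] * b_cov[j]
            for i in range(n):
                r += cov[i, j] * e[i]
            new = r / cc[j] + np.random.normal() * np.sqrt(s2e / cc[j])
            d = new - b_cov[j]
            b_cov[j] = new
            for i in range(n):
                e[i] -= cov[i, j] * d
        # additive genetic effects
        if n_an > 0:
            lam = s2e / s2a
            for i in range(n_an):
                acc = 0.0
                dii = 1.0
                for k in range(aiptr[i], aiptr[i + 1]):
                    jj = aiidx[k]
                    if jj == i:
                        dii = aidat[k]
                    else:
                        acc += aidat[k] * a[jj]
                lo, hi = anptr[i], anptr[i + 1]
                cnt = hi - lo
                r = cnt * a[i] - lam * acc
                for k in range(lo, hi):
                    r += e[anrec[k]]
                dcoef = cnt + lam * dii
                new = r / dcoef + np.random.normal() * np.sqrt(s2e / dcoef)
                d = new - a[i]
                a[i] = new
                for k in range(lo, hi):
                    e[anrec[k]] -= d
        # permanent environment
        if n_pe > 0:
            lamp = s2e / s2p
            for i in range(n_pe):
                lo, hi = peptr[i], peptr[i + 1]
                cnt = hi - lo
                r = cnt * p[i]
                for k in range(lo, hi):
                    r += e[perec[k]]
                dcoef = cnt + lamp
                new = r / dcoef + np.random.normal() * np.sqrt(s2e / dcoef)
                d = new - p[i]
                p[i] = new
                for k in range(lo, hi):
                    e[perec[k]] -= d
        # variance components
        if sample_variances:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = (sse + nu_e * se0) / np.random.chisquare(n + nu_e)
            if n_an > 0:
                qf = 0.0
                for i in range(n_an):
                    for k in range(aiptr[i], aiptr[i + 1]):
                        qf += a[i] * aidat[k] * a[aiidx[k]]
                s2a = (qf + nu_a * sa0) / np.random.chisquare(n_an + nu_a)
            if n_pe > 0:
                pp = 0.0
                for i in range(n_pe):
                    pp += p[i] * p[i]
                s2p = (pp + nu_p * sp0) / np.random.chisquare(n_pe + nu_p)
            # generalized-Gibbs scale moves: rescale a whole random-effect
            # block and its variance together so the chain does not have to
            # random-walk the variance scale (valid only with a proper
            # prior, nu > 0)
            if use_group_moves and n_an > 0 and nu_a > 0.0 and sa0 > 0.0:
                sv = 0.0
                suv = 0.0
                for i in range(n):
                    v = a[an_of_rec[i]]
                    sv += v * v
                    suv += (e[i] + v) * v
                c = _sample_scale(-nu_a - 1.0, sv / (2.0 * s2e), suv / s2e, nu_a * sa0 / (2.0 * s2a), 0.0)
                for i in range(n):
                    e[i] += (1.0 - c) * a[an_of_rec[i]]
                for i in range(n_an):
                    a[i] *= c
                s2a *= c * c
            if use_group_moves and n_pe > 0 and nu_p > 0.0 and sp0 > 0.0:
                sv = 0.0
                suv = 0.0
                for i in range(n):
                    v = p[pe_of_rec[i]]
                    sv += v * v
                    suv += (e[i] + v) * v
                c = _sample_scale(-nu_p - 1.0, sv / (2.0 * s2e), suv / s2e, nu_p * sp0 / (2.0 * s2p), 0.0)
                for i in range(n):
                    e[i] += (1.0 - c) * p[pe_of_rec[i]]
                for i in range(n_pe):
                    p[i] *= c
                s2p *= c * c
        # retain
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            if not (np.isfinite(s2e) and np.isfinite(s2a) and np.isfinite(s2p)):
                return it
            out_vc[kept, 0] = s2a
            out_vc[kept, 1] = s2p
            out_vc[kept, 2] = s2e
            for i in range(n_an):
                out_a[kept, i] = a[i]
            for g in range(n_cg):
                out_b[kept, g] = b_cg[g]
            for j in range(ncov):
                out_b[kept, n_cg + j] = b_cov[j]
            for i in range(n_pe):
                out_p[kept, i] = p[i]
            kept += 1
    return -1


@njit(cache=True)
def run_two_trait(
    y,
    cov,
    trait,
    cgptr,
    cgrec,
    cg_trait,
    anptr,
    anrec,
    an_trait,
    an_of_rec,
    peptr,
    perec,
    pe_trait,
    pe_of_rec,
    aiptr,
    aiidx,
    aidat,
    n_iter,
    burn_in,
    thin,
    seed,
    nu_g,
    v0_11,
    v0_12,
    v0_22,
    nu_p,
    sp0_0,
    sp0_1,
    nu_e,
    se0_0,
    se0_1,
    g_init_11,
    g_init_12,
    g_init_22,
    sample_variances,
    use_group_moves,
    out_vc,
    out_a,
    out_b,
    out_p,
):
    np.random.seed(seed)
    n = y.shape[0]
    n_cg = cgptr.shape[0] - 1
    n_an = anptr.shape[0] - 1
    n_pe = peptr.shape[0] - 1
    ncov = cov.shape[1]

    e = y.copy()
    b_cg = np.zeros(n_cg)
    b_cov = np.zeros(2 * ncov)
    a = np.zeros((2, n_an))
    p = np.zeros(n_pe)

    # per-trait covariate cross-products and record counts
    cc = np.zeros(2 * ncov)
    n_t = np.zeros(2, np.int64)
    for i in range(n):
        t = trait[i]
        n_t[t] += 1
        for j in range(ncov):
            cc[t * ncov + j] += cov[i, j] * cov[i, j]
    n_pe_t = np.zeros(2, np.int64)
    for i in range(n_pe):
        n_pe_t[pe_trait[i]] += 1

    g11, g12, g22 = g_init_11, g_init_12, g_init_22
    s2p = np.array([sp0_0, sp0_1])
    s2e = np.array([se0_0, se0_1])

    kept = 0
    for it in range(n_iter):
        detg = g11 * g22 - g12 * g12
        w11 = g22 / detg
        w12 = -g12 / detg
        w22 = g11 / detg
        # contemporary groups (each level belongs to one trait)
        for g in range(n_cg):
            lo, hi = cgptr[g], cgptr[g + 1]
            cnt = hi - lo
            if cnt == 0:
                continue
            set_ = s2e[cg_trait[g]]
            r = 0.0
            for k in range(lo, hi):
                r += e[cgrec[k]]
            r = r / set_ + (cnt / set_) * b_cg[g]
            dcoef = cnt / set_
            new = r / dcoef + np.random.normal() / np.sqrt(dcoef)
            d = new - b_cg[g]
            b_cg[g] = new
            for k in range(lo, hi):
                e[cgrec[k]] -= d
        # covariates nested within trait
        for t in range(2):
            for j in range(ncov):
                idx = t * ncov + j
                if cc[idx] <= 0.0:
                    continue
                set_ = s2e[t]
                r = 0.0
                for i in range(n):
                    if trait[i] == t:
                        r += cov[i, j] * e[i]
                r = r / set_ + (cc[idx] / set_) * b_cov[idx]
                dcoef = cc[idx] / set_
                new = r / dcoef + np.random.normal() / np.sqrt(dcoef)
                d = new - b_cov[idx]
                b_cov[idx] = new
                for i in range(n):
                    if trait[i] == t:
                        e[i] -= cov[i, j] * d
        # breeding values: the two trait effects of each animal are drawn
        # jointly (2x2 block) — single-site updates mix hopelessly slowly
        # when the genetic correlation is high
        for i in range(n_an):
            acc0 = 0.0
            acc1 = 0.0
            dii = 1.0
            for k in range(aiptr[i], aiptr[i + 1]):
                jj = aiidx[k]
                if jj == i:
                    dii = aidat[k]
                else:
                    v = aidat[k]
                    acc0 += v * a[0, jj]
                    acc1 += v * a[1, jj]
            r0 = -w11 * acc0 - w12 * acc1
            r1 = -w12 * acc0 - w22 * acc1
            p11 = w11 * dii
            p12 = w12 * dii
            p22 = w22 * dii
            t = an_trait[i]
            lo, hi = anptr[i], anptr[i + 1]
            cnt = hi - lo
            if t >= 0 and cnt > 0:
                set_ = s2e[t]
                rr = 0.0
                for k in range(lo, hi):
                    rr += e[anrec[k]]
                if t == 0:
                    r0 += rr / set_ + (cnt / set_) * a[0, i]
                    p11 += cnt / set_
                else:
                    r1 += rr / set_ + (cnt / set_) * a[1, i]
                    p22 += cnt / set_
            detp = p11 * p22 - p12 * p12
            mu0 = (p22 * r0 - p12 * r1) / detp
            mu1 = (-p12 * r0 + p11 * r1) / detp
            lp11 = np.sqrt(p11)
            lp21 = p12 / lp11
            lp22 = np.sqrt(p22 - lp21 * lp21)
            z0 = np.random.normal()
            z1 = np.random.normal()
            x1 = z1 / lp22
            x0 = (z0 - lp21 * x1) / lp11
            new0 = mu0 + x0
            new1 = mu1 + x1
            if t == 0 and cnt > 0:
                d = new0 - a[0, i]
                for k in range(lo, hi):
                    e[anrec[k]] -= d
            elif t == 1 and cnt > 0:
                d = new1 - a[1, i]
                for k in range(lo, hi):
                    e[anrec[k]] -= d
            a[0, i] = new0
            a[1, i] = new1
        # permanent environment (cow lives in one trait)
        for i in range(n_pe):
            t = pe_trait[i]
            set_ = s2e[t]
            lo, hi = peptr[i], peptr[i + 1]
            cnt = hi - lo
            r = 0.0
            for k in range(lo, hi):
                r += e[perec[k]]
            r = r / set_ + (cnt / set_) * p[i]
            dcoef = cnt / set_ + 1.0 / s2p[t]
            new = r / dcoef + np.random.normal() / np.sqrt(dcoef)
            d = new - p[i]
            p[i] = new
            for k in range(lo, hi):
                e[perec[k]] -= d
        # variances
        if sample_variances:
            sse0 = 0.0
            sse1 = 0.0
            for i in range(n):
                if trait[i] == 0:
                    sse0 += e[i] * e[i]
                else:
                    sse1 += e[i] * e[i]
            s2e[0] = (sse0 + nu_e * se0_0) / np.random.chisquare(n_t[0] + nu_e)
            s2e[1] = (sse1 + nu_e * se0_1) / np.random.chisquare(n_t[1] + nu_e)
            pp0 = 0.0
            pp1 = 0.0
            for i in range(n_pe):
                if pe_trait[i] == 0:
                    pp0 += p[i] * p[i]
                else:
                    pp1 += p[i] * p[i]
            if n_pe_t[0] > 0:
                s2p[0] = (pp0 + nu_p * sp0_0) / np.random.chisquare(n_pe_t[0] + nu_p)
            if n_pe_t[1] > 0:
                s2p[1] = (pp1 + nu_p * sp0_1) / np.random.chisquare(n_pe_t[1] + nu_p)
            # G0 | a ~ IW(S + V0, q + nu_g) via Bartlett on the Wishart inverse
            s11 = 0.0
            s12 = 0.0
            s22 = 0.0
            for i in range(n_an):
                r0 = 0.0
                r1 = 0.0
                for k in range(aiptr[i], aiptr[i + 1]):
                    jj = aiidx[k]
                    r0 += aidat[k] * a[0, jj]
                    r1 += aidat[k] * a[1, jj]
                s11 += a[0, i] * r0
                s12 += a[0, i] * r1
                s22 += a[1, i] * r1
            v11 = s11 + v0_11
            v12 = s12 + v0_12
            v22 = s22 + v0_22
            detv = v11 * v22 - v12 * v12
            vi11 = v22 / detv
            vi12 = -v12 / detv
            vi22 = v11 / detv
            L11 = np.sqrt(vi11)
            L21 = vi12 / L11
            L22 = np.sqrt(vi22 - L21 * L21)
            df = n_an + nu_g
            c11 = np.sqrt(np.random.chisquare(df))
            c21 = np.random.normal()
            c22 = np.sqrt(np.random.chisquare(df - 1.0))
            t11 = L11 * c11
            t21 = L21 * c11 + L22 * c21
            t22 = L22 * c22
            # W = T T' is Wishart(df, V^{-1}); G0 = W^{-1}
            W11 = t11 * t11
            W12 = t11 * t21
            W22 = t21 * t21 + t22 * t22
            detw = W11 * W22 - W12 * W12
            g11 = W22 / detw
            g12 = -W12 / detw
            g22 = W11 / detw
            # generalized-Gibbs scale moves per trait: rescale (a_t, G0
            # row/column t) and (p_t, s2p_t) jointly; leaves the posterior
            # invariant and replaces the random walk on the variance scale
            for t in range(2 if use_group_moves else 0):
                det_c = g11 * g22 - g12 * g12
                wtt_c = (g22 if t == 0 else g11) / det_c
                wtx_c = -g12 / det_c
                v0tt = v0_11 if t == 0 else v0_22
                if v0tt <= 0.0:
                    continue
                set_ = s2e[t]
                sv = 0.0
                suv = 0.0
                for i in range(n):
                    if trait[i] == t:
                        v = a[t, an_of_rec[i]]
                        sv += v * v
                        suv += (e[i] + v) * v
                c = _sample_scale(
                    -nu_g - 1.0,
                    sv / (2.0 * set_),
                    suv / set_,
                    v0tt * wtt_c / 2.0,
                    v0_12 * wtx_c,
                )
                for i in range(n):
                    if trait[i] == t:
                        e[i] += (1.0 - c) * a[t, an_of_rec[i]]
                for i in range(n_an):
                    a[t, i] *= c
                if t == 0:
                    g11 *= c * c
                else:
                    g22 *= c * c
                g12 *= c
            # shear moves: a_t <- a_t + gamma a_u with the congruent G0
            # update (unit-Jacobian group action, Gaussian conditional);
            # mixes the genetic covariance directly
            for t in range(2 if use_group_moves else 0):
                u = 1 - t
                det_c = g11 * g22 - g12 * g12
                w11_c = g22 / det_c
                w12_c = -g12 / det_c
                w22_c = g11 / det_c
                # prior contribution: tr(V0 G'^-1) is quadratic in gamma
                if t == 1:
                    a_pr = v0_11 * w22_c / 2.0
                    b_pr = v0_11 * w12_c + v0_12 * w22_c
                else:
                    a_pr = v0_22 * w11_c / 2.0
                    b_pr = v0_22 * w12_c + v0_12 * w11_c
                set_ = s2e[t]
                sv = 0.0
                sev = 0.0
                for i in range(n):
                    if trait[i] == t:
                        v = a[u, an_of_rec[i]]
                        sv += v * v
                        sev += e[i] * v
                a_tot = sv / (2.0 * set_) + a_pr
                b_tot = sev / set_ + b_pr
                gam = b_tot / (2.0 * a_tot) + np.random.normal() / np.sqrt(2.0 * a_tot)
                for i in range(n):
                    if trait[i] == t:
                        e[i] -= gam * a[u, an_of_rec[i]]
                for i in range(n_an):
                    a[t, i] += gam * a[u, i]
                if t == 1:
                    g22 = g22 + 2.0 * gam * g12 + gam * gam * g11
                    g12 = g12 + gam * g11
                else:
                    g11 = g11 + 2.0 * gam * g12 + gam * gam * g22
                    g12 = g12 + gam * g22
            for t in range(2 if use_group_moves else 0):
                sp0t = sp0_0 if t == 0 else sp0_1
                if n_pe_t[t] == 0 or nu_p <= 0.0 or sp0t <= 0.0:
                    continue
                set_ = s2e[t]
                sv = 0.0
                suv = 0.0
                for i in range(n):
                    if trait[i] == t:
                        v = p[pe_of_rec[i]]
                        sv += v * v
                        suv += (e[i] + v) * v
                c = _sample_scale(-nu_p - 1.0, sv / (2.0 * set_), suv / set_, nu_p * sp0t / (2.0 * s2p[t]), 0.0)
                for i in range(n):
                    if trait[i] == t:
                        e[i] += (1.0 - c) * p[pe_of_rec[i]]
                for i in range(n_pe):
                    if pe_trait[i] == t:
                        p[i] *= c
                s2p[t] *= c * c
        # retain
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            ok = (
                np.isfinite(g11)
                and np.isfinite(g12)
                and np.isfinite(g22)
                and np.isfinite(s2e[0])
                and np.isfinite(s2e[1])
                and np.isfinite(s2p[0])
                and np.isfinite(s2p[1])
                and g11 * g22 - g12 * g12 > 0.0
            )
            if not ok:
                return it
            out_vc[kept, 0] = g11
            out_vc[kept, 1] = g12
            out_vc[kept, 2] = g22
            out_vc[kept, 3] = s2p[0]
            out_vc[kept, 4] = s2p[1]
            out_vc[kept, 5] = s2e[0]
            out_vc[kept, 6] = s2e[1]
            for i in range(n_an):
                out_a[kept, 0, i] = a[0, i]
                out_a[kept, 1, i] = a[1, i]
            for g in range(n_cg):
                out_b[kept, g] = b_cg[g]
            for j in range(2 * ncov):
                out_b[kept, n_cg + j] = b_cov[j]
            for i in range(n_pe):
                out_p[kept, i] = p[i]
            kept += 1
    return -1
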