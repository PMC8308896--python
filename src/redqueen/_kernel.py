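"""Compiled inner loop of the co-evolutionary recursion.

One generation advances both species simultaneously from the shared
current state: frequency-dependent viability selection, meiosis with the
strategy-resolved recombination rate, then random union of gametes.  The
loop is written with explicit scalar loops (no BLAS) so results are
bit-reproducible across runs and platforms.

Strategy encoding: per modifier allele a row ``(form, r_lo, r_hi)`` with
``form`` 0 = constant (r_lo == r_hi), 1 = prevention (rate rises linearly
with the class's danger frequency), 2 = remediation (r_hi when infected,
r_lo when resistant, weighted by the post-selection composition of the
class).
"""

import numpy as np
from numba import njit

FORM_CONSTANT = 0
FORM_PREVENTION = 1
FORM_REMEDIATION = 2

N_TRACE = 7  # host A1, host B1, invader modifier, par A1, par B1, wbar_h, wbar_p


@njit(cache=True)
def _allele_rate(form, lo, hi, p, infected):
    if form == FORM_CONSTANT:
        return lo
    elif form == FORM_PREVENTION:
        return lo + p * (hi - lo)
    else:
        return hi if infected else lo


@njit(cache=True)
def run_generations(hz, pz, n_gen, s_h, s_p,
                    pheno_h, pheno_p, mod_i, mod_j,
                    g0, g1, pp,
                    strat_form, strat_lo, strat_hi,
                    a1h, b1h, minv, a1p, b1p,
                    trace):
    """Advance ``n_gen`` generations in place; fill ``trace`` row per gen.

    Returns 0 on success, 1 if a population's mean fitness hit zero
    (extinction), in which case iteration stops at that generation.
    """
    gh = np.zeros(8)
    gp = np.zeros(4)
    fh = np.zeros(4)
    fp = np.zeros(4)
    record = trace.shape[0] >= n_gen
    for gen in range(n_gen):
        for k in range(4):
            fh[k] = 0.0
            fp[k] = 0.0
        for t in range(64):
            fh[pheno_h[t]] += hz[t]
        for u in range(16):
            fp[pheno_p[u]] += pz[u]

        wbar_h = 0.0
        wbar_p = 0.0
        for t in range(64):
            wbar_h += hz[t] * (1.0 - s_h * fp[pheno_h[t]])
        for u in range(16):
            wbar_p += pz[u] * (1.0 - s_p * (1.0 - fh[pheno_p[u]]))
        if wbar_h <= 0.0 or wbar_p <= 0.0:
            return 1

        if record:
            f_a1 = 0.0
            f_b1 = 0.0
            f_m = 0.0
            for i in range(8):
                hap = 0.0
                for j in range(8):
                    hap += hz[8 * i + j]
                f_a1 += hap * a1h[i]
                f_b1 += hap * b1h[i]
                f_m += hap * minv[i]
            f_a1p = 0.0
            f_b1p = 0.0
            for i in range(4):
                hap = 0.0
                for j in range(4):
                    hap += pz[4 * i + j]
                f_a1p += hap * a1p[i]
                f_b1p += hap * b1p[i]
            trace[gen, 0] = f_a1
            trace[gen, 1] = f_b1
            trace[gen, 2] = f_m
            trace[gen, 3] = f_a1p
            trace[gen, 4] = f_b1p
            trace[gen, 5] = wbar_h
            trace[gen, 6] = wbar_p

        # host: selection, per-class effective recombination rate, meiosis
        for k in range(8):
            gh[k] = 0.0
        for t in range(64):
            if hz[t] == 0.0:
                continue
            p = fp[pheno_h[t]]
            w = 1.0 - s_h * p
            if w <= 0.0:
                continue  # class entirely removed by selection
            a = hz[t] * w / wbar_h
            si = mod_i[t]
            sj = mod_j[t]
            r_res = 0.5 * (_allele_rate(strat_form[si], strat_lo[si],
                                        strat_hi[si], p, False)
                           + _allele_rate(strat_form[sj], strat_lo[sj],
                                          strat_hi[sj], p, False))
            if (strat_form[si] == FORM_REMEDIATION
                    or strat_form[sj] == FORM_REMEDIATION):
                r_inf = 0.5 * (_allele_rate(strat_form[si], strat_lo[si],
                                            strat_hi[si], p, True)
                               + _allele_rate(strat_form[sj], strat_lo[sj],
                                              strat_hi[sj], p, True))
                if r_inf == r_res:
                    r_eff = r_res
                else:
                    w_inf = p * (1.0 - s_h) / w
                    r_eff = w_inf * r_inf + (1.0 - w_inf) * r_res
            else:
                r_eff = r_res
            for k in range(8):
                gh[k] += a * (g0[t, k] + r_eff * g1[t, k])

        # parasite: selection and meiosis at the fixed rate baked into pp
        for k in range(4):
            gp[k] = 0.0
        for u in range(16):
            if pz[u] == 0.0:
                continue
            a = pz[u] * (1.0 - s_p * (1.0 - fh[pheno_p[u]])) / wbar_p
            for k in range(4):
                gp[k] += a * pp[u, k]

        s = 0.0
        for k in range(8):
            s += gh[k]
        for k in range(8):
            gh[k] /= s
        s = 0.0
        for k in range(4):
            s += gp[k]
        for k in range(4):
            gp[k] /= s

        # random union of gametes
        for i in range(8):
            for j in range(8):
                hz[8 * i + j] = gh[i] * gh[j]
        for i in range(4):
            for j in range(4):
                pz[4 * i + j] = gp[i] * gp[j]
    return 0
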