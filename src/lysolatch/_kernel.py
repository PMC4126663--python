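"""Numba kernels for exact stochastic simulation.

Two direct-method Gillespie kernels live here: a generic well-mixed kernel
with piecewise-constant propensity segments (checkpoints carry volume changes
and genome-addition events), and a compartmentalised reaction-diffusion
kernel in which diffusion is sampled through per-species aggregate hop
propensities (diffusion events vastly outnumber reaction events when
transport is fast, so they get the cheap sampling path).

Both kernels are statistically exact: rates are constant within a segment,
and restarting the exponential clock at a segment boundary is valid by
memorylessness.  Propensities are refreshed incrementally through reaction
dependency lists and recomputed in full at every checkpoint to cancel
floating-point drift.
"""

import numpy as np
from numba import njit

__all__ = ["ssa_run", "rdme_run"]


@njit(cache=True, inline="always")
def _prop(j, x, keff, order, s1, s2, homo):
    k = keff[j]
    o = order[j]
    if o == 0:
        return k
    a = x[s1[j]]
    if o == 1:
        return k * a
    if homo[j]:
        return k * a * (a - 1) * 0.5
    return k * a * x[s2[j]]


@njit(cache=True)
def ssa_run(
    seed,
    x0,
    order,
    s1,
    s2,
    homo,
    vexp,
    kbase,
    d_indptr,
    d_sp,
    d_val,
    dep_indptr,
    dep_dat,
    ckpt_t,
    ckpt_vol,
    ev_indptr,
    ev_sp,
    ev_val,
    sample_of,
    out_counts,
):
    """Direct-method SSA over piecewise-constant segments.

    Returns 0 on success, 1 if a species count went negative (which would
    indicate a corrupted network specification).
    """
    np.random.seed(seed)
    M = order.shape[0]
    x = x0.copy()
    keff = np.empty(M)
    props = np.empty(M)

    for p in range(ev_indptr[0], ev_indptr[1]):
        x[ev_sp[p]] += ev_val[p]
    if sample_of[0] >= 0:
        out_counts[sample_of[0], :] = x

    nseg = ckpt_t.shape[0] - 1
    for c in range(nseg):
        vol = ckpt_vol[c]
        a0 = 0.0
        for j in range(M):
            if vexp[j] != 0:
                keff[j] = kbase[j] / vol
            else:
                keff[j] = kbase[j]
            pj = _prop(j, x, keff, order, s1, s2, homo)
            props[j] = pj
            a0 += pj
        t = ckpt_t[c]
        t_end = ckpt_t[c + 1]
        while a0 > 1e-13:
            t += np.random.exponential() / a0
            if t >= t_end:
                break
            r = np.random.random() * a0
            acc = 0.0
            jsel = M - 1
            for j in range(M):
                acc += props[j]
                if r < acc:
                    jsel = j
                    break
            for p in range(d_indptr[jsel], d_indptr[jsel + 1]):
                x[d_sp[p]] += d_val[p]
                if x[d_sp[p]] < 0:
                    return 1
            for p in range(dep_indptr[jsel], dep_indptr[jsel + 1]):
                jj = dep_dat[p]
                old = props[jj]
                new = _prop(jj, x, keff, order, s1, s2, homo)
                props[jj] = new
                a0 += new - old
        for p in range(ev_indptr[c + 1], ev_indptr[c + 2]):
            x[ev_sp[p]] += ev_val[p]
        sm = sample_of[c + 1]
        if sm >= 0:
            out_counts[sm, :] = x
    return 0


@njit(cache=True, fastmath=True)
def rdme_run(
    seed,
    x0,
    order,
    s1,
    s2,
    homo,
    keff,
    d_indptr,
    d_sp,
    d_val,
    dep_indptr,
    dep_dat,
    spdep_indptr,
    spdep_dat,
    sdiff,
    rdiff,
    diff_of_species,
    C,
    sample_t,
    out_counts,
):
    """Direct-method SSA on a 1-D compartment grid with reflecting ends.

    ``x0`` is flattened species-major (species s, compartment c at s*C + c).
    ``keff`` already folds the compartment volume into bimolecular constants.
    Diffusion is aggregated per species (hop events dominate when transport
    is fast, so they take the cheap sampling path); reaction channels are
    replicated per compartment.  Returns 0 on success, 1 on a negative count.
    """
    np.random.seed(seed)
    M = order.shape[0]
    ndiff = sdiff.shape[0]
    x = x0.copy()
    props = np.empty(M * C)
    pdiff = np.empty(ndiff)
    ntot = np.empty(ndiff)

    P = sample_t.shape[0]
    if P > 0 and sample_t[0] == 0.0:
        out_counts[0, :] = x
        start = 1
    else:
        start = 0

    t = 0.0
    for sm in range(start, P):
        t_end = sample_t[sm]
        # Full refresh at every output sample: cancels drift.
        a_react = 0.0
        for j in range(M):
            k = keff[j]
            o = order[j]
            i1 = s1[j]
            i2 = s2[j]
            hm = homo[j]
            for c in range(C):
                if o == 0:
                    pj = k
                else:
                    a = x[i1 * C + c]
                    if o == 1:
                        pj = k * a
                    elif hm:
                        pj = k * a * (a - 1) * 0.5
                    else:
                        pj = k * a * x[i2 * C + c]
                props[j * C + c] = pj
                a_react += pj
        a_diff = 0.0
        for si in range(ndiff):
            s = sdiff[si]
            tot = 0.0
            for c in range(C):
                tot += x[s * C + c]
            ntot[si] = tot
            pdiff[si] = rdiff[si] * (2.0 * tot - x[s * C] - x[s * C + C - 1])
            a_diff += pdiff[si]

        while True:
            a0 = a_react + a_diff
            if a0 <= 1e-13:
                break
            t += np.random.exponential() / a0
            if t >= t_end:
                break
            r = np.random.random() * a0
            if r < a_diff:
                # --- hop event: pick species, then compartment and direction.
                si = ndiff - 1
                acc = 0.0
                for k in range(ndiff):
                    acc += pdiff[k]
                    if r < acc:
                        si = k
                        break
                s = sdiff[si]
                rem = (r - (acc - pdiff[si])) / rdiff[si]
                csel = C - 1
                right = False
                acc2 = 0.0
                for c in range(C):
                    w = x[s * C + c] * (2.0 if 0 < c < C - 1 else 1.0)
                    acc2 += w
                    if rem < acc2:
                        csel = c
                        if c == 0:
                            right = True
                        elif c == C - 1:
                            right = False
                        else:
                            right = (acc2 - rem) > x[s * C + c]
                        break
                c2 = csel + 1 if right else csel - 1
                x[s * C + csel] -= 1
                x[s * C + c2] += 1
                if x[s * C + csel] < 0:
                    return 1
                # Dependent reaction channels in the two touched compartments.
                for p in range(spdep_indptr[s], spdep_indptr[s + 1]):
                    j = spdep_dat[p]
                    k1 = keff[j]
                    o = order[j]
                    for half in range(2):
                        cc = csel if half == 0 else c2
                        ch = j * C + cc
                        a = x[s1[j] * C + cc]
                        if o == 1:
                            new = k1 * a
                        elif homo[j]:
                            new = k1 * a * (a - 1) * 0.5
                        else:
                            new = k1 * a * x[s2[j] * C + cc]
                        old = props[ch]
                        props[ch] = new
                        a_react += new - old
                # Totals unchanged; only end-compartment occupancy matters.
                old = pdiff[si]
                pdiff[si] = rdiff[si] * (2.0 * ntot[si] - x[s * C] - x[s * C + C - 1])
                a_diff += pdiff[si] - old
            else:
                # --- reaction event in one compartment.
                rr = r - a_diff
                ch = M * C - 1
                acc = 0.0
                for k in range(M * C):
                    acc += props[k]
                    if rr < acc:
                        ch = k
                        break
                j = ch // C
                c = ch - j * C
                for p in range(d_indptr[j], d_indptr[j + 1]):
                    s = d_sp[p]
                    x[s * C + c] += d_val[p]
                    if x[s * C + c] < 0:
                        return 1
                    si = diff_of_species[s]
                    if si >= 0:
                        ntot[si] += d_val[p]
                        old = pdiff[si]
                        pdiff[si] = rdiff[si] * (
                            2.0 * ntot[si] - x[s * C] - x[s * C + C - 1]
                        )
                        a_diff += pdiff[si] - old
                for p in range(dep_indptr[j], dep_indptr[j + 1]):
                    jj = dep_dat[p]
                    ch2 = jj * C + c
                    k1 = keff[jj]
                    o = order[jj]
                    if o == 0:
                        new = k1
                    else:
                        a = x[s1[jj] * C + c]
                        if o == 1:
                            new = k1 * a
                        elif homo[jj]:
                            new = k1 * a * (a - 1) * 0.5
                        else:
                            new = k1 * a * x[s2[jj] * C + c]
                    old = props[ch2]
                    props[ch2] = new
                    a_react += new - old
        out_counts[sm, :] = x
        t = t_end
    return 0
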