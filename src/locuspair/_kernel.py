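"""Numba kernel for the coalescent with recombination.

Ancestral material is tracked per discrete site as a bitmask of descendant
samples (two 62-bit planes, so up to 124 sampled haplotypes).  Backward in
time, lineages coalesce (per-pair rate 2/x in a deme of relative size x,
time in units of 4*N0 generations), recombine (rate rho_site per breakpoint
spanned by the lineage's ancestral material; breakpoints in trapped,
non-ancestral material split lineages as in the classical ancestral
recombination graph), migrate (per-lineage rate M between two demes), and
mutate (rate theta_site per ancestral site, infinite-sites: every mutation
is a new column).  Sites whose merged sample set reaches the full sample
are locally at their MRCA and are dropped from ancestral material; the
simulation ends when no ancestral material remains.

Demography is a piecewise schedule of up to a few epochs: per-epoch deme
sizes with optional exponential change, symmetric migration, and a flag
merging deme 1 into deme 0 at the epoch start (population split viewed
backward).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_MUT_OVERFLOW = 1
STATUS_LIN_OVERFLOW = 2

_PLANE_BITS = 62


@njit(cache=True)
def _exp_draw(rng, rate):
    if rate <= 0.0:
        return np.inf
    u = rng.random()
    return -np.log(1.0 - u) / rate


@njit(cache=True)
def _coal_wait(rng, k, size, grow, dt_epoch):
    """Waiting time to the next coalescence in a deme with k lineages whose
    relative size is size*exp(-grow * s) for elapsed epoch time s, at epoch
    offset dt_epoch.  Per-pair rate is 2/x -> total k(k-1)/x."""
    if k < 2:
        return np.inf
    expo = grow * dt_epoch
    if expo > 700.0:
        expo = 700.0
    rate0 = k * (k - 1) / size * np.exp(expo)
    u = rng.random()
    E = -np.log(1.0 - u)
    if grow == 0.0:
        return E / rate0
    arg = 1.0 + grow * E / rate0
    if arg <= 0.0:
        return np.inf
    return np.log(arg) / grow


@njit(cache=True)
def simulate_kernel(
    rng,
    n_samples,
    sample_pop,      # int64[n_samples]
    L,
    theta_site,
    rho_site,
    n_epochs,
    ep_start,        # float64[n_epochs]
    ep_size,         # float64[n_epochs, 2]
    ep_grow,         # float64[n_epochs, 2]
    ep_mig,          # float64[n_epochs]
    ep_merge,        # int64[n_epochs] (1 -> deme1 joins deme0 at epoch start)
    max_lin,
    mut_cap,
):
    anc0 = np.zeros((max_lin, L), dtype=np.int64)
    anc1 = np.zeros((max_lin, L), dtype=np.int64)
    pop = np.zeros(max_lin, dtype=np.int64)
    first = np.zeros(max_lin, dtype=np.int64)
    last = np.zeros(max_lin, dtype=np.int64)
    asites = np.zeros(max_lin, dtype=np.int64)
    act = np.zeros(max_lin, dtype=np.int64)
    pos_in_act = np.full(max_lin, -1, dtype=np.int64)
    free = np.zeros(max_lin, dtype=np.int64)

    nb0 = min(n_samples, _PLANE_BITS)
    nb1 = n_samples - nb0
    full0 = (np.int64(1) << nb0) - np.int64(1)
    full1 = (np.int64(1) << nb1) - np.int64(1) if nb1 > 0 else np.int64(0)

    n_act = 0
    n_free = 0
    for r in range(max_lin - 1, n_samples - 1, -1):
        free[n_free] = r
        n_free += 1
    for i in range(n_samples):
        if i < _PLANE_BITS:
            bit0 = np.int64(1) << i
            bit1 = np.int64(0)
        else:
            bit0 = np.int64(0)
            bit1 = np.int64(1) << (i - _PLANE_BITS)
        for s in range(L):
            anc0[i, s] = bit0
            anc1[i, s] = bit1
        pop[i] = sample_pop[i]
        first[i] = 0
        last[i] = L - 1
        asites[i] = L
        act[n_act] = i
        pos_in_act[i] = n_act
        n_act += 1

    tot_gaps = n_samples * (L - 1)
    tot_asites = n_samples * L

    mut_site = np.zeros(mut_cap, dtype=np.int64)
    mut_m0 = np.zeros(mut_cap, dtype=np.int64)
    mut_m1 = np.zeros(mut_cap, dtype=np.int64)
    n_mut = 0

    t = 0.0
    e = 0
    # apply any merges scheduled at t=0 epochs (defensive)
    while True:
        if tot_asites <= 0:
            break
        epoch_end = ep_start[e + 1] if e + 1 < n_epochs else np.inf
        # deme counts
        k0 = 0
        k1 = 0
        for i in range(n_act):
            if pop[act[i]] == 0:
                k0 += 1
            else:
                k1 += 1
        dt_epoch = t - ep_start[e]
        w0 = _coal_wait(rng, k0, ep_size[e, 0], ep_grow[e, 0], dt_epoch)
        w1 = _coal_wait(rng, k1, ep_size[e, 1], ep_grow[e, 1], dt_epoch)
        w_rec = _exp_draw(rng, rho_site * tot_gaps)
        w_mut = _exp_draw(rng, theta_site * tot_asites)
        w_mig = _exp_draw(rng, ep_mig[e] * n_act)

        w = w0
        ev = 0
        if w1 < w:
            w = w1
            ev = 1
        if w_rec < w:
            w = w_rec
            ev = 2
        if w_mut < w:
            w = w_mut
            ev = 3
        if w_mig < w:
            w = w_mig
            ev = 4

        if t + w >= epoch_end:
            t = epoch_end
            e += 1
            if ep_merge[e] == 1:
                for i in range(n_act):
                    pop[act[i]] = 0
            continue
        t += w

        if ev == 0 or ev == 1:
            deme = ev
            # pick two distinct lineages in deme
            kd = k0 if deme == 0 else k1
            i1 = int(rng.random() * kd)
            i2 = int(rng.random() * (kd - 1))
            if i2 >= i1:
                i2 += 1
            ra = -1
            rb = -1
            cnt = 0
            for i in range(n_act):
                r = act[i]
                if pop[r] == deme:
                    if cnt == i1:
                        ra = r
                    if cnt == i2:
                        rb = r
                    cnt += 1
            # merge rb into ra
            tot_gaps -= (last[ra] - first[ra]) + (last[rb] - first[rb])
            tot_asites -= asites[ra] + asites[rb]
            new_first = -1
            new_last = -1
            new_asites = 0
            for s in range(L):
                m0 = anc0[ra, s] | anc0[rb, s]
                m1 = anc1[ra, s] | anc1[rb, s]
                if m0 == full0 and m1 == full1:
                    m0 = np.int64(0)
                    m1 = np.int64(0)
                anc0[ra, s] = m0
                anc1[ra, s] = m1
                if m0 != 0 or m1 != 0:
                    if new_first < 0:
                        new_first = s
                    new_last = s
                    new_asites += 1
            # clear rb
            for s in range(first[rb], last[rb] + 1):
                anc0[rb, s] = 0
                anc1[rb, s] = 0
            # remove rb from actives
            pi_b = pos_in_act[rb]
            lastr = act[n_act - 1]
            act[pi_b] = lastr
            pos_in_act[lastr] = pi_b
            n_act -= 1
            pos_in_act[rb] = -1
            free[n_free] = rb
            n_free += 1
            if new_asites == 0:
                # ra carries nothing; remove it too
                pi_a = pos_in_act[ra]
                lastr = act[n_act - 1]
                act[pi_a] = lastr
                pos_in_act[lastr] = pi_a
                n_act -= 1
                pos_in_act[ra] = -1
                free[n_free] = ra
                n_free += 1
                first[ra] = 0
                last[ra] = 0
                asites[ra] = 0
            else:
                first[ra] = new_first
                last[ra] = new_last
                asites[ra] = new_asites
                tot_gaps += new_last - new_first
                tot_asites += new_asites
        elif ev == 2:
            # recombination: pick lineage weighted by span gaps
            target = rng.random() * tot_gaps
            acc = 0.0
            r = act[0]
            for i in range(n_act):
                r = act[i]
                acc += last[r] - first[r]
                if acc > target:
                    break
            span = last[r] - first[r]
            if span <= 0:
                continue
            b = first[r] + int(rng.random() * span)  # break between b, b+1
            if n_free == 0:
                return mut_site[:n_mut], mut_m0[:n_mut], mut_m1[:n_mut], STATUS_LIN_OVERFLOW
            rn = free[n_free - 1]
            n_free -= 1
            # right part -> rn
            new_first_r = -1
            new_last_r = -1
            na_r = 0
            for s in range(b + 1, last[r] + 1):
                m0 = anc0[r, s]
                m1 = anc1[r, s]
                anc0[rn, s] = m0
                anc1[rn, s] = m1
                anc0[r, s] = 0
                anc1[r, s] = 0
                if m0 != 0 or m1 != 0:
                    if new_first_r < 0:
                        new_first_r = s
                    new_last_r = s
                    na_r += 1
            # left part remains in r
            new_last_l = -1
            na_l = 0
            new_first_l = -1
            for s in range(first[r], b + 1):
                if anc0[r, s] != 0 or anc1[r, s] != 0:
                    if new_first_l < 0:
                        new_first_l = s
                    new_last_l = s
                    na_l += 1
            tot_gaps -= span
            tot_asites -= asites[r]
            first[r] = new_first_l
            last[r] = new_last_l
            asites[r] = na_l
            first[rn] = new_first_r
            last[rn] = new_last_r
            asites[rn] = na_r
            pop[rn] = pop[r]
            tot_gaps += (new_last_l - new_first_l) + (new_last_r - new_first_r)
            tot_asites += na_l + na_r
            act[n_act] = rn
            pos_in_act[rn] = n_act
            n_act += 1
        elif ev == 3:
            # mutation: pick lineage weighted by ancestral sites, then a
            # uniform ancestral site within it
            target = rng.random() * tot_asites
            acc = 0.0
            r = act[0]
            for i in range(n_act):
                r = act[i]
                acc += asites[r]
                if acc > target:
                    break
            k = int(rng.random() * asites[r])
            cnt = 0
            site = first[r]
            for s in range(first[r], last[r] + 1):
                if anc0[r, s] != 0 or anc1[r, s] != 0:
                    if cnt == k:
                        site = s
                        break
                    cnt += 1
            if n_mut >= mut_cap:
                return mut_site[:n_mut], mut_m0[:n_mut], mut_m1[:n_mut], STATUS_MUT_OVERFLOW
            mut_site[n_mut] = site
            mut_m0[n_mut] = anc0[r, site]
            mut_m1[n_mut] = anc1[r, site]
            n_mut += 1
        else:
            # migration: uniform active lineage switches deme
            i = int(rng.random() * n_act)
            r = act[i]
            pop[r] = 1 - pop[r]

    return mut_site[:n_mut], mut_m0[:n_mut], mut_m1[:n_mut], STATUS_OK
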