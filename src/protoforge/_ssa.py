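"""Gillespie direct-method kernel (numba-compiled when available).

The kernel operates on flat arrays prepared by :mod:`protoforge.reactorsim`:
reaction channels (mass-action or mesoscopic enzymatic propensities) plus two
first-order transport channels per membrane-permeable species.  Mechanism
codes: 0 mass_action, 1 mm_uni, 2 ordered_bibi, 3 pingpong_bibi,
4 random_bibi.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn
        return wrap

STATUS_OK = 0
STATUS_MAX_STEPS = 1


@njit(cache=False)
def ssa_kernel(n0, t_end, grid, mech, kcat, km1, km2, kia, alpha, kmass,
               sub1, sub2, enz, inh1, inh2, stoich,
               trans_sp, trans_kin, trans_kout, nav, seed, max_steps):
    np.random.seed(seed)
    n = n0.copy()
    n_sp = n.shape[0]
    nr = mech.shape[0]
    nt = trans_sp.shape[0]
    out = np.zeros((grid.shape[0], n_sp), dtype=np.int64)
    a = np.zeros(nr + 2 * nt)
    t = 0.0
    gi = 0
    steps = 0
    status = STATUS_OK

    while True:
        for r in range(nr):
            if mech[r] == 0:
                if sub1[r] < 0:
                    av = kmass[r] * nav
                elif sub2[r] < 0:
                    av = kmass[r] * n[sub1[r]]
                else:
                    av = kmass[r] / nav * n[sub1[r]] * n[sub2[r]]
            else:
                e = 1.0 if enz[r] < 0 else n[enz[r]] / nav
                A = n[sub1[r]] / nav
                if mech[r] == 1:
                    av = kcat[r] * e * A / (km1[r] + A) * nav if A > 0 else 0.0
                else:
                    B = n[sub2[r]] / nav
                    if A <= 0.0 or B <= 0.0:
                        av = 0.0
                    else:
                        if mech[r] == 2:
                            denom = (kia[r] * km2[r] + km2[r] * A
                                     + km1[r] * B + A * B)
                        elif mech[r] == 3:
                            denom = km2[r] * A + km1[r] * B + A * B
                        else:
                            denom = (alpha[r] * km1[r] * km2[r] + km2[r] * A
                                     + km1[r] * B + A * B)
                        av = kcat[r] * e * A * B / denom * nav
            if inh1[r] >= 0 and n[inh1[r]] > 0:
                av = 0.0
            if inh2[r] >= 0 and n[inh2[r]] > 0:
                av = 0.0
            a[r] = av
        for k in range(nt):
            a[nr + 2 * k] = trans_kin[k]
            a[nr + 2 * k + 1] = trans_kout[k] * n[trans_sp[k]]

        a0 = 0.0
        for idx in range(a.shape[0]):
            a0 += a[idx]
        if a0 <= 0.0:
            break

        tau = -np.log(np.random.random()) / a0
        tn = t + tau
        while gi < grid.shape[0] and grid[gi] < tn:
            for s in range(n_sp):
                out[gi, s] = n[s]
            gi += 1
        if tn > t_end or gi >= grid.shape[0]:
            break
        t = tn

        thr = np.random.random() * a0
        acc = 0.0
        ch = a.shape[0] - 1
        for idx in range(a.shape[0]):
            acc += a[idx]
            if thr <= acc:
                ch = idx
                break
        if ch < nr:
            for s in range(n_sp):
                n[s] += stoich[ch, s]
        else:
            k = (ch - nr) // 2
            if (ch - nr) % 2 == 0:
                n[trans_sp[k]] += 1
            else:
                n[trans_sp[k]] -= 1

        steps += 1
        if steps >= max_steps:
            status = STATUS_MAX_STEPS
            break

    while gi < grid.shape[0]:
        for s in range(n_sp):
            out[gi, s] = n[s]
        gi += 1
    return out, steps, status
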