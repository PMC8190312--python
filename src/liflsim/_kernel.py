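"""Compiled event-loop kernel (numba).

Implements exactly the same event semantics as the pure-Python backend in
:mod:`liflsim.engine` — (time, kind, sequence) tie-breaking, lazy
invalidation of pending firing events, equal-delay delivery batches — for
static-weight, non-bursting networks, where per-event Python overhead would
dominate.  The binary heap and the append-only logs are plain arrays grown
by doubling.  All state mutation happens in-place on the caller's arrays.

Event kinds: 0 = firing, 1 = burning batch; external input deliveries are
merged from a pre-sorted stream and lose ties against both (kind 2).
"""

import numpy as np
from numba import njit

F = 0
B = 1

__all__ = ["run_kernel"]


@njit(cache=True, inline="always")
def _before(t1, k1, s1, t2, k2, s2):
    if t1 != t2:
        return t1 < t2
    if k1 != k2:
        return k1 < k2
    return s1 < s2


@njit(cache=True)
def _push(ht, hk, hs, ha, hb, hn, t, k, s, a, b):
    cap = ht.shape[0]
    if hn >= cap:
        nc = cap * 2
        t2 = np.empty(nc, np.float64); t2[:hn] = ht; ht = t2
        k2 = np.empty(nc, np.uint8); k2[:hn] = hk; hk = k2
        s2 = np.empty(nc, np.int64); s2[:hn] = hs; hs = s2
        a2 = np.empty(nc, np.int64); a2[:hn] = ha; ha = a2
        b2 = np.empty(nc, np.int64); b2[:hn] = hb; hb = b2
    i = hn
    ht[i] = t; hk[i] = k; hs[i] = s; ha[i] = a; hb[i] = b
    while i > 0:
        p = (i - 1) >> 1
        if _before(ht[i], hk[i], hs[i], ht[p], hk[p], hs[p]):
            ht[i], ht[p] = ht[p], ht[i]
            hk[i], hk[p] = hk[p], hk[i]
            hs[i], hs[p] = hs[p], hs[i]
            ha[i], ha[p] = ha[p], ha[i]
            hb[i], hb[p] = hb[p], hb[i]
            i = p
        else:
            break
    return ht, hk, hs, ha, hb, hn + 1


@njit(cache=True)
def _pop(ht, hk, hs, ha, hb, hn):
    t = ht[0]; k = hk[0]; s = hs[0]; a = ha[0]; b = hb[0]
    hn -= 1
    if hn > 0:
        ht[0] = ht[hn]; hk[0] = hk[hn]; hs[0] = hs[hn]
        ha[0] = ha[hn]; hb[0] = hb[hn]
        i = 0
        while True:
            l = 2 * i + 1
            if l >= hn:
                break
            m = l
            r = l + 1
            if r < hn and _before(ht[r], hk[r], hs[r], ht[l], hk[l], hs[l]):
                m = r
            if _before(ht[m], hk[m], hs[m], ht[i], hk[i], hs[i]):
                ht[i], ht[m] = ht[m], ht[i]
                hk[i], hk[m] = hk[m], hk[i]
                hs[i], hs[m] = hs[m], hs[i]
                ha[i], ha[m] = ha[m], ha[i]
                hb[i], hb[m] = hb[m], hb[i]
                i = m
            else:
                break
    return t, k, s, a, b, hn


@njit(cache=True)
def _appf(arr, n, v):
    if n >= arr.shape[0]:
        a2 = np.empty(arr.shape[0] * 2, arr.dtype)
        a2[:n] = arr
        arr = a2
    arr[n] = v
    return arr


@njit(cache=True)
def _do_fire(t, j, S, t_last, mode, refr, fire_ver, t_arp,
             rptr, run_delay,
             ht, hk, hs, ha, hb, hn, seq,
             ft, fn, nf, counts):
    fire_ver[j] += 1
    S[j] = 0.0
    t_last[j] = t
    mode[j] = 2
    refr[j] = t + t_arp[j]
    counts[0] += 1
    ft = _appf(ft, nf, t)
    fn = _appf(fn, nf, j)
    nf += 1
    for r in range(rptr[j], rptr[j + 1]):
        ht, hk, hs, ha, hb, hn = _push(ht, hk, hs, ha, hb, hn,
                                       t + run_delay[r], B, seq, r, 0)
        seq += 1
    return ht, hk, hs, ha, hb, hn, seq, ft, fn, nf


@njit(cache=True)
def _deliver(t, j, amp, S, t_last, mode, refr, fire_ver,
             a, b, c, Dexc, Dinh, expdec, latency,
             ht, hk, hs, ha, hb, hn, seq, counts):
    if mode[j] == 2:
        if t < refr[j]:
            counts[3] += 1
            return ht, hk, hs, ha, hb, hn, seq, False
        mode[j] = 0
        S[j] = 0.0
        t_last[j] = refr[j]
    dt = t - t_last[j]
    if dt < 0.0:
        dt = 0.0
    was_active = mode[j] == 1
    if was_active:
        Tr = 0.0
        if latency[j] == 1:
            x = S[j] - 1.0
            den = a[j] - x * dt
            if den > 0.0:
                Tr = x * x * dt / den
        S[j] = S[j] + Tr + amp
    else:
        if S[j] > 0.0 and dt > 0.0:
            D = Dinh[j] if amp < 0.0 else Dexc[j]
            if expdec[j] == 1:
                Tl = S[j] * (-np.expm1(-dt / D))
            else:
                Tl = dt / D
                if Tl > S[j]:
                    Tl = S[j]
            S[j] = S[j] - Tl
        S[j] = S[j] + amp
    t_last[j] = t
    if S[j] < 0.0:
        S[j] = 0.0
    Sth = 1.0 + c[j]
    Smax = 1.0 + a[j] / b[j] if b[j] > 0.0 else np.inf
    if S[j] >= Smax or (latency[j] == 0 and S[j] >= Sth):
        mode[j] = 1
        return ht, hk, hs, ha, hb, hn, seq, True
    if S[j] >= Sth:
        mode[j] = 1
        fire_ver[j] += 1
        tf = a[j] / (S[j] - 1.0) - b[j]
        ht, hk, hs, ha, hb, hn = _push(ht, hk, hs, ha, hb, hn,
                                       t + tf, F, seq, j, fire_ver[j])
        seq += 1
        return ht, hk, hs, ha, hb, hn, seq, False
    if was_active:
        fire_ver[j] += 1
    mode[j] = 0
    return ht, hk, hs, ha, hb, hn, seq, False


@njit(cache=True)
def run_kernel(post, amp_syn,
               run_start, run_end, run_delay, run_neuron, rptr,
               a, b, c, Dexc, Dinh, t_arp, expdec, latency,
               S0, t_stop,
               in_time, in_target, in_amp, record_burn):
    n = a.shape[0]
    S = np.zeros(n)
    t_last = np.zeros(n)
    mode = np.zeros(n, np.uint8)
    refr = np.zeros(n)
    fire_ver = np.zeros(n, np.int64)

    cap = 1 << 12
    ht = np.empty(cap)
    hk = np.empty(cap, np.uint8)
    hs = np.empty(cap, np.int64)
    ha = np.empty(cap, np.int64)
    hb = np.empty(cap, np.int64)
    hn = 0
    seq = 0

    ft = np.empty(1 << 12)
    fn = np.empty(1 << 12, np.int64)
    nf = 0
    bcap = 1 << 12 if record_burn == 1 else 1
    bt = np.empty(bcap)
    bpost = np.empty(bcap, np.int64)
    bpre = np.empty(bcap, np.int64)
    btf = np.empty(bcap)
    bw = np.empty(bcap)
    nb = 0

    counts = np.zeros(5, np.int64)  # fire, burn, input, discarded, fault

    for j in range(n):
        if S0[j] <= 0.0:
            continue
        S[j] = S0[j]
        Sth = 1.0 + c[j]
        Smax = 1.0 + a[j] / b[j] if b[j] > 0.0 else np.inf
        if S[j] >= Sth:
            mode[j] = 1
            fire_ver[j] = 1
            if S[j] >= Smax or latency[j] == 0:
                sched = 0.0
            else:
                sched = a[j] / (S[j] - 1.0) - b[j]
            ht, hk, hs, ha, hb, hn = _push(ht, hk, hs, ha, hb, hn,
                                           sched, F, seq, j, 1)
            seq += 1

    n_in = in_time.shape[0]
    in_ptr = 0
    current = 0.0
    while True:
        take_heap = hn > 0 and (in_ptr >= n_in or ht[0] <= in_time[in_ptr])
        if take_heap:
            t, kind, _s, af, bf, hn = _pop(ht, hk, hs, ha, hb, hn)
        elif in_ptr < n_in:
            t = in_time[in_ptr]
            kind = np.uint8(2)
            af = np.int64(0)
            bf = np.int64(0)
        else:
            break
        if t >= t_stop:
            break
        if t < current:
            counts[4] = 1
            break
        current = t

        if kind == F:
            j = af
            if mode[j] == 1 and bf == fire_ver[j]:
                ht, hk, hs, ha, hb, hn, seq, ft, fn, nf = _do_fire(
                    t, j, S, t_last, mode, refr, fire_ver, t_arp,
                    rptr, run_delay, ht, hk, hs, ha, hb, hn, seq,
                    ft, fn, nf, counts)
        elif kind == B:
            r = af
            t_emit = t - run_delay[r]
            i_pre = run_neuron[r]
            for s_id in range(run_start[r], run_end[r]):
                jj = post[s_id]
                amp = amp_syn[s_id]
                counts[1] += 1
                if record_burn == 1:
                    bt = _appf(bt, nb, t)
                    bpost = _appf(bpost, nb, jj)
                    bpre = _appf(bpre, nb, i_pre)
                    btf = _appf(btf, nb, t_emit)
                    bw = _appf(bw, nb, amp)
                    nb += 1
                ht, hk, hs, ha, hb, hn, seq, fire_now = _deliver(
                    t, jj, amp, S, t_last, mode, refr, fire_ver,
                    a, b, c, Dexc, Dinh, expdec, latency,
                    ht, hk, hs, ha, hb, hn, seq, counts)
                if fire_now:
                    ht, hk, hs, ha, hb, hn, seq, ft, fn, nf = _do_fire(
                        t, jj, S, t_last, mode, refr, fire_ver, t_arp,
                        rptr, run_delay, ht, hk, hs, ha, hb, hn, seq,
                        ft, fn, nf, counts)
        else:
            jj = in_target[in_ptr]
            amp = in_amp[in_ptr]
            counts[2] += 1
            if record_burn == 1:
                bt = _appf(bt, nb, t)
                bpost = _appf(bpost, nb, jj)
                bpre = _appf(bpre, nb, -1)
                btf = _appf(btf, nb, t)
                bw = _appf(bw, nb, amp)
                nb += 1
            in_ptr += 1
            ht, hk, hs, ha, hb, hn, seq, fire_now = _deliver(
                t, jj, amp, S, t_last, mode, refr, fire_ver,
                a, b, c, Dexc, Dinh, expdec, latency,
                ht, hk, hs, ha, hb, hn, seq, counts)
            if fire_now:
                ht, hk, hs, ha, hb, hn, seq, ft, fn, nf = _do_fire(
                    t, jj, S, t_last, mode, refr, fire_ver, t_arp,
                    rptr, run_delay, ht, hk, hs, ha, hb, hn, seq,
                    ft, fn, nf, counts)

    return (ft[:nf].copy(), fn[:nf].copy(),
            bt[:nb].copy(), bpost[:nb].copy(), bpre[:nb].copy(),
            btf[:nb].copy(), bw[:nb].copy(), counts)
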