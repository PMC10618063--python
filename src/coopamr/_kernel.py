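"""Event-loop kernel of the exact stochastic simulation.

The composite process has five reaction channels — R birth, S birth,
R death, S death, environment flip — all with rates constant between
events, so the standard Gillespie algorithm samples the joint master
equation exactly.  The loop is JIT-compiled with numba when available and
falls back to plain Python otherwise (same code path, same random stream).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def gillespie_core(
    nr,
    ns,
    xi,
    s,
    a,
    nth,
    kplus,
    kminus,
    nu_plus,
    nu_minus,
    horizon,
    seed,
    stop_at_absorption,
    max_events,
    record_interval,
    rec_t,
    rec_nr,
    rec_ns,
    rec_xi,
):
    """Run one replicate from (nr, ns, xi) at t=0 until absorption/horizon.

    Recording: if ``rec_t`` is non-empty the initial state, every switching
    event, the absorption event and (if ``record_interval`` > 0) the first
    event past each grid point are stored; ``record_interval == 0`` stores
    every event.  Returns
    (t, nr, ns, xi, absorb_time, absorb_nr, absorb_ns, n_events, truncated, n_rec).
    """
    np.random.seed(seed)
    t = 0.0
    fr = 1.0 - s
    absorb_time = -1.0
    absorb_nr = -1
    absorb_ns = -1
    rec_cap = rec_t.shape[0]
    n_rec = 0
    if rec_cap > 0:
        rec_t[0] = t
        rec_nr[0] = nr
        rec_ns[0] = ns
        rec_xi[0] = xi
        n_rec = 1
    next_rec = record_interval
    n_events = 0
    truncated = False

    if nr == 0 or ns == 0:
        absorb_time = 0.0
        absorb_nr = nr
        absorb_ns = ns
        if stop_at_absorption or nr + ns == 0:
            return t, nr, ns, xi, absorb_time, absorb_nr, absorb_ns, n_events, truncated, n_rec

    while t < horizon:
        n = nr + ns
        if n == 0:
            break
        if xi == 1:
            K = kplus
            sw = nu_plus
        else:
            K = kminus
            sw = nu_minus
        if nr >= nth:
            fs = 1.0
        else:
            fs = 1.0 - a
        fbar = (fr * nr + fs * ns) / n
        trp = fr / fbar * nr
        tsp = fs / fbar * ns
        percap_death = n / K
        trm = percap_death * nr
        tsm = percap_death * ns
        total = trp + tsp + trm + tsm + sw
        dt = -np.log(1.0 - np.random.random()) / total
        if t + dt > horizon:
            t = horizon
            break
        t += dt
        u = np.random.random() * total
        is_switch = False
        if u < trp:
            nr += 1
        elif u < trp + tsp:
            ns += 1
        elif u < trp + tsp + trm:
            nr -= 1
        elif u < trp + tsp + trm + tsm:
            ns -= 1
        else:
            xi = -xi
            is_switch = True
        n_events += 1

        hit_boundary = (nr == 0 or ns == 0) and absorb_time < 0.0
        if rec_cap > 0 and n_rec < rec_cap:
            take = is_switch or hit_boundary or record_interval == 0.0
            if record_interval > 0.0 and t >= next_rec:
                take = True
                while next_rec <= t:
                    next_rec += record_interval
            if take:
                rec_t[n_rec] = t
                rec_nr[n_rec] = nr
                rec_ns[n_rec] = ns
                rec_xi[n_rec] = xi
                n_rec += 1

        if hit_boundary:
            absorb_time = t
            absorb_nr = nr
            absorb_ns = ns
            if stop_at_absorption or nr + ns == 0:
                break
        elif nr + ns == 0:
            break
        if n_events >= max_events:
            truncated = True
            break

    return t, nr, ns, xi, absorb_time, absorb_nr, absorb_ns, n_events, truncated, n_rec
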