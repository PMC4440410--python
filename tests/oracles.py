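"""Independent reference implementations used only to check the package.

These deliberately use the most literal formulation available (plain
loops, pair counting, full enumeration) and never call the code paths
they verify.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def brute_force_decode(segments, omega_runs, config):
    """Minimum-penalty labeling by literal enumeration of all 2**k
    patterns, with the decoder's published tie-break order.

    ``segments`` is a list of objects with duration_s and after_turn;
    ``omega_runs`` is a list of (start, stop, next_segment_index).
    Returns (labels, penalty).
    """
    k = len(segments)
    best_key = None
    best = None
    for labels in product(("forward", "backward"), repeat=k):
        fwd = bwd = 0.0
        long_runs = 0
        noflip = 0
        nback = 0
        run_label = None
        run_dur = 0.0
        for j in range(k):
            lab = labels[j]
            dur = segments[j].duration_s
            if lab == "forward":
                fwd += dur
            else:
                bwd += dur
            chained = j > 0 and segments[j].after_turn
            if chained and labels[j] == labels[j - 1]:
                noflip += 1
            if chained and run_label == lab:
                run_dur += dur
            else:
                if run_label == "backward" and run_dur > config.long_run_s:
                    long_runs += 1
                run_label, run_dur = lab, dur
                if lab == "backward":
                    nback += 1
        if run_label == "backward" and run_dur > config.long_run_s:
            long_runs += 1
        omega_pen = sum(
            1 for (_, _, nxt) in omega_runs if nxt is not None and labels[nxt] != "forward"
        )
        pen = (
            config.w_long_nonforward * long_runs
            + config.w_omega_not_forward * omega_pen
            + config.w_time_balance * (1 if fwd <= bwd else 0)
        )
        # residual ties resolve by enumeration order, forward first
        order = tuple(0 if lab == "forward" else 1 for lab in labels)
        key = (pen, noflip, -fwd, nback, order)
        if best_key is None or key < best_key:
            best_key, best = key, (labels, pen)
    return best


def mann_whitney_enumeration(a, b):
    """Two-sided exact Mann-Whitney p by enumerating group assignments,
    with U defined by pair counting (ties count 1/2)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)

    def u_of(indices):
        ga = [pooled[i] for i in indices]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(indices)]
        u = 0.0
        for x in ga:
            for y in gb:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    mu = n1 * (len(pooled) - n1) / 2.0
    u_obs = u_of(tuple(range(n1)))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def naive_intersection(t1, t2, t3, q_cut=0.05):
    """Literal re-computation of the three-way DE set logic from raw
    DataFrames (gene_id, log2fc, q_value)."""

    def sig(df):
        return {g for g, q in zip(df["gene_id"], df["q_value"]) if q < q_cut}

    s1, s2, s3 = sig(t1), sig(t2), sig(t3)
    s12 = {g for g in s1 if g in s2}
    final = {g for g in s12 if g not in s3}
    sign1 = dict(zip(t1["gene_id"], np.sign(t1["log2fc"])))
    sign2 = dict(zip(t2["gene_id"], np.sign(t2["log2fc"])))
    conc = {g for g in final if sign1[g] == sign2[g] and sign1[g] != 0}
    return len(s1), len(s12), len(final), len(conc)
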