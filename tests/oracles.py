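"""Independent reference implementations used only to check the package.

These deliberately avoid the package's dynamic-programming and scipy code
paths: HMM scores come from explicit enumeration of every state path, and
rank-sum p-values from enumeration of every rank assignment.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from kinomeprofiler.profile_hmm import encode_sequence


def _emitters(hmm):
    me, ie, null = hmm.match_emissions, hmm.insert_emissions, hmm.null_model

    def emit_m(j, x):
        return me[j - 1, x] / null[x] if x < 20 else 1.0

    def emit_i(j, x):
        return ie[j, x] / null[x] if x < 20 else 1.0

    return emit_m, emit_i


def enumerate_glocal(hmm, seq: str) -> list[float]:
    """Odds weights of every complete begin-to-end path (glocal mode)."""
    idx = encode_sequence(seq)
    L, t = hmm.length, hmm.transitions
    emit_m, emit_i = _emitters(hmm)
    MM, MI, MD, IM, II, DM, DD = range(7)
    weights: list[float] = []

    def rec(state, node, pos, w):
        if node == L:
            if pos == len(idx):
                exit_p = {"M": t[L, MM], "I": t[L, IM], "D": t[L, DM]}[state]
                weights.append(w * exit_p)
            if state == "M" and pos < len(idx):
                rec("I", L, pos + 1, w * t[L, MI] * emit_i(L, idx[pos]))
            if state == "I" and pos < len(idx):
                rec("I", L, pos + 1, w * t[L, II] * emit_i(L, idx[pos]))
            return
        k = node
        if state == "M":
            if pos < len(idx):
                rec("M", k + 1, pos + 1, w * t[k, MM] * emit_m(k + 1, idx[pos]))
                rec("I", k, pos + 1, w * t[k, MI] * emit_i(k, idx[pos]))
            rec("D", k + 1, pos, w * t[k, MD])
        elif state == "I":
            if pos < len(idx):
                rec("M", k + 1, pos + 1, w * t[k, IM] * emit_m(k + 1, idx[pos]))
                rec("I", k, pos + 1, w * t[k, II] * emit_i(k, idx[pos]))
        else:
            if pos < len(idx):
                rec("M", k + 1, pos + 1, w * t[k, DM] * emit_m(k + 1, idx[pos]))
            rec("D", k + 1, pos, w * t[k, DD])

    rec("M", 0, 0, 1.0)
    return weights


def enumerate_local(hmm, seq: str) -> list[float]:
    """Odds weights of every local path: uniform 1/L entry into any match
    state, free exit from any match state, flanking residues cost-free."""
    idx = encode_sequence(seq)
    L, t = hmm.length, hmm.transitions
    emit_m, emit_i = _emitters(hmm)
    MM, MI, MD, IM, II, DM, DD = range(7)
    weights: list[float] = []

    def rec(state, node, pos, w):
        if state == "M":
            weights.append(w)  # a path may stop at any match state
        k = node
        if k == L:
            if state in ("M", "I") and pos < len(idx):
                p = t[L, MI] if state == "M" else t[L, II]
                rec("I", L, pos + 1, w * p * emit_i(L, idx[pos]))
            return
        if state == "M":
            if pos < len(idx):
                rec("M", k + 1, pos + 1, w * t[k, MM] * emit_m(k + 1, idx[pos]))
                rec("I", k, pos + 1, w * t[k, MI] * emit_i(k, idx[pos]))
            rec("D", k + 1, pos, w * t[k, MD])
        elif state == "I":
            if pos < len(idx):
                rec("M", k + 1, pos + 1, w * t[k, IM] * emit_m(k + 1, idx[pos]))
                rec("I", k, pos + 1, w * t[k, II] * emit_i(k, idx[pos]))
        else:
            if pos < len(idx):
                rec("M", k + 1, pos + 1, w * t[k, DM] * emit_m(k + 1, idx[pos]))
            rec("D", k + 1, pos, w * t[k, DD])

    for start in range(len(idx)):
        for j0 in range(1, L + 1):
            rec("M", j0, start + 1, (1.0 / L) * emit_m(j0, idx[start]))
    return weights


def enum_bits(weights: list[float], agg) -> float:
    if not weights:
        return -math.inf
    return math.log2(agg(weights))


def wilcoxon_exact_p(x, y) -> tuple[float, float]:
    """(U statistic of x, two-sided exact p) by enumerating every way the
    pooled ranks can be split between the samples (no ties allowed)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n + m, "oracle requires untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in combinations(range(1, n + m + 1), n):
        us.append(sum(combo) - n * (n + 1) / 2)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))
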