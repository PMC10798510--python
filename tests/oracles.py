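"""Independent brute-force oracles used to pin down the engine implementations.

Everything here is deliberately written from first principles — explicit
branch/path enumeration and plain-loop algorithms — so that agreement with the
package is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tree_branch_enumeration(p_comp: float, p_death_comp: float, p_death_nocomp: float):
    """Enumerate the four leaves of the 30-day tree.

    Returns (p_alive_nocomp, p_alive_comp, p_dead30) by summing leaf
    probabilities explicitly.
    """
    leaves = []
    for comp in (False, True):
        p_branch = p_comp if comp else 1.0 - p_comp
        p_die = p_death_comp if comp else p_death_nocomp
        for dead in (False, True):
            p_leaf = p_branch * (p_die if dead else 1.0 - p_die)
            leaves.append((comp, dead, p_leaf))
    p_dead = sum(p for _, dead, p in leaves if dead)
    p_alive_comp = sum(p for comp, dead, p in leaves if comp and not dead)
    p_alive_nocomp = sum(p for comp, dead, p in leaves if not comp and not dead)
    return p_alive_nocomp, p_alive_comp, p_dead


def markov_path_enumeration(
    init: tuple[float, float, float],
    death_probs: list[float],
    p_comp: float,
    *,
    accrual: str = "start",
    utilities: list[float] | None = None,
    discount_health: float = 0.0,
    discount_cost: float = 0.0,
    per_alive_cost: float = 0.0,
    incident_cost: float = 0.0,
    comp_state_cost: float = 0.0,
):
    """Expected discounted (LY, QALY, cost) of the Markov phase by summing over
    every state path explicitly.

    ``death_probs[k]`` is the death probability of cycle k+1; ``utilities[k]``
    the utility weight of cycle k+1 (defaults to 1).  States: 0 = alive no
    complication, 1 = alive post-complication, 2 = dead.
    """
    n = len(death_probs)
    utilities = utilities if utilities is not None else [1.0] * n

    def trans(cycle_idx: int, s: int, s2: int) -> float:
        q = death_probs[cycle_idx]
        row = {
            0: {0: (1 - q) * (1 - p_comp), 1: (1 - q) * p_comp, 2: q},
            1: {0: 0.0, 1: 1 - q, 2: q},
            2: {0: 0.0, 1: 0.0, 2: 1.0},
        }
        return row[s][s2]

    ly = qaly = cost = 0.0
    for s0, p0 in zip((0, 1, 2), init):
        if p0 == 0.0:
            continue
        for path in itertools.product((0, 1, 2), repeat=n):
            p_path = p0
            prev = s0
            for k, s in enumerate(path):
                p_path *= trans(k, prev, s)
                prev = s
            if p_path == 0.0:
                continue
            prev = s0
            for k, s in enumerate(path):
                cycle = k + 1
                if accrual == "start":
                    occ_alive = 1.0 if prev != 2 else 0.0
                    occ_comp = 1.0 if prev == 1 else 0.0
                elif accrual == "end":
                    occ_alive = 1.0 if s != 2 else 0.0
                    occ_comp = 1.0 if s == 1 else 0.0
                else:  # half
                    occ_alive = 0.5 * ((prev != 2) + (s != 2))
                    occ_comp = 0.5 * ((prev == 1) + (s == 1))
                incident = 1.0 if (prev == 0 and s == 1) else 0.0
                dh = (1.0 + discount_health) ** cycle
                dc = (1.0 + discount_cost) ** cycle
                ly += p_path * occ_alive / dh
                qaly += p_path * occ_alive * utilities[k] / dh
                c = (
                    occ_alive * per_alive_cost
                    + incident * incident_cost
                    + occ_comp * comp_state_cost
                )
                cost += p_path * c / dc
                prev = s
    return ly, qaly, cost


def dl_pool_bruteforce(log_rrs, ses):
    """Independent DerSimonian–Laird pooling (numpy, textbook formulas).

    Returns (pooled_log_rr, tau2, q_stat, ci_low_log, ci_high_log).
    """
    y = np.asarray(log_rrs, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    if k > 1:
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(np.sqrt(1.0 / np.sum(w_re)))
    z = 1.959963984540054
    return mu, tau2, q, mu - z * se, mu + z * se


def greedy_match_bruteforce(treated: dict[int, float], controls: dict[int, float]):
    """Greedy 1:1 matching, independently implemented with explicit scans.

    Treated processed in descending score (ties by ascending id); each scans
    every unused control for the minimum |score difference| (ties by lower
    control id).  Returns ([(tid, cid, diff)], [unmatched tids]).
    """
    order = sorted(treated.items(), key=lambda kv: (-kv[1], kv[0]))
    used: set[int] = set()
    pairs = []
    unmatched = []
    for tid, score in order:
        best_cid = None
        best_diff = math.inf
        for cid in sorted(controls):
            if cid in used:
                continue
            d = abs(controls[cid] - score)
            if d < best_diff:
                best_diff = d
                best_cid = cid
        if best_cid is None:
            unmatched.append(tid)
        else:
            used.add(best_cid)
            pairs.append((tid, best_cid, best_diff))
    return pairs, unmatched
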