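"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: probabilities,
entropies and flux-mode supports are recomputed with plain Python loops,
``itertools`` enumeration, ``math.log2`` and (for flux feasibility) a linear
program, so that agreement with the package is a genuine two-route check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------- information
def combo_probability_per_sample(probs_subset, o):
    """p_s(o) for every sample via an explicit loop. probs_subset is
    (n_samples, d, M); o is a 1-based bin tuple of length d."""
    n = probs_subset.shape[0]
    out = []
    for s in range(n):
        p = 1.0
        for j, b in enumerate(o):
            p *= probs_subset[s, j, b - 1]
        out.append(p)
    return out


def mutual_information_entropy_route(probs_subset, is_control, M):
    """I(B;C) computed as H(C) - H(C|B) from explicit joint probabilities —
    a different algebraic route than the per-combination decomposition."""
    n, d, _ = probs_subset.shape
    is_control = list(is_control)
    n_c = sum(is_control)
    n_v = n - n_c
    p_c, p_v = n_c / n, n_v / n
    H_C = 0.0
    for p in (p_c, p_v):
        if p > 0:
            H_C -= p * math.log2(p)
    H_C_given_B = 0.0
    for o in itertools.product(range(1, M + 1), repeat=d):
        ps = combo_probability_per_sample(probs_subset, o)
        p_o = sum(ps) / n
        if p_o <= 0:
            continue
        for cls_mask, prior in ((is_control, p_c), (list(~np.asarray(is_control)), p_v)):
            cls_n = sum(cls_mask)
            if cls_n == 0:
                continue
            p_o_given = sum(p for p, m in zip(ps, cls_mask) if m) / cls_n
            joint = prior * p_o_given
            if joint > 0:
                H_C_given_B -= joint * math.log2(joint / p_o)
    return H_C - H_C_given_B


def full_engine_reference(probs_subset, is_control, M):
    """Every quantity of the per-subset engine, by enumeration.

    Returns dict with keys: combos (list of tuples), p_o, p_o_control,
    p_o_variable, term_control, term_variable, mi, I, assigned,
    expected_bins {class: tuple}.
    """
    n, d, _ = probs_subset.shape
    is_control = np.asarray(is_control, bool)
    n_c = int(is_control.sum())
    n_v = n - n_c
    prior_c, prior_v = n_c / n, n_v / n
    res = {
        "combos": [], "p_o": [], "p_o_control": [], "p_o_variable": [],
        "term_control": [], "term_variable": [], "mi": [], "assigned": [],
    }
    for o in itertools.product(range(1, M + 1), repeat=d):
        ps = combo_probability_per_sample(probs_subset, o)
        p_oc = sum(p for p, m in zip(ps, is_control) if m) / n_c
        p_ov = sum(p for p, m in zip(ps, is_control) if not m) / n_v
        p_o = prior_c * p_oc + prior_v * p_ov
        t_c = prior_c * p_oc * math.log2(p_oc / p_o) if p_oc > 0 else 0.0
        t_v = prior_v * p_ov * math.log2(p_ov / p_o) if p_ov > 0 else 0.0
        res["combos"].append(o)
        res["p_o"].append(p_o)
        res["p_o_control"].append(p_oc)
        res["p_o_variable"].append(p_ov)
        res["term_control"].append(t_c)
        res["term_variable"].append(t_v)
        res["mi"].append(t_c + t_v)
        res["assigned"].append("variable" if t_v > t_c else "control")
    res["I"] = sum(res["mi"])
    res["expected_bins"] = {}
    for cls in ("control", "variable"):
        idx = [i for i, a in enumerate(res["assigned"]) if a == cls]
        tot = sum(res["mi"][i] for i in idx)
        if tot <= 0:
            mid = math.floor((M + 1) / 2 + 0.5)
            res["expected_bins"][cls] = tuple([mid] * d)
        else:
            bins = []
            for j in range(d):
                avg = sum(res["mi"][i] / tot * res["combos"][i][j] for i in idx)
                bins.append(math.floor(avg + 0.5))  # bins positive: half away = half up
            res["expected_bins"][cls] = tuple(bins)
    return res


# --------------------------------------------------------------- flux modes
def brute_force_efm_supports(network):
    """All elementary flux mode supports of an irreversible network, by
    testing every reaction subset for steady-state feasibility and support
    minimality with a linear program."""
    assert not any(r.reversible for r in network.reactions), "oracle is irreversible-only"
    S = np.array(
        [[float(x) for x in row] for row in network.stoichiometric_matrix()]
    )
    r = S.shape[1]
    ids = [rxn.id for rxn in network.reactions]

    def balanced(support):
        # necessary condition for a strictly positive steady-state flux:
        # every internal metabolite touched by the support has both a
        # producer and a consumer within it (cheap pre-filter before the LP)
        cols = S[:, sorted(support)]
        touched = np.abs(cols).sum(axis=1) > 0
        has_pos = (cols > 0).any(axis=1)
        has_neg = (cols < 0).any(axis=1)
        return bool(((has_pos & has_neg) | ~touched).all())

    def feasible(support):
        if not support or not balanced(support):
            return False
        bounds = [(1, None) if j in support else (0, 0) for j in range(r)]
        res = linprog(c=np.zeros(r), A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        return res.status == 0

    feasible_supports = [
        frozenset(sub)
        for size in range(1, r + 1)
        for sub in itertools.combinations(range(r), size)
        if feasible(frozenset(sub))
    ]
    minimal = [
        s for s in feasible_supports
        if not any(t < s for t in feasible_supports)
    ]
    return {frozenset(ids[j] for j in s) for s in minimal}


def hard_histogram_bins(column, M):
    """Equal-width hard histogram over [min, max]: boundary values fall in the
    higher bin except the maximum, which falls in bin M. 1-based."""
    vmin, vmax = min(column), max(column)
    if vmax == vmin:
        return [1] * len(column)
    out = []
    for v in column:
        z = (v - vmin) / (vmax - vmin) * M
        b = int(math.floor(z)) + 1
        out.append(min(b, M))
    return out
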