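"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they are checking: requirement
trees are evaluated by direct recursion over Python builtins, presence
calls by exhaustive simple-path enumeration, AUC by pairwise concordance
counting, and absorption distributions by Monte-Carlo random walks.
"""

from statistics import fmean

import numpy as np

from glycopath.pathway_model import And, Gene, Or


def brute_force_score(req, tpm, or_rule="max", and_rule="min"):
    """Direct recursive evaluation of a requirement tree."""
    rules = {"max": max, "min": min, "mean": fmean}
    if isinstance(req, Gene):
        return float(tpm.get(req.symbol, 0.0))
    values = [brute_force_score(c, tpm, or_rule, and_rule) for c in req.children]
    if isinstance(req, Or):
        return float(rules[or_rule](values))
    assert isinstance(req, And)
    return float(rules[and_rule](values))


def leaf_values(req, tpm):
    if isinstance(req, Gene):
        return [float(tpm.get(req.symbol, 0.0))]
    out = []
    for c in req.children:
        out.extend(leaf_values(c, tpm))
    return out


def presence_by_path_enumeration(pathway, states):
    """Presence calls from exhaustive enumeration of all simple paths.

    Path quality = min over its reactions of (expressed=2, limited=1,
    unknown=1, absent=0); a structure's call is the max quality over every
    simple root-to-structure path.  Exponential, for tiny pathways only.
    """
    rank = {"expressed": 2, "limited": 1, "unknown": 1, "absent": 0}
    out_edges = {}
    for r in pathway.reactions.values():
        out_edges.setdefault(r.substrate_id, []).append(
            (r.product_id, rank[states[r.id].klass])
        )
    best = {sid: 0 for sid in pathway.structures}
    roots = [sid for sid, s in pathway.structures.items() if s.is_root]
    for root in roots:
        best[root] = 2
        stack = [(root, 2, {root})]
        while stack:
            node, quality, seen = stack.pop()
            for nxt, edge_rank in out_edges.get(node, []):
                if nxt in seen:
                    continue
                q = min(quality, edge_rank)
                if q > best[nxt]:
                    best[nxt] = q
                stack.append((nxt, q, seen | {nxt}))
    call = {2: "present", 1: "rare", 0: "absent"}
    return {sid: call[best[sid]] for sid in pathway.structures}


def mann_whitney_auc(scores, labels):
    """Pairwise concordance: (#(pos > neg) + 0.5 #ties) / (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    gt = sum(1 for p in pos for n in neg if p > n)
    eq = sum(1 for p in pos for n in neg if p == n)
    return (2 * gt + eq) / (2 * len(pos) * len(neg))


def monte_carlo_absorption(model, n_walks, seed):
    """Empirical absorption distribution from seeded random walks."""
    rng = np.random.default_rng(seed)
    t = len(model.transient_states)
    a = len(model.absorbing_states)
    P = np.hstack([model.Q, model.R])  # transient rows over all t+a states
    if model.source in model.absorbing_states:
        idx = model.absorbing_states.index(model.source)
        out = np.zeros(a)
        out[idx] = 1.0
        return dict(zip(model.absorbing_states, out))
    current = np.full(n_walks, model.transient_states.index(model.source))
    while True:
        active = current < t
        if not active.any():
            break
        for state in np.unique(current[active]):
            walkers = np.flatnonzero(current == state)
            current[walkers] = rng.choice(t + a, size=walkers.size, p=P[state])
    counts = np.bincount(current - t, minlength=a)
    return dict(zip(model.absorbing_states, counts / n_walks))
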