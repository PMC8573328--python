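"""Independent brute-force oracles used by the tests.

Everything here is written in plain Python against the definitions of the
statistics, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations


def brute_running_scores(scores, hits, w):
    """Running P_hit - P_miss by direct prefix summation."""
    n = len(scores)
    total = sum(abs(scores[i]) ** w if w > 0 else 1.0 for i in range(n) if hits[i])
    n_miss = n - sum(hits)
    out = []
    p_hit = p_miss = 0.0
    for i in range(n):
        if hits[i]:
            p_hit += (abs(scores[i]) ** w if w > 0 else 1.0) / total
        else:
            p_miss += 1.0 / n_miss
        out.append(p_hit - p_miss)
    return out

def brute_es(scores, hits, w):
    """Signed maximum deviation of the running score."""
    running = brute_running_scores(scores, hits, w)
    best = max(running, key=abs)
    return best

def brute_gene_set_p(scores, hit_idx, w):
    """Exact enumeration of every same-size subset; sign-conditioned p.

    Returns (observed es, p) where p is the fraction of same-sign subset ES
    values at least as extreme as the observed one (the observed subset is
    itself part of the enumeration).
    """
    n = len(scores)
    k = len(hit_idx)
    obs = brute_es(scores, [i in set(hit_idx) for i in range(n)], w)
    same, extreme = 0, 0
    for idx in combinations(range(n), k):
        es = brute_es(scores, [i in set(idx) for i in range(n)], w)
        if es == 0 or (es > 0) != (obs > 0):
            continue
        same += 1
        if abs(es) >= abs(obs):
            extreme += 1
    return obs, extreme / same if same else 1.0
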