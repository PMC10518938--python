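"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is deliberately naive (exact integer enumeration, O(n^2)
scans, three-loop joins) and shares no code with the implementation paths
it checks.
"""

from math import comb

import numpy as np


def fisher_two_tailed_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration with
    integer table weights; tables whose point probability is <= the
    observed one (within 1e-7 relative slack for ties) are summed."""
    n1, n0, k = a + b, c + d, a + c
    lo, hi = max(0, k - n0), min(n1, k)
    weights = {x: comb(n1, x) * comb(n0, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    num = sum(w for w in weights.values() if w - w_obs <= 1e-7 * w_obs)
    return num / total


def overlap_count_oracle(queries, peaks) -> int:
    """All-pairs O(n*m) scan: distinct queries overlapping >=1 peak by >=1 bp."""
    count = 0
    for q in queries:
        for p in peaks:
            if q.chrom == p.chrom and q.start < p.end and p.start < q.end:
                count += 1
                break
    return count


def bh_oracle(p_values) -> np.ndarray:
    """Hand step-up: q_(i) = min_{j>=i} min(1, p_(j) * m / j) on sorted p,
    mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


def auroc_pairwise_oracle(scores, labels) -> float:
    """Mean over all pos x neg pairs of 1[pos > neg] + 0.5 * 1[tie]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (pos.size * neg.size)


def aupr_threshold_oracle(scores, labels) -> float:
    """PR step area by exhaustive enumeration of the distinct thresholds in
    descending order (tied scores processed as one block):
    sum over thresholds of (recall_t - recall_prev) * precision_t."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        predicted = s >= t
        tp = int((predicted & y).sum())
        precision = tp / int(predicted.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def triad_three_loop_oracle(per_condition_scores, assoc_pairs, diseases):
    """Explicit triple join: for every (condition, disease) cell, scan every
    (TF, disease) link and take the maximum linking TF score (0 if none).

    per_condition_scores: {condition: {TF: score}} (TFs uppercased);
    assoc_pairs: iterable of (antigen, disease_id); diseases: column order.
    Returns (score matrix, mediator matrix) as nested lists.
    """
    score = []
    mediator = []
    for cond, tf_scores in per_condition_scores.items():
        row_s, row_m = [], []
        for dis in diseases:
            best, best_tf = 0.0, ""
            for antigen, disease_id in assoc_pairs:
                tf = antigen.upper()
                if disease_id != dis or tf not in tf_scores:
                    continue
                s = tf_scores[tf]
                if s > best:
                    best, best_tf = s, tf
                elif s == best and best > 0 and tf < best_tf:
                    best_tf = tf
            row_s.append(best)
            row_m.append(best_tf)
        score.append(row_s)
        mediator.append(row_m)
    return score, mediator


def ranksum_exact_oracle(group_a, group_b) -> float:
    """Two-tailed rank-sum p by enumerating every assignment of the pooled
    ranks to group A (tie-free inputs only)."""
    from itertools import combinations

    pooled = sorted(list(group_a) + list(group_b))
    n_a = len(group_a)
    obs_u = sum(
        1.0 for x in group_a for y in group_b if x > y
    )
    mean_u = n_a * len(group_b) / 2.0
    count = total = 0
    for combo in combinations(range(len(pooled)), n_a):
        a_vals = [pooled[i] for i in combo]
        b_vals = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1.0 for x in a_vals for y in b_vals if x > y)
        if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total
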