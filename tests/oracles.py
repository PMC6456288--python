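"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: plain-Python loops over count
dictionaries for the information-theoretic statistics, and a literal
line-by-line transcription of the selection procedure (irrelevance filter,
descending sort, nested pivot/victim loops with the two removal rules).
Nothing imports from the package's numerics.
"""

from __future__ import annotations

from collections import Counter
from math import log2


def entropy_from_counts(counts) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * log2(p)
    return h


def entropy_oracle(codes) -> float:
    return entropy_from_counts(Counter(codes).values())


def joint_entropy_oracle(x, y) -> float:
    return entropy_from_counts(Counter(zip(x, y)).values())


def conditional_entropy_oracle(x, y) -> float:
    """H(X|Y) by direct double summation over the joint count table."""
    joint = Counter(zip(x, y))
    y_counts = Counter(y)
    n = len(x)
    h = 0.0
    for yv, ny in y_counts.items():
        inner = 0.0
        for (xv, yv2), c in joint.items():
            if yv2 == yv and c > 0:
                p = c / ny
                inner -= p * log2(p)
        h += (ny / n) * inner
    return h


def info_gain_oracle(x, y) -> float:
    ig = entropy_oracle(x) + entropy_oracle(y) - joint_entropy_oracle(x, y)
    return max(ig, 0.0)


def relevance_oracle(x, y) -> float:
    denom = entropy_oracle(x) + entropy_oracle(y)
    if denom == 0.0:
        return 0.0
    r = 2.0 * info_gain_oracle(x, y) / denom
    return min(max(r, 0.0), 1.0)


def table_to_pairs(counts_2d):
    """Expand a 2-D joint count table into paired code sequences."""
    xs, ys = [], []
    for i, row in enumerate(counts_2d):
        for j, c in enumerate(row):
            xs.extend([i] * c)
            ys.extend([j] * c)
    return xs, ys


def naive_fsbrr(columns, class_codes, tau=0.0, delta=0.08, alpha=0.64):
    """Literal transcription of the selection procedure on coded columns.

    ``columns`` is a list of integer-code sequences (one per feature).
    Returns (selected_indices, removal_log) where removal_log entries are
    (pivot_index_or_None, removed_index, rule).
    """
    n = len(columns)
    r_c = [relevance_oracle(col, class_codes) for col in columns]

    retained = []
    log = []
    for i in range(n):
        if r_c[i] >= tau:
            retained.append(i)
        else:
            log.append((None, i, "irrelevant"))
    if not retained:
        raise ValueError("empty after irrelevance filter")
    r_bar = sum(r_c[i] for i in retained) / len(retained)

    order = sorted(retained, key=lambda i: (-r_c[i], i))
    removed = set()
    for a in range(len(order)):
        i = order[a]
        if i in removed:
            continue
        for b in range(a + 1, len(order)):
            j = order[b]
            if j in removed:
                continue
            r_jc = relevance_oracle(columns[j], class_codes)  # recomputed, as written
            r_ij = relevance_oracle(columns[i], columns[j])
            gap = r_c[i] - r_jc
            if gap <= delta and r_ij >= r_c[i]:
                removed.add(j)
                log.append((i, j, "redundancy_rule_1"))
            elif gap > delta and gap < alpha and r_ij > (r_bar + r_jc) / 2:
                removed.add(j)
                log.append((i, j, "redundancy_rule_2"))
    selected = [i for i in order if i not in removed]
    return selected, log
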