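"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: reverse complement via
an explicit dict, rotation classes by enumerating every rotation, the
Mann-Whitney null by enumerating every group assignment, and BH by the
step-up definition applied literally.
"""
from collections import Counter
from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s):
    return "".join(_COMP[c] for c in reversed(s))


def rotations(s):
    return [s[i:] + s[:i] for i in range(len(s))]


def brute_force_kmer_counts(seqs, k, canonicalize=True, collapse=False):
    """Counter of k-mer (class) -> count plus the total window count,
    enumerating every window of every sequence explicitly."""
    counts = Counter()
    total = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            total += 1
            if canonicalize:
                cands = rotations(w)
                if collapse:
                    cands = cands + rotations(revcomp(w))
                w = min(cands)
            counts[w] += 1
    return counts, total


def u_statistic(x, y):
    """U for group x: favorable pairs plus half the tied pairs."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def permutation_mannwhitney_p(x, y):
    """Exact two-sided p by full enumeration of group assignments:
    the fraction of assignments whose U is at least as far from the null
    mean n_a*n_b/2 as the observed U."""
    pooled = list(x) + list(y)
    n_a = len(x)
    n = len(pooled)
    mu = n_a * len(y) / 2.0
    obs = abs(u_statistic(x, y) - mu)
    extreme = 0
    count = 0
    for idx in combinations(range(n), n_a):
        chosen = set(idx)
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(n) if i not in chosen]
        count += 1
        if abs(u_statistic(gx, gy) - mu) >= obs - 1e-12:
            extreme += 1
    return extreme / count


def stepup_bh(p):
    """Literal BH step-up: sort ascending, p_(i)*m/i, running minimum from
    the largest rank downward, capped at 1, returned in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted
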