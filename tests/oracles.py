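"""Independent brute-force reference implementations.

Every function here is written from first principles with plain loops
and stays deliberately independent of the gradientpop code paths it
cross-checks: pairwise statistics enumerate all pairs explicitly,
Tajima's constants are re-derived term by term, the AMOVA
decomposition follows the sum-of-squares definitions directly, and
the minimum spanning network oracle enumerates every spanning tree.
"""

from __future__ import annotations

import itertools
import math

UNAMBIGUOUS = {"A", "C", "G", "T"}


def pair_diff(s1: str, s2: str) -> tuple[int, int]:
    """(differences, comparable sites) with pairwise deletion."""
    d = comp = 0
    for a, b in zip(s1.upper(), s2.upper()):
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS:
            comp += 1
            if a != b:
                d += 1
    return d, comp


def haplotype_counts(seqs: list[str]) -> list[int]:
    groups: dict[str, int] = {}
    for s in seqs:
        groups[s.upper()] = groups.get(s.upper(), 0) + 1
    return list(groups.values())


def hap_diversity(seqs: list[str]) -> float:
    n = len(seqs)
    sumsq = sum((c / n) ** 2 for c in haplotype_counts(seqs))
    return n / (n - 1) * (1 - sumsq)


def pi_and_khat(seqs: list[str]) -> tuple[float, float]:
    n = len(seqs)
    tot_d = tot_frac = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            d, comp = pair_diff(seqs[i], seqs[j])
            tot_d += d
            tot_frac += d / comp if comp > 0 else 0.0
            npairs += 1
    return tot_frac / npairs, tot_d / npairs


def seg_sites(seqs: list[str]) -> int:
    S = 0
    for col in zip(*[s.upper() for s in seqs]):
        alleles = {c for c in col if c in UNAMBIGUOUS}
        if len(alleles) >= 2:
            S += 1
    return S


def tajimas_d(seqs: list[str]) -> float:
    """Literal term-by-term evaluation of the D statistic."""
    n = len(seqs)
    S = seg_sites(seqs)
    if S == 0:
        return math.nan
    _, khat = pi_and_khat(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (khat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def phi_st(seqs: list[str], labels: list[str]) -> float:
    """AMOVA ΦST from the raw sum-of-squares definitions."""
    n = len(seqs)
    pops = sorted(set(labels))
    assert len(pops) == 2
    d = {}
    for i in range(n):
        for j in range(n):
            d[(i, j)] = pair_diff(seqs[i], seqs[j])[0]
    ssd_total = sum(d[(i, j)] for i in range(n) for j in range(i + 1, n)) / n
    ssd_within = 0.0
    for p in pops:
        idx = [i for i in range(n) if labels[i] == p]
        ssd_within += sum(
            d[(i, j)] for ii, i in enumerate(idx) for j in idx[ii + 1:]
        ) / len(idx)
    ssd_among = ssd_total - ssd_within
    k = 2
    sigma_w = ssd_within / (n - k)
    sizes = [labels.count(p) for p in pops]
    n_c = (n - sum(s**2 for s in sizes) / n) / (k - 1)
    sigma_a = (ssd_among / (k - 1) - sigma_w) / n_c
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


def josts_d(seqs: list[str], labels: list[str]) -> float:
    """Step-by-step Nei-Chesser estimator chain for two populations."""
    pops = sorted(set(labels))
    assert len(pops) == 2
    haps = sorted({s.upper() for s in seqs})
    freqs = []
    ns = []
    for p in pops:
        sub = [s.upper() for s, l in zip(seqs, labels) if l == p]
        ns.append(len(sub))
        freqs.append([sub.count(h) / len(sub) for h in haps])
    h_s = sum(1 - sum(f**2 for f in fr) for fr in freqs) / 2
    n_harm = 2 / (1 / ns[0] + 1 / ns[1])
    h_s_est = n_harm / (n_harm - 1) * h_s
    h_t = 1 - sum(((f1 + f2) / 2) ** 2 for f1, f2 in zip(*freqs))
    h_t_est = h_t + h_s_est / (2 * n_harm * 2)
    if h_s_est >= 1 - 1e-9:
        return math.nan
    return 2 * (h_t_est - h_s_est) / (1 - h_s_est)


def snn(seqs: list[str], labels: list[str]) -> float:
    """Exhaustive nearest-neighbor enumeration, ties included."""
    n = len(seqs)
    total = 0.0
    for i in range(n):
        dists = [pair_diff(seqs[i], seqs[j])[0] for j in range(n)]
        others = [j for j in range(n) if j != i]
        m = min(dists[j] for j in others)
        nearest = [j for j in others if dists[j] == m]
        total += sum(labels[j] == labels[i] for j in nearest) / len(nearest)
    return total / n


def msn_edges(weights: dict[tuple[int, int], int], k: int) -> set[tuple[int, int]]:
    """Edges on at least one minimum spanning tree, by enumerating all
    spanning trees of the complete graph on k haplotypes."""
    all_edges = sorted(weights)
    best = None
    trees = []
    for subset in itertools.combinations(all_edges, k - 1):
        # spanning check by union-find
        parent = list(range(k))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if not ok:
            continue
        w = sum(weights[e] for e in subset)
        if best is None or w < best:
            best = w
            trees = [subset]
        elif w == best:
            trees.append(subset)
    out: set[tuple[int, int]] = set()
    for t in trees:
        out.update(t)
    return out


def pearson_fisher(x: list[float], y: list[float]) -> tuple[float, float, float]:
    """(r, ci_low, ci_high) from the textbook formulas."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    z = 0.5 * math.log((1 + r) / (1 - r))
    se = 1 / math.sqrt(n - 3)
    lo = math.tanh(z - 1.959963984540054 * se)
    hi = math.tanh(z + 1.959963984540054 * se)
    return r, lo, hi
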