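"""Per-population summary statistics.

Haplotype collapsing, pairwise difference counts with pairwise deletion
of ambiguous sites, Nei-Tajima haplotype diversity, Nei nucleotide
diversity, Tajima's D with its beta-approximation test, and a minimum
spanning haplotype network.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import (
    DistanceMatrix,
    DiversityEstimate,
    HaplotypeSpectrum,
    SequenceRecord,
    SpeciesDataset,
)

# Unambiguous bases; everything else (N, IUPAC ambiguity, gaps) is
# excluded pairwise from difference counts.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(dataset: SpeciesDataset) -> np.ndarray:
    """(n, L) int8 matrix; unambiguous bases 0-3, everything else -1."""
    L = dataset.aln_len
    X = np.full((len(dataset.records), L), -1, dtype=np.int8)
    for i, r in enumerate(dataset.records):
        s = r.seq.upper()
        for j, c in enumerate(s):
            X[i, j] = _BASE_CODE.get(c, -1)
    return X


def collapse_haplotypes(dataset: SpeciesDataset) -> HaplotypeSpectrum:
    """Collapse sequences to distinct haplotypes with per-population counts.

    Identity is exact string equality after uppercasing; N and
    ambiguity codes are treated as literal characters here (conservative:
    unsequenced sites never merge haplotypes) even though they are
    excluded pairwise from distances.
    """
    if not dataset.records:
        raise ValueError("cannot collapse an empty dataset")
    dataset.aln_len  # raises on unequal lengths
    pops = dataset.populations
    haplotypes: list[str] = []
    index: dict[str, int] = {}
    counts: dict[str, list[int]] = {p: [] for p in pops}
    for r in dataset.records:
        s = r.seq.upper()
        if s not in index:
            index[s] = len(haplotypes)
            haplotypes.append(s)
            for p in pops:
                counts[p].append(0)
        counts[r.population][index[s]] += 1
    return HaplotypeSpectrum(haplotypes=haplotypes, counts=counts, n=len(dataset.records))


def pairwise_differences(dataset: SpeciesDataset) -> DistanceMatrix:
    """Count pairwise nucleotide differences with pairwise deletion.

    d[i, j] = number of sites where both sequences carry unambiguous,
    different bases; sites with N/ambiguity in either member of the
    pair are excluded and comparable[i, j] decremented accordingly.
    """
    X = _encode(dataset)
    n = X.shape[0]
    valid = X >= 0
    d = np.zeros((n, n), dtype=np.int64)
    comparable = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid
        d[i] = ((X[i] != X) & both).sum(axis=1)
        comparable[i] = both.sum(axis=1)
    np.fill_diagonal(d, 0)
    return DistanceMatrix(
        d=d,
        comparable=comparable,
        ids=[r.id for r in dataset.records],
        labels=[r.population for r in dataset.records],
    )


def haplotype_diversity(spectrum: HaplotypeSpectrum) -> float:
    """Nei-Tajima haplotype diversity H = (n/(n-1)) (1 - sum p_i^2)."""
    n = spectrum.n
    if n < 2:
        return float("nan")
    p = spectrum.p
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(
    dataset: SpeciesDataset, distances: Optional[DistanceMatrix] = None
) -> tuple[float, float]:
    """Return (pi, k_hat).

    k_hat is the mean number of pairwise differences per sequence pair;
    pi is the per-site version, averaging d_ij / comparable_ij over
    pairs (pairwise deletion).
    """
    n = len(dataset.records)
    if n < 2:
        return float("nan"), float("nan")
    dm = distances if distances is not None else pairwise_differences(dataset)
    iu = np.triu_indices(n, k=1)
    dvals = dm.d[iu].astype(float)
    cvals = dm.comparable[iu].astype(float)
    k_hat = float(dvals.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        persite = np.where(cvals > 0, dvals / np.maximum(cvals, 1.0), 0.0)
    pi = float(persite.mean())
    return pi, k_hat


def segregating_sites(dataset: SpeciesDataset) -> int:
    """Sites with at least two distinct unambiguous alleles in the sample."""
    X = _encode(dataset)
    S = 0
    for j in range(X.shape[1]):
        col = X[:, j]
        alleles = np.unique(col[col >= 0])
        if alleles.size >= 2:
            S += 1
    return S


def tajima_constants(n: int) -> dict[str, float]:
    """The a1...e2 constants of Tajima's D for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    dataset: SpeciesDataset, distances: Optional[DistanceMatrix] = None
) -> tuple[float, float, float]:
    """Tajima's D and p-values: (D, p_beta, p_normal).

    D contrasts diversity estimated from mean pairwise differences with
    diversity estimated from the number of segregating sites; negative
    values suggest expansion or a sweep.  With S = 0 the statistic is
    undefined and all three returns are NaN.  The primary p-value uses
    the beta-distribution approximation to D's null range; a standard-
    normal p is also returned for comparison.
    """
    n = len(dataset.records)
    if n < 2:
        return float("nan"), float("nan"), float("nan")
    S = segregating_sites(dataset)
    if S == 0:
        return float("nan"), float("nan"), float("nan")
    _, k_hat = nucleotide_diversity(dataset, distances)
    c = tajima_constants(n)
    D = (k_hat - S / c["a1"]) / np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))

    # Beta approximation (D rescaled to its theoretical [Dmin, Dmax]).
    Dmin = (2.0 / n - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    Dmax = ((n + 1) / (2.0 * n) - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    alpha = -(1.0 + Dmin * Dmax) * Dmax / (Dmax - Dmin)
    beta = (1.0 + Dmin * Dmax) * Dmin / (Dmax - Dmin)
    x = (D - Dmin) / (Dmax - Dmin)
    cdf = stats.beta.cdf(x, beta, alpha)
    p_beta = float(2 * min(cdf, 1 - cdf))
    p_normal = float(2 * stats.norm.sf(abs(D)))
    return float(D), p_beta, p_normal


def diversity_estimate(dataset: SpeciesDataset, population: Optional[str] = None) -> DiversityEstimate:
    """All per-population summaries for one population (or the pooled set)."""
    sub = dataset.subset(population) if population is not None else dataset
    spectrum = collapse_haplotypes(sub)
    dm = pairwise_differences(sub)
    pi, k_hat = nucleotide_diversity(sub, dm)
    D, p_beta, p_normal = tajimas_d(sub, dm)
    return DiversityEstimate(
        population=population or "pooled",
        n=len(sub.records),
        L=sub.aln_len,
        H=haplotype_diversity(spectrum),
        pi=pi,
        k_hat=k_hat,
        S=segregating_sites(sub),
        tajimas_D=D,
        tajima_p_beta=p_beta,
        tajima_p_normal=p_normal,
    )


def haplotype_distances(spectrum: HaplotypeSpectrum) -> np.ndarray:
    """Pairwise difference counts between distinct haplotypes."""
    # placeholder ids/labels: only the sequences matter here
    recs = SpeciesDataset(
        "haplotypes",
        [SequenceRecord(f"h{i}", h, "north") for i, h in enumerate(spectrum.haplotypes)],
    )
    return pairwise_differences(recs).d


def minimum_spanning_network(
    spectrum: HaplotypeSpectrum, distances: Optional[np.ndarray] = None
) -> nx.Graph:
    """Minimum spanning network over haplotypes, retaining tied edges.

    Kruskal by weight class: an edge enters the network if its
    endpoints lie in different components *before any edge of its
    weight* is added, so every edge participating in at least one
    minimum spanning tree is kept.  Nodes carry pooled and
    per-population counts.
    """
    k = len(spectrum.haplotypes)
    if k == 0:
        raise ValueError("spectrum has no haplotypes")
    if distances is None:
        distances = haplotype_distances(spectrum)
    distances = np.asarray(distances)

    G = nx.Graph()
    total = spectrum.total_counts
    for i, h in enumerate(spectrum.haplotypes):
        percounts = {p: spectrum.counts[p][i] for p in spectrum.counts}
        G.add_node(i, haplotype=h, count=int(total[i]), pop_counts=percounts)
    if k == 1:
        return G

    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = [(int(distances[i, j]), i, j) for i in range(k) for j in range(i + 1, k)]
    for w in sorted({e[0] for e in edges}):
        tier = [(i, j) for ww, i, j in edges if ww == w and find(i) != find(j)]
        for i, j in tier:
            G.add_edge(i, j, weight=w)
        for i, j in tier:
            parent[find(i)] = find(j)
    return G


def write_network_edgelist(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype_a\thaplotype_b\tweight\n")
        for a, b, data in G.edges(data=True):
            fh.write(f"{a}\t{b}\t{data['weight']}\n")
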