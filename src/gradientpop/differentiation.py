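"""Between-population differentiation: ΦST, Jost's D, Hudson's Snn.

All three indices are computed from one :class:`DistanceMatrix` /
haplotype spectrum per species, and their significance from one shared
stream of label permutations, so that at a fixed seed the three
p-values refer to the same empirical null.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from .datatypes import (
    AmovaComponents,
    DifferentiationResult,
    DistanceMatrix,
    HaplotypeSpectrum,
    SpeciesDataset,
)
from .popgen import collapse_haplotypes, pairwise_differences

DEFAULT_PERMUTATIONS = 1000


def _within_ssd(D: np.ndarray, mask: np.ndarray) -> float:
    """Sum of d_ij over unordered pairs inside one population."""
    z = mask.astype(float)
    return float(z @ D @ z) / 2.0


def phi_st(
    distances: DistanceMatrix | np.ndarray,
    labels: Optional[Sequence[str]] = None,
) -> tuple[float, AmovaComponents]:
    """ΦST from the AMOVA sum-of-squares decomposition.

    Pairwise difference counts act as squared molecular distances, the
    standard adaptation of the fixation index to mitochondrial
    haplotype data.  Negative estimates are returned as computed; the
    all-identical 0/0 case is 0 by convention.
    """
    if isinstance(distances, DistanceMatrix):
        D = distances.d.astype(float)
        labels = list(distances.labels) if labels is None else list(labels)
    else:
        D = np.asarray(distances, dtype=float)
        if labels is None:
            raise ValueError("labels required when distances is a bare matrix")
        labels = list(labels)
    labs = np.asarray(labels)
    pops = sorted(set(labels))
    if len(pops) != 2:
        raise ValueError(f"ΦST requires exactly 2 populations, got {pops}")
    N = len(labels)
    k = 2
    n_p = np.array([(labs == p).sum() for p in pops], dtype=float)
    if (n_p == 0).any():
        raise ValueError("each population must be non-empty")

    ssd_total = float(np.triu(D, 1).sum()) / N
    ssd_within = sum(_within_ssd(D, labs == p) / n for p, n in zip(pops, n_p))
    ssd_among = ssd_total - ssd_within

    sigma2_w = ssd_within / (N - k)
    n_c = (N - float(np.sum(n_p**2)) / N) / (k - 1)
    sigma2_a = (ssd_among / (k - 1) - sigma2_w) / n_c
    denom = sigma2_a + sigma2_w
    phi = 0.0 if denom == 0 else float(sigma2_a / denom)
    comp = AmovaComponents(
        ssd_total=ssd_total,
        ssd_within=float(ssd_within),
        ssd_among=float(ssd_among),
        sigma2_a=float(sigma2_a),
        sigma2_w=float(sigma2_w),
        n_c=float(n_c),
    )
    return phi, comp


def _jost_from_counts(c1: np.ndarray, c2: np.ndarray) -> float:
    """Two-population Jost's D from per-population haplotype counts.

    Nei-Chesser bias-corrected heterozygosities with harmonic-mean
    sample size, D = (k/(k-1)) (H_T_est - H_S_est)/(1 - H_S_est).
    """
    n1, n2 = float(c1.sum()), float(c2.sum())
    if n1 == 0 or n2 == 0:
        return float("nan")
    p1, p2 = c1 / n1, c2 / n2
    k = 2
    H_S = np.mean([1.0 - np.sum(p1**2), 1.0 - np.sum(p2**2)])
    n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
    H_S_est = (n_harm / (n_harm - 1.0)) * H_S
    pbar = (p1 + p2) / 2.0
    H_T = 1.0 - float(np.sum(pbar**2))
    H_T_est = H_T + H_S_est / (2.0 * n_harm * k)
    if H_S_est >= 1.0 - 1e-9:
        # the estimator diverges as H_S_est -> 1; undefined
        return float("nan")
    return float((k / (k - 1.0)) * (H_T_est - H_S_est) / (1.0 - H_S_est))


def josts_d(spectrum: HaplotypeSpectrum, pops: Optional[Sequence[str]] = None) -> float:
    """Jost's D between the two populations of a haplotype spectrum."""
    if pops is None:
        pops = [p for p in spectrum.counts if sum(spectrum.counts[p]) > 0]
    if len(pops) != 2:
        raise ValueError(f"Jost's D requires exactly 2 populations, got {list(pops)}")
    c1 = np.asarray(spectrum.counts[pops[0]], dtype=float)
    c2 = np.asarray(spectrum.counts[pops[1]], dtype=float)
    return _jost_from_counts(c1, c2)


def nearest_neighbor_sets(D: np.ndarray) -> list[np.ndarray]:
    """For each sequence, all j != i attaining min_{j != i} d_ij.

    Ties and zero distances are included, following Hudson's original
    definition of the nearest-neighbor set.
    """
    D = np.asarray(D)
    n = D.shape[0]
    sets = []
    for i in range(n):
        row = D[i].astype(float).copy()
        row[i] = np.inf
        m = row.min()
        sets.append(np.flatnonzero(row == m))
    return sets


def _snn_precompute(sets: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten neighbor sets for vectorised re-evaluation under relabelings."""
    sizes = np.array([len(s) for s in sets], dtype=float)
    owner = np.repeat(np.arange(len(sets)), [len(s) for s in sets])
    nb_all = np.concatenate(sets) if sets else np.array([], dtype=int)
    return nb_all, owner, sizes


def _snn_eval(pre: tuple[np.ndarray, np.ndarray, np.ndarray], labs: np.ndarray) -> float:
    nb_all, owner, sizes = pre
    same = (labs[nb_all] == labs[owner]).astype(float)
    x = np.bincount(owner, weights=same, minlength=sizes.size) / sizes
    return float(x.mean())


def _snn_from_sets(sets: list[np.ndarray], labs: np.ndarray) -> float:
    return _snn_eval(_snn_precompute(sets), labs)


def snn(
    distances: DistanceMatrix | np.ndarray,
    labels: Optional[Sequence[str]] = None,
) -> float:
    """Hudson's nearest-neighbor statistic Snn.

    The mean over sequences of the fraction of each sequence's nearest
    neighbors (all ties retained) that belong to its own population;
    0.5 is the panmictic expectation for two equal groups, 1 complete
    separation.
    """
    if isinstance(distances, DistanceMatrix):
        D = distances.d
        labels = list(distances.labels) if labels is None else list(labels)
    else:
        D = np.asarray(distances)
        if labels is None:
            raise ValueError("labels required when distances is a bare matrix")
    labs = np.asarray(list(labels))
    if len(labs) < 2:
        raise ValueError("Snn requires at least 2 sequences")
    return _snn_from_sets(nearest_neighbor_sets(D), labs)


def permutation_test(
    statistic: Callable[[np.ndarray], float],
    labels: Sequence[str],
    B: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """One-sided upper-tail permutation p-value with the +1 correction.

    ``statistic`` maps a label array to a value; labels are shuffled
    uniformly without replacement (group sizes preserved) B times and
    p = (1 + #{permuted >= observed}) / (B + 1).  Ties count toward the
    tail.  NaN observed statistics give a NaN p.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    labs = np.asarray(list(labels))
    obs = statistic(labs)
    if not np.isfinite(obs):
        return float("nan")
    hits = 0
    for _ in range(B):
        perm = rng.permutation(labs)
        val = statistic(perm)
        if np.isfinite(val) and val >= obs:
            hits += 1
    return (1 + hits) / (B + 1)


def differentiation_test(
    dataset: SpeciesDataset,
    B: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
    distances: Optional[DistanceMatrix] = None,
    spectrum: Optional[HaplotypeSpectrum] = None,
) -> DifferentiationResult:
    """All three indices with permutation p-values from one label stream.

    For every permutation the same relabeling is applied to ΦST,
    Jost's D and Snn, so the three nulls are coupled; with a fixed
    seed the result is bitwise reproducible.
    """
    if distances is None:
        distances = pairwise_differences(dataset)
    if spectrum is None:
        spectrum = collapse_haplotypes(dataset)
    labs = np.asarray(distances.labels)
    pops = sorted(set(distances.labels))
    if len(pops) != 2:
        raise ValueError(f"differentiation requires exactly 2 populations, got {pops}")

    D = distances.d.astype(float)
    nn_sets = nearest_neighbor_sets(D)
    snn_pre = _snn_precompute(nn_sets)
    # haplotype index per record, for fast per-permutation recounting
    hap_index = {h: i for i, h in enumerate(spectrum.haplotypes)}
    hap_of = np.array([hap_index[r.seq.upper()] for r in dataset.records])
    n_hap = len(spectrum.haplotypes)

    def all_three(labels_arr: np.ndarray) -> tuple[float, float, float]:
        phi, _ = phi_st(D, labels_arr)
        m1 = labels_arr == pops[0]
        c1 = np.bincount(hap_of[m1], minlength=n_hap).astype(float)
        c2 = np.bincount(hap_of[~m1], minlength=n_hap).astype(float)
        jd = _jost_from_counts(c1, c2)
        s = _snn_eval(snn_pre, labels_arr)
        return phi, jd, s

    obs_phi, amova = phi_st(D, labs)
    obs_jd = josts_d(spectrum, pops)
    obs_snn = _snn_eval(snn_pre, labs)

    rng = np.random.default_rng(seed)
    hits = np.zeros(3, dtype=int)
    valid = np.array([np.isfinite(obs_phi), np.isfinite(obs_jd), np.isfinite(obs_snn)])
    for _ in range(B):
        perm = rng.permutation(labs)
        vals = all_three(perm)
        for k, (v, obs) in enumerate(zip(vals, (obs_phi, obs_jd, obs_snn))):
            if valid[k] and np.isfinite(v) and v >= obs:
                hits[k] += 1
    ps = np.where(valid, (1 + hits) / (B + 1), np.nan)
    return DifferentiationResult(
        phi_st=float(obs_phi),
        josts_d=float(obs_jd),
        snn=float(obs_snn),
        p_phi=float(ps[0]),
        p_d=float(ps[1]),
        p_snn=float(ps[2]),
        B=B,
        seed=seed,
        amova=amova,
    )
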