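"""Rarefaction robustness study and diversity-difference testing.

Species with more than 20 sequences in both populations are repeatedly
subsampled to 5, 10 or 15 sequences per population and every statistic
recomputed, to ask how sample size shapes the estimates and whether an
observed lack of differentiation could simply be lack of power.  This
module also provides the equalized-sample-size re-analysis, a
permutation test for North-vs-Baltic diversity differences, and the
cross-species correlation of diversity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .datatypes import ANALYSIS_POPULATIONS, SpeciesDataset
from .differentiation import josts_d, phi_st, snn
from .popgen import (
    collapse_haplotypes,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_differences,
    tajimas_d,
)

RAREFACTION_SIZES = (5, 10, 15)
RAREFACTION_REPS = 100
#: Strict threshold: a population qualifies for rarefaction only with
#: more than 20 sequences.
RAREFACTION_MIN_N = 20

STATISTICS = ("H", "pi", "tajimas_D", "phi_st", "josts_d", "snn")


@dataclass
class RarefactionResult:
    """Distribution of one statistic under repeated subsampling."""

    species: str
    statistic: str
    subsample_size: int | str  # 5 / 10 / 15 or "equalized"
    replicates: list[float]
    full_estimate: float
    n_undefined: int = 0

    @property
    def q2_5(self) -> float:
        return float(np.percentile(self.replicates, 2.5)) if self.replicates else float("nan")

    @property
    def q97_5(self) -> float:
        return float(np.percentile(self.replicates, 97.5)) if self.replicates else float("nan")

    @property
    def range95(self) -> float:
        return self.q97_5 - self.q2_5

    @property
    def bias(self) -> float:
        if not self.replicates or not np.isfinite(self.full_estimate):
            return float("nan")
        return float(np.mean(self.replicates) - self.full_estimate)


@dataclass
class DiversityComparison:
    """North-vs-Baltic contrast of one diversity measure."""

    species: str
    measure: str
    north_estimate: float
    baltic_estimate: float
    p: float
    call: str  # higher_north / higher_baltic / even / NA
    reps: int = 0
    seed: Optional[int] = None

    @property
    def ratio(self) -> float:
        """baltic / north; NaN when the north estimate is 0 or undefined."""
        if not np.isfinite(self.north_estimate) or self.north_estimate == 0:
            return float("nan")
        return self.baltic_estimate / self.north_estimate


def _point_statistics(dataset: SpeciesDataset) -> dict[str, float]:
    """The six statistics tracked through rarefaction.

    Diversity statistics (H, pi, Tajima's D) are computed on the pooled
    two-population sample; differentiation indices on the labeled one.
    """
    dm = pairwise_differences(dataset)
    spectrum = collapse_haplotypes(dataset)
    pi, _ = nucleotide_diversity(dataset, dm)
    D, _, _ = tajimas_d(dataset, dm)
    phi, _ = phi_st(dm)
    return {
        "H": haplotype_diversity(spectrum),
        "pi": pi,
        "tajimas_D": D,
        "phi_st": phi,
        "josts_d": josts_d(spectrum),
        "snn": snn(dm),
    }


def _subsample(
    dataset: SpeciesDataset, n_per_pop: dict[str, int], rng: np.random.Generator
) -> SpeciesDataset:
    """Sample without replacement within each population, keeping order."""
    keep: list[int] = []
    for pop, target in n_per_pop.items():
        idx = [i for i, r in enumerate(dataset.records) if r.population == pop]
        if target > len(idx):
            raise ValueError(
                f"cannot subsample {target} from population {pop!r} with {len(idx)} sequences"
            )
        chosen = rng.choice(len(idx), size=target, replace=False)
        keep.extend(idx[c] for c in chosen)
    keep.sort()
    return SpeciesDataset(dataset.species, [dataset.records[i] for i in keep])


def rarefaction_eligible(dataset: SpeciesDataset, min_n: int = RAREFACTION_MIN_N) -> tuple[bool, str]:
    counts = dataset.counts()
    for pop in ANALYSIS_POPULATIONS:
        if counts.get(pop, 0) <= min_n:
            return False, (
                f"population {pop!r} has {counts.get(pop, 0)} sequences; "
                f"rarefaction requires more than {min_n}"
            )
    return True, ""


def rarefaction_study(
    dataset: SpeciesDataset,
    sizes: Sequence[int | str] = RAREFACTION_SIZES,
    reps: int = RAREFACTION_REPS,
    seed: Optional[int] = None,
) -> list[RarefactionResult]:
    """Recompute all statistics on repeated per-population subsamples.

    Eligibility is strict (> 20 sequences in both populations); an
    ineligible species yields an empty list.  A size of ``"equalized"``
    subsamples the larger population to the smaller one's n.  Undefined
    replicate outcomes (e.g. a monomorphic subsample making Tajima's D
    NA) are dropped from the percentiles and counted.
    """
    ok, _reason = rarefaction_eligible(dataset)
    if not ok:
        return []
    counts = dataset.counts()
    full = _point_statistics(dataset)
    rng = np.random.default_rng(seed)
    results: list[RarefactionResult] = []
    for size in sizes:
        if size == "equalized":
            target = min(counts[p] for p in ANALYSIS_POPULATIONS)
        else:
            target = int(size)
            for pop in ANALYSIS_POPULATIONS:
                if target > counts[pop]:
                    raise ValueError(
                        f"subsample size {target} exceeds population {pop!r} (n={counts[pop]})"
                    )
        reps_by_stat: dict[str, list[float]] = {s: [] for s in STATISTICS}
        undefined = {s: 0 for s in STATISTICS}
        for _ in range(reps):
            sub = _subsample(dataset, {p: target for p in ANALYSIS_POPULATIONS}, rng)
            vals = _point_statistics(sub)
            for s in STATISTICS:
                if np.isfinite(vals[s]):
                    reps_by_stat[s].append(float(vals[s]))
                else:
                    undefined[s] += 1
        for s in STATISTICS:
            results.append(
                RarefactionResult(
                    species=dataset.species,
                    statistic=s,
                    subsample_size=size,
                    replicates=reps_by_stat[s],
                    full_estimate=float(full[s]) if np.isfinite(full[s]) else float("nan"),
                    n_undefined=undefined[s],
                )
            )
    return results


def equalize_sample_sizes(dataset: SpeciesDataset, seed: Optional[int] = None) -> SpeciesDataset:
    """Subsample the larger population to the smaller one's size."""
    counts = dataset.counts()
    pops = [p for p in ANALYSIS_POPULATIONS if counts.get(p, 0) > 0]
    if len(pops) != 2:
        raise ValueError(f"equalization requires both analysis populations, got {pops}")
    target = min(counts[p] for p in pops)
    rng = np.random.default_rng(seed)
    return _subsample(dataset, {p: target for p in pops}, rng)


def diversity_difference_test(
    dataset: SpeciesDataset,
    measure: str = "H",
    reps: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> DiversityComparison:
    """Permutation test for a North-vs-Baltic diversity difference.

    The observed statistic is |measure(north) - measure(baltic)|; the
    null distribution comes from permuting population labels.  The call
    is ``even`` when p >= alpha, otherwise the side with the larger
    estimate.
    """
    if measure not in ("H", "pi"):
        raise ValueError("measure must be 'H' or 'pi'")

    def measure_of(sub: SpeciesDataset) -> float:
        if len(sub.records) < 2:
            return float("nan")
        if measure == "H":
            return haplotype_diversity(collapse_haplotypes(sub))
        return nucleotide_diversity(sub)[0]

    north = measure_of(dataset.subset("north"))
    baltic = measure_of(dataset.subset("baltic"))
    if not (np.isfinite(north) and np.isfinite(baltic)):
        return DiversityComparison(dataset.species, measure, north, baltic, float("nan"), "NA")

    labs = np.array([r.population for r in dataset.records])
    recs = dataset.records
    obs = abs(north - baltic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(labs)
        groups = {
            p: SpeciesDataset(dataset.species, [r for r, l in zip(recs, perm) if l == p])
            for p in ("north", "baltic")
        }
        vals = [measure_of(groups[p]) for p in ("north", "baltic")]
        if all(np.isfinite(v) for v in vals) and abs(vals[0] - vals[1]) >= obs:
            hits += 1
    p = (1 + hits) / (reps + 1)
    if p >= alpha:
        call = "even"
    else:
        call = "higher_north" if north > baltic else "higher_baltic"
    return DiversityComparison(dataset.species, measure, north, baltic, p, call, reps, seed)


def diversity_ratio_correlation(
    h_ratios: Sequence[float], pi_ratios: Sequence[float]
) -> tuple[float, float, float, float]:
    """Pearson correlation of per-species diversity ratios.

    Returns (r, ci_low, ci_high, p): the product-moment correlation of
    baltic/north haplotype-diversity ratios against nucleotide-
    diversity ratios across species, with a 95% Fisher-z confidence
    interval and two-sided p-value.
    """
    h = np.asarray(h_ratios, dtype=float)
    q = np.asarray(pi_ratios, dtype=float)
    ok = np.isfinite(h) & np.isfinite(q)
    h, q = h[ok], q[ok]
    n = h.size
    if n < 3:
        raise ValueError(f"need at least 3 species with both ratios defined, got {n}")
    if np.std(h) == 0 or np.std(q) == 0:
        raise ValueError("zero variance in one of the ratio vectors")
    r, p = sstats.pearsonr(h, q)
    if abs(r) == 1.0:
        return float(r), float(r), float(r), float(p)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = sstats.norm.ppf(0.975)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return float(r), float(lo), float(hi), float(p)
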