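"""Shared domain types.

A :class:`SpeciesDataset` (trimmed alignment + population labels) is the
unit every analysis operates on.  All other containers are lightweight
result records produced by the statistics modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Population labels accepted in a population map.
ALLOWED_POPULATIONS = ("north", "baltic", "transition")

#: The two populations that enter every between-population analysis.
ANALYSIS_POPULATIONS = ("north", "baltic")


@dataclass(frozen=True)
class SequenceRecord:
    """One sampled individual: an aligned sequence plus its population."""

    id: str
    seq: str
    population: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence for {self.id!r} is empty")
        if self.population not in ALLOWED_POPULATIONS:
            raise ValueError(
                f"unknown population {self.population!r} for sample {self.id!r}; "
                f"allowed labels: {', '.join(ALLOWED_POPULATIONS)}"
            )


@dataclass
class SpeciesDataset:
    """Alignment and population labels for one species.

    After QC all sequences share length ``aln_len`` and only the
    ``north`` / ``baltic`` populations remain.
    """

    species: str
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in {self.species!r}: {dupes}")

    @property
    def aln_len(self) -> int:
        """Alignment length; only meaningful once all sequences agree."""
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequences of {self.species!r} have unequal lengths {sorted(lengths)}")
        return lengths.pop()

    @property
    def populations(self) -> list[str]:
        """Distinct population labels, in order of first appearance."""
        seen: list[str] = []
        for r in self.records:
            if r.population not in seen:
                seen.append(r.population)
        return seen

    def subset(self, population: str) -> "SpeciesDataset":
        """Records of a single population, preserving input order."""
        recs = [r for r in self.records if r.population == population]
        return SpeciesDataset(self.species, recs)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.population] = out.get(r.population, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class QCReport:
    """Bookkeeping for :func:`gradientpop.io_qc.trim_and_filter`.

    ``trimmed_window`` is a 0-based half-open column interval on the
    *input* alignment; gap columns inside it are subsequently removed,
    so the final ``aln_len`` may be shorter than the window.
    """

    species: str
    n_input: int
    n_removed_short: int = 0
    n_removed_gapped: int = 0
    n_removed_transition: int = 0
    trimmed_window: tuple[int, int] = (0, 0)
    aln_len: int = 0
    excluded: bool = False
    reason: str = ""
    divergence_flags: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.n_removed_short
            - self.n_removed_gapped
            - self.n_removed_transition
        )


@dataclass
class HaplotypeSpectrum:
    """Distinct haplotypes with per-population counts.

    ``counts[pop]`` aligns with ``haplotypes``; ``p`` are pooled
    relative frequencies.
    """

    haplotypes: list[str]
    counts: dict[str, list[int]]
    n: int

    @property
    def total_counts(self) -> np.ndarray:
        out = np.zeros(len(self.haplotypes), dtype=int)
        for c in self.counts.values():
            out += np.asarray(c, dtype=int)
        return out

    @property
    def p(self) -> np.ndarray:
        """Pooled haplotype frequencies p_i = counts / n."""
        return self.total_counts / self.n


@dataclass
class DistanceMatrix:
    """Pairwise nucleotide difference counts with pairwise deletion.

    ``d[i, j]`` counts sites where both sequences carry unambiguous,
    different bases; ``comparable[i, j]`` counts sites compared for the
    pair (ambiguity codes and N excluded pairwise).
    """

    d: np.ndarray
    comparable: np.ndarray
    ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d)
        self.comparable = np.asarray(self.comparable)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class DiversityEstimate:
    """Per-population summary statistics.

    ``tajimas_d`` and its p-values are NaN when S = 0 (undefined, not 0).
    """

    population: str
    n: int
    L: int
    H: float
    pi: float
    k_hat: float
    S: int
    tajimas_D: float
    tajima_p_beta: float
    tajima_p_normal: float


@dataclass
class AmovaComponents:
    """Sum-of-squares decomposition behind ΦST."""

    ssd_total: float
    ssd_within: float
    ssd_among: float
    sigma2_a: float
    sigma2_w: float
    n_c: float


@dataclass
class DifferentiationResult:
    """Point estimates and permutation p-values for the three indices."""

    phi_st: float
    josts_d: float
    snn: float
    p_phi: float
    p_d: float
    p_snn: float
    B: int
    seed: Optional[int]
    amova: Optional[AmovaComponents] = None

    @property
    def phi_st_clamped(self) -> float:
        """ΦST clamped to [0, 1] for display; the raw estimate is honest."""
        return float(min(max(self.phi_st, 0.0), 1.0))

    @property
    def josts_d_clamped(self) -> float:
        return float(min(max(self.josts_d, 0.0), 1.0))


@dataclass
class SimulationParams:
    """Knobs of the two-deme isolation-with-migration coalescent.

    q1, q2, qA are mutation-scaled sizes (θ per locus) of the north
    deme, baltic deme and ancestor; m12/m21 are backwards-in-time
    per-lineage migration rates; t is the mutation-scaled split time.
    """

    q1: float = 5.0
    q2: float = 5.0
    qA: float = 5.0
    m12: float = 0.0
    m21: float = 0.0
    t: float = 2.0
    L: int = 545
    n1: int = 25
    n2: int = 25
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "qA", "m12", "m21", "t"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.q1 <= 0 or self.q2 <= 0 or self.qA <= 0:
            raise ValueError("population sizes q1, q2, qA must be > 0")
        if self.L < 1:
            raise ValueError("alignment length L must be >= 1")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("sample sizes n1, n2 must be >= 2")
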