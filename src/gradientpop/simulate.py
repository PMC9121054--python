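"""Two-deme isolation-with-migration coalescent simulator.

Generates synthetic :class:`SpeciesDataset` objects with the
statistical structure the analysis assumes: two demes ("north",
"baltic") of mutation-scaled sizes q1 and q2 that split from an
ancestor of size qA at mutation-scaled time t, exchanging lineages
backwards in time at per-lineage rates m12 (north deme) and m21
(baltic deme).  Mutations fall on branches as a Poisson process at
rate 1 per locus per unit of mutation-scaled time and evolve the
sequence under the Jukes-Cantor model, so for a single panmictic deme
E[mean pairwise differences] = q and E[S] = a1 q.

Time units: a lineage pair inside a deme of size q coalesces at rate
2/q, so branch lengths are in expected mutations per locus; the split
time t and the pipeline's divergence-time conversion share this scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SequenceRecord, SimulationParams, SpeciesDataset

_BASES = np.array(list("ACGT"))


@dataclass
class Genealogy:
    """Binary coalescent tree over n1 + n2 tips.

    ``parent[i]`` is the parent node of i (root has -1), ``time[i]``
    the node's age in mutation-scaled units; tips are nodes
    0 .. n_tips-1 with ``time == 0``.
    """

    parent: np.ndarray
    time: np.ndarray
    tip_demes: np.ndarray  # 0 = north, 1 = baltic

    @property
    def n_tips(self) -> int:
        return self.tip_demes.size

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


def simulate_genealogy(params: SimulationParams, rng: np.random.Generator) -> Genealogy:
    """Structured-coalescent genealogy under the two-deme IM model.

    Backwards in time, within-deme coalescence (rate j(j-1)/q_d for j
    lineages) competes with migration (rate j * m_d); at the split time
    t all surviving lineages merge into the ancestral deme of size qA
    and coalesce there.
    """
    n = params.n1 + params.n2
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    tip_demes = np.array([0] * params.n1 + [1] * params.n2)

    # active lineages per deme; deme 2 (index -1 slot) is the ancestor
    lineages: list[list[int]] = [list(range(params.n1)), list(range(params.n1, n))]
    next_node = n
    T = 0.0
    ancestral = False

    def coalesce(pool: list[int], t_event: float) -> None:
        nonlocal next_node
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        for x in sorted((i, j), reverse=True):
            pool.pop(x)
        parent[a] = parent[b] = next_node
        time[next_node] = t_event
        pool.append(next_node)
        next_node += 1

    while sum(len(p) for p in lineages) > 1:
        if not ancestral and T >= params.t:
            lineages = [lineages[0] + lineages[1]]
            ancestral = True
            continue
        if ancestral:
            j = len(lineages[0])
            rate = j * (j - 1) / params.qA
            T += rng.exponential(1.0 / rate)
            coalesce(lineages[0], T)
            continue
        j1, j2 = len(lineages[0]), len(lineages[1])
        rates = np.array([
            j1 * (j1 - 1) / params.q1,   # coalescence, north
            j2 * (j2 - 1) / params.q2,   # coalescence, baltic
            j1 * params.m12,             # north lineage jumps to baltic (backwards)
            j2 * params.m21,             # baltic lineage jumps to north
        ])
        total = rates.sum()
        if total == 0:
            T = params.t
            continue
        dt = rng.exponential(1.0 / total)
        if T + dt >= params.t:
            # no event before the split; enter the ancestral phase
            T = params.t
            continue
        T += dt
        event = rng.choice(4, p=rates / total)
        if event == 0:
            coalesce(lineages[0], T)
        elif event == 1:
            coalesce(lineages[1], T)
        elif event == 2:
            k = int(rng.integers(len(lineages[0])))
            lineages[1].append(lineages[0].pop(k))
        else:
            k = int(rng.integers(len(lineages[1])))
            lineages[0].append(lineages[1].pop(k))

    return Genealogy(parent=parent, time=time, tip_demes=tip_demes)


def _mutate_sequences(gen: Genealogy, L: int, rng: np.random.Generator) -> np.ndarray:
    """Drop Poisson mutations on branches and evolve under Jukes-Cantor.

    The ancestral sequence is uniform over {A,C,G,T}; each mutation
    hits a uniform site and replaces the current base with one of the
    other three.
    """
    seqs = np.empty((gen.n_nodes, L), dtype=np.int8)
    root = gen.root
    seqs[root] = rng.integers(0, 4, size=L)
    bl = gen.branch_lengths()
    # children lists for a preorder walk from the root
    children: list[list[int]] = [[] for _ in range(gen.n_nodes)]
    for i, p in enumerate(gen.parent):
        if p >= 0:
            children[p].append(i)
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in children[node]:
            seq = seqs[node].copy()
            n_mut = rng.poisson(bl[ch])
            for _ in range(n_mut):
                site = int(rng.integers(L))
                seq[site] = (seq[site] + 1 + rng.integers(3)) % 4
            seqs[ch] = seq
            stack.append(ch)
    return seqs[: gen.n_tips]


def simulate_dataset(
    params: SimulationParams, species: str = "simulated"
) -> tuple[SpeciesDataset, dict]:
    """Simulate one species dataset; returns (dataset, true parameters).

    A fixed ``params.seed`` makes the output byte-identical across
    runs: one RNG stream drives the genealogy, mutation placement and
    base choices.
    """
    rng = np.random.default_rng(params.seed)
    gen = simulate_genealogy(params, rng)
    tips = _mutate_sequences(gen, params.L, rng)
    records = []
    for i in range(gen.n_tips):
        deme = "north" if gen.tip_demes[i] == 0 else "baltic"
        sid = f"{deme[0]}{i:04d}"
        records.append(SequenceRecord(sid, "".join(_BASES[tips[i]]), deme))
    truth = {
        "q1": params.q1, "q2": params.q2, "qA": params.qA,
        "m12": params.m12, "m21": params.m21, "t": params.t,
        "L": params.L, "n1": params.n1, "n2": params.n2, "seed": params.seed,
    }
    return SpeciesDataset(species, records), truth


def simulation_suite(
    grid: Sequence[SimulationParams],
    reps: int = 10,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run every pipeline statistic on every simulated dataset.

    Returns a tidy long-format table keyed by the true parameters,
    replicate index and statistic name.
    """
    from .resampling import _point_statistics

    if not grid:
        raise ValueError("parameter grid is empty")
    ss = np.random.SeedSequence(seed)
    rows = []
    for g, params in enumerate(grid):
        for rep in range(reps):
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            p = SimulationParams(
                q1=params.q1, q2=params.q2, qA=params.qA,
                m12=params.m12, m21=params.m21, t=params.t,
                L=params.L, n1=params.n1, n2=params.n2, seed=child_seed,
            )
            ds, truth = simulate_dataset(p, species=f"grid{g}_rep{rep}")
            stats = _point_statistics(ds)
            for name, value in stats.items():
                rows.append({**truth, "replicate": rep, "statistic": name, "value": value})
    cols = ["q1", "q2", "qA", "m12", "m21", "t", "L", "n1", "n2",
            "seed", "replicate", "statistic", "value"]
    return pd.DataFrame(rows, columns=cols)
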