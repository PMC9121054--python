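"""Multi-species orchestration and divergence-time conversion.

Runs QC → per-population diversity → differentiation → diversity
comparison → rarefaction for every species in a config, isolating
failures per species, and assembles the comparative summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import ANALYSIS_POPULATIONS, DifferentiationResult, DiversityEstimate, QCReport
from .differentiation import differentiation_test
from .io_qc import read_alignment_with_populations, trim_and_filter
from .popgen import diversity_estimate
from .resampling import (
    DiversityComparison,
    RarefactionResult,
    diversity_difference_test,
    rarefaction_study,
)

logger = logging.getLogger("gradientpop")

#: COI substitution rate: 1.22% per million years, read as a
#: per-lineage rate of 1.22e-8 substitutions per site per year.
DEFAULT_SUBSTITUTION_RATE = 1.22e-8
DEFAULT_ALPHA = 0.05


@dataclass
class TimeConversion:
    """Mutation-scaled divergence time expressed in years.

    t is in expected mutations per locus, so dividing by the per-locus
    yearly rate r*L gives years; generation time only rescales the
    reported generations, never the years.
    """

    t_scaled: float
    L: int
    r: float
    years: float
    generation_time: float = 1.0

    @property
    def generations(self) -> float:
        return self.years / self.generation_time


def convert_time_to_years(
    t_scaled: float,
    L: int,
    r: float = DEFAULT_SUBSTITUTION_RATE,
    generation_time: float = 1.0,
) -> TimeConversion:
    """Convert a mutation-scaled divergence time to years: t / (r L)."""
    if t_scaled < 0:
        raise ValueError("t_scaled must be >= 0")
    if L < 1 or r <= 0:
        raise ValueError("need L >= 1 and r > 0 so that r*L > 0")
    years = t_scaled / (r * L)
    return TimeConversion(t_scaled=t_scaled, L=int(L), r=r, years=years,
                          generation_time=generation_time)


@dataclass
class SpeciesReport:
    """Everything the pipeline computed for one species."""

    species: str
    qc: QCReport
    diversity: dict[str, DiversityEstimate] = field(default_factory=dict)
    differentiation: Optional[DifferentiationResult] = None
    comparisons: dict[str, DiversityComparison] = field(default_factory=dict)
    rarefaction: list[RarefactionResult] = field(default_factory=list)
    classification: dict[str, str] = field(default_factory=dict)
    error: str = ""

    @property
    def excluded(self) -> bool:
        return self.qc.excluded or bool(self.error)


def _classify(result: DifferentiationResult, alpha: float) -> dict[str, str]:
    out = {}
    for index, p in (("phi_st", result.p_phi), ("josts_d", result.p_d), ("snn", result.p_snn)):
        if not np.isfinite(p):
            out[index] = "NA"
        else:
            out[index] = "differentiated" if p < alpha else "undifferentiated"
    return out


def analyze_species(
    dataset,
    alpha: float = DEFAULT_ALPHA,
    B: int = 1000,
    seed: Optional[int] = None,
    rarefaction_sizes=(5, 10, 15),
    rarefaction_reps: int = 100,
    qc_report: Optional[QCReport] = None,
) -> SpeciesReport:
    """Run the full per-species analysis on an untrimmed dataset."""
    if qc_report is None:
        dataset, qc_report = trim_and_filter(dataset)
    report = SpeciesReport(species=dataset.species, qc=qc_report)
    if qc_report.excluded:
        return report
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    for pop in ANALYSIS_POPULATIONS:
        report.diversity[pop] = diversity_estimate(dataset, pop)
    report.differentiation = differentiation_test(dataset, B=B, seed=seeds[0])
    report.classification = _classify(report.differentiation, alpha)
    for i, measure in enumerate(("H", "pi")):
        report.comparisons[measure] = diversity_difference_test(
            dataset, measure, reps=B, seed=seeds[1 + i], alpha=alpha
        )
    report.rarefaction = rarefaction_study(
        dataset, sizes=rarefaction_sizes, reps=rarefaction_reps, seed=seeds[3]
    )
    return report


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "species" not in cfg:
        raise ValueError(f"config {path} must be a mapping with a 'species' list")
    return cfg


def run_pipeline(config: dict | str | Path) -> tuple[list[SpeciesReport], pd.DataFrame]:
    """Process every species in a config; failures are isolated.

    ``config`` is a mapping (or YAML path) with a ``species`` list of
    ``{name, fasta, popmap}`` entries and optional globals ``alpha``,
    ``permutations``, ``seed``, ``rarefaction_sizes``,
    ``rarefaction_reps``.  Returns the per-species reports and the
    comparative table (one row per non-excluded species).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    alpha = float(config.get("alpha", DEFAULT_ALPHA))
    B = int(config.get("permutations", 1000))
    seed = config.get("seed")
    sizes = tuple(config.get("rarefaction_sizes", (5, 10, 15)))
    reps = int(config.get("rarefaction_reps", 100))

    ss = np.random.SeedSequence(seed)
    reports: list[SpeciesReport] = []
    for entry in config["species"]:
        name = entry["name"]
        sp_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        logger.info("processing %s", name)
        try:
            raw = read_alignment_with_populations(entry["fasta"], entry["popmap"], species=name)
            report = analyze_species(
                raw, alpha=alpha, B=B, seed=sp_seed,
                rarefaction_sizes=sizes, rarefaction_reps=reps,
            )
        except Exception as exc:  # species-level isolation: one bad input must not kill the run
            logger.error("species %s failed: %s", name, exc)
            report = SpeciesReport(
                species=name,
                qc=QCReport(species=name, n_input=0, excluded=True, reason=str(exc)),
                error=str(exc),
            )
        reports.append(report)
    return reports, comparative_table(reports)


def comparative_table(reports: list[SpeciesReport]) -> pd.DataFrame:
    """One row per non-excluded species: diversity, ratios, calls."""
    rows = []
    for r in reports:
        if r.excluded:
            continue
        dn, db = r.diversity["north"], r.diversity["baltic"]
        diff = r.differentiation
        rows.append({
            "species": r.species,
            "n_north": dn.n,
            "n_baltic": db.n,
            "L": dn.L,
            "H_north": dn.H, "H_baltic": db.H,
            "pi_north": dn.pi, "pi_baltic": db.pi,
            "H_ratio": r.comparisons["H"].ratio,
            "pi_ratio": r.comparisons["pi"].ratio,
            "H_call": r.comparisons["H"].call,
            "pi_call": r.comparisons["pi"].call,
            "tajimas_D_north": dn.tajimas_D, "tajimas_D_baltic": db.tajimas_D,
            "phi_st": diff.phi_st, "p_phi": diff.p_phi,
            "josts_d": diff.josts_d, "p_d": diff.p_d,
            "snn": diff.snn, "p_snn": diff.p_snn,
            "phi_st_class": r.classification["phi_st"],
            "josts_d_class": r.classification["josts_d"],
            "snn_class": r.classification["snn"],
        })
    return pd.DataFrame(rows)
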