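"""Alignment input and quality control.

Reads a multi-FASTA alignment plus a sample-to-population map, then
applies the QC rules used throughout the pipeline: drop transition-zone
samples, trim to the largest column window covered by every retained
sequence (greedily dropping short fragments that would shrink the
window below a 400 bp floor), remove gap-containing columns, and flag
datasets that end up below the floor or with fewer than five sequences
in either analysed population.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

from .datatypes import (
    ALLOWED_POPULATIONS,
    ANALYSIS_POPULATIONS,
    QCReport,
    SequenceRecord,
    SpeciesDataset,
)

MIN_ALIGNMENT_LEN = 400
MIN_SEQS_PER_POP = 5
#: Sequences whose mean divergence from their own population exceeds
#: this fraction are flagged (not dropped) as possibly cryptic lineages.
DIVERGENCE_FLAG_THRESHOLD = 0.05

GAP = "-"


def read_population_map(popmap_path: str | Path) -> dict[str, str]:
    """Parse a TSV with header ``sample_id<TAB>population``."""
    popmap: dict[str, str] = {}
    with open(popmap_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"sample_id", "population"} <= set(reader.fieldnames):
            raise ValueError(
                f"population map {popmap_path} must have columns 'sample_id' and 'population'"
            )
        for row in reader:
            sid = row["sample_id"].strip()
            pop = row["population"].strip().lower()
            if pop not in ALLOWED_POPULATIONS:
                raise ValueError(
                    f"unknown population {pop!r} for sample {sid!r} in {popmap_path}; "
                    f"allowed labels: {', '.join(ALLOWED_POPULATIONS)}"
                )
            if sid in popmap:
                raise ValueError(f"duplicate sample id {sid!r} in population map {popmap_path}")
            popmap[sid] = pop
    return popmap


def read_alignment_with_populations(
    fasta_path: str | Path,
    popmap_path: str | Path,
    species: Optional[str] = None,
) -> SpeciesDataset:
    """Read an aligned FASTA and attach population labels.

    Every FASTA record must appear in the map; records keep input
    order.  The result is *untrimmed*: sequences may differ in length
    or contain gaps until :func:`trim_and_filter` is applied.
    """
    popmap = read_population_map(popmap_path)
    if species is None:
        species = Path(fasta_path).stem
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        if rec.id not in popmap:
            raise ValueError(f"sample {rec.id!r} in {fasta_path} is missing from the population map")
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), popmap[rec.id]))
    if not records:
        raise ValueError(f"no sequences found in {fasta_path}")
    return SpeciesDataset(species, records)


def _coverage_window(seq: str) -> tuple[int, int]:
    """0-based half-open interval from first to last non-gap symbol."""
    first = next((i for i, c in enumerate(seq) if c != GAP), None)
    if first is None:
        return (0, 0)
    last = max(i for i, c in enumerate(seq) if c != GAP)
    return (first, last + 1)


def _common_window(windows: list[tuple[int, int]]) -> tuple[int, int]:
    lo = max(w[0] for w in windows)
    hi = min(w[1] for w in windows)
    return (lo, hi) if hi > lo else (lo, lo)


def _window_len(w: tuple[int, int]) -> int:
    return w[1] - w[0]


def trim_and_filter(
    dataset: SpeciesDataset,
    min_len: int = MIN_ALIGNMENT_LEN,
    drop_transition: bool = True,
    min_per_pop: int = MIN_SEQS_PER_POP,
) -> tuple[SpeciesDataset, QCReport]:
    """Trim all sequences to a shared window and apply QC rules.

    Sequences are padded to the longest input length with gaps first so
    that ragged fragments are handled.  The retained window is the
    intersection of per-sequence coverage windows; while it is shorter
    than ``min_len``, the sequence overlapping it least is dropped
    greedily and the window recomputed.  Gap-containing columns inside
    the window are then removed.  Datasets ending below ``min_len`` or
    with fewer than ``min_per_pop`` sequences in north or baltic are
    flagged ``excluded`` rather than raising.
    """
    report = QCReport(species=dataset.species, n_input=len(dataset.records))

    records = list(dataset.records)
    if drop_transition:
        kept = [r for r in records if r.population != "transition"]
        report.n_removed_transition = len(records) - len(kept)
        records = kept

    max_len = max((len(r.seq) for r in records), default=0)
    padded = [(r, r.seq + GAP * (max_len - len(r.seq))) for r in records]

    # All-gap rows carry no information and have an empty window.
    gapped = [r for r, s in padded if _window_len(_coverage_window(s)) == 0]
    report.n_removed_gapped = len(gapped)
    padded = [(r, s) for r, s in padded if _window_len(_coverage_window(s)) > 0]

    if not padded:
        report.excluded = True
        report.reason = "no usable sequences after removing gapped/transition records"
        return SpeciesDataset(dataset.species, []), report

    windows = [_coverage_window(s) for _, s in padded]
    window = _common_window(windows)

    # Greedy fragment dropping: while the shared window is below the
    # floor, discard the sequence whose coverage overlaps the others'
    # common window least, then recompute.
    while _window_len(window) < min_len and len(padded) > 1:
        best_idx, best_window = None, window
        for i in range(len(padded)):
            rest = [w for j, w in enumerate(windows) if j != i]
            cand = _common_window(rest)
            if _window_len(cand) > _window_len(best_window):
                best_idx, best_window = i, cand
        if best_idx is None:
            break  # dropping no single sequence widens the window
        padded.pop(best_idx)
        windows.pop(best_idx)
        window = best_window
        report.n_removed_short += 1

    report.trimmed_window = window
    lo, hi = window

    # Trim to the window, then drop any column still containing a gap
    # (COI is protein-coding: indels signal misalignment).
    cols = np.array([list(s[lo:hi]) for _, s in padded])
    if cols.size:
        keep_cols = ~(cols == GAP).any(axis=0)
        cols = cols[:, keep_cols]
    trimmed = [
        SequenceRecord(r.id, "".join(row), r.population)
        for (r, _), row in zip(padded, cols)
    ] if cols.size else []

    out = SpeciesDataset(dataset.species, trimmed)
    report.aln_len = 0 if not trimmed else len(trimmed[0].seq)

    if report.aln_len < min_len:
        report.excluded = True
        report.reason = f"alignment length below {min_len} bp"
        return out, report

    counts = out.counts()
    for pop in ANALYSIS_POPULATIONS:
        if counts.get(pop, 0) < min_per_pop:
            report.excluded = True
            report.reason = (
                f"fewer than {min_per_pop} sequences in population {pop!r} "
                f"({counts.get(pop, 0)} after QC)"
            )
            return out, report

    report.divergence_flags = _flag_divergent(out)
    return out, report


def _flag_divergent(dataset: SpeciesDataset, threshold: float = DIVERGENCE_FLAG_THRESHOLD) -> list[str]:
    """Flag sequences unusually far from their own population.

    Mean per-site divergence from same-population members above
    ``threshold`` suggests a cryptic or misidentified lineage.  Flagged
    ids are reported, never dropped.
    """
    from .popgen import pairwise_differences  # local import to avoid a cycle

    dm = pairwise_differences(dataset)
    flags: list[str] = []
    labels = np.array(dm.labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(dm.comparable > 0, dm.d / np.maximum(dm.comparable, 1), 0.0)
    for i in range(dm.n):
        same = (labels == labels[i]) & (np.arange(dm.n) != i)
        if same.any() and float(frac[i, same].mean()) > threshold:
            flags.append(dm.ids[i])
    return flags


def write_trimmed_fasta(dataset: SpeciesDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in dataset.records:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_popmap(dataset: SpeciesDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for r in dataset.records:
            fh.write(f"{r.id}\t{r.population}\n")


def write_qc_report(reports: list[QCReport], path: str | Path) -> None:
    """One row per species, TSV."""
    cols = [
        "species", "n_input", "n_kept", "n_removed_short", "n_removed_gapped",
        "n_removed_transition", "window_start", "window_end", "aln_len",
        "excluded", "reason", "divergence_flags",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            fh.write("\t".join(str(x) for x in [
                r.species, r.n_input, r.n_kept, r.n_removed_short, r.n_removed_gapped,
                r.n_removed_transition, r.trimmed_window[0], r.trimmed_window[1],
                r.aln_len, r.excluded, r.reason, ",".join(r.divergence_flags),
            ]) + "\n")
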