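"""Synthetic end-to-end benchmark for the revision verdict rule.

Builds a reproducible case set of consistent and misassigned compounds and
measures verdict accuracy.  Misassigned cases draw from subtype pairs whose
marker sets differ strongly on shared carbon labels (at least two shared
labels ≥ 4 ppm apart, or one ≥ 15 ppm), so the benchmark probes the decision
rule rather than near-degenerate regioisomer pairs the marker table cannot
separate.  Consistent cases cycle through every subtype in the marker table.

Per case the pipeline receives the experimental draw, the claimed code, two
calculated candidates (claimed-subtype model and true-subtype model, each
carrying the DFT-style class offsets plus residual noise), and a reference
collection of noise-free subtype models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .shift_data import CompoundEntry, parse_subtype
from .subtype_rules import MarkerTable, load_marker_table
from .synthetic_data import (
    GeneratorConfig,
    generate_calculated_entry,
    generate_misassignment_case,
    generate_subtype_compound,
)
from .dereplication import ReferenceCollection
from .pipeline import PipelineConfig, RevisionReport, batch_revise

__all__ = ["MISASSIGNED_PAIRS", "BenchmarkResult", "build_cases", "run_benchmark"]

#: (true subtype, claimed subtype) pairs with strongly distinct shared markers
MISASSIGNED_PAIRS: tuple[tuple[str, str], ...] = (
    ("A23", "B31"),
    ("B31", "A23"),
    ("B13", "A20"),
    ("A20", "B13"),
    ("D31", "A23"),
    ("A23", "D31"),
    ("C40", "B31"),
    ("B31", "C40"),
    ("B13", "D31"),
    ("D31", "B13"),
)


@dataclass(frozen=True)
class BenchmarkResult:
    reports: tuple[RevisionReport, ...]
    expected: tuple[str, ...]  # expected verdict per case
    summary: dict

    @property
    def n_cases(self) -> int:
        return len(self.reports)

    @property
    def n_correct(self) -> int:
        return sum(1 for r, e in zip(self.reports, self.expected) if r.verdict == e)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_cases if self.n_cases else 0.0


def _reference_collection(markers: MarkerTable) -> ReferenceCollection:
    """Noise-free subtype models posing as the known-compound collection."""
    zero = GeneratorConfig(marker_jitter_sd=0.0, calc_noise_sd=0.0, seed=0)
    refs = []
    for subtype in sorted(markers):
        refs.append(
            generate_subtype_compound(
                subtype, zero, seed=0, markers=markers, compound_id=f"REF-{subtype}"
            )
        )
    return ReferenceCollection(refs)


def _candidate(
    subtype: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    markers: MarkerTable,
    case_id: str,
) -> CompoundEntry:
    """Calculated candidate: subtype model at zero jitter + offsets + noise."""
    zero = replace(config, marker_jitter_sd=0.0)
    model = generate_subtype_compound(
        subtype, zero, rng=rng, markers=markers, compound_id=f"{case_id}-cand-{subtype}"
    )
    return generate_calculated_entry(model, config, rng=rng)


def build_cases(
    seed: int,
    n_consistent: int = 100,
    n_misassigned: int = 100,
    jitter_sd: float = 0.8,
    noise_sd: float = 1.5,
    markers: MarkerTable | None = None,
):
    """Build the benchmark case list and its expected verdicts."""
    markers = markers if markers is not None else load_marker_table()
    config = GeneratorConfig(marker_jitter_sd=jitter_sd, calc_noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    subtypes = sorted(markers)
    cases, expected = [], []
    for i in range(n_consistent):
        subtype = subtypes[i % len(subtypes)]
        case_id = f"BM-C{i:03d}"
        entry = generate_subtype_compound(
            subtype, config, rng=rng, markers=markers, compound_id=case_id
        )
        alt = MISASSIGNED_PAIRS[i % len(MISASSIGNED_PAIRS)]
        alt_subtype = alt[0] if alt[0] != subtype else alt[1]
        candidates = [
            _candidate(subtype, config, rng, markers, case_id),
            _candidate(alt_subtype, config, rng, markers, case_id),
        ]
        cases.append((entry, subtype, candidates))
        expected.append("consistent")
    for i in range(n_misassigned):
        true_subtype, claimed = MISASSIGNED_PAIRS[i % len(MISASSIGNED_PAIRS)]
        case_id = f"BM-M{i:03d}"
        entry, claimed_code = generate_misassignment_case(
            true_subtype,
            claimed,
            config,
            seed=int(rng.integers(0, 2**31 - 1)),
            markers=markers,
            compound_id=case_id,
        )
        candidates = [
            _candidate(claimed, config, rng, markers, case_id),
            _candidate(true_subtype, config, rng, markers, case_id),
        ]
        cases.append((entry, claimed_code, candidates))
        expected.append("reassign")
    return cases, expected


def run_benchmark(
    seed: int,
    n_consistent: int = 100,
    n_misassigned: int = 100,
    jitter_sd: float = 0.8,
    noise_sd: float = 1.5,
    config: PipelineConfig | None = None,
) -> BenchmarkResult:
    """Run the pipeline over the benchmark and score verdict accuracy."""
    markers = load_marker_table()
    cases, expected = build_cases(
        seed, n_consistent, n_misassigned, jitter_sd, noise_sd, markers
    )
    collection = _reference_collection(markers)
    reports, summary = batch_revise(cases, collection, config or PipelineConfig(), markers)
    return BenchmarkResult(tuple(reports), tuple(expected), summary)
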