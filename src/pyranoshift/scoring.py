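"""Deviation statistics, DP4 candidate probabilities, and ranking.

Candidate calculated structures are compared against an experimental shift
set on their shared carbon labels.  The deviation vector Δ = δ_calc(corrected)
− δ_exp feeds three diagnostics:

* RMSD and maximum absolute deviation (the per-structure table statistics);
* DP4 — the Bayesian probability that candidate *c* is the correct structure,
  P(c) ∝ Π_k S_t(|Δ_k|/σ; ν), where S_t is the Student-t survival function
  with the published ¹³C parameters σ = 2.306 ppm, ν = 11.38 as defaults;
* a single-outlier flag for the "one bad signal" pattern (typographical
  error, misread spectrum, or contamination) with the RMSD recomputed
  excluding the flagged carbon.

DP4 likelihoods are accumulated in log space and renormalized, so vanishing
products do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import t as student_t

from .shift_data import CompoundEntry, ValidationError
from .correction import CorrectionFactors, apply_corrections

__all__ = [
    "DP4_SIGMA",
    "DP4_NU",
    "DeviationVector",
    "CandidateScore",
    "deviations",
    "rmsd",
    "max_dev",
    "dp4",
    "flag_single_outlier",
    "rank_candidates",
    "rescale_calculated",
]

DP4_SIGMA = 2.306  # ppm, published 13C error scale
DP4_NU = 11.38  # degrees of freedom


class AlignmentError(ValidationError):
    """Two entries share no carbon labels after alias normalization."""


class NumericError(ArithmeticError):
    """All candidate likelihoods vanished even in log space."""


@dataclass(frozen=True)
class DeviationVector:
    """Per-label Δ = δ_corrected_calc − δ_exp on shared labels."""

    deltas: tuple[tuple[str, float], ...]
    excluded_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", tuple(self.deltas))
        object.__setattr__(self, "excluded_labels", frozenset(self.excluded_labels))
        if self.n_shared < 1:
            raise AlignmentError("deviation vector needs at least one shared label")
        labels = [lab for lab, _ in self.deltas]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate labels in deviation vector")

    @property
    def n_shared(self) -> int:
        return len(self.deltas)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.deltas)

    @property
    def values(self) -> np.ndarray:
        return np.array([d for _, d in self.deltas], dtype=float)

    def drop(self, label: str) -> "DeviationVector":
        kept = tuple((lab, d) for lab, d in self.deltas if lab != label)
        return DeviationVector(kept, self.excluded_labels | {label})


def deviations(
    experimental: CompoundEntry,
    calculated: CompoundEntry,
    factors: CorrectionFactors | None = None,
) -> DeviationVector:
    """Deviation vector between an experimental and a calculated entry.

    Corrections are applied to the calculated entry first when factors are
    given.  Labels are alias-normalized before alignment; labels present in
    only one entry are listed as excluded.  Double-intensity signals appear
    as repeated values under distinct labels and need no special casing; if
    a label genuinely repeats, occurrences pair positionally and a lone value
    on one side serves both (second occurrence keyed ``label#2``).
    """
    corrected = apply_corrections(calculated, factors)
    exp_map = experimental.shift_map()
    calc_map = corrected.shift_map()
    shared = sorted(set(exp_map) & set(calc_map))
    excluded = (set(exp_map) | set(calc_map)) - set(shared)
    if not shared:
        raise AlignmentError(
            f"entries {experimental.id!r} and {calculated.id!r} share no labels"
        )
    deltas = []
    for lab in shared:
        evs, cvs = sorted(exp_map[lab]), sorted(calc_map[lab])
        n = max(len(evs), len(cvs))
        for k in range(n):
            e = evs[k] if k < len(evs) else evs[-1]
            c = cvs[k] if k < len(cvs) else cvs[-1]
            key = lab if k == 0 else f"{lab}#{k + 1}"
            deltas.append((key, c - e))
    return DeviationVector(tuple(deltas), frozenset(excluded))


def rmsd(dev: DeviationVector) -> float:
    """Root-mean-square deviation in ppm."""
    return float(np.sqrt(np.mean(dev.values**2)))


def max_dev(dev: DeviationVector) -> tuple[float, str]:
    """Maximum absolute deviation and its label."""
    values = dev.values
    i = int(np.argmax(np.abs(values)))
    return float(abs(values[i])), dev.labels[i]


def dp4(
    candidates: Sequence[DeviationVector],
    sigma: float = DP4_SIGMA,
    nu: float = DP4_NU,
) -> np.ndarray:
    """DP4 probabilities over candidates (sum to 1), computed in log space."""
    if len(candidates) == 0:
        raise ValidationError("dp4 requires at least one candidate")
    if not (sigma > 0 and nu > 0):
        raise ValidationError("dp4 requires sigma > 0 and nu > 0")
    log_l = np.array(
        [student_t.logsf(np.abs(c.values) / sigma, df=nu).sum() for c in candidates]
    )
    if not np.any(np.isfinite(log_l)):
        raise NumericError("all DP4 likelihoods underflowed; deviations implausibly large")
    log_l = log_l - log_l[np.isfinite(log_l)].max()
    probs = np.where(np.isfinite(log_l), np.exp(log_l), 0.0)
    return probs / probs.sum()


def flag_single_outlier(
    dev: DeviationVector, t_major: float = 5.0, t_rest: float = 3.0
) -> tuple[str, float] | None:
    """Flag the lone-outlier pattern: one |Δ| ≥ t_major, all others ≤ t_rest.

    Returns (label, RMSD excluding it) or None.  Requires ≥3 shared carbons —
    with fewer, "one bad signal among otherwise good ones" is meaningless.
    """
    if dev.n_shared < 3:
        raise ValidationError("single-outlier flagging needs at least 3 shared labels")
    abs_vals = np.abs(dev.values)
    order = np.argsort(abs_vals)[::-1]
    largest, second = abs_vals[order[0]], abs_vals[order[1]]
    if largest >= t_major and second <= t_rest:
        label = dev.labels[int(order[0])]
        return label, rmsd(dev.drop(label))
    return None


def rescale_calculated(
    experimental: CompoundEntry, calculated: CompoundEntry
) -> CompoundEntry:
    """Goodman-style linear rescaling δ_scaled = (δ_calc − b)/m.

    Fits δ_calc = m·δ_exp + b over shared labels and inverts the fit; an
    opt-in alternative to the additive class corrections (off by default in
    ranking).  With <2 shared labels the entry is returned unchanged.
    """
    exp_map = experimental.shift_map()
    calc_map = calculated.shift_map()
    shared = sorted(set(exp_map) & set(calc_map))
    if len(shared) < 2:
        return calculated
    x = np.array([exp_map[lab][0] for lab in shared])
    y = np.array([calc_map[lab][0] for lab in shared])
    m, b = np.polyfit(x, y, 1)
    if abs(m) < 1e-9:
        return calculated
    from dataclasses import replace

    return calculated.with_shifts(
        replace(rec, shift=(rec.shift - b) / m) for rec in calculated.shifts
    )


@dataclass(frozen=True)
class CandidateScore:
    """Scored candidate: RMSD, max dev (with label), DP4, outlier diagnostics."""

    candidate_id: str
    rmsd: float
    max_dev: float
    max_dev_label: str
    dp4: float
    n_shared: int
    outlier: str | None = None
    rmsd_excluding_outlier: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dp4 <= 1.0 + 1e-12):
            raise ValidationError(f"dp4 {self.dp4} outside [0, 1]")
        if self.rmsd < 0:
            raise ValidationError("rmsd must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "candidate_id": self.candidate_id,
            "rmsd_ppm": self.rmsd,
            "max_dev_ppm": self.max_dev,
            "max_dev_label": self.max_dev_label,
            "dp4": self.dp4,
            "n_shared": self.n_shared,
            "outlier": self.outlier,
            "rmsd_excluding_outlier_ppm": self.rmsd_excluding_outlier,
        }


def rank_candidates(
    experimental: CompoundEntry,
    candidates: Sequence[CompoundEntry],
    factors: CorrectionFactors | None = None,
    sigma: float = DP4_SIGMA,
    nu: float = DP4_NU,
    rescale: bool = False,
    t_major: float = 5.0,
    t_rest: float = 3.0,
) -> list[CandidateScore]:
    """Score and rank candidate structures against an experimental entry.

    DP4 operates on correction-applied deviations by default; ``rescale=True``
    switches to per-candidate linear rescaling instead.  Deterministic order:
    DP4 descending, then RMSD ascending, then candidate id.
    """
    if len(candidates) == 0:
        raise ValidationError("rank_candidates requires at least one candidate")
    devs = []
    for cand in candidates:
        if rescale:
            devs.append(deviations(experimental, rescale_calculated(experimental, cand)))
        else:
            devs.append(deviations(experimental, cand, factors))
    probs = dp4(devs, sigma=sigma, nu=nu)
    scores = []
    for cand, dev, p in zip(candidates, devs, probs):
        md, md_label = max_dev(dev)
        flagged = flag_single_outlier(dev, t_major, t_rest) if dev.n_shared >= 3 else None
        scores.append(
            CandidateScore(
                candidate_id=cand.id,
                rmsd=rmsd(dev),
                max_dev=md,
                max_dev_label=md_label,
                dp4=float(p),
                n_shared=dev.n_shared,
                outlier=flagged[0] if flagged else None,
                rmsd_excluding_outlier=flagged[1] if flagged else None,
            )
        )
    scores.sort(key=lambda s: (-s.dp4, s.rmsd, s.candidate_id))
    return scores
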