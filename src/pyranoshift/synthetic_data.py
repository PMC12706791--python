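"""Synthetic shift data with the statistical structure the analysis assumes.

No public shift tables accompany the study conditions this package targets,
so every stage is exercised on generated data instead:

* an *experimental* compound of a given subtype = the subtype's diagnostic
  marker expectations, plus a fixed stylized xanthone scaffold for the
  non-diagnostic carbons, each perturbed by independent Gaussian jitter;
* its *calculated* counterpart adds the systematic DFT-style class offsets
  (defaults: calc − exp = +2.9 ppm at C-1/C-8, +3.7 at C-1', −2.8 at C-2')
  plus independent residual noise — exactly the error model the empirical
  correction factors are meant to remove;
* a *misassignment case* is an entry generated from one subtype but labelled
  with another, for testing the consistency checker and the revision verdict.

All generators are pure functions of (config, seed): identical inputs give
byte-identical output.  Gaussian noise is the default; a heavier-tailed
Student-t option matches the DP4 error model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .shift_data import (
    CompoundEntry,
    ShiftRecord,
    SubtypeLike,
    ValidationError,
    format_subtype,
    packaged_fixture,
    parse_subtype,
)
from .correction import correction_class
from .subtype_rules import (
    DiagnosticMarker,
    MARKER_ROLE_CLASSES,
    MarkerTable,
    load_marker_table,
)

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "load_scaffold",
    "generate_subtype_compound",
    "generate_calculated_entry",
    "generate_modeling_set",
    "generate_misassignment_case",
]

#: systematic calc − exp offsets injected into calculated entries, keyed by
#: correction class (note the sign: the derived correction is the negative)
DEFAULT_CALC_OFFSETS = {
    "C1_C8": 2.9,
    "pyran_olefinic_1p": 3.7,
    "pyran_olefinic_2p": -2.8,
}


class GenerationError(ValueError):
    """Requested generation is impossible (e.g. subtype without markers)."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    ``seed`` is mandatory for reproducibility (the CLI uses 0 when unset);
    per-call seeds override it.  ``subtype_weights`` defaults to uniform over
    the marker-table subtypes.
    """

    n_compounds: int = 76
    subtype_weights: Mapping[str, float] | None = None
    calc_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALC_OFFSETS)
    )
    calc_noise_sd: float = 1.0
    marker_jitter_sd: float = 0.8
    seed: int = 0
    noise_model: str = "gaussian"  # or "student_t"
    t_dof: float = 11.38

    def __post_init__(self) -> None:
        if self.calc_noise_sd < 0 or self.marker_jitter_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.noise_model not in ("gaussian", "student_t"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.subtype_weights is not None:
            w = dict(self.subtype_weights)
            if any(v < 0 for v in w.values()) or not any(v > 0 for v in w.values()):
                raise ValidationError("subtype weights must be nonnegative, not all zero")
            object.__setattr__(self, "subtype_weights", w)
        object.__setattr__(self, "calc_offsets", dict(self.calc_offsets))


def load_scaffold(subtype: str | None = None) -> tuple[ShiftRecord, ...]:
    """The fixed filler-carbon scaffold (synthetic scaffolding, not data).

    With a subtype given, the subtype's prenylation-site quaternary carbons
    are prepended; they override shared scaffold labels.  These carbons make
    regioisomer models differ where real regioisomers differ, but carry no
    weight in marker classification.
    """
    raw = packaged_fixture("synthetic_scaffold.json")
    rows = []
    if subtype is not None:
        rows.extend(raw.get("subtype_carbons", {}).get(subtype, []))
    taken = {row["label"] for row in rows}
    rows.extend(r for r in raw["carbons"] if r["label"] not in taken)
    return tuple(
        ShiftRecord(label=row["label"], shift=float(row["ppm"]), carbon_class=row["carbon_class"])
        for row in rows
    )


def _noise(rng: np.random.Generator, sd: float, n: int, config: GeneratorConfig) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    if config.noise_model == "student_t":
        draws = rng.standard_t(config.t_dof, size=n)
        scale = np.sqrt(config.t_dof / (config.t_dof - 2.0))
        return sd * draws / scale
    return rng.normal(0.0, sd, size=n)


def _base_records(subtype_text: str, markers: MarkerTable) -> tuple[ShiftRecord, ...]:
    if subtype_text not in markers:
        raise GenerationError(f"subtype {subtype_text!r} has no diagnostic markers")
    marker_records = tuple(
        ShiftRecord(
            label=m.label,
            shift=m.expected,
            carbon_class=MARKER_ROLE_CLASSES.get(m.role, "other"),
        )
        for m in markers[subtype_text]
    )
    marker_labels = {m.label for m in markers[subtype_text]}
    scaffold = tuple(r for r in load_scaffold(subtype_text) if r.label not in marker_labels)
    return marker_records + scaffold


def generate_subtype_compound(
    subtype: SubtypeLike | str,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    markers: MarkerTable | None = None,
    compound_id: str | None = None,
) -> CompoundEntry:
    """Draw one experimental-kind compound of a subtype.

    Every marker expectation and scaffold carbon is perturbed by independent
    jitter of width ``config.marker_jitter_sd``; at zero jitter the shifts
    equal the expectations exactly.  Deterministic given (config, seed).
    """
    config = config or GeneratorConfig()
    markers = markers if markers is not None else load_marker_table()
    code = parse_subtype(subtype) if isinstance(subtype, str) else subtype
    subtype_text = format_subtype(code)
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    base = _base_records(subtype_text, markers)
    jitter = _noise(rng, config.marker_jitter_sd, len(base), config)
    records = tuple(replace(r, shift=r.shift + e) for r, e in zip(base, jitter))
    return CompoundEntry(
        id=compound_id or f"SYN-{subtype_text}",
        name=f"synthetic {subtype_text} pyranoxanthone",
        subtype=code,
        shifts=records,
        kind="experimental",
        solvent="CDCl3",
        source_ref="synthetic",
    )


def generate_calculated_entry(
    experimental: CompoundEntry,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    entry_id: str | None = None,
) -> CompoundEntry:
    """Calculated counterpart: exp + class offset + residual noise per carbon."""
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    noise = _noise(rng, config.calc_noise_sd, len(experimental.shifts), config)
    records = tuple(
        replace(
            rec,
            shift=rec.shift + float(config.calc_offsets.get(correction_class(rec), 0.0)) + e,
        )
        for rec, e in zip(experimental.shifts, noise)
    )
    return CompoundEntry(
        id=entry_id or f"{experimental.id}-calc",
        name=experimental.name,
        subtype=experimental.subtype,
        shifts=records,
        kind="calculated",
        solvent=experimental.solvent,
        source_ref="synthetic",
    )


def generate_modeling_set(
    config: GeneratorConfig | None = None,
    markers: MarkerTable | None = None,
) -> list[tuple[CompoundEntry, CompoundEntry]]:
    """Draw ``config.n_compounds`` (experimental, calculated) pairs.

    Subtypes are sampled from ``config.subtype_weights`` (uniform over the
    marker table by default); the whole set is reproducible from the seed.
    """
    config = config or GeneratorConfig()
    markers = markers if markers is not None else load_marker_table()
    rng = np.random.default_rng(config.seed)
    if config.subtype_weights is None:
        subtypes = sorted(markers)
        weights = np.full(len(subtypes), 1.0 / len(subtypes))
    else:
        subtypes = sorted(k for k, v in config.subtype_weights.items() if v > 0)
        weights = np.array([config.subtype_weights[k] for k in subtypes], dtype=float)
        weights /= weights.sum()
    pairs = []
    for i in range(config.n_compounds):
        subtype = str(rng.choice(subtypes, p=weights))
        exp = generate_subtype_compound(
            subtype,
            config,
            rng=rng,
            markers=markers,
            compound_id=f"SYN-{i + 1:04d}-{subtype}",
        )
        calc = generate_calculated_entry(exp, config, rng=rng)
        pairs.append((exp, calc))
    return pairs


def generate_misassignment_case(
    true_subtype: SubtypeLike | str,
    claimed_subtype: SubtypeLike | str,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    *,
    markers: MarkerTable | None = None,
    compound_id: str | None = None,
):
    """Entry generated from ``true_subtype`` but labelled ``claimed_subtype``.

    Warns when the two subtypes' marker sets agree within tolerance at every
    role (the case is then not discriminable by markers).
    """
    config = config or GeneratorConfig()
    markers = markers if markers is not None else load_marker_table()
    true_code = parse_subtype(true_subtype) if isinstance(true_subtype, str) else true_subtype
    claimed_code = (
        parse_subtype(claimed_subtype) if isinstance(claimed_subtype, str) else claimed_subtype
    )
    true_text, claimed_text = format_subtype(true_code), format_subtype(claimed_code)
    for text in (true_text, claimed_text):
        if text not in markers:
            raise GenerationError(f"subtype {text!r} has no diagnostic markers")
    true_vals = sorted(m.expected for m in markers[true_text])
    discriminable = False
    for m in markers[claimed_text]:
        nearest = min(true_vals, key=lambda v: abs(v - m.expected))
        if abs(nearest - m.expected) > m.tolerance:
            discriminable = True
            break
    if not discriminable:
        warnings.warn(
            f"marker sets of {true_text} and {claimed_text} agree within tolerance; "
            "misassignment case not discriminable"
        )
    entry = generate_subtype_compound(
        true_code,
        config,
        seed,
        markers=markers,
        compound_id=compound_id or f"SYN-MIS-{true_text}-as-{claimed_text}",
    )
    entry = replace(entry, subtype=claimed_code)
    return entry, claimed_code
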