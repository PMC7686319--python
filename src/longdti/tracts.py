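"""Closed vocabularies for tracts, diffusion metrics and categorical covariates.

The 18 default tracts are the major white-matter bundles reconstructed by
TRACULA: the two corpus-callosum forceps (FMAJ, FMIN) plus eight bilateral
pathways carrying ``lh``/``rh`` prefixes. Diffusion metrics are the four
tensor-derived scalars averaged per tract (FA is dimensionless in [0, 1];
AD/RD/MD are diffusivities, here expressed in um^2/ms so their magnitude
is of order one).
"""

from __future__ import annotations

from typing import Sequence

BILATERAL_TRACTS = ("ATR", "CST", "SLFP", "SLFT", "ILF", "CCG", "CAB", "UNC")
MIDLINE_TRACTS = ("FMAJ", "FMIN")

#: Default tract list: 2 midline + 2 x 8 lateralized = 18.
DEFAULT_TRACTS: tuple[str, ...] = MIDLINE_TRACTS + tuple(
    f"{hemi}.{t}" for t in BILATERAL_TRACTS for hemi in ("lh", "rh")
)

#: Diffusion metrics in their canonical order.
DEFAULT_METRICS: tuple[str, ...] = ("FA", "AD", "RD", "MD")

TRACT_SET = frozenset(DEFAULT_TRACTS)
METRIC_SET = frozenset(DEFAULT_METRICS)

GROUPS = ("control", "deletion")
SEXES = ("M", "F")
SCANNERS = ("A", "B")

#: Fixed column order of the behavior (risk-factor) matrix.
RISK_FACTORS = ("uhr", "preterm", "low_baseline_iq", "cognitive_decline", "baseline_anxiety")


def measure_columns(
    tracts: Sequence[str] = DEFAULT_TRACTS,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> list[tuple[str, str]]:
    """Fixed (tract, metric) column order of the brain matrix: metric-major,
    tracts in the configured order within each metric."""
    return [(t, m) for m in metrics for t in tracts]


def measure_label(tract: str, metric: str) -> str:
    """TSV-safe column label for a (tract, metric) measure."""
    return f"{tract}:{metric}"


def validate_vocab(values, allowed, what: str) -> None:
    bad = sorted(set(values) - set(allowed))
    if bad:
        raise ValueError(f"unknown {what}: {bad}; allowed: {sorted(allowed)}")
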