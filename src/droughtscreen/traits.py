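"""Closed registry of the trait vocabulary used in drought-screening trials.

Each trait carries unit and domain metadata so that observations can be
validated at load time: counts must be non-negative, quantum-yield
proportions must lie in [0, 1], and relative water content is a percentage
in [0, 100].  Unknown trait names are rejected unless the caller opts into
custom traits explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Domain(Enum):
    """Admissible value range of a trait."""

    POSITIVE = "positive"          # (0, inf) continuous
    NONNEGATIVE = "nonnegative"    # [0, inf) continuous
    COUNT = "count"                # non-negative integers (stored as float)
    PROPORTION = "proportion"      # [0, 1]
    PERCENTAGE = "percentage"      # [0, 100]


@dataclass(frozen=True)
class TraitDef:
    name: str
    unit: str
    domain: Domain
    description: str
    decreases_under_stress: bool = True


#: The morpho-physiological and yield trait vocabulary of the screening trial.
REGISTRY: dict[str, TraitDef] = {
    t.name: t
    for t in [
        TraitDef("PH", "cm", Domain.POSITIVE, "plant height of tallest tiller"),
        TraitDef("NT", "count/pot", Domain.COUNT, "number of tillers"),
        TraitDef("NL", "count", Domain.COUNT, "number of leaves on primary tiller"),
        TraitDef("RL", "cm", Domain.POSITIVE, "root length"),
        TraitDef("FWT", "g", Domain.POSITIVE, "shoot fresh weight"),
        TraitDef("DMY", "g/plant", Domain.POSITIVE, "dry matter yield"),
        TraitDef("RWC", "%", Domain.PERCENTAGE, "leaf relative water content"),
        TraitDef("Phi2", "unitless", Domain.PROPORTION,
                 "quantum yield of photosystem II photochemistry"),
        TraitDef("PhiNPQ", "unitless", Domain.PROPORTION,
                 "quantum yield of non-photochemical quenching",
                 decreases_under_stress=False),
        TraitDef("SPAD", "SPAD units", Domain.NONNEGATIVE,
                 "relative chlorophyll content"),
        TraitDef("FvFm", "unitless", Domain.PROPORTION,
                 "maximum quantum efficiency of photosystem II"),
    ]
}

#: Case-insensitive aliases accepted in input headers.
ALIASES: dict[str, str] = {
    "fv/fm": "FvFm",
    "fvfm": "FvFm",
    "fv_fm": "FvFm",
    "phi2": "Phi2",
    "phipsii": "Phi2",
    "phinpq": "PhiNPQ",
    "npq": "PhiNPQ",
    **{name.lower(): name for name in REGISTRY},
}


class UnknownTraitError(ValueError):
    pass


def resolve_trait(name: str, allow_custom: bool = False) -> str:
    """Map a (possibly aliased) trait name to its canonical registry name.

    With ``allow_custom`` the name is passed through untouched when it is
    not in the registry; otherwise an :class:`UnknownTraitError` is raised.
    """
    key = name.strip().lower()
    if key in ALIASES:
        return ALIASES[key]
    if allow_custom:
        return name.strip()
    raise UnknownTraitError(
        f"unknown trait {name!r}; known traits: {sorted(REGISTRY)}"
    )


def validate_value(trait: str, value: float) -> str | None:
    """Return an error message if ``value`` violates the trait's domain."""
    import math

    if not math.isfinite(value):
        return f"{trait}: value {value!r} is not finite"
    d = REGISTRY.get(trait)
    if d is None:
        return None  # custom trait: no domain metadata
    if d.domain in (Domain.COUNT, Domain.NONNEGATIVE) and value < 0:
        return f"{trait}: value {value} must be >= 0"
    if d.domain is Domain.POSITIVE and value <= 0:
        return f"{trait}: value {value} must be > 0"
    if d.domain is Domain.PROPORTION and not (0.0 <= value <= 1.0):
        return f"{trait}: value {value} outside [0, 1]"
    if d.domain is Domain.PERCENTAGE and not (0.0 <= value <= 100.0):
        return f"{trait}: value {value} outside [0, 100]"
    return None
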