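"""Morphotype classification and per-plant abundance extrapolation.

Individual prickles are sorted into three morphotypes by comparing their
measured length, base width and curvature against type prototypes:

* **T1** — short, hooked, wide-based (prototype 2.5 mm long x 3 mm wide,
  curvature *hooked*); the anchoring prickle of climbing roses.
* **T2** — thin, slightly curved (prototype 5 mm x 2 mm, curvature
  *slightly_curved*); typical of upright shrub roses.
* **TO** — everything else; the catch-all.

A prickle matches a prototype when its curvature class equals the
prototype's and both dimensions fall within a relative tolerance window
(default +/-50%) around the prototype dimensions.  The prototypes are only
nominal dimensions; the window is this module's decision boundary and is
user-tunable per prototype.

Per-plant prickle abundance is extrapolated from an observed linear density
(prickles per cm of stem) under a plant archetype of twenty 1.5 m stems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError
from .reference import Curvature, PrickleObservation, PrickleType

__all__ = [
    "TypePrototype",
    "PlantArchetype",
    "DEFAULT_PROTOTYPES",
    "classify_prickle",
    "estimate_plant_total",
    "load_prototypes",
]


@dataclass(frozen=True)
class TypePrototype:
    """Nominal dimensions and curvature of one morphotype, with the relative
    tolerance that defines its match window."""

    type: PrickleType
    length_mm: float
    base_width_mm: float
    curvature: Curvature
    tolerance_fraction: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "type", PrickleType(self.type))
        object.__setattr__(self, "curvature", Curvature(self.curvature))
        if self.length_mm <= 0 or self.base_width_mm <= 0:
            raise ValidationError("prototype dimensions must be positive")
        if not 0 < self.tolerance_fraction < 1:
            raise ValidationError("tolerance_fraction must lie in (0, 1)")

    def matches(self, length_mm: float, base_width_mm: float, curvature: Curvature) -> bool:
        if curvature is not self.curvature:
            return False
        tol = self.tolerance_fraction
        return (
            abs(length_mm - self.length_mm) <= tol * self.length_mm
            and abs(base_width_mm - self.base_width_mm) <= tol * self.base_width_mm
        )


DEFAULT_PROTOTYPES: tuple[TypePrototype, ...] = (
    TypePrototype(PrickleType.T1, length_mm=2.5, base_width_mm=3.0, curvature=Curvature.HOOKED),
    TypePrototype(PrickleType.T2, length_mm=5.0, base_width_mm=2.0, curvature=Curvature.SLIGHTLY_CURVED),
)


@dataclass(frozen=True)
class PlantArchetype:
    """Idealized rose bush used for abundance extrapolation: 20 stems of
    1.5 m (150 cm) by default."""

    n_stems: int = 20
    stem_length_cm: float = 150.0

    def __post_init__(self):
        if self.n_stems <= 0 or self.stem_length_cm <= 0:
            raise ValidationError("archetype parameters must be positive")


def classify_prickle(
    obs: PrickleObservation,
    prototypes: tuple[TypePrototype, ...] = DEFAULT_PROTOTYPES,
) -> PrickleType:
    """Assign one of T1/T2/TO to an observed prickle.

    A pre-assigned type always wins.  Otherwise the first prototype whose
    curvature class matches and whose dimension windows contain the
    measurements decides; no match means TO.  Unknown curvature without an
    assigned type classifies as TO with a ``UserWarning`` (classification is
    total: it never raises on valid observations).
    """
    if obs.assigned_type is not None:
        return obs.assigned_type
    if obs.curvature is Curvature.UNKNOWN:
        warnings.warn(
            f"observation {obs.id!r} has unknown curvature and no assigned "
            "type; classifying as TO",
            UserWarning,
            stacklevel=2,
        )
        return PrickleType.TO
    for proto in prototypes:
        if proto.matches(obs.length_mm, obs.base_width_mm, obs.curvature):
            return proto.type
    return PrickleType.TO


def estimate_plant_total(
    density_per_cm: float, archetype: PlantArchetype = PlantArchetype()
) -> float:
    """Prickles per plant = density/cm x stem length (cm) x number of stems.

    Linear in the density and in each archetype parameter; densities of
    roughly 0.17-27 per cm map to ~500-80,000 prickles per bush under the
    default archetype.
    """
    if density_per_cm < 0:
        raise ValidationError(f"density must be non-negative, got {density_per_cm}")
    return density_per_cm * archetype.stem_length_cm * archetype.n_stems


def load_prototypes(path) -> tuple[TypePrototype, ...]:
    """Load prototypes from a YAML/JSON file.

    Expected structure::

        prototypes:
          - {type: T1, length_mm: 2.5, base_width_mm: 3.0,
             curvature: hooked, tolerance_fraction: 0.5}
    """
    with open(Path(path), "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = doc["prototypes"] if isinstance(doc, dict) else doc
    return tuple(TypePrototype(**e) for e in entries)
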