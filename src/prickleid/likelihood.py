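"""Per-taxon morphotype likelihoods estimated from a reference collection.

The categorical variable is the prickle morphotype X in {T1, T2, TO}; the
parameter is the taxon.  Likelihoods p(x | taxon) are the maximum-likelihood
multinomial estimates from pooled raw counts across a taxon's fragments
(implicitly length-weighted), optionally with Laplace smoothing:

    p(x_j | taxon_i) = (count_ij + alpha) / (total_i + 3 * alpha)

alpha defaults to 0 (no smoothing): observed structural zeros stay exact
zeros, which downstream Bayes' rule propagates as posterior zeros.  A taxon
with zero prickles overall and alpha = 0 has no defined row and is flagged
undefined rather than silently filled.

Optional per-plant abundance weighting rescales a taxon's effective counts
by its estimated prickles-per-bush relative to the mean; because rows are
renormalized, per-row probabilities are unchanged — the weighting matters
only where effective counts are consumed (it ships as an explicit opt-in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import TaxonMismatchError, ValidationError
from .reference import TYPES, PrickleType, ReferenceCollection

__all__ = [
    "LikelihoodTable",
    "AbundanceWeights",
    "estimate_likelihoods",
    "apply_abundance_weighting",
    "marginal_likelihood",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class LikelihoodTable:
    """p(prickle type | taxon) for an ordered taxon list.

    ``probs`` maps ``(taxon, PrickleType)`` to a probability; every defined
    taxon row sums to 1 (within 1e-12).  Taxa in ``undefined`` contributed
    no prickles under alpha = 0 and have no row.  ``counts`` carries the
    effective per-type counts behind each row (metadata; scaled by abundance
    weighting, never consulted by Bayes' rule).
    """

    taxa: tuple[str, ...]
    probs: Mapping[tuple[str, PrickleType], float]
    smoothing_alpha: float = 0.0
    weighting: str = "none"
    undefined: frozenset[str] = frozenset()
    counts: Mapping[tuple[str, PrickleType], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.smoothing_alpha < 0:
            raise ValidationError("smoothing_alpha must be non-negative")
        for taxon in self.taxa:
            if taxon in self.undefined:
                continue
            row = [self.probs[(taxon, t)] for t in TYPES]
            if any(p < 0 for p in row):
                raise ValidationError(f"negative probability for {taxon!r}")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValidationError(
                    f"row for {taxon!r} sums to {sum(row)!r}, expected 1"
                )

    # -- accessors ---------------------------------------------------------

    def prob(self, taxon: str, x: PrickleType) -> float:
        return self.probs[(taxon, PrickleType(x))]

    def column(self, x: PrickleType) -> dict[str, float]:
        """Likelihood of one type for every defined taxon, in taxon order."""
        x = PrickleType(x)
        return {t: self.probs[(t, x)] for t in self.taxa if t not in self.undefined}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for taxon in self.taxa:
            if taxon in self.undefined:
                rows.append({"taxon": taxon, "p_T1": np.nan, "p_T2": np.nan, "p_TO": np.nan})
            else:
                rows.append(
                    {
                        "taxon": taxon,
                        "p_T1": self.probs[(taxon, PrickleType.T1)],
                        "p_T2": self.probs[(taxon, PrickleType.T2)],
                        "p_TO": self.probs[(taxon, PrickleType.TO)],
                    }
                )
        return pd.DataFrame(rows, columns=["taxon", "p_T1", "p_T2", "p_TO"])

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, lineterminator="\n")
        return path

    def to_json(self, path=None):
        doc = {
            "taxa": list(self.taxa),
            "smoothing_alpha": self.smoothing_alpha,
            "weighting": self.weighting,
            "undefined": sorted(self.undefined),
            "probs": {
                taxon: {t.value: self.probs[(taxon, t)] for t in TYPES}
                for taxon in self.taxa
                if taxon not in self.undefined
            },
        }
        if path is None:
            return doc
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return Path(path)

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping], **kw) -> "LikelihoodTable":
        """Build from ``{taxon: {"T1": p, "T2": p, "TO": p}}``."""
        probs = {
            (taxon, PrickleType(t)): float(p)
            for taxon, row in rows.items()
            for t, p in row.items()
        }
        return cls(taxa=tuple(rows), probs=probs, **kw)


@dataclass(frozen=True)
class AbundanceWeights:
    """Estimated prickles per bush, per taxon; all strictly positive."""

    weights: Mapping[str, float]

    def __post_init__(self):
        if any(w <= 0 for w in self.weights.values()):
            raise ValidationError("abundance weights must be positive")


def estimate_likelihoods(
    coll: ReferenceCollection,
    smoothing_alpha: float = 0.0,
    organ_filter: str = "both",
) -> LikelihoodTable:
    """Estimate p(type | taxon) from pooled fragment counts.

    Raises :class:`ValidationError` if a taxon has no fragment under the
    organ filter.  With ``smoothing_alpha == 0`` a taxon whose fragments
    bear no prickles at all is flagged undefined instead of raising.
    """
    if smoothing_alpha < 0:
        raise ValidationError("smoothing_alpha must be non-negative")
    sub = coll.subset(organ_filter)
    totals: dict[str, dict[PrickleType, int]] = {
        t: {x: 0 for x in TYPES} for t in coll.taxa
    }
    n_fragments = {t: 0 for t in coll.taxa}
    for r in sub.records:
        n_fragments[r.taxon] += 1
        for x in TYPES:
            totals[r.taxon][x] += r.counts[x]
    missing = [t for t, n in n_fragments.items() if n == 0]
    if missing:
        raise ValidationError(
            f"no fragments under organ filter {organ_filter!r} for: "
            + ", ".join(missing)
        )

    probs: dict[tuple[str, PrickleType], float] = {}
    counts: dict[tuple[str, PrickleType], float] = {}
    undefined = set()
    for taxon in coll.taxa:
        tot = sum(totals[taxon].values())
        denom = tot + 3 * smoothing_alpha
        for x in TYPES:
            counts[(taxon, x)] = float(totals[taxon][x])
        if denom == 0:
            undefined.add(taxon)
            continue
        for x in TYPES:
            probs[(taxon, x)] = (totals[taxon][x] + smoothing_alpha) / denom
    return LikelihoodTable(
        taxa=tuple(coll.taxa),
        probs=probs,
        smoothing_alpha=smoothing_alpha,
        undefined=frozenset(undefined),
        counts=counts,
    )


def apply_abundance_weighting(
    table: LikelihoodTable, weights: AbundanceWeights
) -> LikelihoodTable:
    """Rescale effective counts by per-bush abundance (count * w_i / mean w).

    Row renormalization makes per-row probabilities invariant, so the
    returned table differs only in its ``counts`` metadata and ``weighting``
    tag; with equal weights it equals the input exactly.
    """
    missing = [t for t in table.taxa if t not in weights.weights]
    if missing:
        raise TaxonMismatchError(
            "abundance weights missing for: " + ", ".join(missing), missing=missing
        )
    mean_w = float(np.mean([weights.weights[t] for t in table.taxa]))
    new_counts = {
        (taxon, x): c * weights.weights[taxon] / mean_w
        for (taxon, x), c in table.counts.items()
    }
    return replace(table, counts=new_counts, weighting="per_plant_abundance")


def marginal_likelihood(table: LikelihoodTable, prior, x: PrickleType) -> float:
    """Prior-weighted average of the per-taxon likelihoods of one type:
    p(x) = sum_i p(x | taxon_i) p(taxon_i)."""
    from .bayes import PriorScenario  # local import to avoid a cycle

    if not isinstance(prior, PriorScenario):
        raise TypeError("prior must be a PriorScenario")
    column = table.column(x)
    return prior.expectation(column, table=table)
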