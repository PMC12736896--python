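"""Prior scenarios, Bayes-rule posterior attribution, and inversion.

For a single observed prickle type x and a discrete candidate-taxon space,
the posterior attribution is Bayes' rule

    p(taxon_i | x) = p(x | taxon_i) p(taxon_i) / p(x),

with the marginal p(x) = sum_i p(x | taxon_i) p(taxon_i).  The prior
p(taxon) is a named *scenario*: either uniform neutrality over the
candidates, or weights elicited from historical and biogeographical
evidence (which may legitimately place exact zeros on implausible taxa).

Because published prior columns are rounded to two decimals, a scenario
accepts raw weights summing to 1 within +/-0.02 and renormalizes internally,
keeping the raw values for provenance.

The inversion utility recovers relative likelihoods from a (prior,
posterior) pair — posterior/prior per taxon, renormalized — which is how a
published posterior table under one prior can be consistency-checked
against, or transported to, another prior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

from .errors import (
    ImpossibleObservationError,
    InconsistentPosteriorError,
    TaxonMismatchError,
    UndefinedLikelihoodError,
    ValidationError,
)
from .likelihood import LikelihoodTable
from .reference import PrickleType, normalize_taxon

__all__ = [
    "PriorScenario",
    "PosteriorResult",
    "LikelihoodRecovery",
    "SensitivityReport",
    "uniform_prior",
    "informed_prior",
    "attribute",
    "recover_likelihood_ratios",
    "sensitivity_report",
    "load_scenario",
]

_SUM_TOL = 0.02  # printed priors are 2-dp rounded; 16 x 0.06 sums to 0.96

#: A likelihood source for one observed type: either a full table or a bare
#: taxon -> likelihood column (Bayes' rule is invariant to its scale).
LikelihoodLike = Union[LikelihoodTable, Mapping[str, float]]


@dataclass(frozen=True)
class PriorScenario:
    """A named prior distribution over candidate taxa.

    ``weights`` are the raw (possibly rounded) values as supplied; they must
    be non-negative and sum to 1 within +/-0.02.  ``normalized`` rescales
    them to sum to 1 exactly and is what every computation uses.
    """

    name: str
    weights: Mapping[str, float]

    def __post_init__(self):
        w = {normalize_taxon(t): float(v) for t, v in dict(self.weights).items()}
        if not w:
            raise ValidationError("prior scenario needs at least one taxon")
        neg = [t for t, v in w.items() if v < 0]
        if neg:
            raise ValidationError(f"negative prior weight for: {', '.join(neg)}")
        s = sum(w.values())
        if abs(s - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"prior weights of scenario {self.name!r} sum to {s:.4f}; "
                f"expected 1 within +/-{_SUM_TOL} (pass normalize=True to "
                "informed_prior to rescale arbitrary weights)"
            )
        object.__setattr__(self, "weights", w)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.weights)

    @property
    def normalized(self) -> dict[str, float]:
        s = sum(self.weights.values())
        return {t: v / s for t, v in self.weights.items()}

    def expectation(self, column: Mapping[str, float], table: LikelihoodTable | None = None) -> float:
        """Prior-weighted sum of a per-taxon column (the marginal when the
        column is a likelihood column)."""
        target = set(table.taxa) if table is not None else set(column)
        _check_taxa(set(self.weights), target, self.name)
        norm = self.normalized
        if table is not None:
            bad = [t for t in table.undefined if norm.get(t, 0.0) > 0]
            if bad:
                raise UndefinedLikelihoodError(
                    "prior places mass on taxa with undefined likelihoods: "
                    + ", ".join(bad)
                )
        return sum(column[t] * norm[t] for t in column)


def _check_taxa(prior_taxa: set, table_taxa: set, name: str) -> None:
    if prior_taxa == table_taxa:
        return
    missing = sorted(table_taxa - prior_taxa)
    extra = sorted(prior_taxa - table_taxa)
    parts = []
    if missing:
        parts.append("missing from prior: " + ", ".join(missing))
    if extra:
        parts.append("absent from table: " + ", ".join(extra))
    raise TaxonMismatchError(
        f"scenario {name!r} does not match the likelihood taxa ({'; '.join(parts)})",
        missing=missing,
        extra=extra,
    )


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior distribution over taxa for one observed type, one scenario."""

    observed_type: PrickleType
    scenario: str
    posteriors: Mapping[str, float]
    marginal: float
    map_taxon: str
    ties: tuple[str, ...] = ()

    def __post_init__(self):
        s = sum(self.posteriors.values())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"posteriors sum to {s!r}, expected 1")


def uniform_prior(taxa: Sequence[str], name: str = "uniform") -> PriorScenario:
    """The neutral scenario: weight 1/n on each of n candidate taxa."""
    taxa = list(taxa)
    if not taxa:
        raise ValidationError("cannot build a uniform prior over no taxa")
    return PriorScenario(name=name, weights={t: 1.0 / len(taxa) for t in taxa})


def informed_prior(
    weights: Mapping[str, float], name: str = "informed", normalize: bool = True
) -> PriorScenario:
    """An evidence-based scenario from a taxon -> weight table.

    Zero weights are allowed (a taxon judged implausible).  With
    ``normalize=True`` (default) arbitrary positive-sum weights are rescaled
    to probabilities; with ``normalize=False`` the raw weights must already
    sum to 1 within +/-0.02.
    """
    w = {t: float(v) for t, v in dict(weights).items()}
    neg = [t for t, v in w.items() if v < 0]
    if neg:
        raise ValidationError(f"negative prior weight for: {', '.join(neg)}")
    if normalize:
        s = sum(w.values())
        if s <= 0:
            raise ValidationError("prior weights must have positive sum")
        w = {t: v / s for t, v in w.items()}
    return PriorScenario(name=name, weights=w)


def _column_for(likelihoods: LikelihoodLike, x: PrickleType) -> dict[str, float]:
    if isinstance(likelihoods, LikelihoodTable):
        return likelihoods.column(x)
    col = {normalize_taxon(t): float(v) for t, v in dict(likelihoods).items()}
    if any(v < 0 for v in col.values()):
        raise ValidationError("likelihood values must be non-negative")
    return col


def attribute(
    x: PrickleType, likelihoods: LikelihoodLike, prior: PriorScenario
) -> PosteriorResult:
    """Posterior attribution of one observed type under one prior scenario.

    ``likelihoods`` may be a full :class:`LikelihoodTable` or a bare
    taxon -> likelihood mapping for the observed type; the latter need not
    be normalized (posteriors are invariant to a common scale factor).
    Raises :class:`ImpossibleObservationError` when the marginal is zero.
    """
    x = PrickleType(x)
    table = likelihoods if isinstance(likelihoods, LikelihoodTable) else None
    column = _column_for(likelihoods, x)
    marginal = prior.expectation(column, table=table)
    if marginal <= 0:
        raise ImpossibleObservationError(
            f"type {x.value} has zero marginal likelihood under scenario "
            f"{prior.name!r}: no candidate taxon can have produced it"
        )
    norm = prior.normalized
    taxa = table.taxa if table is not None else tuple(column)
    posteriors = {
        t: (column.get(t, 0.0) * norm[t]) / marginal for t in taxa
    }
    best = max(posteriors.values())
    tied = tuple(t for t, p in posteriors.items() if abs(p - best) <= 1e-12)
    return PosteriorResult(
        observed_type=x,
        scenario=prior.name,
        posteriors=posteriors,
        marginal=marginal,
        map_taxon=tied[0],  # taxon order breaks ties deterministically
        ties=tied if len(tied) > 1 else (),
    )


@dataclass(frozen=True)
class LikelihoodRecovery:
    """Relative likelihoods recovered by inverting Bayes' rule.

    ``ratios`` is posterior/prior per taxon with positive prior, normalized
    to sum to 1; taxa with prior 0 *and* posterior 0 carry no information
    about their likelihood and are listed ``indeterminate``.
    """

    ratios: Mapping[str, float]
    indeterminate: tuple[str, ...] = ()


def recover_likelihood_ratios(
    prior: PriorScenario, posteriors: Mapping[str, float]
) -> LikelihoodRecovery:
    """Invert Bayes' rule: likelihood_i proportional to posterior_i / prior_i.

    A positive posterior on a zero-prior taxon is algebraically impossible
    and raises :class:`InconsistentPosteriorError`.  Under a uniform prior
    the recovered ratios are simply the normalized posterior vector.
    """
    post = {normalize_taxon(t): float(v) for t, v in dict(posteriors).items()}
    norm = prior.normalized
    missing = sorted(set(post) - set(norm))
    if missing:
        raise TaxonMismatchError(
            "posterior taxa absent from prior: " + ", ".join(missing),
            missing=missing,
        )
    ratios = {}
    indeterminate = []
    for t, p in post.items():
        pi = norm[t]
        if pi > 0:
            ratios[t] = p / pi
        elif p > 0:
            raise InconsistentPosteriorError(
                f"taxon {t!r} has posterior {p} but prior 0: inconsistent "
                "with Bayes' rule"
            )
        else:
            indeterminate.append(t)
    s = sum(ratios.values())
    if s <= 0:
        raise ValidationError("all recovered likelihood ratios are zero")
    return LikelihoodRecovery(
        ratios={t: v / s for t, v in ratios.items()},
        indeterminate=tuple(indeterminate),
    )


@dataclass(frozen=True)
class SensitivityReport:
    """Posterior attribution of one type under several prior scenarios."""

    observed_type: PrickleType
    results: tuple[PosteriorResult, ...]
    map_changed: bool
    #: largest |posterior shift| per taxon across any scenario pair
    shifts: Mapping[str, float]

    @property
    def max_shift(self) -> float:
        return max(self.shifts.values()) if self.shifts else 0.0


def sensitivity_report(
    x: PrickleType, likelihoods: LikelihoodLike, scenarios: Sequence[PriorScenario]
) -> SensitivityReport:
    """Attribute one type under every scenario and summarize rank stability.

    Reports whether the MAP taxon changes across scenarios and the largest
    absolute posterior shift each taxon undergoes between any two scenarios.
    Requires at least two scenarios (one scenario has nothing to compare).
    """
    if len(scenarios) < 2:
        raise ValidationError("sensitivity analysis needs at least 2 scenarios")
    results = tuple(attribute(x, likelihoods, sc) for sc in scenarios)
    taxa = set().union(*(r.posteriors for r in results))
    shifts = {
        t: max(r.posteriors.get(t, 0.0) for r in results)
        - min(r.posteriors.get(t, 0.0) for r in results)
        for t in taxa
    }
    map_changed = len({r.map_taxon for r in results}) > 1
    return SensitivityReport(
        observed_type=PrickleType(x),
        results=results,
        map_changed=map_changed,
        shifts=shifts,
    )


def load_scenario(path) -> PriorScenario:
    """Load a prior scenario from YAML or JSON: ``{name, weights: {taxon: w}}``."""
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    return informed_prior(doc["weights"], name=doc.get("name", Path(path).stem))
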