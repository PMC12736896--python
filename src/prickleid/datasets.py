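"""Bundled case-study data: the Monteagudo almunia rose-prickle attribution.

The published analysis of the rose prickles from the Almunia del Castillejo
(Monteagudo, Murcia, Spain) attributes two archaeological prickle
morphotypes (T1 hooked, T2 slightly curved) to sixteen candidate taxa —
fifteen *Rosa* taxa plus *Rubus ulmifolius* — under two prior scenarios:

* **historical** (scenario A): priors elicited from medieval and
  post-medieval literature and biogeography of the lower Segura valley;
* **uniform** (scenario B): the neutral 1/16 prior.

This module ships the published prior and posterior columns verbatim (two
decimals, as printed).  Because the uniform-prior posterior column is
proportional to the likelihood column, the table over-determines the
likelihoods: the whole analysis can be reconstructed, transported between
priors, and consistency-checked from these numbers alone.  The raw
fragment-level training counts behind the likelihoods were not published;
:func:`calibrated_profiles` provides synthetic stand-in taxon profiles
whose T1/T2 likelihood columns are proportional to the published
uniform-prior posterior columns, for end-to-end pipeline exercises.
"""

from __future__ import annotations

import pandas as pd

from .bayes import PriorScenario, informed_prior, uniform_prior
from .errors import ValidationError
from .simulate import TaxonProfile

__all__ = [
    "case_study_taxa",
    "case_study_table",
    "case_study_prior",
    "case_study_posteriors",
    "calibrated_profiles",
]

# taxon, prior A, p(taxon|T1) A, p(taxon|T2) A, p(taxon|T1) B, p(taxon|T2) B
# (the uniform scenario-B prior prints as 0.06 for every row)
_TABLE = [
    ("R. agrestis Savi", 0.11, 0.23, 0.04, 0.12, 0.03),
    ("R. bicolor Jacq.", 0.04, 0.00, 0.00, 0.00, 0.00),
    ("R. canina L.", 0.02, 0.18, 0.00, 0.50, 0.00),
    ("R. foetida Herrm.", 0.11, 0.00, 0.30, 0.00, 0.25),
    ("R. gallica L.", 0.02, 0.00, 0.00, 0.00, 0.02),
    ("R. hemisphaerica Herrm.", 0.05, 0.00, 0.02, 0.00, 0.03),
    ("R. lutea var. persiana Lem.", 0.11, 0.00, 0.52, 0.00, 0.44),
    ("R. moschata Herrm.", 0.11, 0.54, 0.00, 0.28, 0.00),
    ("R. rubiginosa L.", 0.01, 0.00, 0.01, 0.00, 0.08),
    ("R. sempervirens Savi", 0.01, 0.01, 0.00, 0.08, 0.00),
    ("R. sp. Tea", 0.00, 0.00, 0.00, 0.00, 0.00),
    ("R. x alba L.", 0.05, 0.01, 0.02, 0.02, 0.04),
    ("R. x bifera (Poir.) Pers.", 0.05, 0.00, 0.03, 0.00, 0.05),
    ("R. x centifolia L.", 0.11, 0.00, 0.04, 0.00, 0.04),
    ("R. x damascena Herrm.", 0.11, 0.02, 0.01, 0.01, 0.01),
    ("Rubus ulmifolius Schott.", 0.09, 0.00, 0.00, 0.00, 0.00),
]

_COLUMNS = [
    "taxon",
    "prior_historical",
    "pA_T1",
    "pA_T2",
    "pB_T1",
    "pB_T2",
]


def case_study_taxa() -> tuple[str, ...]:
    """The sixteen candidate taxa, in published row order."""
    return tuple(row[0] for row in _TABLE)


def case_study_table() -> pd.DataFrame:
    """The published two-scenario prior/posterior table as a DataFrame.

    Columns: ``prior_historical`` (scenario A prior), ``pA_T1``/``pA_T2``
    (posteriors under A), ``pB_T1``/``pB_T2`` (posteriors under the uniform
    scenario B).  All values are the printed two-decimal figures.
    """
    return pd.DataFrame(_TABLE, columns=_COLUMNS)


def case_study_prior(scenario: str = "historical") -> PriorScenario:
    """One of the two published prior scenarios.

    ``"historical"`` returns the literature/biogeography-informed weights
    (which include an exact 0 on the Tea group); ``"uniform"`` returns the
    neutral 1/16 prior.
    """
    if scenario == "historical":
        return informed_prior(
            {row[0]: row[1] for row in _TABLE}, name="historical"
        )
    if scenario == "uniform":
        return uniform_prior(case_study_taxa(), name="uniform")
    raise ValidationError(
        f"unknown scenario {scenario!r}; expected 'historical' or 'uniform'"
    )


def case_study_posteriors(scenario: str, x) -> dict[str, float]:
    """The published posterior column for one (scenario, type) pair."""
    key = {("historical", "T1"): 2, ("historical", "T2"): 3,
           ("uniform", "T1"): 4, ("uniform", "T2"): 5}
    code = getattr(x, "value", x)
    try:
        col = key[(scenario, code)]
    except KeyError:
        raise ValidationError(
            f"no published posterior column for scenario={scenario!r}, x={code!r}"
        ) from None
    return {row[0]: row[col] for row in _TABLE}


def calibrated_profiles(
    density_per_cm: float = 2.0, to_floor: float = 0.2
) -> list[TaxonProfile]:
    """Synthetic taxon profiles calibrated to the published posterior table.

    Both the T1 and the T2 per-taxon likelihood columns are set
    proportional to the corresponding uniform-prior posterior columns (the
    proportionality the uniform prior guarantees), with one common scale
    factor chosen so that the taxon richest in T1+T2 mass keeps a TO
    fraction of ``to_floor``; TO absorbs the per-taxon remainder.  TO
    fractions and the per-cm density are synthetic stand-ins — the
    published table does not constrain them — so only ratios *within* the
    T1 and T2 columns are meaningful.
    """
    b1 = {row[0]: row[4] for row in _TABLE}
    b2 = {row[0]: row[5] for row in _TABLE}
    top = max(b1[t] + b2[t] for t in b1)
    scale = (1.0 - to_floor) / top
    profiles = []
    for t in case_study_taxa():
        p1, p2 = scale * b1[t], scale * b2[t]
        profiles.append(
            TaxonProfile(
                taxon=t,
                type_proportions=(p1, p2, 1.0 - p1 - p2),
                density_per_cm=density_per_cm,
            )
        )
    return profiles
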