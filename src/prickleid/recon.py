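"""Reconstruction of the bundled case-study posterior table.

A two-scenario published posterior table over-determines the likelihoods:

* the uniform-prior posterior column *is* the normalized likelihood column
  (Bayes' rule with a flat prior), so the informed-scenario posteriors
  follow by one forward application of Bayes' rule;
* conversely, dividing an informed-scenario posterior column by its prior
  recovers the relative likelihoods, which renormalize into the
  uniform-prior posteriors.

Running both directions from the printed two-decimal columns and comparing
against the printed posteriors is the table's internal-consistency check:
agreement is limited only by the rounding of the inputs.
"""

from __future__ import annotations

from .bayes import attribute, recover_likelihood_ratios, uniform_prior
from .datasets import case_study_posteriors, case_study_prior, case_study_taxa
from .reference import PrickleType

__all__ = ["reconstruct_posteriors", "consistency_errors", "well_conditioned"]


def well_conditioned(
    prior: float, posterior: float, half_ulp: float = 0.005, max_rel: float = 0.5
) -> bool:
    """Is a printed (prior, posterior) cell usable for Bayes inversion?

    The recovered ratio posterior/prior inherits a relative error of up to
    ``half_ulp/posterior + half_ulp/prior`` from the rounding of its two
    printed inputs (half a printed unit each).  A cell is well-conditioned
    when that bound stays below ``max_rel``; e.g. a 0.01/0.01 cell can be
    off by 100% from rounding alone and is not.  Zero-posterior cells are
    exact (zeros are structural) and always well-conditioned.
    """
    if posterior == 0.0:
        return True
    if prior == 0.0:
        return False
    return half_ulp / posterior + half_ulp / prior <= max_rel


def reconstruct_posteriors() -> dict[str, dict[str, dict[str, float]]]:
    """Recompute all four posterior columns from the printed table.

    Returns ``{scenario: {type: {taxon: posterior}}}`` where the
    ``historical`` columns are computed *forward* (uniform-prior posteriors
    taken as likelihoods, historical prior applied) and the ``uniform``
    columns are computed *inverse* (historical posteriors divided by the
    historical prior, renormalized).
    """
    hist = case_study_prior("historical")
    uni = uniform_prior(case_study_taxa(), name="uniform")
    out: dict[str, dict[str, dict[str, float]]] = {"historical": {}, "uniform": {}}
    for x in (PrickleType.T1, PrickleType.T2):
        forward = attribute(x, case_study_posteriors("uniform", x), hist)
        out["historical"][x.value] = dict(forward.posteriors)
        recovery = recover_likelihood_ratios(
            hist, case_study_posteriors("historical", x)
        )
        ratios = {t: recovery.ratios.get(t, 0.0) for t in case_study_taxa()}
        inverse = attribute(x, ratios, uni)
        out["uniform"][x.value] = dict(inverse.posteriors)
    return out


def consistency_errors() -> dict[str, dict[str, dict[str, float]]]:
    """Absolute difference between each reconstructed and printed posterior."""
    recon = reconstruct_posteriors()
    return {
        sc: {
            x: {
                t: abs(col[t] - case_study_posteriors(sc, x)[t])
                for t in col
            }
            for x, col in cols.items()
        }
        for sc, cols in recon.items()
    }
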