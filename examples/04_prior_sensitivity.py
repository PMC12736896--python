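"""How much do the attributions depend on the prior?

Runs the case-study likelihoods under both bundled priors and summarizes
rank stability: does the most probable taxon change, and how far does each
taxon's posterior move?
"""

from prickleid import PrickleType, sensitivity_report
from prickleid.datasets import case_study_posteriors, case_study_prior

scenarios = [case_study_prior("historical"), case_study_prior("uniform")]

for x in (PrickleType.T1, PrickleType.T2):
    rep = sensitivity_report(x, case_study_posteriors("uniform", x), scenarios)
    print(f"type {x.value}: MAP changed across priors: {rep.map_changed}; "
          f"max posterior shift {rep.max_shift:.2f}")
    movers = sorted(rep.shifts.items(), key=lambda kv: -kv[1])[:3]
    for taxon, shift in movers:
        print(f"    {taxon:<30} shifts by {shift:.2f}")

# T1 is prior-sensitive (musk rose vs dog rose trade places); T2 is not:
# the yellow roses dominate under either prior, which is what makes that
# attribution robust.
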