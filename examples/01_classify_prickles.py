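"""Classify measured prickles into the three morphotypes.

Builds a handful of observations with measured length, base width and
curvature class, runs them through the prototype classifier, and
extrapolates what a bush of a given prickle density would carry.
"""

from prickleid import (
    Curvature,
    PrickleObservation,
    classify_prickle,
    estimate_plant_total,
)

observations = [
    # the two archetypal finds: a short hooked climber prickle and a thin
    # slightly curved shrub prickle
    PrickleObservation("west", length_mm=2.5, base_width_mm=3.0, curvature=Curvature.HOOKED),
    PrickleObservation("east", length_mm=4.0, base_width_mm=2.5, curvature=Curvature.SLIGHTLY_CURVED),
    # a long straight spine: no prototype matches, falls into the catch-all
    PrickleObservation("stray", length_mm=12.0, base_width_mm=1.0, curvature=Curvature.STRAIGHT),
]

for obs in observations:
    t = classify_prickle(obs)
    print(f"{obs.id:>6}: {obs.length_mm} x {obs.base_width_mm} mm, "
          f"{obs.curvature.value:>15} -> {t.value}")

# A bush with 1 prickle per cm of stem, under the default archetype of
# twenty 1.5 m stems, carries 3000 prickles; the densities seen across
# reference taxa (~0.17-27 per cm) span ~500-80,000 per plant.
for d in (0.1667, 1.0, 26.67):
    print(f"density {d:6.4f}/cm -> {estimate_plant_total(d):8.0f} prickles/plant")
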