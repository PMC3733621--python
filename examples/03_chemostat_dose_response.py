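"""Dose-response of biomass to weak-organic-acid stress in a chemostat.

The WOA enters by diffusion and must be pumped back out at an ATP cost, so
rising uptake drains energy from growth.  Three expression scenarios are
compared on the yeast-like model: measured changes (GED, here an up-
regulated glucose uptake / fermentation response), no changes (NoGED), and
the measured changes extrapolated on a log scale (ratios squared).
Cultures with no expression response produce the most biomass at the lowest
uptake but wash out earliest; the extrapolated response tolerates the
highest uptake.
"""

from gemkin import ExpressionVector
from gemkin.analyses import dose_response
from gemkin.fixtures import reference_chemostat, woa_family

model, setup = reference_chemostat()
build = woa_family(model)
g = ExpressionVector(g={"glk": 1.5, "pdc": 1.3, "oxp": 1.2, "oxp_iso": 1.2})

curve = dose_response(build, g, [0.5, 1, 2, 3, 4, 5, 6, 7], setup)
frame = curve.to_frame().round(3)
print("biomass (relative to reference) vs WOA uptake rate:")
print(frame.to_string())
print("\n0.000 = washed out (culture cannot grow at the dilution rate)")
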