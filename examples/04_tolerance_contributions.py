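"""Which expression changes buy stress tolerance? NTC and NUC metrics.

Both metrics compare four tolerance evaluations per reaction subset: with
all expression changes (GED), with none (NoGED), with only the subset's
changes added in, and with only the subset's changes left out.  The
symmetric average of the add-in and leave-out effects, normalized by the
total expression-driven gain, is 1 when the subset accounts for the whole
gain and 0 when its expression did not change.
"""

from gemkin import ExpressionVector
from gemkin.analyses import ntc, nuc, tolerance_inhibition, tolerance_woa
from gemkin.fixtures import (
    chemostat_toy,
    toy_inhibition_family,
    toy_woa_family,
)

model, setup = chemostat_toy()

# inhibition stress: only the catalytic step's expression changed
build_i = toy_inhibition_family(model)
g = ExpressionVector(g={"cat": 2.0})
tol_ged = tolerance_inhibition(build_i, g, setup)
tol_noged = tolerance_inhibition(build_i, ExpressionVector(), setup)
print(f"max tolerated inhibition depth: {tol_ged:.4f} (GED) "
      f"vs {tol_noged:.4f} (NoGED)")
for subset in (["cat"], ["up"]):
    value = ntc(build_i, g, subset, setup, tol_ged=tol_ged, tol_noged=tol_noged)
    print(f"  NTC{subset}: {value:.3f}")

# WOA stress: only the uptake step's expression changed
build_w = toy_woa_family(model)
gw = ExpressionVector(g={"up": 2.0})
wur_ged = tolerance_woa(build_w, gw, setup)
wur_noged = tolerance_woa(build_w, ExpressionVector(), setup)
print(f"tolerated WOA uptake (biomass >= 5% of reference): "
      f"{wur_ged:.2f} (GED) vs {wur_noged:.2f} (NoGED)")
for subset in (["up"], ["cat"]):
    value = nuc(build_w, gw, subset, setup, wur_ged=wur_ged, wur_noged=wur_noged)
    print(f"  NUC{subset}: {value:.3f}")
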