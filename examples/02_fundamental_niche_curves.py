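"""Build the slider turtle's temperature tolerance curve and compare it with
the temperatures its occurrences actually occupy.

The fundamental niche is encoded from literature tolerance limits: optima for
egg incubation (29.5 C) and daily activity (25.6 C), ranges for feeding
(16.8-32.1 C), normal activity (10-37 C) and basking (26.7-31.2 C), all
bounded by the lethal limits (-12.6 to 42.3 C). Occupied temperatures are
taken here from a simulated occurrence sample.
"""

import numpy as np

from nichefill import (
    ScenarioTruth,
    compose_tolerance_curve,
    make_invasion_scenario,
    occupied_range,
    unfilled_tolerance_report,
)
from nichefill.pipeline import env_matrix_for
from nichefill.synthetic_data import CLIMATE_VARS

curve = compose_tolerance_curve()
print(f"tolerance support      : {curve.support[0]} to {curve.support[1]} C (lethal limits)")
print(f"tolerance optimum      : {curve.max_location:.2f} C (inside the basking/incubation zone)")

scenario = make_invasion_scenario(ScenarioTruth(target_unfilling=0.4, target_expansion=0.3, seed=5))
bio1 = CLIMATE_VARS.index("BIO1")
temps_native = env_matrix_for(scenario.occ_native, scenario.landscape_native)[:, bio1]
temps_nonnative = env_matrix_for(scenario.occ_nonnative, scenario.landscape_nonnative)[:, bio1]

(lo_n, hi_n), _ = occupied_range(temps_native)
(lo_i, hi_i), _ = occupied_range(temps_nonnative)
print(f"occupied native        : {lo_n:.1f} to {hi_n:.1f} C")
print(f"occupied non-native    : {lo_i:.1f} to {hi_i:.1f} C")

low, high = unfilled_tolerance_report((min(lo_n, lo_i), max(hi_n, hi_i)), curve)
print(f"unfilled tolerance     : {100 * low:.0f}% on the cold side, {100 * high:.0f}% on the warm side")
print()
print("A nonzero warm-side fraction means climates inside the physiological")
print("tolerance remain unoccupied - potential range under invasion or warming.")
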