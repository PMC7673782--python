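"""Derive indirect-calorimetry quantities from a VO2/VCO2 time series.

Builds a small table of measurements (already normalized to kg^0.75) and
prints RER, energy expenditure and substrate oxidation rates.
"""

import pandas as pd

from ampedit.calorimetry import derive

measurements = pd.DataFrame(
    {
        "time_min": [0, 15, 30, 45],
        "vo2": [1000.0, 950.0, 1100.0, 1020.0],
        "vco2": [700.0, 900.0, 1100.0, 850.0],
    }
)
out = derive(measurements)
print(out.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print("\nRER = VCO2/VO2 (0.7 ~ lipid fuel, 1.0 ~ carbohydrate); energy "
      "expenditure in kcal/day/kg^0.75; oxidation rates in g/min/kg^0.75 "
      "(negative values are flagged, not clipped).")
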