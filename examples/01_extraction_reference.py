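"""Reference chlorophyll quantification from extract absorbances.

Builds a tiny absorbance table (663.6 / 646.6 / 750 nm readings with the
pelleted culture volume), applies the 80% acetone / 20% methanol
extinction-coefficient equations, and prints the resulting chlorophyll a,
b and total concentrations of the original culture.
"""

import pandas as pd

from chloropix.extraction import chlorophyll_table

absorbances = pd.DataFrame(
    {
        "sample_id": ["dense", "mid", "near-blank"],
        "a663_6": [0.842, 0.310, 0.012],
        "a646_6": [0.395, 0.148, 0.008],
        "a750": [0.004, 0.003, 0.002],
        "culture_volume_ml": [0.5, 1.0, 2.0],
        "extract_volume_ml": [1.0, 1.0, 1.0],
    }
)

table = chlorophyll_table(absorbances)
print(table[["sample_id", "chl_a", "chl_b", "chl_total"]].round(3).to_string(index=False))
print(
    "\nConcentrations are ug/ml of the original culture; chl_total is exactly"
    "\nchl_a + chl_b because the total coefficients are the sums of the a and b"
    "\ncoefficients. The dense sample used only 0.5 ml of culture so its"
    "\nabsorbances stay below 1.00, and the division by volume rescales it."
)
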