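"""Published descriptive statistics for tea apical-bud size traits.

These are the printed population-level values for the four bud size features
across a 280-accession tea germplasm panel.  They serve two purposes: as
default parameters for the synthetic phenotype simulator (so simulated
populations live on a realistic scale) and as reference values for
summary-statistic sanity checks.
"""

from __future__ import annotations

import pandas as pd

#: Descriptive statistics per trait: max, min, mean, SD, CV (%), Shannon-Wiener
#: diversity index H' (nats, 10-class grading), broad-sense heritability h^2.
TRAIT_REFERENCE = pd.DataFrame(
    [
        ("length", 4.91, 1.46, 2.65, 0.38, 14.53, 1.97, 0.72),
        ("width", 0.71, 0.22, 0.35, 0.05, 15.46, 1.93, 0.90),
        ("perimeter", 10.62, 3.23, 5.75, 0.83, 14.45, 1.95, 0.71),
        ("area", 1.48, 0.27, 0.58, 0.14, 24.74, 1.95, 0.60),
    ],
    columns=["trait", "max", "min", "mean", "sd", "cv_pct", "h_prime", "h2"],
).set_index("trait")

#: Units of each bud size trait.
TRAIT_UNITS = {
    "length": "cm",
    "width": "cm",
    "perimeter": "cm",
    "area": "cm2",
}

#: Canonical trait order used throughout the package.
TRAITS = list(TRAIT_REFERENCE.index)

#: Provinces/regions of origin represented in the germplasm panel, used as
#: the default label pool for simulated accession origins.
DEFAULT_REGIONS = [
    "Fujian",
    "Yunnan",
    "Zhejiang",
    "Guangxi",
    "Anhui",
    "Hunan",
    "Guizhou",
    "Sichuan",
    "Guangdong",
    "Jiangxi",
    "Hubei",
    "Jiangsu",
    "Henan",
    "Shaanxi",
    "Hainan",
]
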