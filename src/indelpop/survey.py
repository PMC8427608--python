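"""Published inputs for the ADPRHL1 104-bp indel.

The F2 resource population's genotype counts and the 13-population breed
survey (sample sizes, printed genotype and allele frequencies) are the only
raw data published for this locus; they are the inputs to the locus-summary
statistics and the polymorphism classification.

For the non-F2 breeds only rounded frequencies are printed, not counts, so
their He/Ne/PIC can be recomputed only from the 3-decimal allele frequencies.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import GenotypePanel

#: Genotype counts in the Gushi x Anak F2 resource population (n = 783).
F2_PANEL = GenotypePanel(population="F2", n_DD=23, n_ID=423, n_II=337)

#: Breed groups used in the survey.
COMMERCIAL_BROILERS = ("Ross308", "817", "AA", "Cobb", "Hubbard")
DUAL_PURPOSE = ("GS", "GF", "WH", "XC", "CS")
COMMERCIAL_LAYERS = ("HL", "LM")

_SURVEY_ROWS = [
    # population, group, n, freq_DD, freq_ID, freq_II, p_D, p_I
    ("F2",      "F2 resource population", 783, 0.03, 0.54, 0.43, 0.299, 0.701),
    ("Ross308", "commercial broiler",     192, 0.04, 0.29, 0.67, 0.188, 0.812),
    ("817",     "commercial broiler",      74, 0.00, 0.30, 0.70, 0.149, 0.851),
    ("AA",      "commercial broiler",     552, 0.00, 0.01, 0.99, 0.003, 0.997),
    ("Cobb",    "commercial broiler",     237, 0.01, 0.25, 0.74, 0.133, 0.867),
    ("Hubbard", "commercial broiler",     595, 0.00, 0.23, 0.77, 0.116, 0.884),
    ("GS",      "dual-purpose",           284, 0.01, 0.62, 0.37, 0.320, 0.680),
    ("GF",      "dual-purpose",           156, 0.28, 0.47, 0.25, 0.513, 0.487),
    ("WH",      "dual-purpose",           441, 0.11, 0.43, 0.46, 0.324, 0.676),
    ("XC",      "dual-purpose",           572, 0.08, 0.46, 0.47, 0.305, 0.695),
    ("CS",      "dual-purpose",           184, 0.14, 0.48, 0.39, 0.375, 0.625),
    ("HL",      "commercial layer",       392, 0.11, 0.67, 0.22, 0.444, 0.556),
    ("LM",      "commercial layer",        64, 0.13, 0.45, 0.42, 0.352, 0.648),
]


def breed_survey() -> pd.DataFrame:
    """The published 13-population survey as a DataFrame."""
    return pd.DataFrame(
        _SURVEY_ROWS,
        columns=["population", "group", "n", "freq_DD", "freq_ID", "freq_II",
                 "p_D", "p_I"],
    )
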