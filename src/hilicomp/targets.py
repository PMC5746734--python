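"""The packaged 54-metabolite target list.

The analyzed mixture spans five families — nucleosides, amino acids,
sugars, organic acids and others — chosen to cover the polar metabolome
HILIC is meant for.  Each entry stores the compound's molecular formula
(textbook values); the expected m/z is the protonated [M+H]+ or
deprotonated [M-H]- monoisotopic ion, computed at load time with
pyteomics, according to the family's customary ionization mode:
amines/amino acids/nucleosides in positive mode, sugars and organic
acids in negative mode.  Nucleosides ionize well in both modes and are
marked "either".
"""

from __future__ import annotations

from functools import lru_cache

import pandas as pd
from pyteomics import mass as _mass

from .retention import MetaboliteTarget

__all__ = ["TARGET_FORMULAS", "default_targets", "targets_dataframe"]

# (name, family, molecular formula, preferred polarity)
TARGET_FORMULAS: list[tuple[str, str, str, str]] = [
    # nucleosides (10)
    ("1-methyladenosine", "nucleoside", "C11H15N5O4", "either"),
    ("2'-O-methylcytidine", "nucleoside", "C10H15N3O5", "either"),
    ("2-thiocytidine", "nucleoside", "C9H13N3O4S", "either"),
    ("5-methylcytidine", "nucleoside", "C10H15N3O5", "either"),
    ("cytidine", "nucleoside", "C9H13N3O5", "either"),
    ("guanosine", "nucleoside", "C10H13N5O5", "either"),
    ("inosine", "nucleoside", "C10H12N4O5", "either"),
    ("pseudouridine", "nucleoside", "C9H12N2O6", "either"),
    ("ribothymidine", "nucleoside", "C10H14N2O6", "either"),
    ("uridine", "nucleoside", "C9H12N2O6", "either"),
    # amino acids (31)
    ("1-methyl-L-histidine", "amino_acid", "C7H11N3O2", "positive"),
    ("3-methyl-L-histidine", "amino_acid", "C7H11N3O2", "positive"),
    ("4-hydroxy-L-proline", "amino_acid", "C5H9NO3", "positive"),
    ("5-hydroxylysine", "amino_acid", "C6H14N2O3", "positive"),
    ("beta-alanine", "amino_acid", "C3H7NO2", "positive"),
    ("creatinine", "amino_acid", "C4H7N3O", "positive"),
    ("cysteine", "amino_acid", "C3H7NO2S", "positive"),
    ("L-proline", "amino_acid", "C5H9NO2", "positive"),
    ("L-arginine", "amino_acid", "C6H14N4O2", "positive"),
    ("L-cystathionine", "amino_acid", "C7H14N2O4S", "positive"),
    ("L-lysine", "amino_acid", "C6H14N2O2", "positive"),
    ("L-2-aminoadipic acid", "amino_acid", "C6H11NO4", "positive"),
    ("L-2-amino-n-butyric acid", "amino_acid", "C4H9NO2", "positive"),
    ("L-alanine", "amino_acid", "C3H7NO2", "positive"),
    ("L-anserine", "amino_acid", "C10H16N4O3", "positive"),
    ("L-carnosine", "amino_acid", "C9H14N4O3", "positive"),
    ("L-citrulline", "amino_acid", "C6H13N3O3", "positive"),
    ("L-glutamic acid", "amino_acid", "C5H9NO4", "positive"),
    ("L-histidine", "amino_acid", "C6H9N3O2", "positive"),
    ("L-homocystine", "amino_acid", "C8H16N2O4S2", "positive"),
    ("L-isoleucine", "amino_acid", "C6H13NO2", "positive"),
    ("L-leucine", "amino_acid", "C6H13NO2", "positive"),
    ("L-methionine", "amino_acid", "C5H11NO2S", "positive"),
    ("L-ornithine", "amino_acid", "C5H12N2O2", "positive"),
    ("L-serine", "amino_acid", "C3H7NO3", "positive"),
    ("L-threonine", "amino_acid", "C4H9NO3", "positive"),
    ("L-tryptophan", "amino_acid", "C11H12N2O2", "positive"),
    ("L-valine", "amino_acid", "C5H11NO2", "positive"),
    ("taurine", "amino_acid", "C2H7NO3S", "positive"),
    ("sarcosine", "amino_acid", "C3H7NO2", "positive"),
    ("L-aspartic acid", "amino_acid", "C4H7NO4", "positive"),
    # sugars (4)
    ("D-ribose", "sugar", "C5H10O5", "negative"),
    ("glucose", "sugar", "C6H12O6", "negative"),
    ("trehalose", "sugar", "C12H22O11", "negative"),
    ("mannitol", "sugar", "C6H14O6", "negative"),
    # organic acids (5)
    ("citric acid", "organic_acid", "C6H8O7", "negative"),
    ("ketoglutaric acid", "organic_acid", "C5H6O5", "negative"),
    ("pimelic acid", "organic_acid", "C7H12O4", "negative"),
    ("succinic acid", "organic_acid", "C4H6O4", "negative"),
    ("creatine", "organic_acid", "C4H9N3O2", "positive"),
    # others (4)
    ("hypoxanthine", "other", "C5H4N4O", "positive"),
    ("L-carnitine", "other", "C7H15NO3", "positive"),
    ("serotonin", "other", "C10H12N2O", "positive"),
    ("tryptamine", "other", "C10H12N2", "positive"),
]


def _ion_mz(formula: str, polarity: str) -> float:
    charge = -1 if polarity == "negative" else 1
    return float(_mass.calculate_mass(formula=formula, charge=charge))


@lru_cache(maxsize=1)
def default_targets() -> tuple[MetaboliteTarget, ...]:
    """The 54 packaged targets with expected ion m/z."""
    return tuple(
        MetaboliteTarget(name, family, _ion_mz(formula, pol), pol)
        for name, family, formula, pol in TARGET_FORMULAS
    )


def targets_dataframe() -> pd.DataFrame:
    """Targets as a DataFrame (name, family, expected_mz, polarity, formula)."""
    rows = [
        {"name": t.name, "family": t.family, "expected_mz": t.expected_mz,
         "polarity": t.preferred_polarity, "formula": f}
        for t, (_, _, f, _) in zip(default_targets(), TARGET_FORMULAS)
    ]
    return pd.DataFrame(rows)
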