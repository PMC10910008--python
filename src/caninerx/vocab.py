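"""Drug vocabulary and static reference data.

The 13 antibiotics in scope, the reference category used in every
contrast, the four major organ systems tracked by keyword flags, and the
standardized wholesale treatment costs (GBP, relative to co-amoxiclav)
used for labeling.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: All antibiotics in the study vocabulary, alphabetical.
DRUGS: tuple[str, ...] = (
    "amoxicillin",
    "cefovecin",
    "cephalexin",
    "clindamycin",
    "co-amoxiclav",
    "doxycycline",
    "enrofloxacin",
    "erythromycin",
    "marbofloxacin",
    "metronidazole",
    "oxytetracycline",
    "pradofloxacin",
    "trimethoprim-sulfonamide",
)

#: Most frequently dispensed drug; reference category in every binomial contrast.
REFERENCE_DRUG = "co-amoxiclav"

#: Major organ systems flagged by clinical-note keywords, in canonical order.
ORGAN_SYSTEMS: tuple[str, ...] = ("gastrointestinal", "respiratory", "urinary", "skin")

#: Organ membership categories: the four systems plus "unspecified" (no flag).
ORGAN_CATEGORIES: tuple[str, ...] = ORGAN_SYSTEMS + ("unspecified",)

#: Columns a transaction table must carry.
REQUIRED_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "date",
    "sex",
    "neutered",
    "weight_kg",
    "age_y",
    "drug",
    "quantity",
    "cost",
    "flag_gastrointestinal",
    "flag_respiratory",
    "flag_urinary",
    "flag_skin",
)

FLAG_COLUMNS: tuple[str, ...] = tuple(f"flag_{s}" for s in ORGAN_SYSTEMS)


def standardized_costs() -> pd.DataFrame:
    """Standardized wholesale treatment cost relative to co-amoxiclav.

    Static reference table used only for labeling and summaries; it plays
    no role in model fitting.
    """
    with resources.files("caninerx").joinpath("data/standardized_costs.csv").open() as fh:
        return pd.read_csv(fh)
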