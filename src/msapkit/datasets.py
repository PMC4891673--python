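"""Bundled study inputs: printed band-type counts and uDMF retention table.

These are the published input tables of the grafting study this package
analyses; they are data, not expected outputs — every derived number is
recomputed by the operations in :mod:`msapkit.msap` and
:mod:`msapkit.inheritance`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .inheritance import InheritanceSeries, load_inheritance_table
from .msap import MethylationState, SampleProfile

#: scored individuals per selfed generation, GS2 through GS5
GENERATION_PANEL_SIZES: tuple[int, ...] = (15, 15, 10, 10)

#: the study's GS1 DMF inventory: 32 uniform + 44 distinctive of 926 loci
DMF_INVENTORY = {"uniform": 32, "distinctive": 44, "n_loci": 926, "n_individuals": 7}


def _data_path(name: str) -> Path:
    return Path(resources.files("msapkit.data").joinpath(name))  # type: ignore[arg-type]


def load_band_type_counts() -> pd.DataFrame:
    """Per-sample MSAP state counts (rows: samples; columns I, II, III, IV)."""
    df = pd.read_csv(_data_path("msap_type_counts.tsv"), sep="\t", index_col="sample")
    return df


def band_type_profiles() -> list[SampleProfile]:
    """The bundled count table as SampleProfile objects."""
    df = load_band_type_counts()
    states = {
        "I": MethylationState.UNMETHYLATED,
        "II": MethylationState.CHG,
        "III": MethylationState.CG,
        "IV": MethylationState.CG_CHG,
    }
    profiles = []
    for sample, row in df.iterrows():
        counts = {state: int(row[col]) for col, state in states.items()}
        profiles.append(SampleProfile(str(sample), counts, n_loci=sum(counts.values())))
    return profiles


def load_udmf_inheritance() -> list[InheritanceSeries]:
    """The bundled uDMF retention table across four generation transitions."""
    return load_inheritance_table(
        _data_path("udmf_inheritance.tsv"), panel_sizes=GENERATION_PANEL_SIZES
    )
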