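"""Published catalog compositions and builders for reference fixtures.

The 1376-gene innate-immunity catalog of record derives from InnateDB
(http://www.innatedb.com); its published composition over 5 subcellular
locations and 14 functional types is reproduced here so that a structurally
faithful catalog can be rebuilt without shipping the (weekly-updated)
symbol list itself.  Symbols in the rebuilt catalog are placeholders.
"""

from __future__ import annotations

from innatome_miner.catalog import GeneCatalog

INNATOME_SIZE = 1376

# Subcellular-location composition of the InnateDB-derived catalog.
INNATOME_LOCATION_COUNTS: dict[str, int] = {
    "cytoplasm": 481,
    "extracellular space": 151,
    "nucleus": 405,
    "plasma membrane": 86,
    "other": 253,
}

# Functional-type composition of the same catalog.
INNATOME_FUNCTION_COUNTS: dict[str, int] = {
    "cytokine": 53,
    "enzyme": 232,
    "g-protein-coupled receptor": 22,
    "growth factor": 21,
    "ion channel": 8,
    "kinase": 113,
    "ligand-dependent nuclear receptor": 6,
    "other": 459,
    "peptidase": 54,
    "phosphatase": 22,
    "transcription regulator": 229,
    "translation regulator": 10,
    "transmembrane receptor": 88,
    "transporter": 59,
}

HOUSEKEEPING_GENES = ("CHMP2A", "PSMB4", "ACTB", "GAPDH")

# Default panel sizes used by the synthetic generator.
TRAINED_IMMUNITY_PANEL_SIZE = 102
ROS_PANEL_SIZE = 84
HEAT_SHOCK_PANEL_SIZE = 82


def build_innatome_catalog(name: str = "innatome") -> GeneCatalog:
    """Build a 1376-gene catalog with the published location/function composition.

    Placeholder symbols IG0001..IG1376 are annotated so that every category
    carries exactly its published count under both schemes (the two schemes
    are assigned independently; their joint distribution is arbitrary).
    """
    assert sum(INNATOME_LOCATION_COUNTS.values()) == INNATOME_SIZE
    assert sum(INNATOME_FUNCTION_COUNTS.values()) == INNATOME_SIZE

    symbols = [f"IG{i:04d}" for i in range(1, INNATOME_SIZE + 1)]
    locations: list[str] = []
    for category, count in INNATOME_LOCATION_COUNTS.items():
        locations.extend([category] * count)
    functions: list[str] = []
    for category, count in INNATOME_FUNCTION_COUNTS.items():
        functions.extend([category] * count)

    annotations = {
        symbol: {"location_class": loc, "function_class": fun}
        for symbol, loc, fun in zip(symbols, locations, functions)
    }
    return GeneCatalog(
        name=name, species="agnostic", genes=set(symbols), annotations=annotations
    )


def housekeeping_catalog() -> GeneCatalog:
    """The four-gene housekeeping panel used for contrast QC."""
    return GeneCatalog(
        name="housekeeping", species="agnostic", genes=set(HOUSEKEEPING_GENES)
    )
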