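"""Published study conditions used as analysis inputs.

The printed per-CDR contact tables, docking geometries, SPR analyte ladders
and rate constants of the three p53R175H-specific TCRs (12-6, 38-10, 1a2)
against p53R175H-HLA-A2.  These are inputs to the synthetic generator and
the table arithmetic, not expected test outputs.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

from .contacts import LOOP_COLUMNS, ContactTable

#: per-CDR atomic contact counts, row order CDR1a..CDR3b (4.0 A cutoff)
TABLE2: Dict[str, Dict[str, Tuple[int, ...]]] = {
    "12-6": {"peptide": (0, 0, 0, 3, 0, 0, 0, 61),
             "mhc": (5, 39, 0, 28, 5, 3, 0, 12)},
    "38-10": {"peptide": (12, 0, 0, 54, 11, 1, 0, 4),
              "mhc": (8, 6, 0, 14, 5, 2, 0, 3)},
    "1a2": {"peptide": (11, 0, 0, 13, 0, 1, 0, 36),
            "mhc": (13, 18, 0, 28, 0, 0, 0, 1)},
}

#: (crossing angle, incident angle) in degrees
DOCKING: Dict[str, Tuple[float, float]] = {
    "12-6": (51.0, 20.0),
    "38-10": (34.0, 27.0),
    "1a2": (30.0, 1.0),
}

#: analyte concentration ladders (uM) flowed over immobilized pMHC
LADDERS_uM: Dict[str, Tuple[float, ...]] = {
    "12-6": (0.19, 0.39, 0.78, 1.56, 3.12, 6.25, 12.5, 25, 50),
    "38-10": (0.39, 0.78, 1.56, 3.12, 6.25, 12.5, 25, 50.0, 100),
    "1a2": (0.19, 0.39, 0.78, 1.56, 3.12, 6.25, 12.5, 50),
}

#: equilibrium dissociation constants (uM)
EQUILIBRIUM_KD_uM: Dict[str, float] = {"12-6": 1.1, "38-10": 39.9, "1a2": 16.2}

#: measured kinetic rates for the highest-affinity TCR
KON_12_6: float = 2.5e4   # M^-1 s^-1
KOFF_12_6: float = 0.032  # s^-1

RMAX_RU: float = 100.0    # simulated surface capacity, response units


def contact_table(tcr: str) -> ContactTable:
    """The printed per-CDR contact counts of one TCR as a ContactTable."""
    counts = {}
    for target, row in TABLE2[tcr].items():
        for loop, c in zip(LOOP_COLUMNS, row):
            counts[(loop, target)] = c
    return ContactTable(counts=counts)


def contact_layout(tcr: str) -> Mapping[str, Mapping[str, int]]:
    """The printed counts as a synthetic-generator planting layout."""
    layout: Dict[str, Dict[str, int]] = {}
    for target, row in TABLE2[tcr].items():
        for loop, c in zip(LOOP_COLUMNS, row):
            if c:
                layout.setdefault(loop, {})[target] = c
    return layout
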