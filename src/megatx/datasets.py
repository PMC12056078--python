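"""Reported inputs for the Tn_CO-1 case study in *Thermoanaerobacter kivui*.

These are the published coordinates, depths, junction 50-mers and
steady-state chemostat measurements for the CO-adapted strain CO-1 and its
86-kb circular megatransposon.  They serve as worked-example inputs: the
package recomputes the derived quantities (circle length, copy ratio,
yields, stoichiometric ratios, carbon balances) from them at run time.
"""

from __future__ import annotations

import pandas as pd

from .intervals import Segment

#: chromosomal coordinates (1-based inclusive) of the two duplicated regions
#: whose head-to-tail join forms the circular element
TN_CO1_DUP1 = Segment("chromosome", 1_839_957, 1_900_058)
TN_CO1_DUP2 = Segment("chromosome", 1_908_405, 1_934_113)

#: a 2,438-span deletion found in the CO-adapted strains
CO1_DELETION = Segment("chromosome", 233_431, 235_869)

#: mean short-read coverage inside each duplication and genome-wide
DUPLICATION_DEPTHS = {"dup1": 1765.0, "dup2": 1739.0, "background": 802.0}

#: the two circle-specific junction 50-mers (25 bp per flank) used for PCR
#: validation and read-based quantification
JUNCTION_P1P2 = "AAAACAGGGCACTTAAGTGCCCTGTTCAGACTGTTGACAAAATATCGGGA"
JUNCTION_P3P4 = "AGTATATCTTTTTTATATTATCCATATTGCAAAAGCAAGACAAGTTGGAA"

#: long-read junction abundance observed on CO vs glucose (reads per Gb)
READS_PER_GB_CO = 300.0
READS_PER_GB_GLUCOSE_RANGE = (0.0, 34.0)

#: growth rates quoted for carboxydotrophic growth (h^-1)
MU_MAX_CO1 = 0.25
MU_MAX_C_AUTOETHANOGENUM = 0.12

_CHEMOSTAT_ROWS = [
    # strain, gas, D, biomass±sd, acetate±sd, q_h2±sd, q_co2±sd, q_co±sd,
    # q_ace±sd, y_biomass_s±sd, y_ace_biomass±sd, c_balance±sd
    ("G-1", "H2/CO2", 0.10, 0.07, 0.01, 1.60, 0.18, 172.4, 45.6, 80.3, 22.0,
     None, None, 40.8, 10.6, 0.60, 0.14, 0.41, 0.11, 108.5, 3.1),
    ("G-1", "syngas", 0.10, 0.30, 0.02, 6.12, 0.07, 97.6, 1.5, 21.4, 4.2,
     52.3, 6.6, 34.3, 2.3, None, None, 0.34, 0.02, 99.2, 4.9),
    ("CO-1", "H2/CO2", 0.10, 0.10, 0.01, 2.32, 0.14, 175.2, 14.0, 89.2, 7.2,
     None, None, 40.8, 1.3, 0.57, 0.05, 0.41, 0.01, 104.8, 8.0),
    ("CO-1", "syngas", 0.10, 0.29, 0.02, 6.01, 0.09, 92.9, 6.0, 20.7, 1.0,
     52.2, 5.7, 34.3, 2.9, None, None, 0.34, 0.03, 95.8, 4.0),
    ("CO-1", "CO", 0.10, 0.24, 0.02, 2.18, 0.09, -16.7, 3.9, -47.0, 6.0,
     80.0, 8.9, 14.6, 0.5, 1.26, 0.14, 0.15, 0.01, 102.4, 4.1),
    ("CO-1", "CO", 0.20, 0.26, 0.01, 2.12, 0.13, -26.1, 0.4, -75.0, 0.7,
     122.2, 18.9, 27.3, 0.5, 1.66, 0.26, 0.14, 0.01, 109.4, 1.0),
]

_CHEMOSTAT_COLUMNS = [
    "strain", "gas", "dilution_rate",
    "biomass", "biomass_sd", "acetate", "acetate_sd",
    "q_h2", "q_h2_sd", "q_co2", "q_co2_sd", "q_co", "q_co_sd",
    "q_ace", "q_ace_sd", "y_biomass_s", "y_biomass_s_sd",
    "y_ace_biomass", "y_ace_biomass_sd", "c_balance", "c_balance_sd",
]


def chemostat_table() -> pd.DataFrame:
    """Published steady-state chemostat measurements (mean ± s.d. columns).

    Yields and balances here are averages of per-replicate ratios, so
    recomputing a ratio from the mean columns can differ from the printed
    mean by up to roughly one standard deviation (ratio of means is not the
    mean of ratios).
    """
    return pd.DataFrame(_CHEMOSTAT_ROWS, columns=_CHEMOSTAT_COLUMNS)


def chemostat_record(strain: str, gas: str, dilution_rate: float):
    """One published condition as a SteadyStateRecord."""
    from .physio import SteadyStateRecord

    table = chemostat_table()
    row = table[
        (table.strain == strain)
        & (table.gas == gas)
        & (table.dilution_rate == dilution_rate)
    ]
    if len(row) != 1:
        raise KeyError(f"no unique condition {strain}/{gas}/D={dilution_rate}")
    r = row.iloc[0]
    return SteadyStateRecord(
        strain=r.strain,
        gas=r.gas,
        dilution_rate=float(r.dilution_rate),
        biomass=float(r.biomass),
        acetate=float(r.acetate),
        q_h2=None if pd.isna(r.q_h2) else float(r.q_h2),
        q_co2=None if pd.isna(r.q_co2) else float(r.q_co2),
        q_co=None if pd.isna(r.q_co) else float(r.q_co),
        q_ace=None if pd.isna(r.q_ace) else float(r.q_ace),
    )
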