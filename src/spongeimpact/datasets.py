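"""Published reference inputs for the Flemish Cap sponge-ground assessment.

These are the printed constants the worked examples and acceptance checks
run on: the *Geodia barretti* physiological rates, the reported NAFO 3M
catch statistics with ex-vessel values, the Ashbridges Bay Treatment Plant
(ABTP) cost figures, US inflation rates to 2018, and the reported biomass
totals by NAFO division.  Nothing here is computed; everything downstream
of these numbers is.
"""

from __future__ import annotations

import pandas as pd

#: Reported sponge wet-weight biomass (t) by NAFO division, modelling approach,
#: over the 135,056.82 km² modelled area of the Flemish Cap region.
DIVISION_BIOMASS_T: dict[str, float] = {
    "3L": 28_060.0,
    "3M": 147_837.0,
    "3N": 51_543.0,
    "3O": 3_696.0,
}

#: Total modelled sponge biomass (t wet weight) over the modelled area.
TOTAL_MODELLED_BIOMASS_T: float = 231_136.0

#: Modelled area of seabed (km²), 50-2000 m depth.
MODELLED_AREA_KM2: float = 135_056.82

#: Reported sponge removal (t) by trawling 2010-2012 in Division 3M
#: (modelling approach), the basis of the filtration-loss valuation.
REMOVAL_3M_MODEL_T: float = 2_580.0

#: Reported swept-area footprint of the 2010-2012 trawl fleet (km²) and the
#: NAFO fishing-footprint area it sits in.
FLEET_FOOTPRINT_KM2: float = 22_765.18
NAFO_FOOTPRINT_AREA_KM2: float = 120_047.80

#: Modelled / grid-cell sponge biomass totals (t) within the NAFO fishing
#: footprint, the reference denominators for removal percentages.
FOOTPRINT_BIOMASS_MODEL_T: float = 116_143.0
FOOTPRINT_BIOMASS_GRID_T: float = 81_169.0

#: Swept area (m²) of one research-vessel survey tow, by trawl gear.
#: Campelen gear was used in Divisions 3LNO, Lofoten gear in 3M.
GEAR_SWEPT_AREA_M2: dict[str, float] = {"Campelen": 67_000.0, "Lofoten": 39_000.0}

#: Kilometres per nautical mile; 1 knot = 1 nm/h = 1.852 km/h.
KM_PER_NM: float = 1.852

#: Average US inflation rate from each catch year to the 2018 reference year.
INFLATION_RATE_TO_2018: dict[int, float] = {2010: 0.0178, 2011: 0.0158, 2012: 0.0150}
REFERENCE_YEAR: int = 2018


def catch_table_3m() -> pd.DataFrame:
    """Reported fish catch and ex-vessel value, NAFO Division 3M, 2010-2012.

    One row per species-year with a reported landing; ``value_usd`` is the
    reported ex-vessel value (catch × global reconstructed unit price).
    """
    rows = [
        ("Atlantic cod", 2010, 9_564, 18_735_451),
        ("Atlantic cod", 2011, 15_960, 33_102_275),
        ("Atlantic cod", 2012, 14_500, 24_822_180),
        ("Groundfish (NS)", 2010, 4_658, 5_181_757),
        ("Groundfish (NS)", 2011, 3_786, 4_291_103),
        ("Groundfish (NS)", 2012, 3_838, 4_894_955),
        ("Atlantic redfishes", 2010, 4_233, 5_436_154),
        ("Atlantic redfishes", 2011, 5_133, 8_669_485),
        ("Atlantic redfishes", 2012, 338, 534_995),
        ("Mixed species (marine fish nei)", 2010, 3_783, 2_033_120),
        ("Greenland halibut", 2010, 795, 2_322_683),
        ("Greenland halibut", 2012, 243, 782_402),
        ("Shrimps (Pandalus borealis)", 2010, 784, 1_412_739),
    ]
    return pd.DataFrame(rows, columns=["species", "year", "catch_t", "value_usd"])
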