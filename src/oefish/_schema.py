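"""Canonical column names shared across the pipeline.

A reach table has one row per river segment; a survey table has one row per
sampling event.  Species occupy one 0/1 column each in the survey table, named
by their species identifier.
"""

REACH_ID = "reach_id"
RIVER_CLASS = "river_class"

# Reach covariates (units in the name where ambiguity is possible)
US_NATIVE = "us_native"                  # upstream native-vegetation proportion, [0, 1]
US_PASTURE = "us_pasture"                # upstream pasture proportion, [0, 1]
RIP_NATIVE_PCT = "rip_native_pct"        # riparian native cover, percent [0, 100]
RIP_SHADE = "rip_shade"                  # riparian shade proportion, [0, 1]
RIP_SHADE_PREHUMAN = "rip_shade_prehuman"  # shade under complete pre-human vegetation
NO3N = "no3n_mgl"                        # nitrate-nitrogen, mg/L
DRP = "drp_mgl"                          # dissolved reactive phosphorus, mg/L
DS_DAM = "ds_dam"                        # downstream dam / obstruction indicator {0, 1}
SEG_SLOPE = "seg_slope_deg"              # segment slope, degrees
JAN_AIR_TEMP = "jan_air_temp_c"          # summer (January) air temperature, deg C
FLOOD_FREQ = "flood_freq"                # annual frequency of flows > 3x median flow
DIST_COAST = "dist_coast_km"             # distance to coast, km

CORE_COVARIATES = [
    US_NATIVE,
    US_PASTURE,
    RIP_NATIVE_PCT,
    RIP_SHADE,
    NO3N,
    DRP,
    DS_DAM,
    SEG_SLOPE,
    JAN_AIR_TEMP,
    FLOOD_FREQ,
    DIST_COAST,
]

# Survey table columns
SITE_ID = "site_id"
DATE = "date"
METHOD = "method"
REACH_LENGTH_M = "reach_length_m"

SURVEY_FIELDS = [SITE_ID, REACH_ID, DATE, METHOD, REACH_LENGTH_M]

ELECTRIC_METHODS = frozenset({"efi", "ef", "electric", "electric fishing", "electric-fishing"})
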