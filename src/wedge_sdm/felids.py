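"""Published summary counts from the motivating six-felid field study.

The pipeline emulates, at desk scale, a continental presence-only study of
the six wild felids of Mexico (jaguar, bobcat, ocelot, cougar, margay,
jaguarundi) whose suitability predictions were confronted with camera-trap
capture rates in central-western Mexico.  The study's published summary
counts are kept here as reference inputs for bookkeeping cross-checks
(per-species counts must reproduce the published totals).
"""

#: 10 x 10 km grid cells with at least one presence, per species
PRESENCE_CELLS = {
    "bobcat": 2268,
    "cougar": 1091,
    "ocelot": 345,
    "jaguar": 298,
    "jaguarundi": 286,
    "margay": 220,
}

#: published total of presence cells across the six species
TOTAL_PRESENCE_CELLS = 4508

#: independent camera-trap events per species over the whole survey
INDEPENDENT_EVENTS = {
    "jaguar": 60,
    "bobcat": 560,
    "ocelot": 507,
    "cougar": 402,
    "margay": 134,
    "jaguarundi": 25,
}

#: published total of independent events
TOTAL_INDEPENDENT_EVENTS = 1688

#: cumulative survey effort in camera-days and number of camera sites
TOTAL_CAMERA_DAYS = 26784
N_CAMERA_SITES = 241
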