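"""Published reference performance values used as frozen expectations.

Each entry is (label, numerator, denominator, reported integer percent):
specificity rows count correct rejections among 30 healthy-control eyes,
sensitivity rows count true positives among 17 definitely-progressing eyes,
and the precision row counts confirmed true positives among flagged patient
eyes.  The rounding convention (half-up to integer percent) must reproduce
every reported percentage from its count pair.
"""

# Event analysis at the 2.5th-percentile cut-off: single OCT metrics.
EVENT_OCT = [
    # specificity (correct rejections / 30)
    ("G_small/spec", 29, 30, 97), ("T_small/spec", 29, 30, 97),
    ("TI_small/spec", 28, 30, 93), ("TS_small/spec", 30, 30, 100),
    ("N_small/spec", 29, 30, 97), ("NI_small/spec", 29, 30, 97),
    ("NS_small/spec", 28, 30, 93),
    ("G_MRW/spec", 24, 30, 80), ("T_MRW/spec", 27, 30, 90),
    ("TI_MRW/spec", 27, 30, 90), ("TS_MRW/spec", 29, 30, 97),
    ("N_MRW/spec", 29, 30, 97), ("NI_MRW/spec", 28, 30, 93),
    ("NS_MRW/spec", 30, 30, 100),
    ("G_GCL/spec", 29, 30, 97), ("I_GCL/spec", 30, 30, 100),
    ("TI_GCL/spec", 30, 30, 100), ("NI_GCL/spec", 26, 30, 87),
    ("S_GCL/spec", 29, 30, 97), ("TS_GCL/spec", 30, 30, 100),
    ("NS_GCL/spec", 28, 30, 93),
    # sensitivity (true positives / 17)
    ("G_small/sens", 11, 17, 65), ("T_small/sens", 7, 17, 41),
    ("TI_small/sens", 13, 17, 77), ("TS_small/sens", 13, 17, 77),
    ("N_small/sens", 5, 17, 29), ("NI_small/sens", 10, 17, 59),
    ("NS_small/sens", 11, 17, 65),
    ("G_MRW/sens", 11, 17, 65), ("T_MRW/sens", 4, 17, 24),
    ("TI_MRW/sens", 7, 17, 41), ("TS_MRW/sens", 9, 17, 53),
    ("N_MRW/sens", 6, 17, 35), ("NI_MRW/sens", 7, 17, 41),
    ("NS_MRW/sens", 8, 17, 47),
    ("G_GCL/sens", 14, 17, 82), ("I_GCL/sens", 9, 17, 53),
    ("TI_GCL/sens", 13, 17, 77), ("NI_GCL/sens", 11, 17, 65),
    ("S_GCL/sens", 5, 17, 29), ("TS_GCL/sens", 6, 17, 35),
    ("NS_GCL/sens", 6, 17, 35),
]

# Event analysis: single VF metrics.
EVENT_VF = [
    ("MD_24/spec", 29, 30, 97), ("supMD_24/spec", 29, 30, 97),
    ("infMD_24/spec", 30, 30, 100), ("PSD_24/spec", 28, 30, 93),
    ("VFI_24/spec", 28, 30, 93),
    ("MD_10/spec", 29, 30, 97), ("supMD_10/spec", 29, 30, 97),
    ("infMD_10/spec", 30, 30, 100), ("PSD_10/spec", 27, 30, 90),
    ("MD_24/sens", 9, 17, 53), ("supMD_24/sens", 7, 17, 41),
    ("infMD_24/sens", 5, 17, 29), ("PSD_24/sens", 4, 17, 24),
    ("VFI_24/sens", 4, 17, 24),
    ("MD_10/sens", 7, 17, 41), ("supMD_10/sens", 5, 17, 29),
    ("infMD_10/sens", 4, 17, 24), ("PSD_10/sens", 5, 17, 29),
]

# Event analysis: structure-structure combinations.
EVENT_SS = [
    ("G_small OR G_MRW/spec", 24, 30, 80), ("G_small AND G_MRW/spec", 29, 30, 97),
    ("TI_small OR TI_MRW/spec", 25, 30, 83), ("TI_small AND TI_MRW/spec", 30, 30, 100),
    ("TS_small OR TS_MRW/spec", 29, 30, 97), ("TS_small AND TS_MRW/spec", 30, 30, 100),
    ("G_small AND G_GCL/spec", 30, 30, 100), ("G_small OR G_GCL/spec", 28, 30, 93),
    ("InferiorSS/spec", 30, 30, 100), ("TI or GCL/spec", 28, 30, 93),
    ("SuperiorSS/spec", 30, 30, 100), ("TS or GCL/spec", 29, 30, 97),
    ("SS/spec", 30, 30, 100),
    ("G_small OR G_MRW/sens", 15, 17, 88), ("G_small AND G_MRW/sens", 7, 17, 41),
    ("TI_small OR TI_MRW/sens", 14, 17, 82), ("TI_small AND TI_MRW/sens", 6, 17, 35),
    ("TS_small OR TS_MRW/sens", 13, 17, 77), ("TS_small AND TS_MRW/sens", 9, 17, 53),
    ("G_small AND G_GCL/sens", 10, 17, 59), ("G_small OR G_GCL/sens", 15, 17, 88),
    ("InferiorSS/sens", 12, 17, 71), ("TI or GCL/sens", 15, 17, 88),
    ("SuperiorSS/sens", 6, 17, 35), ("TS or GCL/sens", 15, 17, 88),
    ("SS/sens", 13, 17, 77),
]

# Event analysis: structure-function combinations.
EVENT_SF = [
    ("G_small AND MD_24/spec", 30, 30, 100), ("G_small OR MD_24/spec", 28, 30, 93),
    ("G_GCL AND MD_10/spec", 30, 30, 100), ("G_GCL OR MD_10/spec", 28, 30, 93),
    ("globals OR-AND/spec", 30, 30, 100), ("globals AND-AND/spec", 30, 30, 100),
    ("SF_global/spec", 30, 30, 100), ("SF_sec/spec", 30, 30, 100),
    ("G_small AND MD_24/sens", 6, 17, 35), ("G_small OR MD_24/sens", 14, 17, 82),
    ("G_GCL AND MD_10/sens", 7, 17, 41), ("G_GCL OR MD_10/sens", 14, 17, 82),
    ("globals OR-AND/sens", 10, 17, 59), ("globals AND-AND/sens", 4, 17, 24),
    ("SF_global/sens", 10, 17, 59), ("SF_sec/sens", 11, 17, 65),
]

# Trend-vs-event specificity comparison (trend columns).
TREND_SPEC = [
    ("G_small/trend_spec", 25, 30, 83), ("G_MRW/trend_spec", 24, 30, 80),
    ("TS_small/trend_spec", 29, 30, 97), ("TI_GCL/trend_spec", 28, 30, 93),
    ("MD_24/trend_spec", 27, 30, 90), ("MD_10/trend_spec", 27, 30, 90),
    ("G_small AND G_GCL/trend_spec", 29, 30, 97), ("SS/trend_spec", 30, 30, 100),
    ("globals OR-AND/trend_spec", 28, 30, 93), ("SF_sec/trend_spec", 29, 30, 97),
]

PRECISION = [("SS/precision", 13, 15, 87)]

ALL_PRINTED = EVENT_OCT + EVENT_VF + EVENT_SS + EVENT_SF + TREND_SPEC + PRECISION

# Reported 95% bootstrap CIs (1000 resamples, empirical 2.5/97.5 percentiles)
# for the most common count pairs: (successes, n) -> (lo_pct, hi_pct).
BOOTSTRAP_CIS = {
    (11, 17): (41, 88),
    (29, 30): (90, 100),
}
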