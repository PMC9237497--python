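"""Published summary statistics from a two-variety cowpea mutagenesis trial.

These are the printed per-population summary tables of a multi-generation
gamma-ray / sodium-azide field experiment on the cowpea varieties
Gomati VU-89 and Pusa-578: treatment-mean matrices for the ten quantitative
traits in the M2 generation, plant-yield mean rows for the M2 and M3
generations, and a handful of printed (GCV %, h2 %, GA %) triples.

They serve two purposes: (i) as reference *inputs* for analyses whose raw
replicate data were never deposited (inter-population distances, genetic-gain
accounting, the GA identity), and (ii) as the source of the simulator's
default treatment mean shifts, so that synthetic trials reproduce the
published effect-size structure.

Trait codes: PH plant height (cm), DF days to flowering, DM days to
maturity, PPP pods per plant, BPP branches per plant, SPP seeds per pod,
SW 100-seed weight (g), PL pod length (cm), PY plant yield (g),
HI harvest index (%).
"""

from __future__ import annotations

import pandas as pd

TRAITS = ("PH", "DF", "DM", "PPP", "BPP", "SPP", "SW", "PL", "PY", "HI")

#: The 13 populations retained after the germination-based dose exclusion:
#: untreated control, four gamma doses (100-400 Gy), four sodium-azide doses
#: (0.01-0.04 %), and the four pairwise combinations.
M2_POPULATIONS = (
    "C", "G1", "G2", "G3", "G4",
    "S1", "S2", "S3", "S4",
    "G1+S1", "G2+S2", "G3+S3", "G4+S4",
)

#: Populations advanced to the M3 generation (six treated + control).
M3_POPULATIONS = ("C", "G1", "G2", "S1", "S2", "G1+S1", "G2+S2")

# M2 generation, variety Gomati VU-89: treatment means, one row per trait.
_GOMATI_M2 = {
    "PH": (182.61, 179.92, 178.82, 178.31, 176.72, 181.79, 179.19, 177.57,
           174.41, 178.87, 177.63, 175.89, 174.36),
    "DF": (80.16, 77.46, 77.36, 77.86, 77.66, 77.56, 77.76, 78.00, 78.26,
           77.96, 77.80, 79.10, 78.53),
    "DM": (154.83, 150.16, 150.26, 150.46, 149.80, 151.20, 149.03, 150.26,
           149.36, 149.73, 148.86, 145.00, 143.10),
    "PPP": (60.10, 66.46, 64.20, 62.53, 61.00, 63.10, 65.53, 65.30, 59.43,
            64.50, 68.03, 58.03, 56.96),
    "BPP": (8.63, 11.50, 10.00, 9.13, 9.23, 10.66, 9.50, 9.03, 8.80, 10.00,
            12.46, 9.03, 9.76),
    "SPP": (12.00, 12.50, 12.40, 12.30, 12.10, 12.80, 12.40, 12.26, 12.23,
            12.20, 12.03, 12.00, 11.96),
    "SW": (13.00, 13.50, 13.40, 13.30, 13.20, 13.70, 13.40, 13.20, 13.20,
           13.45, 13.06, 13.00, 12.90),
    "PL": (29.57, 30.73, 31.02, 31.12, 30.58, 31.29, 31.54, 30.43, 29.63,
           31.06, 32.03, 29.58, 29.17),
    "PY": (93.75, 112.00, 106.67, 102.28, 97.42, 110.01, 108.00, 105.50,
           95.94, 103.80, 106.97, 90.52, 87.80),
    "HI": (27.13, 41.25, 36.62, 38.31, 36.37, 40.66, 39.02, 36.65, 34.87,
           37.13, 35.90, 32.52, 30.05),
}

#: M2 Gomati VU-89 trait-mean matrix, populations x traits.
GOMATI_M2_MEANS = pd.DataFrame(_GOMATI_M2, index=list(M2_POPULATIONS))

#: Printed plant-yield mean rows, keyed (variety, generation).
PLANT_YIELD_MEANS = {
    ("Gomati VU-89", "M2"): pd.Series(_GOMATI_M2["PY"], index=list(M2_POPULATIONS)),
    ("Pusa-578", "M2"): pd.Series(
        (83.51, 105.54, 101.90, 93.17, 86.09, 110.63, 97.76, 94.09, 81.01,
         100.38, 89.37, 83.29, 78.39),
        index=list(M2_POPULATIONS),
    ),
    ("Gomati VU-89", "M3"): pd.Series(
        (92.64, 119.27, 110.52, 115.28, 112.90, 106.72, 109.99),
        index=list(M3_POPULATIONS),
    ),
    ("Pusa-578", "M3"): pd.Series(
        (80.29, 112.83, 108.42, 117.01, 101.25, 105.90, 94.80),
        index=list(M3_POPULATIONS),
    ),
}

#: Printed (GCV %, h2 %, GA % of mean) triples used to check the genetic
#: advance identity GA% = k * GCV% * sqrt(h2%/100) with k = 2.64.
#: (variety, generation, trait, population) -> (gcv_pct, h2_pct, ga_pct)
GA_IDENTITY_CELLS = {
    ("Gomati VU-89", "M2", "PY", "G1"): (7.43, 82.46, 17.81),
    ("Gomati VU-89", "M2", "HI", "G1"): (9.35, 74.87, 21.36),
    ("Gomati VU-89", "M2", "PPP", "G1"): (13.64, 90.39, 34.24),
    ("Pusa-578", "M2", "PY", "G1"): (5.01, 86.26, 12.28),
    ("Gomati VU-89", "M3", "PY", "G1"): (9.41, 96.01, 24.34),
}
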