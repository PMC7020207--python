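"""Published summary of the two French national maize weed surveys.

The raw field records of the 1970s and 2000s monitoring campaigns were
never deposited, but the published species-level summary table is public:
regional frequency (%) and local abundance (individuals/m^2) in the 2000s
with 95% stratified-bootstrap confidence intervals, the corresponding
1970s point values, the categorical status call for each metric, and the
within-2000s Spearman trend.  The 1970s survey recorded only the 29 most
frequent species, so 1970s frequencies below the 2.3% recording floor are
given as ``<2.3`` (parsed to NaN with ``below_detection=True``).

These printed values serve as worked-example inputs: recomputing the
status calls, frequency differences and top-list overlaps from them
exercises the classification arithmetic without the raw data.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

#: 1970s recording floor: only species with frequency >= 2.3% were recorded
DETECTION_THRESHOLD_1970S = 2.3

_SURVEY_SUMMARY_CSV = """\
rank,species,f2000,f2000_lo,f2000_hi,f1970,f_status,a2000,a2000_lo,a2000_hi,a1970,a_status,rho,p_value,trend
1,Chenopodium album,64.3,57.7,70.3,60.3,=,13.9,11.2,16.6,12.4,=,-0.250,0.594,=
2,Solanum nigrum,39.1,33.1,45.1,26.5,+,7.5,5.5,9.6,6.9,=,-0.143,0.783,=
3,Echinochloa crus-galli,35.5,29.7,41.1,38.0,=,8.4,6.2,10.6,12.9,-,0.357,0.444,=
4,Persicaria maculata + P. lapathifolia,26.7,21.1,32.0,35.1,-,4.9,3.4,6.6,3.1,+,0.786,0.048,+
5,Amaranthus retroflexus,21.1,16.0,25.7,26.7,-,3.6,2.3,5.2,5.8,-,0.071,0.906,=
6,Mercurialis annua,20.1,15.5,25.1,15.4,+,3.3,2.1,4.7,3.9,=,0.286,0.556,=
7,Digitaria sanguinalis,19.8,15.4,24.6,40.2,-,5.2,3.4,7.1,14.5,-,0.214,0.662,=
8,Polygonum aviculare,16.6,12.6,21.1,26.4,-,2.1,1.4,3.1,7.5,-,-0.357,0.444,=
9,Fallopia convolvulus,13.9,9.7,18.3,21.3,-,1.8,1.0,2.6,4.1,-,0.536,0.236,=
10,Calystegia sepium,12.3,8.0,16.6,<2.3,N,1.7,1.0,2.6,?,N,0.750,0.066,(+)
11,Lysimachia arvensis,12.0,8.0,16.0,13.2,=,1.1,0.6,1.9,2.9,-,0.571,0.200,=
12,Stellaria media,11.3,7.4,15.4,14.3,=,2.6,1.4,4.0,3.6,=,-0.928,0.007,-
13,Convolvulus arvensis,10.6,6.9,14.3,15.5,-,1.4,0.8,2.2,2.8,-,0.143,0.783,=
14,Senecio vulgaris,10.5,6.9,14.3,<2.3,N,1.2,0.9,1.7,?,N,0.714,0.088,(+)
15,Sonchus asper,10.0,6.8,13.7,<2.3,N,1.2,0.8,1.7,?,N,0.893,0.012,+
16,Setaria pumila,9.6,6.3,16.1,9.8,=,2.9,1.4,4.5,3.6,=,0.464,0.302,=
17,Matricaria chamomilla + Tripleurospermum inodorum,8.4,5.1,12.0,7.9,=,1.3,0.7,2.1,2.3,-,0.607,0.167,=
18,Poa annua,8.1,4.6,11.4,<2.3,N,1.4,0.6,2.5,?,N,0.857,0.024,+
19,Setaria verticillata,7.5,4.0,10.9,<2.3,N,0.9,0.4,1.6,?,?,0.750,0.066,(+)
20,Cynodon dactylon,7.2,4.0,10.3,5.2,=,1.5,0.6,2.6,1.3,=,0.857,0.024,+
21,Atriplex patula,7.1,4.0,10.3,10.3,=,1.0,0.4,1.6,2.8,-,0.429,0.353,=
22,Setaria viridis,7.1,4.0,10.3,10.3,=,1.3,0.5,2.3,4.2,-,0.286,0.556,=
23,Capsella bursa-pastoris,7.0,4.0,10.3,<2.3,N,1.0,0.5,1.8,?,N,-0.643,0.139,=
24,Veronica persica,6.6,3.4,9.7,<2.3,N,1.0,0.4,1.8,?,?,0.250,0.595,=
25,Lolium multiflorum,5.2,2.3,8.0,<2.3,N,0.7,0.3,1.2,?,?,-0.464,0.302,=
26,Datura stramonium,5.1,2.3,8.0,<2.3,N,1.1,0.4,1.9,?,?,-0.036,0.964,=
27,Lipandra polyspermum,4.3,1.7,7.4,<2.3,?,0.5,0.2,1.0,?,?,-0.071,0.906,=
28,Equisetum arvense,3.9,1.7,6.3,6.2,=,0.5,0.2,1.1,1.9,-,0.071,0.906,=
29,Kickxia spuria,3.9,1.7,6.3,<2.3,?,0.4,0.2,0.7,?,?,0.607,0.167,=
30,Panicum miliaceum,3.7,1.7,6.3,<2.3,?,0.7,0.2,1.3,?,?,-0.179,0.713,=
31,Cirsium arvense,3.6,1.7,6.3,6.3,=,0.5,0.3,0.9,1.6,-,-0.214,0.662,=
32,Fumaria officinalis,3.6,1.7,6.3,6.4,-,0.8,0.3,1.4,1.4,=,0.536,0.236,=
33,Panicum dichotomiflorum,3.6,1.1,6.3,<2.3,?,0.8,0.2,1.6,?,?,0.036,0.966,=
34,Sonchus oleraceus,3.4,1.1,5.7,<2.3,?,0.5,0.3,0.9,?,?,0.214,0.662,=
35,Alopecurus myosuroides,3.2,1.1,5.1,2.9,=,0.8,0.2,1.5,0.8,=,-0.821,0.034,-
36,Galium aparine subsp. aparine,3.2,1.1,5.1,4.6,=,0.4,0.2,0.8,1.1,-,0.500,0.267,=
37,Viola arvensis,2.9,1.1,5.1,4.6,=,0.4,0.1,1.0,1.4,-,-0.464,0.302,=
38,Sinapis arvensis,2.9,1.1,5.1,4.6,=,0.4,0.2,0.8,2.0,-,-0.428,0.354,=
39,Lamium purpureum,2.8,1.1,5.1,<2.3,?,0.4,0.1,0.9,?,?,-0.929,0.007,-
40,Portulacca oleracea,2.8,1.1,5.1,2.3,=,0.8,0.1,1.6,1.8,-,-0.429,0.353,=
42,Raphanus raphanistrum,2.3,0.6,4.6,15.6,-,0.4,0.1,1.1,3.0,-,0.643,0.139,=
44,Elytrigia repens,1.9,0.6,4.0,4.5,-,0.3,0.1,0.8,2.1,-,0.107,0.840,=
77,Spergula arvensis,0.6,0.0,1.7,6.9,-,0.1,0.0,0.2,2.9,-,-0.211,0.669,=
81,Galinsoga quadriradiata + G. parviflora,0.6,0.0,1.7,2.3,-,0.1,0.0,0.3,0.4,-,0.556,0.256,=
"""

#: 1970s per-region field counts used as bootstrap strata
STRATA_1970S = {
    "East": 26,
    "South-West": 64,
    "North-Parisian basin": 41,
    "West": 26,
    "South-East": 17,
}

#: number of fields surveyed in the 2000s campaign
N_FIELDS_2000S = 484


def survey_summary() -> pd.DataFrame:
    """Return the published survey-comparison table as a DataFrame.

    ``f1970``/``a1970`` are numeric with NaN where the 1970s value was
    below the recording floor; the boolean ``below_detection`` marks those
    rows.
    """
    df = pd.read_csv(_io.StringIO(_SURVEY_SUMMARY_CSV), dtype={"species": str})
    df["below_detection"] = df["f1970"] == "<2.3"
    df["f1970"] = pd.to_numeric(df["f1970"], errors="coerce")
    df["a1970"] = pd.to_numeric(df["a1970"], errors="coerce")
    for col in ("f2000", "f2000_lo", "f2000_hi", "a2000", "a2000_lo",
                "a2000_hi", "rho", "p_value"):
        df[col] = df[col].astype(float)
    return df.set_index("species")


def top_frequency_overlap(df: pd.DataFrame | None = None, k: int = 10) -> int:
    """Number of taxa shared between the two periods' top-k frequency lists."""
    if df is None:
        df = survey_summary()
    top_new = set(df["f2000"].nlargest(k).index)
    top_old = set(df["f1970"].dropna().nlargest(k).index)
    return len(top_new & top_old)


def frequency_difference(df: pd.DataFrame | None = None,
                         species: str | None = None) -> float:
    """Rounded 2000s minus 1970s regional frequency (percentage points)."""
    if df is None:
        df = survey_summary()
    row = df.loc[species]
    if np.isnan(row["f1970"]):
        raise ValueError(f"{species}: no 1970s frequency on record")
    return float(np.round(row["f2000"] - row["f1970"]))
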