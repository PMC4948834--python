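"""Published per-sample sequencing summaries for the eight-patient COPD sputum cohort.

Four moderate (GOLD 2) and four severe (GOLD 3) male COPD patients were
profiled both by 16S rRNA V4 amplicon sequencing (plus a no-template
negative control) and by shotgun metatranscriptome sequencing.  The raw
sequence data are deposited externally; the per-sample accounting printed
in the study report is reproduced here as the input to the aggregate
checks (column totals, group means, human read fractions).

Counts are exact integers as printed; Shannon indices are printed to two
decimals.
"""

from __future__ import annotations

import pandas as pd

SAMPLES = [
    "Moderate 1", "Moderate 2", "Moderate 3", "Moderate 4",
    "Severe 1", "Severe 2", "Severe 3", "Severe 4",
]

GROUPS = pd.Series(
    ["moderate"] * 4 + ["severe"] * 4, index=SAMPLES, name="group"
)


def amplicon_summary() -> pd.DataFrame:
    """Per-sample 16S rRNA amplicon accounting (patients only).

    Columns: raw, high-quality and reference-mapped read counts, counts
    after negative-control correction, OTU richness, and Shannon index
    before/after correction.
    """
    data = {
        "raw_reads":         [49760, 83694, 26473, 34861, 60355, 25345, 68394, 71108],
        "high_quality_reads": [25597, 47387, 12615, 19059, 24008, 22870, 11715, 37500],
        "mapped_reads":       [14312, 25733,  6006, 10926, 10736, 12714,  5392, 21888],
        "corrected_reads":    [3718, 17301,  1798,  2642,  7605,  9954,  3385, 17427],
        "otus":               [105,    381,    93,    73,   178,   251,    82,   117],
        "shannon":            [1.78,  2.69,  1.97,  1.47,  2.40,  2.31,  1.95,  1.65],
        "corrected_shannon":  [1.66,  2.65,  2.01,  1.45,  2.31,  2.30,  1.93,  1.60],
    }
    return pd.DataFrame(data, index=pd.Index(SAMPLES, name="sample"))


# Negative-control amplicon accounting: raw / high-quality / mapped reads,
# OTU count and Shannon index of the no-template control library.
NEGATIVE_CONTROL = {
    "raw_reads": 91697,
    "high_quality_reads": 91496,
    "mapped_reads": 63632,
    "otus": 61,
    "shannon": 0.77,
}


def metatranscriptome_summary() -> pd.DataFrame:
    """Per-sample metatranscriptome accounting.

    Kingdom-level read counts partition the mapped reads: per sample,
    human + bacteria + archaea + virus + fungi + others equals
    ``mapped_reads`` exactly.
    """
    data = {
        "raw_reads": [
            45555205, 40292441, 45334008, 73477585,
            49577314, 44179073, 42193436, 43128219,
        ],
        "high_quality_reads": [
            41642413, 32981685, 41793501, 21741202,
            45066829, 28706855, 37742565, 38178530,
        ],
        "mapped_reads": [
            38894741, 30470762, 40182052, 16552345,
            35038934, 16435822, 35813197, 35511293,
        ],
        "human": [
            34490886, 20904452, 38201059, 7385255,
            16521576, 7617886, 21650789, 33489840,
        ],
        "bacteria": [211591, 807492, 32935, 4001802, 807492, 5313659, 301170, 124862],
        "archaea": [30495, 7049, 4368, 3217, 543, 886, 6408, 11275],
        "virus": [1794, 3737, 1458, 342982, 5960, 18288, 258223, 2364],
        "fungi": [9333, 43800, 909, 156386, 75889, 22396, 69756, 1600],
        "others": [
            4150642, 8704232, 1941323, 4662703,
            12565610, 3462707, 13526851, 1881352,
        ],
        "shannon": [0.48, 2.27, 0.48, 2.18, 2.26, 2.26, 2.59, 1.34],
    }
    return pd.DataFrame(data, index=pd.Index(SAMPLES, name="sample"))


KINGDOM_COLUMNS = ["human", "bacteria", "archaea", "virus", "fungi", "others"]
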