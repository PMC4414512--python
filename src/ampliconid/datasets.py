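"""Bundled example data: a published dilution-series count table.

These are mapped-read counts from a validation experiment in which two
mammalian DNA pools contained pig and horse DNA at 1:10 and 1:50 of the
five majority species (cattle, sheep, rabbit, human, rat), amplified with
the three bundled universal primer pairs and sequenced on a semiconductor
platform.  They serve as a worked example for the counting, correlation and
detection-call operations, and as a realistic input for threshold
exploration.  The run-level base counts of the same sequencing run are
included for the Q20 arithmetic example.
"""

from __future__ import annotations

import pandas as pd

from .quantify import CountTable

__all__ = [
    "RUN_CALLED_NT",
    "RUN_Q20_NT",
    "dilution_series_counts",
    "dilution_series_tables",
]

#: Total called nucleotides / Q20 nucleotides of the example sequencing run.
RUN_CALLED_NT = 33_294_511
RUN_Q20_NT = 29_109_688

# (species) -> counts per pair for the 1:10 and 1:50 libraries
_DILUTION_COUNTS = {
    #            12S_KH        16S_KH        16S_Ki
    #          1:10  1:50    1:10  1:50    1:10  1:50
    "pig":    ((26, 7),      (21, 8),      (30, 12)),
    "horse":  ((6, 1),       (1, 0),       (26, 17)),
    "cattle": ((1681, 1554), (1650, 1728), (4949, 3429)),
    "sheep":  ((193, 174),   (156, 196),   (561, 375)),
    "rabbit": ((1698, 1587), (746, 817),   (4103, 2830)),
    "human":  ((1559, 1494), (467, 558),   (6430, 4596)),
    "rat":    ((98, 100),    (69, 84),     (540, 286)),
}

_PAIRS = ("12S_KH", "16S_KH", "16S_Ki")


def dilution_series_counts() -> pd.DataFrame:
    """The dilution-series counts as a tidy DataFrame
    (columns: species, pair, library, count)."""
    rows = []
    for sp, per_pair in _DILUTION_COUNTS.items():
        for pair, (c10, c50) in zip(_PAIRS, per_pair):
            rows.append(dict(species=sp, pair=pair, library="1:10", count=c10))
            rows.append(dict(species=sp, pair=pair, library="1:50", count=c50))
    return pd.DataFrame(rows)


def dilution_series_tables() -> tuple[CountTable, CountTable]:
    """The two dilution libraries as :class:`CountTable` objects
    (library ids ``dilution_1:10`` and ``dilution_1:50``)."""
    c10 = {}
    c50 = {}
    for sp, per_pair in _DILUTION_COUNTS.items():
        for pair, (a, b) in zip(_PAIRS, per_pair):
            c10[(sp, pair)] = a
            c50[(sp, pair)] = b
    return (
        CountTable(library_id="dilution_1:10", counts=c10),
        CountTable(library_id="dilution_1:50", counts=c50),
    )
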