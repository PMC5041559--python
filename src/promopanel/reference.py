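"""Published 2x2 marker-vs-subtype counts for the two study cohorts.

The discovery cohort restricts to the diagnostically difficult subtypes
(12 non-lepidic AD vs 3 PDSCC); the validation cohort is an independent
group (16 non-lepidic AD vs 11 PDSCC). Counts are (a, b, c, d) =
(condition-positive called positive, condition-negative called positive,
condition-positive called negative, condition-negative called negative),
with the condition-positive class given by the marker class.
"""

from .diagnostics import ConfusionTable
from .ihc import MarkerDefinition

#: marker name -> (definition, discovery counts, validation counts)
REFERENCE_MARKERS: dict[str, tuple[MarkerDefinition, ConfusionTable, ConfusionTable]] = {
    "ST6GALNAC1": (
        MarkerDefinition("ST6GALNAC1", "AD", "novel"),
        ConfusionTable(8, 0, 4, 3),
        ConfusionTable(15, 0, 1, 11),
    ),
    "TTF-1": (
        MarkerDefinition("TTF-1", "AD", "established"),
        ConfusionTable(5, 0, 7, 3),
        ConfusionTable(10, 0, 6, 11),
    ),
    "napsin A": (
        MarkerDefinition("napsin A", "AD", "established"),
        ConfusionTable(2, 0, 10, 3),
        ConfusionTable(12, 0, 4, 11),
    ),
    "SPATS2": (
        MarkerDefinition("SPATS2", "SCC", "novel"),
        ConfusionTable(2, 0, 1, 12),
        ConfusionTable(7, 0, 4, 16),
    ),
    "CK5": (
        MarkerDefinition("CK5", "SCC", "established"),
        ConfusionTable(1, 0, 2, 12),
        ConfusionTable(7, 0, 4, 16),
    ),
    "DSG3": (
        MarkerDefinition("DSG3", "SCC", "established"),
        ConfusionTable(0, 0, 3, 12),
        ConfusionTable(6, 0, 5, 16),
    ),
    "p40": (
        MarkerDefinition("p40", "SCC", "established"),
        ConfusionTable(1, 0, 2, 12),
        ConfusionTable(7, 0, 4, 16),
    ),
    "CK6": (
        MarkerDefinition("CK6", "SCC", "established"),
        ConfusionTable(0, 0, 3, 12),
        ConfusionTable(5, 9, 6, 7),
    ),
}
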