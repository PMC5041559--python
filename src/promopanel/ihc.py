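"""Immunohistochemistry scores: the two scoring schemes and binarization.

Markers are graded 0/1/2 on a glass slide. Novel markers (identified by the
promoter screen, antibodies not yet clinically optimized) use a stringent
scheme: score 2 requires more than 50 % of tumor cells with moderate or
stronger immunoreactivity. Established clinical markers use the conventional
scheme: score 2 when 10 % or more of tumor cells show any immunoreactivity.
Under both schemes only score 2 counts as a positive marker call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VALID_SCORES = (0, 1, 2)
INTENSITY_CLASSES = ("none", "weak", "moderate-or-stronger")


@dataclass(frozen=True)
class MarkerDefinition:
    name: str
    marker_class: str  # "AD" or "SCC": which super-type the marker indicates
    scheme: str  # "novel" or "established"

    def __post_init__(self) -> None:
        if self.marker_class not in ("AD", "SCC"):
            raise ValueError(f"marker_class must be AD or SCC, got {self.marker_class!r}")
        if self.scheme not in ("novel", "established"):
            raise ValueError(f"scheme must be novel or established, got {self.scheme!r}")


def percent_to_score(
    percent_positive: float, intensity_class: str, scheme: str
) -> int:
    """Map a stained-cell percentage and intensity grade to an IHC score.

    Novel scheme: 0 iff no tumor cells stain; 2 iff more than 50 % of tumor
    cells show moderate-or-stronger immunoreactivity (strict); else 1.
    Established scheme: 0 iff no tumor cells stain; 2 iff 10 % or more stain
    (inclusive), regardless of intensity; else 1.
    """
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError(f"percent must be in [0, 100], got {percent_positive}")
    if intensity_class not in INTENSITY_CLASSES:
        raise ValueError(f"unknown intensity class {intensity_class!r}")
    if scheme == "novel":
        if percent_positive == 0:
            return 0
        if percent_positive > 50 and intensity_class == "moderate-or-stronger":
            return 2
        return 1
    if scheme == "established":
        if percent_positive == 0:
            return 0
        return 2 if percent_positive >= 10 else 1
    raise ValueError(f"unknown scheme {scheme!r}")


def validate_scores(scores: pd.DataFrame) -> None:
    bad = ~scores.isin(VALID_SCORES)
    if bad.any().any():
        loc = [(i, c) for i, c in zip(*bad.to_numpy().nonzero())]
        raise ValueError(f"scores outside {{0,1,2}} at {len(loc)} positions")


def binarize(scores: pd.DataFrame) -> pd.DataFrame:
    """Marker calls from IHC scores: positive iff score == 2."""
    validate_scores(scores)
    return scores == 2


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    validate_scores(df)
    return df


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="sample_id")


def read_marker_definitions(path) -> list[MarkerDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [
        MarkerDefinition(r["name"], r["marker_class"], r["scheme"])
        for _, r in df.iterrows()
    ]


def write_marker_definitions(markers, path) -> None:
    pd.DataFrame(
        [(m.name, m.marker_class, m.scheme) for m in markers],
        columns=["name", "marker_class", "scheme"],
    ).to_csv(path, sep="\t", index=False)
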