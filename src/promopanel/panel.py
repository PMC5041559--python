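"""Two-marker definitive-diagnosis panels.

A panel pairs one AD marker with one SCC marker. A sample is called AD when
only the AD marker is positive, SCC when only the SCC marker is positive,
and inconclusive otherwise (both positive or both negative). Accuracy counts
inconclusive samples in the denominator and never as correct. A sequential
strategy applies a second panel only to the samples the first left
inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ihc import MarkerDefinition

INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class PanelRule:
    ad_marker: str
    scc_marker: str


@dataclass(frozen=True)
class PanelOutcome:
    classification: pd.Series = field(repr=False)  # per-sample AD/SCC/inconclusive
    n_correct: int
    n_incorrect: int
    n_inconclusive: int

    @property
    def total(self) -> int:
        return self.n_correct + self.n_incorrect + self.n_inconclusive

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.total

    @property
    def inconclusive_rate(self) -> float:
        return self.n_inconclusive / self.total


def apply_rule(rule: PanelRule, calls: pd.DataFrame) -> pd.Series:
    """Classify every sample as AD, SCC or inconclusive."""
    for name in (rule.ad_marker, rule.scc_marker):
        if name not in calls.columns:
            raise KeyError(f"no calls for marker {name!r}")
        if calls[name].isna().any():
            raise ValueError(f"missing call for marker {name!r}")
    ad = calls[rule.ad_marker].astype(bool)
    scc = calls[rule.scc_marker].astype(bool)
    out = pd.Series(INCONCLUSIVE, index=calls.index, dtype=object)
    out[ad & ~scc] = "AD"
    out[scc & ~ad] = "SCC"
    return out


def evaluate_rule(
    rule: PanelRule, calls: pd.DataFrame, labels: pd.Series
) -> PanelOutcome:
    """Score a panel's classifications against SCC/AD super-type labels."""
    cls = apply_rule(rule, calls.loc[labels.index])
    inconclusive = cls == INCONCLUSIVE
    correct = (cls == labels) & ~inconclusive
    return PanelOutcome(
        classification=cls,
        n_correct=int(correct.sum()),
        n_incorrect=int((~correct & ~inconclusive).sum()),
        n_inconclusive=int(inconclusive.sum()),
    )


def exhaustive_search(
    markers: list[MarkerDefinition], calls: pd.DataFrame, labels: pd.Series
) -> list[tuple[PanelRule, PanelOutcome]]:
    """Evaluate every AD x SCC marker pair, best first.

    Ranked by accuracy descending, ties broken by fewer inconclusive calls,
    then lexicographically by the pair's names.
    """
    ad_markers = sorted(m.name for m in markers if m.marker_class == "AD")
    scc_markers = sorted(m.name for m in markers if m.marker_class == "SCC")
    if not ad_markers or not scc_markers:
        raise ValueError("need at least one AD marker and one SCC marker")
    scored = [
        (rule := PanelRule(ad, scc), evaluate_rule(rule, calls, labels))
        for ad in ad_markers
        for scc in scc_markers
    ]
    scored.sort(
        key=lambda ro: (
            -ro[1].accuracy,
            ro[1].n_inconclusive,
            ro[0].ad_marker,
            ro[0].scc_marker,
        )
    )
    return scored


@dataclass(frozen=True)
class SequentialOutcome:
    overall: PanelOutcome
    stage1: PanelOutcome
    stage2: PanelOutcome | None  # among stage-1 inconclusive samples; None if none


def sequential_panel(
    first: PanelRule,
    second: PanelRule,
    calls: pd.DataFrame,
    labels: pd.Series,
) -> SequentialOutcome:
    """Two-step strategy: apply ``second`` only where ``first`` is inconclusive."""
    stage1 = evaluate_rule(first, calls, labels)
    residual = stage1.classification.index[stage1.classification == INCONCLUSIVE]
    stage2 = None
    cls = stage1.classification.copy()
    if len(residual):
        stage2 = evaluate_rule(second, calls.loc[residual], labels.loc[residual])
        cls.loc[residual] = stage2.classification
    inconclusive = cls == INCONCLUSIVE
    correct = (cls == labels) & ~inconclusive
    overall = PanelOutcome(
        classification=cls,
        n_correct=int(correct.sum()),
        n_incorrect=int((~correct & ~inconclusive).sum()),
        n_inconclusive=int(inconclusive.sum()),
    )
    return SequentialOutcome(overall=overall, stage1=stage1, stage2=stage2)


def search_table(results: list[tuple[PanelRule, PanelOutcome]]) -> pd.DataFrame:
    """Flatten ranked search results for TSV export."""
    rows = [
        {
            "rank": i + 1,
            "ad_marker": r.ad_marker,
            "scc_marker": r.scc_marker,
            "n_correct": o.n_correct,
            "n_incorrect": o.n_incorrect,
            "n_inconclusive": o.n_inconclusive,
            "accuracy": o.accuracy,
            "inconclusive_rate": o.inconclusive_rate,
        }
        for i, (r, o) in enumerate(results)
    ]
    return pd.DataFrame(rows).set_index("rank")
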