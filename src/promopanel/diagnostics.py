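"""Per-marker diagnostic performance with exact binomial confidence intervals.

Each marker call is compared with the histological gold standard in a 2x2
table; sensitivity, specificity, PPV, NPV and accuracy are each treated as an
independent binomial proportion with an exact Clopper-Pearson 95 % CI. For an
AD marker the condition-positive class is AD; for an SCC marker it is SCC.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy.stats import beta

from .ihc import MarkerDefinition


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: a = condition-positive called positive, b = condition-negative
    called positive, c = condition-positive called negative, d = condition-negative
    called negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ConfusionTable":
        """Swap the roles of condition and call polarity (d<->a, b<->c)."""
        return ConfusionTable(self.d, self.c, self.b, self.a)


@dataclass(frozen=True)
class Proportion:
    """A binomial proportion with its exact CI; undefined when denominator = 0."""

    numerator: int
    denominator: int
    estimate: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.denominator > 0


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    accuracy: Proportion


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) CI for a binomial proportion x/n.

    The bounds invert the binomial tail probabilities; equivalently they are
    Beta quantiles: low = Beta(alpha/2; x, n-x+1), high = Beta(1-alpha/2;
    x+1, n-x), with low = 0 at x = 0 and high = 1 at x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _proportion(x: int, n: int, conf: float) -> Proportion:
    if n == 0:
        return Proportion(0, 0, None, None, None)
    low, high = clopper_pearson(x, n, conf)
    return Proportion(x, n, x / n, low, high)


def performance(t: ConfusionTable, conf: float = 0.95) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs."""
    return DiagnosticPerformance(
        sensitivity=_proportion(t.a, t.a + t.c, conf),
        specificity=_proportion(t.d, t.b + t.d, conf),
        ppv=_proportion(t.a, t.a + t.b, conf),
        npv=_proportion(t.d, t.c + t.d, conf),
        accuracy=_proportion(t.a + t.d, t.total, conf),
    )


def confusion(
    calls: pd.Series,
    sample_table: pd.DataFrame,
    marker: MarkerDefinition,
    restrict_subtypes: set[str] | None = None,
) -> ConfusionTable:
    """Tally a marker's boolean calls against the histological super-type.

    ``restrict_subtypes`` limits the evaluation cohort (e.g. to the
    difficult-to-diagnose non-lepidic AD and PDSCC cases).
    """
    table = sample_table
    if restrict_subtypes is not None:
        table = table[table["subtype"].isin(restrict_subtypes)]
    if table.empty:
        raise ValueError("no samples left after cohort restriction")
    missing = table.index.difference(calls.index)
    if len(missing):
        raise ValueError(f"missing calls for samples: {list(missing)}")
    cond_pos = table["supertype"] == marker.marker_class
    called = calls.loc[table.index].astype(bool)
    return ConfusionTable(
        a=int((cond_pos & called).sum()),
        b=int((~cond_pos & called).sum()),
        c=int((cond_pos & ~called).sum()),
        d=int((~cond_pos & ~called).sum()),
    )


def round_half_up(x: float, digits: int = 3) -> float:
    """Round half away from zero at ``digits`` decimals (table formatting)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _format_metric(p: Proportion) -> str:
    if not p.defined:
        return "N.A."
    return (
        f"{round_half_up(p.estimate):.3f} "
        f"({round_half_up(p.ci_low):.3f}-{round_half_up(p.ci_high):.3f})"
    )


def evaluate_markers(
    calls: pd.DataFrame,
    sample_table: pd.DataFrame,
    markers: list[MarkerDefinition],
    restrict_subtypes: set[str] | None = None,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-marker performance table in the layout of the published tables."""
    rows = []
    for m in markers:
        t = confusion(calls[m.name], sample_table, m, restrict_subtypes)
        perf = performance(t, conf)
        rows.append(
            {
                "marker": m.name,
                "class": m.marker_class,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "sensitivity": _format_metric(perf.sensitivity),
                "specificity": _format_metric(perf.specificity),
                "ppv": _format_metric(perf.ppv),
                "npv": _format_metric(perf.npv),
                "accuracy": _format_metric(perf.accuracy),
            }
        )
    return pd.DataFrame(rows).set_index("marker")
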