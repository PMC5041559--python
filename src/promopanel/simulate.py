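"""Synthetic CAGE-like cohorts and IHC score tables with known ground truth.

The generator emulates a surgical lung-cancer cohort profiled at the
promoter level: 97 tumors (22 SCC: 5 WD / 14 MD / 3 PD; 75 AD: 7
pure-lepidic / 56 mixed-lepidic / 12 non-lepidic) with negative-binomially
distributed region counts, log-normal library sizes, planted fold-change
promoters and planted completely separating promoters between the two
difficult-to-diagnose groups (PDSCC vs non-lepidic AD). IHC tables are drawn
per marker from specified sensitivity/specificity, so parameter recovery is
testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ihc import MarkerDefinition, write_marker_definitions, write_scores
from .matrix import (
    CountMatrix,
    PromoterRegion,
    make_sample_table,
    write_bed,
    write_counts,
    write_library_sizes,
    write_sample_table,
)
from .screen import complete_separation

#: Discovery-cohort composition (histological subtype -> number of tumors).
DEFAULT_GROUP_SIZES = {
    "WDSCC": 5,
    "MDSCC": 14,
    "PDSCC": 3,
    "pure-lepidic AD": 7,
    "mixed-lepidic AD": 56,
    "non-lepidic AD": 12,
}


@dataclass
class CohortConfig:
    """Study conditions for a simulated promoter-count cohort.

    ``baseline_mean_log_range`` is the log10 range of unnormalized relative
    abundances (normalized to sum to 1, so a region's expected CPM is its
    relative abundance x 1e6). ``dispersion`` is the NB dispersion phi with
    variance mu + phi*mu^2; 0.15 corresponds to a biological CV of ~0.39,
    typical of heterogeneous human tumor cohorts. Planted fold-change and
    separator regions act on the ``contrast`` groups (default PDSCC vs
    non-lepidic AD, the clinically ambiguous pair).
    """

    n_regions: int = 4000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    baseline_mean_log_range: tuple[float, float] = (-7.0, -3.0)
    dispersion: float = 0.15
    libsize_median: float = 5e6
    libsize_log_sd: float = 0.25
    n_de: int = 50
    de_log2fc: float = 3.0
    n_separators: int = 7
    sep_log2_margin: float = 2.0
    contrast: tuple[str, str] = ("non-lepidic AD", "PDSCC")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions <= 0:
            raise ValueError("n_regions must be positive")
        if not self.group_sizes:
            raise ValueError("group_sizes is empty")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be >= 0")
        if self.n_de + self.n_separators > self.n_regions:
            raise ValueError("n_de + n_separators exceeds n_regions")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated cohort."""

    de_regions: pd.DataFrame  # region_id, direction (group name), log2fc
    separator_regions: pd.DataFrame  # region_id, direction (group name)
    relative_abundance: pd.Series  # baseline relative abundance per region

    def to_frame(self) -> pd.DataFrame:
        de = self.de_regions.assign(kind="de")
        sep = self.separator_regions.assign(kind="separator", log2fc=np.nan)
        return pd.concat([de, sep], ignore_index=True)[
            ["region_id", "kind", "direction", "log2fc"]
        ]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a promoter-count cohort with planted markers.

    Counts are NB(mean = library_size x relative_abundance x fold term,
    dispersion phi). Planted fold-change regions get an expected CPM fold of
    2**de_log2fc between the contrast groups; planted separator regions are
    redrawn (bounded retries, escalating shift) until the realized CPM ranges
    of the contrast groups are disjoint by at least ``sep_log2_margin`` in
    log2.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_plant, rng_abund, rng_lib, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    subtypes = [g for g, k in config.group_sizes.items() for _ in range(k)]
    n_samples = len(subtypes)
    if n_samples == 0:
        raise ValueError("no samples: all group sizes are zero")
    sample_ids = [f"T{i + 1:03d}" for i in range(n_samples)]
    samples = make_sample_table(sample_ids, subtypes)

    lo, hi = config.baseline_mean_log_range
    abundance = 10.0 ** rng_abund.uniform(lo, hi, size=config.n_regions)

    n_planted = config.n_de + config.n_separators
    planted = rng_plant.choice(config.n_regions, size=n_planted, replace=False)
    de_idx, sep_idx = planted[: config.n_de], planted[config.n_de :]
    # planted regions get mid-range baseline abundance so they are expressed
    # but not dominant (roughly 2-20 CPM at baseline)
    abundance[planted] = 10.0 ** rng_plant.uniform(-5.3, -4.3, size=n_planted)
    abundance = abundance / abundance.sum()

    lib_sizes = np.rint(
        config.libsize_median
        * np.exp(rng_lib.normal(0.0, config.libsize_log_sd, size=n_samples))
    ).astype(np.int64)

    group_low, group_high = config.contrast
    for g in config.contrast:
        if g not in config.group_sizes:
            raise ValueError(f"contrast group {g!r} not in group_sizes")
    in_low = np.array([s == group_low for s in subtypes])
    in_high = np.array([s == group_high for s in subtypes])
    # planted effects act on the whole super-type containing each contrast
    # group (markers of the SCC/AD split, as in real cohorts); the stated
    # fold between the two contrast groups holds a fortiori
    from .matrix import SUBTYPE_TO_SUPERTYPE

    supertypes = np.array([SUBTYPE_TO_SUPERTYPE[s] for s in subtypes])
    super_low = supertypes == SUBTYPE_TO_SUPERTYPE[group_low]
    super_high = supertypes == SUBTYPE_TO_SUPERTYPE[group_high]

    fold = np.ones((config.n_regions, n_samples))
    de_dirs = []
    for k, r in enumerate(de_idx):
        # most planted fold changes point toward the second contrast group,
        # echoing the asymmetry typical of SCC-vs-AD comparisons
        if k % 20 == 19:
            fold[r, super_low] = 2.0**config.de_log2fc
            de_dirs.append(group_low)
        else:
            fold[r, super_high] = 2.0**config.de_log2fc
            de_dirs.append(group_high)

    sep_dirs = []
    sep_shift = 2.0 ** (config.sep_log2_margin + 5)
    for k, r in enumerate(sep_idx):
        high_mask = super_high if k % 2 == 0 else super_low
        fold[r, high_mask] = sep_shift
        sep_dirs.append(group_high if k % 2 == 0 else group_low)

    mean = abundance[:, None] * lib_sizes[None, :] * fold
    counts = _nb_draw(rng_counts, mean, config.dispersion)

    # complete separation is a property of realized data: verify each planted
    # separator and redraw it (escalating the shift) if sampling violated it
    cpm_scale = 1e6 / lib_sizes
    names = (group_low, group_high)
    for k, r in enumerate(sep_idx):
        high_mask = super_high if k % 2 == 0 else super_low
        shift = sep_shift
        for attempt in range(40):
            row_cpm = counts[r] * cpm_scale
            sep = complete_separation(
                row_cpm[in_low], row_cpm[in_high], names=names
            )
            if (
                sep is not None
                and sep.direction == sep_dirs[k]
                and sep.margin >= config.sep_log2_margin
            ):
                break
            if attempt >= 19:
                shift *= 2.0
            row_mean = abundance[r] * lib_sizes.astype(float)
            row_mean[high_mask] *= shift
            counts[r] = _nb_draw(rng_counts, row_mean, config.dispersion)
        else:
            raise RuntimeError(
                f"could not realize a separator at region index {r} "
                f"(margin {config.sep_log2_margin})"
            )

    region_ids = [f"region_{i:05d}" for i in range(config.n_regions)]
    regions = [
        PromoterRegion(
            chrom="chrS",
            start=1000 * i,
            end=1000 * i + 500,
            strand="+" if i % 2 == 0 else "-",
            region_id=rid,
        )
        for i, rid in enumerate(region_ids)
    ]
    counts_df = pd.DataFrame(counts, index=region_ids, columns=sample_ids)
    m = CountMatrix(
        counts_df,
        library_sizes=pd.Series(lib_sizes, index=sample_ids),
        regions=regions,
    )
    truth = GroundTruth(
        de_regions=pd.DataFrame(
            {
                "region_id": [region_ids[i] for i in de_idx],
                "direction": de_dirs,
                "log2fc": config.de_log2fc,
            }
        ),
        separator_regions=pd.DataFrame(
            {
                "region_id": [region_ids[i] for i in sep_idx],
                "direction": sep_dirs,
            }
        ),
        relative_abundance=pd.Series(abundance, index=region_ids),
    )
    return m, samples, truth


@dataclass(frozen=True)
class MarkerSimConfig:
    """One simulated IHC marker: P(score 2 | condition positive) = sensitivity,
    P(score 2 | condition negative) = 1 - specificity; sub-threshold mass is
    split between scores 1 and 0 by ``score1_fraction``."""

    name: str
    marker_class: str  # AD or SCC
    scheme: str  # novel or established
    sensitivity: float
    specificity: float
    score1_fraction: float = 0.25

    def __post_init__(self) -> None:
        for p in (self.sensitivity, self.specificity, self.score1_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def definition(self) -> MarkerDefinition:
        return MarkerDefinition(self.name, self.marker_class, self.scheme)


#: Default marker panel: the two screen-derived markers plus six established
#: clinical markers, with per-marker sensitivity/specificity set to the
#: validation-cohort point estimates. Novel-scheme markers carry more score-1
#: (sub-threshold) mass because their stringent criterion downgrades weak or
#: focal staining.
DEFAULT_IHC_MARKERS = [
    MarkerSimConfig("ST6GALNAC1", "AD", "novel", 0.938, 1.0, 0.5),
    MarkerSimConfig("TTF-1", "AD", "established", 0.625, 1.0, 0.25),
    MarkerSimConfig("napsin A", "AD", "established", 0.750, 1.0, 0.25),
    MarkerSimConfig("SPATS2", "SCC", "novel", 0.636, 1.0, 0.5),
    MarkerSimConfig("CK5", "SCC", "established", 0.636, 1.0, 0.25),
    MarkerSimConfig("DSG3", "SCC", "established", 0.545, 1.0, 0.25),
    MarkerSimConfig("p40", "SCC", "established", 0.636, 1.0, 0.25),
    MarkerSimConfig("CK6", "SCC", "established", 0.455, 0.438, 0.25),
]


@dataclass
class IHCSimConfig:
    markers: list[MarkerSimConfig] = field(
        default_factory=lambda: list(DEFAULT_IHC_MARKERS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")


def simulate_ihc(config: IHCSimConfig, samples: pd.DataFrame) -> pd.DataFrame:
    """Draw an IHC score table (samples x markers, scores in {0,1,2})."""
    if not set(samples["supertype"]).issubset({"AD", "SCC"}):
        bad = sorted(set(samples["supertype"]) - {"AD", "SCC"})
        raise ValueError(f"unknown super-type labels: {bad}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    scores = {}
    for mk in config.markers:
        cond_pos = (samples["supertype"] == mk.marker_class).to_numpy()
        p2 = np.where(cond_pos, mk.sensitivity, 1.0 - mk.specificity)
        u = rng.uniform(size=len(samples))
        v = rng.uniform(size=len(samples))
        col = np.where(u < p2, 2, np.where(v < mk.score1_fraction, 1, 0))
        scores[mk.name] = col
    return pd.DataFrame(scores, index=samples.index)


def write_cohort(
    out_dir: str | Path,
    m: CountMatrix,
    samples: pd.DataFrame,
    truth: GroundTruth,
    scores: pd.DataFrame | None = None,
    markers: list[MarkerSimConfig] | None = None,
) -> dict[str, Path]:
    """Write all simulated inputs as plain-text files; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "regions": out / "regions.bed",
        "counts": out / "counts.tsv",
        "library_sizes": out / "library_sizes.tsv",
        "samples": out / "samples.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_bed(m.regions, paths["regions"])
    write_counts(m, paths["counts"])
    write_library_sizes(m, paths["library_sizes"])
    write_sample_table(samples, paths["samples"])
    truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
    if scores is not None:
        paths["ihc_scores"] = out / "ihc_scores.tsv"
        write_scores(scores, paths["ihc_scores"])
    if markers is not None:
        paths["markers"] = out / "markers.tsv"
        write_marker_definitions([mk.definition for mk in markers], paths["markers"])
    return paths
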