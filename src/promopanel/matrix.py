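"""Promoter-level count matrices: loading, QC, CPM normalization, inactivity
filtering and MDS embedding.

The counting unit is a promoter (TSS) region; raw signal is the number of
mapped 5'-end reads starting in the region, and the library size is the total
number of mapped reads of the sample (which may exceed the in-region total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Histological subtypes and the carcinoma super-type each belongs to.
SUBTYPE_TO_SUPERTYPE = {
    "WDSCC": "SCC",
    "MDSCC": "SCC",
    "PDSCC": "SCC",
    "pure-lepidic AD": "AD",
    "mixed-lepidic AD": "AD",
    "non-lepidic AD": "AD",
}

SUPERTYPES = ("AD", "SCC")


@dataclass(frozen=True)
class PromoterRegion:
    """A TSS region in 0-based half-open genomic coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    region_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.region_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"region {self.region_id}: invalid strand {self.strand!r}")


class CountMatrix:
    """Regions x samples integer count matrix with per-sample library sizes.

    Parameters
    ----------
    counts
        DataFrame indexed by region id, columns are sample ids, values are
        non-negative integers.
    library_sizes
        Per-sample total mapped reads. Defaults to the column sums, but a
        supplied value may exceed them (reads mapping outside any region).
    regions
        Optional region annotation; when given, its ids must match the
        count index.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: pd.Series | None = None,
        regions: Sequence[PromoterRegion] | None = None,
    ) -> None:
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        library_sizes = library_sizes.reindex(counts.columns)
        if library_sizes.isna().any():
            raise ValueError("library_sizes missing for some samples")
        if (library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        self.library_sizes = library_sizes.astype(np.int64)
        if regions is not None:
            ids = [r.region_id for r in regions]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate region ids in annotation")
            if list(counts.index) != ids:
                raise ValueError("region annotation does not match count index")
        self.regions = list(regions) if regions is not None else None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def region_ids(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(
            self.counts[ids], self.library_sizes[ids], regions=self.regions
        )

    def subset_regions(self, region_ids: Iterable[str]) -> "CountMatrix":
        ids = pd.Index(region_ids)
        regions = None
        if self.regions is not None:
            keep = set(ids)
            regions = [r for r in self.regions if r.region_id in keep]
        return CountMatrix(self.counts.loc[ids], self.library_sizes, regions=regions)


def make_sample_table(sample_ids: Sequence[str], subtypes: Sequence[str]) -> pd.DataFrame:
    """Build a sample table with the super-type derived from the subtype."""
    if len(sample_ids) != len(subtypes):
        raise ValueError("sample_ids and subtypes differ in length")
    unknown = sorted(set(subtypes) - set(SUBTYPE_TO_SUPERTYPE))
    if unknown:
        raise ValueError(f"unknown subtype labels: {unknown}")
    return pd.DataFrame(
        {
            "subtype": list(subtypes),
            "supertype": [SUBTYPE_TO_SUPERTYPE[s] for s in subtypes],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def qc_libraries(m: CountMatrix, min_mapped: int = 2_000_000) -> CountMatrix:
    """Drop samples whose library size is not strictly above ``min_mapped``.

    A library with exactly ``min_mapped`` reads is excluded.
    """
    keep = m.library_sizes > min_mapped
    removed = [s for s, k in zip(m.samples, keep) if not k]
    if removed:
        logger.info("qc_libraries removed %d samples: %s", len(removed), removed)
    if not keep.any():
        raise ValueError(
            f"all samples removed by library-size QC (threshold > {min_mapped})"
        )
    return m.subset_samples([s for s, k in zip(m.samples, keep) if k])


def cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads: count * 1e6 / library_size, no pseudocount."""
    if (m.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return m.counts * 1e6 / m.library_sizes.astype(float)


def filter_inactive(
    cpm_matrix: pd.DataFrame,
    sample_table: pd.DataFrame,
    cpm_threshold: float = 1.0,
    frac: float = 0.77,
    groups: tuple[str, str] = ("AD", "SCC"),
    pooled: bool = False,
) -> pd.Index:
    """Return ids of regions retained after the inactivity filter.

    A region is removed iff within *each* of the two super-type groups the
    fraction of samples with CPM <= ``cpm_threshold`` is strictly greater
    than ``frac``. With ``pooled=True`` the rule is applied once to the
    pooled samples of both groups instead (alternative reading).
    """
    if not (0.0 <= frac <= 1.0):
        raise ValueError(f"frac must be in [0, 1], got {frac}")
    labels = sample_table.loc[cpm_matrix.columns, "supertype"]
    cols = {g: labels.index[labels == g] for g in groups}
    for g, ids in cols.items():
        if len(ids) == 0:
            raise ValueError(f"group {g!r} has no samples")
    inactive = cpm_matrix <= cpm_threshold
    if pooled:
        ids = cols[groups[0]].union(cols[groups[1]])
        remove = inactive[ids].mean(axis=1) > frac
    else:
        remove = pd.Series(True, index=cpm_matrix.index)
        for g in groups:
            remove &= inactive[cols[g]].mean(axis=1) > frac
    retained = cpm_matrix.index[~remove]
    logger.info(
        "filter_inactive removed %d of %d regions", int(remove.sum()), len(remove)
    )
    return retained


def leading_logfc_distances(
    cpm_matrix: pd.DataFrame, top_n: int = 500, prior: float = 0.5
) -> pd.DataFrame:
    """Pairwise leading log-fold-change distances between samples.

    For each pair of samples, the distance is the root-mean-square of the
    ``top_n`` largest absolute log2 fold changes of shifted log-CPM
    (log2(CPM + prior)) between the pair.
    """
    logc = np.log2(cpm_matrix.values + prior)
    n = logc.shape[1]
    k = min(top_n, logc.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(logc[:, i] - logc[:, j])
            if k < diff.size:
                sel = np.partition(diff, diff.size - k)[-k:]
            else:
                sel = diff
            d[i, j] = d[j, i] = np.sqrt(np.mean(sel**2))
    return pd.DataFrame(d, index=cpm_matrix.columns, columns=cpm_matrix.columns)


def classical_mds(dist: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a distance matrix.

    Axis signs are canonicalized so that the largest-magnitude coordinate
    on each axis is positive.
    """
    n = dist.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples for {dims}-d MDS")
    d2 = np.asarray(dist, dtype=float) ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    for a in range(dims):
        if coords[np.argmax(np.abs(coords[:, a])), a] < 0:
            coords[:, a] = -coords[:, a]
    return pd.DataFrame(
        coords, index=dist.index, columns=[f"dim{k + 1}" for k in range(dims)]
    )


def mds(cpm_matrix: pd.DataFrame, top_n: int = 500, dims: int = 2) -> pd.DataFrame:
    """Embed samples in ``dims`` dimensions from leading log-fold-change distances."""
    if cpm_matrix.shape[1] < 3:
        raise ValueError("MDS requires at least 3 samples")
    return classical_mds(leading_logfc_distances(cpm_matrix, top_n=top_n), dims=dims)


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path: str | Path) -> list[PromoterRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 line with {len(fields)} fields: {line!r}")
            chrom, start, end, name, _score, strand = fields[:6]
            regions.append(PromoterRegion(chrom, int(start), int(end), strand, name))
    return regions


def write_bed(regions: Sequence[PromoterRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t{r.strand}\n")


def read_counts(
    path: str | Path, library_sizes_path: str | Path | None = None
) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    lib = None
    if library_sizes_path is not None:
        lib = pd.read_csv(
            library_sizes_path, sep="\t", index_col=0
        ).iloc[:, 0]
    return CountMatrix(counts, library_sizes=lib)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="region_id")


def write_library_sizes(m: CountMatrix, path: str | Path) -> None:
    m.library_sizes.rename("library_size").to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return make_sample_table(df.index, df["subtype"])


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")
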