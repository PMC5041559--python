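"""End-to-end orchestration: simulate -> QC -> CPM -> filter -> MDS -> screen
-> per-marker evaluation -> panel search -> clustering, with a machine-
readable run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .cluster import cluster_profiles, heatmap_order
from .diagnostics import evaluate_markers
from .ihc import binarize
from .matrix import cpm, filter_inactive, mds, qc_libraries
from .panel import PanelRule, search_table, sequential_panel, exhaustive_search
from .screen import ScreenThresholds, run_screen
from .simulate import (
    CohortConfig,
    IHCSimConfig,
    simulate_cohort,
    simulate_ihc,
    write_cohort,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "cpm", "filter", "mds", "screen", "evaluate", "panel", "cluster")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the study's thresholds."""

    out_dir: str = "promopanel_run"
    seed: int = 0
    # library QC / normalization / filtering
    min_mapped: int = 2_000_000
    cpm_threshold: float = 1.0
    frac: float = 0.77
    # candidate screen
    max_fdr: float = 0.01
    min_fold: float = 4.0
    min_cpm: float = 4.0
    group_a: str = "non-lepidic AD"
    group_b: str = "PDSCC"
    # evaluation / embedding
    conf: float = 0.95
    mds_top_n: int = 500
    # synthetic-cohort knobs (generator defaults otherwise)
    n_regions: int = 4000
    dispersion: float = 0.15
    n_de: int = 50
    de_log2fc: float = 3.0
    n_separators: int = 7
    sep_log2_margin: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value YAML config; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a flat mapping")
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_regions=self.n_regions,
            dispersion=self.dispersion,
            n_de=self.n_de,
            de_log2fc=self.de_log2fc,
            n_separators=self.n_separators,
            sep_log2_margin=self.sep_log2_margin,
            contrast=(self.group_a, self.group_b),
            seed=self.seed,
        )

    def thresholds(self) -> ScreenThresholds:
        return ScreenThresholds(
            max_fdr=self.max_fdr, min_fold=self.min_fold, min_cpm=self.min_cpm
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated cohort; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_outputs: dict[str, list[str]] = {}

    def record(stage: str, *paths: Path) -> None:
        stage_outputs[stage] = [str(p.relative_to(out)) for p in paths]
        logger.info("[%s] wrote %s", stage, stage_outputs[stage])

    def fail(stage: str, exc: Exception) -> RuntimeError:
        return RuntimeError(f"stage {stage!r} failed: {exc}")

    # simulate
    try:
        m, samples, truth = simulate_cohort(config.cohort_config())
        ihc_cfg = IHCSimConfig(seed=config.seed + 1)
        scores = simulate_ihc(ihc_cfg, samples)
        inputs = write_cohort(
            out / "simulate", m, samples, truth, scores=scores, markers=ihc_cfg.markers
        )
        record("simulate", *inputs.values())
    except Exception as exc:  # noqa: BLE001
        raise fail("simulate", exc) from exc

    # qc
    try:
        m_qc = qc_libraries(m, min_mapped=config.min_mapped)
        qc_path = out / "qc_samples.tsv"
        pd.Series(m_qc.samples, name="sample_id").to_csv(qc_path, sep="\t", index=False)
        record("qc", qc_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("qc", exc) from exc

    # cpm
    try:
        cpm_df = cpm(m_qc)
        cpm_path = out / "cpm.tsv"
        cpm_df.to_csv(cpm_path, sep="\t", index_label="region_id", float_format="%.6g")
        record("cpm", cpm_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("cpm", exc) from exc

    # filter
    try:
        retained = filter_inactive(
            cpm_df, samples, cpm_threshold=config.cpm_threshold, frac=config.frac
        )
        filt_path = out / "retained_regions.tsv"
        retained.to_series().to_csv(
            filt_path, sep="\t", index=False, header=["region_id"]
        )
        record("filter", filt_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("filter", exc) from exc

    # mds
    try:
        coords = mds(cpm_df.loc[retained], top_n=config.mds_top_n)
        mds_path = out / "mds.tsv"
        coords.join(samples[["subtype", "supertype"]]).to_csv(
            mds_path, sep="\t", index_label="sample_id", float_format="%.6g"
        )
        record("mds", mds_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("mds", exc) from exc

    # screen (differential + separators)
    try:
        de = run_screen(
            m_qc.subset_regions(retained),
            samples,
            config.group_a,
            config.group_b,
            thresholds=config.thresholds(),
        )
        de_path = out / "de_results.tsv"
        de.to_csv(de_path, sep="\t", index_label="region_id", float_format="%.6g")
        ma_path = out / "ma_plot.tsv"
        de[["mean_cpm", "log2fc"]].to_csv(
            ma_path, sep="\t", index_label="region_id", float_format="%.6g"
        )
        record("screen", de_path, ma_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("screen", exc) from exc

    # evaluate markers on the difficult subtypes
    try:
        calls = binarize(scores)
        defs = [mk.definition for mk in ihc_cfg.markers]
        table = evaluate_markers(
            calls,
            samples,
            defs,
            restrict_subtypes={config.group_a, config.group_b},
            conf=config.conf,
        )
        eval_path = out / "marker_performance.tsv"
        table.to_csv(eval_path, sep="\t")
        record("evaluate", eval_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("evaluate", exc) from exc

    # panel search + sequential two-step strategy
    try:
        labels = samples["supertype"]
        ranked = exhaustive_search(defs, calls, labels)
        panel_path = out / "panel_search.tsv"
        search_table(ranked).to_csv(panel_path, sep="\t", float_format="%.6g")
        best = ranked[0][0]
        second_candidates = [r for r, _ in ranked[1:] if r != best] or [best]
        seq = sequential_panel(best, second_candidates[0], calls, labels)
        seq_path = out / "sequential_panel.tsv"
        pd.DataFrame(
            [
                {
                    "stage": "overall",
                    "ad_marker": best.ad_marker,
                    "scc_marker": best.scc_marker,
                    "n_correct": seq.overall.n_correct,
                    "n_incorrect": seq.overall.n_incorrect,
                    "n_inconclusive": seq.overall.n_inconclusive,
                    "accuracy": seq.overall.accuracy,
                }
            ]
        ).to_csv(seq_path, sep="\t", index=False, float_format="%.6g")
        record("panel", panel_path, seq_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("panel", exc) from exc

    # cluster
    try:
        sample_tree, marker_tree, _profile = cluster_profiles(scores)
        s_path = out / "samples.nwk"
        k_path = out / "markers.nwk"
        s_path.write_text(sample_tree.to_newick() + "\n")
        k_path.write_text(marker_tree.to_newick() + "\n")
        ordered = heatmap_order(scores, sample_tree, marker_tree)
        h_path = out / "heatmap_matrix.tsv"
        ordered.to_csv(h_path, sep="\t", index_label="sample_id")
        record("cluster", s_path, k_path, h_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("cluster", exc) from exc

    manifest = {
        "promopanel_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "thresholds": {
            "min_mapped": config.min_mapped,
            "cpm_threshold": config.cpm_threshold,
            "frac": config.frac,
            "max_fdr": config.max_fdr,
            "min_fold": config.min_fold,
            "min_cpm": config.min_cpm,
            "conf": config.conf,
        },
        "input_checksums": {k: _sha256(p) for k, p in inputs.items()},
        "stages": stage_outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
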