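"""Gene-wise standardization of tumor-specific signals into inference Z-scores.

The tumor-specific depleted promoter 5mC (d_T) and gene-body 5hmC (m_T)
both increase with gene expression.  Each is standardized gene-wise
against the baseline plasma cohort (mean and n−1 sd over baseline
samples), giving Z^M and Z^H; their equally weighted average is the
composite inference Z — the transcriptome-like readout.  Restaging and
progression samples are scored against the same baseline anchors
("baseline-anchored" mode), so a later timepoint's Z measures change in
baseline-cohort standard-deviation units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tumor_deconvolution import DeconvolvedMatrix


@dataclass
class BaselineStats:
    """Per-gene baseline anchors per modality (mean and n−1 sd).

    5mC anchors are computed on depleted fractions d_T.  Genes with
    fewer than two baseline observations or zero variance in either
    modality are dropped and listed in ``dropped``.
    """

    mean_m: pd.Series
    sd_m: pd.Series
    mean_h: pd.Series
    sd_h: pd.Series
    n_baseline: int
    dropped: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class GeneZMatrix:
    """Per-modality and composite inference Z-scores, genes × samples."""

    z_5mc: pd.DataFrame
    z_5hmc: pd.DataFrame
    composite: pd.DataFrame
    anchor_mode: str  # "baseline_cohort" or "baseline_anchored"


def baseline_stats(decon: DeconvolvedMatrix, meta: pd.DataFrame) -> BaselineStats:
    """Baseline anchors from the cohort's baseline plasma samples."""
    baseline_ids = [
        s
        for s in decon.tumor_5hmc.columns
        if meta.loc[s, "source"] == "plasma" and meta.loc[s, "timepoint"] == "baseline"
    ]
    if len(baseline_ids) < 2:
        raise ValueError("need ≥2 baseline plasma samples for gene-wise anchors")
    d = decon.depleted_5mc[baseline_ids]
    h = decon.tumor_5hmc[baseline_ids]
    mean_m, sd_m, drop_m = _moments(d)
    mean_h, sd_h, drop_h = _moments(h)
    keep = mean_m.index.intersection(mean_h.index)
    dropped = {
        "5mC": sorted(set(d.index) - set(mean_m.index)),
        "5hmC": sorted(set(h.index) - set(mean_h.index)),
    }
    return BaselineStats(
        mean_m.loc[keep],
        sd_m.loc[keep],
        mean_h.loc[keep],
        sd_h.loc[keep],
        len(baseline_ids),
        dropped,
    )


def _moments(mat: pd.DataFrame):
    n_obs = mat.notna().sum(axis=1)
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    keep = (n_obs >= 2) & (sd > 0)
    return mean[keep], sd[keep], list(mat.index[~keep])


def zscore(value: float, mean: float, sd: float) -> float:
    """Standardize a value against a gene's baseline anchor."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return (value - mean) / sd


def composite_z(z_m, z_h):
    """Equally weighted average of the two modality Z-scores.

    Missing either modality yields missing — no single-mark fallback, so
    the composite always means the same thing.
    """
    return (np.asarray(z_m, dtype=float) + np.asarray(z_h, dtype=float)) / 2.0


def anchored_scores(
    decon: DeconvolvedMatrix, stats: BaselineStats, meta: pd.DataFrame
) -> GeneZMatrix:
    """Score every plasma sample against the baseline anchors.

    Baseline samples' scores coincide exactly with the baseline-cohort
    standardization (same formula, same anchors), so per gene the
    baseline columns have mean 0 and sd 1.
    """
    genes = stats.mean_m.index
    d = decon.depleted_5mc.reindex(genes)
    h = decon.tumor_5hmc.reindex(genes)
    z_m = d.sub(stats.mean_m, axis=0).div(stats.sd_m, axis=0)
    z_h = h.sub(stats.mean_h, axis=0).div(stats.sd_h, axis=0)
    comp = (z_m + z_h) / 2.0
    return GeneZMatrix(z_m, z_h, comp, anchor_mode="baseline_anchored")


def baseline_cohort_scores(
    decon: DeconvolvedMatrix, stats: BaselineStats, meta: pd.DataFrame
) -> GeneZMatrix:
    """Baseline-only view of the anchored scores (anchor_mode baseline_cohort)."""
    z = anchored_scores(decon, stats, meta)
    baseline_ids = [
        s
        for s in z.composite.columns
        if meta.loc[s, "source"] == "plasma" and meta.loc[s, "timepoint"] == "baseline"
    ]
    return GeneZMatrix(
        z.z_5mc[baseline_ids],
        z.z_5hmc[baseline_ids],
        z.composite[baseline_ids],
        anchor_mode="baseline_cohort",
    )


@dataclass(frozen=True)
class SubtypePanel:
    """A lineage-defining gene panel (e.g. AD / NE / DN prostate subtypes)."""

    panel_name: str
    gene_ids: tuple[str, ...]


def subtype_panel_matrix(
    z: GeneZMatrix, panels: list[SubtypePanel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel-ordered composite-Z matrix plus per-panel mean scores.

    A positive composite Z predicts greater expression, so the per-panel
    mean over present genes reads as the activity of that lineage
    program in each sample.  Panels with no present genes get NaN.
    """
    rows = []
    index = []
    scores = {}
    for panel in panels:
        present = [g for g in panel.gene_ids if g in z.composite.index]
        if present:
            sub = z.composite.loc[present]
            rows.append(sub)
            index.extend((panel.panel_name, g) for g in present)
            scores[panel.panel_name] = sub.mean(axis=0)
        else:
            scores[panel.panel_name] = pd.Series(np.nan, index=z.composite.columns)
    matrix = pd.concat(rows) if rows else pd.DataFrame(columns=z.composite.columns)
    if rows:
        matrix.index = pd.MultiIndex.from_tuples(index, names=["panel", "gene_id"])
    return matrix, pd.DataFrame(scores).T


def default_subtype_panels() -> list[SubtypePanel]:
    """Editable default AD/NE/DN lineage panels shipped as package data."""
    from importlib.resources import files

    from .io_formats import read_gmt

    gmt = read_gmt(files("methylotype").joinpath("data/panels.gmt"))
    return [SubtypePanel(name, tuple(genes)) for name, genes in gmt.sets.items()]


def classify_ctdna_status(purity: float) -> str:
    """ctDNA positivity by tumor fraction: negative iff purity < 0.1."""
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    return "negative" if purity < 0.1 else "positive"
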