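"""Two-component tumor/normal deconvolution of bulk cfDNA methylation.

Plasma cfDNA is a mixture of tumor-derived and normal (mostly
hematopoietic) DNA.  Given the sample's tumor fraction p (ctDNA
"purity") and a gene-wise background profile estimated from buffy-coat
controls, the bulk gene-level modification fraction is inverted to a
tumor-specific fraction:

* 5hmC (gene body):      m_T = (m_bulk − (1−p)·m_N) / p
* 5mC (promoter window): m_T = (m_bulk·(CN_T + CN_N) − m_N·CN_N) / CN_T
  with effective copy-number weights CN_T = p·cn_tumor and
  CN_N = (1−p)·cn_normal (2 on autosomes, 1 on X/Y for a male cohort).

With cn_tumor = 2 on an autosome the 5mC form reduces algebraically to
the 5hmC form.  Tumor 5mC is reported alongside its depleted fraction
d_T = 1 − m_T so that both marks increase with inferred expression.

Solutions outside [0, 1] are clipped and flagged; samples below the
ctDNA-positivity purity threshold (0.1) are rejected, since the 1/p
amplification makes their deconvolution meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_PURITY = 0.1  # ctDNA fraction < 0.1 ⇒ ctDNA-negative


class PurityError(ValueError):
    """Sample purity below the ctDNA-positivity threshold."""


@dataclass
class BackgroundProfile:
    """Gene-wise mean normal fractions per timepoint class and modality.

    ``mean[modality]`` is a genes × {BL, TR} DataFrame.  A class with no
    buffy-coat controls falls back to the all-control mean and is
    recorded in ``fallback_classes``.
    """

    mean: dict[str, pd.DataFrame]
    n_controls: dict[str, int]
    fallback_classes: set = field(default_factory=set)


@dataclass
class DeconvolvedMatrix:
    """Tumor-specific fractions for plasma samples (genes × samples)."""

    tumor_5hmc: pd.DataFrame
    tumor_5mc: pd.DataFrame
    depleted_5mc: pd.DataFrame
    clip_5hmc: pd.DataFrame
    clip_5mc: pd.DataFrame


def background_profile(
    buffy_hmc: pd.DataFrame, buffy_mc: pd.DataFrame, meta: pd.DataFrame
) -> BackgroundProfile:
    """Per-class, per-gene mean normal fractions from buffy-coat controls.

    Buffy-coat samples are selected by source flag.  Classes without
    controls fall back (flagged) to the mean over all controls.
    """
    buffy = meta[meta["source"] == "buffycoat"]
    if len(buffy) == 0:
        raise ValueError("no buffy-coat control samples in the sample sheet")
    means: dict[str, pd.DataFrame] = {}
    n_controls: dict[str, int] = {}
    fallback: set = set()
    for modality, mat in (("5hmC", buffy_hmc), ("5mC", buffy_mc)):
        cols = {}
        for cls in ("BL", "TR"):
            ids = [s for s in buffy["sample_id"] if buffy.loc[s, "timepoint_class"] == cls]
            ids = [s for s in ids if s in mat.columns]
            n_controls[cls] = len(ids)
            if ids:
                cols[cls] = mat[ids].mean(axis=1)
            else:
                all_ids = [s for s in buffy["sample_id"] if s in mat.columns]
                cols[cls] = mat[all_ids].mean(axis=1)
                fallback.add(cls)
        means[modality] = pd.DataFrame(cols)
    return BackgroundProfile(means, n_controls, fallback)


def _check_purity(purity, min_purity: float) -> None:
    p = np.asarray(purity, dtype=float)
    if np.any(p < min_purity):
        raise PurityError(
            f"purity below {min_purity}: sample is ctDNA-negative and cannot be deconvolved"
        )


def deconvolve_5hmc(bulk, background, purity, min_purity: float = MIN_PURITY):
    """Tumor-specific 5hmC fraction (vectorized).

    Returns (value, clipped) where values are clipped into [0, 1] and
    ``clipped`` marks cells whose unclipped solution fell outside.
    """
    _check_purity(purity, min_purity)
    bulk = np.asarray(bulk, dtype=float)
    background = np.asarray(background, dtype=float)
    p = np.asarray(purity, dtype=float)
    raw = (bulk - (1.0 - p) * background) / p
    clipped = (raw < 0.0) | (raw > 1.0)
    clipped &= ~np.isnan(raw)
    return np.clip(raw, 0.0, 1.0), clipped


def deconvolve_5mc(
    bulk,
    background,
    purity,
    cn_tumor,
    cn_normal_chrom=2,
    min_purity: float = MIN_PURITY,
):
    """Tumor-specific 5mC fraction with copy-number weighting (vectorized).

    CN_T = p·cn_tumor, CN_N = (1−p)·cn_normal_chrom.  cn_tumor = 0
    (homozygous deletion: no tumor template) yields NaN, never a
    division failure.
    """
    _check_purity(purity, min_purity)
    bulk = np.asarray(bulk, dtype=float)
    background = np.asarray(background, dtype=float)
    p = np.asarray(purity, dtype=float)
    cn_t = p * np.asarray(cn_tumor, dtype=float)
    cn_n = (1.0 - p) * np.asarray(cn_normal_chrom, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(cn_t > 0, (bulk * (cn_t + cn_n) - background * cn_n) / cn_t, np.nan)
    clipped = (raw < 0.0) | (raw > 1.0)
    clipped &= ~np.isnan(raw)
    return np.clip(raw, 0.0, 1.0), clipped


def depleted_fraction(m):
    """Complement 1 − m, orienting promoter 5mC with expression."""
    return 1.0 - m


def deconvolve_cohort(
    bulk_hmc: pd.DataFrame,
    bulk_mc: pd.DataFrame,
    background: BackgroundProfile,
    meta: pd.DataFrame,
    gene_cn: pd.DataFrame,
    cn_normal: pd.Series,
    min_purity: float = MIN_PURITY,
) -> DeconvolvedMatrix:
    """Deconvolve every ctDNA-positive plasma sample gene-wise.

    ``gene_cn`` is genes × plasma-samples tumor copy number; ``cn_normal``
    is the per-gene normal copy number (2 autosomes, 1 X/Y).  Each sample
    uses the background of its timepoint class.  Missing inputs (bulk,
    background, or copy number) propagate to missing outputs.
    """
    plasma = meta[meta["source"] == "plasma"]
    if plasma["purity"].isna().any():
        bad = plasma.loc[plasma["purity"].isna(), "sample_id"].tolist()
        raise ValueError(f"plasma sample(s) missing purity: {bad}")
    plasma = plasma[plasma["purity"] >= min_purity]
    genes = bulk_hmc.index
    samples = [s for s in plasma["sample_id"] if s in bulk_hmc.columns]

    t_hmc = pd.DataFrame(np.nan, index=genes, columns=samples)
    t_mc = pd.DataFrame(np.nan, index=genes, columns=samples)
    c_hmc = pd.DataFrame(False, index=genes, columns=samples)
    c_mc = pd.DataFrame(False, index=genes, columns=samples)
    bg_h = background.mean["5hmC"].reindex(genes)
    bg_m = background.mean["5mC"].reindex(genes)
    cn_norm = cn_normal.reindex(genes).values

    for sid in samples:
        p = float(plasma.loc[sid, "purity"])
        cls = plasma.loc[sid, "timepoint_class"]
        vals, clip = deconvolve_5hmc(
            bulk_hmc[sid].values, bg_h[cls].values, p, min_purity
        )
        t_hmc[sid] = vals
        c_hmc[sid] = clip
        cn = gene_cn[sid].reindex(genes).values if sid in gene_cn.columns else np.full(
            len(genes), np.nan
        )
        vals, clip = deconvolve_5mc(
            bulk_mc[sid].values, bg_m[cls].values, p, cn, cn_norm, min_purity
        )
        t_mc[sid] = vals
        c_mc[sid] = clip
    return DeconvolvedMatrix(t_hmc, t_mc, 1.0 - t_mc, c_hmc, c_mc)
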