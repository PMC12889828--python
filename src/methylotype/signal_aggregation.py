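"""Collapse per-CpG calls into gene-level modification fractions.

Gene-body 5hmC and promoter-window 5mC are the two gene-level signals
feeding tumor/normal deconvolution.  The promoter window spans 1 kb
upstream to 5 kb downstream of the TSS, strand-aware.  Region fractions
are pooled-count fractions (sum of modified counts over sum of depths),
so deeper CpG sites carry proportionally more weight; a region with
fewer than ``min_sites`` qualifying CpG sites is missing.

Also provides RNA normalization (CPM → log10 → within-sample Z) with
blood-marker exclusion, the quantile-binned median correlation used to
validate epigenetic expression estimates against RNA, and the ±30 bp
central-coverage summary for TFBS footprinting profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel

MODALITY_COLUMNS = {"5mC": "n_5mC", "5hmC": "n_5hmC"}


def promoter_window(gene: GeneModel, upstream: int = 1000, downstream: int = 5000):
    """Strand-aware promoter interval around the TSS, clipped at 0.

    On + the window is [tss−upstream, tss+downstream); on − it is the
    mirror image [tss−downstream+1, tss+upstream+1).
    """
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream + 1, gene.tss + upstream + 1
    return max(lo, 0), max(hi, 0)


def aggregate_region_fraction(
    calls: pd.DataFrame,
    chrom: str,
    interval: tuple[int, int],
    modality: str,
    min_sites: int = 10,
) -> float:
    """Pooled-count modification fraction over CpG sites in a region.

    ``calls`` must already be site-depth filtered.  Returns NaN when
    fewer than ``min_sites`` CpG sites fall inside the half-open
    interval (or the region is empty).
    """
    col = MODALITY_COLUMNS[modality]
    lo, hi = interval
    if hi <= lo:
        return float("nan")
    sub = calls[(calls["chrom"] == chrom) & (calls["pos"] >= lo) & (calls["pos"] < hi)]
    if len(sub) < max(min_sites, 1):
        return float("nan")
    depth = int(sub["depth"].sum())
    if depth == 0:
        return float("nan")
    return float(sub[col].sum()) / float(depth)


def build_gene_matrices(
    calls_by_sample: dict[str, pd.DataFrame],
    genes: list[GeneModel],
    meta: pd.DataFrame,
    min_sites: int = 10,
    upstream: int = 1000,
    downstream: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level bulk matrices: 5hmC over gene bodies, 5mC over promoters.

    Returns (hmc, mc) DataFrames over genes × samples in the sample-sheet
    order; cells failing the ``min_sites`` rule are NaN.
    """
    missing = [s for s in meta["sample_id"] if s not in calls_by_sample]
    if missing:
        raise ValueError(f"no CpG calls for sample(s): {missing}")
    sample_ids = list(meta["sample_id"])
    gene_ids = [g.gene_id for g in genes]
    hmc = np.full((len(genes), len(sample_ids)), np.nan)
    mc = np.full_like(hmc, np.nan)
    for j, sid in enumerate(sample_ids):
        calls = calls_by_sample[sid]
        # index per chromosome once per sample for speed
        by_chrom = {c: sub.sort_values("pos") for c, sub in calls.groupby("chrom")}
        for i, g in enumerate(genes):
            sub = by_chrom.get(g.chrom)
            if sub is None:
                continue
            pos = sub["pos"].values
            hmc[i, j] = _pooled(sub, pos, g.start, g.end, "n_5hmC", min_sites)
            plo, phi = promoter_window(g, upstream, downstream)
            mc[i, j] = _pooled(sub, pos, plo, phi, "n_5mC", min_sites)
    hmc_df = pd.DataFrame(hmc, index=gene_ids, columns=sample_ids)
    mc_df = pd.DataFrame(mc, index=gene_ids, columns=sample_ids)
    return hmc_df, mc_df


def _pooled(sub: pd.DataFrame, pos: np.ndarray, lo: int, hi: int, col: str, min_sites: int):
    a, b = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
    if b - a < max(min_sites, 1):
        return np.nan
    depth = sub["depth"].values[a:b].sum()
    if depth == 0:
        return np.nan
    return sub[col].values[a:b].sum() / depth


# ---------------------------------------------------------------------------
# RNA normalization and the binned-median validation correlation
# ---------------------------------------------------------------------------

def rna_normalize(counts: pd.DataFrame, exclude: list[str] | None = None) -> pd.DataFrame:
    """CPM → log10(CPM+1) → within-sample Z-scores.

    ``exclude`` lists erythroid/platelet marker genes removed *before*
    library totals are computed (anucleated cells contribute RNA but no
    DNA, so their transcripts are dropped for comparability with the
    methylome).  Each output column has mean 0 and sd 1 over retained
    genes.
    """
    if (counts.fillna(0) < 0).any().any():
        raise ValueError("RNA counts must be ≥ 0")
    if exclude:
        counts = counts.drop(index=[g for g in exclude if g in counts.index])
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    cpm = counts.div(totals, axis=1) * 1e6
    logged = np.log10(cpm + 1.0)
    z = logged.sub(logged.mean(axis=0), axis=1).div(logged.std(axis=0, ddof=1), axis=1)
    return z


def binned_median_correlation(
    x: pd.Series, y: pd.Series, nbins: int = 50
) -> tuple[float, float]:
    """Pearson correlation of per-bin medians over quantile bins of ``x``.

    Genes are ranked by ``x`` into ``nbins`` as-equal-as-possible bins
    (the first n mod nbins bins receive one extra gene); the Pearson r
    and two-sided p are computed on the nbins (median x, median y)
    pairs.  Smooths gene-level noise so that monotone agreement between
    two expression surrogates is visible.
    """
    paired = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    n = len(paired)
    if n < nbins:
        raise ValueError(f"need ≥ {nbins} paired genes, got {n}; reduce nbins")
    order = np.argsort(paired["x"].values, kind="stable")
    sizes = np.full(nbins, n // nbins)
    sizes[: n % nbins] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    mx = np.empty(nbins)
    my = np.empty(nbins)
    xv, yv = paired["x"].values[order], paired["y"].values[order]
    for b in range(nbins):
        sl = slice(edges[b], edges[b + 1])
        mx[b] = np.median(xv[sl])
        my[b] = np.median(yv[sl])
    r, p = stats.pearsonr(mx, my)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# TFBS central coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Normalized coverage around one site, offsets in bp from center."""

    site_id: str
    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must align")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be ≥ 0")


def central_coverage(profiles: list[CoverageProfile], flank: int = 30) -> float:
    """Mean normalized coverage within ±flank bp, averaged across sites.

    Depletion of central coverage at a factor's binding sites indicates
    nucleosome displacement, i.e. factor activity.
    """
    if not profiles:
        raise ValueError("no coverage profiles given")
    site_means = []
    for p in profiles:
        if p.offsets.min() > -flank or p.offsets.max() < flank:
            raise ValueError(f"profile {p.site_id} does not span ±{flank} bp")
        mask = np.abs(p.offsets) <= flank
        site_means.append(float(p.values[mask].mean()))
    return float(np.mean(site_means))
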