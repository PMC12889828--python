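"""Baseline association of inferred expression with clinical outcome.

Gene-wise Cox proportional-hazards screening of the composite inference
Z against rPFS/OS, Spearman ranking of genes against PFS feeding
preranked GSEA, exact 2×2 categorical tests, Kaplan-Meier medians with
log-rank comparison, and Shannon diversity indices for T-cell
clonotype repertoires and subclonal architectures.

Cox p-values are deliberately left unadjusted: the screen's purpose is
to select a P < 0.05 gene list for downstream pathway analysis, not to
declare single-gene discoveries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .expression_inference import GeneZMatrix
from .io_formats import GeneSetCollection

LN2 = float(np.log(2.0))


def genewise_cox(
    z_baseline: GeneZMatrix,
    survival: pd.DataFrame,
    endpoint: str = "rPFS",
    case_of: pd.Series | None = None,
) -> pd.DataFrame:
    """One single-covariate Cox fit per gene on baseline samples.

    Each baseline plasma sample maps to its case's survival record via
    ``case_of`` (sample_id → case_id; defaults to the identity when the
    matrix columns already are case ids).  Returns a DataFrame indexed
    by gene with log2 hazard ratio, its standard error, the Wald
    p-value and n; genes whose fit fails (constant covariate,
    separation) are reported with NaN estimates and the failure reason.
    """
    time_col, event_col = _endpoint_columns(endpoint)
    comp = z_baseline.composite
    if case_of is None:
        case_of = pd.Series(comp.columns, index=comp.columns)
    missing = [s for s in comp.columns if case_of.get(s) not in survival.index]
    if missing:
        raise ValueError(f"baseline sample(s) without survival record: {missing}")
    times = np.array([survival.loc[case_of[s], time_col] for s in comp.columns], dtype=float)
    events = np.array([survival.loc[case_of[s], event_col] for s in comp.columns], dtype=bool)
    if events.sum() == 0:
        raise ValueError("no events observed for endpoint " + endpoint)

    rows = {}
    for gene, zvals in comp.iterrows():
        z = zvals.values.astype(float)
        ok = ~np.isnan(z)
        n = int(ok.sum())
        if n < 3 or np.nanstd(z) == 0:
            rows[gene] = (np.nan, np.nan, np.nan, n, "constant or too few values")
            continue
        df = pd.DataFrame({"time": times[ok], "event": events[ok], "z": z[ok]})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            beta = float(cph.params_["z"])
            se = float(cph.standard_errors_["z"])
            p = float(cph.summary.loc["z", "p"])
            rows[gene] = (beta / LN2, se / LN2, p, n, "")
        except Exception as exc:  # inestimable coefficient
            rows[gene] = (np.nan, np.nan, np.nan, n, str(exc)[:80])
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["log2_hr", "se", "p", "n", "note"]
    )
    out.index.name = "gene_id"
    return out


def _endpoint_columns(endpoint: str):
    key = endpoint.lower()
    if key in ("rpfs", "pfs"):
        return "rpfs_months", "rpfs_event"
    if key == "os":
        return "os_months", "os_event"
    raise ValueError(f"unknown endpoint {endpoint!r}")


def attach_case_survival(meta: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    """Join per-sample metadata with its case's survival record."""
    return meta.join(survival.drop(columns=["case_id"]), on="case_id")


def spearman_rank_genes(z_baseline: GeneZMatrix, pfs_months: pd.Series) -> pd.DataFrame:
    """Rank genes by Spearman correlation of composite Z with PFS.

    Returns genes sorted by decreasing rho (average ranks for ties);
    constant genes get rho 0.  The ranked statistic feeds preranked
    GSEA, so a positive rho means predicted expression tracks longer
    PFS.
    """
    comp = z_baseline.composite
    samples = [s for s in comp.columns if s in pfs_months.index]
    if len(samples) < 3:
        raise ValueError("need ≥3 samples with PFS")
    z = comp[samples].values
    y = pfs_months.loc[samples].values.astype(float)
    ry = stats.rankdata(y)
    rz = np.apply_along_axis(stats.rankdata, 1, z)
    # Pearson on ranks == Spearman; constant rows yield sd 0 → rho 0
    rz_c = rz - rz.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rz_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rz_c @ ry_c / denom, 0.0)
    out = pd.DataFrame({"rho": rho}, index=comp.index)
    out.index.name = "gene_id"
    return out.sort_values("rho", ascending=False, kind="stable")


def preranked_gsea(
    ranked: pd.Series,
    sets: GeneSetCollection,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 2000,
    permutations: int = 10000,
) -> pd.DataFrame:
    """Preranked GSEA (weighted running-sum, gene-permutation null).

    ``ranked`` maps unique gene ids to the ranking statistic.  Nominal
    p-values come from the permutation null and are BH-adjusted across
    sets; NES signs match the enrichment direction.  Sets emptied by the
    presence/size filter are skipped.
    """
    import gseapy

    if ranked.index.duplicated().any():
        raise ValueError("ranked list must have unique genes")
    rnk = ranked.sort_values(ascending=False)
    present = set(rnk.index)
    usable = {
        name: [g for g in genes if g in present]
        for name, genes in sets.sets.items()
    }
    usable = {k: v for k, v in usable.items() if min_size <= len(v) <= max_size}
    if not usable:
        raise ValueError("no gene sets usable after filtering")
    res = gseapy.prerank(
        rnk=rnk.reset_index(),
        gene_sets=usable,
        permutation_num=permutations,
        min_size=min_size,
        max_size=max_size,
        seed=int(seed),
        outdir=None,
        no_plot=True,
        threads=1,
        verbose=False,
    ).res2d
    p_floor = 1.0 / permutations
    p = np.maximum(res["NOM p-val"].astype(float).values, p_floor)
    out = pd.DataFrame(
        {
            "es": res["ES"].astype(float).values,
            "nes": res["NES"].astype(float).values,
            "p": p,
            "p_adj": np.maximum(multipletests(p, method="fdr_bh")[1], p),
            "leading_edge": [
                str(le).split(";") if isinstance(le, str) and le else []
                for le in res["Lead_genes"]
            ],
        },
        index=res["Term"].values,
    )
    out.index.name = "set_name"
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table (probability-mass rule)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2×2")
    if (arr < 0).any():
        raise ValueError("table entries must be ≥ 0")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def km_median_logrank(
    groups: pd.Series, times: pd.Series, events: pd.Series
) -> tuple[dict, float]:
    """Kaplan-Meier median per group and the log-rank p across groups.

    Medians are NaN when the survival curve never crosses 0.5.
    """
    groups, times, events = (
        pd.Series(groups).reset_index(drop=True),
        pd.Series(times).reset_index(drop=True),
        pd.Series(events).reset_index(drop=True),
    )
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need ≥2 groups")
    medians = {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        med = kmf.median_survival_time_
        medians[lab] = float(med) if np.isfinite(med) else float("nan")
    if len(labels) == 2:
        m0, m1 = groups == labels[0], groups == labels[1]
        res = logrank_test(times[m0], times[m1], events[m0], events[m1])
    else:
        res = multivariate_logrank_test(times, groups, events)
    return medians, float(res.p_value)


def shannon_index(counts) -> float:
    """Shannon-Weiner diversity H = −Σ p·ln p (natural log).

    Zero counts are excluded; invariant to rescaling all counts.  H is 0
    iff a single category carries all the abundance, and at most ln k
    for k categories.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be ≥ 0")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("need at least one positive count")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def subclone_sdi(ccfs) -> float:
    """Shannon diversity of a case's subclone CCFs at one timepoint."""
    return shannon_index(ccfs)


def clonotype_diversity(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """Shannon index per (sample, locus) from a clonotype count table."""
    rows = [
        {"sample_id": sid, "locus": locus, "shannon": shannon_index(sub["count"].values)}
        for (sid, locus), sub in clonotypes.groupby(["sample_id", "locus"])
    ]
    return pd.DataFrame(rows)
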