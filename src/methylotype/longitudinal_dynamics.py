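"""Longitudinal change statistics on baseline-anchored inference Z-scores.

Treatment-exposure effects are estimated gene-wise with a linear mixed
model (fixed exposure effect, case-level random intercept); within-case
change vectors ΔgeneZ (progression − baseline) are summarized by their
root-mean-square (ΔRMS); subclonal remodeling is quantified by the
cumulative absolute CCF shift; and cases are stratified along two
non-mutually exclusive resistance axes — clonal remodeling (CCF shift
> 0.1) and intrinsic resistance (radiographic progression < 2 months).
Differential change between axis groups uses a gene-wise linear model
with empirical-Bayes variance moderation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .expression_inference import GeneZMatrix

CCF_SHIFT_THRESHOLD = 0.1  # strict: > 0.1 defines the high-shift arm
RAPID_RPFS_MONTHS = 2.0  # strict: < 2 months defines rapid progression


# ---------------------------------------------------------------------------
# exposure mixed model
# ---------------------------------------------------------------------------

def fit_exposure_lmm(
    z: GeneZMatrix, meta: pd.DataFrame, progression_only: bool = False
) -> pd.DataFrame:
    """Gene-wise mixed model: z ~ Exposed + (1 | Case).

    "Exposed" pools restaging and progression samples against baseline
    (restrict with ``progression_only``).  β(Exposed) is the mean change
    in baseline-anchored Z upon treatment exposure.  The Wald t uses a
    between-within degrees-of-freedom approximation
    (df = n_obs − n_cases − 1); p-values are unadjusted.
    """
    import statsmodels.api as sm

    exposed_tps = {"progression"} if progression_only else {"restaging", "progression"}
    plasma = meta[(meta["source"] == "plasma")]
    samples = [s for s in z.composite.columns if s in plasma.index]
    exposed = np.array([plasma.loc[s, "timepoint"] in exposed_tps for s in samples])
    cases = np.array([plasma.loc[s, "case_id"] for s in samples])
    both = {
        c
        for c in np.unique(cases)
        if exposed[cases == c].any() and (~exposed[cases == c]).any()
    }
    if len(both) < 2:
        raise ValueError("need ≥2 cases with both baseline and exposed samples")

    rows = {}
    comp = z.composite[samples]
    for gene, vals in comp.iterrows():
        y = vals.values.astype(float)
        ok = ~np.isnan(y)
        if not (exposed[ok].any() and (~exposed[ok]).any()):
            rows[gene] = (np.nan, np.nan, np.nan, np.nan, int(ok.sum()), 0, "missing arm")
            continue
        yy, xx, gg = y[ok], exposed[ok].astype(float), cases[ok]
        n_cases = len(np.unique(gg))
        ddf = len(yy) - n_cases - 1
        if ddf < 1:
            rows[gene] = (np.nan, np.nan, np.nan, np.nan, len(yy), n_cases, "no residual df")
            continue
        exog = np.column_stack([np.ones_like(yy), xx])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(yy, exog, groups=gg)
                try:
                    fit = model.fit(reml=True)
                except Exception:
                    fit = model.fit(reml=True, method="powell")
            beta = float(fit.fe_params[1])
            se = float(fit.bse_fe[1])
            p = 2.0 * stats.t.sf(abs(beta / se), ddf) if se > 0 else np.nan
            rows[gene] = (beta, se, p, float(ddf), len(yy), n_cases, "")
        except Exception as exc:
            rows[gene] = (np.nan, np.nan, np.nan, np.nan, len(yy), n_cases, str(exc)[:60])
    out = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["beta", "se", "p", "df", "n_samples", "n_cases", "note"],
    )
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# paired change vectors
# ---------------------------------------------------------------------------

@dataclass
class DeltaVector:
    """Per-case gene-wise ΔgeneZ (progression − baseline) and its RMS."""

    case_id: str
    deltas: pd.Series
    delta_rms: float


def delta_gene_z(z: GeneZMatrix, meta: pd.DataFrame, case: str) -> DeltaVector:
    """Paired per-gene change for one case.

    Requires exactly one baseline and one progression plasma sample with
    scores; genes missing in either sample are omitted from both the
    vector and the RMS.
    """
    plasma = meta[(meta["source"] == "plasma") & (meta["case_id"] == case)]
    base = [s for s in plasma.index[plasma["timepoint"] == "baseline"] if s in z.composite]
    prog = [s for s in plasma.index[plasma["timepoint"] == "progression"] if s in z.composite]
    if len(base) != 1 or len(prog) != 1:
        raise ValueError(
            f"case {case}: need exactly one scored baseline and one progression sample "
            f"(found {len(base)} and {len(prog)})"
        )
    deltas = (z.composite[prog[0]] - z.composite[base[0]]).dropna()
    rms = float(np.sqrt(np.mean(np.square(deltas.values)))) if len(deltas) else float("nan")
    return DeltaVector(case, deltas, rms)


def delta_matrix(z: GeneZMatrix, meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """ΔgeneZ vectors for every case with a paired baseline/progression.

    Returns (genes × cases matrix, per-case ΔRMS series).
    """
    plasma = meta[meta["source"] == "plasma"]
    vectors = {}
    rms = {}
    for case in plasma["case_id"].unique():
        try:
            dv = delta_gene_z(z, meta, case)
        except ValueError:
            continue
        vectors[case] = dv.deltas
        rms[case] = dv.delta_rms
    if not vectors:
        raise ValueError("no case has a paired baseline/progression sample")
    return pd.DataFrame(vectors), pd.Series(rms, name="delta_rms")


# ---------------------------------------------------------------------------
# clonal dynamics and resistance axes
# ---------------------------------------------------------------------------

def ccf_shift(
    ccfs: pd.DataFrame,
    case: str,
    from_timepoint: str = "baseline",
    to_timepoint: str = "progression",
) -> float:
    """Cumulative absolute CCF change across all subclones of a case.

    Clones absent at a timepoint contribute their full CCF (emergence
    from, or extinction to, 0); the statistic is symmetric in the two
    timepoints.
    """
    sub = ccfs[ccfs["case_id"] == case]
    if len(sub) == 0:
        raise ValueError(f"case {case} absent from CCF table")
    a = sub[sub["timepoint"] == from_timepoint].set_index("clone_id")["ccf"]
    b = sub[sub["timepoint"] == to_timepoint].set_index("clone_id")["ccf"]
    clones = a.index.union(b.index)
    return float(
        (b.reindex(clones, fill_value=0.0) - a.reindex(clones, fill_value=0.0)).abs().sum()
    )


@dataclass(frozen=True)
class ResistanceLabels:
    """The two non-mutually exclusive resistance-axis labels for a case."""

    case_id: str
    ccf_shift: float
    rpfs_months: float
    high_ccf: bool
    rapid: bool


def classify_resistance(
    case_id: str, ccf_shift_value: float, rpfs_months: float
) -> ResistanceLabels:
    """Apply the two axis thresholds (both strict inequalities)."""
    if not (np.isfinite(ccf_shift_value) and np.isfinite(rpfs_months)):
        raise ValueError("inputs must be finite")
    return ResistanceLabels(
        case_id=case_id,
        ccf_shift=float(ccf_shift_value),
        rpfs_months=float(rpfs_months),
        high_ccf=bool(ccf_shift_value > CCF_SHIFT_THRESHOLD),
        rapid=bool(rpfs_months < RAPID_RPFS_MONTHS),
    )


def resistance_labels(ccfs: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    """Label every case present in both the CCF and survival tables."""
    rows = []
    for case in survival.index:
        if case not in set(ccfs["case_id"]):
            continue
        shift = ccf_shift(ccfs, case)
        lab = classify_resistance(case, shift, float(survival.loc[case, "rpfs_months"]))
        rows.append(vars(lab))
    if not rows:
        raise ValueError("no case shared between CCF and survival tables")
    return pd.DataFrame(rows).set_index("case_id")


# ---------------------------------------------------------------------------
# empirical-Bayes moderated two-group test
# ---------------------------------------------------------------------------

def moderated_group_test(
    deltas: pd.DataFrame, group: pd.Series, top_n: int = 500
) -> pd.DataFrame:
    """Gene-wise two-group comparison of ΔgeneZ with variance moderation.

    Per gene, an ordinary two-group linear model gives the group-mean
    difference and residual variance; residual variances are shrunk
    toward a pooled inverse-chi-square prior fitted by moments
    (limma-style empirical Bayes), giving moderated t statistics with
    df = d_prior + d_residual and unadjusted two-sided p-values.  The
    ``selected`` column marks the top ``top_n`` genes by moderated t in
    each direction (fewer when the matrix is small).
    """
    group = group.reindex(deltas.columns)
    if group.isna().any():
        raise ValueError("every case needs a group label")
    g = group.values.astype(bool)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need ≥2 cases per group")
    x = deltas.values
    m1 = np.nanmean(x[:, g], axis=1)
    m0 = np.nanmean(x[:, ~g], axis=1)
    diff = m1 - m0
    resid = np.concatenate([x[:, g] - m1[:, None], x[:, ~g] - m0[:, None]], axis=1)
    d_resid = n1 + n0 - 2
    s2 = np.nansum(resid**2, axis=1) / d_resid
    d0, s0_sq = _fit_f_dist(s2[s2 > 0], d_resid)
    if np.isfinite(d0):
        s2_post = (d0 * s0_sq + d_resid * s2) / (d0 + d_resid)
        df_total = d0 + d_resid
    else:
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    stderr = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / stderr
    p = 2.0 * (
        stats.t.sf(np.abs(t), df_total) if np.isfinite(df_total) else stats.norm.sf(np.abs(t))
    )
    out = pd.DataFrame(
        {"t": t, "p": p, "diff": diff, "df": df_total}, index=deltas.index
    )
    desc = out["t"].sort_values(ascending=False)
    up = desc[desc > 0].index[:top_n]
    asc = out["t"].sort_values(ascending=True)
    down = asc[asc < 0].index[:top_n]
    out["selected"] = ""
    out.loc[up, "selected"] = "up"
    out.loc[down, "selected"] = "down"
    out.index.name = "gene_id"
    return out


def _fit_f_dist(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment fit of a scaled-F prior to sample variances (limma-style).

    Returns (prior df d0, prior variance s0²); d0 = inf when the
    observed log-variances are under-dispersed relative to chi-square
    sampling noise alone.
    """
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)
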