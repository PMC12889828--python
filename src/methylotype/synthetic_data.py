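"""Seeded synthetic cfDNA methylome cohort with known ground truth.

The generator emulates the data shapes of a dual 5mC/5hmC plasma
sequencing study: a latent tumor expression Z per gene and sample is
mapped through an affine link to tumor-specific gene-body 5hmC and
promoter 5mC fractions, forward-mixed with a blood background at the
sample's ctDNA purity (and per-gene copy number for 5mC), and emitted
either as gene-level matrices or as per-CpG call files together with
the sample sheet, segments, survival, CCF, clonotype, RNA and
regulator-set inputs the pipeline consumes.

The affine link (tumor fraction = α_g + β_g·Z) makes the noiseless
pipeline an exact inverse: forward mixing followed by deconvolution and
baseline standardization returns the stored truth to numerical
precision.  Gaussian noise on bulk fractions (default sd 0.003,
matching pooled binomial error over multi-kb regions at ~20-30×
coverage) provides the default noise model; the file-level emitter uses
binomial per-CpG counts instead.

Study conditions baked into the defaults: purity uniform on
[0.10, 0.85], three timepoints (baseline/restaging/progression) per
case, nine buffy-coat controls split across timepoint classes, an
exposure program shifted by +0.8 Z at treated timepoints, and two
non-mutually exclusive resistance arms whose progression samples are
displaced along different gene programs (clonal remodeling with CCF
shift > 0.1, rapid progression with rPFS < 2 months).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import (
    GeneModel,
    GeneSetCollection,
    write_ccf_table,
    write_clonotype_table,
    write_cpg_calls,
    write_gene_matrix,
    write_gene_models_bed,
    write_gmt,
    write_sample_sheet,
    write_segments,
    write_survival,
)

CHROMS = ("chr1", "chr2", "chr3", "chrX")
PROGRAM_NAMES = ("exposure", "arm_high_ccf", "arm_rapid", "survival")

#: regulator sets derived from the three trajectory analyses; these form
#: the regulator-score block of the latent-space integration (the
#: survival regulators are outcome-derived, not trajectory-derived)
TRAJECTORY_REGULATORS = (
    "REG_EXPOSURE",
    "REG_EXPOSURE_PARTIAL",
    "REG_ARM_HIGH_CCF",
    "REG_ARM_HIGH_CCF_PARTIAL",
    "REG_ARM_RAPID",
    "REG_ARM_RAPID_PARTIAL",
)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    seed: int = 17
    n_cases: int = 20
    n_genes: int = 400
    n_programs: int = 4
    program_size: int = 40
    program_loading: float = 0.8
    purity_range: tuple = (0.10, 0.85)
    n_controls_bl: int = 5
    n_controls_tr: int = 4
    # affine link latent Z → tumor fraction
    link_intercept_range: tuple = (0.45, 0.55)
    link_slope_range: tuple = (0.05, 0.09)
    latent_clip: float = 3.0
    # noise (gene-level Gaussian, matrix emitter)
    noise_sd: float = 0.003
    buffy_noise_sd: float = 0.003
    # planted effects
    exposure_shift: float = 0.8
    arm_shift: float = 1.5
    frac_high_ccf: float = 0.4
    frac_rapid: float = 0.4
    # survival model
    log_hazard_per_unit: float = 0.7
    base_scale_months: float = 6.0
    censoring_rate: float = 0.2
    # copy number
    cn_values: tuple = (1, 2, 3, 4)
    cn_probs: tuple = (0.10, 0.70, 0.15, 0.05)
    # clonal architecture
    n_clones: int = 3
    high_shift_range: tuple = (0.10, 0.30)
    low_shift_range: tuple = (0.0, 0.04)
    # genome layout (file emitter)
    gene_length: int = 10000
    gene_spacing: int = 50000
    body_sites_range: tuple = (40, 120)
    promoter_sites_range: tuple = (12, 40)
    site_depth_range: tuple = (2, 60)  # sites below depth 3 exercise the filter
    noiseless_depth: int = 50
    noiseless_body_sites: int = 50
    noiseless_promoter_sites: int = 20
    # RNA model (buffy-coat validation)
    rna_library_size: int = 2_000_000
    rna_dispersion: float = 0.2


@dataclass
class SimTruth:
    """Ground truth aligned with every emitted input."""

    config: SimConfig
    genes: list
    meta: pd.DataFrame
    survival: pd.DataFrame
    bulk_hmc: pd.DataFrame
    bulk_mc: pd.DataFrame
    buffy_hmc: pd.DataFrame
    buffy_mc: pd.DataFrame
    background_hmc: pd.DataFrame  # genes × {BL, TR}
    background_mc: pd.DataFrame
    gene_cn: pd.DataFrame
    cn_normal: pd.Series
    tumor_hmc: pd.DataFrame
    tumor_mc: pd.DataFrame
    true_z: pd.DataFrame  # baseline-standardized latent expression
    programs: dict
    arm_of_case: pd.Series  # "high_ccf" / "rapid" / "none"
    case_activity: pd.DataFrame
    ccf: pd.DataFrame
    clonotypes: pd.DataFrame
    rna_counts: pd.DataFrame
    regulator_sets: GeneSetCollection
    feature_block: pd.DataFrame


def forward_mix(tumor, background, purity, cn_tumor=2, cn_normal_chrom=2, modality="5hmC"):
    """Mix tumor and normal fractions into the observed bulk fraction.

    5hmC: bulk = p·tumor + (1−p)·background.  5mC additionally weights
    the two compartments by their effective copy numbers
    CN_T = p·cn_tumor and CN_N = (1−p)·cn_normal_chrom.  This is the
    exact algebraic inverse of the deconvolution equations.
    """
    tumor = np.asarray(tumor, dtype=float)
    background = np.asarray(background, dtype=float)
    p = np.asarray(purity, dtype=float)
    if modality == "5hmC":
        return p * tumor + (1.0 - p) * background
    cn_t = p * np.asarray(cn_tumor, dtype=float)
    cn_n = (1.0 - p) * np.asarray(cn_normal_chrom, dtype=float)
    total = cn_t + cn_n
    if np.any(total == 0):
        raise ValueError("CN_T + CN_N must be positive")
    return (tumor * cn_t + background * cn_n) / total


# ---------------------------------------------------------------------------
# matrix-level cohort
# ---------------------------------------------------------------------------

def _make_gene_models(cfg: SimConfig) -> list[GeneModel]:
    genes = []
    per_chrom = {c: 0 for c in CHROMS}
    for i in range(cfg.n_genes):
        chrom = CHROMS[i % len(CHROMS)]
        k = per_chrom[chrom]
        per_chrom[chrom] += 1
        start = 20000 + k * cfg.gene_spacing
        strand = "+" if (i // len(CHROMS)) % 2 == 0 else "-"
        genes.append(
            GeneModel(f"G{i:04d}", chrom, strand, start, start + cfg.gene_length)
        )
    return genes


def _standardize_baseline(mat: np.ndarray, baseline_cols: np.ndarray) -> np.ndarray:
    mu = mat[:, baseline_cols].mean(axis=1, keepdims=True)
    sd = mat[:, baseline_cols].std(axis=1, ddof=1, keepdims=True)
    return (mat - mu) / sd


def simulate_truth_matrices(config: SimConfig | None = None, seed: int | None = None) -> SimTruth:
    """Generate a full cohort at the gene-matrix level, with ground truth.

    All randomness flows from one generator seeded by ``seed`` (falling
    back to ``config.seed``); draws happen in a fixed documented order
    (genes → backgrounds → cases → latent expression → links → copy
    number → noise → survival → clones → clonotypes → RNA), so runs are
    bit-reproducible.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = _make_gene_models(cfg)
    gene_ids = [g.gene_id for g in genes]
    n_genes = cfg.n_genes

    # blood latent expression drives both the background methylome and RNA
    blood_latent = rng.normal(size=n_genes)
    bg_h_bl = 0.02 + 0.13 * expit(blood_latent)
    bg_m_bl = 0.85 - 0.55 * expit(blood_latent)  # expressed ⇒ hypomethylated promoter
    bg_h_tr = np.clip(bg_h_bl + rng.normal(0, 0.005, n_genes), 0.005, 0.995)
    bg_m_tr = np.clip(bg_m_bl + rng.normal(0, 0.005, n_genes), 0.005, 0.995)
    background_hmc = pd.DataFrame({"BL": bg_h_bl, "TR": bg_h_tr}, index=gene_ids)
    background_mc = pd.DataFrame({"BL": bg_m_bl, "TR": bg_m_tr}, index=gene_ids)

    # cases, arms, samples
    cases = [f"C{i:02d}" for i in range(1, cfg.n_cases + 1)]
    order = rng.permutation(cfg.n_cases)
    n_high = int(round(cfg.frac_high_ccf * cfg.n_cases))
    n_rapid = int(round(cfg.frac_rapid * cfg.n_cases))
    arm = pd.Series("none", index=cases, name="arm")
    arm.iloc[order[:n_high]] = "high_ccf"
    arm.iloc[order[n_high : n_high + n_rapid]] = "rapid"

    rows = []
    for c in cases:
        for tp, suffix in (("baseline", "BL"), ("restaging", "RS"), ("progression", "PG")):
            rows.append(
                {
                    "sample_id": f"{c}-{suffix}",
                    "case_id": c,
                    "timepoint": tp,
                    "source": "plasma",
                    "purity": rng.uniform(*cfg.purity_range),
                }
            )
    control_cases = cases[: cfg.n_controls_bl + cfg.n_controls_tr]
    for i, c in enumerate(control_cases):
        tp = "baseline" if i < cfg.n_controls_bl else "restaging"
        rows.append(
            {"sample_id": f"{c}-BC", "case_id": c, "timepoint": tp,
             "source": "buffycoat", "purity": 0.0}
        )
    meta = pd.DataFrame(rows)
    meta["timepoint_class"] = meta["timepoint"].map(
        {"baseline": "BL", "restaging": "TR", "progression": "TR"}
    )
    meta = meta.set_index("sample_id", drop=False)
    plasma = meta[meta["source"] == "plasma"]
    plasma_ids = list(plasma["sample_id"])
    is_baseline = (plasma["timepoint"] == "baseline").values
    exposed = (plasma["timepoint"] != "baseline").values
    progressing = (plasma["timepoint"] == "progression").values
    case_of = plasma["case_id"].values

    # latent tumor expression: program activity + gene-level noise;
    # program size shrinks for small test cohorts so programs never
    # swallow the whole gene panel
    program_size = min(cfg.program_size, max(2, n_genes // (cfg.n_programs + 1)))
    programs = {
        PROGRAM_NAMES[p]: gene_ids[p * program_size : (p + 1) * program_size]
        for p in range(cfg.n_programs)
    }
    activity = rng.normal(size=(cfg.n_cases, cfg.n_programs))
    case_activity = pd.DataFrame(activity, index=cases, columns=PROGRAM_NAMES)
    prog_of_gene = np.full(n_genes, -1)
    for p in range(cfg.n_programs):
        prog_of_gene[p * program_size : (p + 1) * program_size] = p
    eps = rng.normal(size=(n_genes, len(plasma_ids)))
    lam = cfg.program_loading
    resid = np.sqrt(1.0 - lam**2)
    case_idx = pd.Index(cases).get_indexer(case_of)
    act_per_sample = activity[case_idx, :]  # samples × programs
    G = eps.copy()
    for p in range(cfg.n_programs):
        gmask = prog_of_gene == p
        G[gmask, :] = lam * act_per_sample[:, p][None, :] + resid * eps[gmask, :]
    E = np.clip(_standardize_baseline(G, is_baseline), -cfg.latent_clip, cfg.latent_clip)
    # exposure program shifts at every treated timepoint; the two arm
    # programs displace asymmetrically in time — intrinsic resistance
    # (rapid) builds gradually from restaging, clonal remodeling
    # (high CCF) appears only at progression — mirroring their biology
    # and making the two arm directions identifiable in the latent map
    shift = np.zeros_like(E)
    shift[np.ix_(prog_of_gene == 0, np.where(exposed)[0])] += cfg.exposure_shift
    is_high = pd.Series(case_of).map(arm).eq("high_ccf").values
    is_rapid = pd.Series(case_of).map(arm).eq("rapid").values
    restaging = (plasma["timepoint"] == "restaging").values
    shift[np.ix_(prog_of_gene == 1, np.where(progressing & is_high)[0])] += cfg.arm_shift
    shift[np.ix_(prog_of_gene == 2, np.where(progressing & is_rapid)[0])] += cfg.arm_shift
    shift[np.ix_(prog_of_gene == 2, np.where(restaging & is_rapid)[0])] += cfg.arm_shift / 2.0
    E = E + shift
    true_z = pd.DataFrame(
        _standardize_baseline(E, is_baseline), index=gene_ids, columns=plasma_ids
    )

    # affine link to tumor-specific fractions
    a_h = rng.uniform(*cfg.link_intercept_range, n_genes)
    b_h = rng.uniform(*cfg.link_slope_range, n_genes)
    a_m = rng.uniform(*cfg.link_intercept_range, n_genes)
    b_m = rng.uniform(*cfg.link_slope_range, n_genes)
    tumor_hmc = a_h[:, None] + b_h[:, None] * E
    depleted = a_m[:, None] + b_m[:, None] * E
    tumor_mc = 1.0 - depleted

    # copy number (X/Y normal copy 1 for the all-male cohort)
    cn = rng.choice(cfg.cn_values, size=(n_genes, len(plasma_ids)), p=cfg.cn_probs)
    cn_normal = pd.Series(
        [1 if g.chrom in ("chrX", "chrY") else 2 for g in genes], index=gene_ids
    )

    purity = plasma["purity"].values
    cls = plasma["timepoint_class"].values
    bg_h = np.where(cls == "BL", 0, 1)
    bg_h_mat = background_hmc.values[:, bg_h]
    bg_m_mat = background_mc.values[:, bg_h]
    bulk_hmc = forward_mix(tumor_hmc, bg_h_mat, purity, modality="5hmC")
    bulk_mc = forward_mix(
        tumor_mc, bg_m_mat, purity, cn, cn_normal.values[:, None], modality="5mC"
    )
    if cfg.noise_sd > 0:
        bulk_hmc = np.clip(bulk_hmc + rng.normal(0, cfg.noise_sd, bulk_hmc.shape), 0, 1)
        bulk_mc = np.clip(bulk_mc + rng.normal(0, cfg.noise_sd, bulk_mc.shape), 0, 1)

    # buffy-coat control matrices around the class background
    buffy = meta[meta["source"] == "buffycoat"]
    buffy_ids = list(buffy["sample_id"])
    b_cls = np.where(buffy["timepoint_class"].values == "BL", 0, 1)
    buffy_h = background_hmc.values[:, b_cls]
    buffy_m = background_mc.values[:, b_cls]
    if cfg.buffy_noise_sd > 0:
        buffy_h = np.clip(buffy_h + rng.normal(0, cfg.buffy_noise_sd, buffy_h.shape), 0, 1)
        buffy_m = np.clip(buffy_m + rng.normal(0, cfg.buffy_noise_sd, buffy_m.shape), 0, 1)

    survival = simulate_survival(
        cfg, case_activity["survival"], arm.eq("rapid"), rng
    )
    ccf = _simulate_ccf(cfg, cases, arm, rng)
    clonotypes = _simulate_clonotypes(cfg, buffy, survival, rng)
    rna_counts = _simulate_rna(cfg, blood_latent, buffy_ids, rng)
    regulator_sets = _regulator_sets(programs, gene_ids, rng)
    features = _feature_block(cfg, plasma, arm, ccf, rng)

    return SimTruth(
        config=cfg,
        genes=genes,
        meta=meta,
        survival=survival,
        bulk_hmc=pd.DataFrame(bulk_hmc, index=gene_ids, columns=plasma_ids),
        bulk_mc=pd.DataFrame(bulk_mc, index=gene_ids, columns=plasma_ids),
        buffy_hmc=pd.DataFrame(buffy_h, index=gene_ids, columns=buffy_ids),
        buffy_mc=pd.DataFrame(buffy_m, index=gene_ids, columns=buffy_ids),
        background_hmc=background_hmc,
        background_mc=background_mc,
        gene_cn=pd.DataFrame(cn, index=gene_ids, columns=plasma_ids),
        cn_normal=cn_normal,
        tumor_hmc=pd.DataFrame(tumor_hmc, index=gene_ids, columns=plasma_ids),
        tumor_mc=pd.DataFrame(tumor_mc, index=gene_ids, columns=plasma_ids),
        true_z=true_z,
        programs=programs,
        arm_of_case=arm,
        case_activity=case_activity,
        ccf=ccf,
        clonotypes=clonotypes,
        rna_counts=rna_counts,
        regulator_sets=regulator_sets,
        feature_block=features,
    )


def simulate_survival(
    config: SimConfig, program_scores: pd.Series, rapid: pd.Series, rng
) -> pd.DataFrame:
    """Exponential proportional-hazards rPFS/OS linked to a program score.

    Non-rapid cases draw rPFS = 2.2 + Exp(scale·e^{−β·score}) months —
    hazard rises with the survival-program activity — with independent
    uniform censoring at the configured rate; rapid cases progress
    before 2 months by design.  OS scales off rPFS.
    """
    if config.censoring_rate >= 1.0:
        raise ValueError("censoring_rate 1.0 leaves no events")
    rows = []
    for case in program_scores.index:
        if bool(rapid.get(case, False)):
            t = rng.uniform(0.6, 1.9)
            event = True
        else:
            scale = config.base_scale_months * np.exp(
                -config.log_hazard_per_unit * float(program_scores[case])
            )
            t = 2.2 + rng.exponential(scale)
            event = True
            if rng.uniform() < config.censoring_rate:
                t = 2.2 + rng.uniform() * (t - 2.2)
                event = False
        os_t = t * rng.uniform(1.5, 3.0) + 2.0
        rows.append(
            {
                "case_id": case,
                "rpfs_months": float(t),
                "rpfs_event": event,
                "os_months": float(os_t),
                "os_event": bool(rng.uniform() < 0.8),
            }
        )
    return pd.DataFrame(rows).set_index("case_id", drop=False)


def null_cox_cohort(n_genes: int, n_samples: int, seed: int, censoring_rate: float = 0.2):
    """Gene Z matrix independent of survival, for type-I calibration.

    Returns (composite genes × samples DataFrame, survival DataFrame)
    where event times are exponential and unrelated to any gene.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    z = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=samples,
    )
    t = rng.exponential(6.0, n_samples)
    event = np.ones(n_samples, dtype=bool)
    cens = rng.uniform(size=n_samples) < censoring_rate
    t[cens] *= rng.uniform(size=cens.sum())
    event[cens] = False
    surv = pd.DataFrame(
        {
            "case_id": samples,
            "rpfs_months": t,
            "rpfs_event": event,
            "os_months": t,
            "os_event": event,
        }
    ).set_index("case_id", drop=False)
    return z, surv


def single_gene_hazard_cohort(n_samples: int, log2_hr: float, seed: int):
    """One gene whose Z multiplies the hazard by 2^log2_hr per unit.

    Event times are exponential with rate 0.1·2^{log2_hr·z}; light
    (15%) independent censoring.  Returns (z Series, survival frame).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    z = pd.Series(rng.normal(size=n_samples), index=samples)
    rate = 0.1 * np.power(2.0, log2_hr * z.values)
    t = rng.exponential(1.0 / rate)
    event = np.ones(n_samples, dtype=bool)
    cens = rng.uniform(size=n_samples) < 0.15
    t[cens] *= rng.uniform(size=cens.sum())
    event[cens] = False
    surv = pd.DataFrame(
        {
            "case_id": samples,
            "rpfs_months": t,
            "rpfs_event": event,
            "os_months": t,
            "os_event": event,
        }
    ).set_index("case_id", drop=False)
    return z, surv


def _simulate_ccf(cfg: SimConfig, cases, arm: pd.Series, rng) -> pd.DataFrame:
    rows = []
    for case in cases:
        base = rng.dirichlet(np.full(cfg.n_clones, 2.0))
        lo, hi = (
            cfg.high_shift_range if arm[case] == "high_ccf" else cfg.low_shift_range
        )
        transfer = rng.uniform(lo, hi)
        donor, recipient = int(np.argmax(base)), int(np.argmin(base))
        transfer = min(transfer, base[donor])
        prog = base.copy()
        prog[donor] -= transfer
        prog[recipient] += transfer
        mid = (base + prog) / 2.0
        for tp, vals in (("baseline", base), ("restaging", mid), ("progression", prog)):
            for k in range(cfg.n_clones):
                rows.append(
                    {"case_id": case, "clone_id": f"clone{k}", "timepoint": tp,
                     "ccf": float(vals[k])}
                )
    return pd.DataFrame(rows)


def _simulate_clonotypes(cfg: SimConfig, buffy: pd.DataFrame, survival, rng) -> pd.DataFrame:
    # repertoire evenness (hence Shannon index) increases with rPFS
    ranks = survival["rpfs_months"].rank(pct=True)
    rows = []
    for sid in buffy["sample_id"]:
        case = buffy.loc[sid, "case_id"]
        u = float(ranks.get(case, 0.5))
        for locus, ratio in (("TRA", 0.72 + 0.24 * u), ("TRB", 0.85)):
            weights = ratio ** np.arange(50)
            counts = np.maximum(1, rng.poisson(5000 * weights / weights.sum()))
            for k, n in enumerate(counts):
                rows.append(
                    {"sample_id": sid, "locus": locus,
                     "clonotype_id": f"{locus}_ct{k:03d}", "count": int(n)}
                )
    return pd.DataFrame(rows)


def _simulate_rna(cfg: SimConfig, blood_latent, buffy_ids, rng) -> pd.DataFrame:
    # expression monotone in the same blood latent that shapes the
    # background methylome, so RNA validates the epigenetic composite
    weights = np.exp(1.2 * blood_latent)
    mean = cfg.rna_library_size * weights / weights.sum()
    n_nb = 1.0 / cfg.rna_dispersion
    counts = {}
    for sid in buffy_ids:
        counts[sid] = rng.negative_binomial(n_nb, n_nb / (n_nb + mean))
    return pd.DataFrame(counts, index=[f"G{i:04d}" for i in range(cfg.n_genes)])


def _regulator_sets(programs: dict, gene_ids, rng) -> GeneSetCollection:
    sets = {}
    attrs = {}
    for name, genes in programs.items():
        reg = f"REG_{name.upper()}"
        sets[reg] = list(genes)
        attrs[reg] = {"activation": 2.2, "p": 0.004}
        half = f"REG_{name.upper()}_PARTIAL"
        sets[half] = list(genes[: len(genes) // 2])
        attrs[half] = {"activation": 1.8, "p": 0.02}
    null = list(rng.choice(gene_ids, size=min(30, max(2, len(gene_ids) // 4)), replace=False))
    sets["REG_NULL"] = null
    attrs["REG_NULL"] = {"activation": 0.4, "p": 0.6}
    return GeneSetCollection(sets, attrs)


def _feature_block(cfg: SimConfig, plasma: pd.DataFrame, arm, ccf, rng) -> pd.DataFrame:
    from .longitudinal_dynamics import ccf_shift

    ordinal = plasma["timepoint"].map({"baseline": 0, "restaging": 1, "progression": 2})
    shift_of = {c: ccf_shift(ccf, c) for c in plasma["case_id"].unique()}
    # the clonal-remodeling arm is the genomically driven one: its
    # instability metrics (SV count, percent genome altered) climb
    # faster over treatment, while intrinsic resistance stays
    # transcriptional; case-constant offsets cancel in within-case
    # deltas, so the arm signal is placed in the temporal part
    high = {c: arm[c] == "high_ccf" for c in shift_of}
    pga_case = {c: rng.uniform(0.05, 0.35) for c in shift_of}
    wgd_case = {c: float(rng.uniform() < 0.15) for c in shift_of}
    rows = {}
    for sid in plasma["sample_id"]:
        case = plasma.loc[sid, "case_id"]
        o = int(ordinal[sid])
        sv_extra = 4 * (o == 2) if high[case] else 0
        rows[sid] = {
            "ccf_shift_to_date": shift_of[case] * o / 2.0,
            "n_sv": float(rng.poisson(3 + 2 * o + sv_extra)),
            "pga": pga_case[case] + (0.03 + 0.07 * high[case]) * o,
            "wgd": wgd_case[case],
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# file-level cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig | None = None, out_dir=None, seed: int | None = None):
    """Emit the full cohort as files plus a manifest and truth tables.

    Per-CpG call files carry binomial counts at each region's target
    bulk fraction (exercising the depth and site filters); with
    ``noise_sd == 0`` counts are laid out deterministically so the
    pooled region fraction equals the emitted bulk value exactly, and
    the recorded truth is the realized (quantized) tumor fraction
    obtained by the generator's own inverse algebra.  Returns
    (manifest dict, SimTruth).
    """
    cfg = config or SimConfig()
    if out_dir is None:
        raise ValueError("out_dir is required")
    truth = simulate_truth_matrices(cfg, seed=seed)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 1])
    )
    noiseless = cfg.noise_sd == 0

    os.makedirs(out_dir, exist_ok=True)
    calls_dir = os.path.join(out_dir, "calls")
    seg_dir = os.path.join(out_dir, "segments")
    truth_dir = os.path.join(out_dir, "truth")
    for d in (calls_dir, seg_dir, truth_dir):
        os.makedirs(d, exist_ok=True)

    genes = truth.genes
    plasma_ids = list(truth.bulk_hmc.columns)
    buffy_ids = list(truth.buffy_hmc.columns)

    # per-sample region layouts are shared so samples are comparable
    if noiseless:
        body_sites = np.full(cfg.n_genes, cfg.noiseless_body_sites)
        prom_sites = np.full(cfg.n_genes, cfg.noiseless_promoter_sites)
    else:
        body_sites = rng.integers(*cfg.body_sites_range, cfg.n_genes, endpoint=True)
        prom_sites = rng.integers(*cfg.promoter_sites_range, cfg.n_genes, endpoint=True)

    files = []
    realized_bulk = {"5hmC": {}, "5mC": {}}
    for sid in plasma_ids + buffy_ids:
        if sid in truth.bulk_hmc.columns:
            hf, mf = truth.bulk_hmc[sid].values, truth.bulk_mc[sid].values
        else:
            hf, mf = truth.buffy_hmc[sid].values, truth.buffy_mc[sid].values
        calls, rh, rm = _emit_calls(cfg, genes, body_sites, prom_sites, hf, mf, rng, noiseless)
        realized_bulk["5hmC"][sid] = rh
        realized_bulk["5mC"][sid] = rm
        path = os.path.join(calls_dir, f"{sid}.tsv")
        write_cpg_calls(calls, path)
        files.append({"kind": "cpg_calls", "path": f"calls/{sid}.tsv"})

    for sid in plasma_ids:
        segs = _emit_segments(cfg, genes, truth.gene_cn[sid].values)
        write_segments(segs, os.path.join(seg_dir, f"{sid}.tsv"))
        files.append({"kind": "segments", "path": f"segments/{sid}.tsv"})

    write_sample_sheet(truth.meta, os.path.join(out_dir, "sample_sheet.tsv"))
    write_survival(truth.survival, os.path.join(out_dir, "survival.tsv"))
    write_gene_models_bed(genes, os.path.join(out_dir, "genes.bed"))
    write_ccf_table(truth.ccf, os.path.join(out_dir, "ccf.tsv"))
    write_clonotype_table(truth.clonotypes, os.path.join(out_dir, "clonotypes.tsv"))
    write_gene_matrix(truth.rna_counts, os.path.join(out_dir, "rna_counts.tsv"))
    write_gmt(truth.regulator_sets, os.path.join(out_dir, "regulators.gmt"))
    truth.feature_block.to_csv(os.path.join(out_dir, "features.tsv"), sep="\t")
    files += [
        {"kind": "sample_sheet", "path": "sample_sheet.tsv"},
        {"kind": "survival", "path": "survival.tsv"},
        {"kind": "gene_models", "path": "genes.bed"},
        {"kind": "ccf", "path": "ccf.tsv"},
        {"kind": "clonotypes", "path": "clonotypes.tsv"},
        {"kind": "rna_counts", "path": "rna_counts.tsv"},
        {"kind": "gmt", "path": "regulators.gmt"},
    ]

    if noiseless:
        # truth = realized quantized values, inverted by generator algebra
        gene_ids = [g.gene_id for g in genes]
        rb_h = pd.DataFrame(
            {s: realized_bulk["5hmC"][s] for s in plasma_ids}, index=gene_ids
        )
        rb_m = pd.DataFrame(
            {s: realized_bulk["5mC"][s] for s in plasma_ids}, index=gene_ids
        )
        buffy_h = pd.DataFrame(
            {s: realized_bulk["5hmC"][s] for s in buffy_ids}, index=gene_ids
        )
        buffy_m = pd.DataFrame(
            {s: realized_bulk["5mC"][s] for s in buffy_ids}, index=gene_ids
        )
        bmeta = truth.meta.loc[buffy_ids]
        cls_cols = {
            "BL": bmeta.index[bmeta["timepoint_class"] == "BL"],
            "TR": bmeta.index[bmeta["timepoint_class"] == "TR"],
        }
        # mirror the pipeline's all-control fallback for an empty class
        cls_cols = {c: ids if len(ids) else bmeta.index for c, ids in cls_cols.items()}
        bg_h = pd.DataFrame({c: buffy_h[ids].mean(axis=1) for c, ids in cls_cols.items()})
        bg_m = pd.DataFrame({c: buffy_m[ids].mean(axis=1) for c, ids in cls_cols.items()})
        purity = truth.meta.loc[plasma_ids, "purity"].values
        cls = truth.meta.loc[plasma_ids, "timepoint_class"].values
        idx = np.where(cls == "BL", 0, 1)
        t_h = (rb_h.values - (1 - purity) * bg_h.values[:, idx]) / purity
        cn_t = purity * truth.gene_cn.values
        cn_n = (1 - purity) * truth.cn_normal.values[:, None]
        t_m = (rb_m.values * (cn_t + cn_n) - bg_m.values[:, idx] * cn_n) / cn_t
        truth.bulk_hmc, truth.bulk_mc = rb_h, rb_m
        truth.buffy_hmc, truth.buffy_mc = buffy_h, buffy_m
        truth.tumor_hmc = pd.DataFrame(t_h, index=gene_ids, columns=plasma_ids)
        truth.tumor_mc = pd.DataFrame(t_m, index=gene_ids, columns=plasma_ids)
        base_cols = (truth.meta.loc[plasma_ids, "timepoint"] == "baseline").values
        comp = (
            _standardize_baseline(1.0 - t_m, base_cols)
            + _standardize_baseline(t_h, base_cols)
        ) / 2.0
        truth.true_z = pd.DataFrame(comp, index=gene_ids, columns=plasma_ids)

    for name, mat in (
        ("true_z", truth.true_z),
        ("tumor_5hmC", truth.tumor_hmc),
        ("tumor_5mC", truth.tumor_mc),
    ):
        write_gene_matrix(mat, os.path.join(truth_dir, f"{name}.tsv"))
    truth.arm_of_case.to_frame().to_csv(os.path.join(truth_dir, "arms.tsv"), sep="\t")

    manifest = {"seed": int(cfg.seed if seed is None else seed), "files": files,
                "config": {k: v for k, v in asdict(cfg).items()}}
    with open(os.path.join(out_dir, "MANIFEST.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest, truth


def _emit_calls(cfg, genes, body_sites, prom_sites, hmc_frac, mc_frac, rng, noiseless):
    """Per-CpG calls for one sample; returns (table, realized fractions).

    The promoter window (−1 kb/+5 kb of the TSS) inherently overlaps the
    gene body, and the aggregator pools every site inside an interval,
    so the realized region fractions are computed here with the same
    interval rule over the emitted sites (body sites sit at odd
    positions, promoter sites at even positions, so the two ladders
    never collide).
    """
    from .signal_aggregation import promoter_window

    chroms, positions, depths, n_h, n_m = [], [], [], [], []
    realized_h = np.empty(len(genes))
    realized_m = np.empty(len(genes))
    for i, g in enumerate(genes):
        # gene body: 5hmC is the aggregated signal, 5mC a filler
        ph = float(hmc_frac[i])
        pos_b = np.linspace(g.start + 50, g.end - 50, body_sites[i]).astype(int)
        pos_b = pos_b - (pos_b % 2) + 1  # odd ladder
        d_b, c_bh, c_bm = _region_counts(cfg, body_sites[i], ph, 0.6 * (1 - ph), rng, noiseless)
        plo, phi = promoter_window(g)
        pm = float(mc_frac[i])
        pos_p = np.linspace(plo + 10, phi - 10, prom_sites[i]).astype(int)
        pos_p = pos_p - (pos_p % 2)  # even ladder
        d_p, c_pm, c_ph = _region_counts(cfg, prom_sites[i], pm, 0.08 * (1 - pm), rng, noiseless)

        # realized fractions pool every emitted site inside each region,
        # after the pipeline's per-site depth filter
        keep_b = d_b >= 3
        keep_p = d_p >= 3
        in_body = keep_p & (pos_p >= g.start) & (pos_p < g.end)
        in_prom = keep_b & (pos_b >= plo) & (pos_b < phi)
        realized_h[i] = (c_bh[keep_b].sum() + c_ph[in_body].sum()) / (
            d_b[keep_b].sum() + d_p[in_body].sum()
        )
        realized_m[i] = (c_pm[keep_p].sum() + c_bm[in_prom].sum()) / (
            d_p[keep_p].sum() + d_b[in_prom].sum()
        )
        chroms += [g.chrom] * (body_sites[i] + prom_sites[i])
        positions += [pos_b, pos_p]
        depths += [d_b, d_p]
        n_h += [c_bh, c_ph]
        n_m += [c_bm, c_pm]
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.concatenate(positions),
            "depth": np.concatenate(depths),
            "n_5mC": np.concatenate(n_m),
            "n_5hmC": np.concatenate(n_h),
        }
    )
    return df.reset_index(drop=True), realized_h, realized_m


def _region_counts(cfg, n_sites, p_primary, p_filler, rng, noiseless):
    """Depths plus primary/filler modification counts for one region."""
    if noiseless:
        d = np.full(n_sites, cfg.noiseless_depth)
        total = int(round(p_primary * d.sum()))
        base, extra = divmod(total, n_sites)
        primary = np.full(n_sites, base)
        primary[:extra] += 1
        filler = np.minimum(
            np.round(p_filler * d).astype(int), d - primary
        )
        return d, primary, filler
    d = rng.integers(*cfg.site_depth_range, n_sites, endpoint=True)
    rest = max(1.0 - p_primary - p_filler, 0.0)
    probs = np.array([p_primary, p_filler, rest])
    probs = probs / probs.sum()
    draws = rng.multinomial(d, probs)
    return d, draws[:, 0], draws[:, 1]


def _emit_segments(cfg, genes, cn_values) -> pd.DataFrame:
    """One segment per gene carrying its tumor copy number."""
    rows = []
    half_gap = cfg.gene_spacing // 2 - cfg.gene_length
    for g, cn in zip(genes, cn_values):
        rows.append(
            {
                "chrom": g.chrom,
                "start": max(g.start - 6000, 0),
                "end": g.end + half_gap,
                "cn_tumor": int(cn),
            }
        )
    return pd.DataFrame(rows)
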