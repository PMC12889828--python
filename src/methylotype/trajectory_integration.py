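"""Latent-space integration of regulator programs and genomic features.

Upstream-regulator target sets (externally derived, with activation Z
and overlap p attributes) are projected onto the baseline-anchored
geneZ matrix as mean-target scores per sample.  The regulator-score
blocks and a per-sample genomic feature block are integrated by a
multiblock sparse PLS with the ordinal timepoint
(baseline/restaging/progression → 0/1/2) as the response, producing a
shared 2-D latent map of coordinated temporal variation.  Resistance
"arms" are summarized geometrically: a unit vector from the baseline
centroid to the progression centroid of each arm's cases, per-sample
projections onto each arm, and per-case progression-minus-baseline arm
deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_inference import GeneZMatrix
from .io_formats import GeneSetCollection


def filter_sv_records(
    sv: pd.DataFrame, min_taf: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep structural variants with tumor allele frequency above min_taf.

    TAF = supporting fragments / total fragments; the threshold is
    strict (a record at exactly min_taf is dropped).  Records with zero
    total fragments are dropped with a warning.  Returns the filtered
    table and per-sample, per-type counts.
    """
    sv = sv.copy()
    zero = sv["total"] <= 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} SV record(s) with zero total fragments")
        sv = sv[~zero]
    kept = sv[sv["supporting"] / sv["total"] > min_taf].reset_index(drop=True)
    counts = (
        kept.groupby(["sample_id", "sv_type"]).size().unstack(fill_value=0)
        if len(kept)
        else pd.DataFrame()
    )
    return kept, counts


def regulator_scores(
    z: GeneZMatrix,
    regulators: GeneSetCollection,
    min_targets: int = 5,
    min_activation: float = 1.5,
    max_p: float = 0.05,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Mean target-gene composite Z per sample for each regulator.

    Regulator sets carrying activation/p attributes are filtered to
    |activation| > ``min_activation`` and p < ``max_p`` unless
    ``prefiltered``.  A regulator with fewer than ``min_targets`` target
    genes present in the matrix scores NaN.  Rows are samples, columns
    regulators.
    """
    if not prefiltered and any(
        "activation" in a for a in regulators.attrs.values()
    ):
        regulators = regulators.filtered(min_activation, max_p)
    if len(regulators) == 0:
        raise ValueError("no regulator sets left after activation/p filtering")
    present_index = set(z.composite.index)
    cols = {}
    for name, targets in regulators.sets.items():
        present = [g for g in targets if g in present_index]
        if len(present) < min_targets:
            cols[name] = pd.Series(np.nan, index=z.composite.columns)
        else:
            cols[name] = z.composite.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# multiblock sparse PLS
# ---------------------------------------------------------------------------

TIMEPOINT_ORDINAL = {"baseline": 0.0, "restaging": 1.0, "progression": 2.0}


@dataclass
class LatentEmbedding:
    """2-D consensus coordinates with per-block weights and scores."""

    coords: pd.DataFrame  # samples × 2 (consensus = mean of block scores)
    block_scores: dict
    loadings: dict  # per block: features × 2 weight vectors
    response: pd.Series
    imputed: dict  # per block: count of mean-imputed cells


def multiblock_spls(
    blocks: dict[str, pd.DataFrame],
    response: pd.Series,
    ncomp: int = 2,
    keep: dict[str, int] | None = None,
    seed: int = 0,
    response_encoding: str = "ordinal",
    design_weight: float = 0.1,
) -> LatentEmbedding:
    """Multiblock sparse PLS with a shared response, 2 components.

    Per component, block weight vectors are iterated to a fixed point
    that maximizes the summed covariances of each block score with the
    response and with every other block score (fully connected design,
    horst scheme); block-block edges carry ``design_weight`` (default
    0.1, the response-focused design recommended for DIABLO-style
    integrations) relative to the response edges.  Per-sample consensus
    coordinates are the unweighted mean of block scores, and both the
    blocks (on their own scores) and the response (on the consensus
    score) are deflated between components.  Features are centered and unit-variance scaled per
    block; missing cells are mean-imputed (counted in ``imputed``).
    ``keep`` optionally retains only the top-k |weight| features per
    block (sparse variant); the default keeps all.  Deterministic for a
    fixed seed and input ordering.

    ``response_encoding`` "ordinal" uses the numeric 0/1/2 timepoint
    column; "indicator" uses the dominant axis of the timepoint dummy
    matrix.
    """
    if len(blocks) < 2:
        raise ValueError("need ≥2 blocks")
    samples = response.index
    rng = np.random.default_rng(seed)  # reserved for stochastic variants
    del rng

    X = {}
    imputed = {}
    feat_names = {}
    for name, df in blocks.items():
        df = df.reindex(samples)
        if df.isna().all(axis=0).any():
            df = df.loc[:, ~df.isna().all(axis=0)]
        imputed[name] = int(df.isna().sum().sum())
        arr = df.to_numpy(dtype=float)
        col_mean = np.nanmean(arr, axis=0)
        idx = np.where(np.isnan(arr))
        arr[idx] = np.take(col_mean, idx[1])
        sd = arr.std(axis=0, ddof=1)
        keep_cols = sd > 0
        if not keep_cols.any():
            raise ValueError(f"block {name!r} has only zero-variance features")
        arr = (arr[:, keep_cols] - arr[:, keep_cols].mean(axis=0)) / sd[keep_cols]
        X[name] = arr
        feat_names[name] = list(df.columns[keep_cols])

    if response_encoding == "ordinal":
        y = response.map(TIMEPOINT_ORDINAL).to_numpy(dtype=float)
        if np.isnan(y).any():
            y = response.to_numpy(dtype=float)
        Y = (y - y.mean())[:, None]
    elif response_encoding == "indicator":
        dummies = pd.get_dummies(response).to_numpy(dtype=float)
        Y = dummies - dummies.mean(axis=0)
    else:
        raise ValueError("response_encoding must be 'ordinal' or 'indicator'")

    n = len(samples)
    names = list(X)
    coords = np.zeros((n, ncomp))
    block_scores = {b: np.zeros((n, ncomp)) for b in X}
    weights = {b: np.zeros((X[b].shape[1], ncomp)) for b in X}

    def _sparsify(w, name):
        if keep and keep.get(name):
            k = int(keep[name])
            if k < len(w):
                cutoff = np.sort(np.abs(w))[-k]
                w = np.where(np.abs(w) >= cutoff, w, 0.0)
        norm = np.linalg.norm(w)
        return w / norm if norm > 0 else w

    Yres = Y.copy()
    for h in range(ncomp):
        # fully connected design: every data block couples to every other
        # block and to the response; iterate covariance maximization
        # (horst scheme) to a fixed point, then deflate
        if Yres.shape[1] == 1:
            u = Yres[:, 0].copy()
        else:
            u = np.linalg.svd(Yres, full_matrices=False)[0][:, 0]
        if np.allclose(u, 0):
            u = np.ones(n)
        w = {b: _sparsify(X[b].T @ u, b) for b in names}
        t = {b: X[b] @ w[b] for b in names}
        for _ in range(200):
            q = Yres.T @ sum(t[b] for b in names)
            qn = np.linalg.norm(q)
            u = Yres @ (q / qn) if qn > 0 else u
            w_new = {}
            for b in names:
                inner = u + design_weight * sum(t[b2] for b2 in names if b2 != b)
                w_new[b] = _sparsify(X[b].T @ inner, b)
            delta = max(np.linalg.norm(w_new[b] - w[b]) for b in names)
            w = w_new
            t = {b: X[b] @ w[b] for b in names}
            if delta < 1e-10:
                break
        t_cons = np.mean([t[b] for b in names], axis=0)
        coords[:, h] = t_cons
        for b in names:
            weights[b][:, h] = w[b]
            block_scores[b][:, h] = t[b]
        # deflate blocks on their own scores, response on the consensus
        for b in names:
            tb = t[b]
            denom = tb @ tb
            if denom > 0:
                X[b] = X[b] - np.outer(tb, (tb @ X[b]) / denom)
        denom = t_cons @ t_cons
        if denom > 0:
            Yres = Yres - np.outer(t_cons, (t_cons @ Yres) / denom)

    comp_names = [f"comp{i+1}" for i in range(ncomp)]
    return LatentEmbedding(
        coords=pd.DataFrame(coords, index=samples, columns=comp_names),
        block_scores={
            b: pd.DataFrame(s, index=samples, columns=comp_names)
            for b, s in block_scores.items()
        },
        loadings={
            b: pd.DataFrame(weights[b], index=feat_names[b], columns=comp_names)
            for b in X
        },
        response=response,
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# arm geometry
# ---------------------------------------------------------------------------

@dataclass
class ArmGeometry:
    """Baseline centroid, unit arm directions, arm scores and deltas."""

    baseline_centroid: np.ndarray
    directions: pd.DataFrame  # arms × 2 unit vectors
    sample_scores: pd.DataFrame  # samples × arms
    case_deltas: pd.DataFrame  # cases × arms (progression − baseline)


def arm_geometry(
    embedding: LatentEmbedding, meta: pd.DataFrame, labels: pd.DataFrame
) -> ArmGeometry:
    """Arm vectors from the baseline centroid to arm progression centroids.

    Arms are the boolean label columns of ``labels`` (``high_ccf``,
    ``rapid``); a case carrying both labels contributes to both
    centroids (the axes are non-mutually exclusive).  Sample arm score =
    (coords − baseline centroid) · unit arm vector; case arm delta =
    progression score − baseline score.
    """
    coords = embedding.coords
    samples = coords.index
    tp = meta.loc[samples, "timepoint"]
    case = meta.loc[samples, "case_id"]
    base_mask = (tp == "baseline").values
    if not base_mask.any():
        raise ValueError("no baseline samples in the embedding")
    b = coords.values[base_mask].mean(axis=0)

    arm_cols = [c for c in ("high_ccf", "rapid") if c in labels.columns]
    directions = {}
    for arm in arm_cols:
        arm_cases = set(labels.index[labels[arm].astype(bool)])
        mask = (tp == "progression").values & case.isin(arm_cases).values
        if not mask.any():
            raise ValueError(f"arm {arm!r} has no progression samples")
        centroid = coords.values[mask].mean(axis=0)
        vec = centroid - b
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError(f"arm {arm!r} centroid coincides with the baseline centroid")
        directions[arm] = vec / norm
    dir_df = pd.DataFrame(directions, index=coords.columns).T

    centered = coords.values - b
    scores = pd.DataFrame(
        {arm: centered @ dir_df.loc[arm].values for arm in arm_cols}, index=samples
    )
    deltas = {}
    for c in case.unique():
        b_ids = samples[(case == c).values & (tp == "baseline").values]
        p_ids = samples[(case == c).values & (tp == "progression").values]
        if len(b_ids) and len(p_ids):
            deltas[c] = scores.loc[p_ids].mean(axis=0) - scores.loc[b_ids].mean(axis=0)
    return ArmGeometry(
        baseline_centroid=b,
        directions=dir_df,
        sample_scores=scores,
        case_deltas=pd.DataFrame(deltas).T,
    )
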