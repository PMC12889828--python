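import numpy as np
import pandas as pd
import pytest

import methylotype as mt


@pytest.fixture(scope="session")
def truth():
    """Default synthetic cohort (study-condition defaults, fixed seed)."""
    return mt.simulate_truth_matrices(mt.SimConfig())


@pytest.fixture(scope="session")
def pipeline(truth):
    """Deconvolution → anchors → baseline-anchored Z on the default cohort."""
    meta = truth.meta
    bg = mt.background_profile(truth.buffy_hmc, truth.buffy_mc, meta)
    decon = mt.deconvolve_cohort(
        truth.bulk_hmc, truth.bulk_mc, bg, meta, truth.gene_cn, truth.cn_normal
    )
    stats = mt.baseline_stats(decon, meta)
    z = mt.anchored_scores(decon, stats, meta)
    return {"meta": meta, "background": bg, "decon": decon, "stats": stats, "z": z}


@pytest.fixture(scope="session")
def noiseless():
    """Noise-free cohort: the pipeline is an exact inverse of the generator."""
    cfg = mt.SimConfig(seed=5, noise_sd=0.0, buffy_noise_sd=0.0)
    truth = mt.simulate_truth_matrices(cfg)
    meta = truth.meta
    bg = mt.background_profile(truth.buffy_hmc, truth.buffy_mc, meta)
    decon = mt.deconvolve_cohort(
        truth.bulk_hmc, truth.bulk_mc, bg, meta, truth.gene_cn, truth.cn_normal
    )
    z = mt.anchored_scores(decon, mt.baseline_stats(decon, meta), meta)
    return {"truth": truth, "meta": meta, "decon": decon, "z": z}


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Small file-level cohort emitted to disk (with CpG-level noise)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = mt.SimConfig(seed=8, n_genes=48, n_cases=6)
    manifest, truth = mt.simulate_cohort(cfg, out_dir=str(out))
    return {"dir": str(out), "manifest": manifest, "truth": truth}


@pytest.fixture
def toy_meta():
    rows = [
        ("P1-BL", "P1", "baseline", "plasma", 0.5),
        ("P1-PG", "P1", "progression", "plasma", 0.4),
        ("P2-BL", "P2", "baseline", "plasma", 0.3),
        ("P2-PG", "P2", "progression", "plasma", 0.6),
        ("B1", "P1", "baseline", "buffycoat", 0.0),
        ("B2", "P2", "restaging", "buffycoat", 0.0),
    ]
    meta = pd.DataFrame(
        rows, columns=["sample_id", "case_id", "timepoint", "source", "purity"]
    )
    meta["timepoint_class"] = meta["timepoint"].map(
        {"baseline": "BL", "restaging": "TR", "progression": "TR"}
    )
    return meta.set_index("sample_id", drop=False)
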