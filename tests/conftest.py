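import numpy as np
import pandas as pd
import pytest

import giscan as g


@pytest.fixture(scope="session")
def panel():
    return g.load_gene_panel()


def build_profile(
    gc: np.ndarray,
    depth: np.ndarray,
    sample_id: str = "s",
    kind: str = "bin",
    bin_size: int = 100_000,
) -> g.DepthProfile:
    n = len(gc)
    feats = pd.DataFrame({
        "feature_id": [f"f{i}" for i in range(n)],
        "kind": kind,
        "chrom": "chr1",
        "start": np.arange(n) * bin_size,
        "end": (np.arange(n) + 1) * bin_size,
        "gc": np.asarray(gc, float),
        "raw_depth": np.asarray(depth, float),
        "norm_depth": np.nan,
        "flag": False,
    })
    return g.DepthProfile(sample_id=sample_id, features=feats)


@pytest.fixture
def profile_factory():
    return build_profile


@pytest.fixture(scope="session")
def mini_cohort(panel):
    """Small but realistic simulated cohort shared across tests (1 Mb bins)."""
    cfg = g.SimConfig(seed=43, bin_size=1_000_000, n_controls=10, n_patients=12,
                      tumor_fraction=0.5)
    return g.simulate_cohort(cfg, panel)


@pytest.fixture(scope="session")
def mini_scored(mini_cohort, panel):
    ncfg = g.NormalizationConfig()
    controls = [g.loess_gc_normalize(p, ncfg) for p in mini_cohort.controls]
    ref = g.build_reference(controls)
    patients = [g.loess_gc_normalize(p, ncfg) for p in mini_cohort.patients]
    zps = [g.zscore(p, ref) for p in patients]
    return {"ref": ref, "controls": controls, "patients": patients, "zprofiles": zps}


def table1_records() -> list[g.ClinicalRecord]:
    """40 clinical records matching the study cohort's printed composition."""
    stages = ["I"] * 9 + ["II"] * 2 + ["III"] * 26 + ["IV"] * 3
    hists = (["HGSC"] * 23 + ["LGSC"] * 3 + ["mucinous"] * 5
             + ["endometrioid"] * 4 + ["clear_cell"] * 5)
    brca = ["pathogenic"] * 6 + ["wild_type"] * 34
    recur = [1] * 20 + [0] * 20
    recs = []
    for i in range(40):
        dfs = 11.0 if recur[i] else 50.0
        recs.append(g.ClinicalRecord(
            patient_id=f"P{i:02d}", ca125=575.5, figo_stage=stages[i],
            histology=hists[i], dfs_months=dfs, dfs_event=recur[i],
            os_months=50.0, os_event=0, brca_status=brca[i]))
    return recs
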