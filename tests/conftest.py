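"""Shared fixtures: simulated study designs processed through the pipeline.

Session-scoped so the heavier simulations (QA + selection on the full
curve design) run once for the whole suite.
"""

import numpy as np
import pandas as pd
import pytest

import lipocurve as lc


@pytest.fixture(scope="session")
def cd3():
    """The 6-count x 5-replicate curve fixture (70 cell + 1000 background
    signals, noise CV 0.10) carried through batch correction, QA and
    widest-interval selection."""
    cfg = lc.SimConfig.cd3_curve(seed=0)
    matrix, samples, truth = lc.simulate_cell_curve(cfg)
    corrected, _ = lc.interbatch_qc_median(matrix, samples)
    qa_matrix, report = lc.run_qa(corrected, samples)
    selection = lc.select_correlated(
        qa_matrix, samples, lc.widest_interval(samples)
    )
    return {
        "cfg": cfg,
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "qa_matrix": qa_matrix,
        "report": report,
        "selection": selection,
    }


@pytest.fixture(scope="session")
def hmvec():
    """The 4-count curve + paired acute/baseline experiment fixture
    (200 cell signals, 20 with a planted 3-fold time effect, 8 subjects
    per group)."""
    cfg = lc.SimConfig.hmvec_experiment(seed=0)
    matrix, samples, truth = lc.simulate_experiment(cfg)
    corrected, _ = lc.interbatch_qc_median(matrix, samples)
    qa_matrix, report = lc.run_qa(corrected, samples)
    selection = lc.select_correlated(
        qa_matrix, samples, lc.widest_interval(samples)
    )
    return {
        "cfg": cfg,
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "qa_matrix": qa_matrix,
        "report": report,
        "selection": selection,
    }


@pytest.fixture(scope="session")
def balanced_design():
    """3 groups x 8 subjects, each paired across acute/baseline."""
    rows = [
        {"subject": f"{g}S{i:02d}", "timepoint": tp, "group": g}
        for g in ("IgE", "COX", "MRGPRX2")
        for i in range(8)
        for tp in ("baseline", "acute")
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def qa_toy():
    """Hand-computable 4-signal QA toy.

    A passes every stage; B fails the blank rule (all condition means below
    the blank mean); C is detected in only 2 of 4 QCs; D has QC CV ~0.41.
    """
    samples = lc.samples_to_frame([
        lc.SampleInfo("blank1", "blank", 1),
        lc.SampleInfo("blank2", "blank", 2),
        lc.SampleInfo("qc1", "qc", 3),
        lc.SampleInfo("c100_r1", "curve", 4, cell_count=100),
        lc.SampleInfo("c100_r2", "curve", 5, cell_count=100),
        lc.SampleInfo("qc2", "qc", 6),
        lc.SampleInfo("c200_r1", "curve", 7, cell_count=200),
        lc.SampleInfo("c200_r2", "curve", 8, cell_count=200),
        lc.SampleInfo("qc3", "qc", 9),
        lc.SampleInfo("qc4", "qc", 10),
    ])
    cols = ["blank1", "blank2", "qc1", "c100_r1", "c100_r2", "qc2",
            "c200_r1", "c200_r2", "qc3", "qc4"]
    data = {
        # blank mean 10; condition means 100 and 200; QC CV 0
        "A": [10, 10, 100, 95, 105, 100, 195, 205, 100, 100],
        # blank mean 100; condition means 50 and 80: fails any_condition
        "B": [100, 100, 70, 45, 55, 70, 75, 85, 70, 70],
        # detected in 2/4 QCs only
        "C": [10, 10, np.nan, 100, 110, np.nan, 120, 130, 95, 105],
        # QC values (50, 100, 100, 150): CV = 40.82/100 > 0.30
        "D": [10, 10, 50, 100, 110, 100, 120, 130, 100, 150],
    }
    abundance = pd.DataFrame(data, index=cols).T
    return lc.FeatureMatrix(abundance), samples
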