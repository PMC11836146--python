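"""Shared fixtures: one full synthetic study ensemble per test session.

The ensemble reproduces the study conditions: 17 helmets x 3 impact
locations on the canonical 600-sample/30 ms grid, with FE-like strain
fields over a 2000-element mesh.
"""

import numpy as np
import pandas as pd
import pytest

from helmstrain import headmetrics, kinio, synthio, tractstrain

SESSION_SEED = 1


def make_record(t_ms=None, lin=None, ang=None, ang_acc=None,
                helmet="HelmetA", location="XRot"):
    """Build a KinematicsRecord from per-axis arrays (zeros by default)."""
    if t_ms is None:
        t_ms = kinio.canonical_grid()
    n = len(t_ms)
    zeros = np.zeros((n, 3))
    rec = kinio.KinematicsRecord(
        helmet_id=helmet, location=location, t=np.asarray(t_ms, float),
        lin_acc=zeros.copy() if lin is None else np.asarray(lin, float),
        ang_vel=zeros.copy() if ang is None else np.asarray(ang, float),
        ang_acc=None if ang_acc is None else np.asarray(ang_acc, float),
    )
    return rec


@pytest.fixture(scope="session")
def gen_config():
    return synthio.GeneratorConfig(seed=SESSION_SEED, n_elements=2000)


@pytest.fixture(scope="session")
def kin_ensemble(gen_config):
    return synthio.generate_kinematics_ensemble(gen_config)


@pytest.fixture(scope="session")
def prepared_ensemble(kin_ensemble):
    return {key: kinio.prepare_record(rec) for key, rec in kin_ensemble.items()}


@pytest.fixture(scope="session")
def strain_results(gen_config, kin_ensemble):
    """Per-impact strain peak tables and percentile summaries."""
    tables = {}
    summaries = {}
    for key, fields in synthio.iter_strain_ensemble(gen_config, kin_ensemble):
        tab = tractstrain.compute_peak_table(
            fields["F"], fields["regions"], fields["fibers"],
            fields["element_ids"])
        tables[key] = tab
        summaries[key] = tractstrain.summarize_peaks(tab)
    summary_df = pd.DataFrame(summaries).T
    summary_df.index.names = ["helmet_id", "location"]
    return {"tables": tables, "summaries": summary_df}


@pytest.fixture(scope="session")
def metric_df(prepared_ensemble, strain_results):
    """Full 51-row table: 7 kinematic metrics + 5 strain summaries."""
    kin_table = headmetrics.metric_table(prepared_ensemble.values())
    return kin_table.join(strain_results["summaries"])
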