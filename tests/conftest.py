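import numpy as np
import pandas as pd
import pytest

from metabocorr import FeatureTable, SampleManifest, SyntheticConfig, generate_study


def make_manifest(groups_orders, study_id=1, ion_mode="positive"):
    """Build a manifest from [(sample_id, group, injection_order), ...]."""
    ids = [g[0] for g in groups_orders]
    return SampleManifest(pd.DataFrame({
        "study_id": study_id,
        "group": [g[1] for g in groups_orders],
        "injection_order": [g[2] for g in groups_orders],
        "ion_mode": ion_mode,
    }, index=pd.Index(ids, name="sample_id")))


def make_table(intensities, manifest, mz=None, rt=None, ion_mode="positive"):
    """Build a FeatureTable from a (feature x sample) DataFrame."""
    n = len(intensities)
    features = pd.DataFrame({
        "mz": mz if mz is not None else np.linspace(100, 500, n),
        "rt": rt if rt is not None else np.linspace(60, 600, n),
        "ion_mode": ion_mode,
    }, index=intensities.index)
    return FeatureTable(features, intensities, manifest)


@pytest.fixture
def small_config():
    """Fast two-study config with effects and one reversal block."""
    return SyntheticConfig(
        n_metabolites=24, n_differential=6, n_reversal_blocks=1, block_size=5,
        seed=11,
    )


@pytest.fixture
def small_study(small_config):
    return generate_study(small_config, 2)


@pytest.fixture
def qc_manifest():
    """One run: 10 leading QCs, 8 biological in blocks of 4, 2 trailing QCs."""
    rows = []
    order = 1
    for i in range(10):
        rows.append((f"QC{i + 1:02d}", "QC", order)); order += 1
    bio = [("ND_UT", 4), ("DM_UT", 4)]
    qn = 11
    k = 0
    for group, n in bio:
        for j in range(n):
            rows.append((f"{group}_{j + 1}", group, order)); order += 1
            k += 1
            if k % 4 == 0:
                rows.append((f"QC{qn:02d}", "QC", order)); order += 1; qn += 1
    # last appended QC doubles as run-interior; add two final QCs
    rows.append((f"QC{qn:02d}", "QC", order)); order += 1; qn += 1
    rows.append((f"QC{qn:02d}", "QC", order))
    return make_manifest(rows)
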