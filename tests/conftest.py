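import numpy as np
import pandas as pd
import pytest

from strainsweep import synthetic
from strainsweep.read_clouds import ReadCloudSet


@pytest.fixture
def rng():
    return np.random.default_rng(20211)


def make_cloud_set(rows):
    """Build a ReadCloudSet from (timepoint, barcode, species, contig, pos,
    allele[, snv_id, gene]) tuples."""
    cols = ["timepoint", "barcode", "species", "contig", "pos", "allele", "snv_id", "gene"]
    padded = [tuple(r) + (-1, "")[len(r) - 6 :] if len(r) < 8 else tuple(r) for r in rows]
    return ReadCloudSet(pd.DataFrame(padded, columns=cols))


@pytest.fixture
def impure_community():
    """Small community + two-strain panel + impure read clouds with ground truth."""
    cfg = synthetic.CommunityConfig(
        n_species=8, timepoints=[0.0, 7.0, 14.0], abundance_sigma=0.4,
        noise_sigma=0.05, seed=5,
    )
    community = synthetic.simulate_community(cfg)
    focal = community.iloc[:, 0].idxmax()
    panel_cfg = synthetic.StrainPanelConfig(n_snvs=20, strain_divergence=1e-3)
    panel = synthetic.simulate_strain_panel(panel_cfg, seed=6, species=focal)
    cloud_cfg = synthetic.CloudConfig(n_clouds=600, mean_fragments=6.0,
                                      reads_per_fragment=6.0)
    strain2 = pd.DataFrame([[0.5, 0.5, 0.5]], index=[focal], columns=community.columns)
    clouds = synthetic.simulate_read_clouds(community, panel, cloud_cfg, seed=7,
                                            strain2_freq=strain2)
    return community, panel, clouds, focal
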