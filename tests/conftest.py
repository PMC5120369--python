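import numpy as np
import pandas as pd
import pytest

import dmpenrich as dm

TOY_SPEC = dm.FixtureSpec(
    n_probes=2100,
    chromosomes={"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000},
    n_samples=8,
    planted_set_size=30,
    pi0=0.1,
    pi1=0.8,
)


@pytest.fixture(scope="session")
def toy_study():
    """One synthetic study shared across tests: manifest, planted set, panel, matrix."""
    rng = np.random.default_rng(12345)
    manifest = dm.generate_manifest(TOY_SPEC, rng)
    planted = dm.plant_test_set(manifest, TOY_SPEC, rng)
    tracks, metadata, truth = dm.generate_hotspot_panel(
        manifest, TOY_SPEC, rng, planted_probes=planted)
    matrix = dm.build_overlap_matrix(manifest, tracks)
    return {
        "spec": TOY_SPEC,
        "manifest": manifest,
        "planted": planted,
        "tracks": tracks,
        "metadata": metadata,
        "truth": truth,
        "matrix": matrix,
    }


@pytest.fixture()
def tiny_manifest():
    """A handcrafted six-probe manifest for exact-by-hand checks."""
    return pd.DataFrame({
        "probe_id": ["cg01", "cg02", "cg03", "cg04", "cg05", "cg06"],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr3"],
        "pos": [100, 500, 2000, 100, 5000, 150],
        "gene_group": ["Body", "TSS200", "IGR", "Body", "1stExon", "IGR"],
        "cpg_relation": ["N_Shore", "Island", "OpenSea", "S_Shelf", "Island",
                         "OpenSea"],
    })
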