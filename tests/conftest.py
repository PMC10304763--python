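import numpy as np
import pandas as pd
import pytest

from cfmeth.atlas import MethylationAtlas, SignatureMatrix


@pytest.fixture()
def toy_atlas() -> MethylationAtlas:
    """4 probes x 2 cell types with coordinates, for hand-checkable selection."""
    beta = pd.DataFrame(
        {
            "A": [0.8, 0.6, 0.1, 0.4],
            "B": [0.2, 0.6, 0.9, 0.1],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
    )
    coords = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [1000, 1049, 1051, 1000],
            "strand": "+",
        },
        index=beta.index,
    )
    return MethylationAtlas(beta, coords)


@pytest.fixture(scope="session")
def random_signature() -> SignatureMatrix:
    """Seeded full-rank 50-probe x 5-type signature."""
    rng = np.random.default_rng(7)
    probes = pd.Index([f"cg{i:05d}" for i in range(50)], name="probe_id")
    beta = pd.DataFrame(rng.uniform(0, 1, (50, 5)), index=probes, columns=list("ABCDE"))
    return SignatureMatrix(beta, pd.Series("differential", index=probes))


@pytest.fixture(scope="session")
def marker_atlas():
    """Synthetic atlas with planted markers plus its truth table."""
    from cfmeth.synthetic import make_synthetic_atlas

    return make_synthetic_atlas(
        n_cell_types=6, n_cpgs=1200, n_markers_per_type=15, marker_contrast=0.9, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort():
    """29-sample cohort over a 1500-CpG atlas with 5 planted DMRs per group."""
    from cfmeth.synthetic import CohortSpec, make_synthetic_atlas, simulate_wgbs_cohort

    atlas, _ = make_synthetic_atlas(
        n_cell_types=6, n_cpgs=1500, n_markers_per_type=10, marker_contrast=0.9, seed=5
    )
    spec = CohortSpec(n_planted_dmrs=5, effect_size_pp=40.0, seed=23)
    return atlas, simulate_wgbs_cohort(spec, atlas)
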