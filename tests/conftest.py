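import pytest

from promland.codec import RegionMap
from promland.simulate import (
    BinningSpec,
    mutagenize_library,
    phenotype_to_bin,
    sample_landscape,
)

# one fixed wild type for small-scale tests
WT20 = "ACGTACGTTGCAATGCCGTA"


@pytest.fixture(scope="session")
def region_map_20() -> RegionMap:
    return RegionMap.from_report_coords(
        {"CRP1": (-20, -14), "RNAP1": (-10, -2)}, 20
    )


@pytest.fixture(scope="session")
def small_truth(region_map_20):
    """L=20 block-structured ground truth with moderate pairwise epistasis."""
    return sample_landscape(
        L=20,
        region_map=region_map_20,
        epistatic_sparsity=0.05,
        epistatic_scale=0.6,
        seed=1,
        wildtype=WT20,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    """Sequences, noiseless latent values and a 9-gate binning for L=20."""
    seqs = mutagenize_library(small_truth.wildtype, 6000, per_site_rate=0.2, seed=2)
    latent = small_truth.model.predict(seqs, small_truth.wildtype)
    spec = BinningSpec.default_for_latent(latent, K=9)
    bins = phenotype_to_bin(latent, spec, seed=3)
    return {
        "truth": small_truth,
        "sequences": seqs,
        "latent": latent,
        "spec": spec,
        "bins": bins,
    }
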