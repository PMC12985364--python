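import pytest

from h2a.graph import build_knn_graph
from h2a.slide_io import PatchStack
from h2a.synthetic import SyntheticSlideConfig, generate_synthetic_slide


@pytest.fixture(scope="session")
def small_slide():
    """A 6x6 hex slide with 4 cell types, noise-free."""
    cfg = SyntheticSlideConfig(n_rows=6, n_cols=6, grid="hex",
                               n_cell_types=4, patch_size_px=16,
                               spot_spacing_px=16.0, noise_sd=0.0, seed=7)
    return generate_synthetic_slide(cfg)


@pytest.fixture(scope="session")
def small_graph(small_slide):
    return build_knn_graph(small_slide.coords, 6, small_slide.spot_ids)


@pytest.fixture(scope="session")
def small_patchstack(small_slide):
    return PatchStack(small_slide.patches, small_slide.spot_ids,
                      small_slide.config.patch_size_px)


def random_coords(rng, n, scale=100.0):
    return rng.uniform(0, scale, size=(n, 2))
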