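import numpy as np
import pytest

from renalmil import fixtures

CLASS_ORDER = ("ccRCC", "ccpRCC", "parenchyma", "fat")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240423)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 12 slides, 4 classes, seed 7 (in memory)."""
    spec = fixtures.default_spec(seed=7)
    records, images = fixtures.render_dataset(spec)
    return spec, records, images


@pytest.fixture(scope="session")
def tissue_image(rng):
    """A fully saturated 'tissue' image with no background pixels."""
    base = np.array([200, 120, 160], dtype=np.float64)
    img = base + rng.normal(0, 6, size=(500, 500, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A tiny on-disk two-class dataset for file-level pipeline tests."""
    spec = fixtures.default_spec(seed=11)
    spec = fixtures.FixtureSpec(
        classes=(spec.classes[0], spec.classes[3]),
        n_slides_per_class=2,
        slide_size=(560, 560),
        seed=11,
    )
    out = tmp_path_factory.mktemp("small_ds")
    manifest = fixtures.make_dataset(spec, out, overwrite=True)
    return spec, out, manifest
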