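import numpy as np
import pytest

from stereovary import SectionSpec, generate_section, render_grayscale


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixed_section():
    """Small previtellogenic section with a known mixed composition."""
    spec = SectionSpec(
        width=800,
        height=700,
        px_per_um=0.5,
        composition={"og": 0.2, "po1": 0.2, "po2": 0.3, "cao": 0.3},
        seed=5,
    )
    return generate_section(spec)


@pytest.fixture(scope="session")
def mixed_gray(mixed_section):
    return render_grayscale(mixed_section)


@pytest.fixture(scope="session")
def pca_section():
    spec = SectionSpec(
        width=500, height=400, px_per_um=0.5, composition={"pca": 1.0}, seed=1
    )
    return generate_section(spec)


def recount_truth(label_image):
    """Independent exhaustive pixel-count oracle for germ-area fractions.

    Walks the raw label array, resolving zona pellucida codes to their owner
    stage via the legend names, and returns fractions over germ pixels.
    """
    from stereovary.stages import GERM_STAGES

    counts = {}
    values, pixel_counts = np.unique(label_image.labels, return_counts=True)
    for code, n in zip(values, pixel_counts):
        name = label_image.legend[int(code)]
        if name.startswith("zp:"):
            name = name.split(":", 1)[1]
        if name in GERM_STAGES:
            counts[name] = counts.get(name, 0) + int(n)
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()}
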