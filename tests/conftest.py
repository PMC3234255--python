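import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitofilter as mf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_layout() -> mf.ArrayLayout:
    """120-position toy layout: positions 6..115 interrogable, redundant
    tiling (2 sets) over the first 30 positions."""
    mask = np.zeros(120, dtype=bool)
    mask[5:115] = True
    return mf.ArrayLayout(
        genome_length=120,
        interrogable_mask=mask,
        control_region_spans=[(1, 30)],
        redundant_sets_k=2,
    )


@pytest.fixture(scope="session")
def small_reference(small_layout) -> str:
    rng = np.random.default_rng(2024)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, small_layout.genome_length)])


def make_sample(
    layout: mf.ArrayLayout,
    sample_id: str = "s",
    quality=30.0,
    intensities=(1050.0, 50.0, 50.0, 50.0),
    haploid="A",
    diploid=None,
) -> mf.SampleDataset:
    """Build a primary-only sample with constant or per-position values."""
    pos = layout.interrogable_positions
    n = len(pos)
    q = np.broadcast_to(np.asarray(quality, dtype=float), (n,)).copy()
    inten = np.broadcast_to(np.asarray(intensities, dtype=float), (n, 4)).copy()
    hap = np.broadcast_to(np.asarray(haploid, dtype="<U1"), (n,)).copy()
    dip = hap.copy() if diploid is None else np.broadcast_to(
        np.asarray(diploid, dtype="<U1"), (n,)
    ).copy()
    block = mf.ProbeBlock(0, pos, inten, inten.copy(), q, hap, dip)
    return mf.SampleDataset(sample_id, {0: block})


@pytest.fixture(scope="session")
def qc_batch24():
    """24 full-genome samples: 20 clean, 3 degraded, 1 carrying the canonical
    5,791 bp deletion (10154, 15945]."""
    specs = [mf.SampleSpec(f"S{i:02d}") for i in range(1, 21)]
    specs += [mf.SampleSpec(f"D{i}", degraded=True) for i in (1, 2, 3)]
    specs += [mf.SampleSpec("DEL1", deletion=(10154, 15945))]
    cfg = mf.GeneratorConfig(seed=11, samples=specs)
    batch, truth = mf.generate_batch(cfg)
    return batch, truth


@pytest.fixture(scope="session")
def noise_free_batch():
    """4 noise-free full-genome samples with planted variants and one
    heteroplasmy (minor fraction 0.3)."""
    rng = np.random.default_rng(5)
    ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 16569)])

    def alt(p):
        return "A" if ref[p - 1] != "A" else "G"

    specs = [
        mf.SampleSpec("P1", variants=[(3243, alt(3243)), (11778, alt(11778))]),
        mf.SampleSpec("P2", variants=[(12264, alt(12264))]),
        mf.SampleSpec("P3", heteroplasmies=[(5049, alt(5049), 0.3)]),
        mf.SampleSpec("P4"),
    ]
    cfg = mf.GeneratorConfig(
        seed=7, samples=specs, reference=ref, intensity_noise_sd=0.0, q_clean_sd=0.0
    )
    batch, truth = mf.generate_batch(cfg)
    return batch, truth
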