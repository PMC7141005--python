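import numpy as np
import pandas as pd
import pytest

import immusig as im


@pytest.fixture(scope="session")
def tiny_bundle() -> im.ReferenceBundle:
    """Hand-built 3-type bundle with disjoint two-gene signatures."""
    genes = ["a1", "a2", "b1", "b2", "c1", "c2"]
    types = ["A", "B", "C"]
    base = np.full((6, 3), 2.0)
    st = np.zeros((6, 3))
    for row, col in [(0, 0), (1, 0), (2, 1), (3, 1), (4, 2), (5, 2)]:
        base[row, col] = 10.0
        st[row, col] = 1.0
    return im.ReferenceBundle(
        cell_types=types,
        rt=pd.DataFrame(base, index=genes, columns=types),
        st=pd.DataFrame(st, index=genes, columns=types),
        signatures={"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1", "c2"]},
    )


@pytest.fixture(scope="session")
def small_bundle() -> im.ReferenceBundle:
    """Synthetic 6-type bundle with a 2-level hierarchy and some overlap."""
    hierarchy = im.CellTypeHierarchy({"CT01": frozenset({"CT03", "CT04"})})
    spec = im.SyntheticBundleSpec(
        n_cell_types=6,
        n_marker_per_type=8,
        overlap_fraction=0.25,
        overlap_pairs=((4, 5),),
        hierarchy=hierarchy,
        seed=3,
    )
    return im.generate_bundle(spec)


@pytest.fixture(scope="session")
def default_bundle() -> im.ReferenceBundle:
    return im.default_bundle(seed=0)


@pytest.fixture(scope="session")
def small_sim(small_bundle):
    """Simulated mixtures over the small bundle (two strata)."""
    fr = im.random_fractions(60, small_bundle.cell_types, seed=21)
    tumor, _ = im.generate_mixture(small_bundle, fr, noise_sd=0.25, seed=22)
    spec = im.MixtureSimulationSpec(
        candidate_genes=tuple(small_bundle.marker_genes),
        strata={"s1": tumor.data.iloc[:, :30], "s2": tumor.data.iloc[:, 30:]},
        n_samples=150,
        seed=23,
    )
    return im.simulate_mixtures(spec, small_bundle.rt)


def make_response_cohort(n, n_feat, effect, seed, name="c"):
    """Gaussian features; feature 0 shifted by *effect* for responders."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    x = rng.normal(0.0, 1.0, size=(n, n_feat))
    x[:, 0] += effect * labels
    idx = [f"{name}{i:03d}" for i in range(n)]
    return im.ResponseCohort(
        features=pd.DataFrame(x, index=idx, columns=[f"f{j}" for j in range(n_feat)]),
        labels=pd.Series(labels, index=idx),
        name=name,
    )
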