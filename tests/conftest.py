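import numpy as np
import pytest

from metapls.synthgen import StudyDesign, generate_metabolite_table


def two_group_design(
    n_markers: int = 10,
    n_metabolites: int = 42,
    n_per_group: int = 8,
    effect_size: float = 2.0,
    seed: int = 0,
) -> StudyDesign:
    """Two-group (NC reference, M model) design with planted markers."""
    mets = tuple(f"met{j + 1:02d}" for j in range(n_metabolites))
    effect = {
        (mets[k], "M"): (effect_size if k % 2 == 0 else -effect_size)
        for k in range(n_markers)
    }
    return StudyDesign(
        groups=("NC", "M"),
        n_per_group=n_per_group,
        metabolites=mets,
        effect_table=effect,
        seed=seed,
    )


def null_xy(n_per_class: int = 8, n_vars: int = 20, seed: int = 0):
    """Centered matrix with labels independent of X."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, n_vars))
    X -= X.mean(axis=0)
    labels = np.asarray(["A"] * n_per_class + ["B"] * n_per_class)
    return X, labels


def planted_xy(seed: int = 0, d: float = 2.0, n_per_group: int = 8):
    """Centered planted-marker matrix (NC vs M), labels, and marker names."""
    design = two_group_design(effect_size=d, n_per_group=n_per_group, seed=seed)
    table = generate_metabolite_table(design)
    X = table.values - table.values.mean(axis=0)
    return X, np.asarray(table.group_labels), table


@pytest.fixture
def planted_table():
    return generate_metabolite_table(two_group_design(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
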