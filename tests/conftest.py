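import numpy as np
import pytest

import rxnmix as rx


def grid_bin(fuzzy, lo=0.0, hi=12.0, bin_width=0.1, step=1e-4):
    """Independent binning oracle: trapezoid quadrature on a fine ppm grid."""
    edges = lo + bin_width * np.arange(int(round((hi - lo) / bin_width)) + 1)
    out = np.zeros(len(edges) - 1)
    for k in range(len(out)):
        x = np.arange(edges[k], edges[k + 1] + step / 2, step)
        out[k] = np.trapezoid(fuzzy.intensity(x), x)
    return out


@pytest.fixture(scope="session")
def registry():
    return rx.default_registry()


@pytest.fixture(scope="session")
def small_reactions():
    """Small synthetic dataset: 23 reactions over all six types."""
    return rx.generate_dataset(
        rx.GeneratorConfig(per_type_counts=(4, 4, 3, 5, 3, 4), seed=7)
    )


@pytest.fixture(scope="session")
def small_problem(small_reactions, registry):
    """Descriptors, mixtures and the descriptor map of the small dataset."""
    ids, desc = rx.descriptor_matrix(small_reactions)
    descriptors = dict(zip(ids, desc))
    mixtures = rx.enumerate_mixtures(small_reactions, registry)
    return {
        "reactions": small_reactions,
        "descriptors": descriptors,
        "mixtures": mixtures,
        "X": rx.mixture_matrix(mixtures, descriptors),
        "y": np.array([m.mclass for m in mixtures], dtype=object),
    }
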