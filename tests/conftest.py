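import numpy as np
import pytest

from zonemark import preprocess, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """The default seeded two-species synthetic dataset (seed 1)."""
    return simulate.generate_dataset(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_norms(default_bundle):
    """Log-normalized matrices for both species, ortholog-harmonized."""
    from zonemark import io

    matrix_a = io.filter_genes_min_fraction(
        io.filter_spots_in_tissue(default_bundle.matrix_a)
    )
    matrix_b = io.filter_genes_min_fraction(
        io.filter_spots_in_tissue(default_bundle.matrix_b)
    )
    matrix_b = io.apply_ortholog_map(matrix_b, default_bundle.ortholog_map)
    return (
        preprocess.log_normalize(matrix_a),
        preprocess.log_normalize(matrix_b),
    )


@pytest.fixture(scope="session")
def truth_labels(default_bundle, default_norms):
    """Cluster labels taken straight from the planted zones."""
    norm_a, norm_b = default_norms
    zones = {}
    for layout in default_bundle.truth.spots.values():
        in_tissue = layout[layout["in_tissue"] == 1]
        zones.update(dict(zip(in_tissue["barcode"], in_tissue["zone"])))
    barcodes = list(norm_a.barcodes) + list(norm_b.barcodes)
    species = [simulate.SPECIES_A] * norm_a.n_spots + [
        simulate.SPECIES_B
    ] * norm_b.n_spots
    return preprocess.labels_from_zones(zones, barcodes, species)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
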