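import numpy as np
import pytest

from ptrkit.io_tables import AbundanceTable, OrthologMap
from ptrkit.preprocess import ProfilePair, preprocess_condition, protein_scale
from ptrkit.synthetic import default_config, generate_study


def build_pairs(study, **kwargs):
    """Full preprocessing path (protein scaling + detection) for a study."""
    scaled = dict(zip(study.protein, protein_scale(list(study.protein.values()))))
    pairs = {}
    for cond in study.condition_ids:
        *_, pair, _ = preprocess_condition(study.mrna[cond], scaled[cond], **kwargs)
        pairs[cond] = pair
    return pairs


def make_pair(condition_id, gene_ids, mrna, protein):
    mrna = np.asarray(mrna, dtype=float)
    protein = np.asarray(protein, dtype=float)
    return ProfilePair(condition_id, list(gene_ids), mrna, protein,
                       np.zeros_like(mrna), np.zeros_like(protein))


def noise_free_config(seed, **overrides):
    """All stochastic noise off: abundances emitted directly, no dropout."""
    params = dict(
        seed=seed,
        replicate_noise_sd=0.0,
        measurement_noise_sd=0.0,
        species_ptr_sd=0.0,
        condition_mrna_sd=0.0,
        library_depth=None,
        protein_dropout_slope=0.0,
        outlier_magnitude=4.0,
        outlier_fraction=0.04,
        outlier_sign_bias=0.8,
        essential_fraction=0.0,
    )
    params.update(overrides)
    return default_config(**params)


@pytest.fixture(scope="session")
def study_default():
    return generate_study(default_config(seed=1))


@pytest.fixture(scope="session")
def pairs_default(study_default):
    return build_pairs(study_default)


@pytest.fixture(scope="session")
def study8():
    return generate_study(default_config(seed=1, n_conditions=8))


@pytest.fixture(scope="session")
def pairs8(study8):
    return build_pairs(study8)


@pytest.fixture
def tiny_table():
    return AbundanceTable(
        "cA", "mrna", ["g1", "g2", "g3"],
        np.array([[10.0, 20.0, 30.0, 40.0],
                  [90.0, 80.0, 70.0, 60.0],
                  [0.0, 0.0, 0.0, 0.0]]),
        ["r1", "r2", "r3", "r4"],
    )


@pytest.fixture
def tiny_orthomap():
    return OrthologMap(
        {
            "OG1": {"cA": ["a1"], "cB": ["b1"]},
            "OG2": {"cA": ["a2", "a3"], "cB": ["b2"]},
            "OG3": {"cB": ["b3"]},
        },
        condition_ids=["cA", "cB"],
    )
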