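import warnings

import pytest

from decoygen import (
    FixtureSpec,
    build_repeat_models,
    gc_profile,
    make_toy_genome,
    train_model,
)


@pytest.fixture(scope="session")
def toy():
    """Toy genome with planted repeats, masks and annotations."""
    return make_toy_genome(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def toy_model(toy):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_model(
            toy.genome, [toy.gene_mask, toy.repeat_mask], k=4, source="toy"
        )


@pytest.fixture(scope="session")
def toy_repeats(toy):
    profiles = {n: gc_profile(s) for n, s in toy.genome.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_repeat_models(
            toy.rm_annotations, toy.consensus, profiles, toy.trf_annotations
        )
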