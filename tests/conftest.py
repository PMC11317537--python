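import numpy as np
import pytest

from kinemoe.curation import curate_pipeline
from kinemoe.evalsplit import SplitSpec, stratified_split
from kinemoe.featurize import featurize_entries, fit_aux_spec
from kinemoe.synthetic import HashEmbedder, SynthSpec, gen_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """300 entries with planted violations and duplicate groups."""
    spec = SynthSpec(
        n_entries=300,
        seed=11,
        n_duplicate_groups=8,
        planted_violations={
            "incomplete": 5,
            "small_substrate": 5,
            "large_substrate": 3,
            "fragment": 5,
            "nonpositive": 5,
            "unknown_unit": 2,
            "bad_mutation": 2,
        },
    )
    records, truth = gen_dataset(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def curated(small_dataset):
    _, records, _ = small_dataset
    entries, report = curate_pipeline(records)
    return entries, report


@pytest.fixture(scope="session")
def featurized(small_dataset, curated):
    spec, _, _ = small_dataset
    entries, _ = curated
    train_e, val_e, test_e = stratified_split(entries, SplitSpec(seed=3))
    enz = HashEmbedder("hash-enzyme", spec.enzyme_dim, salt=1)
    sub = HashEmbedder("hash-substrate", spec.substrate_dim, salt=2)
    aux = fit_aux_spec(train_e, aux_dim=spec.aux_dim)
    return tuple(
        featurize_entries(split, enz, sub, aux)
        for split in (train_e, val_e, test_e)
    )
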