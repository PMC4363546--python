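import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from indirank import (
    Dataset,
    DrugRecord,
    IndicationCatalog,
    InteractionTable,
    SimilarityProvider,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_dataset(labels: dict[str, list[str]], catalog: list[str] | None = None,
                 smiles: dict[str, str] | None = None) -> Dataset:
    """Build a dataset from {drug_id: [tags]} with empty SMILES by default."""
    tags = catalog
    if tags is None:
        tags = []
        for ts in labels.values():
            for t in ts:
                if t not in tags:
                    tags.append(t)
    smiles = smiles or {}
    return Dataset(
        IndicationCatalog(tags),
        [DrugRecord(d, smiles.get(d, ""), frozenset(ts)) for d, ts in labels.items()],
    )


def random_fixture(rng: np.random.Generator, n_drugs: int, n_categories: int):
    """A small random corpus for oracle-equivalence tests.

    Labels are drawn uniformly (1–3 per drug); interaction scores and
    similarities are independent random symmetric pairwise weights, sparse
    for interactions and dense for similarity.
    """
    tags = [f"D_{i + 1}" for i in range(n_categories)]
    ids = [f"X{j:03d}" for j in range(n_drugs)]
    labels = {
        d: list(rng.choice(tags, size=rng.integers(1, min(3, n_categories) + 1),
                           replace=False))
        for d in ids
    }
    dataset = make_dataset(labels, catalog=tags)
    interactions = InteractionTable()
    sim_table: dict[tuple[str, str], float] = {}
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            if rng.random() < 0.3:
                interactions.set(ids[i], ids[j], float(rng.uniform(0.05, 1.0)))
            sim_table[(ids[i], ids[j])] = float(rng.uniform(0.0, 1.0))
    similarity = SimilarityProvider(table=sim_table)
    return dataset, interactions, similarity


@pytest.fixture
def toy_dataset() -> Dataset:
    """Five drugs, three categories, one two-label drug."""
    return make_dataset(
        {
            "a": ["D_1"],
            "b": ["D_1", "D_2"],
            "c": ["D_2"],
            "d": ["D_3"],
            "e": ["D_3"],
        },
        catalog=["D_1", "D_2", "D_3"],
    )
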