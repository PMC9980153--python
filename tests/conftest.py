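import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from preprotac.properties import AMINO_ACIDS
from preprotac.sequence_io import ProteinRecord


def random_peptides(n, min_len, max_len, seed):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        out.append(ProteinRecord(id=f"pep{i}", sequence=seq))
    return out


@pytest.fixture(scope="session")
def peptides_5_50():
    """50 random peptides of length 5-50 for descriptor oracle checks."""
    return random_peptides(50, 5, 50, seed=20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-motif cohort with fixture embeddings and labels."""
    from preprotac import embedding, synthetic

    spec = synthetic.SyntheticSpec(
        n_pos=30, n_neg=30, length_range=(50, 90), motif="WCKDHE",
        insertion_prob_pos=1.0, insertion_prob_neg=0.0, seed=11,
    )
    dataset, truth = synthetic.generate(spec)
    emb = embedding.FixtureEmbedder(dim=64, k=3, seed=11)
    fm = embedding.embed_records(dataset.records, emb)
    y = np.array([dataset.labels[s] for s in fm.sample_ids])
    return dataset, truth, emb, fm, y


@pytest.fixture(scope="session")
def small_rf(small_cohort):
    from sklearn.ensemble import RandomForestClassifier

    _, _, _, fm, y = small_cohort
    return RandomForestClassifier(n_estimators=30, random_state=5).fit(fm.values, y)
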