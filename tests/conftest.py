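import json
import random

import pytest

from termlex.lexical_metrics import TokenizationConfig
from termlex.synthetic_data import SyntheticSpec, VocabularyBlock


@pytest.fixture(scope="session")
def config() -> TokenizationConfig:
    return TokenizationConfig()


@pytest.fixture
def tiny_export_json() -> str:
    """Three concept objects under the default export key names."""
    return json.dumps(
        [
            {
                "ui": "C0034619",
                "name": "Radiation therapy of brain",
                "rootSource": "MTH",
                "semanticTypes": ["Therapeutic or Preventive Procedure"],
            },
            {
                "ui": "C0034618",
                "name": "Radiotherapy",
                "rootSource": "MSH",
                "semanticTypes": [],
            },
            {
                "ui": "C1522449",
                "name": "Intensity-modulated radiation therapy (IMRT)",
                "rootSource": "NCI",
                "semanticTypes": [
                    "Therapeutic or Preventive Procedure",
                    "Health Care Activity",
                ],
            },
        ]
    )


def random_small_spec(seed: int) -> SyntheticSpec:
    """A randomized small corpus spec: <=10 vocabularies x <=20 concepts."""
    rng = random.Random(seed)
    blocks = []
    for v in range(rng.randint(1, 10)):
        length_min = rng.randint(1, 3)
        blocks.append(
            VocabularyBlock(
                code=f"V{v}",
                n_concepts=rng.randint(1, 20),
                word_pool_size=rng.randint(1, 12),
                length_min=length_min,
                length_max=rng.randint(length_min, 6),
                stopword_rate=rng.uniform(0.0, 0.5),
                shared_word_rate=rng.uniform(0.0, 0.6),
            )
        )
    return SyntheticSpec(
        seed=rng.randrange(2**31),
        vocabularies=tuple(blocks),
        duplicate_fraction=rng.uniform(0.0, 0.3),
        shared_pool_size=rng.randint(0, 8),
    )
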