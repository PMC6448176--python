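import numpy as np
import pytest

from problist.corpus import Corpus, ProblemListItem, truncate_to_category


def make_item(item_id, description, code=None, patient="P1"):
    return ProblemListItem(
        patient_id=patient,
        item_id=item_id,
        description=description,
        code=truncate_to_category(code) if code else None,
    )


@pytest.fixture
def small_corpus():
    """Six items, two patients, two ICD-10 topics, one uncoded item each."""
    return Corpus(
        [
            make_item("i1", "Akutes Nierenversagen", "N17.0"),
            make_item("i2", "Nierenversagen akut", "N17"),
            make_item("i3", "Nierenversagen akut"),
            make_item("i4", "Hyperkaliämie", "E87.5", patient="P2"),
            make_item("i5", "Hyperkaliaemie", "E87", patient="P2"),
            make_item("i6", "Hyperkaliämie", patient="P2"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
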