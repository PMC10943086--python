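import pytest

from ncgseek.corpus import corpus_fragments
from ncgseek.grouping import build_group_table
from ncgseek.primers import design_primer_map
from ncgseek.strands import encode_corpus
from ncgseek.synthetic import FixturePlan, generate_corpus


@pytest.fixture(scope="session")
def primer_map3():
    """Primer pairs for a 3-file pool plus the reference pool."""
    return design_primer_map(3, seed=0)


@pytest.fixture(scope="session")
def small_setup(primer_map3):
    """A 3-file corpus with planted keywords, its dictionary, and its pool."""
    plan = FixturePlan(
        n_files=3, words_per_file=60,
        keyword_plan=[("storage", 0, 3), ("cryptography", 1, 2)], seed=1,
    )
    corpus, truth = generate_corpus(plan)
    table = build_group_table(corpus_fragments(corpus))
    pool = encode_corpus(corpus, table, primer_map3)
    return {"corpus": corpus, "truth": truth, "table": table, "pool": pool,
            "primer_map": primer_map3}
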