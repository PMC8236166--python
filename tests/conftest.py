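import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oncolit.lexicon import EntityLexicon, LexiconEntry
from oncolit.synthetic import GeneratorConfig, cancer_id, compound_id, generate_corpus


@pytest.fixture(scope="session")
def oncology_lexicon() -> EntityLexicon:
    """Hand-built lexicon mirroring well-known cancer/compound synonym sets."""
    return EntityLexicon.from_entries(
        [
            LexiconEntry(
                "liver_cancer", "cancer", "liver cancer",
                ("liver cancer", "hepatocellular carcinoma"), "cancerlivercancer",
            ),
            LexiconEntry(
                "stomach_cancer", "cancer", "stomach cancer",
                ("stomach cancer", "cancer of the stomach", "gastric cancer"),
                "cancerstomachcancer",
            ),
            LexiconEntry(
                "breast_cancer", "cancer", "breast cancer",
                ("breast cancer", "breast carcinoma"), "cancerbreastcancer",
            ),
            LexiconEntry(
                "5-fluorouracil", "compound", "5-fluorouracil",
                ("5-fluorouracil", "5-FU"), "5-fluorouracil",
            ),
            LexiconEntry(
                "mitomycin-c", "compound", "mitomycin C",
                ("mitomycin C", "mitomycin-c"), "mitomycin-c",
            ),
            LexiconEntry(
                "doxorubicin", "compound", "doxorubicin",
                ("doxorubicin", "adriamycin"), "doxorubicin",
            ),
            LexiconEntry("brca1", "gene", "BRCA1", ("BRCA1", "breast cancer type 1 susceptibility protein"), "brca1"),
            LexiconEntry("alb", "gene", "ALB", ("ALB", "Albumin"), "albumin"),
        ]
    )


@pytest.fixture(scope="session")
def small_planted_corpus():
    """1000-document corpus with one strongly planted compound-cancer pair."""
    config = GeneratorConfig(
        seed=101,
        n_reference_docs=1000,
        n_cancers=3,
        n_compounds=4,
        n_genes=10,
        association_effect={(compound_id(0), cancer_id(0)): 3.0},
    )
    docs, lexicon, truth = generate_corpus(config)
    return config, docs, lexicon, truth
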