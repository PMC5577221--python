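import pytest

import codoncontext as cc


@pytest.fixture(scope="session")
def code():
    return cc.genetic_code()


@pytest.fixture(scope="session")
def meer():
    """Toy gene: ATG GAA GAG CGT TAA -> protein MEER."""
    return cc.make_cds("meer", "ATGGAAGAGCGTTAA")


@pytest.fixture(scope="session")
def context_rule():
    """Deterministic k=2 rule: Glu is GAG when the residue two positions to
    the left is Arg or Lys, GAA otherwise. The decisive residue sits at
    distance 2, so 3-residue windows cannot resolve it but 5- and 7-residue
    windows determine the codon exactly."""
    return cc.rule("E", 2, {"R***": "GAG", "K***": "GAG", "****": "GAA"},
                   determinism=1.0)


@pytest.fixture(scope="session")
def ruled_corpus(context_rule):
    """A medium synthetic corpus governed by the deterministic context rule."""
    spec = cc.CorpusSpec(n_genes=150, length_range=(60, 120),
                         rules=(context_rule,), seed=11)
    return spec, cc.generate_corpus(spec)


@pytest.fixture(scope="session")
def free_corpus():
    """A context-free corpus (codon choice independent of neighbours)."""
    spec = cc.CorpusSpec(n_genes=150, length_range=(60, 120), seed=13)
    return spec, cc.generate_corpus(spec)


@pytest.fixture(scope="session")
def synthetic_index(free_corpus):
    """A w=5 CSI with >=1000 records, used as a search-oracle arena."""
    _, corpus = free_corpus
    index = cc.build_index(corpus, 5)
    assert len(index) >= 1000
    return index
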