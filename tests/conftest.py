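import pytest

from mitofounder.mito_model import (load_gene_annotation,
                                    load_pathogenicity_table, load_reference)


@pytest.fixture(scope="session")
def ref_seq():
    return load_reference()


@pytest.fixture(scope="session")
def annotations():
    return load_gene_annotation()


@pytest.fixture(scope="session")
def pathogenicity(annotations, ref_seq):
    return load_pathogenicity_table(annotations=annotations, ref_seq=ref_seq)
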