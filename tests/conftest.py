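import io

import pytest

from taxbench.taxonomy import TaxNode, TaxonomyTree

MINI_NODES_DMP = (
    "1\t|\t1\t|\tno rank\t|\n"
    "10\t|\t1\t|\tgenus\t|\n"
    "20\t|\t1\t|\tgenus\t|\n"
    "100\t|\t10\t|\tspecies\t|\n"
    "101\t|\t10\t|\tspecies\t|\n"
    "200\t|\t20\t|\tspecies\t|\n"
    "150\t|\t100\t|\tstrain\t|\n"
)

MINI_NAMES_DMP = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "10\t|\tAlphagenus\t|\t\t|\tscientific name\t|\n"
    "20\t|\tBetagenus\t|\t\t|\tscientific name\t|\n"
    "100\t|\tAlphagenus primus\t|\t\t|\tscientific name\t|\n"
    "101\t|\tAlphagenus secundus\t|\t\t|\tscientific name\t|\n"
    "200\t|\tBetagenus unus\t|\t\t|\tscientific name\t|\n"
    "150\t|\tAlphagenus primus str. X\t|\t\t|\tscientific name\t|\n"
)


@pytest.fixture
def mini_tree():
    """Two genera, three species, one strain: the minimal useful taxonomy."""
    from taxbench.taxonomy import load_taxonomy

    return load_taxonomy(io.StringIO(MINI_NODES_DMP), io.StringIO(MINI_NAMES_DMP))


@pytest.fixture
def host_tree():
    """Mini taxonomy extended with a host lineage (taxid 9606 analogue)."""
    nodes = {
        1: TaxNode(1, 1, "no rank", "root"),
        10: TaxNode(10, 1, "genus", "Alphagenus"),
        100: TaxNode(100, 10, "species", "Alphagenus primus"),
        101: TaxNode(101, 10, "species", "Alphagenus secundus"),
        9605: TaxNode(9605, 1, "genus", "Homo"),
        9606: TaxNode(9606, 9605, "species", "Homo sapiens"),
    }
    return TaxonomyTree(nodes=nodes, root=1)
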