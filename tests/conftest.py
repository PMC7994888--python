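import pytest

from phaselink import parse_newick


@pytest.fixture
def cherry_tree():
    """Three alleles over two accessions with one support value."""
    return parse_newick("((A|0:0.1,A|1:0.1)90:0.2,B|s:0.3);")


@pytest.fixture
def weighted_pair():
    """The 4-leaf worked example: lengths 0.1, supports 0.9/1.0/1.0/1.0."""
    a = parse_newick("((a:1,b:1)0.9:0.1,(c:1,d:1)1.0:0.1);")
    b = parse_newick("((a:1,c:1)1.0:0.1,(b:1,d:1)1.0:0.1);")
    return a, b


@pytest.fixture
def fixture_newicks():
    """A small zoo of Newick strings used for round-trip checks."""
    return [
        "((A|0:0.1,A|1:0.1)90:0.2,B|s:0.3);",
        "((A|0,A|1),B|s);",
        "(((A|0.0:0.1,A|0.1:0.1)75:0.1,A|1:0.2)88:0.3,B|s:0.1);",
        "(H63-15-15|0.0:0.01,(His.his.2|s:0.02,caeb.Jbo.2:0.03)50:0.005);",
        "A|0:0.5;",
        "((a:1,b:1)0.9:0.1,(c:1,d:1)1:0.1);",
    ]
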