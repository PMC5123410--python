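import pytest

from igphylo.genomes import Genome, parse_genomes


@pytest.fixture(scope="session")
def fig_pair():
    """The worked unequal-content pair: A=(1,-3,5), B=(1,2,3,4), circular."""
    a, b = parse_genomes(">A\n1 -3 5 @\n>B\n1 2 3 4 @\n")
    return a, b


@pytest.fixture(scope="session")
def toy_linear():
    """(a,b,c,d) as one chromosome, fragmented, and reordered variants."""
    x, y, z = parse_genomes(
        ">X\n1 2 3 4 $\n"
        ">Y\n1 $\n2 $\n3 $\n4 $\n"
        ">Z\n1 3 2 4 $\n"
    )
    return x, y, z
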