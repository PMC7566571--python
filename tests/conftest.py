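import pytest

from isomirkit import catalog, synthetic

# The two miR-140-3p seed-register isomiRs, written as RNA.
MIR140_3P1 = "ACCACAGGGUAGAACCACGGAC"
MIR140_3P2 = "UACCACAGGGUAGAACCACGGA"


@pytest.fixture(scope="session")
def mir140_context():
    """A hairpin-style context embedding miR-140-3p.2 so that the next
    templated base continues into miR-140-3p.1 (which is the -1-shifted
    register of the same stem arm)."""
    flank5 = "GGAUACCGGU"
    flank3 = "GUUCAGGAUC"
    ctx = flank5 + MIR140_3P2 + "C" + flank3
    ref = catalog.MatureRef(
        name="mir-140-3p.2",
        sequence=MIR140_3P2,
        hairpin_name="mir-140",
        start=len(flank5),
        arm="3p",
    )
    return ctx, ref, len(flank5)


@pytest.fixture(scope="session")
def locus():
    return synthetic.gen_locus(1)


@pytest.fixture()
def locus_refs(locus):
    """MatureRef + HairpinContext pair for the synthetic locus 3p arm."""
    ann = locus.mature("3p")
    ref = catalog.MatureRef(
        name="syn-3p",
        sequence=locus.mature_seq("3p"),
        hairpin_name=locus.hairpin_name,
        start=len(locus.flank5) + ann.start,
        arm="3p",
    )
    hp = catalog.HairpinContext(name=locus.hairpin_name, hairpin_seq=locus.context)
    return ref, {locus.hairpin_name: hp}
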