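import pytest

from pepscreen import CleavageRule, Enzyme, EnzymeLibrary, bundled_library


def make_rule(sites, exceptions=()):
    """Build a CleavageRule from {label: residue-string} mappings."""
    conv = lambda patterns: tuple(
        {label: frozenset(res) for label, res in p.items()} for p in patterns
    )
    return CleavageRule(site_patterns=conv(sites), exception_patterns=conv(exceptions))


def make_enzyme(name, sites, exceptions=()):
    return Enzyme(name=name, rule=make_rule(sites, exceptions))


@pytest.fixture(scope="session")
def library():
    return bundled_library()


@pytest.fixture()
def toy_library():
    """Three single-position enzymes plus a never-cleaving Null enzyme."""
    return EnzymeLibrary(
        [
            make_enzyme("AfterK", [{"P1": "K"}]),
            make_enzyme("BeforeD", [{"P1'": "D"}]),
            make_enzyme("AfterG", [{"P1": "G"}]),
            make_enzyme("Null", []),
        ]
    )
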