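"""Reaction-set loading, validation, and lossless round-tripping."""

import math

import pytest

import frickesim as fs
from frickesim.chemistry import ReactionSetError, load_reaction_set, validate_reaction_set

# every rate constant the mechanism prints, checked to survive packaging
PRINTED_RATES = [
    (("e-aq", "H+"), ("H",), 2.3e10),
    (("H", "O2"), ("HO2",), 2.1e10),
    (("OH", "Fe2+"), ("Fe3+", "OH-"), 3.4e8),
    (("HO2", "Fe2+"), ("Fe3+", "HO2-"), 7.9e5),
    (("HO2-", "H+"), ("H2O2",), 5.0e10),
    (("H2O2", "Fe2+"), ("Fe3+", "OH", "OH-"), 52.0),
    (("H", "Fe2+"), ("Fe3+", "H2"), 1.3e7),
    (("RSSR", "e-aq"), ("RSSR-",), 4.1e10),
    (("RSSR", "H"), ("RS", "RSH"), 8.0e9),
    (("RSSR", "OH"), ("RSSR+", "OH-"), 1.7e10),
    (("Fe2+", "RS"), ("Fe3+", "RS-"), 2.5e8),
    (("Fe2+", "RSSR+"), ("Fe3+", "RSSR"), 2.0e6),
    (("RS", "RSSR"), ("RSSSR", "R"), 1.0e6),
    (("R", "O2"), ("ROO",), 2.0e9),
    (("Fe2+", "ROO"), ("Fe3+", "ROO-"), 7.9e5),
    (("RSSR+", "RSSR+"), ("RSSR2+", "RSSR"), 2.5e9),
    (("SO4-", "Fe2+"), ("Fe3+", "SO42-"), 9.9e8),
]


@pytest.fixture(scope="module")
def full_set():
    return load_reaction_set("fricke_cystamine_full")


def test_packaged_full_set_self_validates(full_set):
    assert validate_reaction_set(full_set) == []
    assert len(full_set.reactions) >= 25
    printed = [r for r in full_set.reactions if r.provenance == "printed-in-paper"]
    assert len(printed) >= 17


@pytest.mark.parametrize("reactants,products,k0", PRINTED_RATES,
                         ids=lambda v: "+".join(v) if isinstance(v, tuple) else str(v))
def test_printed_rate_constants_present(full_set, reactants, products, k0):
    matches = [r for r in full_set.reactions
               if sorted(r.reactants) == sorted(reactants)
               and sorted(r.products) == sorted(products)]
    assert len(matches) == 1
    assert matches[0].k0 == k0              # exact round-trip through packaging


def test_charge_conservation_of_every_packaged_reaction(full_set):
    z = {name: sp.charge for name, sp in full_set.species.items()}
    for r in full_set.reactions:
        lhs = sum(z[s] for s in (*r.reactants, *r.co_reactants))
        rhs = sum(z[s] for s in r.products)
        assert lhs == rhs, r.label


def test_subset_load_contains_expected_reactions():
    core = load_reaction_set("fricke_core")
    assert any(sorted(r.reactants) == ["H+", "e-aq"] and r.k0 == 2.3e10
               for r in core.reactions)
    cys = load_reaction_set("cystamine")
    assert any(sorted(r.reactants) == ["OH", "RSSR"] and r.k0 == 1.7e10
               for r in cys.reactions)


def test_csv_and_json_round_trip_losslessly(full_set, tmp_path):
    for suffix in (".csv", ".json"):
        path = tmp_path / f"rt{suffix}"
        full_set.save(path)
        back = load_reaction_set(path)
        assert len(back.reactions) == len(full_set.reactions)
        for a, b in zip(full_set.reactions, back.reactions):
            assert a.reactants == b.reactants
            assert a.products == b.products
            assert a.k0 == b.k0              # bit-exact: repr round-trip
            assert a.kind == b.kind
            assert a.provenance == b.provenance


def test_charge_unbalanced_file_rejected_with_line_identified(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text(
        "label,reactants,products,co_reactants,k0,kind,zA,zB,exempt_ionic,provenance,note\n"
        "X1,OH;Fe2+,Fe3+;H2O2,,1e9,scavenging,0,2,false,literature-default,\n")
    with pytest.raises(ReactionSetError, match="X1"):
        load_reaction_set(bad)


def test_unknown_species_rejected(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text(
        "label,reactants,products,co_reactants,k0,kind,zA,zB,exempt_ionic,provenance,note\n"
        "X2,OH;Unobtainium,OH-,,1e9,scavenging,0,0,false,literature-default,\n")
    with pytest.raises(ReactionSetError, match="X2"):
        load_reaction_set(bad)


def test_non_positive_rate_rejected(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text(
        "label,reactants,products,co_reactants,k0,kind,zA,zB,exempt_ionic,provenance,note\n"
        "X3,OH;OH,H2O2,,0,pair_diffusive,0,0,false,literature-default,\n")
    with pytest.raises(ReactionSetError, match="X3"):
        load_reaction_set(bad)


def test_union_rejects_duplicate_channels():
    a = load_reaction_set("fricke_core")
    b = load_reaction_set("fricke_core")
    with pytest.raises(ReactionSetError, match="duplicate"):
        a.union(b)


def test_empty_set_gives_empty_report():
    assert validate_reaction_set(fs.ReactionSet()) == []


def test_unknown_packaged_name_rejected():
    with pytest.raises(ReactionSetError):
        load_reaction_set("no_such_set")
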