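"""Cross-link assembly, fragment enumeration and spectrum assignment."""

from itertools import combinations_with_replacement

import pytest

from collagen_ptm.chem import free_amino_acid, mz, parse_formula, round_half_up
from collagen_ptm.crosslinks import (
    DEFAULT_LOSS_GRAMMAR,
    assemble,
    assign_species,
    builtin_species,
    enumerate_fragments,
)

O = 15.99491


@pytest.mark.parametrize(
    "name, formula, mh",
    [
        ("LNL", "C12H25N3O4", 276.19),
        ("HLNL", "C12H25N3O5", 292.19),
        ("HHMD", "C24H43N7O9", 574.32),
        ("d-HHMD", "C24H43N7O8", 558.32),
    ],
)
def test_builtin_recipes_reproduce_printed_chemistry(name, formula, mh):
    s = assemble(name)
    assert s.formula == parse_formula(formula)
    assert round_half_up(s.mh(1), 2) == mh


def test_mass_conservation_of_assembly():
    s = assemble("HHMD")
    expected = (
        2 * free_amino_acid("Lysald").mass
        + free_amino_acid("H").mass
        + free_amino_acid("Hyl").mass
        - 2 * parse_formula("H2O").mass
        + parse_formula("H2").mass
    )
    assert s.mass == pytest.approx(expected, abs=1e-9)


def test_hydroxyl_pairs_differ_by_one_oxygen():
    assert assemble("HLNL").mass - assemble("LNL").mass == pytest.approx(O, abs=1e-5)
    assert assemble("HHMD").mass - assemble("d-HHMD").mass == pytest.approx(O, abs=1e-5)


def test_glycosylated_recipes():
    hexose = parse_formula("C6H10O5").mass
    assert assemble("G-HLNL").mass - assemble("HLNL").mass == pytest.approx(hexose, abs=1e-9)
    assert assemble("GG-HLNL").mass - assemble("HLNL").mass == pytest.approx(2 * hexose, abs=1e-9)


def test_dehydro_precursors_lack_the_reduction():
    h2 = parse_formula("H2").mass
    for name in ("LNL", "HLNL", "HHMD", "d-HHMD"):
        assert assemble(name).mass - assemble(f"dehydro-{name}").mass == pytest.approx(h2, abs=1e-9)


def test_unknown_recipe_and_negative_counts():
    with pytest.raises(KeyError):
        assemble("pyridinoline")
    with pytest.raises(ValueError):
        assemble("broken", components=("G",), n_water=5, n_h2=0)


def _brute_force_fragments(species, max_losses=3):
    """Exhaustive oracle: all loss multisets + all component releases."""
    out = set()
    losses = sorted(DEFAULT_LOSS_GRAMMAR)
    out.add(species.formula)
    for k in range(1, max_losses + 1):
        for combo in combinations_with_replacement(losses, k):
            f = species.formula
            ok = True
            for name in combo:
                try:
                    f = f - DEFAULT_LOSS_GRAMMAR[name]
                except ValueError:
                    ok = False
                    break
            if ok:
                out.add(f)
    H = parse_formula("H")
    for code in set(species.components):
        released = free_amino_acid(code)
        pieces = [released]
        try:
            pieces.append(species.formula - released)
        except ValueError:
            pass
        for base in pieces:
            for variant in (base, base + H):
                if variant.mass <= species.mass:
                    out.add(variant)
            try:
                f = base - H
            except ValueError:
                continue
            if f.mass <= species.mass:
                out.add(f)
    return out


@pytest.mark.parametrize("name", ["LNL", "HLNL", "HHMD", "d-HHMD"])
def test_fragment_enumeration_matches_exhaustive_oracle(name):
    s = assemble(name)
    fs = enumerate_fragments(s)
    got = {f.formula for f in fs.fragments}
    assert got == _brute_force_fragments(s)
    mzs = fs.mz_values()
    assert mzs == sorted(mzs)
    assert max(mzs) <= s.mh(1) + 1e-9


def test_histidine_release_lands_at_156_08():
    for name in ("HHMD", "d-HHMD"):
        fs = enumerate_fragments(assemble(name))
        assert any(round_half_up(f.mz, 2) == 156.08 for f in fs.fragments)


def test_zero_losses_keeps_precursor():
    s = assemble("LNL")
    fs = enumerate_fragments(s, max_losses=0)
    assert any(abs(f.mz - s.mh(1)) < 1e-9 for f in fs.fragments)


def test_assignment_uses_lys_marker_fragments():
    """d-HHMD vs HHMD at precursor 558.32: Lys-release fragments decide."""
    d = assemble("d-HHMD")
    lys_fragment = mz(free_amino_acid("K").mass, 1)  # 147.11
    result = assign_species(
        observed_precursor=558.32,
        observed_fragments=[156.08, lys_fragment],
        candidates=builtin_species(),
    )
    assert result.decision == "assigned"
    assert result.species.name == "d-HHMD"
    assert result.n_matched == 2


def test_assignment_unassigned_far_precursor():
    result = assign_species(900.0, [156.08], builtin_species())
    assert result.decision == "unassigned"
    assert result.species is None


def test_assignment_tie_is_ambiguous():
    # two candidates within tolerance of the precursor, equal fragment support
    a = assemble("HLNL")
    b = assemble("twin", components=("Lysald", "Hyl"), n_water=1, n_h2=1)
    result = assign_species(a.mh(1), [], [a, b], tolerance=0.05)
    assert result.decision == "ambiguous"


def test_empty_candidates_is_error():
    with pytest.raises(ValueError):
        assign_species(558.32, [], [])
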