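"""The substitution engine: sites, surgery, single/simultaneous modes, dedup."""

import pytest

from rxnaug.augment import (
    AugmentationSpec,
    SubstitutionError,
    augment_record,
    dedup_and_merge,
    find_augmentable_sites,
    find_sites_in_species,
    simultaneous_augment,
    single_augment,
    substitute_group,
)
from rxnaug.chem_core import Molecule, canonicalize_smiles, parse_reaction_smiles
from rxnaug.synthetic_fixtures import enumerate_fake_strings
from rxnaug.templates import classify_reaction
from tests.conftest import AUG_ROLES


class TestFindSites:
    def test_printed_reaction_has_one_halide_site(self, fig_record, templates, fg_classes):
        sites = find_augmentable_sites(fig_record, templates["hiyama"], fg_classes["halogen"])
        assert len(sites) == 1
        assert sites[0].member.name == "bromo"
        assert sites[0].leaving_group_confirmed

    def test_two_halogens_in_one_species_is_ambiguous(self, templates, fg_classes):
        rec = parse_reaction_smiles(
            "Clc1ccc(Br)cc1.OB(O)c1ccc(C)cc1>>Cc1ccc(-c2ccc(Cl)cc2)cc1"
        )
        assert classify_reaction(rec) == "suzuki"
        assert find_augmentable_sites(rec, templates["suzuki"], fg_classes["halogen"]) == []

    def test_spectator_halide_in_product_is_not_a_site(self, fg_classes):
        # the chloride on the boron partner survives into the product
        rec = parse_reaction_smiles(
            "Brc1ccc(C#N)cc1.OB(O)c1ccc(Cl)cc1>>N#Cc1ccc(-c2ccc(Cl)cc2)cc1"
        )
        partner_idx = next(
            i for i, m in enumerate(rec.reactants) if "Cl" in m.smiles
        )
        sites = find_sites_in_species(rec, partner_idx, fg_classes["halogen"])
        assert [s.leaving_group_confirmed for s in sites] == [False]

    def test_grignard_halide_requires_mg_attachment(self, fg_classes):
        rec = parse_reaction_smiles(
            "Brc1ccc(C)cc1.C[Mg]Br>>Cc1ccc(C)cc1"
        )
        grignard_idx = next(i for i, m in enumerate(rec.reactants) if "Mg" in m.smiles)
        sites = find_sites_in_species(rec, grignard_idx, fg_classes["grignard_halide"])
        assert len(sites) == 1  # the Br on Mg, not the aryl Br


class TestSubstituteGroup:
    def test_bromide_to_iodide(self, fg_classes):
        halogen = fg_classes["halogen"]
        mol = Molecule.from_smiles("N#Cc1ccc(Br)cc1")
        rec = parse_reaction_smiles("N#Cc1ccc(Br)cc1>>N#Cc1ccccc1")
        (site,) = [
            s for s in find_sites_in_species(rec, 0, halogen)
        ]
        out = substitute_group(mol, site, halogen.member("iodo"))
        assert out.smiles == canonicalize_smiles("N#Cc1ccc(I)cc1")

    def test_identity_replacement_rejected(self, fg_classes):
        halogen = fg_classes["halogen"]
        mol = Molecule.from_smiles("N#Cc1ccc(Br)cc1")
        rec = parse_reaction_smiles("N#Cc1ccc(Br)cc1>>N#Cc1ccccc1")
        (site,) = find_sites_in_species(rec, 0, halogen)
        with pytest.raises(SubstitutionError):
            substitute_group(mol, site, halogen.member("bromo"))

    def test_boronic_acid_to_pinacolate_is_valid(self, fg_classes):
        boron = fg_classes["boron"]
        mol = Molecule.from_smiles("OB(O)c1ccccc1")
        rec = parse_reaction_smiles("OB(O)c1ccccc1.Brc1ccccc1>>c1ccc(-c2ccccc2)cc1")
        (site,) = find_sites_in_species(rec, 0, boron)
        out = substitute_group(mol, site, boron.member("pinacol_boronate"))
        # emitted SMILES re-parses to a valence-valid molecule
        reparsed = Molecule.from_smiles(out.smiles)
        assert reparsed.smiles == out.smiles
        assert "B" in reparsed.formula()


class TestSingleAugment:
    def test_printed_reaction_yields_two_halide_fakes(self, fig_record, templates):
        fakes = single_augment(fig_record, templates["hiyama"], "aryl_halide")
        assert len(fakes) == 2
        for fake in fakes:
            assert fake.provenance == "fake"
            assert fake.product.smiles == fig_record.product.smiles
            # each fake re-parses and passes its parent's template
            from rxnaug.chem_core import write_reaction_smiles

            reparsed = parse_reaction_smiles(write_reaction_smiles(fake))
            assert classify_reaction(reparsed) == "hiyama"
        halides = {f.canonical_string for f in fakes}
        assert len(halides) == 2

    def test_no_class_member_in_role_species_yields_empty(self, fig_record, templates):
        # the printed reaction's dichloro(ethyl)silane matches the silicon
        # role pattern but is not one of the shipped silicon class members,
        # so the silicon role has no substitutable site
        assert single_augment(fig_record, templates["hiyama"], "organosilicon") == []

    def test_chan_lam_augments_boron_role_only(self, templates, all_type_pairs):
        rec, _ = all_type_pairs["chan_lam"][0]
        fakes = single_augment(rec, templates["chan_lam"], "organoboron")
        assert len(fakes) == 2  # |boron members| - 1
        for fake in fakes:
            assert fake.product.smiles == rec.product.smiles


class TestSimultaneousAugment:
    def test_hiyama_count_identity(self, hiyama_pairs, templates):
        rec, _ = hiyama_pairs[0]
        fakes = simultaneous_augment(
            rec, templates["hiyama"], ("aryl_halide", "organosilicon")
        )
        assert len(fakes) == 3 * 4 - 1  # halogen x silicon members minus original

    def test_kumada_count_identity(self, templates, all_type_pairs):
        rec, _ = all_type_pairs["kumada"][0]
        fakes = simultaneous_augment(
            rec, templates["kumada"], ("organyl_halide", "grignard")
        )
        assert len(fakes) == 3 * 3 - 1

    def test_product_never_changes(self, templates, all_type_pairs):
        for rxn_type, pairs in all_type_pairs.items():
            mode, roles = AUG_ROLES[rxn_type]
            for rec, _ in pairs:
                fakes = augment_record(
                    rec, templates[rxn_type], AugmentationSpec(mode, roles)
                )
                for fake in fakes:
                    assert fake.product.smiles == rec.product.smiles
                    assert fake.canonical_string != rec.canonical_string


class TestCountLawsAgainstOracle:
    """Engine output equals a brute-force text-substitution enumerator."""

    @pytest.mark.parametrize("rxn_type", sorted(AUG_ROLES))
    def test_fakes_match_enumerator(self, rxn_type, templates, all_type_pairs):
        mode, roles = AUG_ROLES[rxn_type]
        for rec, recipe in all_type_pairs[rxn_type]:
            fakes = augment_record(
                rec, templates[rxn_type], AugmentationSpec(mode, roles)
            )
            expected = enumerate_fake_strings(recipe, mode, roles)
            assert {f.canonical_string for f in fakes} == expected

    def test_single_mode_count_is_members_minus_one(self, hiyama_pairs, templates):
        for rec, recipe in hiyama_pairs:
            fakes = single_augment(rec, templates["hiyama"], "aryl_halide")
            assert len(fakes) == 3 - 1
            assert {f.canonical_string for f in fakes} == enumerate_fake_strings(
                recipe, "single", ("aryl_halide",)
            )


class TestDedupAndMerge:
    def test_merge_with_empty_fakes_is_identity(self, hiyama_pairs):
        records = [r for r, _ in hiyama_pairs]
        assert dedup_and_merge(records, []) == records

    def test_fake_identical_to_raw_is_dropped(self, hiyama_pairs):
        records = [r for r, _ in hiyama_pairs]
        clone = records[0].replace(provenance="fake")
        merged = dedup_and_merge(records, [clone])
        assert len(merged) == len(records)

    def test_merging_twice_is_idempotent(self, hiyama_pairs, templates):
        records = [r for r, _ in hiyama_pairs]
        fakes = simultaneous_augment(
            records[0], templates["hiyama"], ("aryl_halide", "organosilicon")
        )
        once = dedup_and_merge(records, fakes)
        twice = dedup_and_merge(once, fakes)
        assert [r.canonical_string for r in once] == [r.canonical_string for r in twice]

    def test_guard_drops_colliding_fakes(self, hiyama_pairs, templates):
        records = [r for r, _ in hiyama_pairs]
        fakes = simultaneous_augment(
            records[0], templates["hiyama"], ("aryl_halide", "organosilicon")
        )
        guard = {fakes[0].canonical_string}
        merged = dedup_and_merge(records, fakes, guard=guard)
        assert fakes[0].canonical_string not in {r.canonical_string for r in merged}
        assert len(merged) == len(records) + len(fakes) - 1

    def test_spec_guard_field_filters_fakes(self, hiyama_pairs, templates):
        rec, _ = hiyama_pairs[0]
        all_fakes = simultaneous_augment(
            rec, templates["hiyama"], ("aryl_halide", "organosilicon")
        )
        spec = AugmentationSpec(
            "simultaneous",
            ("aryl_halide", "organosilicon"),
            drop_colliding_with=frozenset({all_fakes[0].canonical_string}),
        )
        filtered = augment_record(rec, templates["hiyama"], spec)
        assert len(filtered) == len(all_fakes) - 1


class TestAugmentationSpecValidation:
    def test_single_needs_one_role(self):
        with pytest.raises(ValueError):
            AugmentationSpec("single", ("a", "b"))

    def test_simultaneous_needs_two_roles(self):
        with pytest.raises(ValueError):
            AugmentationSpec("simultaneous", ("a",))
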