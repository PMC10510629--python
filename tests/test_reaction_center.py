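"""Reacting-atom identification and tagging-template mining."""

import pytest
from rdkit import Chem

from retroroute.centers import (
    TagTemplate,
    apply_templates,
    extract_templates,
    reacting_atoms,
    tag_product,
    template_for_reaction,
    templates_from_frame,
    templates_to_frame,
)
from retroroute.smiles import SmilesError, canonicalize, reaction_from_smiles

ESTERIFICATION = "[CH3:1][OH:2].[CH3:3][C:4](=O)Cl>>[CH3:1][O:2][C:4](=O)[CH3:3]"


def brute_force_reacting(rxn):
    """Independent oracle: per-atom environment diff done longhand."""

    def env_by_label(smiles_list):
        out = {}
        for s in smiles_list:
            mol = Chem.MolFromSmiles(s)
            for atom in mol.GetAtoms():
                if not atom.GetAtomMapNum():
                    continue
                neighbours = []
                for nbr in atom.GetNeighbors():
                    bond = mol.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
                    neighbours.append((nbr.GetAtomicNum(), bond.GetBondTypeAsDouble()))
                out[atom.GetAtomMapNum()] = (
                    atom.GetFormalCharge(),
                    atom.GetTotalNumHs(),
                    sorted(neighbours),
                )
        return out

    sm = env_by_label(rxn.starting_materials)
    prod = env_by_label([rxn.product])
    return frozenset(
        label for label, env in prod.items() if label not in sm or sm[label] != env
    )


class TestReactingAtoms:
    def test_esterification(self):
        rxn = reaction_from_smiles(ESTERIFICATION)
        assert reacting_atoms(rxn) == frozenset({2, 4})

    def test_identity_reaction_has_no_reacting_atoms(self):
        rxn = reaction_from_smiles("[CH4:1]>>[CH4:1]")
        assert reacting_atoms(rxn) == frozenset()

    def test_label_absent_from_sm_side_is_reacting(self):
        rxn = reaction_from_smiles("[CH3:1][OH:2]>>[CH3:1][O:2][CH3:5]")
        assert 5 in reacting_atoms(rxn)

    def test_unmapped_product_raises(self):
        rxn = reaction_from_smiles("[CH3:1]O>>CO".replace(">>", ">>"))
        with pytest.raises(SmilesError):
            reacting_atoms(rxn)

    def test_matches_brute_force_oracle_on_mock_corpus(self, world):
        corpus = world.corpus()[:60]
        assert corpus
        for rxn in corpus:
            assert reacting_atoms(rxn) == brute_force_reacting(rxn)


class TestTagProduct:
    def test_esterification_tags_ester_oxygen_and_carbonyl_carbon(self):
        rxn = reaction_from_smiles(ESTERIFICATION)
        tm = tag_product(rxn)
        mol = Chem.MolFromSmiles(tm.molecule.smiles)
        symbols = sorted(mol.GetAtomWithIdx(i).GetSymbol() for i in tm.tagged_atoms)
        assert symbols == ["C", "O"]
        # the tagged carbon is the carbonyl carbon
        carbon = next(
            mol.GetAtomWithIdx(i)
            for i in tm.tagged_atoms
            if mol.GetAtomWithIdx(i).GetSymbol() == "C"
        )
        assert any(
            b.GetBondType() == Chem.BondType.DOUBLE for b in carbon.GetBonds()
        )

    def test_identity_reaction_skipped(self):
        assert tag_product(reaction_from_smiles("[CH4:1]>>[CH4:1]")) is None

    def test_corpus_pass_conserves_counts(self, world):
        corpus = world.corpus()[:40]
        tagged = [tag_product(r) for r in corpus]
        kept = [t for t in tagged if t is not None]
        assert len(kept) + tagged.count(None) == len(corpus)


class TestExtractTemplates:
    def test_identical_reactions_merge(self):
        rxn = reaction_from_smiles(ESTERIFICATION)
        templates = extract_templates([rxn, rxn, rxn], radius=1)
        assert len(templates) == 1
        assert templates[0].support == 3
        assert templates[0].radius == 1

    def test_single_occurrence_filtered(self):
        a = reaction_from_smiles(ESTERIFICATION)
        b = reaction_from_smiles("[CH3:1][OH:2]>>[CH3:1][O:2][CH3:5]")
        assert extract_templates([a, b], radius=1) == []

    def test_empty_corpus(self):
        assert extract_templates([], radius=2) == []

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            extract_templates([], radius=0)

    def test_support_counts_sum_over_disjoint_corpus(self):
        a = reaction_from_smiles(ESTERIFICATION)
        b = reaction_from_smiles(
            "[CH3:1][C:2](=[O:3])[OH:4].[NH2:5][CH3:6]>>[CH3:1][C:2](=[O:3])[NH:5][CH3:6]"
        )
        templates = extract_templates([a, a, b, b, b], radius=1)
        assert sorted(t.support for t in templates) == [2, 3]

    def test_radius_three_environment_contains_radius_one(self, world):
        for rxn in world.corpus()[:30]:
            t1 = template_for_reaction(rxn, radius=1)
            t3 = template_for_reaction(rxn, radius=3)
            if t1 is None:
                continue
            # the shallower pattern occurs within the deeper one
            frag3 = Chem.MolFromSmarts(t3.pattern)
            q1 = Chem.MolFromSmarts(t1.pattern)
            assert frag3.GetNumAtoms() >= q1.GetNumAtoms()

    def test_reactive_atom_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            TagTemplate(pattern="[#6:1]", reactive_positions=(), radius=1, support=2)


class TestApplyTemplates:
    BENZENE_CH = TagTemplate(
        pattern="[#6;a;R;D2;+0:1]", reactive_positions=(0,), radius=1, support=2
    )

    def test_symmetric_matches_collapse(self):
        out = apply_templates(canonicalize("c1ccccc1"), [self.BENZENE_CH])
        assert len(out) == 1

    def test_no_match_gives_empty(self):
        assert apply_templates(canonicalize("CCCC"), [self.BENZENE_CH]) == []

    def test_output_has_no_duplicates(self, world):
        corpus = world.corpus()[:20]
        templates = extract_templates(corpus, radius=2, min_support=1)
        product = canonicalize(corpus[0].product)
        out = apply_templates(product, templates)
        serialized = [t.serialized() for t in out]
        assert len(serialized) == len(set(serialized))

    def test_self_consistency_on_own_product(self, world):
        """The template mined from a reaction re-tags its own product with
        the original tag set."""
        for rxn in world.corpus()[:30]:
            original = tag_product(rxn)
            if original is None:
                continue
            for radius in (1, 2, 3):
                template = template_for_reaction(rxn, radius)
                tagged = apply_templates(original.molecule, [template])
                assert original in tagged


def test_template_csv_round_trip(world):
    templates = extract_templates(world.corpus()[:40], radius=2, min_support=1)
    assert templates
    frame = templates_to_frame(templates)
    assert templates_from_frame(frame) == templates
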