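"""Mapping parsing, type-1 filters (perfect alignment, homology culling,
protein-only) and the type-2 structure-quality filter."""

import itertools

import numpy as np
import pytest

from shiftforge.alignment import global_align, percent_identity
from shiftforge.fixtures import FixtureSpec, build_structure
from shiftforge.mapping import (
    EntityMetadata,
    MappingEntry,
    MappingParseError,
    cull_homologs,
    filter_energy,
    filter_perfect_alignment,
    filter_protein_only,
    get_scorer,
    read_mapping,
    register_scorer,
)


class TestReadMapping:
    def test_two_data_lines(self):
        entries = read_mapping("1ABC 4023\n2XYZ 4711")
        assert [(e.pdb_id, e.bmrb_id) for e in entries] == \
            [("1ABC", "4023"), ("2XYZ", "4711")]

    def test_comments_and_blank_lines_ignored(self):
        assert read_mapping("# header\n\n  # only comments\n") == []

    def test_single_token_line_reports_line_number(self):
        with pytest.raises(MappingParseError) as err:
            read_mapping("1ABC 4023\n2XYZ\n")
        assert err.value.line_number == 2

    def test_inline_comment_stripped(self):
        entries = read_mapping("1ABC 4023  # solution structure")
        assert len(entries) == 1

    def test_empty_ids_rejected(self):
        with pytest.raises(ValueError):
            MappingEntry(pdb_id="", bmrb_id="4023")


class TestPerfectAlignmentFilter:
    @staticmethod
    def _entry(seq_a, seq_b):
        e = MappingEntry("1ABC", "4023")
        e.alignment = global_align(seq_a, seq_b)
        return e

    def test_retains_exactly_identity_100(self):
        entries = [self._entry("MKVA", "MKVA"),
                   self._entry("MKVA", "MKLA"),
                   self._entry("GGG", "GGG")]
        kept = filter_perfect_alignment(entries)
        assert len(kept) == 2
        assert all(e.alignment.identity == 100.0 for e in kept)

    def test_empty_input(self):
        assert filter_perfect_alignment([]) == []

    def test_gapped_alignment_is_rejected(self):
        # all residues of the shorter sequence match, but the overhang
        # column breaks 100 % identity
        e = self._entry("MKV", "MKVL")
        assert e.alignment.matches == 3
        assert filter_perfect_alignment([e]) == []

    def test_unaligned_entry_is_an_error(self):
        with pytest.raises(ValueError, match="no alignment"):
            filter_perfect_alignment([MappingEntry("1ABC", "4023")])


def brute_force_cull(sequences: dict, cutoff: float) -> int:
    """Largest subset with all pairwise identities <= cutoff (exhaustive)."""
    keys = list(sequences)
    best = 0
    for r in range(len(keys), 0, -1):
        for combo in itertools.combinations(keys, r):
            ok = all(
                percent_identity(sequences[a], sequences[b]) <= cutoff
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                return r
    return best


class TestHomologyCulling:
    def test_identical_pair_keeps_one(self):
        kept = cull_homologs({"a": "MKVLAW", "b": "MKVLAW"}, 10.0)
        assert len(kept) == 1

    def test_dissimilar_pair_kept(self):
        a, b = "AAAAAAAAAAAAAAAAAAAA", "WWWWWWWWWWWWWWWWWWWC"
        assert percent_identity(a, b) <= 10.0
        assert len(cull_homologs({"a": a, "b": b}, 10.0)) == 2

    def test_triangle_keeps_the_low_identity_pair(self):
        # AB similar, AC and BC dissimilar -> 2 retained
        seqs = {"a": "AAAAAAAAAAAAAAAAAAAA",
                "b": "AAAAAAAAAAAAAAAAAAAC",
                "c": "WWWWWWWWWWWWWWWWWWWW"}
        assert brute_force_cull(seqs, 50.0) == 2
        assert len(cull_homologs(seqs, 50.0)) == 2

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            cull_homologs({"a": "MKV"}, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_soundness_and_near_optimality_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                        size=int(rng.integers(8, 15))))
            for i in range(n)
        }
        cutoff = 30.0
        kept = cull_homologs(seqs, cutoff)
        # soundness: post-hoc all-pairs check
        for a, b in itertools.combinations(kept, 2):
            assert percent_identity(seqs[a], seqs[b]) <= cutoff
        # near-optimality: within one sequence of the exhaustive optimum
        assert len(kept) >= brute_force_cull(seqs, cutoff) - 1

    def test_deterministic_given_input_order(self):
        seqs = {"a": "MKVLAW", "b": "MKVLAF", "c": "GGSGGS"}
        assert cull_homologs(seqs, 40.0) == cull_homologs(seqs, 40.0)


class TestProteinOnlyFilter:
    def test_protein_and_water_kept(self):
        meta = EntityMetadata(polymer_types=["protein"], n_waters=12)
        keep, reason = filter_protein_only(MappingEntry("1ABC", "1"), meta)
        assert keep

    def test_nucleic_polymer_dropped(self):
        meta = EntityMetadata(polymer_types=["nucleic", "protein"])
        keep, reason = filter_protein_only(MappingEntry("1ABC", "1"), meta)
        assert not keep and reason == "nucleic polymer"

    def test_ligand_dropped(self):
        meta = EntityMetadata(polymer_types=["protein"], ligands=["HEM"])
        keep, reason = filter_protein_only(MappingEntry("1ABC", "1"), meta)
        assert not keep and reason == "ligand"

    def test_missing_metadata_kept_undetermined(self):
        entry = MappingEntry("1ABC", "1")
        keep, reason = filter_protein_only(entry, None)
        assert keep and reason == "undetermined"
        assert any("undetermined" in n for n in entry.notes)


@pytest.fixture(scope="module")
def structure():
    return build_structure(FixtureSpec(pdb_id="ENER", sequence="AAAAA"))


class TestEnergyFilter:

    def test_score_below_cutoff_kept(self, structure):
        keep, score, _ = filter_energy(structure, cutoff=1000.0,
                                       scorer=lambda s: 500.0)
        assert keep and score == 500.0

    def test_score_above_cutoff_dropped(self, structure):
        keep, score, reason = filter_energy(structure, cutoff=1000.0,
                                            scorer=lambda s: 1500.0)
        assert not keep and "above cutoff" in reason

    def test_score_exactly_at_cutoff_kept(self, structure):
        keep, _, _ = filter_energy(structure, cutoff=1000.0,
                                   scorer=lambda s: 1000.0)
        assert keep

    def test_scorer_failure_drops_with_reason(self, structure):
        def broken(_):
            raise RuntimeError("boom")

        keep, score, reason = filter_energy(structure, scorer=broken)
        assert not keep and score is None and reason == "unscorable"

    def test_default_scorer_accepts_ideal_geometry(self, structure):
        keep, score, _ = filter_energy(structure)
        assert keep, f"ideal helix scored {score}"

    def test_default_scorer_penalizes_clashes(self, structure):
        # two intact copies of the helix 3 A apart: many van der Waals
        # overlaps with unchanged intramolecular bond graphs
        from shiftforge.structure import Atom, Chain, ProteinStructure, \
            Residue

        chains = []
        for k, dx in enumerate((np.zeros(3), np.array([3.0, 0.0, 0.0]))):
            nc = Chain(index=k + 1, original_id="AB"[k])
            for res in structure.chains[0].residues:
                nr = Residue(res.index, res.name, res.original_index)
                for n, a in res.atoms.items():
                    nr.atoms[n] = Atom(a.name, a.element, a.pos + dx)
                nc.residues.append(nr)
            chains.append(nc)
        clashing = ProteinStructure("CLSH", chains)
        _, relaxed, _ = filter_energy(structure)
        keep, clashed, _ = filter_energy(clashing)
        assert clashed > relaxed
        assert not keep

    def test_unknown_scorer_name(self):
        with pytest.raises(KeyError, match="unknown scorer"):
            get_scorer("no-such-scorer")

    def test_duplicate_scorer_registration_rejected(self):
        with pytest.raises(ValueError, match="already registered"):
            register_scorer("default-nb", lambda s: 0.0)
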