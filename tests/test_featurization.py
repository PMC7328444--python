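"""Descriptor correctness: hand counts, normalization invariants, and an
independent CTD enumeration oracle."""

import numpy as np
import pytest

from pcmlab import featurization as ft


class TestEcfp6:
    def test_same_molecule_different_notation(self):
        np.testing.assert_array_equal(ft.ecfp6("C"), ft.ecfp6("[CH4]"))

    def test_binary_and_length(self):
        v = ft.ecfp6("c1ccccc1CCO", n_bits=1024)
        assert v.shape == (1024,)
        assert set(np.unique(v)) <= {0.0, 1.0}

    def test_distinct_molecules_differ(self):
        assert not np.array_equal(ft.ecfp6("CCO"), ft.ecfp6("CCC"))

    def test_atom_order_invariance(self):
        np.testing.assert_array_equal(ft.ecfp6("OCC"), ft.ecfp6("CCO"))


class TestPhyschem:
    def test_benzene_hand_counts(self):
        v = ft.physchem("c1ccccc1")
        named = dict(zip(ft.PHYSCHEM_NAMES, v))
        assert named["heavy_atoms"] == 6
        assert named["ring_count"] == 1
        assert named["rotatable_bonds"] == 0
        assert named["num_hbd"] == 0
        assert named["num_hba"] == 0

    def test_ethanol_hand_counts(self):
        named = dict(zip(ft.PHYSCHEM_NAMES, ft.physchem("CCO")))
        assert named["num_hbd"] == 1
        assert named["heavy_atoms"] == 3

    def test_vector_length(self):
        assert ft.physchem("CC(=O)O").shape == (8,)


class TestAac:
    def test_uniform_four_residues(self):
        v = ft.aac("ACDE")
        assert v[ft.AMINO_ACIDS.index("A")] == 0.25
        assert v.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v) == 4

    def test_homopolymer(self):
        v = ft.aac("AAAA")
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_alternating(self):
        v = ft.aac("AC" * 50)
        assert v[ft.AMINO_ACIDS.index("A")] == 0.5
        assert v[ft.AMINO_ACIDS.index("C")] == 0.5

    def test_non_canonical_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            ft.aac("ACXDE")


class TestDpc:
    def test_homopolymer(self):
        v = ft.dpc("AAA")
        assert v[0] == 1.0  # AA is the first dipeptide
        assert v.sum() == pytest.approx(1.0)

    def test_aca(self):
        v = ft.dpc("ACA")
        assert v[ft.DIPEPTIDES.index("AC")] == 0.5
        assert v[ft.DIPEPTIDES.index("CA")] == 0.5

    def test_sums_to_one_random(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            seq = "".join(rng.choice(list(ft.AMINO_ACIDS), size=30))
            assert ft.dpc(seq).sum() == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ft.dpc("A")


def ctd_oracle(sequence: str) -> np.ndarray:
    """Independent direct-enumeration CTD: explicit position lists, no shared
    code with the implementation."""
    import math

    out = []
    for _, groups in ft.CTD_ATTRIBUTES:
        lab = []
        for res in sequence:
            for gi, g in enumerate(groups):
                if res in g:
                    lab.append(gi)
        L = len(lab)
        comp = [lab.count(g) / L for g in range(3)]
        t12 = t13 = t23 = 0
        for a, b in zip(lab, lab[1:]):
            pair = {a, b}
            if pair == {0, 1}:
                t12 += 1
            elif pair == {0, 2}:
                t13 += 1
            elif pair == {1, 2}:
                t23 += 1
        trans = [t12 / (L - 1), t13 / (L - 1), t23 / (L - 1)]
        dist = []
        for g in range(3):
            occ = [i + 1 for i, x in enumerate(lab) if x == g]
            if not occ:
                dist.extend([0.0] * 5)
                continue
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                k = 1 if frac == 0 else math.ceil(frac * len(occ))
                dist.append(100.0 * occ[k - 1] / L)
        out.extend(comp + trans + dist)
    return np.array(out)


class TestCtd:
    def test_homopolymer_composition_and_transitions(self):
        v = ft.ctd("AAAAA")
        for att in range(7):
            block = v[att * 21 : (att + 1) * 21]
            assert block[:3].sum() == pytest.approx(1.0)
            assert np.count_nonzero(block[:3]) == 1  # single group holds all A's
            np.testing.assert_array_equal(block[3:6], 0.0)

    def test_distribution_percentile_rule_at_length_four(self):
        v = ft.ctd("AAAA")
        # for A's group in every attribute the distribution block is
        # [25, 25, 50, 75, 100]
        for att, (_, groups) in enumerate(ft.CTD_ATTRIBUTES):
            g = next(i for i, grp in enumerate(groups) if "A" in grp)
            block = v[att * 21 + 6 + g * 5 : att * 21 + 6 + g * 5 + 5]
            np.testing.assert_allclose(block, [25, 25, 50, 75, 100])

    def test_same_group_pair_has_zero_transitions(self):
        # A and G share the hydrophobicity 'neutral' group
        v = ft.ctd("AG")
        hydro = v[:21]
        np.testing.assert_array_equal(hydro[3:6], [0.0, 0.0, 0.0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            L = int(rng.integers(2, 16))
            seq = "".join(rng.choice(list(ft.AMINO_ACIDS), size=L))
            np.testing.assert_allclose(ft.ctd(seq), ctd_oracle(seq), atol=1e-12)

    def test_value_ranges(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(ft.AMINO_ACIDS), size=200))
        v = ft.ctd(seq)
        for att in range(7):
            block = v[att * 21 : (att + 1) * 21]
            assert block[:3].sum() == pytest.approx(1.0)
            assert np.all((block[3:6] >= 0) & (block[3:6] <= 1))
            assert np.all((block[6:] >= 0) & (block[6:] <= 100))


class TestProteinVector:
    def test_dimension_and_ordering(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(ft.AMINO_ACIDS), size=120))
        v = ft.protein_vector(seq)
        assert v.shape == (567,)
        np.testing.assert_array_equal(v[:20], ft.aac(seq))
        np.testing.assert_array_equal(v[20:420], ft.dpc(seq))
        np.testing.assert_array_equal(v[420:], ft.ctd(seq))

    def test_deterministic(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        np.testing.assert_array_equal(ft.protein_vector(seq), ft.protein_vector(seq))


class TestAssembleMatrix:
    def test_schema_and_scaling(self, small_dataset, small_curated):
        proteins, _, _, _ = small_dataset
        pairs, _ = small_curated
        keys = list(zip(pairs["canonical_smiles"], pairs["uniprot_id"]))[:50]
        mat = ft.assemble_matrix(keys, proteins)
        assert mat.n_features == 4096 + 8 + 567 == 4671
        assert set(np.unique(mat.block("fingerprint"))) <= {0.0, 1.0}
        cont = mat.values[:, 4096:]
        varying = mat.scaler_scale != 1.0
        assert np.allclose(cont.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(cont.std(axis=0)[varying], 1.0, atol=1e-8)

    def test_scaler_reuse_on_held_out_rows(self, small_dataset, small_curated):
        proteins, _, _, _ = small_dataset
        pairs, _ = small_curated
        keys = list(zip(pairs["canonical_smiles"], pairs["uniprot_id"]))
        train = ft.assemble_matrix(keys[:40], proteins, n_bits=256)
        valid = ft.assemble_matrix(
            keys[40:60], proteins, n_bits=256,
            scaler=(train.scaler_mean, train.scaler_scale),
        )
        np.testing.assert_array_equal(valid.scaler_mean, train.scaler_mean)
        # held-out rows are not exactly standardized
        assert not np.allclose(valid.values[:, 256:].mean(axis=0), 0.0, atol=1e-8)

    def test_duplicate_pairs_identical_rows_and_row_permutation(self, small_dataset):
        proteins, ligands, _, _ = small_dataset
        pid = next(iter(proteins))
        keys = [(ligands[0], pid), (ligands[1], pid), (ligands[0], pid)]
        mat = ft.assemble_matrix(keys, proteins, n_bits=128)
        np.testing.assert_array_equal(mat.values[0], mat.values[2])
        permuted = ft.assemble_matrix(keys[::-1], proteins, n_bits=128,
                                      scaler=(mat.scaler_mean, mat.scaler_scale))
        np.testing.assert_allclose(permuted.values, mat.values[::-1])

    def test_missing_sequence_named(self, small_dataset):
        _, ligands, _, _ = small_dataset
        with pytest.raises(KeyError, match="P99999"):
            ft.assemble_matrix([(ligands[0], "P99999")], {})
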