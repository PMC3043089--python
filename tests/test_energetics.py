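import numpy as np
import pytest

from trpmhc.energetics import (
    PotentialTable,
    TableFormatError,
    ThermoConstants,
    binding_energy,
    binding_energy_bruteforce,
    dg_from_kd,
    kd_from_dg,
    load_default_table,
    load_potential_table,
    train_dfire_table,
)
from trpmhc.structures import Atom, Chain, ChainRole, ComplexStructure, Residue
from trpmhc.synth import ToyComplexSpec, generate_toy_complex

from conftest import rigid_transform


def _atom_unit(uid, name, resname, xyz, role=ChainRole.MHC_ALPHA, chain="A"):
    res = Residue(resname, (1, ""), (Atom(name, name[0], tuple(xyz)),))
    return ComplexStructure(id=uid, chains={chain: Chain(chain, role, [res])})


@pytest.fixture(scope="module")
def toy_table():
    return load_default_table()


@pytest.fixture()
def two_type_table(tmp_path):
    u = np.zeros((2, 2, 2))
    u[0, 1] = u[1, 0] = [-1.0, -0.25]
    u[0, 0] = [0.5, 0.0]
    return PotentialTable(
        atom_typing="residue",
        types=["ASP", "LYS"],
        bin_edges=np.array([0.0, 4.0, 8.0]),
        u_bar=u,
        table_id="two-type",
    )


class TestTableIO:
    def test_roundtrip_exact(self, two_type_table, tmp_path):
        p = tmp_path / "t.tsv"
        two_type_table.save(p)
        back = load_potential_table(p)
        assert back.types == two_type_table.types
        assert np.array_equal(back.bin_edges, two_type_table.bin_edges)
        assert np.array_equal(back.u_bar, two_type_table.u_bar)

    def test_asymmetric_entries_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#typing\tresidue\n#bin_edges\t0\t4\n"
            "type_i\ttype_j\tbin_index\tu_bar\n"
            "ASP\tLYS\t0\t-1.0\nLYS\tASP\t0\t-2.0\n"
        )
        with pytest.raises(TableFormatError, match="asymmetric"):
            load_potential_table(p)

    def test_nonmonotone_bins_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#typing\tresidue\n#bin_edges\t0\t4\t3\n"
            "type_i\ttype_j\tbin_index\tu_bar\nASP\tASP\t0\t1.0\n"
        )
        with pytest.raises(TableFormatError, match="increasing"):
            load_potential_table(p)

    def test_declared_bin_arithmetic(self):
        # 29 half-Angstrom bins running out to a 14.5 A cutoff
        edges = np.arange(0.0, 14.5 + 0.25, 0.5)
        t = PotentialTable(
            atom_typing="residue",
            types=["GLY"],
            bin_edges=edges,
            u_bar=np.zeros((1, 1, len(edges) - 1)),
        )
        assert t.n_bins == 29
        assert t.r_cut == pytest.approx(14.5)

    def test_missing_entries_counted(self, tmp_path):
        p = tmp_path / "sparse.tsv"
        p.write_text(
            "#typing\tresidue\n#bin_edges\t0\t4\t8\n"
            "type_i\ttype_j\tbin_index\tu_bar\nASP\tLYS\t0\t-1.0\n"
        )
        t = load_potential_table(p)
        assert t.n_missing_filled > 0
        assert t.lookup("ASP", "ASP", 1.0) == 0.0


class TestBindingEnergy:
    def test_beyond_cutoff_is_zero(self, two_type_table):
        a = _atom_unit("a", "CA", "ASP", (0, 0, 0))
        b = _atom_unit("b", "CA", "LYS", (20, 0, 0), role=ChainRole.TR_ALPHA, chain="D")
        r = binding_energy(a, b, two_type_table)
        assert r.be == 0.0 and r.n_pairs_scored == 0

    def test_symmetric_in_units(self, toy_units, toy_table):
        pmhc, tr = toy_units
        assert binding_energy(pmhc, tr, toy_table).be == pytest.approx(
            binding_energy(tr, pmhc, toy_table).be
        )

    def test_hand_evaluated_single_pair(self, two_type_table):
        a = _atom_unit("a", "CA", "ASP", (0, 0, 0))
        b = _atom_unit("b", "CA", "LYS", (5.0, 0, 0), role=ChainRole.TR_ALPHA, chain="D")
        r = binding_energy(a, b, two_type_table)
        # 5.0 A falls in the [4, 8) bin where u(ASP, LYS) = -0.25
        assert r.be == pytest.approx(-0.25)
        assert r.n_pairs_scored == 1

    def test_additive_over_disjoint_partners(self, toy_units, toy_table):
        pmhc, tr = toy_units
        chains = list(tr.chains)
        part1 = ComplexStructure(id="p1", chains={chains[0]: tr.chains[chains[0]]})
        part2 = ComplexStructure(id="p2", chains={chains[1]: tr.chains[chains[1]]})
        whole = binding_energy(pmhc, tr, toy_table).be
        split = binding_energy(pmhc, part1, toy_table).be + binding_energy(pmhc, part2, toy_table).be
        assert whole == pytest.approx(split, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_complex, toy_table):
        from trpmhc.structures import truncate_complex

        structure, _ = toy_complex
        rot, t = rigid_transform(np.random.default_rng(4))
        moved = _apply_rigid(structure, rot, t)
        p0, t0 = truncate_complex(structure)
        p1, t1 = truncate_complex(moved)
        assert binding_energy(p1, t1, toy_table).be == pytest.approx(
            binding_energy(p0, t0, toy_table).be, abs=1e-9
        )

    def test_extending_cutoff_with_zero_bins_is_noop(self, two_type_table, toy_units):
        pmhc, tr = toy_units
        extended = PotentialTable(
            atom_typing="residue",
            types=two_type_table.types,
            bin_edges=np.concatenate([two_type_table.bin_edges, [12.0, 16.0]]),
            u_bar=np.concatenate(
                [two_type_table.u_bar, np.zeros((2, 2, 2))], axis=2
            ),
        )
        assert binding_energy(pmhc, tr, extended).be == pytest.approx(
            binding_energy(pmhc, tr, two_type_table).be
        )

    def test_matches_bruteforce_exactly(self, toy_units, toy_table):
        pmhc, tr = toy_units
        fast = binding_energy(pmhc, tr, toy_table).be
        slow = binding_energy_bruteforce(pmhc, tr, toy_table)
        assert fast == pytest.approx(slow, abs=1e-9)


def _apply_rigid(c, rot, t):
    from trpmhc.structures import Chain, ComplexStructure, Residue, Atom

    out = ComplexStructure(id=c.id, mhc_class=c.mhc_class)
    for cid, chain in c.chains.items():
        residues = []
        for res in chain:
            atoms = tuple(
                Atom(a.name, a.element, tuple(rot @ a.xyz + t), a.occupancy, a.altloc, a.is_hetero)
                for a in res.atoms
            )
            residues.append(Residue(res.name, res.seq_id, atoms))
        out.chains[cid] = Chain(cid, chain.role, residues)
    return out


class TestThermo:
    def test_kd_one_molar_is_zero(self):
        assert dg_from_kd(1.0) == 0.0

    def test_antisymmetry(self):
        assert dg_from_kd(1e-3) == pytest.approx(-dg_from_kd(1e3))

    def test_micromolar_reference_value(self):
        # R = 1.987e-3 kcal/(mol K), T = 298.15 K, Kd = 1 uM
        assert dg_from_kd(1e-6, ThermoConstants()) == pytest.approx(-8.18, abs=0.01)

    def test_kd_roundtrip(self):
        assert kd_from_dg(dg_from_kd(3.2e-9)) == pytest.approx(3.2e-9)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            dg_from_kd(0.0)


@pytest.fixture(scope="module")
def trained():
    structures = [
        generate_toy_complex(ToyComplexSpec(theta_true=30 + 10 * i, seed=i))[0]
        for i in range(4)
    ]
    return train_dfire_table(structures, bin_edges=np.arange(0.0, 15.5, 1.0))


class TestDfireTrainer:
    def test_symmetric_and_zero_at_cutoff(self, trained):
        assert np.allclose(trained.u_bar, np.swapaxes(trained.u_bar, 0, 1))
        assert np.all(trained.u_bar[:, :, -1] == 0.0)

    def test_usable_for_scoring(self, trained, toy_units):
        pmhc, tr = toy_units
        r = binding_energy(pmhc, tr, trained)
        assert np.isfinite(r.be) and r.n_pairs_scored > 0

    def test_roundtrips_through_file(self, trained, tmp_path):
        p = tmp_path / "trained.tsv"
        trained.save(p)
        back = load_potential_table(p)
        got = {t: i for i, t in enumerate(back.types)}
        for t1 in back.types:
            for t2 in back.types:
                i1, i2 = trained.types.index(t1), trained.types.index(t2)
                assert np.allclose(
                    back.u_bar[got[t1], got[t2]], trained.u_bar[i1, i2], atol=1e-5
                )
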