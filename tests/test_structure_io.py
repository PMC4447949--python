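import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from etsface.errors import GeometryError, ParseError, SelectionError
from etsface.structure_io import (
    Atom,
    parse_structure,
    select,
    superpose,
    write_pdb,
)
from etsface.synthetic_structures import build_bdna, build_ets_like_complex


def test_write_parse_round_trip_preserves_coordinates(tmp_path):
    """PDB round trip is exact to the format's 3-decimal precision."""
    st, _ = build_ets_like_complex()
    path = tmp_path / "complex.pdb"
    write_pdb(st, path)
    st2 = parse_structure(path)
    assert st2.n_atoms == st.n_atoms
    assert np.abs(st.coords() - st2.coords()).max() < 5.1e-4
    kinds = {r.kind for r in st2.residues()}
    assert kinds == {"protein", "dna"}
    # author numbering preserved
    assert [r.seq_id for r in st2.chain("A").residues] == \
        [r.seq_id for r in st.chain("A").residues]


def test_parse_reads_model_1_only(tmp_path):
    """A two-model file yields only the first model's atoms; the expected
    count comes from an independent record-count of the MODEL 1 block."""
    st = build_bdna("ACGT")
    p1 = tmp_path / "m1.pdb"
    write_pdb(st, p1)
    body = p1.read_text().replace("END", "").rstrip()
    two_models = "MODEL        1\n" + body + "\nENDMDL\nMODEL        2\n" + \
        body + "\nENDMDL\nEND\n"
    p2 = tmp_path / "two_models.pdb"
    p2.write_text(two_models)
    # oracle: count ATOM/HETATM lines inside the first MODEL block
    n_expected = 0
    in_first = False
    for line in two_models.splitlines():
        if line.startswith("MODEL"):
            in_first = line.split()[1] == "1"
        if in_first and line[:6] in ("ATOM  ", "HETATM"):
            n_expected += 1
    assert parse_structure(p2).n_atoms == n_expected


def test_parse_errors(tmp_path):
    with pytest.raises(ParseError):
        parse_structure(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(ParseError):
        parse_structure(empty)


class TestSelect:
    def test_select_all_is_identity(self, consensus_duplex):
        sub = select(consensus_duplex, "all")
        assert sub.n_atoms == consensus_duplex.n_atoms

    def test_empty_selection_flagged_not_error(self, consensus_duplex):
        with pytest.warns(UserWarning):
            sub = select(consensus_duplex, "kind water")
        assert sub.n_atoms == 0
        assert sub.meta.get("empty") is True

    def test_residue_range_matches_bruteforce(self):
        st, _ = build_ets_like_complex()
        sub = select(st, "chain A and res 379-399")
        expected = sum(len(r.atoms) for ch in st.chains if ch.id == "A"
                       for r in ch.residues if 379 <= r.seq_id <= 399)
        assert sub.n_atoms == expected

    def test_negation_and_atom_names(self, consensus_duplex):
        sub = select(consensus_duplex, "name P,OP1,OP2")
        with_p = select(consensus_duplex, "not name P,OP1,OP2")
        assert sub.n_atoms + with_p.n_atoms == consensus_duplex.n_atoms
        # both strands omit the 5'-terminal phosphate group
        assert sub.n_atoms == 3 * (10 - 1) * 2

    def test_selection_idempotent(self, consensus_duplex):
        expr = "chain X and element P"
        once = select(consensus_duplex, expr)
        twice = select(once, expr)
        assert twice.n_atoms == once.n_atoms

    def test_malformed_expression_reports_position(self):
        st = build_bdna("ACGT")
        with pytest.raises(SelectionError) as err:
            select(st, "chain X and bogus Y")
        assert err.value.position is not None


class TestSuperpose:
    def test_self_superposition_is_identity(self, consensus_duplex):
        pairs = [(a, a) for a in consensus_duplex.atoms()]
        res = superpose(consensus_duplex, consensus_duplex, pairs)
        assert res.rmsd < 1e-10
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_recovers_planted_rotation(self, consensus_duplex):
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t = np.array([5.0, -3.0, 12.0])
        moved = consensus_duplex.transformed(R, t)
        pairs = list(zip(moved.atoms(), consensus_duplex.atoms()))
        res = superpose(moved, consensus_duplex, pairs)
        assert res.rmsd < 1e-8
        assert np.allclose(res.rotation @ R, np.eye(3), atol=1e-6)

    def test_rmsd_symmetric_and_rotation_orthonormal(self, rng):
        from etsface.structure_io import Chain, Residue, Structure

        def cloud(seed):
            r = np.random.default_rng(seed)
            st = Structure(id=f"cloud{seed}")
            ch = Chain(id="A")
            for i, xyz in enumerate(r.normal(0, 5, (10, 3))):
                res = Residue(name="ALA", seq_id=i + 1, chain_id="A")
                res.atoms.append(Atom(name="CA", element="C", xyz=xyz))
                ch.residues.append(res)
            st.chains.append(ch)
            return st

        a, b = cloud(1), cloud(2)
        fwd = superpose(a, b, list(zip(a.atoms(), b.atoms())))
        rev = superpose(b, a, list(zip(b.atoms(), a.atoms())))
        assert fwd.rmsd == pytest.approx(rev.rmsd, abs=1e-10)
        assert np.allclose(fwd.rotation.T @ fwd.rotation, np.eye(3), atol=1e-8)
        assert np.linalg.det(fwd.rotation) == pytest.approx(1.0, abs=1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_quaternion_oracle(self, seed):
        """Kabsch equals the independent quaternion-eigenvalue solution."""
        r = np.random.default_rng(seed)
        P = r.normal(0, 4, (10, 3))
        Q = r.normal(0, 4, (10, 3))
        from etsface.structure_io import kabsch
        _, _, rmsd = kabsch(P, Q)

        # oracle: Horn's closed form via the quaternion 4x4 eigenproblem
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        Sxx, Sxy, Sxz = (Pc[:, 0] @ Qc[:, 0], Pc[:, 0] @ Qc[:, 1], Pc[:, 0] @ Qc[:, 2])
        Syx, Syy, Syz = (Pc[:, 1] @ Qc[:, 0], Pc[:, 1] @ Qc[:, 1], Pc[:, 1] @ Qc[:, 2])
        Szx, Szy, Szz = (Pc[:, 2] @ Qc[:, 0], Pc[:, 2] @ Qc[:, 1], Pc[:, 2] @ Qc[:, 2])
        K = np.array([
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
        lam = np.linalg.eigvalsh(K)[-1]
        e2 = ((Pc ** 2).sum() + (Qc ** 2).sum() - 2 * lam) / len(P)
        assert rmsd == pytest.approx(np.sqrt(max(e2, 0.0)), abs=1e-4)

    def test_too_few_or_collinear_pairs(self, consensus_duplex):
        atoms = list(consensus_duplex.atoms())
        with pytest.raises(GeometryError):
            superpose(consensus_duplex, consensus_duplex,
                      [(atoms[0], atoms[0]), (atoms[1], atoms[1])])
        from etsface.structure_io import Chain, Residue, Structure
        line = Structure(id="line")
        ch = Chain(id="A")
        for i in range(5):
            res = Residue(name="GLY", seq_id=i + 1, chain_id="A")
            res.atoms.append(Atom(name="CA", element="C",
                                  xyz=np.array([float(i), 0.0, 0.0])))
            ch.residues.append(res)
        line.chains.append(ch)
        pairs = [(a, a) for a in line.atoms()]
        with pytest.raises(GeometryError):
            superpose(line, line, pairs)
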