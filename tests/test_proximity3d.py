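"""3D environments: parsing, terminal-atom distances, burden, clustering."""

import numpy as np
import pandas as pd
import pytest

from cpdaa.proximity3d import (
    StructureModel,
    StructureResidue,
    candidate_filter,
    cluster_burden,
    compute_environments,
    environment_burden,
    parse_structure,
    rank_by_vus,
    residue_environment,
    terminal_atom_name,
    type_enrichment_3d,
    union_environments,
)
from cpdaa.sequence_io import ProteinRecord
from cpdaa.simulate import (
    HelixGeometry,
    SimConfig,
    helix_ca_chord,
    simulate_proteome,
    structure_map_rows,
    write_structure_pdb,
)
from cpdaa.variants import classify_variants


def toy_model(residues):
    """residues: list of (chain, num, name, [(atom, xyz), ...])"""
    return StructureModel("toy", [
        StructureResidue(c, n, name, [a for a, _ in atoms],
                         np.array([xyz for _, xyz in atoms], dtype=float))
        for c, n, name, atoms in residues
    ])


def toy_map(n, accession="P1", chain="A"):
    return pd.DataFrame({
        "accession": accession, "position": range(1, n + 1),
        "structure_id": "toy", "chain": chain,
        "structure_residue_number": range(1, n + 1),
        "structure_aa": "?", "aa_match": True,
    })


class TestTerminalAtom:
    @pytest.mark.parametrize("rtype,atom", [("C", "SG"), ("K", "NZ"), ("Y", "OH")])
    def test_mapping(self, rtype, atom):
        assert terminal_atom_name(rtype) == atom

    def test_unsupported(self):
        with pytest.raises(ValueError):
            terminal_atom_name("A")


class TestParseStructure:
    def test_minimal_and_roundtrip(self, tmp_path):
        prot = ProteinRecord("P1", "G1", "ACKY")
        path = tmp_path / "s.pdb"
        geom = HelixGeometry()
        write_structure_pdb(prot, path, geom)
        model = parse_structure(path)
        assert len(model.residues) == 4
        # coordinates round-trip at PDB precision (3 decimals)
        from cpdaa.simulate import structure_atoms
        expected = structure_atoms(prot, geom)
        got = {(r.chain, r.number, a): r.coords[i]
               for r in model.residues for i, a in enumerate(r.atom_names)}
        for chain, num, resname, name, xyz in expected:
            assert np.allclose(got[(chain, num, name)], np.round(xyz, 3), atol=1e-9)

    def test_altloc_first_kept(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      3  CA  CYS A   2       3.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        model = parse_structure(path)
        ala = model.residues[0]
        assert len(ala.coords) == 1
        assert np.allclose(ala.coords[0], [0, 0, 0])

    def test_waters_excluded(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        path = tmp_path / "w.pdb"
        path.write_text(pdb)
        model = parse_structure(path)
        assert len(model.residues) == 1


class TestResidueEnvironment:
    def test_three_four_five_triangle(self):
        model = toy_model([
            ("A", 1, "CYS", [("CA", (1, 1, 1)), ("SG", (0, 0, 0))]),
            ("A", 2, "ALA", [("CA", (3, 4, 0)), ("CB", (6, 8, 0))]),
            ("A", 3, "ALA", [("CA", (0, 0, 10.5))]),
        ])
        smap = toy_map(3)
        row = {"accession": "P1", "position": 1, "residue_type": "C"}
        env = residue_environment(model, smap, row)
        assert set(env["neighbor_position"]) == {2}
        assert env["min_distance"].iloc[0] == pytest.approx(5.0)

    def test_missing_terminal_atom_skipped(self):
        model = toy_model([("A", 1, "CYS", [("CA", (0, 0, 0))])])
        row = {"accession": "P1", "position": 1, "residue_type": "C"}
        assert residue_environment(model, toy_map(1), row) is None

    def test_other_chain_included_same_position_excluded(self):
        model = toy_model([
            ("A", 1, "CYS", [("SG", (0, 0, 0))]),
            ("B", 1, "CYS", [("SG", (4, 0, 0))]),   # chain copy of position 1
            ("B", 2, "ALA", [("CA", (0, 3, 0))]),
        ])
        smap = pd.concat([toy_map(2, chain="A"), toy_map(2, chain="B")],
                         ignore_index=True)
        row = {"accession": "P1", "position": 1, "residue_type": "C"}
        env = residue_environment(model, smap, row)
        # chain B copy of residue 1 excluded; chain B residue 2 included
        assert set(env["neighbor_position"]) == {2}
        assert set(env["chain"]) == {"B"}


def brute_force_neighbors(pdb_path, anchor_chain, anchor_resnum, anchor_atom,
                          max_radius=10.0):
    """Independent oracle: parse ATOM records by fixed columns and do a
    quadratic all-atom scan."""
    atoms = []
    for line in open(pdb_path):
        if not line.startswith("ATOM"):
            continue
        atoms.append({
            "name": line[12:16].strip(),
            "chain": line[21],
            "resnum": int(line[22:26]),
            "xyz": np.array([float(line[30:38]), float(line[38:46]),
                             float(line[46:54])]),
        })
    anchor = next(a["xyz"] for a in atoms
                  if a["chain"] == anchor_chain and a["resnum"] == anchor_resnum
                  and a["name"] == anchor_atom)
    best: dict = {}
    for a in atoms:
        key = (a["chain"], a["resnum"])
        d = float(np.linalg.norm(a["xyz"] - anchor))
        if key not in best or d < best[key]:
            best[key] = d
    return {k: v for k, v in best.items() if v <= max_radius}


class TestOracleEquivalence:
    def test_fifty_seeded_structures(self, tmp_path):
        """Environment computation equals a brute-force all-atom scan and
        cutoff nesting holds, over 50 seeded helix structures."""
        geom = HelixGeometry()
        n_checked = 0
        for seed in range(50):
            cfg = SimConfig(n_proteins=1, length_range=(25, 40), seed=seed)
            rng = cfg.rng()
            proteins, _ = simulate_proteome(cfg, rng)
            prot = proteins[0]
            two = seed % 2 == 0
            path = tmp_path / f"s{seed}.pdb"
            write_structure_pdb(prot, path, geom, two_chains=two, chain_offset=6.0)
            model = parse_structure(path)
            smap = structure_map_rows(prot, f"s{seed}", two_chains=two)
            cky = [(i + 1, aa) for i, aa in enumerate(prot.sequence) if aa in "CKY"]
            for pos, aa in cky[:3]:
                row = {"accession": prot.accession, "position": pos,
                       "residue_type": aa}
                env = residue_environment(model, smap, row)
                assert env is not None
                oracle = brute_force_neighbors(
                    path, "A", pos, terminal_atom_name(aa))
                # collapse oracle to sequence positions (min over chain copies),
                # dropping the anchor's own position
                by_pos: dict = {}
                for (chain, resnum), d in oracle.items():
                    if resnum == pos:
                        continue
                    by_pos[resnum] = min(d, by_pos.get(resnum, np.inf))
                impl = env.groupby("neighbor_position")["min_distance"].min().to_dict()
                assert set(impl) == set(by_pos)
                for p, d in by_pos.items():
                    assert abs(impl[p] - round(d, 3)) <= 1e-9
                # nesting across cutoffs
                n6 = set(env.loc[env["min_distance"] <= 6, "neighbor_position"])
                n8 = set(env.loc[env["min_distance"] <= 8, "neighbor_position"])
                n10 = set(env["neighbor_position"])
                assert n6 <= n8 <= n10
                n_checked += 1
        assert n_checked >= 50

    def test_helix_chord_closed_form(self):
        geom = HelixGeometry()
        from cpdaa.simulate import helix_coords
        for delta in (1, 2, 5):
            d = np.linalg.norm(helix_coords(delta, geom) - helix_coords(0, geom))
            assert d == pytest.approx(helix_ca_chord(delta, geom), abs=1e-6)


def env_frame(rows):
    return pd.DataFrame(rows, columns=[
        "accession", "cpdaa_position", "residue_type", "structure_id",
        "neighbor_position", "chain", "min_distance"])


class TestEnvironmentBurden:
    def test_allele_uniqueness_unit(self):
        env = env_frame([
            ("P1", 50, "C", "s1", 100, "A", 4.0),
            ("P1", 50, "C", "s1", 104, "A", 6.0),
        ])
        raw = pd.DataFrame([
            {"accession": "P1", "position": 100, "ref_aa": "A", "alt_aa": "V",
             "ref_codon": "GCT", "alt_codon": "GTT",
             "clinical_label": "pathogenic", "allele_frequency": float("nan")},
            {"accession": "P1", "position": 100, "ref_aa": "A", "alt_aa": "D",
             "ref_codon": "GCT", "alt_codon": "GAT",
             "clinical_label": "pathogenic", "allele_frequency": float("nan")},
        ])
        v, _ = classify_variants(raw)
        b = environment_burden(env, v, cutoff=8)
        assert b["count_pathogenic"].iloc[0] == 2

    def test_union_across_structures(self):
        env = env_frame([
            ("P1", 50, "C", "s1", 100, "A", 4.0),
            ("P1", 50, "C", "s2", 104, "A", 6.0),
            ("P1", 50, "C", "s2", 100, "A", 7.0),
        ])
        uni = union_environments(env)
        assert set(uni["neighbor_position"]) == {100, 104}
        assert uni.set_index("neighbor_position")["min_distance"][100] == 4.0

    def test_union_never_exceeds_contributors(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in ("s1", "s2", "s3"):
            for p in rng.choice(np.arange(10, 40), size=10, replace=False):
                rows.append(("P1", 5, "C", s, int(p), "A",
                             round(float(rng.uniform(2, 10)), 3)))
        env = env_frame(rows)
        uni = union_environments(env).set_index("neighbor_position")["min_distance"]
        for _, r in env.iterrows():
            assert uni[r["neighbor_position"]] <= r["min_distance"]


class TestTypeEnrichment3D:
    def test_arithmetic_example(self):
        rows = []
        for i in range(4):
            rows.append({"accession": "P1", "cpdaa_position": i + 1,
                         "residue_type": "C", "contains_pathogenic": i < 3})
        for i in range(8):
            rows.append({"accession": "P1", "cpdaa_position": i + 10,
                         "residue_type": "K", "contains_pathogenic": i < 2})
        res = type_enrichment_3d(pd.DataFrame(rows))
        by = {r.label: r for r in res}
        assert by["C:pathogenic"].table.tolist() == [[3, 1], [2, 6]]
        assert by["C:pathogenic"].odds_ratio == pytest.approx(9.0)

    def test_single_type_rejected(self):
        df = pd.DataFrame([{"accession": "P1", "cpdaa_position": 1,
                            "residue_type": "C", "contains_pathogenic": True}])
        with pytest.raises(ValueError):
            type_enrichment_3d(df)


class TestRankByVus:
    def make_burdens(self, counts):
        return pd.DataFrame([
            {"accession": acc, "cpdaa_position": pos, "residue_type": "C",
             "count_vus": n, "count_pathogenic": 0, "count_background": 0}
            for (acc, pos), n in counts.items()
        ])

    def test_order_and_ties(self):
        b = self.make_burdens({("a", 1): 10, ("b", 1): 3, ("c", 1): 7,
                               ("a", 2): 10})
        cadd = pd.DataFrame(columns=["accession", "position", "mean_phred",
                                     "deleterious"])
        ranked, frac = rank_by_vus(b, cadd, k=4)
        assert list(zip(ranked["accession"], ranked["cpdaa_position"])) == \
            [("a", 1), ("a", 2), ("c", 1), ("b", 1)]
        assert frac == 0.0

    def test_deleterious_fraction(self):
        b = self.make_burdens({("a", 1): 10, ("b", 1): 3})
        cadd = pd.DataFrame([{"accession": "a", "position": 1,
                              "mean_phred": 30.0, "deleterious": True}])
        ranked, frac = rank_by_vus(b, cadd, k=2)
        assert bool(ranked.iloc[0]["deleterious"])
        assert frac == 0.5


class TestClusterBurden:
    def test_toy_two_groups(self):
        m = pd.DataFrame({
            "count_pathogenic": [10, 12, 2, 2, 3],
            "count_vus": [10, 12, 1, 2, 2],
            "count_background": [5, 6, 1, 1, 1],
        })
        out = cluster_burden(m)
        assert list(out["burden_group"]) == ["high", "high", "low", "low", "low"]
        assert list(out["total_missense"]) == [25, 30, 4, 5, 6]

    def test_identical_rows_degenerate(self):
        m = pd.DataFrame({"count_pathogenic": [2, 2, 2],
                          "count_vus": [2, 2, 2]})
        out = cluster_burden(m)
        assert out.attrs["degenerate"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_burden(pd.DataFrame({"count_vus": [1]}))

    def test_fh_like_separation(self):
        # 3 residues with >20 local alleles, 13 with <10: high group size 3
        rng = np.random.default_rng(6)
        rows = []
        for i in range(3):
            rows.append({"count_pathogenic": int(rng.integers(4, 8)),
                         "count_vus": int(rng.integers(15, 25)),
                         "count_background": int(rng.integers(2, 6))})
        for i in range(13):
            rows.append({"count_pathogenic": int(rng.integers(0, 3)),
                         "count_vus": int(rng.integers(0, 5)),
                         "count_background": int(rng.integers(0, 3))})
        out = cluster_burden(pd.DataFrame(rows))
        assert (out["burden_group"] == "high").sum() == 3
        assert (out.loc[out["burden_group"] == "high", "total_missense"] > 20).all()


class TestCandidateFilter:
    def make(self):
        prots = [ProteinRecord("P1", "G1", "A" * 510),
                 ProteinRecord("P2", "G2", "A" * 1200)]
        raw = pd.DataFrame([
            {"accession": a, "position": p, "ref_aa": "A", "alt_aa": "V",
             "ref_codon": "GCT", "alt_codon": "GTT",
             "clinical_label": lab, "allele_frequency": af}
            for a in ("P1", "P2")
            for p, lab, af in [(1, "pathogenic", float("nan")),
                               (2, "benign", 0.2)]
        ])
        variants, _ = classify_variants(raw)
        cpdaa = pd.DataFrame({"accession": ["P1", "P2"], "position": [5, 5],
                              "residue_type": ["C", "C"]})
        burdens = pd.DataFrame([
            {"accession": "P1", "cpdaa_position": 5, "residue_type": "C",
             "contains_pathogenic": True},
            {"accession": "P2", "cpdaa_position": 5, "residue_type": "C",
             "contains_pathogenic": True},
        ])
        return prots, variants, cpdaa, burdens

    def test_length_criterion(self):
        prots, variants, cpdaa, burdens = self.make()
        out = candidate_filter(prots, variants, {"P1", "P2"}, cpdaa, burdens)
        by = out.set_index("accession")
        assert bool(by.loc["P1", "passes"])
        assert not bool(by.loc["P2", "passes"])
        assert not bool(by.loc["P2", "length_lt_1000"])

    def test_no_structure_fails(self):
        prots, variants, cpdaa, burdens = self.make()
        out = candidate_filter(prots, variants, set(), cpdaa, burdens)
        assert not out["passes"].any()
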