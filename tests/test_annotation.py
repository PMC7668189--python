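import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from var3d.annotation import (
    DEFAULT_AA_GROUPS,
    MAX_ASA_TIEN_2013,
    AnnotationConfig,
    DSSPParseError,
    StructureResidue,
    aa_groups,
    annotate_positions,
    bin_exposure,
    compute_rsa,
    consolidate,
    parse_dssp,
    parse_pdb_ca,
    ptm_proximity,
    read_residue_features,
    vectors_to_frame,
    write_residue_features,
)
from var3d.catalog import EXPOSURE_FEATURES
from var3d.simulate import write_dssp, write_pdb_ca


def _res(resnum, aa="A", ss="H", asa=50.0, ca=None, chain="A"):
    return StructureResidue("test", chain, resnum, aa, ss, asa, ca)


# ---------------------------------------------------------------------------
# DSSP parsing
# ---------------------------------------------------------------------------

def test_parse_dssp_roundtrip(tmp_path):
    residues = [
        _res(1, "M", "H", 120.0, np.array([0.0, 0.0, 0.0])),
        _res(2, "A", "I", 129.0, np.array([3.8, 0.0, 0.0])),  # π-helix line
        _res(3, "G", "-", 0.0, np.array([7.6, 0.0, 0.0])),
    ]
    path = tmp_path / "test.dssp"
    write_dssp(residues, path)
    parsed = parse_dssp(path)
    assert [r.resnum for r in parsed] == [1, 2, 3]
    assert parsed[1].ss == "I"
    assert parsed[1].asa == 129.0
    assert np.allclose(parsed[0].ca, [0.0, 0.0, 0.0])


def test_parse_dssp_empty_body(tmp_path):
    path = tmp_path / "empty.dssp"
    write_dssp([], path)
    assert parse_dssp(path) == []


def test_parse_dssp_skips_chain_breaks_and_maps_blank_ss(tmp_path):
    path = tmp_path / "breaks.dssp"
    write_dssp([_res(1, "A", "-", 10.0)], path)
    lines = path.read_text().splitlines()
    body = lines[-1]
    # blank structure column and an interleaved chain-break line
    blank_ss = body[:16] + " " + body[17:]
    brk = body[:13] + "!" + body[14:]
    path.write_text("\n".join(lines[:-1] + [blank_ss, brk]) + "\n")
    parsed = parse_dssp(path)
    assert len(parsed) == 1
    assert parsed[0].ss == "-"


def test_parse_dssp_malformed_line_reports_lineno(tmp_path):
    path = tmp_path / "bad.dssp"
    write_dssp([_res(1, "A")], path)
    lines = path.read_text().splitlines()
    lines[-1] = lines[-1][:34] + "abcd" + lines[-1][38:]
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(DSSPParseError, match="bad.dssp:4"):
        parse_dssp(path)


def test_parse_dssp_agrees_with_biopython(tmp_path):
    """Cross-check the fixed-column parser against Bio.PDB's DSSP reader."""
    from Bio.PDB.DSSP import make_dssp_dict

    residues = [
        _res(i, aa, ss, asa, np.array([3.8 * i, 0.0, 0.0]))
        for i, (aa, ss, asa) in enumerate(
            [("M", "H", 55.0), ("F", "E", 0.0), ("K", "T", 180.0), ("G", "S", 33.0)],
            start=1,
        )
    ]
    path = tmp_path / "xc.dssp"
    write_dssp(residues, path)
    ours = parse_dssp(path)
    theirs, _keys = make_dssp_dict(str(path))
    assert len(theirs) == len(ours)
    for r in ours:
        aa, ss, acc = theirs[("A", (" ", r.resnum, " "))][:3]
        assert (aa, ss, acc) == (r.aa, r.ss, int(r.asa))


def test_parse_pdb_ca(tmp_path):
    residues = [_res(i, "A", "H", 10.0, np.array([1.0 * i, 2.0, 3.0])) for i in (1, 2)]
    path = tmp_path / "fx.pdb"
    write_pdb_ca(residues, path)
    coords = parse_pdb_ca(path)
    assert set(coords) == {("A", 1), ("A", 2)}
    assert np.allclose(coords[("A", 2)], [2.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# RSA, exposure, amino-acid groups
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "asa,aa,expected",
    [
        (0.0, "F", 0.0),
        (129.0, "A", 1.0),  # at the MaxASA reference
        (64.5, "A", 0.5),
        (500.0, "G", 1.0),  # capped
    ],
)
def test_compute_rsa(asa, aa, expected):
    assert compute_rsa(asa, aa) == pytest.approx(expected)


def test_compute_rsa_unknown_residue():
    with pytest.raises(KeyError):
        compute_rsa(10.0, "B")


@pytest.mark.parametrize(
    "rsa,expected",
    [
        (0.03, "exp_core"),
        (0.05, "exp_buried"),  # left edge inclusive
        (0.249, "exp_buried"),
        (0.25, "exp_medium_buried"),
        (0.80, "exp_exposed"),
        (1.0, "exp_exposed"),
    ],
)
def test_bin_exposure(rsa, expected):
    assert bin_exposure(rsa) == expected


def test_bin_exposure_rejects_out_of_range():
    with pytest.raises(ValueError):
        bin_exposure(1.2)


@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
@settings(derandomize=True, max_examples=200)
def test_exposure_bins_partition_unit_interval(rsa):
    assert bin_exposure(rsa) in EXPOSURE_FEATURES


@pytest.mark.parametrize("aa", sorted(DEFAULT_AA_GROUPS))
def test_aa_groups_pure_function(aa):
    """Each of the 20 residues maps deterministically to one group."""
    first = aa_groups(aa)
    assert aa_groups(aa) == first
    assert len(first) == 1


def test_aa_groups_fixed_memberships():
    assert aa_groups("C") == {"aa_special"}
    assert aa_groups("W") == {"aa_aromatic"}
    with pytest.raises(ValueError):
        aa_groups("B")


def test_config_rejects_moving_fixed_groups():
    groups = dict(DEFAULT_AA_GROUPS, C="aa_polar")
    with pytest.raises(ValueError):
        AnnotationConfig(aa_groups=groups)


# ---------------------------------------------------------------------------
# PTM proximity
# ---------------------------------------------------------------------------

def test_ptm_proximity_no_sites():
    out = ptm_proximity(_res(1, ca=np.zeros(3)), [])
    assert all(flag is False and np.isnan(d) for flag, d in out.values())


def test_ptm_proximity_self_site_distance_zero():
    target = _res(5, "S", ca=np.array([1.0, 1.0, 1.0]))
    out = ptm_proximity(target, [(target, "phosphorylation")])
    assert out["phosphorylation"] == (True, 0.0)


@pytest.mark.parametrize("z,flag", [(9.9, True), (10.0, False)])
def test_ptm_proximity_strict_boundary(z, flag):
    target = _res(1, ca=np.zeros(3))
    site = _res(9, "S", ca=np.array([0.0, 0.0, z]))
    got_flag, dist = ptm_proximity(target, [(site, "sumoylation")])["sumoylation"]
    assert got_flag is flag
    assert dist == pytest.approx(z)


def test_ptm_proximity_missing_coordinates_warns():
    target = _res(1, ca=np.zeros(3))
    site = _res(2, "S", ca=None)
    with pytest.warns(UserWarning, match="skipped"):
        out = ptm_proximity(target, [(site, "phosphorylation")])
    assert out["phosphorylation"][0] is False


@given(
    st.floats(min_value=0.1, max_value=30.0),
    st.floats(min_value=0.1, max_value=30.0),
)
@settings(derandomize=True, max_examples=100)
def test_ptm_proximity_monotone_in_cutoff(dist, extra):
    """Raising the cutoff never clears a proximity flag."""
    target = _res(1, ca=np.zeros(3))
    site = _res(2, "S", ca=np.array([dist, 0.0, 0.0]))
    small = ptm_proximity(target, [(site, "methylation")],
                          AnnotationConfig(ptm_cutoff=dist + 0.001))
    large = ptm_proximity(target, [(site, "methylation")],
                          AnnotationConfig(ptm_cutoff=dist + 0.001 + extra))
    assert small["methylation"][0] <= large["methylation"][0]
    assert small["methylation"][0] is True


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def test_consolidate_worked_example_bits(catalog):
    """A BRCT-core phenylalanine near a phosphosite gets exactly the
    domain/core/strand/proximal/aromatic (+ input H-bond) bits."""
    target = _res(1704, "F", "E", 0.0, np.zeros(3), chain="X")
    site = _res(1708, "S", "E", 45.0, np.array([6.8, 0.0, 0.0]), chain="X")
    prox = ptm_proximity(target, [(site, "phosphorylation")])
    vec = consolidate(
        "BRCA1", 1704, "F", [target], [prox],
        bond_flags=["hydrogen"], region_features=["modular_domain"],
    )
    assert vec.features(catalog) == {
        "func_modular_domain", "exp_core", "ss_strand",
        "ptm_near_phosphorylation", "aa_aromatic", "bond_hydrogen",
    }
    assert vec.resolved


def test_consolidate_unmapped_glycine_only_physicochemical(catalog):
    vec = consolidate("P1", 10, "G", mapped=[])
    assert vec.features(catalog) == {"aa_special"}
    assert not vec.resolved


def test_consolidate_any_structure_rule_sets_both_exposure_bits(catalog):
    exposed = _res(7, "A", "H", 120.0)
    core = _res(7, "A", "H", 2.0, chain="B")
    vec = consolidate("P1", 7, "A", [exposed, core])
    feats = vec.features(catalog)
    assert {"exp_exposed", "exp_core"} <= feats


def test_consolidate_rejects_unknown_flags():
    with pytest.raises(KeyError):
        consolidate("P1", 1, "A", [], bond_flags=["covalent"])
    with pytest.raises(KeyError):
        consolidate("P1", 1, "A", [], region_features=["nonsense"])


# ---------------------------------------------------------------------------
# Pipeline & TSV round trip
# ---------------------------------------------------------------------------

def test_annotate_positions_end_to_end(catalog):
    dssp = {
        ("fx", "A"): {
            1: _res(1, "F", "E", 0.0, np.zeros(3)),
            2: _res(2, "S", "T", 80.0, np.array([4.0, 0.0, 0.0])),
        }
    }
    mapping = pd.DataFrame(
        {
            "pdb_id": ["fx", "fx"],
            "chain": ["A", "A"],
            "pdb_resnum": [1, 2],
            "protein": ["P1", "P1"],
            "uniprot_pos": [11, 12],
        }
    )
    ptm = pd.DataFrame(
        {"protein": ["P1"], "uniprot_pos": [12], "ptm_type": ["phosphorylation"]}
    )
    regions = pd.DataFrame(
        {"protein": ["P1"], "start": [10], "end": [11], "category": ["modular_domain"]}
    )
    df = annotate_positions(mapping, dssp, ptm, regions, catalog=catalog)
    assert len(df) == 2
    row11 = df[df["pos"] == 11].iloc[0]
    assert row11["ref_aa"] == "F"
    assert row11["ptm_near_phosphorylation"] == 1  # 4 Å < 10 Å
    assert row11["func_modular_domain"] == 1
    assert row11["exp_core"] == 1
    row12 = df[df["pos"] == 12].iloc[0]
    assert row12["ptm_site_phosphorylation"] == 1
    assert row12["func_modular_domain"] == 0


def test_residue_features_tsv_roundtrip(tmp_path, catalog):
    target = _res(3, "W", "B", 30.0)
    vec = consolidate("P2", 3, "W", [target], region_features=["motif"])
    df = vectors_to_frame([vec], catalog)
    path = tmp_path / "residue_features.tsv"
    write_residue_features(df, path)
    back = read_residue_features(path, catalog)
    pd.testing.assert_frame_equal(
        back, df.astype(back.dtypes.to_dict()), check_dtype=False
    )
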