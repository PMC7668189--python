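"""Residue-level structural annotation.

Turns raw structural inputs (DSSP output files, PDB coordinate files, a
SIFTS-like residue mapping, PTM-site and functional-region tables, plus
precomputed bond flags) into one binary 40-feature vector per UniProt
position. Structure-derived bits (secondary structure, exposure, PTM
proximity) follow an "any mapped structure" consolidation rule; the
physicochemical bits are a pure function of the reference amino acid;
bond and functional bits are consumed as input flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    BOND_FEATURES,
    DSSP_CODES,
    EXPOSURE_FEATURES,
    FUNCTIONAL_FEATURES,
    PTM_TYPES,
    SS_FEATURES,
    FeatureCatalog,
    default_catalog,
)

#: Theoretical maximum accessible surface area per residue (Å²),
#: Tien et al. 2013 ("theoretical" column); used to normalise DSSP ASA
#: into relative solvent accessibility. Configurable via AnnotationConfig.
MAX_ASA_TIEN_2013: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Editable default physicochemical grouping of the 20 standard residues.
#: Only 'special' (C, G, P) and 'aromatic' (F, W, Y) are fixed by
#: convention; the remaining memberships are a documented default.
DEFAULT_AA_GROUPS: dict[str, str] = {
    "A": "aa_aliphatic", "I": "aa_aliphatic", "L": "aa_aliphatic",
    "M": "aa_aliphatic", "V": "aa_aliphatic",
    "F": "aa_aromatic", "W": "aa_aromatic", "Y": "aa_aromatic",
    "D": "aa_charged", "E": "aa_charged", "H": "aa_charged",
    "K": "aa_charged", "R": "aa_charged",
    "S": "aa_neutral", "T": "aa_neutral",
    "N": "aa_polar", "Q": "aa_polar",
    "C": "aa_special", "G": "aa_special", "P": "aa_special",
}

_FIXED_GROUPS = {"C": "aa_special", "G": "aa_special", "P": "aa_special",
                 "F": "aa_aromatic", "W": "aa_aromatic", "Y": "aa_aromatic"}


@dataclass
class AnnotationConfig:
    """Tunables of the annotation stage.

    exposure_edges: interior RSA bin edges (fractions, strictly increasing);
        bins are half-open [lo, hi), so RSA = 0.05 is 'buried', not 'core'.
    ptm_cutoff: strict distance threshold in Å for PTM proximity (<10 Å).
    distance: 'ca' for Cα–Cα (default) — the only convention for which
        coordinates are generally available from DSSP output alone.
    """

    exposure_edges: tuple[float, ...] = (0.05, 0.25, 0.50, 0.75)
    ptm_cutoff: float = 10.0
    distance: str = "ca"
    max_asa: Mapping[str, float] = field(default_factory=lambda: dict(MAX_ASA_TIEN_2013))
    aa_groups: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_AA_GROUPS))

    def __post_init__(self) -> None:
        edges = tuple(self.exposure_edges)
        if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
            raise ValueError("exposure_edges must be strictly increasing")
        if not all(0.0 < e < 1.0 for e in edges):
            raise ValueError("exposure_edges must lie in (0, 1)")
        if len(edges) != len(EXPOSURE_FEATURES) - 1:
            raise ValueError("need one fewer edge than exposure bins")
        if self.ptm_cutoff <= 0:
            raise ValueError("ptm_cutoff must be positive")
        for aa, grp in self._fixed_violations():
            raise ValueError(f"{aa} must stay in group {grp}")

    def _fixed_violations(self):
        for aa, grp in _FIXED_GROUPS.items():
            if self.aa_groups.get(aa) != grp:
                yield aa, grp


@dataclass
class StructureResidue:
    """One residue line of a DSSP file (author numbering)."""

    pdb_id: str
    chain: str
    resnum: int
    aa: str
    ss: str
    asa: float
    ca: np.ndarray | None = None  # Cα coordinates in Å, or None

    def __post_init__(self) -> None:
        if self.asa < 0:
            raise ValueError("ASA must be non-negative")
        if self.ss not in DSSP_CODES:
            raise ValueError(f"unknown DSSP code {self.ss!r}")


@dataclass
class ResidueFeatureVector:
    """Consolidated binary feature vector for one UniProt position."""

    protein: str
    pos: int
    ref_aa: str
    bits: np.ndarray
    resolved: bool = True
    provenance: tuple[str, ...] = ()

    def features(self, catalog: FeatureCatalog) -> frozenset[str]:
        if len(self.bits) != len(catalog):
            raise ValueError("vector length does not match catalog size")
        return frozenset(fid for fid, b in zip(catalog.ids, self.bits) if b)


class DSSPParseError(ValueError):
    pass


def parse_dssp(path: str | Path) -> list[StructureResidue]:
    """Parse a DSSP output file into :class:`StructureResidue` records.

    Fixed-column format: residue lines follow the '  #  RESIDUE' header;
    chain breaks ('!') are skipped; a blank structure column maps to '-'.
    Cα coordinates are read when the line is long enough to carry them.
    """
    path = Path(path)
    pdb_id = path.stem
    residues: list[StructureResidue] = []
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not in_body:
                if line.startswith("  #  RESIDUE"):
                    in_body = True
                continue
            if len(line.rstrip("\n")) < 38:
                raise DSSPParseError(f"{path.name}:{lineno}: truncated residue line")
            aa = line[13]
            if aa == "!":  # chain break
                continue
            ss = line[16]
            if ss == " ":
                ss = "-"
            try:
                resnum = int(line[5:10])
                asa = float(line[34:38])
            except ValueError as exc:
                raise DSSPParseError(f"{path.name}:{lineno}: {exc}") from None
            ca = None
            if len(line) >= 136:
                try:
                    ca = np.array(
                        [float(line[115:122]), float(line[122:129]), float(line[129:136])]
                    )
                except ValueError:
                    ca = None
            try:
                residues.append(
                    StructureResidue(pdb_id, line[11], resnum, aa.upper(), ss, asa, ca)
                )
            except ValueError as exc:
                raise DSSPParseError(f"{path.name}:{lineno}: {exc}") from None
    return residues


def parse_pdb_ca(path: str | Path) -> dict[tuple[str, int], np.ndarray]:
    """Extract Cα coordinates from a PDB coordinate file.

    Returns ``{(chain, author residue number): xyz}``.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    coords: dict[tuple[str, int], np.ndarray] = {}
    model = next(structure.get_models())
    for chain in model:
        for res in chain:
            if "CA" in res:
                coords[(chain.id, res.id[1])] = np.asarray(
                    res["CA"].coord, dtype=float
                )
    return coords


def compute_rsa(asa: float, aa: str, table: Mapping[str, float] | None = None) -> float:
    """Relative solvent accessibility: ASA / MaxASA(aa), capped at 1."""
    table = MAX_ASA_TIEN_2013 if table is None else table
    if aa not in table:
        raise KeyError(f"no MaxASA reference for residue {aa!r}")
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    return min(1.0, asa / table[aa])


def bin_exposure(rsa: float, config: AnnotationConfig | None = None) -> str:
    """Map an RSA fraction to one of the five exposure features.

    Bins are half-open [lo, hi): RSA < 5% is core, 5% ≤ RSA < 25% buried,
    then 25/50/75% continuations; RSA = 1 falls in the last bin.
    """
    config = config or AnnotationConfig()
    if not 0.0 <= rsa <= 1.0:
        raise ValueError(f"RSA must be in [0, 1], got {rsa}")
    idx = int(np.searchsorted(config.exposure_edges, rsa, side="right"))
    return EXPOSURE_FEATURES[idx]


def aa_groups(aa: str, mapping: Mapping[str, str] | None = None) -> frozenset[str]:
    """Physicochemical group feature(s) of a standard residue letter.

    Pure function of the reference amino acid; returns a (singleton, under
    the default partition) set of group feature ids.
    """
    mapping = DEFAULT_AA_GROUPS if mapping is None else mapping
    aa = aa.upper()
    if aa not in mapping:
        raise ValueError(f"nonstandard amino-acid code {aa!r}")
    return frozenset([mapping[aa]])


def ptm_proximity(
    target: StructureResidue,
    sites: Sequence[tuple[StructureResidue, str]],
    config: AnnotationConfig | None = None,
) -> dict[str, tuple[bool, float]]:
    """Per-PTM-type proximity of ``target`` to annotated PTM sites.

    Returns ``{ptm_type: (flag, min_distance)}`` for every type in the
    catalog; flag is True iff the minimum Cα–Cα distance is strictly
    below the cutoff (default < 10 Å). A site that *is* the target yields
    distance 0. Sites without coordinates are skipped with a warning;
    types with no usable site report ``(False, nan)``.
    """
    config = config or AnnotationConfig()
    out: dict[str, tuple[bool, float]] = {t: (False, math.nan) for t in PTM_TYPES}
    if target.ca is None:
        warnings.warn(
            f"target {target.pdb_id}:{target.chain}{target.resnum} has no Cα; "
            "PTM proximity undetermined"
        )
        return out
    best: dict[str, float] = {}
    for site, ptype in sites:
        if ptype not in out:
            raise ValueError(f"unknown PTM type {ptype!r}")
        if site.ca is None:
            warnings.warn(
                f"PTM site {site.pdb_id}:{site.chain}{site.resnum} has no Cα; skipped"
            )
            continue
        d = float(np.linalg.norm(target.ca - site.ca))
        if ptype not in best or d < best[ptype]:
            best[ptype] = d
    for ptype, d in best.items():
        out[ptype] = (d < config.ptm_cutoff, d)
    return out


def consolidate(
    protein: str,
    pos: int,
    ref_aa: str,
    mapped: Sequence[StructureResidue],
    ptm_results: Iterable[Mapping[str, tuple[bool, float]]] = (),
    ptm_site_types: Iterable[str] = (),
    bond_flags: Iterable[str] = (),
    region_features: Iterable[str] = (),
    catalog: FeatureCatalog | None = None,
    config: AnnotationConfig | None = None,
) -> ResidueFeatureVector:
    """Build the consolidated feature vector for one UniProt position.

    Structure-derived bits (secondary structure, exposure, PTM proximity)
    are set if they fire in at least one mapped structure residue.
    Physicochemical bits come from ``ref_aa`` alone; bond and functional
    bits from input flags. With no mapped structure the record is flagged
    unresolved (structural bits absent) — such positions are excluded
    from burden analysis.
    """
    catalog = catalog or default_catalog()
    config = config or AnnotationConfig()
    bits = np.zeros(len(catalog), dtype=np.uint8)

    def set_bit(fid: str) -> None:
        bits[catalog.index(fid)] = 1

    for grp in aa_groups(ref_aa, config.aa_groups):
        set_bit(grp)

    for res in mapped:
        set_bit(SS_FEATURES[res.ss])
        set_bit(bin_exposure(compute_rsa(res.asa, res.aa, config.max_asa), config))
    for prox in ptm_results:
        for ptype, (flag, _dist) in prox.items():
            if flag:
                set_bit(f"ptm_near_{ptype}")
    for ptype in ptm_site_types:
        fid = f"ptm_site_{ptype}"
        if fid not in catalog.ids:
            raise KeyError(f"unknown PTM type {ptype!r}")
        set_bit(fid)
    for bond in bond_flags:
        fid = bond if bond.startswith("bond_") else f"bond_{bond}"
        if fid not in BOND_FEATURES:
            raise KeyError(f"unknown bond flag {bond!r}")
        set_bit(fid)
    for region in region_features:
        fid = region if region.startswith("func_") else f"func_{region}"
        if fid not in FUNCTIONAL_FEATURES:
            raise KeyError(f"unknown functional feature {region!r}")
        set_bit(fid)

    return ResidueFeatureVector(
        protein=protein,
        pos=pos,
        ref_aa=ref_aa.upper(),
        bits=bits,
        resolved=len(mapped) > 0,
        provenance=tuple(f"{r.pdb_id}:{r.chain}:{r.resnum}" for r in mapped),
    )


# ---------------------------------------------------------------------------
# Tabular inputs and the residue_features.tsv interface
# ---------------------------------------------------------------------------

MAPPING_COLUMNS = ["pdb_id", "chain", "pdb_resnum", "protein", "uniprot_pos"]
PTM_COLUMNS = ["protein", "uniprot_pos", "ptm_type"]
REGION_COLUMNS = ["protein", "start", "end", "category"]
BOND_COLUMNS = ["protein", "uniprot_pos", "bond"]


def read_mapping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pdb_id": str, "chain": str, "protein": str})
    missing = set(MAPPING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mapping TSV missing columns {sorted(missing)}")
    return df


def read_ptm_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "ptm_type": str})
    missing = set(PTM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PTM TSV missing columns {sorted(missing)}")
    bad = set(df["ptm_type"]) - set(PTM_TYPES)
    if bad:
        raise ValueError(f"unknown PTM types {sorted(bad)}")
    return df


def read_regions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "category": str})
    missing = set(REGION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region TSV missing columns {sorted(missing)}")
    return df


def annotate_positions(
    mapping: pd.DataFrame,
    dssp_residues: Mapping[tuple[str, str], Mapping[int, StructureResidue]],
    ptm_sites: pd.DataFrame | None = None,
    regions: pd.DataFrame | None = None,
    bonds: pd.DataFrame | None = None,
    catalog: FeatureCatalog | None = None,
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Run the annotation pipeline over all mapped positions.

    ``dssp_residues`` indexes parsed structures as
    ``{(pdb_id, chain): {author resnum: StructureResidue}}``.
    Returns the residue-feature table (one row per protein/position).
    """
    catalog = catalog or default_catalog()
    config = config or AnnotationConfig()
    ptm_sites = ptm_sites if ptm_sites is not None else pd.DataFrame(columns=PTM_COLUMNS)
    regions = regions if regions is not None else pd.DataFrame(columns=REGION_COLUMNS)
    bonds = bonds if bonds is not None else pd.DataFrame(columns=BOND_COLUMNS)

    ptm_by_protein: dict[str, dict[int, set[str]]] = {}
    for row in ptm_sites.itertuples(index=False):
        ptm_by_protein.setdefault(row.protein, {}).setdefault(
            int(row.uniprot_pos), set()
        ).add(row.ptm_type)
    bond_by_pos: dict[tuple[str, int], set[str]] = {}
    for row in bonds.itertuples(index=False):
        bond_by_pos.setdefault((row.protein, int(row.uniprot_pos)), set()).add(row.bond)

    # structure residues and uniprot positions per (pdb, chain)
    vectors: list[ResidueFeatureVector] = []
    grouped = mapping.groupby("protein", sort=True)
    for protein, pmap in grouped:
        # per structure chain: uniprot_pos -> StructureResidue
        chain_maps: list[dict[int, StructureResidue]] = []
        for (pdb_id, chain), cmap in pmap.groupby(["pdb_id", "chain"], sort=True):
            res_by_num = dssp_residues.get((pdb_id, chain), {})
            chain_maps.append(
                {
                    int(r.uniprot_pos): res_by_num[int(r.pdb_resnum)]
                    for r in cmap.itertuples(index=False)
                    if int(r.pdb_resnum) in res_by_num
                }
            )
        prot_ptms = ptm_by_protein.get(protein, {})
        prot_regions = regions[regions["protein"] == protein]
        positions = sorted({int(p) for p in pmap["uniprot_pos"]})
        for pos in positions:
            mapped = [cm[pos] for cm in chain_maps if pos in cm]
            if not mapped:
                continue
            ref_aa = mapped[0].aa
            prox_results = []
            for cm in chain_maps:
                if pos not in cm:
                    continue
                sites = [
                    (cm[ppos], ptype)
                    for ppos, ptypes in prot_ptms.items()
                    if ppos in cm
                    for ptype in ptypes
                ]
                if sites:
                    prox_results.append(ptm_proximity(cm[pos], sites, config))
            region_feats = [
                r.category
                for r in prot_regions.itertuples(index=False)
                if int(r.start) <= pos <= int(r.end)
            ]
            vectors.append(
                consolidate(
                    protein,
                    pos,
                    ref_aa,
                    mapped,
                    prox_results,
                    ptm_site_types=prot_ptms.get(pos, ()),
                    bond_flags=bond_by_pos.get((protein, pos), ()),
                    region_features=region_feats,
                    catalog=catalog,
                    config=config,
                )
            )
    return vectors_to_frame(vectors, catalog)


def vectors_to_frame(
    vectors: Sequence[ResidueFeatureVector], catalog: FeatureCatalog | None = None
) -> pd.DataFrame:
    """Stack feature vectors into the residue-feature table."""
    catalog = catalog or default_catalog()
    rows = {
        "protein": [v.protein for v in vectors],
        "pos": [v.pos for v in vectors],
        "ref_aa": [v.ref_aa for v in vectors],
        "resolved": [int(v.resolved) for v in vectors],
    }
    bits = (
        np.stack([v.bits for v in vectors])
        if vectors
        else np.zeros((0, len(catalog)), dtype=np.uint8)
    )
    df = pd.DataFrame(rows)
    for j, fid in enumerate(catalog.ids):
        df[fid] = bits[:, j] if len(vectors) else np.array([], dtype=np.uint8)
    return df


def write_residue_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_residue_features(
    path: str | Path, catalog: FeatureCatalog | None = None
) -> pd.DataFrame:
    catalog = catalog or default_catalog()
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "ref_aa": str})
    missing = set(catalog.ids) - set(df.columns)
    if missing:
        raise ValueError(f"residue feature TSV missing feature columns {sorted(missing)}")
    for fid in catalog.ids:
        df[fid] = df[fid].astype(np.uint8)
    return df
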