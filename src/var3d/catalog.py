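"""The 3D feature catalog.

Each amino-acid position in a protein structure is described by a fixed,
ordered vector of binary features drawn from seven main categories:
secondary structure (DSSP 8-class), residue exposure (five relative
solvent-accessibility bins), physicochemical class of the reference amino
acid, interaction/bond participation, PTM-site identity, spatial proximity
to PTM sites, and functional-region membership. The default catalog has
exactly 40 features; its order is frozen so that vector index == catalog
index everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field


CATEGORY_SECONDARY_STRUCTURE = "secondary_structure"
CATEGORY_EXPOSURE = "residue_exposure"
CATEGORY_PHYSICOCHEMICAL = "physicochemical"
CATEGORY_INTERACTION = "interaction"
CATEGORY_PTM_SITE = "ptm_site"
CATEGORY_PTM_PROXIMITY = "ptm_proximity"
CATEGORY_FUNCTIONAL = "functional"

MAIN_CATEGORIES = (
    CATEGORY_SECONDARY_STRUCTURE,
    CATEGORY_EXPOSURE,
    CATEGORY_PHYSICOCHEMICAL,
    CATEGORY_INTERACTION,
    CATEGORY_PTM_SITE,
    CATEGORY_PTM_PROXIMITY,
    CATEGORY_FUNCTIONAL,
)


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry: a stable id, a display name, its main category
    and a tag naming the rule that derives it from raw annotations."""

    id: str
    name: str
    category: str
    derivation: str


# DSSP 8-class secondary structure codes, in DSSP's own alphabet.
DSSP_CODES = "HGIEBTS-"

#: DSSP code -> secondary-structure feature id
SS_FEATURES: dict[str, str] = {
    "H": "ss_helix_alpha",
    "G": "ss_helix_310",
    "I": "ss_helix_pi",
    "E": "ss_strand",
    "B": "ss_bridge",
    "T": "ss_turn",
    "S": "ss_bend",
    "-": "ss_coil",
}

#: exposure bins in ascending RSA order
EXPOSURE_FEATURES = (
    "exp_core",
    "exp_buried",
    "exp_medium_buried",
    "exp_medium_exposed",
    "exp_exposed",
)

PHYSICOCHEMICAL_FEATURES = (
    "aa_aliphatic",
    "aa_aromatic",
    "aa_charged",
    "aa_neutral",
    "aa_polar",
    "aa_special",
)

BOND_FEATURES = (
    "bond_hydrogen",
    "bond_salt_bridge",
    "bond_disulfide",
)

#: PTM types considered, both as site identity and as spatial neighbourhood
PTM_TYPES = (
    "phosphorylation",
    "acetylation",
    "methylation",
    "ubiquitination",
    "sumoylation",
    "oglcnac",
)

PTM_SITE_FEATURES = tuple(f"ptm_site_{t}" for t in PTM_TYPES)
PTM_PROXIMITY_FEATURES = tuple(f"ptm_near_{t}" for t in PTM_TYPES)

FUNCTIONAL_FEATURES = (
    "func_modular_domain",
    "func_modified_residue",
    "func_binding_region",
    "func_molecule_processing",
    "func_motif",
    "func_topological_region",
)


def _default_feature_defs() -> tuple[FeatureDef, ...]:
    defs: list[FeatureDef] = []
    ss_names = {
        "ss_helix_alpha": "α-helix",
        "ss_helix_310": "3₁₀-helix",
        "ss_helix_pi": "π-helix",
        "ss_strand": "β-strand",
        "ss_bridge": "β-bridge",
        "ss_turn": "turn",
        "ss_bend": "bend",
        "ss_coil": "coil/loop",
    }
    for code in DSSP_CODES:
        fid = SS_FEATURES[code]
        defs.append(
            FeatureDef(fid, ss_names[fid], CATEGORY_SECONDARY_STRUCTURE, f"dssp:{code}")
        )
    exp_names = {
        "exp_core": "core (RSA < 5%)",
        "exp_buried": "buried (5–25%)",
        "exp_medium_buried": "medium-buried (25–50%)",
        "exp_medium_exposed": "medium-exposed (50–75%)",
        "exp_exposed": "exposed (≥75%)",
    }
    for fid in EXPOSURE_FEATURES:
        defs.append(FeatureDef(fid, exp_names[fid], CATEGORY_EXPOSURE, "rsa_bin"))
    for fid in PHYSICOCHEMICAL_FEATURES:
        defs.append(
            FeatureDef(fid, fid.removeprefix("aa_"), CATEGORY_PHYSICOCHEMICAL, "aa_group")
        )
    bond_names = {
        "bond_hydrogen": "hydrogen bond",
        "bond_salt_bridge": "salt bridge",
        "bond_disulfide": "disulfide bond",
    }
    for fid in BOND_FEATURES:
        defs.append(FeatureDef(fid, bond_names[fid], CATEGORY_INTERACTION, "input_flag"))
    for t, fid in zip(PTM_TYPES, PTM_SITE_FEATURES):
        defs.append(FeatureDef(fid, f"{t} site", CATEGORY_PTM_SITE, "ptm_site"))
    for t, fid in zip(PTM_TYPES, PTM_PROXIMITY_FEATURES):
        defs.append(
            FeatureDef(fid, f"near {t} site (<10 Å)", CATEGORY_PTM_PROXIMITY, "ptm_distance")
        )
    func_names = {
        "func_modular_domain": "modular domain",
        "func_modified_residue": "modified residue",
        "func_binding_region": "functional/binding region",
        "func_molecule_processing": "molecule processing region",
        "func_motif": "sequence motif",
        "func_topological_region": "topological region",
    }
    for fid in FUNCTIONAL_FEATURES:
        defs.append(FeatureDef(fid, func_names[fid], CATEGORY_FUNCTIONAL, "region_flag"))
    return tuple(defs)


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, immutable collection of :class:`FeatureDef`.

    The vector position of a feature is its index here; all feature
    matrices, TSV columns and association sets are keyed by these ids.
    """

    features: tuple[FeatureDef, ...] = field(default_factory=_default_feature_defs)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        bad = {f.category for f in self.features} - set(MAIN_CATEGORIES)
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    def index(self, feature_id: str) -> int:
        try:
            return self.ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def by_category(self, category: str) -> tuple[str, ...]:
        return tuple(f.id for f in self.features if f.category == category)


def default_catalog() -> FeatureCatalog:
    """The default 40-feature catalog (7 main categories)."""
    cat = FeatureCatalog()
    assert len(cat) == 40
    return cat
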