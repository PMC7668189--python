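"""Per-feature, per-protein-class burden analysis.

For every 3D feature and every gene group (all genes pooled, plus each
protein functional class) a 2×2 table is built over pathogenic vs
population variants × feature present vs absent, and summarised by the
sample odds ratio, a 95% Woolf logit confidence interval, a two-sided
Fisher exact p, a Bonferroni-style corrected q = min(1, p·m), and the
relative risk. Features with OR > 1 and q < α form the pathogenic
association set of the group; OR < 1 and q < α the population set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import FeatureCatalog, default_catalog

#: group id under which all genes are pooled (the study-wide context)
ALL_GENES = "all_genes"

VARIANT_COLUMNS = ["gene", "protein", "pos", "ref_aa", "alt_aa", "label", "source"]
VARIANT_KEY = ["gene", "protein", "pos", "ref_aa", "alt_aa"]
LABELS = ("pathogenic", "population", "benign")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a/b pathogenic with/without feature, c/d population with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def untestable(self) -> bool:
        """True when a row or column margin is empty (Fisher undefined)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class BurdenConfig:
    """alpha: significance on q; correction: fixed multiplier (e.g. the
    study-wide 1,000 = 40 features × 25 groups) or None to use the number
    of tests actually run; ci_method/or zero-cell handling documented on
    :func:`or_ci`."""

    alpha: float = 0.05
    correction: int | None = None
    ci_level: float = 0.95
    dedupe: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.correction is not None and self.correction < 1:
            raise ValueError("correction multiplier must be >= 1")


@dataclass(frozen=True)
class BurdenResult:
    feature: str
    group: str
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    rr: float
    association: str  # 'pathogenic' | 'population' | 'none'


class AssociationTable:
    """Per-group pathogenic- and population-associated feature sets.

    These are the universes from which the per-residue P3DFi counts
    (3DF_PATH, 3DF_POP) are drawn; the two sets are disjoint for every
    group by construction (a feature cannot have OR > 1 and OR < 1).
    """

    def __init__(self, sets: Mapping[str, tuple[frozenset[str], frozenset[str]]]):
        for group, (path, pop) in sets.items():
            if path & pop:
                raise ValueError(f"association sets overlap for group {group!r}")
        self._sets = dict(sets)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self._sets)

    def __contains__(self, group: str) -> bool:
        return group in self._sets

    def pathogenic(self, group: str) -> frozenset[str]:
        return self._sets[group][0]

    def population(self, group: str) -> frozenset[str]:
        return self._sets[group][1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self._sets):
            path, pop = self._sets[group]
            for f in sorted(path):
                rows.append({"group": group, "feature": f, "association": "pathogenic"})
            for f in sorted(pop):
                rows.append({"group": group, "feature": f, "association": "population"})
        return pd.DataFrame(rows, columns=["group", "feature", "association"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssociationTable":
        sets: dict[str, tuple[set[str], set[str]]] = {}
        for row in df.itertuples(index=False):
            path, pop = sets.setdefault(row.group, (set(), set()))
            if row.association == "pathogenic":
                path.add(row.feature)
            elif row.association == "population":
                pop.add(row.feature)
            else:
                raise ValueError(f"bad association label {row.association!r}")
        return cls({g: (frozenset(p), frozenset(q)) for g, (p, q) in sets.items()})

    @classmethod
    def read(cls, path: str | Path) -> "AssociationTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Component statistics
# ---------------------------------------------------------------------------

def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (probability-ordering / 'minlike' rule)."""
    if table.untestable:
        raise ValueError("table has an empty margin; Fisher test undefined")
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def sample_or(table: ContingencyTable) -> float:
    """Sample odds ratio ad/bc with 0, inf and nan sentinels."""
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def or_ci(table: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf logit interval exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d)).

    Any zero cell triggers the Haldane–Anscombe +0.5 correction applied
    to all four cells for the interval only (the point OR is unchanged).
    """
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    z = stats.norm.ppf(0.5 + level / 2)
    log_or = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = math.sqrt((1.0 / cells).sum())
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def correct_p(p: float, m: int) -> float:
    """Bonferroni-style q = min(1, p·m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("multiplier must be >= 1")
    return min(1.0, p * m)


def relative_risk(table: ContingencyTable) -> float:
    """RR = P(pathogenic | feature) / P(pathogenic | no feature)."""
    if table.a + table.c == 0 or table.b + table.d == 0:
        return math.nan
    p1 = table.a / (table.a + table.c)
    p0 = table.b / (table.b + table.d)
    if p0 == 0:
        return math.inf if p1 > 0 else math.nan
    return p1 / p0


def conditional_mle_or(table: ContingencyTable) -> float:
    """Conditional maximum-likelihood OR (cross-check alternative to ad/bc)."""
    from scipy.stats.contingency import odds_ratio

    return float(odds_ratio(table.as_array(), kind="conditional").statistic)


# ---------------------------------------------------------------------------
# Cohort-level analysis
# ---------------------------------------------------------------------------

def dedupe_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Collapse variants observed in several sources to one record.

    Identity is (gene, protein, pos, ref, alt); on conflicting labels the
    pathogenic record wins (label precedence pathogenic > population >
    benign), mirroring removal of overlap between discovery and
    validation sets.
    """
    order = {lab: i for i, lab in enumerate(LABELS)}
    df = variants.copy()
    df["_rank"] = df["label"].map(order)
    df = df.sort_values(VARIANT_KEY + ["_rank"], kind="mergesort")
    df = df.drop_duplicates(subset=VARIANT_KEY, keep="first").drop(columns="_rank")
    return df.reset_index(drop=True)


def build_table(
    variants: pd.DataFrame,
    features: pd.DataFrame,
    feature: str,
    group: str,
    class_map: pd.DataFrame,
) -> ContingencyTable:
    """2×2 counts for one feature × one gene group.

    Only pathogenic/population variants with a structure-resolved residue
    vector qualify; a variant has the feature iff the bit at its
    reference position is set. Genes in several classes contribute to
    each of their groups.
    """
    presence = _presence_matrix(variants, features, [feature])
    genes = _genes_in_group(group, class_map)
    return _tables_from_presence(presence, [feature], genes)[feature]


def _genes_in_group(group: str, class_map: pd.DataFrame) -> set[str] | None:
    if group == ALL_GENES:
        return None
    genes = set(class_map.loc[class_map["class"] == group, "gene"])
    return genes


def _presence_matrix(
    variants: pd.DataFrame, features: pd.DataFrame, feature_ids: list[str]
) -> pd.DataFrame:
    """Qualifying variants joined with their residue feature bits."""
    keep = variants[variants["label"].isin(["pathogenic", "population"])]
    cols = ["protein", "pos", "resolved"] + feature_ids
    merged = keep.merge(features[cols], on=["protein", "pos"], how="inner")
    merged = merged[merged["resolved"] == 1]
    return merged


def _tables_from_presence(
    presence: pd.DataFrame, feature_ids: list[str], genes: set[str] | None
) -> dict[str, ContingencyTable]:
    sub = presence if genes is None else presence[presence["gene"].isin(genes)]
    is_path = (sub["label"] == "pathogenic").to_numpy()
    out = {}
    for fid in feature_ids:
        has = sub[fid].to_numpy().astype(bool)
        a = int((is_path & has).sum())
        b = int((is_path & ~has).sum())
        c = int((~is_path & has).sum())
        d = int((~is_path & ~has).sum())
        out[fid] = ContingencyTable(a, b, c, d)
    return out


def run_burden(
    variants: pd.DataFrame,
    features: pd.DataFrame,
    class_map: pd.DataFrame,
    catalog: FeatureCatalog | None = None,
    config: BurdenConfig | None = None,
) -> list[BurdenResult]:
    """One burden test per feature × group (all-genes pool first).

    Untestable tables are reported with p = q = nan and association
    'none'. Results are ordered by (group, feature) for reproducible
    serialisation.
    """
    catalog = catalog or default_catalog()
    config = config or BurdenConfig()
    if config.dedupe:
        variants = dedupe_variants(variants)
    feature_ids = list(catalog.ids)
    presence = _presence_matrix(variants, features, feature_ids)
    groups = [ALL_GENES] + sorted(set(class_map["class"]))

    tables: list[tuple[str, str, ContingencyTable]] = []
    for group in groups:
        per_feature = _tables_from_presence(
            presence, feature_ids, _genes_in_group(group, class_map)
        )
        for fid in feature_ids:
            tables.append((group, fid, per_feature[fid]))

    n_testable = sum(1 for _, _, t in tables if not t.untestable)
    m = config.correction if config.correction is not None else max(1, n_testable)

    results: list[BurdenResult] = []
    for group, fid, t in sorted(tables, key=lambda x: (x[0], x[1])):
        or_ = sample_or(t)
        lo, hi = or_ci(t, config.ci_level) if not t.untestable else (math.nan, math.nan)
        if t.untestable:
            p = q = math.nan
            assoc = "none"
        else:
            p = fisher_two_sided(t)
            q = correct_p(p, m)
            if q < config.alpha and or_ > 1:
                assoc = "pathogenic"
            elif q < config.alpha and or_ < 1:
                assoc = "population"
            else:
                assoc = "none"
        results.append(
            BurdenResult(fid, group, t, or_, lo, hi, p, q, relative_risk(t), assoc)
        )
    return results


def derive_associations(
    results: list[BurdenResult], alpha: float = 0.05
) -> AssociationTable:
    """Association sets per group from burden results (OR vs 1, q < α)."""
    sets: dict[str, tuple[set[str], set[str]]] = {}
    for r in results:
        path, pop = sets.setdefault(r.group, (set(), set()))
        if math.isnan(r.q) or r.q >= alpha:
            continue
        if r.odds_ratio > 1:
            path.add(r.feature)
        elif r.odds_ratio < 1:
            pop.add(r.feature)
    return AssociationTable(
        {g: (frozenset(p), frozenset(q)) for g, (p, q) in sets.items()}
    )


def results_to_frame(results: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "feature": [r.feature for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "OR": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "RR": [r.rr for r in results],
            "association": [r.association for r in results],
        }
    )


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "protein": str})
    missing = set(VARIANT_COLUMNS) - {"source"} - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown variant labels {sorted(bad)}")
    if (df["ref_aa"] == df["alt_aa"]).any():
        raise ValueError("variant with identical ref and alt amino acid")
    return df


def read_class_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "class": str})
    if not {"gene", "class"} <= set(df.columns):
        raise ValueError("class TSV must have columns gene, class")
    return df
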