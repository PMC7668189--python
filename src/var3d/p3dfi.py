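"""The pathogenic 3D feature index (P3DFi).

For a residue with feature set F and a context group's association sets
(PATH, POP), 3DF_PATH = |F ∩ PATH| and 3DF_POP = |F ∩ POP|; the index is
their difference. A positive index marks a 3D mutational hotspot
(features of the site match those enriched in pathogenic variants), a
negative one a site resembling population-variant territory. The module
also provides the standard downstream analyses: integer binning
(<−2 … >2), tail-based high-confidence classification, a two-sided
Mann–Whitney U comparison between variant classes, and Pearson
correlation against mutagenesis fitness readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ResidueFeatureVector
from .burden import AssociationTable
from .catalog import FeatureCatalog, default_catalog

BIN_LABELS = ("<-2", "-2", "-1", "0", "1", "2", ">2")


@dataclass(frozen=True)
class P3DFiScore:
    protein: str
    pos: int
    ref_aa: str
    context: str
    n_path: int
    n_pop: int

    @property
    def index(self) -> int:
        return self.n_path - self.n_pop

    @property
    def hotspot(self) -> bool:
        return self.index > 0


@dataclass(frozen=True)
class RankTestResult:
    u: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    p: float
    n: int


def compute_p3dfi(
    vector: ResidueFeatureVector,
    assoc: AssociationTable,
    group: str,
    catalog: FeatureCatalog | None = None,
) -> P3DFiScore:
    """Score one residue against a context group's association sets."""
    catalog = catalog or default_catalog()
    if group not in assoc:
        raise KeyError(f"group {group!r} not present in association table")
    feats = vector.features(catalog)
    return P3DFiScore(
        protein=vector.protein,
        pos=vector.pos,
        ref_aa=vector.ref_aa,
        context=group,
        n_path=len(feats & assoc.pathogenic(group)),
        n_pop=len(feats & assoc.population(group)),
    )


def compute_p3dfi_frame(
    features: pd.DataFrame,
    assoc: AssociationTable,
    group: str,
    catalog: FeatureCatalog | None = None,
) -> pd.DataFrame:
    """Vectorised P3DFi over a residue-feature table.

    Returns columns protein, pos, ref_aa, context, n_path, n_pop, index,
    bin — the `p3dfi.tsv` schema.
    """
    catalog = catalog or default_catalog()
    if group not in assoc:
        raise KeyError(f"group {group!r} not present in association table")
    path_cols = sorted(assoc.pathogenic(group))
    pop_cols = sorted(assoc.population(group))
    unknown = (set(path_cols) | set(pop_cols)) - set(catalog.ids)
    if unknown:
        raise ValueError(f"association features not in catalog: {sorted(unknown)}")
    out = features[["protein", "pos", "ref_aa"]].copy()
    out["context"] = group
    out["n_path"] = (
        features[path_cols].to_numpy().sum(axis=1).astype(np.int64)
        if path_cols
        else 0
    )
    out["n_pop"] = (
        features[pop_cols].to_numpy().sum(axis=1).astype(np.int64)
        if pop_cols
        else 0
    )
    out["index"] = out["n_path"] - out["n_pop"]
    out["bin"] = [bin_p3dfi(i) for i in out["index"]]
    return out


def bin_p3dfi(index: int) -> str:
    """Integer index -> one of the seven bins <−2, −2, −1, 0, 1, 2, >2."""
    index = int(index)
    if index < -2:
        return "<-2"
    if index > 2:
        return ">2"
    return str(index)


def classify_high_confidence(
    index: int, upper: int = 2, lower: int = -2
) -> str:
    """Tail classification: index > upper → pathogenic-like, index < lower
    → benign-like, otherwise indeterminate (boundaries are strict)."""
    if upper <= lower:
        raise ValueError("upper threshold must exceed lower threshold")
    if index > upper:
        return "pathogenic-like"
    if index < lower:
        return "benign-like"
    return "indeterminate"


# ---------------------------------------------------------------------------
# Rank test
# ---------------------------------------------------------------------------

#: exact enumeration is used when n1*n2 is at or below this
EXACT_LIMIT = 400


def _exact_u_pvalue(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p for U by dynamic programming over rank splits.

    Counts, among all C(n1+n2, n1) equally likely assignments of the
    pooled midranks to the first sample, the fraction with
    |U − n1·n2/2| ≥ |u_obs − n1·n2/2|. Ties are handled exactly because
    the enumeration is over the realised midranks.
    """
    n = len(pooled_ranks)
    n2 = n - n1
    doubled = np.round(pooled_ranks * 2).astype(int)  # midranks -> integers
    # dp[k] maps achievable doubled rank-sum -> count, for subsets of size k
    dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in doubled:
        for k in range(n1 - 1, -1, -1):
            if not dp[k]:
                continue
            nxt = dp[k + 1]
            for s, cnt in dp[k].items():
                nxt[s + r] = nxt.get(s + r, 0) + cnt
    mu2 = n1 * n2  # doubled U mean = 2 * n1*n2/2
    dev_obs = abs(2 * u_obs - mu2)
    hits = 0
    denom = math.comb(n, n1)
    for s2, cnt in dp[n1].items():
        u2 = s2 - n1 * (n1 + 1)  # doubled U = 2*(R1 - n1(n1+1)/2)
        if abs(u2 - mu2) >= dev_obs - 1e-9:
            hits += cnt
    return hits / denom


def mann_whitney_two_sided(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> RankTestResult:
    """Two-sided Mann–Whitney U test with midrank ties.

    U is the statistic of the first sample. The p value comes from exact
    enumeration of rank splits when n1·n2 ≤ ``exact_limit`` and from the
    tie-corrected normal approximation above it. Identical samples give
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if np.ptp(pooled) == 0:
        return RankTestResult(u, 1.0)
    if n1 * n2 <= exact_limit:
        p = _exact_u_pvalue(ranks, n1, u)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
        )
    return RankTestResult(u, min(1.0, p))


def permutation_u_oracle(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Brute-force permutation reference for small samples.

    Enumerates every split of the pooled values into groups of sizes
    (n1, n2) and counts splits at least as extreme as observed (by
    |U − n1·n2/2|). Independent of the DP route; intended for testing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
        total += 1
    return RankTestResult(u_obs, hits / total)


def correlate_fitness(
    p3dfi: pd.DataFrame, fitness: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation of per-position P3DFi against mean fitness.

    Joins on (protein, pos); reports squared r, the two-sided p from the
    t transform, and the number of paired positions. Requires ≥3 pairs
    and non-constant inputs.
    """
    merged = p3dfi.merge(fitness, on=["protein", "pos"], how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 paired positions")
    x = merged["index"].to_numpy(dtype=float)
    y = merged["fitness"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r2=float(r) ** 2, p=float(p), n=len(merged))
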