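"""Replicated 1:1 matching within exact strata and propensity-score deciles.

Babies are first grouped exactly by birth-year band (four 2-year bands) and
cord-pH band (<6.9, 6.9-7.0, >7.0, and by default a fourth band for missing
pH); within each stratum, propensity-score deciles are computed from the
stratum's own empirical score distribution (type-7 quantiles, boundary
scores to the lower bin).  Within each stratum x decile cell, fed and unfed
babies are paired off after independent seeded random permutations; the
surplus group is left unmatched.  Because the pairing is random, the whole
procedure is replicated (default 25 times) with child seeds derived
deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateSet",
    "assign_strata",
    "decile_bins",
    "match_replicate",
    "replicate_matching",
    "standardized_difference",
    "balance_report",
]


@dataclass
class ReplicateSet:
    replicates: list[pd.DataFrame]  # columns fed_id, unfed_id, stratum, decile
    seeds: list[int]
    master_seed: int

    @property
    def R(self) -> int:
        return len(self.replicates)


def assign_strata(df: pd.DataFrame, drop_missing_ph: bool = False) -> pd.Series:
    """Exact-matching stratum key per baby: 'year_band|ph_band'.

    With drop_missing_ph=True the missing-pH babies get a null key and are
    excluded from matching (the strict 12-group reading); by default they
    form their own pH band (16 cells).
    """
    key = df["year_band"].astype(str) + "|" + df["ph_band"].astype(str)
    key.index = df.index
    if drop_missing_ph:
        key[df["ph_band"] == "missing"] = None
    return key.rename("stratum")


def decile_bins(scores: np.ndarray) -> np.ndarray:
    """Decile bin label (1-based) for each score within one stratum.

    Bin edges are the stratum's empirical deciles (type-7 / linear
    interpolation); a score equal to an edge goes to the lower bin; strata
    with few distinct scores collapse to one bin per distinct edge.
    """
    scores = np.asarray(scores, float)
    if len(scores) == 0:
        return np.array([], dtype=int)
    edges = np.quantile(scores, np.arange(1, 10) / 10.0, method="linear")
    edges = np.unique(edges)
    return np.searchsorted(edges, scores, side="left") + 1


def _cells(df: pd.DataFrame, strata: pd.Series, bins: pd.Series) -> list[tuple]:
    """(stratum, decile, fed_ids, unfed_ids) per non-empty cell, in sorted order."""
    work = pd.DataFrame(
        {
            "infant_id": df["infant_id"].to_numpy(),
            "fed": (df["exposure"] == "FED").to_numpy(),
            "stratum": strata.to_numpy(),
            "decile": bins.to_numpy(),
        }
    )
    work = work[work["stratum"].notna()]
    out = []
    for (stratum, decile), cell in work.groupby(["stratum", "decile"], sort=True):
        fed_mask = cell["fed"].to_numpy()
        ids = cell["infant_id"].to_numpy()
        out.append((stratum, decile, ids[fed_mask], ids[~fed_mask]))
    return out


def _pair_cells(cells: list[tuple], rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for stratum, decile, fed_ids, unfed_ids in cells:
        k = min(len(fed_ids), len(unfed_ids))
        if k == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "fed_id": rng.permutation(fed_ids)[:k],
                    "unfed_id": rng.permutation(unfed_ids)[:k],
                    "stratum": stratum,
                    "decile": decile,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["fed_id", "unfed_id", "stratum", "decile"])
    return pd.concat(frames, ignore_index=True)


def match_replicate(df: pd.DataFrame, strata: pd.Series, bins: pd.Series, seed: int) -> pd.DataFrame:
    """One randomized 1:1 matched cohort.

    Within each stratum x decile cell, min(#fed, #unfed) pairs are formed by
    independently permuting the two groups with the seeded generator and
    zipping them; the pair count is therefore fixed by the table and only
    pair composition varies with the seed.
    """
    return _pair_cells(_cells(df, strata, bins), np.random.default_rng(seed))


def child_seed(master_seed: int, r: int) -> int:
    """Stable per-replicate seed derived from (master seed, replicate index)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(r,))
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def replicate_matching(
    df: pd.DataFrame,
    strata: pd.Series,
    bins: pd.Series,
    R: int = 25,
    master_seed: int = 0,
) -> ReplicateSet:
    """R independent randomized matched cohorts from the same filtered table."""
    if R < 1:
        raise ValueError("R must be >= 1")
    seeds = [child_seed(master_seed, r) for r in range(R)]
    cells = _cells(df, strata, bins)
    reps = [_pair_cells(cells, np.random.default_rng(seed)) for seed in seeds]
    return ReplicateSet(replicates=reps, seeds=seeds, master_seed=master_seed)


def standardized_difference(x1, x2, kind: str) -> float:
    """Standardised difference between two groups for one variable.

    binary: (p1-p2)/sqrt((p1(1-p1)+p2(1-p2))/2);
    continuous: (m1-m2)/sqrt((s1^2+s2^2)/2) with sample variances.
    Missing values are excluded per group; 0/0 is defined as 0.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    x1 = x1[~np.isnan(x1)]
    x2 = x2[~np.isnan(x2)]
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "binary":
        p1, p2 = x1.mean(), x2.mean()
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
        num = p1 - p2
    elif kind == "continuous":
        v1 = x1.var(ddof=1) if len(x1) > 1 else 0.0
        v2 = x2.var(ddof=1) if len(x2) > 1 else 0.0
        denom = np.sqrt((v1 + v2) / 2.0)
        num = x1.mean() - x2.mean()
    else:
        raise ValueError(f"unknown variable kind {kind!r}")
    if denom == 0.0:
        return 0.0 if num == 0.0 else float(np.sign(num)) * np.inf
    return float(num / denom)


def balance_report(
    df: pd.DataFrame,
    covariate_columns: list[str],
    column_kinds: dict[str, str],
    replicate_set: ReplicateSet,
) -> pd.DataFrame:
    """Standardised differences before matching and (averaged) after matching.

    Before-values are computed on the full filtered table; after-values are
    the mean (with SD) over replicates of the within-replicate standardised
    difference between matched fed and unfed groups.
    """
    if replicate_set.R == 0 or all(len(r) == 0 for r in replicate_set.replicates):
        raise ValueError("empty replicate set")
    indexed = df.set_index("infant_id")
    fed_mask = df["exposure"] == "FED"
    rows = []
    for col in covariate_columns:
        kind = column_kinds[col]
        before = standardized_difference(df.loc[fed_mask, col], df.loc[~fed_mask, col], kind)
        after = []
        for rep in replicate_set.replicates:
            x_fed = indexed.loc[rep["fed_id"], col]
            x_unfed = indexed.loc[rep["unfed_id"], col]
            after.append(standardized_difference(x_fed, x_unfed, kind))
        after = np.asarray(after)
        rows.append(
            {
                "variable": col,
                "before": before,
                "after_mean": float(after.mean()),
                "after_sd": float(after.std(ddof=1)) if len(after) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
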