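"""Phenotype-side computation: efficiency indices, contrast groups and
redundancy pruning.

Core quantities, in the field's standard notation:

* shoot P content (mg pot⁻¹) = shoot dry matter (g pot⁻¹) × shoot P
  concentration (mg g⁻¹);
* phosphorus utilisation efficiency PUE (g DM mg⁻¹ P) = shoot dry
  matter / shoot P content;
* stress tolerance index STI = Y_p·Y_s / (mean Y_p)², where Y_p and Y_s
  are an accession's performance under control (HP) and stress (LP)
  conditions and mean Y_p the control mean over all accessions;
* ΔRDM = mean root dry matter under HP − mean root dry matter under LP,
  the ranking variable for the High/Low contrast groups.

The module also provides Spearman correlation, a fixed-effects two-way
ANOVA with an additive replicate block (a contract-level stand-in for a
replicate-random-effect mixed model), and uncorrected p-distance
deduplication of accessions from a SNP matrix with missing data.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

HIGH_GROUP = "High dRDM"
LOW_GROUP = "Low dRDM"


def shoot_p_content(sdm, concentration):
    """Shoot P content in mg/pot from dry matter (g/pot) and concentration (mg/g)."""
    sdm = np.asarray(sdm, dtype=float)
    concentration = np.asarray(concentration, dtype=float)
    if (sdm < 0).any() or (concentration < 0).any():
        raise ValueError("dry matter and P concentration must be non-negative")
    out = sdm * concentration
    return float(out) if out.ndim == 0 else out


def pue(sdm, p_content):
    """Phosphorus utilisation efficiency: g shoot DM per mg shoot P."""
    sdm = np.asarray(sdm, dtype=float)
    p_content = np.asarray(p_content, dtype=float)
    if (p_content <= 0).any():
        raise ValueError("shoot P content must be positive")
    out = sdm / p_content
    return float(out) if out.ndim == 0 else out


def sti(y_p, y_s, mean_y_p):
    """Stress tolerance index Y_p·Y_s / (mean Y_p)².

    Invariant under a common rescaling of all three inputs; grows with
    stress-condition performance at fixed potential.
    """
    y_p = np.asarray(y_p, dtype=float)
    y_s = np.asarray(y_s, dtype=float)
    if mean_y_p <= 0:
        raise ValueError("mean control performance must be positive")
    out = y_p * y_s / (mean_y_p ** 2)
    return float(out) if out.ndim == 0 else out


def percent_change(mean_hp, mean_lp) -> float:
    """Signed percent change from HP to LP: 100·(LP − HP)/HP.

    Reductions are negative; report |value| as a "reduction" when
    formatting.
    """
    if mean_hp <= 0:
        raise ValueError("HP mean must be positive")
    return 100.0 * (mean_lp - mean_hp) / mean_hp


def treatment_means(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Accession × treatment replicate means for one trait (long-format input)."""
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    return sub.pivot_table(index="accession", columns="treatment", values="value",
                           aggfunc="mean")


def delta_rdm_groups(
    table: pd.DataFrame,
    trait: str = "RDM",
    n_extreme: int = 30,
    n_pick: int = 10,
    picker: Callable[[pd.DataFrame, int, str], Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Rank accessions by ΔRDM and label High/Low contrast groups.

    ΔRDM = mean(HP) − mean(LP) per accession (signed; negative values —
    more root mass under LP — fall into the Low pool).  From the
    ``n_extreme`` accessions with the largest and the smallest ΔRDM,
    ``n_pick`` each are chosen by the ``picker`` hook; the default picks
    the most extreme by signed ΔRDM.  The 10-of-30 choice in a real
    panel also weighs biostatus and origin, which is why the hook is
    pluggable.
    """
    means = treatment_means(table, trait)
    missing = means.index[means.isna().any(axis=1)]
    for acc in missing:
        log.warning("accession %s lacks a treatment; excluded from ΔRDM ranking", acc)
    means = means.dropna()
    counts = table[table["trait"] == trait].groupby(["accession", "treatment"]).size()
    if (counts < 3).any():
        log.warning("fewer than 3 replicates for some accession × treatment cells")
    delta = (means["HP"] - means["LP"]).sort_values(ascending=False)
    out = pd.DataFrame({"accession": delta.index, "delta_rdm": delta.values})
    out["group"] = "none"

    top_pool = out.iloc[:n_extreme]
    bottom_pool = out.iloc[-n_extreme:]
    if picker is None:
        def picker(pool: pd.DataFrame, n: int, which: str) -> Sequence[str]:
            ordered = pool.sort_values("delta_rdm", ascending=(which == "low"))
            return list(ordered["accession"].iloc[:n])

    high = set(picker(top_pool, n_pick, "high"))
    low = set(picker(bottom_pool, n_pick, "low"))
    out.loc[out["accession"].isin(high), "group"] = HIGH_GROUP
    out.loc[out["accession"].isin(low), "group"] = LOW_GROUP
    return out.reset_index(drop=True)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def efficiency_indices(
    table: pd.DataFrame,
    sdm_trait: str = "SDM",
    rdm_trait: str = "RDM",
    conc_trait: str = "shoot_P_conc",
) -> pd.DataFrame:
    """Per-accession indices: shoot P content, PUE (both treatments), STI, ΔRDM.

    STI's mean Y_p is the HP mean over *all* accessions in the analysis
    set.  PUE × shoot P content returns the same pot's shoot dry matter
    by construction.
    """
    sdm = treatment_means(table, sdm_trait)
    conc = treatment_means(table, conc_trait)
    rdm = treatment_means(table, rdm_trait)
    accs = sdm.index
    content_hp = shoot_p_content(sdm["HP"].to_numpy(), conc.loc[accs, "HP"].to_numpy())
    content_lp = shoot_p_content(sdm["LP"].to_numpy(), conc.loc[accs, "LP"].to_numpy())
    out = pd.DataFrame({
        "accession": accs,
        "shoot_P_content_HP": content_hp,
        "shoot_P_content_LP": content_lp,
        "PUE_HP": pue(sdm["HP"].to_numpy(), content_hp),
        "PUE_LP": pue(sdm["LP"].to_numpy(), content_lp),
        "STI_sdm": sti(sdm["HP"].to_numpy(), sdm["LP"].to_numpy(), sdm["HP"].mean()),
        "STI_rdm": sti(rdm.loc[accs, "HP"].to_numpy(), rdm.loc[accs, "LP"].to_numpy(),
                       rdm["HP"].mean()),
        "delta_RDM": (rdm.loc[accs, "HP"] - rdm.loc[accs, "LP"]).to_numpy(),
    })
    return out.reset_index(drop=True)


def anova_two_way(
    table: pd.DataFrame,
    trait: str,
    group_col: str = "group",
    return_table: bool = False,
):
    """Fixed-effects two-way ANOVA with an additive replicate block.

    Type-I sums of squares in the fixed order block, treatment, group,
    treatment × group; returns the F-test p-values.  This is a
    contract-level approximation of a replicate-random-effect mixed
    model — with a balanced design the fixed-block F-tests for the
    treatment terms coincide closely.  Factors with a single level are
    skipped with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = table[table["trait"] == trait].copy() if "trait" in table.columns else table.copy()
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present")
    sub = sub.rename(columns={group_col: "group"})
    terms = []
    for name, col in (("block", "replicate"), ("treatment", "treatment"), ("group", "group")):
        if sub[col].nunique() > 1:
            terms.append((name, f"C({col})"))
        else:
            warnings.warn(f"factor {name!r} has one level; term skipped", UserWarning,
                          stacklevel=2)
    formula_terms = [t for _, t in terms]
    has_interaction = sub["treatment"].nunique() > 1 and sub["group"].nunique() > 1
    if has_interaction:
        formula_terms.append("C(treatment):C(group)")
    model = smf.ols("value ~ " + " + ".join(formula_terms), data=sub).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    rename = {"C(replicate)": "block", "C(treatment)": "treatment", "C(group)": "group",
              "C(treatment):C(group)": "interaction"}
    pvals = {rename.get(idx, idx): tab.loc[idx, "PR(>F)"] for idx in tab.index
             if idx != "Residual"}
    series = pd.Series(pvals)
    if return_table:
        return series, tab.rename(index=rename)
    return series


def _pairwise_p_distance(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uncorrected p-distance over pairwise-complete sites; NaN = missing."""
    obs = ~np.isnan(X)
    n = X.shape[0]
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            shared[i, j] = shared[j, i] = m
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
            else:
                d = float(np.mean(X[i, both] != X[j, both]))
                dist[i, j] = dist[j, i] = d
    return dist, shared


def pdistance_dedup(
    snp_matrix: pd.DataFrame,
    similarity_threshold: float = 0.9997,
    rounds: int = 3,
) -> list[str]:
    """Iteratively prune near-duplicate accessions from a SNP matrix.

    Per round: compute uncorrected p-distances over pairwise-complete
    sites, connect pairs with similarity 1 − d at or above the
    threshold, and keep from each connected component the accession
    with the least missing data (ties broken by lexicographic id).
    Pairs with no overlapping sites are treated as non-redundant (with
    a warning).  Repeats for ``rounds`` rounds or until stable.
    """
    frame = snp_matrix.copy()
    for _ in range(rounds):
        ids = list(frame.index)
        X = frame.to_numpy(dtype=float)
        dist, shared = _pairwise_p_distance(X)
        if np.isnan(dist[np.triu_indices(len(ids), 1)]).any():
            log.warning("pairs with zero overlapping sites treated as non-redundant")
        # union-find over redundant pairs
        parent = list(range(len(ids)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if shared[i, j] > 0 and 1.0 - dist[i, j] >= similarity_threshold:
                    parent[find(i)] = find(j)

        missing = np.isnan(X).sum(axis=1)
        best: dict[int, int] = {}
        for i in range(len(ids)):
            root = find(i)
            if root not in best:
                best[root] = i
            else:
                b = best[root]
                if (missing[i], ids[i]) < (missing[b], ids[b]):
                    best[root] = i
        retained = sorted(best.values())
        if len(retained) == len(ids):
            break
        frame = frame.iloc[retained]
    # post-condition audit
    X = frame.to_numpy(dtype=float)
    dist, shared = _pairwise_p_distance(X)
    for i in range(len(frame)):
        for j in range(i + 1, len(frame)):
            if shared[i, j] > 0 and 1.0 - dist[i, j] >= similarity_threshold:
                log.warning("redundant pair survived pruning: %s / %s",
                            frame.index[i], frame.index[j])
    return list(frame.index)
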