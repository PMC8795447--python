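"""Multiple-comparison machinery and GRK-selectivity classification.

Saturating-concentration Δ net BRET fold changes for each GPCR–arrestin pair
are compared across the rescue conditions (quadruple-kinase-knockout
background + empty vector or + GRK2/3/5/6) with one-way ANOVA followed by
Bonferroni-adjusted contrasts against the knockout + empty-vector reference.
Each pair's contrasts are summarised as a signed −log10(p) heatmap row,
pairs are clustered by Canberra distance with complete linkage, and a rule
assigns the selectivity group:

* GRK2/3/5/6-regulated — {GRK2 or GRK3} and {GRK5 or GRK6} rescue each
  significantly restore recruitment;
* GRK2/3-regulated — {GRK2 or GRK3} restores it, neither GRK5 nor GRK6 does;
* unclassified — otherwise.

Pre-coupling (ligand-independent receptor–arrestin association) is detected
as a baseline BRET ratio significantly elevated over the knockout + empty
vector baseline by a one-sided many-to-one (Dunnett) test.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import canberra as _scipy_canberra

from .types import (
    ComparisonResult,
    ConfigurationError,
    DataError,
    SelectivityCall,
)

__all__ = [
    "anova_oneway",
    "pairwise_bonferroni",
    "dunnett_test",
    "tukey_hsd",
    "transform_p_matrix",
    "canberra_distance",
    "hierarchical_cluster",
    "call_selectivity",
    "call_precoupling",
    "classify_matrix",
]

GRK_NAMES = ("GRK2", "GRK3", "GRK5", "GRK6")
REFERENCE_CONDITION = "dQ-GRK+EV"

# fixed internal seed for the multivariate-t evaluation inside the Dunnett
# test, so adjusted p-values are reproducible run to run
_DUNNETT_SEED = 186283


def _check_groups(groups) -> None:
    for i, g in enumerate(groups):
        if np.asarray(g).size < 2:
            raise DataError(f"group {i} has fewer than 2 observations")


def anova_oneway(*groups) -> tuple:
    """Classical one-way fixed-effects ANOVA; returns (F, p)."""
    if len(groups) < 2:
        raise DataError("ANOVA requires at least 2 groups")
    _check_groups(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def _pooled_mse(groups: dict) -> tuple:
    """ANOVA residual mean square and its degrees of freedom."""
    sse, df = 0.0, 0
    for g in groups.values():
        g = np.asarray(g, dtype=float)
        sse += float(((g - g.mean()) ** 2).sum())
        df += g.size - 1
    return sse / df, df


def pairwise_bonferroni(
    groups: dict,
    contrasts: list,
    label: str = "",
    pooled_error: bool = True,
) -> list:
    """Two-sided t contrasts with Bonferroni adjustment over the family.

    With ``pooled_error`` (default) each contrast's t uses the ANOVA residual
    variance pooled over *all* groups (df = N − k), the classical
    ANOVA-then-Bonferroni multiple-comparison procedure; otherwise each
    contrast is a plain pooled two-sample t.  ``p_adjusted = min(1, m·p)``
    with m the number of contrasts supplied.
    """
    for a, b in contrasts:
        if a not in groups or b not in groups:
            raise ConfigurationError(f"contrast ({a!r}, {b!r}) references unknown condition")
    _check_groups(list(groups.values()))
    m = len(contrasts)
    results = []
    if pooled_error:
        mse, df = _pooled_mse(groups)
    for a, b in contrasts:
        ga = np.asarray(groups[a], dtype=float)
        gb = np.asarray(groups[b], dtype=float)
        diff = float(ga.mean() - gb.mean())
        if pooled_error:
            se = np.sqrt(mse * (1.0 / ga.size + 1.0 / gb.size))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                tstat = diff / se
                p = float(2.0 * stats.t.sf(abs(tstat), df))
        else:
            res = stats.ttest_ind(ga, gb, equal_var=True)
            p = float(res.pvalue)
            if np.isnan(p):
                p = 1.0 if diff == 0 else 0.0
        results.append(
            ComparisonResult(
                label=label,
                contrast=(a, b),
                direction=int(np.sign(diff)),
                p_unadjusted=p,
                p_adjusted=min(1.0, m * p),
                method="bonferroni" + ("/pooled" if pooled_error else ""),
            )
        )
    return results


def dunnett_test(
    groups: dict,
    control,
    sidedness: str = "two-sided",
) -> dict:
    """Many-to-one comparisons against a control (Dunnett's test).

    ``control`` is either a key of ``groups`` or an array of control
    observations.  Adjusted p-values come from the multivariate-t reference
    distribution (evaluated with a fixed internal seed, so results are
    reproducible to ~1e-3).  ``sidedness``: "two-sided" or "greater"
    (one-sided elevation over control).
    """
    if isinstance(control, str):
        if control not in groups:
            raise ConfigurationError(f"control group {control!r} missing")
        control_values = np.asarray(groups[control], dtype=float)
        others = {k: v for k, v in groups.items() if k != control}
    else:
        control_values = np.asarray(control, dtype=float)
        others = dict(groups)
    if not others:
        raise ConfigurationError("Dunnett test needs at least one non-control group")
    _check_groups([control_values] + list(others.values()))
    if sidedness not in ("two-sided", "greater", "less"):
        raise ConfigurationError(f"unknown sidedness {sidedness!r}")
    names = list(others)
    samples = [np.asarray(others[k], dtype=float) for k in names]
    res = stats.dunnett(
        *samples,
        control=control_values,
        alternative=sidedness,
        random_state=np.random.default_rng(_DUNNETT_SEED),
    )
    return {k: float(p) for k, p in zip(names, res.pvalue)}


def tukey_hsd(groups: dict, return_frame: bool = False):
    """All-pairs comparisons via the studentized range (Tukey–Kramer).

    q_ij = |mean_i − mean_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)) with the ANOVA
    residual MSE; adjusted p = SF of the studentized-range distribution with
    k groups and N − k degrees of freedom.  Returns a dict
    (name_i, name_j) → adjusted p.
    """
    if len(groups) < 2:
        raise DataError("Tukey HSD requires at least 2 groups")
    _check_groups(list(groups.values()))
    names = list(groups)
    mse, df = _pooled_mse(groups)
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi = np.asarray(groups[names[i]], dtype=float)
            gj = np.asarray(groups[names[j]], dtype=float)
            diff = abs(float(gi.mean() - gj.mean()))
            se = np.sqrt(mse / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = diff / se
                p = float(stats.studentized_range.sf(q, len(names), df))
            out[(names[i], names[j])] = min(1.0, p)
    if return_frame:
        return pd.DataFrame(
            [{"a": a, "b": b, "p_adjusted": p} for (a, b), p in out.items()]
        )
    return out


def transform_p_matrix(
    results_per_row: dict,
    contrasts: list,
    cap: float = 16.0,
) -> pd.DataFrame:
    """Signed −log10(unadjusted p) heatmap matrix, capped at ±cap.

    Rows are GPCR–arrestin pairs, columns contrasts; the sign encodes the
    direction of the mean difference so loss- and gain-of-recruitment
    contrasts are distinguishable.  Missing contrasts map to 0.
    """
    rows = {}
    for row_label, results in results_per_row.items():
        by_contrast = {r.contrast: r for r in results}
        vals = []
        for contrast in contrasts:
            r = by_contrast.get(tuple(contrast))
            if r is None:
                vals.append(0.0)
                continue
            p = r.p_unadjusted
            mag = cap if p <= 0 else min(cap, -np.log10(p))
            vals.append(float(r.direction) * mag)
        rows[row_label] = vals
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{a} vs {b}" for a, b in contrasts]
    )


def canberra_distance(u, v) -> float:
    """Canberra distance Σ |u_i − v_i| / (|u_i| + |v_i|); 0/0 terms contribute 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DataError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(_scipy_canberra(u, v))


def hierarchical_cluster(matrix: pd.DataFrame, method: str = "complete"):
    """Agglomerative clustering of heatmap rows on Canberra distances.

    Returns ``(Z, leaf_order, newick)``: the linkage matrix, the row labels
    in dendrogram leaf order (deterministic; ties broken by input order) and
    a Newick rendering of the tree.
    """
    labels = [str(x) for x in matrix.index]
    X = matrix.to_numpy(dtype=float)
    if len(labels) < 2:
        return None, labels, f"({labels[0]});" if labels else ";"
    Z = linkage(X, method=method, metric="canberra")
    order = [labels[i] for i in leaves_list(Z)]
    import skbio  # deferred: slow import

    tree = skbio.TreeNode.from_linkage_matrix(Z, labels)
    newick = str(tree).strip()
    return Z, order, newick


def _grk_of(condition: str) -> str | None:
    for g in GRK_NAMES:
        if condition.endswith("+" + g) or condition == g:
            return g
    return None


def call_selectivity(results: list, alpha: float = 0.05) -> str:
    """Assign the selectivity group from the four GRK-rescue contrasts.

    Each result's contrast must be (GRK condition, knockout reference).
    "significant-positive" means adjusted p < alpha with the GRK condition's
    mean above the reference's.  Order of the supplied contrasts is
    irrelevant.
    """
    sig = {}
    for r in results:
        g = _grk_of(r.contrast[0])
        if g is not None:
            sig[g] = bool(r.p_adjusted < alpha and r.direction > 0)
    missing = [g for g in GRK_NAMES if g not in sig]
    if missing:
        raise ConfigurationError(f"missing contrast(s) for {missing}")
    grk23 = sig["GRK2"] or sig["GRK3"]
    grk56 = sig["GRK5"] or sig["GRK6"]
    if grk23 and grk56:
        return "GRK2/3/5/6"
    if grk23 and not grk56:
        return "GRK2/3"
    return "unclassified"


def call_precoupling(
    baselines: dict,
    reference_condition: str = REFERENCE_CONDITION,
    alpha: float = 0.05,
    net_folds: dict | None = None,
) -> dict:
    """Flag ligand-independent pre-coupling per GRK condition.

    A GRK condition is flagged when its normalised baseline BRET ratio is
    significantly elevated over the knockout + empty-vector reference
    (one-sided Dunnett).  When replicate Δ net fold changes are supplied, a
    companion ``dampened`` flag records conditions whose dynamic response
    does not exceed the reference's — the elevated-baseline / dampened-
    dynamics pre-coupling signature.
    """
    if reference_condition not in baselines:
        raise ConfigurationError(f"reference condition {reference_condition!r} missing")
    others = {k: v for k, v in baselines.items() if k != reference_condition}
    pvals = dunnett_test(others, control=np.asarray(baselines[reference_condition], dtype=float), sidedness="greater")
    flags, dampened = {}, {}
    ref_net = None
    if net_folds is not None and reference_condition in net_folds:
        ref_net = float(np.mean(net_folds[reference_condition]))
    for cond, p in pvals.items():
        g = _grk_of(cond) or cond
        flags[g] = bool(p < alpha)
        if net_folds is not None and cond in net_folds and ref_net is not None:
            dampened[g] = bool(float(np.mean(net_folds[cond])) <= ref_net)
    return {"flags": flags, "p_values": {(_grk_of(c) or c): p for c, p in pvals.items()}, "dampened": dampened}


def classify_matrix(
    matrix: pd.DataFrame,
    reference_condition: str = REFERENCE_CONDITION,
    alpha: float = 0.05,
    cap: float = 16.0,
    linkage_method: str = "complete",
    pooled_error: bool = True,
):
    """Full selectivity analysis of a saturating-concentration matrix.

    ``matrix`` is long format (pair, condition, replicate, value).  Returns a
    dict with per-pair comparison results, the transformed heatmap, linkage
    and leaf order, the Newick dendrogram, and one SelectivityCall per pair.
    """
    required = {"pair", "condition", "value"}
    if not required.issubset(matrix.columns):
        raise DataError(f"matrix must have columns {sorted(required)}")
    grk_conditions = [
        c for c in matrix["condition"].unique() if _grk_of(str(c)) is not None
    ]
    if reference_condition not in set(matrix["condition"]):
        raise ConfigurationError(f"reference condition {reference_condition!r} missing")
    contrasts = [(c, reference_condition) for c in sorted(grk_conditions)]
    results_per_pair = {}
    for pair, grp in matrix.groupby("pair", sort=True):
        groups = {
            cond: sub["value"].to_numpy(dtype=float)
            for cond, sub in grp.groupby("condition")
        }
        results_per_pair[pair] = pairwise_bonferroni(
            groups, contrasts, label=str(pair), pooled_error=pooled_error
        )
    heatmap = transform_p_matrix(results_per_pair, contrasts, cap=cap)
    Z, leaf_order, newick = hierarchical_cluster(heatmap, method=linkage_method)
    calls = []
    for pair, results in results_per_pair.items():
        calls.append(
            SelectivityCall(
                pair=str(pair),
                group=call_selectivity(results, alpha=alpha),
                heatmap_row=tuple(heatmap.loc[pair]),
                leaf_position=leaf_order.index(str(pair)),
            )
        )
    return {
        "comparisons": results_per_pair,
        "heatmap": heatmap,
        "linkage": Z,
        "leaf_order": leaf_order,
        "newick": newick,
        "calls": calls,
    }
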