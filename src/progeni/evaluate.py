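"""Benchmarking protocol for prioritization methods.

Repeated k-fold cross-validation in which each training fold re-ranks the
genes, a Gaussian-kernel support vector regression is trained on the
top-ranked genes (network-smoothed expression for the walk-based methods,
plain normalized expression for the baselines) and test-set response is
predicted. Fold quality is a concordance index (or its probabilistic,
rescaled variant). Methods are compared per treatment by mean score,
percent of improved folds (PIF) and BH-adjusted Wilcoxon signed-rank
tests, and overall by a one-sided signed-rank test on per-treatment means.

Also here: the hub-bias diagnostic (hypergeometric overlap of a top list
with the highest-degree nodes) and the treatment-specificity analysis
(split-half rankings, cross-treatment top-list intersections, uniform-rank
p-values combined by Fisher's method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, smooth_expression
from .network import GeneNetwork, build_transition, smoothing_matrix
from .prioritize import (
    NETWORK_METHODS,
    ResponseVector,
    align_samples,
    score_genes,
)

DEFAULT_SVR_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]}


@dataclass
class FoldResult:
    """Outcome of one train/test split for one method."""

    method: str
    repeat: int
    fold: int
    train_samples: list[str]
    test_samples: list[str]
    selected_genes: list[str]
    predictions: pd.Series
    score: float


@dataclass
class ComparisonResult:
    """Per-treatment and overall comparison of two methods."""

    method_a: str
    method_b: str
    per_treatment: pd.DataFrame  # mean_a, mean_b, pif, p_value, fdr
    overall_p: float


def concordance_score(
    predicted,
    observed,
    mode: str = "cindex",
    error_sd: float | None = None,
) -> float:
    """Pairwise ordering agreement between predictions and observations.

    ``cindex``: fraction of sample pairs (untied in the observed values)
    whose predicted ordering matches the observed one; predicted ties
    count 1/2. ``spci``: each pair is weighted by the probability, under a
    normal measurement-error model with standard deviation ``error_sd``,
    that the observed ordering is the true one; the resulting expected
    agreement is affinely rescaled so that 0 is a fully discordant and 1 a
    fully concordant prediction.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 test samples")
    i, j = np.triu_indices(obs.size, k=1)
    d_obs = obs[i] - obs[j]
    untied = d_obs != 0
    if not untied.any():
        raise ValueError("all observed values are equal; concordance undefined")
    d_obs = d_obs[untied]
    d_pred = pred[i][untied] - pred[j][untied]
    agree = np.where(d_pred == 0, 0.5, (np.sign(d_pred) == np.sign(d_obs)).astype(float))
    if mode == "cindex":
        return float(agree.mean())
    if mode == "spci":
        if error_sd is None or error_sd <= 0:
            raise ValueError("mode='spci' requires a positive error_sd")
        q = stats.norm.cdf(np.abs(d_obs) / (error_sd * np.sqrt(2.0)))
        raw = float((agree * q + (1.0 - agree) * (1.0 - q)).mean())
        lo = float((1.0 - q).mean())
        hi = float(q.mean())
        return (raw - lo) / (hi - lo)
    raise ValueError(f"unknown mode {mode!r}")


def pif(scores_a, scores_b) -> float:
    """Percent of folds where A strictly beats B (ties do not count)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold score vectors must have equal length")
    return 100.0 * int(np.sum(a > b)) / a.size


def make_partitions(
    n_samples: int, k: int = 5, n_repeats: int = 50, seed: int = 0
) -> list[list[np.ndarray]]:
    """Test-index partitions for repeated k-fold CV, shared across methods."""
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(n_repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        partitions.append([test for _, test in kf.split(np.arange(n_samples))])
    return partitions


def _wilcoxon_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    if np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative=alternative).pvalue)


def cross_validate(
    network: GeneNetwork,
    X: ExpressionMatrix,
    d: ResponseVector,
    methods=("progeni", "pcc_baseline"),
    n_genes: int = 500,
    k: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    m: int = 100,
    p: float = 0.5,
    metric: str = "cindex",
    error_sd: float | None = None,
    svr_grid: dict | None = None,
    partitions: list[list[np.ndarray]] | None = None,
) -> dict[str, list[FoldResult]]:
    """Repeated k-fold CV benchmark of one or more prioritization methods.

    Every method sees exactly the same partitions. Within each fold, genes
    are ranked on the training samples only; the top ``n_genes`` expressed
    genes become SVR features (smoothed values for walk-based methods, the
    normalized values for baselines). SVR hyperparameters are selected by
    an inner 4-fold grid search on the training fold.
    """
    if X.stage != "normalized":
        raise ValueError("cross_validate expects a normalized expression matrix")
    if svr_grid is None:
        svr_grid = DEFAULT_SVR_GRID
    _, y_all, samples = align_samples(X, d)
    Xa = ExpressionMatrix(data=X.data.loc[samples], stage="normalized")
    n = len(samples)
    if partitions is None:
        partitions = make_partitions(n, k=k, n_repeats=n_repeats, seed=seed)

    B = build_transition(network)
    V = smoothing_matrix(network, Xa.gene_ids, p=p, B=B)
    Xs = smooth_expression(Xa.restrict_genes(V.shared_genes), V)

    results: dict[str, list[FoldResult]] = {meth: [] for meth in methods}
    for meth in methods:
        features = Xs.data if meth in NETWORK_METHODS else Xa.data
        for rep, folds in enumerate(partitions):
            for fold_i, test_idx in enumerate(folds):
                test_mask = np.zeros(n, dtype=bool)
                test_mask[test_idx] = True
                train_samples = [s for s, t in zip(samples, test_mask) if not t]
                test_samples = [s for s, t in zip(samples, test_mask) if t]
                X_train = ExpressionMatrix(
                    data=Xa.data.loc[train_samples], stage="normalized"
                )
                d_train = ResponseVector(
                    d.values.loc[train_samples], treatment_id=d.treatment_id
                )
                ranking = score_genes(
                    network, X_train, d_train, method=meth, m=m, p=p, B=B, V=V
                )
                expressed = set(features.columns)
                available = [g for g in ranking["gene_id"] if g in expressed]
                if n_genes > len(available):
                    warnings.warn(
                        f"requested {n_genes} genes but only {len(available)} "
                        "available; using all"
                    )
                selected = available[:n_genes]
                model = GridSearchCV(SVR(kernel="rbf"), svr_grid, cv=4)
                model.fit(features.loc[train_samples, selected], y_all[~test_mask])
                pred = model.predict(features.loc[test_samples, selected])
                score = concordance_score(
                    pred, y_all[test_mask], mode=metric, error_sd=error_sd
                )
                results[meth].append(
                    FoldResult(
                        method=meth,
                        repeat=rep,
                        fold=fold_i,
                        train_samples=train_samples,
                        test_samples=test_samples,
                        selected_genes=selected,
                        predictions=pd.Series(pred, index=test_samples),
                        score=score,
                    )
                )
    return results


def fold_scores(results: list[FoldResult]) -> np.ndarray:
    return np.array([fr.score for fr in results], dtype=float)


def compare_methods(
    treatment_scores: dict[str, dict[str, np.ndarray]],
    method_a: str,
    method_b: str,
) -> ComparisonResult:
    """Compare two methods from per-treatment fold-score vectors.

    Per treatment: mean scores, PIF of A over B, two-sided Wilcoxon
    signed-rank p (BH-adjusted across treatments). Overall: one-sided
    signed-rank test that A's per-treatment mean scores exceed B's.
    """
    rows = []
    for treatment, by_method in treatment_scores.items():
        a = np.asarray(by_method[method_a], dtype=float)
        b = np.asarray(by_method[method_b], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"unequal fold counts for treatment {treatment!r}")
        rows.append(
            {
                "treatment": treatment,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "pif": pif(a, b),
                "p_value": _wilcoxon_p(a, b, "two-sided"),
            }
        )
    table = pd.DataFrame(rows).set_index("treatment")
    table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    if len(table) < 2:
        raise ValueError("need at least 2 treatments for the overall test")
    overall_p = _wilcoxon_p(
        table["mean_a"].to_numpy(), table["mean_b"].to_numpy(), "greater"
    )
    return ComparisonResult(
        method_a=method_a, method_b=method_b, per_treatment=table, overall_p=overall_p
    )


def top_network_genes(ranked: pd.DataFrame, n_top: int) -> set[str]:
    """Top-ranked on-network genes of a ranking table."""
    on_net = ranked.loc[~ranked["off_network"].astype(bool)]
    return set(on_net.sort_values("rank")["gene_id"].head(n_top))


def hub_bias(
    ranked: pd.DataFrame,
    network: GeneNetwork,
    n_top: int = 500,
    n_hubs: int = 200,
) -> tuple[int, float]:
    """Overlap of the top list with the highest-(weighted-)degree nodes.

    Returns the intersection size and the upper-tail hypergeometric
    p-value of drawing at least that overlap when sampling ``n_top`` nodes
    from the network at random.
    """
    if n_top > network.n_nodes or n_hubs > network.n_nodes:
        raise ValueError("n_top and n_hubs must not exceed the network size")
    degree = pd.Series(network.weighted_degree(), index=network.node_ids)
    hubs = set(
        degree.to_frame("deg")
        .reset_index(names="gene")
        .sort_values(["deg", "gene"], ascending=[False, True], kind="mergesort")
        .head(n_hubs)["gene"]
    )
    overlap = len(top_network_genes(ranked, n_top) & hubs)
    p = float(stats.hypergeom.sf(overlap - 1, network.n_nodes, n_hubs, n_top))
    return overlap, p


@dataclass
class SpecificityResult:
    """Split-half treatment-specificity of top gene lists."""

    per_treatment: pd.DataFrame  # mean_same_intersection, rank, p_value
    intersections: pd.DataFrame  # mean |top(t, half1) & top(s, half2)|
    fisher_statistic: float
    fisher_p: float


def drug_specificity(
    network: GeneNetwork,
    X: ExpressionMatrix,
    responses: dict[str, ResponseVector],
    method: str = "progeni",
    n_repeats: int = 100,
    n_top: int = 500,
    seed: int = 0,
    m: int = 100,
    p: float = 0.5,
) -> SpecificityResult:
    """How specific are the top genes to the treatment they came from?

    Each repeat splits the samples into two halves (floor/ceil sizes),
    ranks genes per treatment on each half, and intersects the top
    ``n_top`` list of treatment t on half 1 with that of every treatment
    on half 2. The same-treatment intersection's rank among the K
    treatments (1 = largest; competition ranking on ties) yields
    p = rank / K under a uniform null, and the K p-values are combined
    with Fisher's method (chi-square with 2K degrees of freedom).
    """
    treatments = sorted(responses)
    K = len(treatments)
    if K < 2:
        raise ValueError("need at least 2 treatments")
    if X.stage != "normalized":
        raise ValueError("drug_specificity expects a normalized expression matrix")
    rng = np.random.default_rng(seed)
    samples = np.array(X.sample_ids)
    n_half = len(samples) // 2
    B = build_transition(network)
    V = smoothing_matrix(network, X.gene_ids, p=p, B=B)

    inter = np.zeros((K, K))
    for _ in range(n_repeats):
        perm = rng.permutation(len(samples))
        halves = (samples[perm[:n_half]], samples[perm[n_half:]])
        tops = []
        for half in halves:
            rows = [s for s in X.sample_ids if s in set(half)]
            X_half = ExpressionMatrix(data=X.data.loc[rows], stage="normalized")
            tops.append(
                {
                    t: top_network_genes(
                        score_genes(
                            network,
                            X_half,
                            _subset_response(responses[t], rows),
                            method=method,
                            m=m,
                            p=p,
                            B=B,
                            V=V,
                        ),
                        n_top,
                    )
                    for t in treatments
                }
            )
        for ti, t in enumerate(treatments):
            for si, s in enumerate(treatments):
                inter[ti, si] += len(tops[0][t] & tops[1][s])
    inter /= n_repeats

    rows = []
    for ti, t in enumerate(treatments):
        same = inter[ti, ti]
        rank = 1 + int(np.sum(inter[ti] > same))
        rows.append({"treatment": t, "mean_same_intersection": same, "rank": rank,
                     "p_value": rank / K})
    table = pd.DataFrame(rows).set_index("treatment")
    statistic = float(-2.0 * np.log(table["p_value"]).sum())
    fisher_p = float(stats.chi2.sf(statistic, df=2 * K))
    return SpecificityResult(
        per_treatment=table,
        intersections=pd.DataFrame(inter, index=treatments, columns=treatments),
        fisher_statistic=statistic,
        fisher_p=fisher_p,
    )


def _subset_response(d: ResponseVector, samples: list[str]) -> ResponseVector:
    keep = [s for s in samples if s in d.values.index]
    return ResponseVector(d.values.loc[keep], treatment_id=d.treatment_id)
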