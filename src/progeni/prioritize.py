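"""Gene prioritization: ProGENI scoring and its published variants.

ProGENI proper: z-score expression, smooth it through the network
(X' = XV), take the m genes whose smoothed expression correlates most with
the response (the RCG set), run an RWR restarting on the RCGs with weights
proportional to their correlations, and rank genes by v_RCG - v_global,
where v_global is the uniform-restart equilibrium. The subtraction removes
the topology-only (hub) component of the score.

Variants exposed through ``score_genes(method=...)``:

- ``progeni``      v_RCG - v_global (the full method)
- ``progeni_nh``   v_RCG only (no hub adjustment)
- ``nhds``         v_global only (response ignored entirely)
- ``progeni_pcc``  |PCC| of smoothed expression vs response
- ``progeni_acg``  all genes in the restart set, weights prop. to |PCC|
- ``pcc_baseline`` |PCC| of unsmoothed expression vs response
- ``elastic_net_baseline`` |standardized coefficient| of a cross-validated
  L1/L2 regression, nonzero coefficients first

All network nodes are scored by the walk-based methods (unexpressed nodes
can still accumulate probability); expressed genes absent from the network
cannot be smoothed and are appended to the ranking by raw |PCC| with the
``off_network`` flag set. Ties are always broken by lexicographic gene ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV

from .expression import ExpressionMatrix, smooth_expression
from .network import (
    GeneNetwork,
    SmoothingMatrix,
    TransitionMatrix,
    build_transition,
    global_equilibrium,
    rwr_direct,
    smoothing_matrix,
)

METHODS = (
    "progeni",
    "progeni_pcc",
    "progeni_acg",
    "progeni_nh",
    "nhds",
    "pcc_baseline",
    "elastic_net_baseline",
)

#: methods whose SVR features are network-smoothed expression
NETWORK_METHODS = ("progeni", "progeni_pcc", "progeni_acg", "progeni_nh", "nhds")

RANKING_COLUMNS = ["rank", "gene_id", "score", "abs_pcc", "is_rcg", "off_network"]


@dataclass
class ResponseVector:
    """One continuous phenotype value per sample (e.g. -log EC50)."""

    values: pd.Series
    treatment_id: str = ""

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in response")
        if self.values.notna().sum() < 3:
            raise ValueError("need at least 3 non-missing response values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def align_samples(X: ExpressionMatrix, d: ResponseVector) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pairwise deletion: keep samples present in both with non-missing d.

    Order follows the expression matrix. Returns (expression values,
    response values, kept sample ids).
    """
    d_nonmissing = d.values.dropna()
    keep = [s for s in X.sample_ids if s in d_nonmissing.index]
    if len(keep) < 3:
        raise ValueError("fewer than 3 paired samples after alignment")
    return (
        X.data.loc[keep].to_numpy(dtype=float),
        d_nonmissing.loc[keep].to_numpy(dtype=float),
        keep,
    )


def abs_pearson(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation of each column of ``values`` with ``y``.

    Zero-variance columns (or a zero-variance y) yield 0 rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != y.shape[0]:
        raise ValueError("sample mismatch between expression and response")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 paired samples")
    xc = values - values.mean(axis=0)
    yc = y - y.mean()
    xsd = np.sqrt((xc**2).sum(axis=0))
    ysd = np.sqrt((yc**2).sum())
    denom = xsd * ysd
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(xc.T @ yc) / np.where(denom == 0, 1.0, denom)
    r[denom == 0] = 0.0
    return np.clip(r, 0.0, 1.0)


def response_correlation(Xs: ExpressionMatrix, d: ResponseVector) -> pd.Series:
    """Per-gene |PCC| between (smoothed) expression and the response."""
    values, y, _ = align_samples(Xs, d)
    return pd.Series(abs_pearson(values, y), index=Xs.gene_ids, name="abs_pcc")


def _top_m(profile: pd.Series, m: int) -> pd.Index:
    """Top-m genes by correlation, ties at the cutoff broken by gene ID."""
    order = profile.to_frame("r").reset_index(names="gene")
    order = order.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Index(order["gene"].head(m))


def rcg_restart(profile: pd.Series, m: int = 100) -> pd.Series:
    """Restart weights over the response-correlated genes (RCGs).

    Support is the top-m genes of the correlation profile; weights are
    proportional to the correlations and sum to one.
    """
    if m < 1:
        raise ValueError("RCG size m must be >= 1")
    if (profile == 0).all():
        raise ValueError("no informative genes: all correlations are zero")
    top = _top_m(profile, m)
    w = pd.Series(0.0, index=profile.index)
    w[top] = profile[top]
    total = w.sum()
    if total == 0:
        raise ValueError("no informative genes: selected correlations are zero")
    return w / total


def _restart_over_network(network: GeneNetwork, weights: pd.Series) -> np.ndarray:
    w = np.zeros(network.n_nodes)
    w[network.index_of(weights.index)] = weights.to_numpy()
    return w


def _ranked_frame(parts: list[pd.DataFrame]) -> pd.DataFrame:
    out = pd.concat(parts, ignore_index=True) if len(parts) > 1 else parts[0].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out[RANKING_COLUMNS].reset_index(drop=True)


def _sorted_part(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _elastic_net_scores(values: np.ndarray, y: np.ndarray, random_state: int = 0) -> np.ndarray:
    """|standardized coefficient| from an elastic net with CV-chosen penalties."""
    model = ElasticNetCV(
        l1_ratio=[0.2, 0.5, 0.8],
        alphas=20,
        cv=5,
        max_iter=5000,
        random_state=random_state,
    )
    sd = values.std(axis=0, ddof=1)
    scale = np.where(sd == 0, 1.0, sd)
    model.fit(values / scale, y)
    return np.abs(model.coef_)


def score_genes(
    network: GeneNetwork,
    X: ExpressionMatrix,
    d: ResponseVector,
    method: str = "progeni",
    m: int = 100,
    p: float = 0.5,
    B: TransitionMatrix | None = None,
    V: SmoothingMatrix | None = None,
) -> pd.DataFrame:
    """Rank genes for one treatment with the chosen prioritization method.

    Parameters
    ----------
    network, X, d
        The gene network, a *normalized* expression matrix and the aligned
        response vector.
    method
        One of :data:`METHODS`.
    m
        RCG set size (walk-based methods).
    p
        Restart probability shared by every RWR.
    B, V
        Optional precomputed transition and smoothing matrices; passing
        them avoids refactorizing when many rankings share one network.

    Returns
    -------
    DataFrame with columns rank, gene_id, score, abs_pcc, is_rcg,
    off_network; ranks are 1-based, scores non-increasing, ties broken by
    gene ID.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if X.stage != "normalized":
        raise ValueError("score_genes expects a normalized expression matrix")

    values, y, _ = align_samples(X, d)
    genes = pd.Index(X.gene_ids)
    r_raw = pd.Series(abs_pearson(values, y), index=genes)
    in_network = genes.isin(set(network.node_ids))

    if method == "pcc_baseline":
        part = pd.DataFrame(
            {
                "gene_id": genes,
                "score": r_raw.to_numpy(),
                "abs_pcc": r_raw.to_numpy(),
                "is_rcg": False,
                "off_network": ~in_network,
            }
        )
        return _ranked_frame([_sorted_part(part)])

    if method == "elastic_net_baseline":
        coefs = _elastic_net_scores(values, y)
        part = pd.DataFrame(
            {
                "gene_id": genes,
                "score": coefs,
                "abs_pcc": r_raw.to_numpy(),
                "is_rcg": False,
                "off_network": ~in_network,
            }
        )
        return _ranked_frame([_sorted_part(part)])

    # --- network-aware methods ---
    if B is None:
        B = build_transition(network)
    if V is None:
        V = smoothing_matrix(network, X.gene_ids, p=p, B=B)
    X_shared = X.restrict_genes(V.shared_genes)
    Xs = smooth_expression(X_shared, V)
    svalues, sy, _ = align_samples(Xs, d)
    r_smooth = pd.Series(abs_pearson(svalues, sy), index=V.shared_genes)

    off_genes = genes[~in_network]
    off_part = pd.DataFrame(
        {
            "gene_id": off_genes,
            "score": r_raw[off_genes].to_numpy(),
            "abs_pcc": r_raw[off_genes].to_numpy(),
            "is_rcg": False,
            "off_network": True,
        }
    )

    if method == "progeni_pcc":
        net_part = pd.DataFrame(
            {
                "gene_id": list(V.shared_genes),
                "score": r_smooth.to_numpy(),
                "abs_pcc": r_smooth.to_numpy(),
                "is_rcg": False,
                "off_network": False,
            }
        )
        return _ranked_frame([_sorted_part(net_part), _sorted_part(off_part)])

    node_ids = pd.Index(network.node_ids)
    abs_pcc_nodes = r_smooth.reindex(node_ids).to_numpy()
    is_rcg = np.zeros(network.n_nodes, dtype=bool)

    if method == "nhds":
        score = global_equilibrium(B, p).v
    else:
        if method == "progeni_acg":
            if (r_smooth == 0).all():
                raise ValueError("no informative genes: all correlations are zero")
            weights = r_smooth / r_smooth.sum()
        else:  # progeni, progeni_nh
            weights = rcg_restart(r_smooth, m=m)
        support = weights[weights > 0]
        is_rcg[network.index_of(support.index)] = True
        w = _restart_over_network(network, weights)
        v_rcg = rwr_direct(B, w, p).v
        if method == "progeni_nh":
            score = v_rcg
        else:
            score = v_rcg - global_equilibrium(B, p).v

    net_part = pd.DataFrame(
        {
            "gene_id": node_ids,
            "score": score,
            "abs_pcc": abs_pcc_nodes,
            "is_rcg": is_rcg,
            "off_network": False,
        }
    )
    parts = [_sorted_part(net_part)]
    if len(off_part):
        parts.append(_sorted_part(off_part))
    return _ranked_frame(parts)
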