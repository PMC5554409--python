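"""Robust ranking: bootstrap subsampling of samples + Borda aggregation.

Each repeat draws a fixed fraction (default 80%) of the samples without
replacement, reruns the prioritization, and the per-repeat rankings are
combined by the geometric mean of Borda scores (top of a K-gene list
scores K, bottom scores 1, so the geometric mean is always defined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import GeneNetwork, TransitionMatrix, SmoothingMatrix, build_transition, smoothing_matrix
from .prioritize import RANKING_COLUMNS, ResponseVector, score_genes

logger = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    n_repeats: int = 100
    sample_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")


def bootstrap_rankings(
    network: GeneNetwork,
    X: ExpressionMatrix,
    d: ResponseVector,
    config: BootstrapConfig,
    method: str = "progeni",
    m: int = 100,
    p: float = 0.5,
    B: TransitionMatrix | None = None,
    V: SmoothingMatrix | None = None,
    return_samples: bool = False,
) -> list[pd.DataFrame]:
    """Rank genes on ``n_repeats`` independent sample subsets.

    Subsets are drawn without replacement; a draw whose response has zero
    variance is redrawn (up to 10 attempts). Fully reproducible from
    ``config.seed``. With ``return_samples`` the per-repeat sample lists
    are returned alongside the rankings.
    """
    rng = np.random.default_rng(config.seed)
    d_nonmissing = d.values.dropna()
    samples = [s for s in X.sample_ids if s in d_nonmissing.index]
    n_keep = int(np.floor(config.sample_fraction * len(samples)))
    if n_keep < 3:
        raise ValueError("subsample would have fewer than 3 samples")
    if B is None:
        B = build_transition(network)
    if V is None and method != "pcc_baseline":
        V = smoothing_matrix(network, X.gene_ids, p=p, B=B)

    rankings = []
    subsamples = []
    for rep in range(config.n_repeats):
        for attempt in range(10):
            chosen = sorted(rng.choice(len(samples), size=n_keep, replace=False))
            subset = [samples[i] for i in chosen]
            if d_nonmissing.loc[subset].nunique() > 1:
                break
            logger.info("repeat %d: degenerate response draw, resampling", rep)
        else:
            raise ValueError(
                f"repeat {rep}: response constant in 10 consecutive subsamples"
            )
        X_sub = ExpressionMatrix(data=X.data.loc[subset], stage=X.stage)
        d_sub = ResponseVector(d_nonmissing.loc[subset], treatment_id=d.treatment_id)
        rankings.append(
            score_genes(network, X_sub, d_sub, method=method, m=m, p=p, B=B, V=V)
        )
        subsamples.append(subset)
    if return_samples:
        return rankings, subsamples
    return rankings


def borda_aggregate(
    rankings: list[pd.DataFrame], offset: int = 1
) -> pd.DataFrame:
    """Aggregate ranked lists by the geometric mean of Borda scores.

    The Borda score of a gene at rank ``rank`` in a K-gene list is
    ``K - rank + offset`` (offset 1 keeps every score positive, so the
    geometric mean never collapses to zero). Output is ordered by
    descending aggregate score, ties broken by gene ID.
    """
    if not rankings:
        raise ValueError("no rankings to aggregate")
    universe = set(rankings[0]["gene_id"])
    for i, rk in enumerate(rankings[1:], start=1):
        other = set(rk["gene_id"])
        if other != universe:
            diff = sorted(universe ^ other)
            raise ValueError(
                f"ranking {i} covers a different gene universe; "
                f"symmetric difference: {diff[:10]}"
            )
    K = len(universe)
    log_sum = pd.Series(0.0, index=sorted(universe))
    for rk in rankings:
        borda = K - rk["rank"].to_numpy(dtype=float) + offset
        log_sum = log_sum.add(
            pd.Series(np.log(borda), index=rk["gene_id"].to_numpy()), fill_value=0.0
        )
    score = np.exp(log_sum / len(rankings))
    out = score.rename("score").to_frame().reset_index(names="gene_id")
    out = out.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["abs_pcc"] = np.nan
    out["is_rcg"] = False
    out["off_network"] = False
    # carry the off_network flag through from the (identical) input universes
    flags = rankings[0].set_index("gene_id")["off_network"]
    out["off_network"] = out["gene_id"].map(flags).to_numpy()
    return out[RANKING_COLUMNS]


def robust_rank(
    network: GeneNetwork,
    X: ExpressionMatrix,
    d: ResponseVector,
    config: BootstrapConfig,
    method: str = "progeni",
    m: int = 100,
    p: float = 0.5,
) -> pd.DataFrame:
    """Bootstrap + Borda in one call (the Robust-ProGENI pipeline)."""
    return borda_aggregate(
        bootstrap_rankings(network, X, d, config, method=method, m=m, p=p)
    )
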