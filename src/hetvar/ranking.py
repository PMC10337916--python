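"""Breeding-value summaries and re-ranking diagnostics across analyses.

Accuracy of an estimated breeding value (EBV) uses the classical
r = sqrt(1 - PEV / sigma2_a), with the prediction-error variance (PEV)
taken as the posterior variance of the animal's breeding-value chain and
sigma2_a as the posterior-mean additive variance.  Re-ranking between the
general, low-SD and high-SD analyses is quantified by Spearman rank
correlations over all shared animals, over the top 20% ranked by the
general-analysis EBV, and by the overlap of top-10 lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


def ebv_accuracy(a_draws: np.ndarray, sigma2_a_draws, animal_ids=None) -> pd.DataFrame:
    """EBV, PEV and accuracy per animal from posterior draws.

    a_draws has shape (n_draws, n_animals).  Accuracy is clamped to [0, 1]:
    PEV = 0 gives 1 (perfect), PEV = sigma2_a gives 0 (no information).
    """
    a_draws = np.asarray(a_draws, dtype=float)
    if a_draws.ndim != 2 or a_draws.shape[0] < 100:
        raise ValueError("need a (n_draws >= 100, n_animals) draw matrix")
    s2a = float(np.mean(sigma2_a_draws))
    if s2a <= 0:
        raise ValueError("posterior-mean additive variance must be positive")
    ebv = a_draws.mean(axis=0)
    pev = a_draws.var(axis=0, ddof=1)
    acc = np.sqrt(np.clip(1.0 - pev / s2a, 0.0, 1.0))
    idx = pd.Index(animal_ids if animal_ids is not None else range(a_draws.shape[1]), name="animal")
    return pd.DataFrame({"ebv": ebv, "pev": pev, "accuracy": acc}, index=idx)


def spearman(x: pd.Series, y: pd.Series) -> float:
    """Spearman rho over the animals shared by two EBV sets (midranks)."""
    x, y = pd.Series(x), pd.Series(y)
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared animals, got {len(shared)}")
    rho = stats.spearmanr(x.loc[shared], y.loc[shared]).statistic
    return float(rho)


@dataclass
class RankComparison:
    set_a: str
    set_b: str
    rho_all: float
    rho_top20: float
    top10_overlap: int


def _top_animals(ebvs: pd.Series, k: int) -> pd.Index:
    """Top-k animals by EBV, descending; ties broken by animal id."""
    df = ebvs.rename("ebv").rename_axis("animal").reset_index()
    df = df.sort_values(["ebv", "animal"], ascending=[False, True], kind="mergesort")
    return pd.Index(df["animal"].head(k))


def compare_analyses(
    ebvs_by_analysis: Mapping[str, pd.Series],
    top_fraction: float = 0.2,
    top_k: int = 10,
) -> list[RankComparison]:
    """Pairwise re-ranking summary over the general/low/high EBV sets.

    All statistics use the animals shared by the three sets.  The top-20%
    subset (floor(top_fraction * n), minimum 2) is selected by the
    general-analysis EBV, as published re-ranking tables do; top-k overlap
    counts shared members of the two sets' own top-k lists, so the
    (general, general) self-check equals k.
    """
    for key in ("general", "low", "high"):
        if key not in ebvs_by_analysis:
            raise ValueError(f"missing EBV set {key!r}")
    sets = {k: pd.Series(v) for k, v in ebvs_by_analysis.items()}
    shared = sets["general"].index
    for s in sets.values():
        shared = shared.intersection(s.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 animals shared across analyses")
    sets = {k: v.loc[shared] for k, v in sets.items()}

    n_top = max(2, int(np.floor(top_fraction * len(shared))))
    top_set = _top_animals(sets["general"], n_top)
    k = min(top_k, len(shared))
    top10 = {name: set(_top_animals(s, k)) for name, s in sets.items()}

    out = []
    for a, b in (("general", "low"), ("general", "high"), ("low", "high")):
        if len(top_set) >= 3:
            rho_top = spearman(sets[a].loc[top_set], sets[b].loc[top_set])
        else:
            rho_top = float("nan")  # a rank correlation of two animals is vacuous
        out.append(
            RankComparison(
                set_a=a,
                set_b=b,
                rho_all=spearman(sets[a], sets[b]),
                rho_top20=rho_top,
                top10_overlap=len(top10[a] & top10[b]),
            )
        )
    return out


def rank_report(comparisons: list[RankComparison], top_k: int = 10) -> dict:
    """JSON-ready report mirroring the published rho/overlap table layout."""
    return {
        "pairs": [
            {
                "set_a": c.set_a,
                "set_b": c.set_b,
                "rho_all": c.rho_all,
                "rho_top20": c.rho_top20,
                "top10_overlap": c.top10_overlap,
            }
            for c in comparisons
        ],
        "top10_self_check": top_k,
    }
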