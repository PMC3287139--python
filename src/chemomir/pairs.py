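"""Pre/post-treatment pair evaluation against a fitted risk model.

Two proof-of-principle questions are scored for each clinical responder
pair: (1) was the pre-treatment tumor called low-risk (chemosensitive) by
the predictor, and (2) did the post-treatment tumor — sampled when acquired
resistance emerged — receive a strictly higher predictive index than the
pre-treatment tumor?  Ties count as incorrect: the call requires a *higher*
index, and the model is never refit on pair samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .risk import RiskModel, assign_risk_group, pi_percentile, predict_pi

__all__ = ["PairResult", "PairSummary", "evaluate_pair", "evaluate_pairs",
           "summarize_pairs"]


@dataclass
class PairResult:
    pair_id: str
    pre_pi: float
    post_pi: float
    pre_percentile: float
    post_percentile: float
    pre_group: str       # low | high
    correct: bool        # post PI strictly greater than pre PI

    @property
    def overall(self) -> str:
        return "correct" if self.correct else "incorrect"


@dataclass
class PairSummary:
    n_pairs: int
    n_pre_low: int
    n_correct: int

    @property
    def pre_low_fraction(self) -> float:
        return self.n_pre_low / self.n_pairs

    @property
    def correct_fraction(self) -> float:
        return self.n_correct / self.n_pairs


def evaluate_pair(model: RiskModel, x_pre, x_post, pair_id="pair") -> PairResult:
    """Score one pre/post pair; both samples must cover the model's features."""
    pre_pi = predict_pi(model, x_pre)
    post_pi = predict_pi(model, x_post)
    pre_pct = pi_percentile(model, pre_pi)
    post_pct = pi_percentile(model, post_pi)
    return PairResult(
        pair_id=pair_id,
        pre_pi=pre_pi,
        post_pi=post_pi,
        pre_percentile=pre_pct,
        post_percentile=post_pct,
        pre_group=assign_risk_group(pre_pct, model.cutoff_percentile),
        correct=post_pi > pre_pi,
    )


def evaluate_pairs(model: RiskModel, X: pd.DataFrame, pairs: pd.DataFrame) -> list:
    """Score every pair in a ``pair_id, pre, post`` table against ``X``
    (features-by-samples)."""
    results = []
    for _, row in pairs.iterrows():
        results.append(evaluate_pair(model, X[row["pre"]], X[row["post"]],
                                     pair_id=row["pair_id"]))
    return results


def summarize_pairs(results) -> PairSummary:
    """Counts of pre-treatment low-risk calls and overall-correct pairs."""
    results = list(results)
    if not results:
        raise ValueError("no pairs to summarize")
    return PairSummary(
        n_pairs=len(results),
        n_pre_low=sum(r.pre_group == "low" for r in results),
        n_correct=sum(r.correct for r in results),
    )


def pairs_table(results) -> pd.DataFrame:
    """Long-format table mirroring the published pre/post layout."""
    rows = []
    for r in results:
        rows.append({"sample": f"{r.pair_id} pre",
                     "predictive_index_percentile": round(r.pre_percentile),
                     "pretreatment_prediction": r.pre_group,
                     "overall_prediction": r.overall})
        rows.append({"sample": f"{r.pair_id} post",
                     "predictive_index_percentile": round(r.post_percentile),
                     "pretreatment_prediction": "",
                     "overall_prediction": ""})
    return pd.DataFrame(rows)
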