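"""AICc model comparison with the uninformative-parameter rule and averaging.

Candidate models are ranked by AICc = -2 logL + 2k + 2k(k+1)/(n-k-1).  Models
within 2 dAICc of the best are competitive, but a model is excluded as
carrying uninformative parameters when a strictly nested, simpler candidate
is within 2 AICc units of it (adding the parameter did not buy a 2-unit
improvement).  When more than one model survives, coefficients are averaged
with AICc weights renormalized over the surviving set, with unconditional
standard errors combining within-model variance and between-model spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np

__all__ = ["aicc", "CandidateFit", "ModelComparison", "compare_models"]


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    if n_obs - n_params - 1 <= 0:
        return np.inf
    return (
        -2.0 * loglik
        + 2.0 * n_params
        + 2.0 * n_params * (n_params + 1.0) / (n_obs - n_params - 1.0)
    )


@dataclass
class CandidateFit:
    """One fitted candidate model: its fixed-effect terms and coefficients."""

    terms: FrozenSet[str]
    loglik: float
    n_params: int
    n_obs: int
    coef: Dict[str, float] = field(default_factory=dict)
    se: Dict[str, float] = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.n_params, self.n_obs)

    @property
    def label(self) -> str:
        return "+".join(sorted(self.terms)) if self.terms else "intercept-only"


@dataclass
class ModelComparison:
    candidates: List[CandidateFit]
    delta: Dict[str, float]
    weight: Dict[str, float]
    selected: List[CandidateFit]
    averaged_coef: Dict[str, float]
    averaged_se: Dict[str, float]

    @property
    def best(self) -> CandidateFit:
        return self.selected[0]

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": [c.label for c in self.candidates],
                "logLik": [c.loglik for c in self.candidates],
                "n_params": [c.n_params for c in self.candidates],
                "AICc": [c.aicc for c in self.candidates],
                "dAICc": [self.delta[c.label] for c in self.candidates],
                "weight": [self.weight[c.label] for c in self.candidates],
                "selected": [c in self.selected for c in self.candidates],
            }
        ).sort_values("AICc", ignore_index=True)


def _is_uninformative(cand: CandidateFit, others: Sequence[CandidateFit]) -> bool:
    """True if a strictly simpler nested model is within 2 AICc of ``cand``."""
    for other in others:
        if other.terms < cand.terms and other.aicc - cand.aicc < 2.0:
            return True
    return False


def compare_models(
    candidates: Sequence[CandidateFit], delta_threshold: float = 2.0
) -> ModelComparison:
    """Rank candidates, apply the competitive/uninformative rules, average."""
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidate models")
    aiccs = np.array([c.aicc for c in cands])
    best_aicc = aiccs.min()
    delta = {c.label: float(c.aicc - best_aicc) for c in cands}
    raw_w = np.exp(-0.5 * (aiccs - best_aicc))
    weights = raw_w / raw_w.sum()
    weight = {c.label: float(w) for c, w in zip(cands, weights)}

    competitive = [c for c in cands if delta[c.label] < delta_threshold]
    selected = [c for c in competitive if not _is_uninformative(c, cands)]
    if not selected:  # every competitive model nested above a simpler one
        selected = [min(competitive, key=lambda c: (len(c.terms), c.aicc))]
    selected.sort(key=lambda c: c.aicc)

    avg_coef: Dict[str, float] = {}
    avg_se: Dict[str, float] = {}
    sel_w = np.array([weight[c.label] for c in selected])
    sel_w = sel_w / sel_w.sum()
    all_terms = sorted({t for c in selected for t in c.coef})
    for term in all_terms:
        # average over models containing the term (natural averaging)
        present = [(w, c) for w, c in zip(sel_w, selected) if term in c.coef]
        wsum = sum(w for w, _ in present)
        if wsum <= 0:
            continue
        b = sum(w * c.coef[term] for w, c in present) / wsum
        var = (
            sum(
                w * (c.se.get(term, 0.0) ** 2 + (c.coef[term] - b) ** 2)
                for w, c in present
            )
            / wsum
        )
        avg_coef[term] = float(b)
        avg_se[term] = float(np.sqrt(var))
    return ModelComparison(
        candidates=cands,
        delta=delta,
        weight=weight,
        selected=selected,
        averaged_coef=avg_coef,
        averaged_se=avg_se,
    )
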