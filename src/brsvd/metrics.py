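"""Confusion-matrix validity metrics for SNP selection against a causal list.

Selected vs. truly-causal SNP sets are scored by sensitivity (power),
specificity, positive/negative predictive value and false-positive rate.
Ratios with a zero denominator are *undefined* (None), never silently 0,
and replicate averaging tracks how many replicates defined each rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["ConfusionMetrics", "confusion_metrics", "select_significant",
           "average_over_replicates", "read_causal_list", "write_causal_list"]


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sen(self) -> float | None:
        """Sensitivity TP/(TP+FN), the power to pick up causal SNPs."""
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def spe(self) -> float | None:
        d = self.fp + self.tn
        return self.tn / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.fn + self.tn
        return self.tn / d if d else None

    @property
    def fpr(self) -> float | None:
        spe = self.spe
        return None if spe is None else 1.0 - spe

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "sen": self.sen, "spe": self.spe, "ppv": self.ppv,
                "npv": self.npv, "fpr": self.fpr}


def confusion_metrics(selected: Iterable[str], causal: Iterable[str],
                      all_snps: Sequence[str]) -> ConfusionMetrics:
    """Score a selected SNP set against the causal truth by set algebra."""
    universe = set(all_snps)
    selected = set(selected)
    causal = set(causal)
    if not causal <= universe:
        missing = sorted(causal - universe)[:5]
        raise ValueError(f"causal SNP id(s) absent from the SNP universe: {missing}")
    if not selected <= universe:
        missing = sorted(selected - universe)[:5]
        raise ValueError(f"selected SNP id(s) absent from the SNP universe: {missing}")
    tp = len(selected & causal)
    fp = len(selected - causal)
    fn = len(causal - selected)
    tn = len(universe) - tp - fp - fn
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def select_significant(results: Mapping[str, float] | pd.DataFrame,
                       alpha: float = 0.05) -> set[str]:
    """SNP ids with p-value strictly below alpha.

    ``results`` is either a mapping snp_id -> p-value or a DataFrame with
    ``snp_id`` and ``p_value`` columns (covariate rows are the caller's
    responsibility to exclude; ``PermutationResult.snp_table`` already does).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if isinstance(results, pd.DataFrame):
        items = zip(results["snp_id"], results["p_value"])
    else:
        items = results.items()
    return {sid for sid, p in items if p < alpha}


RATE_NAMES = ("sen", "spe", "ppv", "npv", "fpr")


def average_over_replicates(metrics: Sequence[ConfusionMetrics]) -> dict:
    """Arithmetic mean of counts and of each defined rate.

    Undefined rates are excluded from that rate's mean; ``n_defined``
    records the per-rate denominator actually used.
    """
    if not metrics:
        raise ValueError("need at least one replicate")
    out: dict = {"n_replicates": len(metrics)}
    for count in ("tp", "fp", "fn", "tn"):
        out[count] = sum(getattr(m, count) for m in metrics) / len(metrics)
    out["n_defined"] = {}
    for rate in RATE_NAMES:
        vals = [getattr(m, rate) for m in metrics if getattr(m, rate) is not None]
        out[rate] = sum(vals) / len(vals) if vals else None
        out["n_defined"][rate] = len(vals)
    return out


def read_causal_list(path) -> set[str]:
    """Causal-truth list: one SNP id per line (an 'answer sheet')."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_causal_list(path, causal: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for sid in sorted(causal):
            fh.write(f"{sid}\n")
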