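"""Batch-effect screening with the Dispersion Separability Criterion.

DSC is the ratio of between-batch to within-batch dispersion,

    S_b = sqrt( sum_k (n_k/N) * ||mu_k - mu||^2 )
    S_w = sqrt( sum_k (n_k/N) * (1/n_k) * sum_{i in k} ||x_i - mu_k||^2 )
    DSC = S_b / S_w,

with a permutation p-value (fraction of batch-label shuffles whose DSC is
>= the observed one).  Batches are screened per histotype by a greedy
loop: while the stop rule is unmet and more than one batch remains, the
batch whose removal minimizes the DSC of the remainder is removed.

The published procedure removes batches "until DSC < 0.3 and p < 0.05".
Read literally this keeps removing while the batch structure is
non-significant; since a low p flags a strong batch effect, the intended
stop is arguably DSC < 0.3 or p >= 0.05.  Both rules are available
(``stop_rule="literal"`` is the default, ``"lenient"`` the disjunction) and
the report records which condition ended the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import Annotations, ProteinMatrix

DSC_THRESHOLD = 0.3
P_THRESHOLD = 0.05
DEFAULT_N_PERM = 1000


@dataclass
class DscResult:
    dsc: float
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        assert self.dsc >= 0 and 0 <= self.p_value <= 1


@dataclass
class BatchScreenReport:
    """Per-histotype removal trace."""

    removed: dict[str, list[str]] = field(default_factory=dict)
    trace: dict[str, list[DscResult]] = field(default_factory=dict)
    removed_case_count: int = 0
    stop_rule: str = "literal"
    stop_reason: dict[str, str] = field(default_factory=dict)

    def kept_cases(self, annotations: Annotations) -> list[str]:
        """Cases surviving the screen, in annotation order."""
        drop = set()
        batch = annotations.batch_id
        for histotype, batches in self.removed.items():
            hcases = annotations.cases_of(histotype)
            drop |= {c for c in hcases if batch[c] in set(batches)}
        return [c for c in annotations.case_ids if c not in drop]

    def trace_table(self) -> pd.DataFrame:
        rows = []
        for histotype, batches in self.removed.items():
            trace = self.trace[histotype]
            for step, res in enumerate(trace):
                rows.append({
                    "histotype": histotype,
                    "step": step,
                    "removed_batch": batches[step - 1] if step > 0 else "",
                    "dsc": res.dsc,
                    "p_value": res.p_value,
                })
        return pd.DataFrame(rows)


def _dsc_value(values: np.ndarray, codes: np.ndarray, n_batches: int) -> float:
    n = len(values)
    mu = values.mean(axis=0)
    s_b = 0.0
    s_w = 0.0
    for k in range(n_batches):
        members = values[codes == k]
        n_k = len(members)
        if n_k == 0:
            continue
        mu_k = members.mean(axis=0)
        s_b += (n_k / n) * float(((mu_k - mu) ** 2).sum())
        s_w += (n_k / n) * float(((members - mu_k) ** 2).sum()) / n_k
    s_b, s_w = np.sqrt(s_b), np.sqrt(s_w)
    if s_w == 0:
        raise ValueError("degenerate data: within-batch dispersion is zero")
    return s_b / s_w


def compute_dsc(
    matrix: ProteinMatrix,
    batch_labels: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> DscResult:
    """DSC of the given batch partition with a permutation p-value.

    A single batch has no between-batch dispersion: DSC = 0, p = 1.
    """
    values = matrix.values
    if len(values) < 2:
        raise ValueError("need at least 2 cases")
    labels = batch_labels.loc[matrix.case_ids]
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        return DscResult(dsc=0.0, p_value=1.0, n_perm=0, seed=seed)

    observed = _dsc_value(values, codes, len(uniques))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _dsc_value(values, perm, len(uniques)) >= observed - 1e-12:
            hits += 1
    return DscResult(dsc=float(observed), p_value=hits / n_perm, n_perm=n_perm, seed=seed)


def _stop(res: DscResult, rule: str, dsc_thr: float, p_thr: float) -> str | None:
    """Return the reason the loop should stop, or None to continue."""
    if rule == "literal":
        if res.dsc < dsc_thr and res.p_value < p_thr:
            return f"dsc<{dsc_thr} and p<{p_thr}"
    elif rule == "lenient":
        if res.dsc < dsc_thr:
            return f"dsc<{dsc_thr}"
        if res.p_value >= p_thr:
            return f"p>={p_thr} (no significant batch structure)"
    else:
        raise ValueError("stop_rule must be 'literal' or 'lenient'")
    return None


def screen_batches(
    matrix: ProteinMatrix,
    annotations: Annotations,
    dsc_threshold: float = DSC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    stop_rule: str = "literal",
) -> BatchScreenReport:
    """Greedy per-histotype batch removal.

    Each round evaluates, for every remaining batch, the DSC of the data
    with that batch removed, and removes the batch minimizing it.  The loop
    ends when the stop rule fires or a single batch remains.
    """
    report = BatchScreenReport(stop_rule=stop_rule)
    batch = annotations.batch_id
    rng = np.random.default_rng(seed)

    for histotype in sorted(annotations.histotype.unique()):
        cases = annotations.cases_of(histotype)
        removed: list[str] = []
        trace: list[DscResult] = []
        while True:
            keep = [c for c in cases if batch[c] not in set(removed)]
            sub = matrix.subset_cases(keep)
            res = compute_dsc(sub, batch, n_perm=n_perm,
                              seed=int(rng.integers(2**31)))
            trace.append(res)
            remaining = sorted(batch.loc[keep].unique())
            reason = _stop(res, stop_rule, dsc_threshold, p_threshold)
            if reason is not None:
                report.stop_reason[histotype] = reason
                break
            if len(remaining) <= 1:
                report.stop_reason[histotype] = "single batch left"
                break
            # candidate evaluation: DSC of the remainder after each removal
            best_batch, best_dsc = None, np.inf
            for cand in remaining:
                rest = [c for c in keep if batch[c] != cand]
                rest_codes, rest_uniq = pd.factorize(batch.loc[rest])
                if len(rest_uniq) < 2:
                    cand_dsc = 0.0
                else:
                    cand_dsc = _dsc_value(
                        matrix.subset_cases(rest).values, rest_codes, len(rest_uniq)
                    )
                if cand_dsc < best_dsc:
                    best_batch, best_dsc = cand, cand_dsc
            removed.append(best_batch)
        report.removed[histotype] = removed
        report.trace[histotype] = trace
        report.removed_case_count += sum(
            1 for c in cases if batch[c] in set(removed)
        )
    return report
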