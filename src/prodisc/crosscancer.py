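"""Cross-cancer effects, classification effectivity scores, and the
drug-response concordance test.

A cross-cancer effect exists when the same pair of genetic classes is
discriminable on protein profiles in two different histotypes AND the
characteristic proteins overlap in the same direction more than expected by
chance.  With s1A/s2A the proteins increased for class 1 / class 2 in
histotype A (and s1B/s2B likewise in histotype B), the intersection count
is

    ni = |s1A ∩ s1B| + |s2A ∩ s2B|

(directions matched, never crossed) and significance is the one-tailed
hypergeometric upper tail P(X >= ni) over the protein universe (the panel
size, 120 for the study's RPPA panel).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from .discriminability import EnergyResult, adjust_bh


@dataclass
class CrossCancerResult:
    """Directional characteristic-protein overlap for one class pair
    observed in two histotypes."""

    class_1: str
    class_2: str
    histotype_a: str
    histotype_b: str
    s1a: frozenset[str]
    s2a: frozenset[str]
    s1b: frozenset[str]
    s2b: frozenset[str]
    ni: int
    p_fisher: float
    n_proteins: int
    shared_up_1: frozenset[str]
    shared_up_2: frozenset[str]
    p_adj: float | None = None
    significant: bool | None = None


def intersect_count(s1a, s2a, s1b, s2b) -> int:
    """Directional intersection count ni = |s1A∩s1B| + |s2A∩s2B|."""
    s1a, s2a, s1b, s2b = map(frozenset, (s1a, s2a, s1b, s2b))
    if s1a & s2a or s1b & s2b:
        raise ValueError("direction sets within one histotype must be disjoint")
    return len(s1a & s1b) + len(s2a & s2b)


def overlap_pvalue(ni: int, size_a: int, size_b: int, n_proteins: int = 120) -> float:
    """One-tailed overlap significance: P(X >= ni), X hypergeometric with
    population ``n_proteins``, ``size_a`` marked, ``size_b`` drawn."""
    if not (0 <= ni <= min(size_a, size_b) <= n_proteins):
        raise ValueError(
            f"inconsistent sizes: ni={ni}, size_a={size_a}, "
            f"size_b={size_b}, n_proteins={n_proteins}"
        )
    if max(size_a, size_b) > n_proteins:
        raise ValueError("set size exceeds protein universe")
    return float(hypergeom.sf(ni - 1, n_proteins, size_a, size_b))


def find_cross_cancer_effects(
    results: list[EnergyResult],
    n_proteins: int | None = None,
    alpha: float = 0.05,
) -> list[CrossCancerResult]:
    """Search significant subtests for same-class-pair, different-histotype
    candidates and test their directional characteristic-protein overlap.

    Only BH-significant subtests with contribution profiles are candidates.
    All candidates (including ni = 0, assigned p = 1) form one BH family;
    an effect is flagged when the adjusted p < ``alpha`` and ni >= 1.
    ``n_proteins`` defaults to the panel width recorded on the contribution
    profiles.
    """
    usable = [
        r for r in results
        if r.significant and r.contributions is not None
    ]
    by_class_pair: dict[tuple[str, str], list[EnergyResult]] = {}
    for r in usable:
        key = (r.pair.class_a, r.pair.class_b)
        by_class_pair.setdefault(key, []).append(r)

    candidates: list[CrossCancerResult] = []
    for (c1, c2), members in sorted(by_class_pair.items()):
        for ra, rb in itertools.combinations(
            sorted(members, key=lambda r: r.pair.histotype), 2
        ):
            if ra.pair.histotype == rb.pair.histotype:
                continue
            universe = n_proteins or len(ra.contributions.contributions)
            s1a, s2a = ra.contributions.up_in_a, ra.contributions.up_in_b
            s1b, s2b = rb.contributions.up_in_a, rb.contributions.up_in_b
            ni = intersect_count(s1a, s2a, s1b, s2b)
            size_a = len(s1a) + len(s2a)
            size_b = len(s1b) + len(s2b)
            if min(size_a, size_b) == 0:
                p = 1.0
            else:
                p = overlap_pvalue(ni, size_a, size_b, universe)
            candidates.append(CrossCancerResult(
                class_1=c1, class_2=c2,
                histotype_a=ra.pair.histotype, histotype_b=rb.pair.histotype,
                s1a=s1a, s2a=s2a, s1b=s1b, s2b=s2b,
                ni=ni, p_fisher=p, n_proteins=universe,
                shared_up_1=frozenset(s1a & s1b),
                shared_up_2=frozenset(s2a & s2b),
            ))

    p_adj, flags = adjust_bh([c.p_fisher for c in candidates], alpha=alpha)
    for c, pa, sig in zip(candidates, p_adj, flags):
        c.p_adj = float(pa)
        c.significant = bool(sig) and c.ni >= 1
    return candidates


def cross_cancer_table(candidates: list[CrossCancerResult]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "class_1": c.class_1,
            "class_2": c.class_2,
            "histotype_a": c.histotype_a,
            "histotype_b": c.histotype_b,
            "ni": c.ni,
            "p_fisher": c.p_fisher,
            "p_adj": c.p_adj,
            "significant": c.significant,
            "shared_up_1": ";".join(sorted(c.shared_up_1)),
            "shared_up_2": ";".join(sorted(c.shared_up_2)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classification effectivity score
# ---------------------------------------------------------------------------

@dataclass
class CesReport:
    """Percent of evaluated class-vs-class subtests found significant,
    globally and broken down by class or histotype."""

    classification_name: str
    global_ces: float | None
    global_counts: tuple[int, int]  # (significant, evaluated)
    per_class: pd.DataFrame  # class, significant, evaluated, ces
    per_histotype: pd.DataFrame


def _pct(significant: int, evaluated: int) -> float | None:
    return 100.0 * significant / evaluated if evaluated else None


def ces(results: list[EnergyResult], classification_name: str = "") -> CesReport:
    """Classification effectivity score at the global, class, and histotype
    level.  Evaluated subtests are exactly the enumerated ones (the minimum
    group-size rule is applied at enumeration)."""
    n_eval = len(results)
    n_sig = sum(1 for r in results if r.significant)

    class_rows = {}
    for r in results:
        for cls in (r.pair.class_a, r.pair.class_b):
            sig, tot = class_rows.get(cls, (0, 0))
            class_rows[cls] = (sig + bool(r.significant), tot + 1)
    per_class = pd.DataFrame(
        [
            {"class": cls, "significant": s, "evaluated": t, "ces": _pct(s, t)}
            for cls, (s, t) in sorted(class_rows.items())
        ]
    )

    hist_rows = {}
    for r in results:
        sig, tot = hist_rows.get(r.pair.histotype, (0, 0))
        hist_rows[r.pair.histotype] = (sig + bool(r.significant), tot + 1)
    per_histotype = pd.DataFrame(
        [
            {"histotype": h, "significant": s, "evaluated": t, "ces": _pct(s, t)}
            for h, (s, t) in sorted(hist_rows.items())
        ]
    )

    return CesReport(
        classification_name=classification_name,
        global_ces=_pct(n_sig, n_eval),
        global_counts=(n_sig, n_eval),
        per_class=per_class,
        per_histotype=per_histotype,
    )


# ---------------------------------------------------------------------------
# Drug-response / discriminability concordance
# ---------------------------------------------------------------------------

def concordance_fisher(table: pd.DataFrame) -> tuple[np.ndarray, float]:
    """One-tailed Fisher exact test for a positive association between cell
    line drug response and protein-profile discriminability.

    ``table`` needs binary columns ``response`` and ``discriminable``
    (values Y/N or booleans), one row per actionable gene-histotype pair.
    Returns the 2x2 counts [[YY, YN], [NY, NN]] (response x discriminable)
    and the upper-tail p-value.  Degenerate margins give p = 1.
    """
    if len(table) == 0:
        raise ValueError("concordance table is empty")

    def as_bool(col: pd.Series) -> pd.Series:
        if col.dtype == bool:
            return col
        up = col.astype(str).str.strip().str.upper()
        if not up.isin(("Y", "N")).all():
            raise ValueError(f"non-Y/N value in column {col.name!r}")
        return up == "Y"

    resp = as_bool(table["response"])
    disc = as_bool(table["discriminable"])
    counts = np.array([
        [int((resp & disc).sum()), int((resp & ~disc).sum())],
        [int((~resp & disc).sum()), int((~resp & ~disc).sum())],
    ])
    if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        import warnings

        warnings.warn("degenerate margin in concordance table; p = 1")
        return counts, 1.0
    _, p = fisher_exact(counts, alternative="greater")
    return counts, float(p)
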