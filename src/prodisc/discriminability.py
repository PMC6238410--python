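"""Energy-distance discriminability of class pairs on protein profiles.

For two groups of cases from one histotype, the (unnormalized) energy
distance is

    de = sum of within-group pairwise Euclidean distances of group A
       + sum of within-group pairwise Euclidean distances of group B
       - 2 * sum of cross-group pairwise distances.

More negative de means the two groups are more separated relative to their
internal spread.  Significance is assessed by Monte-Carlo permutation:
random re-splits of the pooled cases into groups of the original sizes, the
p-value being the frequency of a permuted de lower than or equal to the
observed one (ties count).  A per-protein contribution profile is obtained
by re-evaluating the same sum with the one-dimensional distance
|x_k - y_k| on a single protein k; proteins whose (negative) contribution
exceeds in magnitude the largest positive contribution — a dynamic estimate
of the contribution noise floor — are the "characteristic proteins" of the
pair, split by group-mean comparison into the set increased in A and the
set increased in B.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from statsmodels.stats.multitest import multipletests

from .core_data import Annotations, ClassAssignment, ProteinMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1_000_000
MIN_GROUP = 5


@dataclass(frozen=True)
class GroupPair:
    """Two disjoint within-histotype case groups defined by class labels."""

    histotype: str
    class_a: str
    class_b: str
    cases_a: tuple[str, ...]
    cases_b: tuple[str, ...]

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.cases_a), len(self.cases_b)


@dataclass
class ContributionProfile:
    """Per-protein contributions to de and the characteristic-protein sets.

    ``contributions`` holds the raw per-protein energy-distance sums;
    ``centered`` subtracts each protein's exact permutation mean (see
    :func:`protein_contributions`), and the threshold rule operates on
    whichever scale was selected.
    """

    contributions: pd.Series  # index = protein_id, raw scale
    centered: pd.Series
    threshold: float
    up_in_a: frozenset[str]
    up_in_b: frozenset[str]


@dataclass
class EnergyResult:
    """Outcome of one class-vs-class subtest."""

    pair: GroupPair
    de: float
    s_dis: float  # de / (i * j)
    p_raw: float
    s_rand: float  # mean of permuted de / (i * j)
    n_perm: int
    seed: int
    p_adj: float | None = None
    significant: bool | None = None
    contributions: ContributionProfile | None = None


def energy_distance(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Unnormalized energy distance between two groups of row vectors."""
    x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
    if x_a.shape[1] != x_b.shape[1]:
        raise ValueError(
            f"protein dimension mismatch: {x_a.shape[1]} vs {x_b.shape[1]}"
        )
    within_a = pdist(x_a).sum() if len(x_a) > 1 else 0.0
    within_b = pdist(x_b).sum() if len(x_b) > 1 else 0.0
    cross = cdist(x_a, x_b).sum()
    return float(within_a + within_b - 2.0 * cross)


def _pooled_distances(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    pooled = np.vstack([np.atleast_2d(x_a), np.atleast_2d(x_b)])
    n = len(pooled)
    dmat = np.zeros((n, n))
    dmat[np.triu_indices(n, 1)] = pdist(pooled)
    return dmat + dmat.T


def _de_from_dmat(dmat: np.ndarray, idx_a: np.ndarray) -> float:
    """de for the split (idx_a, complement) given the pooled distance matrix."""
    mask = np.zeros(len(dmat), dtype=bool)
    mask[idx_a] = True
    within_a = dmat[np.ix_(mask, mask)].sum() / 2.0
    within_b = dmat[np.ix_(~mask, ~mask)].sum() / 2.0
    total = dmat.sum() / 2.0
    cross = total - within_a - within_b
    return float(within_a + within_b - 2.0 * cross)


def mc_pvalue(
    x_a: np.ndarray,
    x_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    pseudocount: bool = False,
) -> tuple[float, float]:
    """Monte-Carlo permutation p-value and mean permuted score.

    Random re-splits of the pooled cases into groups of sizes (i, j) are
    drawn uniformly; ``p_raw`` is the frequency of a permuted de <= the
    observed de (ties satisfy the event).  ``s_rand`` is the mean permuted
    de divided by i*j.  With ``pseudocount`` the (r+1)/(n+1) estimator is
    used instead of the raw frequency.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
    i, j = len(x_a), len(x_b)
    de_obs = energy_distance(x_a, x_b)
    dmat = _pooled_distances(x_a, x_b)
    n = i + j
    total = dmat.sum() / 2.0

    rng = np.random.default_rng(seed)
    tol = 1e-9 * max(1.0, abs(de_obs))  # tie tolerance for float noise
    hits = 0
    de_sum = 0.0
    # de depends on the split only through the within-group sums:
    # de = 3*(W_A + W_B) - 2*total.  Chunked vectorized evaluation.
    chunk = max(1, min(n_perm, 4096))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # uniform random subsets of size i via argpartition of random keys
        keys = rng.random((m, n))
        idx_a = np.argpartition(keys, i - 1, axis=1)[:, :i]
        rows_a = dmat[idx_a[:, :, None], idx_a[:, None, :]]
        w_a = rows_a.sum(axis=(1, 2)) / 2.0
        mask = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask, idx_a, True, axis=1)
        # W_B = total - W_A - cross; cross = z D (1-z) computed via row sums
        row_sums = mask @ dmat  # (m, n): sum of D[a, :] over a in A
        cross = (row_sums * ~mask).sum(axis=1)
        w_b = total - w_a - cross
        de_perm = 3.0 * (w_a + w_b) - 2.0 * total
        hits += int((de_perm <= de_obs + tol).sum())
        de_sum += float(de_perm.sum())
        done += m

    if pseudocount:
        p_raw = (hits + 1) / (n_perm + 1)
    else:
        p_raw = hits / n_perm
    s_rand = de_sum / n_perm / (i * j)
    return p_raw, s_rand


def exhaustive_pvalue(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Exact permutation p-value by enumerating all C(i+j, i) splits.

    Intended as a small-n oracle and cross-check for :func:`mc_pvalue`.
    """
    x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
    i = len(x_a)
    de_obs = energy_distance(x_a, x_b)
    dmat = _pooled_distances(x_a, x_b)
    n = len(dmat)
    tol = 1e-9 * max(1.0, abs(de_obs))
    hits = 0
    count = 0
    for combo in itertools.combinations(range(n), i):
        de = _de_from_dmat(dmat, np.array(combo))
        hits += de <= de_obs + tol
        count += 1
    return hits / count


def enumerate_subtests(
    assignment: ClassAssignment,
    annotations: Annotations,
    min_group: int = MIN_GROUP,
) -> list[GroupPair]:
    """One GroupPair per unordered class pair per histotype with both
    groups of at least ``min_group`` cases."""
    pairs: list[GroupPair] = []
    labels = assignment.labels
    for histotype in sorted(annotations.histotype.unique()):
        cases = [c for c in annotations.cases_of(histotype) if c in labels.index]
        by_class: dict[str, list[str]] = {}
        for c in cases:
            by_class.setdefault(labels[c], []).append(c)
        eligible = sorted(k for k, v in by_class.items() if len(v) >= min_group)
        for class_a, class_b in itertools.combinations(eligible, 2):
            pairs.append(GroupPair(
                histotype=histotype,
                class_a=class_a,
                class_b=class_b,
                cases_a=tuple(by_class[class_a]),
                cases_b=tuple(by_class[class_b]),
            ))
    return pairs


def adjust_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, significance flags at ``alpha``).
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def dynamic_threshold(values: np.ndarray) -> tuple[float, np.ndarray]:
    """The characteristic-protein selection rule on a contribution vector.

    The threshold is the largest positive contribution (an estimate of the
    contribution noise floor; 0 when none is positive); selected are the
    proteins with negative contribution whose magnitude exceeds it.
    """
    values = np.asarray(values, dtype=float)
    positive = values[values > 0]
    tau = float(positive.max()) if len(positive) else 0.0
    return tau, (values < 0) & (np.abs(values) > tau)


def protein_contributions(
    x_a: np.ndarray,
    x_b: np.ndarray,
    protein_ids,
    center: str = "permutation-mean",
) -> ContributionProfile:
    """Per-protein contribution profile and characteristic-protein sets.

    The contribution of protein k is the energy-distance sum evaluated with
    the distance |x_k - y_k| instead of the Euclidean distance in full
    protein space.  Characteristic proteins have negative contribution with
    magnitude above the largest positive contribution (the dynamic noise
    threshold); their direction is the group with the higher mean.  Proteins
    with exactly equal group means are excluded from both direction sets and
    logged.

    The raw sum carries a group-size bias: its expectation over random
    re-splits is (C(i,2) + C(j,2) - 2ij) times the mean pooled pairwise
    1-D distance, which is far from zero unless (i-j)^2 = i+j, so for
    balanced groups every raw contribution is negative and the dynamic
    threshold would select essentially the whole panel.  With the default
    ``center="permutation-mean"`` each contribution is centered at this
    exact permutation expectation before thresholding, making the noise
    floor meaningful for any group sizes; ``center="none"`` applies the
    rule to the raw sums.
    """
    if center not in ("permutation-mean", "none"):
        raise ValueError("center must be 'permutation-mean' or 'none'")
    x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
    protein_ids = list(protein_ids)
    if x_a.shape[1] != len(protein_ids):
        raise ValueError("protein_ids length does not match matrix width")
    i, j = len(x_a), len(x_b)
    n = i + j

    contrib = np.empty(len(protein_ids))
    centered = np.empty(len(protein_ids))
    size_factor = (i * (i - 1) + j * (j - 1)) / 2.0 - 2.0 * i * j
    n_pairs = n * (n - 1) / 2.0
    for k in range(len(protein_ids)):
        wa = pdist(x_a[:, [k]]).sum() if i > 1 else 0.0
        wb = pdist(x_b[:, [k]]).sum() if j > 1 else 0.0
        cross = cdist(x_a[:, [k]], x_b[:, [k]]).sum()
        contrib[k] = wa + wb - 2.0 * cross
        pooled_mean = (wa + wb + cross) / n_pairs
        centered[k] = contrib[k] - size_factor * pooled_mean

    basis = centered if center == "permutation-mean" else contrib
    threshold, characteristic = dynamic_threshold(basis)

    mean_a = x_a.mean(axis=0)
    mean_b = x_b.mean(axis=0)
    up_a, up_b = set(), set()
    for k in np.flatnonzero(characteristic):
        if mean_a[k] > mean_b[k]:
            up_a.add(protein_ids[k])
        elif mean_b[k] > mean_a[k]:
            up_b.add(protein_ids[k])
        else:
            logger.info(
                "characteristic protein %s has equal group means; "
                "excluded from both direction sets", protein_ids[k],
            )
    return ContributionProfile(
        contributions=pd.Series(contrib, index=protein_ids),
        centered=pd.Series(centered, index=protein_ids),
        threshold=threshold,
        up_in_a=frozenset(up_a),
        up_in_b=frozenset(up_b),
    )


def run_subtests(
    matrix: ProteinMatrix,
    assignment: ClassAssignment,
    annotations: Annotations,
    n_perm: int = DEFAULT_N_PERM,
    min_group: int = MIN_GROUP,
    alpha: float = 0.05,
    seed: int = 0,
    bh_scope: str = "classification",
    with_contributions: bool = True,
) -> list[EnergyResult]:
    """Full discriminability analysis for one classification.

    Subtests are enumerated per histotype, each gets its own permutation
    stream derived from (seed, subtest index), and BH correction is applied
    across all subtests of the classification (``bh_scope="classification"``,
    default) or within each histotype (``bh_scope="histotype"``).
    Contribution profiles are computed for BH-significant subtests.
    """
    if bh_scope not in ("classification", "histotype"):
        raise ValueError("bh_scope must be 'classification' or 'histotype'")
    pairs = enumerate_subtests(assignment, annotations, min_group=min_group)
    results: list[EnergyResult] = []
    for idx, pair in enumerate(pairs):
        x_a = matrix.data.loc[list(pair.cases_a)].to_numpy()
        x_b = matrix.data.loc[list(pair.cases_b)].to_numpy()
        i, j = pair.sizes
        de = energy_distance(x_a, x_b)
        # one independent, reproducible stream per subtest
        sub_seed = int(
            np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31)
        )
        p_raw, s_rand = mc_pvalue(x_a, x_b, n_perm=n_perm, seed=sub_seed)
        results.append(EnergyResult(
            pair=pair, de=de, s_dis=de / (i * j),
            p_raw=p_raw, s_rand=s_rand, n_perm=n_perm, seed=sub_seed,
        ))

    if bh_scope == "classification":
        families = {None: results}
    else:
        families = {}
        for r in results:
            families.setdefault(r.pair.histotype, []).append(r)
    for fam in families.values():
        p_adj, flags = adjust_bh([r.p_raw for r in fam], alpha=alpha)
        for r, pa, sig in zip(fam, p_adj, flags):
            r.p_adj = float(pa)
            r.significant = bool(sig)

    if with_contributions:
        for r in results:
            if r.significant:
                x_a = matrix.data.loc[list(r.pair.cases_a)].to_numpy()
                x_b = matrix.data.loc[list(r.pair.cases_b)].to_numpy()
                r.contributions = protein_contributions(
                    x_a, x_b, matrix.protein_ids
                )
    return results


def results_table(results: list[EnergyResult]) -> pd.DataFrame:
    """Flat listing of subtest results (one row per class-vs-class subtest)."""
    rows = []
    for r in results:
        cp = r.contributions
        rows.append({
            "histotype": r.pair.histotype,
            "class_a": r.pair.class_a,
            "class_b": r.pair.class_b,
            "n_a": r.pair.sizes[0],
            "n_b": r.pair.sizes[1],
            "de": r.de,
            "s_dis": r.s_dis,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "s_rand": r.s_rand,
            "significant": r.significant,
            "up_in_a": ";".join(sorted(cp.up_in_a)) if cp else "",
            "up_in_b": ";".join(sorted(cp.up_in_b)) if cp else "",
        })
    return pd.DataFrame(rows)
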