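"""Genetic tumor classifications: the three-gene complexity-reduction
scheme, binary actionable-gene classes, nearest-mutational-neighbor
classes, and pass-through of published class tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    Annotations,
    ClassAssignment,
    CnaProfile,
    MutationProfile,
    normalize_protein_change,
)

logger = logging.getLogger(__name__)

#: The three genes of the complexity-reduction classification.  A case's
#: class is the binary number TP53|TTN|BRAF (TP53 the high bit), giving
#: classes 0-7: e.g. no mutation in any -> 0, all three mutated -> 7.
GCR_GENES = ("TP53", "TTN", "BRAF")

RULE_KINDS = ("any-nonsilent", "protein-change", "protein-change-prefix", "amplification")


@dataclass(frozen=True)
class VariantFilter:
    """An actionable-alteration rule for one gene.

    ``rule_kind`` is one of ``any-nonsilent`` (any nonsilent mutation),
    ``protein-change`` (exact match against a list, e.g. G12C;G12D),
    ``protein-change-prefix`` (e.g. ``V600`` matches V600E and V600K), or
    ``amplification`` (copy-number call).  Protein changes are compared in
    normalized short form (no leading ``p.``).
    """

    gene_symbol: str
    rule_kind: str
    rule_value: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rule_kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.rule_kind!r}")
        if self.rule_kind in ("protein-change", "protein-change-prefix") and (
            not self.rule_value or any(not v for v in self.rule_value)
        ):
            raise ValueError(f"rule {self.rule_kind!r} needs a non-empty value")


def read_variant_filters(path: str | Path) -> list[VariantFilter]:
    """Read filters from a TSV with columns gene, rule_kind, rule_value."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    filters = []
    for _, row in df.iterrows():
        values = tuple(v for v in str(row["rule_value"]).split(";") if v)
        filters.append(VariantFilter(row["gene"], row["rule_kind"], values))
    return filters


def gcr_classify(mutations: MutationProfile, name: str = "gcr") -> ClassAssignment:
    """Three-gene complexity-reduction classes 0-7.

    class = 4*[TP53 mutated] + 2*[TTN mutated] + 1*[BRAF mutated].
    """
    ind = mutations.indicator()
    cols = {g: ind[g] if g in ind.columns else pd.Series(False, index=ind.index)
            for g in GCR_GENES}
    code = (4 * cols["TP53"].astype(int)
            + 2 * cols["TTN"].astype(int)
            + 1 * cols["BRAF"].astype(int))
    return ClassAssignment(name, code.astype(str))


def actionable_classify(
    mutations: MutationProfile,
    cna: CnaProfile | None,
    variant_filter: VariantFilter,
    name: str | None = None,
) -> ClassAssignment:
    """Binary classification: cases matching the filter vs all others.

    Labels are ``mutated`` / ``wildtype``; the case universe is the
    mutation profile's (amplification filters use the CNA profile's).
    """
    gene = variant_filter.gene_symbol
    kind = variant_filter.rule_kind
    name = name or f"{gene}_{kind}"

    if kind == "amplification":
        if cna is None or gene not in cna.amplified.columns:
            raise ValueError(f"gene {gene!r} absent from the CNA profile")
        mutated = cna.amplified[gene]
    else:
        rec = mutations.records
        if gene not in set(rec["gene_symbol"]):
            raise ValueError(f"gene {gene!r} absent from the mutation profile")
        if kind == "any-nonsilent":
            ind = mutations.indicator()
            mutated = ind[gene]
        else:
            sub = rec[rec["gene_symbol"] == gene]
            pc = normalize_protein_change(sub["protein_change"])
            if kind == "protein-change":
                hit = pc.isin(variant_filter.rule_value)
            else:  # protein-change-prefix
                hit = pc.str.startswith(variant_filter.rule_value)
            cases = set(sub.loc[hit, "case_id"])
            mutated = pd.Series(
                [c in cases for c in mutations.case_ids], index=mutations.case_ids
            )
    labels = mutated.map({True: "mutated", False: "wildtype"})
    return ClassAssignment(name, labels, binary=True)


# ---------------------------------------------------------------------------
# Nearest-neighbor machinery (shared with neighbor_similarity)
# ---------------------------------------------------------------------------

def jaccard_distances(indicator: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between binary row vectors.

    Two all-zero vectors are defined to be at distance 0 (identical-empty);
    this situation is logged.
    """
    x = np.asarray(indicator, dtype=float)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - inter / union
    empty = union == 0
    if empty.any():
        logger.info("Jaccard distance of empty profiles defined as 0 "
                    "(%d pair(s))", int(empty.sum() - len(x)) // 2)
        dist[empty] = 0.0
    np.fill_diagonal(dist, 0.0)
    return dist


def euclidean_distances(values: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(np.asarray(values, dtype=float)))


def nearest_neighbor_indices(dist: np.ndarray) -> np.ndarray:
    """Index of each row's nearest other row (self excluded); exact ties go
    to the lowest index."""
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    return d.argmin(axis=1)  # argmin breaks ties at the lowest index


def nearest_neighbor_classify(
    mutations: MutationProfile,
    annotations: Annotations,
    metric: str = "jaccard",
    name: str = "nearest-neighbor",
) -> ClassAssignment:
    """Assign each case the class ``to<HISTOTYPE>`` of its nearest
    mutational neighbor (Jaccard distance on binary gene vectors by
    default; ``metric="euclidean"`` available)."""
    ind = mutations.indicator()
    cases = list(ind.index)
    if len(cases) < 2:
        raise ValueError("need at least 2 cases for neighbor classification")
    if metric == "jaccard":
        dist = jaccard_distances(ind.to_numpy())
    elif metric == "euclidean":
        dist = euclidean_distances(ind.to_numpy().astype(float))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    nn = nearest_neighbor_indices(dist)
    histotype = annotations.histotype
    labels = pd.Series(
        ["to" + histotype[cases[k]] for k in nn], index=cases
    )
    return ClassAssignment(name, labels)
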