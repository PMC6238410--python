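"""Nearest-molecular-neighbor consistency with histotype.

For every case, find the closest other case in mutation space (Jaccard on
binary gene vectors) or protein space (Euclidean on expression vectors).
The chord (confusion) matrix counts cases by (own histotype, neighbor's
histotype); its trace fraction is the consistency — the proportion of
cases whose nearest molecular neighbor shares their histological type.
An optional merge map (e.g. colon + rectal as one histotype) is applied
when re-scoring the tally only; the neighbor search is never re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    euclidean_distances,
    jaccard_distances,
    nearest_neighbor_indices,
)
from .core_data import Annotations, MutationProfile, ProteinMatrix

logger = logging.getLogger(__name__)


@dataclass
class ConsistencyReport:
    space: str  # "mutation" or "protein"
    metric: str
    chord_matrix: pd.DataFrame  # rows = own histotype, cols = neighbor's
    consistency: float
    merged_consistency: float | None = None
    merge_map: Mapping[str, str] | None = None


def _chord(own: pd.Series, neighbor: pd.Series, histotypes: list[str]) -> pd.DataFrame:
    mat = pd.crosstab(own, neighbor)
    return mat.reindex(index=histotypes, columns=histotypes, fill_value=0)


def _consistency(chord: pd.DataFrame) -> float:
    return float(np.diag(chord.to_numpy()).sum() / chord.to_numpy().sum())


def neighbor_consistency(
    data: ProteinMatrix | MutationProfile,
    annotations: Annotations,
    metric: str | None = None,
    merge_map: Mapping[str, str] | None = None,
    genes: Sequence[str] | None = None,
) -> ConsistencyReport:
    """Nearest-neighbor histotype consistency in protein or mutation space.

    ``metric`` defaults to Euclidean for a protein matrix and Jaccard for a
    mutation profile.  ``genes`` restricts a mutation profile to a gene
    subset (e.g. the genes with corresponding proteins on the panel) before
    the search.  Histotypes with a single case are kept (their neighbor is
    necessarily foreign) and logged.
    """
    if isinstance(data, ProteinMatrix):
        space = "protein"
        metric = metric or "euclidean"
        cases = data.case_ids
        if metric != "euclidean":
            raise ValueError("protein space uses Euclidean distance")
        dist = euclidean_distances(data.values)
    else:
        space = "mutation"
        metric = metric or "jaccard"
        profile = gene_subset(data, genes) if genes is not None else data
        ind = profile.indicator()
        cases = list(ind.index)
        if metric == "jaccard":
            dist = jaccard_distances(ind.to_numpy())
        elif metric == "euclidean":
            dist = euclidean_distances(ind.to_numpy().astype(float))
        else:
            raise ValueError(f"unknown metric {metric!r}")

    if len(cases) < 2:
        raise ValueError("need at least 2 cases")
    histotype = annotations.histotype.loc[cases]
    singletons = histotype.value_counts()
    for h in singletons.index[singletons == 1]:
        logger.info("histotype %s has a single case; its neighbor is foreign", h)

    nn = nearest_neighbor_indices(dist)
    own = histotype.reset_index(drop=True)
    neigh = pd.Series([histotype.iloc[k] for k in nn])
    histotypes = sorted(histotype.unique())
    chord = _chord(own, neigh, histotypes)

    merged = None
    if merge_map:
        mapped_own = own.map(lambda h: merge_map.get(h, h))
        mapped_neigh = neigh.map(lambda h: merge_map.get(h, h))
        merged_types = sorted(mapped_own.unique())
        merged = _consistency(_chord(mapped_own, mapped_neigh, merged_types))

    return ConsistencyReport(
        space=space,
        metric=metric,
        chord_matrix=chord,
        consistency=_consistency(chord),
        merged_consistency=merged,
        merge_map=merge_map,
    )


def gene_subset(profile: MutationProfile, genes: Sequence[str]) -> MutationProfile:
    """Restrict the mutation profile to the listed genes (cases unchanged).

    Genes absent from the profile are dropped with a warning.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    present = set(profile.records["gene_symbol"])
    missing = [g for g in genes if g not in present]
    if missing:
        logger.warning("gene_subset: %d gene(s) absent, dropped: %s",
                       len(missing), missing[:10])
    keep = set(genes) - set(missing)
    rec = profile.records[profile.records["gene_symbol"].isin(keep)]
    return MutationProfile(rec, case_ids=list(profile.case_ids))
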