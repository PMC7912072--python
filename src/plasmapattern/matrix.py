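"""Catalogue filtering and descriptive summaries of the presence matrix.

The study's filtering rule drops "unrepresentative" proteins (identified in
at most one sample) and "non-specific" proteins (identified in every
sample) before any clustering or modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError
from .io import CohortTable, PresenceMatrix


@dataclass
class CatalogSummary:
    """Descriptive protein-catalogue counts.

    ``n_total``: distinct proteins in the matrix; ``n_core``: proteins
    present in every sample; ``per_group_union``: group label (or merged
    label like ``"OW+OB1"``) -> number of proteins identified in at least
    one sample of that group; ``n_after_filter``: columns surviving the
    singleton/ubiquitous filter.
    """

    n_total: int
    n_core: int
    per_group_union: dict[str, int]
    n_after_filter: int


def filter_proteins(m: PresenceMatrix) -> PresenceMatrix:
    """Drop singleton (occurrence <= 1) and ubiquitous (occurrence == n)
    columns; column order is preserved among survivors. Idempotent."""
    n = len(m.sample_ids)
    counts = m.column_counts()
    keep = (counts > 1) & (counts < n)
    proteins = [p for p, k in zip(m.protein_ids, keep) if k]
    return PresenceMatrix(m.sample_ids, proteins, m.values[:, keep])


def summarize_catalog(
    m: PresenceMatrix,
    cohort: CohortTable,
    merged_groups: Mapping[str, Sequence[str]] | None = None,
) -> CatalogSummary:
    """Catalogue counts for a (typically unfiltered) presence matrix.

    ``merged_groups`` adds union counts over pooled group sets, e.g.
    ``{"OW+OB": ["OW", "OB1", "OB2", "OB3"]}``.
    """
    cohort_ids = set(cohort.sample_ids)
    missing = [s for s in m.sample_ids if s not in cohort_ids]
    if missing:
        raise DataError(f"matrix sample(s) missing from cohort: {missing}")
    n = len(m.sample_ids)
    counts = m.column_counts()
    group_of = {s.sample_id: s.group for s in cohort.samples}
    groups_here = []
    for sid in m.sample_ids:
        g = group_of[sid]
        if g not in groups_here:
            groups_here.append(g)

    def union_count(labels: Sequence[str]) -> int:
        rows = [i for i, sid in enumerate(m.sample_ids) if group_of[sid] in set(labels)]
        if not rows:
            return 0
        return int((m.values[rows].sum(axis=0) > 0).sum())

    per_group = {g: union_count([g]) for g in groups_here}
    if merged_groups:
        for label, members in merged_groups.items():
            per_group[label] = union_count(list(members))
    return CatalogSummary(
        n_total=len(m.protein_ids),
        n_core=int((counts == n).sum()) if n else 0,
        per_group_union=per_group,
        n_after_filter=len(filter_proteins(m).protein_ids),
    )


def subset_samples(
    m: PresenceMatrix,
    cohort: CohortTable,
    exclude_groups: set[str] | Sequence[str],
    refilter: bool = True,
) -> tuple[PresenceMatrix, CohortTable]:
    """Remove samples of the excluded groups from matrix and cohort.

    Occurrence counts change after subsetting, so the singleton/ubiquitous
    filter is re-applied by default (``refilter=False`` to keep columns).
    """
    exclude = set(exclude_groups)
    group_of = {s.sample_id: s.group for s in cohort.samples}
    keep_ids = [sid for sid in m.sample_ids if group_of.get(sid) not in exclude]
    if not keep_ids:
        warnings.warn("all samples excluded; returning empty structures", stacklevel=2)
        empty = PresenceMatrix([], m.protein_ids, np.zeros((0, len(m.protein_ids)), dtype=np.int8))
        return (filter_proteins(empty) if refilter else empty), cohort.subset([])
    sub_m = m.select_samples(keep_ids)
    if refilter:
        sub_m = filter_proteins(sub_m)
    return sub_m, cohort.subset(keep_ids)
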