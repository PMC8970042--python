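"""Bookkeeping arithmetic for classification and network summaries.

These helpers turn raw per-step counts into the rates a family survey
reports (subgroup/group classification percentages, syntenic fractions,
edge-type percentages), so the arithmetic lives in one audited place and
is reusable on any set of counts — the pipeline's own audit tables or
counts taken from a published survey.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synteny import truncate_pct


@dataclass(frozen=True)
class ClassificationSummary:
    """Derived totals and rates of a four-step classification run."""

    n_hits: int
    n_non_family: int
    n_family: int
    subgroup_by_step: dict
    n_subgroup: int
    n_group_only: int
    n_group_level: int
    n_unclassified: int
    subgroup_rate_pct: float
    group_rate_pct: float


def classification_summary(
    step_counts: dict,
    n_group_only: int,
    n_hits: int,
    n_non_family: int = 0,
) -> ClassificationSummary:
    """Derive totals and rates from per-step subgroup counts.

    ``step_counts`` maps step name → number of genes subgroup-classified
    at that step; ``n_hits`` is the total number of family-domain search
    hits including the ``n_non_family`` ones later rejected. The family
    size is hits minus non-family; the subgroup total is the sum over
    steps; the group-level total additionally counts group-only genes;
    rates are percentages of the family size truncated to one decimal
    (the same truncation convention as the edge-type percentages).
    """
    n_family = n_hits - n_non_family
    n_subgroup = sum(step_counts.values())
    n_group_level = n_subgroup + n_group_only
    return ClassificationSummary(
        n_hits=n_hits,
        n_non_family=n_non_family,
        n_family=n_family,
        subgroup_by_step=dict(step_counts),
        n_subgroup=n_subgroup,
        n_group_only=n_group_only,
        n_group_level=n_group_level,
        n_unclassified=n_family - n_group_level,
        subgroup_rate_pct=truncate_pct(100.0 * n_subgroup / n_family, 1)
        if n_family else 0.0,
        group_rate_pct=truncate_pct(100.0 * n_group_level / n_family, 1)
        if n_family else 0.0,
    )


def syntenic_fraction_pct(n_syntenic: int, n_family: int,
                          decimals: int = 1) -> float:
    """Percentage of family genes retained in collinear blocks."""
    if not n_family:
        return 0.0
    return round(100.0 * n_syntenic / n_family, decimals)


def edge_type_percentages(counts: dict) -> dict:
    """Edge-type percentages over the total edge count, truncated to
    three decimals (the conventional reporting precision)."""
    total = sum(counts.values())
    return {t: truncate_pct(100.0 * n / total) if total else 0.0
            for t, n in counts.items()}
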