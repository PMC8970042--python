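"""Lineage typology of synteny communities and the phylogenetic profile.

Each community is categorised by the lineages of the species it spans —
angiosperm-wide down to single-species — via a fixed-precedence decision
tree, and the community × species gene-count matrix is assembled with
rows ordered by hierarchical clustering of presence/absence profiles
(the heatmap workflow, without binding to a plotting tool).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import ALGAE_LINEAGES, DataError, SpeciesLineage

COMMUNITY_TYPES = (
    "angiosperm_wide",
    "BE_specific",
    "BM_specific",
    "eudicot_wide",
    "monocot_wide",
    "EFO_specific",
    "MFO_specific",
    "ES_specific",
    "MS_specific",
    "basal_specific",
    "AFO_specific",
    "MoS_specific",
    "LS_specific",
    "other_mixed",  # fallback for compositions outside the 13-type scheme
)


@dataclass(frozen=True)
class CommunityCategory:
    """Typology verdict for one community."""

    community_type: str
    level: str = ""  # "family" or "order" for the within-order/family types
    flagged: bool = False  # composition outside the canonical definitions


def _taxon_scope(species: Sequence[SpeciesLineage]) -> tuple[str, str]:
    """Whether distinct species share one family ("family"), one order
    ("order"), or neither ("none"); tested family-first."""
    families = {s.family for s in species}
    orders = {s.order for s in species}
    if len(families) == 1 and "" not in families:
        return "family", next(iter(families))
    if len(orders) == 1 and "" not in orders:
        return "order", next(iter(orders))
    return "none", ""


def categorize_community(
    member_species: Iterable[str],
    lineages: Mapping[str, SpeciesLineage],
) -> CommunityCategory:
    """Categorise one community from the species its members represent.

    Precedence (first match wins):

    1. >= 1 eudicot and >= 1 monocot → ``angiosperm_wide``
    2. basal angiosperm + eudicot → ``BE_specific``
    3. basal angiosperm + monocot → ``BM_specific``
    4. basal angiosperms only → ``basal_specific``
    5. eudicots only: single species → ``ES_specific``; several species of
       one family/order → ``EFO_specific``; otherwise ``eudicot_wide``
    6. monocots only: the analogous ``MS`` / ``MFO`` / ``monocot_wide``
    7. algae only → ``AFO_specific``
    8. mosses only → ``MoS_specific``
    9. lycophytes only → ``LS_specific``
    10. anything else → ``other_mixed`` (flagged)

    Single-species algae/moss/lycophyte communities fold into their
    lineage type with ``flagged=True`` (the canonical definitions cover
    only the multi-species case).
    """
    species_ids = sorted(set(member_species))
    rows = []
    for sp in species_ids:
        if sp not in lineages:
            raise DataError(f"species {sp} has no lineage annotation")
        rows.append(lineages[sp])
    if not rows:
        raise DataError("community has no members")

    present = {r.lineage for r in rows}
    has_eu = "eudicot" in present
    has_mo = "monocot" in present
    has_basal = "basal_angiosperm" in present

    if has_eu and has_mo:
        return CommunityCategory("angiosperm_wide")
    if has_basal and has_eu:
        return CommunityCategory("BE_specific")
    if has_basal and has_mo:
        return CommunityCategory("BM_specific")
    if present == {"basal_angiosperm"}:
        return CommunityCategory("basal_specific",
                                 flagged=len(species_ids) < 2)
    if present == {"eudicot"} or present == {"monocot"}:
        wide, fo, ss = (("eudicot_wide", "EFO_specific", "ES_specific")
                        if has_eu else
                        ("monocot_wide", "MFO_specific", "MS_specific"))
        if len(species_ids) == 1:
            return CommunityCategory(ss)
        scope, _ = _taxon_scope(rows)
        if scope in {"family", "order"}:
            return CommunityCategory(fo, level=scope)
        return CommunityCategory(wide)
    if present <= ALGAE_LINEAGES:
        scope, _ = _taxon_scope(rows)
        return CommunityCategory("AFO_specific",
                                 level=scope if len(species_ids) > 1 else "",
                                 flagged=len(species_ids) < 2)
    if present == {"moss"}:
        return CommunityCategory("MoS_specific", flagged=len(species_ids) > 1)
    if present == {"lycophyte"}:
        return CommunityCategory("LS_specific", flagged=len(species_ids) > 1)
    return CommunityCategory("other_mixed", flagged=True)


@dataclass
class ProfileMatrix:
    """Community × species gene counts with per-community typology."""

    counts: pd.DataFrame  # rows: community ids, columns: species panel
    types: pd.Series  # community id -> community_type
    communities: dict[str, set[str]]  # community id -> member gene ids

    def __post_init__(self) -> None:
        row_sums = self.counts.sum(axis=1)
        for cid, members in self.communities.items():
            if row_sums.loc[cid] != len(members):
                raise DataError(f"{cid}: row sum {row_sums.loc[cid]} != "
                                f"community size {len(members)}")


def build_profile_matrix(
    communities: Sequence[set[str]],
    species_of: Mapping[str, str],
    lineages: Mapping[str, SpeciesLineage],
    species_panel: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Assemble the phylogenetic profile of the synteny communities.

    ``species_of`` maps gene id → species id. Column order follows
    ``species_panel`` (default: sorted lineage-table species); rows are
    ordered by average-linkage hierarchical clustering of the Jaccard
    distances between presence/absence profiles (deterministic
    tie-breaks), which groups communities of similar species occupancy
    the way profile heatmaps are conventionally drawn.
    """
    panel = list(species_panel) if species_panel is not None else sorted(lineages)
    ids = [f"K{k:03d}" for k in range(1, len(communities) + 1)]
    comm_map = {cid: set(c) for cid, c in zip(ids, communities)}
    counts = pd.DataFrame(0, index=ids, columns=panel, dtype=int)
    types = {}
    for cid in ids:
        members = comm_map[cid]
        member_species = []
        for g in sorted(members):
            sp = species_of.get(g)
            if sp is None:
                raise DataError(f"gene {g} has no species annotation")
            if sp not in counts.columns:
                raise DataError(f"species {sp} missing from the species panel")
            counts.loc[cid, sp] += 1
            member_species.append(sp)
        types[cid] = categorize_community(member_species, lineages).community_type

    if len(ids) > 2:
        from scipy.cluster.hierarchy import leaves_list, linkage
        from scipy.spatial.distance import pdist

        presence = (counts.to_numpy() > 0).astype(float)
        dist = pdist(presence, metric="jaccard")
        dist = np.nan_to_num(dist, nan=0.0)
        order = leaves_list(linkage(dist, method="average"))
        ids_ordered = [ids[i] for i in order]
        counts = counts.loc[ids_ordered]
    return ProfileMatrix(counts, pd.Series(types).loc[counts.index],
                         {cid: comm_map[cid] for cid in counts.index})


def summarize_category_counts(profile: ProfileMatrix) -> pd.DataFrame:
    """Per-type community and gene counts (totals conserve both)."""
    rows = []
    for ctype in COMMUNITY_TYPES:
        cids = [cid for cid in profile.counts.index
                if profile.types.loc[cid] == ctype]
        if not cids:
            continue
        rows.append({
            "community_type": ctype,
            "n_communities": len(cids),
            "n_genes": int(profile.counts.loc[cids].to_numpy().sum()),
        })
    return pd.DataFrame(rows, columns=["community_type", "n_communities", "n_genes"])


def write_profile(profile: ProfileMatrix, path: str | Path) -> None:
    out = profile.counts.copy()
    out.insert(0, "community_type", profile.types)
    out.to_csv(path, sep="\t", index_label="community_id")


def plot_profile_heatmap(profile: ProfileMatrix, path: str | Path) -> None:
    """Optional heatmap rendering of the profile matrix (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.3 * profile.counts.shape[1]),
                                    max(3, 0.2 * profile.counts.shape[0])))
    im = ax.imshow(profile.counts.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(profile.counts.shape[1]))
    ax.set_xticklabels(profile.counts.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(profile.counts.shape[0]))
    ax.set_yticklabels([f"{cid} ({t})" for cid, t in profile.types.items()],
                       fontsize=6)
    fig.colorbar(im, ax=ax, label="gene count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
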