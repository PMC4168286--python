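"""Species- and group-level discrimination scoring on an unrooted tree.

A species with two or more accessions is *discriminated* when its accessions
form an exclusive cluster: some bipartition of the (zero-collapsed, possibly
multifurcating) tree separates exactly that species' accessions from all
others. Evaluating on the zero-collapsed tree avoids crediting discrimination
to arbitrary resolutions of zero-length edges.

A single-accession species cannot be tested for monophyly; by default it is
discriminated when its minimum distance to every heterospecific accession is
strictly positive (an identical sequence elsewhere means it cannot be told
apart). This convention is switchable via ``singleton_policy``:
``"nonzero_distance"`` (default), ``"always"`` or ``"never"``.

An informal taxonomic group is discriminated when some clade (one side of an
edge-removal bipartition) contains only that group's accessions and covers at
least 50 % of the group's sampled species (distinct species, not accessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from typing import Mapping, Sequence

import dendropy

from .distance import DistanceMatrix
from .io import BarcodevalError, SampleTable

logger = logging.getLogger(__name__)

SINGLETON_POLICIES = ("nonzero_distance", "always", "never")


@dataclass(frozen=True)
class DiscriminationReport:
    """Outcome of scoring one locus combination under one missing-data mode."""

    combination: tuple[str, ...]
    mode: str
    per_species: dict  # species -> {n_accessions, discriminated}
    per_group: dict  # group -> {n_species_sampled, largest_exclusive_clade_species, discriminated}
    totals: dict
    aligned_bp: int = 0
    scheme: str = ""

    def __post_init__(self) -> None:
        t = self.totals
        n_disc = sum(1 for v in self.per_species.values() if v["discriminated"])
        n_groups = sum(1 for v in self.per_group.values() if v["discriminated"])
        if t["n_species_discriminated"] != n_disc or t["n_groups_discriminated"] != n_groups:
            raise BarcodevalError("DiscriminationReport: totals inconsistent with maps")

    @property
    def pct_species(self) -> float:
        return self.totals["pct_species"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "combination": list(self.combination),
                "mode": self.mode,
                "scheme": self.scheme,
                "aligned_bp": self.aligned_bp,
                "per_species": self.per_species,
                "per_group": self.per_group,
                "totals": self.totals,
            },
            indent=2,
            sort_keys=True,
        )


def clade_leaf_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Leaf-label sets of both sides of every edge-removal bipartition."""
    all_leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )
    sets: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if 0 < len(below) < len(all_leaves):
            sets.add(below)
            sets.add(all_leaves - below)
    return sets


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def species_discrimination(
    tree: dendropy.Tree,
    table: SampleTable,
    dmat: DistanceMatrix | None = None,
    singleton_policy: str = "nonzero_distance",
) -> dict[str, bool]:
    """Per-species discrimination outcomes on a zero-collapsed tree.

    ``dmat`` is required for the default singleton policy.
    """
    if singleton_policy not in SINGLETON_POLICIES:
        raise BarcodevalError(f"unknown singleton_policy {singleton_policy!r}")
    leaves = _leaf_labels(tree)
    species_of = table.species_of()
    missing_meta = [l for l in leaves if l not in species_of]
    if missing_meta:
        raise BarcodevalError(f"leaves without metadata rows: {missing_meta}")
    by_species: dict[str, list[str]] = {}
    for leaf in leaves:
        by_species.setdefault(species_of[leaf], []).append(leaf)

    clades = clade_leaf_sets(tree)
    all_leaves = frozenset(leaves)
    out: dict[str, bool] = {}
    for sp, accs in by_species.items():
        acc_set = frozenset(accs)
        if len(accs) >= 2:
            out[sp] = acc_set in clades or acc_set == all_leaves
        else:
            if singleton_policy == "always":
                out[sp] = True
            elif singleton_policy == "never":
                out[sp] = False
            else:
                if dmat is None:
                    raise BarcodevalError(
                        "singleton_policy 'nonzero_distance' needs a distance matrix"
                    )
                others = [l for l in leaves if species_of[l] != sp]
                if not others:
                    out[sp] = True
                else:
                    out[sp] = dmat.min_distance_to_others(accs[0], others) > 0.0
    return out


def group_discrimination(
    tree: dendropy.Tree, table: SampleTable
) -> dict[str, dict]:
    """Per-group outcomes: best exclusive clade vs the 50 % species rule."""
    leaves = _leaf_labels(tree)
    species_of = table.species_of()
    group_of = table.group_of_species()
    missing_meta = [l for l in leaves if l not in species_of]
    if missing_meta:
        raise BarcodevalError(f"leaves without metadata rows: {missing_meta}")

    sampled_species: dict[str, set[str]] = {}
    for leaf in leaves:
        sp = species_of[leaf]
        sampled_species.setdefault(group_of[sp], set()).add(sp)

    candidates = clade_leaf_sets(tree) | {frozenset(leaves)}
    out: dict[str, dict] = {}
    for grp in table.df["group"].unique():
        n_sampled = len(sampled_species.get(grp, ()))
        if n_sampled == 0:
            logger.info("group %r: no sampled species, skipped", grp)
            continue
        best = 0
        for clade in candidates:
            if all(group_of[species_of[l]] == grp for l in clade):
                n_sp = len({species_of[l] for l in clade})
                best = max(best, n_sp)
        out[grp] = {
            "n_species_sampled": n_sampled,
            "largest_exclusive_clade_species": best,
            "discriminated": best >= 0.5 * n_sampled,
        }
    return out


def score_tree(
    tree: dendropy.Tree,
    table: SampleTable,
    dmat: DistanceMatrix | None,
    combination: Sequence[str],
    mode: str,
    singleton_policy: str = "nonzero_distance",
    aligned_bp: int = 0,
    scheme: str = "",
) -> DiscriminationReport:
    """Assemble the full discrimination report for one combination x mode."""
    species_ok = species_discrimination(
        tree, table, dmat=dmat, singleton_policy=singleton_policy
    )
    group_info = group_discrimination(tree, table)
    species_of = table.species_of()
    n_acc: dict[str, int] = {}
    for leaf in _leaf_labels(tree):
        sp = species_of[leaf]
        n_acc[sp] = n_acc.get(sp, 0) + 1

    per_species = {
        sp: {"n_accessions": n_acc[sp], "discriminated": bool(ok)}
        for sp, ok in sorted(species_ok.items())
    }
    endangered = table.endangered_species()
    n_sampled = len(per_species)
    n_disc = sum(1 for v in per_species.values() if v["discriminated"])
    n_endangered = sum(
        1 for sp, v in per_species.items() if v["discriminated"] and sp in endangered
    )
    totals = {
        "n_species_sampled": n_sampled,
        "n_species_discriminated": n_disc,
        "n_endangered_sampled": sum(1 for sp in per_species if sp in endangered),
        "n_endangered_discriminated": n_endangered,
        "n_groups_sampled": len(group_info),
        "n_groups_discriminated": sum(
            1 for v in group_info.values() if v["discriminated"]
        ),
        "pct_species": 100.0 * n_disc / n_sampled if n_sampled else 0.0,
    }
    return DiscriminationReport(
        combination=tuple(combination),
        mode=mode,
        per_species=per_species,
        per_group={g: group_info[g] for g in sorted(group_info)},
        totals=totals,
        aligned_bp=aligned_bp,
        scheme=scheme,
    )
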