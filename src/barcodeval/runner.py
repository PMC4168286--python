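"""Orchestration of the full evaluation grid.

For every requested locus combination and missing-data mode the runner
concatenates the loci, computes K2P (or p) distances with pairwise deletion,
builds a neighbour-joining tree, collapses zero-length internal edges and
scores species- and group-level discrimination. Combinations whose distance
matrix contains undefined (saturated) pairs are reported as failures, not
fatal errors. The whole pipeline is deterministic: identical inputs yield
byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations as _combinations
from pathlib import Path
from typing import Sequence

from .distance import build_distance_matrix
from .io import (
    BarcodevalError,
    ConcatenatedMatrix,
    LocusAlignment,
    SampleTable,
    concatenate,
    write_newick,
)
from .scoring import DiscriminationReport, score_tree
from .trees import collapse_zero_branches, neighbor_joining

logger = logging.getLogger(__name__)

#: Default nuclear locus key; every other locus is treated as plastid.
DEFAULT_ITS = "ITS"

SCHEMES = ("singles", "pairs", "all_plastid", "its_plus_each", "all")

REPORT_COLUMNS = (
    "combination",
    "mode",
    "aligned_bp",
    "n_species_total",
    "n_species_discriminated",
    "n_endangered_discriminated",
    "n_groups_discriminated",
    "pct_species",
)


def enumerate_combinations(
    loci: Sequence[str], scheme: str, its: str = DEFAULT_ITS
) -> list[tuple[str, ...]]:
    """Deterministic list of locus combinations for one scheme.

    ``singles`` covers every locus; ``pairs`` all pairs of plastid loci;
    ``all_plastid`` the plastid set combined; ``its_plus_each`` the nuclear
    locus with each plastid locus; ``all`` everything combined. Ordering
    follows the input locus order.
    """
    if len(set(loci)) != len(loci):
        raise BarcodevalError(f"duplicate locus names: {list(loci)}")
    if scheme not in SCHEMES:
        raise BarcodevalError(f"unknown scheme {scheme!r} (choose from {SCHEMES})")
    plastid = [l for l in loci if l != its]
    if scheme == "singles":
        return [(l,) for l in loci]
    if scheme == "pairs":
        return [tuple(p) for p in _combinations(plastid, 2)]
    if scheme == "all_plastid":
        if not plastid:
            raise BarcodevalError("scheme all_plastid: no plastid loci present")
        return [tuple(plastid)]
    if scheme == "its_plus_each":
        if its not in loci:
            raise BarcodevalError(f"scheme its_plus_each: locus {its!r} absent")
        return [(its, p) for p in plastid]
    return [tuple(loci)]


@dataclass(frozen=True)
class EvaluationResult:
    reports: tuple[DiscriminationReport, ...]
    failures: tuple[dict, ...]  # {combination, mode, reason}


def run_evaluation(
    loci: Sequence[LocusAlignment],
    table: SampleTable,
    schemes: Sequence[str] = ("singles", "pairs", "all_plastid", "its_plus_each", "all"),
    modes: Sequence[str] = ("A", "B"),
    model: str = "k2p",
    its: str = DEFAULT_ITS,
    singleton_policy: str = "nonzero_distance",
    pairs_only_mode_b: bool = False,
    collapse_tol: float = 1e-9,
    out_dir: str | Path | None = None,
) -> EvaluationResult:
    """Run the concatenate -> distance -> NJ -> collapse -> score pipeline
    over every scheme x combination x mode; optionally write all outputs.
    """
    by_name = {a.locus_name: a for a in loci}
    if len(by_name) != len(loci):
        raise BarcodevalError("duplicate locus names among inputs")
    locus_names = [a.locus_name for a in loci]

    reports: list[DiscriminationReport] = []
    failures: list[dict] = []
    trees: list[tuple[str, object]] = []
    for scheme in schemes:
        for combo in enumerate_combinations(locus_names, scheme, its=its):
            for mode in modes:
                name = "+".join(combo)
                try:
                    matrix = concatenate(
                        [by_name[l] for l in combo],
                        table=table,
                        mode=mode,
                        pairs_only_mode_b=pairs_only_mode_b,
                    )
                    dmat = build_distance_matrix(matrix, model=model)
                    if not dmat.fully_defined:
                        raise BarcodevalError(
                            f"{len(dmat.undefined_pairs())} saturated/undefined "
                            "distance pair(s)"
                        )
                    tree = neighbor_joining(dmat)
                    collapsed = collapse_zero_branches(tree, tol=collapse_tol)
                    report = score_tree(
                        collapsed,
                        table,
                        dmat,
                        combination=combo,
                        mode=mode,
                        singleton_policy=singleton_policy,
                        aligned_bp=matrix.aligned_length,
                        scheme=scheme,
                    )
                except BarcodevalError as exc:
                    logger.warning("combination %s mode %s failed: %s", name, mode, exc)
                    failures.append(
                        {"combination": name, "mode": mode, "reason": str(exc)}
                    )
                    continue
                reports.append(report)
                trees.append((f"{name}.mode{mode}", tree))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.tsv").write_text(format_report_table(reports))
        for stem, tree in trees:
            write_newick(tree, out_dir / f"tree.{stem.replace('+', '_')}.nwk")
        with (out_dir / "reports.json").open("w") as fh:
            json.dump(
                [json.loads(r.to_json()) for r in reports], fh, indent=2, sort_keys=True
            )
        manifest = {
            "schemes": list(schemes),
            "modes": list(modes),
            "model": model,
            "its": its,
            "singleton_policy": singleton_policy,
            "pairs_only_mode_b": pairs_only_mode_b,
            "collapse_tol": collapse_tol,
            "loci": {
                a.locus_name: {
                    "aligned_bp": a.aligned_length,
                    "n_accessions": len(a),
                    "sha256": hashlib.sha256(
                        "".join(f">{k}\n{v}\n" for k, v in a.sequences.items()).encode()
                    ).hexdigest(),
                }
                for a in loci
            },
            "n_failures": len(failures),
            "failures": failures,
        }
        with (out_dir / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return EvaluationResult(reports=tuple(reports), failures=tuple(failures))


def format_report_table(reports: Sequence[DiscriminationReport]) -> str:
    """Table-shaped TSV: one row per combination x mode, sorted by scheme
    block (input order) then combination name.
    """
    if not reports:
        raise BarcodevalError("format_report_table: no reports")
    scheme_rank = {s: i for i, s in enumerate(SCHEMES)}
    rows = sorted(
        reports,
        key=lambda r: (
            scheme_rank.get(r.scheme, len(SCHEMES)),
            "+".join(r.combination),
            r.mode,
        ),
    )
    lines = ["\t".join(REPORT_COLUMNS)]
    for r in rows:
        t = r.totals
        lines.append(
            "\t".join(
                [
                    "+".join(r.combination),
                    r.mode,
                    str(r.aligned_bp),
                    str(t["n_species_sampled"]),
                    str(t["n_species_discriminated"]),
                    str(t["n_endangered_discriminated"]),
                    str(t["n_groups_discriminated"]),
                    f"{t['pct_species']:.2f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
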