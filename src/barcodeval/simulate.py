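"""Synthetic island-radiation generator.

Emulates the structure of a barcode study of an island radiation: several
informal taxonomic groups (clades) with distinct stem ages, a handful of
species per clade, one to a few accessions per species, six barcode loci of
differing substitution rates evolving under HKY+Gamma, and per-accession
missing loci emulating failed amplifications.

Each clade is a Yule (pure-birth) tree conditioned on its species count and
rescaled so its crown age equals ``stem_age * crown_age_fraction``; clades
hang off a ladder-shaped backbone at their stem ages (equal stems become a
polytomy; the youngest clade shares the youngest backbone node). Below each
species tip, accessions coalesce at uniform depths bounded by
``intraspecific_depth_mya``. Branch lengths are in Myr; a locus' expected
substitutions per site on a branch are ``subst_rate * branch_length * site
rate multiplier`` with multipliers from an equal-probability discretized
Gamma (mean per category).

All randomness flows from a single seed through named per-operation streams,
so each component is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .io import (
    BarcodevalError,
    LocusAlignment,
    SampleTable,
    write_locus_fasta,
    write_newick,
    write_sample_table,
)

_BASES = "ACGT"
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


@dataclass(frozen=True)
class CladeConfig:
    name: str
    stem_age_mya: float
    n_species: int
    crown_age_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.stem_age_mya <= 0:
            raise BarcodevalError(f"clade {self.name}: stem age must be > 0")
        if not (0 < self.crown_age_fraction < 1):
            raise BarcodevalError(f"clade {self.name}: crown_age_fraction in (0,1)")
        if self.n_species < 1:
            raise BarcodevalError(f"clade {self.name}: need >=1 species")

    @property
    def crown_age_mya(self) -> float:
        return self.stem_age_mya * self.crown_age_fraction


@dataclass(frozen=True)
class LocusConfig:
    name: str
    length: int
    subst_rate: float  # substitutions / site / Myr
    kappa: float = 2.0  # transition/transversion rate ratio
    gamma_shape: float = 0.8
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        if self.length < 1 or self.subst_rate <= 0:
            raise BarcodevalError(f"locus {self.name}: bad length/rate")
        if self.kappa <= 0 or self.gamma_shape <= 0 or self.n_rate_categories < 1:
            raise BarcodevalError(f"locus {self.name}: bad HKY+Gamma parameters")


@dataclass(frozen=True)
class SimulationConfig:
    clades: tuple[CladeConfig, ...]
    loci: tuple[LocusConfig, ...]
    accessions_per_species: tuple[int, int] = (1, 4)
    intraspecific_depth_mya: float = 0.05
    min_split_fraction: float = 0.1
    missing_fraction: float = 0.05
    endangered_fraction: float = 0.3
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.accessions_per_species
        if not (1 <= lo <= hi):
            raise BarcodevalError("accessions_per_species must satisfy 1 <= lo <= hi")
        if not (0 <= self.missing_fraction < 1):
            raise BarcodevalError("missing_fraction must be in [0, 1)")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise BarcodevalError("base_freqs must sum to 1")


#: Aligned lengths follow the six barcode regions of the motivating study;
#: per-Myr rates are literature-scale (plastid coding slowest, ITS fastest).
DEFAULT_LOCI = (
    LocusConfig("ITS", 621, 5.0e-3),
    LocusConfig("trnH-psbA", 342, 2.5e-3),
    LocusConfig("matK", 867, 1.5e-3),
    LocusConfig("rpoC1", 511, 8.0e-4),
    LocusConfig("rbcL", 588, 5.0e-4),
    LocusConfig("rpoB", 354, 4.0e-4),
)


def lotus_like_config(seed: int = 0, include_young: bool = False) -> SimulationConfig:
    """Preset mirroring the nine informal groups of a Macaronesian-legume
    style radiation: stem ages drawn from the five dated divergence nodes
    (groups sharing a node share its age), ~38 species, six loci at the
    study's aligned lengths. ``include_young`` appends two very recent
    (0.5 Mya) radiations for age-contrast experiments.
    """
    clades = [
        CladeConfig("purpureus", 4.78, 6),
        CladeConfig("jolyi", 4.78, 1),
        CladeConfig("arenarius", 4.55, 3),
        CladeConfig("campylocladus", 4.34, 7),
        CladeConfig("glaucus", 4.34, 6),
        CladeConfig("assakensis", 4.34, 3),
        CladeConfig("sessilifolius", 3.71, 5),
        CladeConfig("rhyncholotus", 3.71, 4),
        CladeConfig("argyrodes", 2.53, 3),
    ]
    if include_young:
        # very recent bursts: long colonization lag, radiation in the last
        # ~0.1 Myr (short crown relative to stem)
        clades += [
            CladeConfig("young_a", 0.5, 5, crown_age_fraction=0.25),
            CladeConfig("young_b", 0.5, 4, crown_age_fraction=0.25),
        ]
    return SimulationConfig(clades=tuple(clades), loci=DEFAULT_LOCI, seed=seed)


def uniform_radiation_config(
    stem_age_mya: float,
    n_clades: int = 3,
    n_species: int = 5,
    seed: int = 0,
    loci: tuple[LocusConfig, ...] = DEFAULT_LOCI,
) -> SimulationConfig:
    """All clades share one stem age — for age-gradient experiments."""
    clades = tuple(
        CladeConfig(f"clade{i+1:02d}", stem_age_mya, n_species)
        for i in range(n_clades)
    )
    return SimulationConfig(clades=clades, loci=loci, seed=seed)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent child stream of the master seed."""
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Dated species/accession tree
# ---------------------------------------------------------------------------

def _new_node(age: float) -> dendropy.Node:
    nd = dendropy.Node()
    nd.age = age
    return nd


def _accession_subtree(
    species: str,
    n_acc: int,
    depth_cap: float,
    rng: np.random.Generator,
    leaf_registry: list[tuple[dendropy.Node, str]],
) -> dendropy.Node:
    """Pectinate within-species genealogy; returns its top node (age <= cap)."""
    def leaf(i: int) -> dendropy.Node:
        nd = _new_node(0.0)
        leaf_registry.append((nd, f"{species}_x{i}"))
        return nd

    if n_acc == 1:
        return leaf(1)
    depths = np.sort(rng.uniform(0.0, depth_cap, size=n_acc - 1))[::-1]
    top = _new_node(float(depths[0]))
    cur = top
    for i in range(n_acc - 1):
        cur.add_child(leaf(i + 1))
        if i < n_acc - 2:
            nxt = _new_node(float(depths[i + 1]))
            cur.add_child(nxt)
            cur = nxt
        else:
            cur.add_child(leaf(n_acc))
    return top


def _yule_crown(
    crown_age: float,
    n_species: int,
    rng: np.random.Generator,
    min_split_fraction: float = 0.1,
) -> tuple[dendropy.Node, list[dendropy.Node]]:
    """Yule tree on ``n_species`` tips conditioned to the given crown age.

    Topology follows the Yule process (each lineage equally likely to split
    next); the ``n_species - 2`` non-crown split ages are i.i.d. uniform on
    ``(min_split_fraction * crown_age, crown_age)``, the slow-speciation
    limit of the conditioned Yule process. The lower bound emulates
    extinction pruning: in a mature radiation the surviving, recognized
    species are separated by at least a fraction of the clade's depth,
    while a very young radiation (small crown age) keeps its shallow splits.

    Returns the crown node and one parent node per pending species lineage
    (a node appears once per descending lineage).
    """
    floor = min_split_fraction * crown_age
    ages = np.sort(rng.uniform(floor, crown_age, size=n_species - 2))[::-1]
    crown = _new_node(crown_age)
    active: list[dendropy.Node] = [crown, crown]
    for age in ages:
        parent = active.pop(int(rng.integers(len(active))))
        nd = _new_node(float(age))
        parent.add_child(nd)
        active.extend([nd, nd])
    return crown, active


def simulate_dated_tree(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, dict]:
    """Dated accession-level tree (branch lengths in Myr) plus truth tables.

    Truth maps: ``species_clade`` (species -> clade), ``accession_species``,
    and per-clade stem/crown ages.
    """
    rng = _stream(config.seed, "tree")
    clades = sorted(config.clades, key=lambda c: (-c.stem_age_mya, c.name))
    names = [c.name for c in clades]
    if len(set(names)) != len(names):
        raise BarcodevalError(f"duplicate clade names: {names}")

    leaf_registry: list[tuple[dendropy.Node, str]] = []
    truth = {"species_clade": {}, "accession_species": {}, "clade_ages": {}}
    lo, hi = config.accessions_per_species

    def build_clade(clade: CladeConfig, attach: dendropy.Node) -> None:
        truth["clade_ages"][clade.name] = {
            "stem_age_mya": clade.stem_age_mya,
            "crown_age_mya": clade.crown_age_mya if clade.n_species > 1 else None,
        }

        def add_species(parent: dendropy.Node, j: int) -> None:
            sp = f"{clade.name}_sp{j:02d}"
            truth["species_clade"][sp] = clade.name
            n_acc = int(rng.integers(lo, hi + 1))
            cap = min(config.intraspecific_depth_mya, parent.age)
            top = _accession_subtree(sp, n_acc, cap, rng, leaf_registry)
            parent.add_child(top)

        if clade.n_species == 1:
            add_species(attach, 1)
            return
        crown, lineage_parents = _yule_crown(
            clade.crown_age_mya,
            clade.n_species,
            rng,
            min_split_fraction=config.min_split_fraction,
        )
        attach.add_child(crown)
        for j, parent in enumerate(lineage_parents, start=1):
            add_species(parent, j)

    root: dendropy.Node | None = None
    current: dendropy.Node | None = None
    for idx, clade in enumerate(clades):
        is_last = idx == len(clades) - 1
        if current is None:
            current = _new_node(clade.stem_age_mya)
            root = current
        elif not is_last and clade.stem_age_mya < current.age - 1e-12:
            nxt = _new_node(clade.stem_age_mya)
            current.add_child(nxt)
            current = nxt
        build_clade(clade, current)

    tns = dendropy.TaxonNamespace()
    for nd, label in leaf_registry:
        nd.taxon = tns.new_taxon(label)
        truth["accession_species"][label] = label.rsplit("_x", 1)[0]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = max(0.0, nd.parent_node.age - nd.age)
    return tree, truth


# ---------------------------------------------------------------------------
# Sequence simulation (HKY + discretized Gamma)
# ---------------------------------------------------------------------------

def hky_rate_matrix(kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """HKY instantaneous rate matrix scaled to 1 expected sub/site/unit time."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in _TRANSITIONS else 1.0)
        Q[i, i] = -Q[i].sum()
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rate per equal-probability category of a mean-1 Gamma."""
    if n_categories == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(
        np.linspace(0.0, 1.0, n_categories + 1), a=shape, scale=1.0 / shape
    )
    upper = gammainc(shape + 1.0, shape * bounds[1:])
    lower = gammainc(shape + 1.0, shape * bounds[:-1])
    return n_categories * (upper - lower)


def simulate_sequences(
    tree: dendropy.Tree,
    locus: LocusConfig,
    seed: int,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> LocusAlignment:
    """Evolve one locus down a dated tree; returns an aligned locus.

    The root sequence is drawn from the stationary base frequencies; each
    site carries a fixed Gamma rate-category multiplier along the whole tree.
    """
    rng = _stream(seed, f"sequences:{locus.name}")
    L = locus.length
    cats = rng.integers(0, locus.n_rate_categories, size=L)
    cat_rates = discrete_gamma_rates(locus.gamma_shape, locus.n_rate_categories)
    Q = hky_rate_matrix(locus.kappa, base_freqs)

    root = tree.seed_node
    seqs: dict[int, np.ndarray] = {
        id(root): rng.choice(4, size=L, p=np.asarray(base_freqs))
    }
    out: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            current = seqs[id(nd)]
        else:
            parent_seq = seqs[id(nd.parent_node)]
            blen = nd.edge.length or 0.0
            child = parent_seq.copy()
            if blen > 0:
                for c in range(locus.n_rate_categories):
                    t_eff = locus.subst_rate * blen * cat_rates[c]
                    P = expm(Q * t_eff)
                    for s in range(4):
                        idx = np.flatnonzero((cats == c) & (parent_seq == s))
                        if idx.size:
                            child[idx] = rng.choice(4, size=idx.size, p=P[s])
            seqs[id(nd)] = child
            current = child
        if nd.is_leaf():
            out[nd.taxon.label] = "".join(_BASES[b] for b in current)
    return LocusAlignment(locus_name=locus.name, sequences=out)


def inject_missing(
    loci: Sequence[LocusAlignment], fraction: float, seed: int
) -> list[LocusAlignment]:
    """Delete whole (accession, locus) sequences independently with the given
    probability, keeping at least one locus per accession.
    """
    if not (0 <= fraction < 1):
        raise BarcodevalError("inject_missing: fraction must be in [0, 1)")
    if fraction == 0:
        return list(loci)
    rng = _stream(seed, "missing")
    accessions = sorted({acc for aln in loci for acc in aln.sequences})
    drop = rng.random((len(accessions), len(loci))) < fraction
    for i, acc in enumerate(accessions):
        present = [k for k, aln in enumerate(loci) if acc in aln.sequences]
        if all(drop[i, k] for k in present):
            keep = present[int(rng.integers(len(present)))]
            drop[i, keep] = False
    acc_index = {a: i for i, a in enumerate(accessions)}
    out = []
    for k, aln in enumerate(loci):
        kept = {
            acc: seq
            for acc, seq in aln.sequences.items()
            if not drop[acc_index[acc], k]
        }
        if not kept:
            raise BarcodevalError(
                f"inject_missing: locus {aln.locus_name!r} lost every accession"
            )
        out.append(LocusAlignment(locus_name=aln.locus_name, sequences=kept))
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    truth: dict
    loci: tuple[LocusAlignment, ...]
    table: SampleTable
    ages: "object"  # pandas DataFrame: group, age_mya, n_species


def make_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Simulate a complete ready-to-evaluate dataset plus ground truth.

    Writes, when ``out_dir`` is given: one aligned FASTA per locus,
    ``samples.tsv``, ``ages.tsv``, ``tree.nwk`` and ``truth.json``.
    """
    import pandas as pd

    tree, truth = simulate_dated_tree(config)
    loci = [
        simulate_sequences(tree, locus, config.seed, config.base_freqs)
        for locus in config.loci
    ]
    loci = inject_missing(loci, config.missing_fraction, config.seed)

    flag_rng = _stream(config.seed, "endangered")
    species = sorted(truth["species_clade"])
    endangered = {
        sp: bool(flag_rng.random() < config.endangered_fraction) for sp in species
    }
    rows = []
    for acc in sorted(truth["accession_species"]):
        sp = truth["accession_species"][acc]
        clade = truth["species_clade"][sp]
        rows.append(
            {
                "accession_id": acc,
                "species": sp,
                "group": clade,
                "endangered": endangered[sp],
                "region": clade,
            }
        )
    table = SampleTable(pd.DataFrame(rows))

    n_per_clade: dict[str, int] = {}
    for sp, clade in truth["species_clade"].items():
        n_per_clade[clade] = n_per_clade.get(clade, 0) + 1
    ages = pd.DataFrame(
        [
            {
                "group": clade.name,
                # MRCA age of the sampled species: crown for radiations,
                # stem for single-species clades
                "age_mya": (
                    clade.crown_age_mya if clade.n_species > 1 else clade.stem_age_mya
                ),
                "n_species": n_per_clade[clade.name],
            }
            for clade in sorted(config.clades, key=lambda c: c.name)
        ]
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for aln in loci:
            write_locus_fasta(aln, out_dir / f"{aln.locus_name}.fasta")
        write_sample_table(table, out_dir / "samples.tsv")
        ages.to_csv(out_dir / "ages.tsv", sep="\t", index=False)
        write_newick(tree, out_dir / "tree.nwk")
        with (out_dir / "truth.json").open("w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)

    return SimulatedDataset(
        config=config,
        tree=tree,
        truth=truth,
        loci=tuple(loci),
        table=table,
        ages=ages,
    )
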