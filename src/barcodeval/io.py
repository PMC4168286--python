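"""Alignment, metadata and tree I/O plus multilocus concatenation.

The containers here are deliberately thin: a :class:`LocusAlignment` is an
aligned barcode region keyed by accession id, a :class:`SampleTable` maps
accessions to species and informal taxonomic groups, and a
:class:`ConcatenatedMatrix` is a supermatrix built from several loci under one
of two missing-data conventions:

* **mode A** — keep every accession seen in any included locus; a locus the
  accession lacks is padded with ``'?'`` (missing datum).
* **mode B** — keep only accessions sequenced for *every* included locus.

``'?'`` marks a missing datum (e.g. failed amplification) while ``'-'`` is an
alignment gap; both are excluded from distance computation downstream but are
distinct characters on disk. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

MISSING = "?"
GAP = "-"
#: Unambiguous nucleotide states used in distance and variability computations.
STANDARD_STATES = frozenset("ACGT")
#: Characters accepted in an aligned barcode sequence.
ALLOWED_CHARS = frozenset("ACGTURYSWKMBDHVN" + GAP + MISSING)

REQUIRED_METADATA_COLUMNS = ("accession_id", "species", "group", "endangered", "region")

_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


class BarcodevalError(ValueError):
    """Base class for domain errors raised by this package."""


class RaggedAlignmentError(BarcodevalError):
    """Sequences in one locus do not all share the same aligned length."""


class DuplicateAccessionError(BarcodevalError):
    """The same accession id appears more than once."""


@dataclass(frozen=True)
class LocusAlignment:
    """One aligned barcode region (e.g. *matK*), keyed by accession id."""

    locus_name: str
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise BarcodevalError(f"locus {self.locus_name!r}: empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                f"locus {self.locus_name!r}: ragged alignment, lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise BarcodevalError(f"locus {self.locus_name!r}: zero-length alignment")
        bad = {c for s in self.sequences.values() for c in s} - ALLOWED_CHARS
        if bad:
            raise BarcodevalError(
                f"locus {self.locus_name!r}: unexpected characters {sorted(bad)}"
            )

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class SampleTable:
    """Per-accession metadata: species, informal group, threat flag, region.

    Invariant: every species belongs to exactly one informal taxonomic group.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.df.columns]
        if missing:
            raise BarcodevalError(f"sample table: missing required columns {missing}")
        if self.df["accession_id"].duplicated().any():
            dups = self.df.loc[self.df["accession_id"].duplicated(), "accession_id"]
            raise DuplicateAccessionError(
                f"sample table: duplicate accession ids {sorted(set(dups))}"
            )
        groups_per_species = self.df.groupby("species")["group"].nunique()
        conflicted = groups_per_species[groups_per_species > 1]
        if len(conflicted):
            raise BarcodevalError(
                "sample table: species mapped to more than one group: "
                f"{sorted(conflicted.index)}"
            )

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "SampleTable":
        return cls(pd.DataFrame.from_records(list(records)))

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(self.df["accession_id"])

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.df["accession_id"], self.df["species"]))

    def group_of_species(self) -> dict[str, str]:
        return dict(zip(self.df["species"], self.df["group"]))

    def endangered_species(self) -> frozenset[str]:
        return frozenset(self.df.loc[self.df["endangered"].astype(bool), "species"])

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ConcatenatedMatrix:
    """Supermatrix of one or more loci with partition bookkeeping."""

    loci_included: tuple[str, ...]
    sequences: Mapping[str, str]
    partition_bounds: tuple[tuple[str, int, int], ...]  # (locus, start, end), half-open
    mode: str  # "A" or "B"

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def read_locus_fasta(path: str | Path, locus_name: str | None = None) -> LocusAlignment:
    """Read one aligned FASTA file into a :class:`LocusAlignment`.

    Sequences are upper-cased; the locus name defaults to the file stem.
    Raises on missing/empty files, ragged alignments and duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if locus_name is None:
        locus_name = path.stem
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise DuplicateAccessionError(
                f"locus {locus_name!r}: duplicate accession id {record.id!r}"
            )
        sequences[record.id] = str(record.seq).upper().replace("U", "T")
    if not sequences:
        raise BarcodevalError(f"{path}: no FASTA records found")
    return LocusAlignment(locus_name=locus_name, sequences=sequences)


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for acc, seq in aln.sequences.items():
            fh.write(f">{acc}\n{seq}\n")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read the per-accession metadata TSV.

    The header must contain ``accession_id, species, group, endangered,
    region``; ``endangered`` accepts 0/1/true/false. Extra columns are kept
    but ignored (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise BarcodevalError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_METADATA_COLUMNS]
    if extra:
        logger.info("sample table %s: ignoring extra columns %s", path, extra)

    def parse_flag(value: str) -> bool:
        v = value.strip().lower()
        if v in _TRUTHY:
            return True
        if v in _FALSY:
            return False
        raise BarcodevalError(f"sample table: unparseable endangered flag {value!r}")

    df = df.copy()
    df["endangered"] = df["endangered"].map(parse_flag)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    out = table.df.copy()
    out["endangered"] = out["endangered"].astype(bool).map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)


def concatenate(
    loci: Sequence[LocusAlignment],
    table: SampleTable | None = None,
    mode: str = "A",
    pairs_only_mode_b: bool = False,
) -> ConcatenatedMatrix:
    """Concatenate loci into a supermatrix under missing-data mode A or B.

    Mode A keeps the union of accession ids and pads absent loci with ``'?'``;
    mode B keeps only the intersection. ``pairs_only_mode_b`` restores the
    original convention in which the exclusion rule applied only to two-locus
    combinations (larger combinations then fall back to mode A padding).
    """
    if not loci:
        raise BarcodevalError("concatenate: need at least one locus")
    if mode not in ("A", "B"):
        raise BarcodevalError(f"concatenate: unknown mode {mode!r}")
    names = [a.locus_name for a in loci]
    if len(set(names)) != len(names):
        raise BarcodevalError(f"concatenate: duplicate locus names {names}")

    effective_mode = mode
    if mode == "B" and pairs_only_mode_b and len(loci) != 2:
        effective_mode = "A"

    id_sets = [set(a.sequences) for a in loci]
    if effective_mode == "A":
        ids = sorted(set.union(*id_sets))
    else:
        ids = sorted(set.intersection(*id_sets))
        if len(ids) < 2:
            raise BarcodevalError(
                f"concatenate mode B: only {len(ids)} accession(s) shared by all "
                f"loci {names}"
            )
    if table is not None:
        known = set(table.accession_ids)
        unknown = [i for i in ids if i not in known]
        if unknown:
            raise BarcodevalError(
                f"concatenate: accessions absent from sample table: {unknown}"
            )

    bounds: list[tuple[str, int, int]] = []
    start = 0
    for aln in loci:
        bounds.append((aln.locus_name, start, start + aln.aligned_length))
        start += aln.aligned_length

    sequences = {
        acc: "".join(
            aln.sequences.get(acc, MISSING * aln.aligned_length) for aln in loci
        )
        for acc in ids
    }
    return ConcatenatedMatrix(
        loci_included=tuple(names),
        sequences=sequences,
        partition_bounds=tuple(bounds),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Trees (Newick round-trip; the tree container is a dendropy.Tree throughout)
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree as Newick with branch lengths (labels quoted as needed)."""
    newick = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
        real_value_format_specifier="",
    )
    Path(path).write_text(newick)


def read_newick(path: str | Path) -> dendropy.Tree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
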