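"""Pairwise nucleotide distances under the Kimura two-parameter model.

For each sequence pair only *comparable* sites are used: columns where both
sequences carry one of A, C, G, T (pairwise deletion — gaps, ``?`` and
ambiguity codes are excluded even when compatible, for determinism). With
transition proportion P (A<->G, C<->T) and transversion proportion Q over the
n comparable sites,

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

A pair is *undefined* (saturated) when n = 0 or either log argument is <= 0;
undefined pairs are carried in a mask rather than imputed, and tree building
refuses matrices containing them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import BarcodevalError, ConcatenatedMatrix, LocusAlignment

logger = logging.getLogger(__name__)

# A,C,G,T -> 0..3; everything else (gap, ?, ambiguity) -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_PURINES = (0, 2)  # A, G


class UndefinedDistanceError(BarcodevalError):
    """A required pairwise distance is undefined (saturated or no overlap)."""


class K2PResult(NamedTuple):
    d: float  # nan when undefined
    P: float
    Q: float
    n_sites: int
    defined: bool


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(n_comparable, n_transitions, n_transversions) for two encoded rows."""
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        return 0, 0, 0
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    # transition: both purines or both pyrimidines (same purine-ness on both sides)
    transitions = int((diff & (((aa == 0) | (aa == 2)) == ((bb == 0) | (bb == 2)))).sum())
    transversions = int(diff.sum()) - transitions
    return n, transitions, transversions


def k2p_from_proportions(P: float, Q: float) -> float:
    """Closed-form K2P distance; nan if outside the model's domain."""
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return math.nan
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise BarcodevalError(
            f"k2p_distance: unequal lengths {len(seq_a)} vs {len(seq_b)}"
        )
    n, ts, tv = _pair_counts(encode(seq_a), encode(seq_b))
    if n == 0:
        return K2PResult(math.nan, math.nan, math.nan, 0, False)
    P, Q = ts / n, tv / n
    d = k2p_from_proportions(P, Q)
    return K2PResult(d, P, Q, n, not math.isnan(d))


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Proportion of mismatches over comparable sites (nan when none)."""
    if len(seq_a) != len(seq_b):
        raise BarcodevalError(
            f"p_distance: unequal lengths {len(seq_a)} vs {len(seq_b)}"
        )
    n, ts, tv = _pair_counts(encode(seq_a), encode(seq_b))
    if n == 0:
        return math.nan, 0
    return (ts + tv) / n, n


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with an undefined-pair mask.

    ``d[i, j]`` is nan exactly where ``defined[i, j]`` is False (diagonal is
    always 0/defined). ``P``, ``Q`` and ``n_sites`` retain per-pair
    diagnostics.
    """

    taxa: tuple[str, ...]
    d: np.ndarray
    defined: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    n_sites: np.ndarray

    @property
    def fully_defined(self) -> bool:
        return bool(self.defined.all())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if not self.defined[i, j]:
                    out.append((self.taxa[i], self.taxa[j]))
        return out

    def index_of(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa)}

    def min_distance_to_others(self, taxon: str, others: list[str]) -> float:
        """Smallest defined distance from ``taxon`` to any of ``others``.

        Undefined (saturated) pairs are treated as arbitrarily large, i.e.
        they never produce the minimum unless every pair is undefined (inf).
        """
        idx = self.index_of()
        i = idx[taxon]
        best = math.inf
        for o in others:
            j = idx[o]
            if self.defined[i, j]:
                best = min(best, float(self.d[i, j]))
        return best


def build_distance_matrix(
    matrix: ConcatenatedMatrix | LocusAlignment, model: str = "k2p"
) -> DistanceMatrix:
    """All-pairs distances with pairwise deletion over the (concatenated)
    columns. Undefined pairs are masked and logged, never fatal here.
    """
    if model not in ("k2p", "p"):
        raise BarcodevalError(f"build_distance_matrix: unknown model {model!r}")
    taxa = tuple(sorted(matrix.sequences))
    if len(taxa) < 2:
        raise BarcodevalError("build_distance_matrix: need at least 2 accessions")
    rows = np.stack([encode(matrix.sequences[t]) for t in taxa])
    n = len(taxa)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    n_sites = np.zeros((n, n), dtype=int)
    defined = np.ones((n, n), dtype=bool)
    np.fill_diagonal(n_sites, (rows < 4).sum(axis=1))
    for i in range(n):
        for j in range(i + 1, n):
            ns, ts, tv = _pair_counts(rows[i], rows[j])
            n_sites[i, j] = n_sites[j, i] = ns
            if ns == 0:
                d[i, j] = d[j, i] = math.nan
                P[i, j] = P[j, i] = math.nan
                Q[i, j] = Q[j, i] = math.nan
                defined[i, j] = defined[j, i] = False
                continue
            p_ts, p_tv = ts / ns, tv / ns
            P[i, j] = P[j, i] = p_ts
            Q[i, j] = Q[j, i] = p_tv
            if model == "k2p":
                dist = k2p_from_proportions(p_ts, p_tv)
            else:
                dist = p_ts + p_tv
            d[i, j] = d[j, i] = dist
            if math.isnan(dist):
                defined[i, j] = defined[j, i] = False
    dm = DistanceMatrix(taxa=taxa, d=d, defined=defined, P=P, Q=Q, n_sites=n_sites)
    if not dm.fully_defined:
        logger.warning(
            "distance matrix: %d undefined (saturated or non-overlapping) pairs",
            len(dm.undefined_pairs()),
        )
    return dm


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP-like TSV; undefined entries written as 'NA'."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.taxa) + "\n")
        for i, t in enumerate(dm.taxa):
            cells = [
                f"{dm.d[i, j]:.9f}" if dm.defined[i, j] else "NA"
                for j in range(len(dm.taxa))
            ]
            fh.write(t + "\t" + "\t".join(cells) + "\n")
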