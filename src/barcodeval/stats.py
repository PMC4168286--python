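"""Alignment variability summaries: variable sites, parsimony-informative
sites and indel events.

Only the four unambiguous nucleotides count as states; gaps (``-``), missing
data (``?``) and IUPAC ambiguity codes are ignored when tallying column
states, which keeps the counts conservative. An indel *event* is an
equivalence class of maximal gap runs sharing identical start and end
columns across sequences — two sequences gapped over exactly the same
columns contribute one event, not two.
"""

from __future__ import annotations

from collections import Counter

from .io import GAP, STANDARD_STATES, LocusAlignment


def _column_state_counts(aln: LocusAlignment) -> list[Counter]:
    seqs = list(aln.sequences.values())
    counts = []
    for col in range(aln.aligned_length):
        c = Counter(s[col] for s in seqs if s[col] in STANDARD_STATES)
        counts.append(c)
    return counts


def count_variable_sites(aln: LocusAlignment) -> int:
    """Columns with at least two distinct unambiguous states."""
    return sum(1 for c in _column_state_counts(aln) if len(c) >= 2)


def count_parsimony_informative(aln: LocusAlignment) -> int:
    """Columns where at least two states each occur in at least two sequences."""
    return sum(
        1
        for c in _column_state_counts(aln)
        if sum(1 for n in c.values() if n >= 2) >= 2
    )


def _gap_runs(seq: str) -> set[tuple[int, int]]:
    """Maximal runs of '-' as 0-based half-open (start, end) intervals."""
    runs = set()
    start = None
    for i, ch in enumerate(seq):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.add((start, i))
            start = None
    if start is not None:
        runs.add((start, len(seq)))
    return runs


def count_indel_events(aln: LocusAlignment) -> int:
    """Distinct gap events: maximal '-' runs pooled by identical coordinates."""
    events: set[tuple[int, int]] = set()
    for seq in aln.sequences.values():
        events |= _gap_runs(seq)
    return len(events)


def summarize_alignment(aln: LocusAlignment) -> dict:
    """One row of the per-locus variability report."""
    return {
        "locus": aln.locus_name,
        "aligned_bp": aln.aligned_length,
        "n_accessions": len(aln),
        "variable": count_variable_sites(aln),
        "informative": count_parsimony_informative(aln),
        "indel_events": count_indel_events(aln),
    }
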