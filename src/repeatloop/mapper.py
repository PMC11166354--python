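"""Exact-match short-read placement with unique/multi/unmapped classification.

Reproduces the contract of a zero-mismatch, suppress-multimapper aligner:
a read's occurrences are counted over both strands of all references; zero
occurrences -> unmapped, exactly one -> unique (with its placement),
two or more -> multi (no placement reported).  A perfectly palindromic read
matching one locus on both strands counts as two occurrences and is
therefore multi.  N never matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .haplotype import VALID_BASES, reverse_complement

UNIQUE = "unique"
MULTI = "multi"
UNMAPPED = "unmapped"


@dataclass
class ReadAlignment:
    read_id: str
    status: str
    length: int
    ref_name: str | None = None
    start: int | None = None
    strand: str | None = None

    @property
    def end(self) -> int:
        if self.start is None:
            raise ValueError("unplaced alignment has no end")
        return self.start + self.length


def _find_all(haystack: str, needle: str, limit: int | None):
    """Yield all start offsets of ``needle`` in ``haystack`` (overlapping),
    stopping after ``limit`` hits if given."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        if limit is not None and len(hits) >= limit:
            break
        i = haystack.find(needle, i + 1)
    return hits


SEED_K = 8


class SequenceIndex:
    """Named reference sequences supporting exact two-strand location
    queries, backed by an 8-mer seed table with full verification."""

    def __init__(self, references):
        if isinstance(references, dict):
            items = list(references.items())
        else:
            items = [(name, seq) for name, seq in references]
        if not items:
            raise ValueError("no reference sequences")
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference names")
        for name, seq in items:
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"reference {name}: invalid bases {sorted(bad)}")
        self.references: dict[str, str] = dict(items)
        self._seeds: dict[str, dict[str, list[int]]] = {}
        for name, seq in self.references.items():
            table: dict[str, list[int]] = {}
            for i in range(len(seq) - SEED_K + 1):
                kmer = seq[i : i + SEED_K]
                if "N" in kmer:
                    continue
                table.setdefault(kmer, []).append(i)
            self._seeds[name] = table
        # classification is memoised per sequence: sRNA libraries are highly
        # redundant and this dominates pipeline runtime
        self._classify_cached = lru_cache(maxsize=1_000_000)(self._classify_seq)

    def _occurrences(self, name: str, needle: str, limit: int | None):
        seq = self.references[name]
        if len(needle) < SEED_K:
            return _find_all(seq, needle, limit)
        hits = []
        for i in self._seeds[name].get(needle[:SEED_K], ()):
            if seq.startswith(needle, i):
                hits.append(i)
                if limit is not None and len(hits) >= limit:
                    break
        return hits

    def locate(self, read: str, limit: int | None = 2) -> list[tuple[str, int, str]]:
        """All placements of ``read`` (both strands), as (ref, start, strand).

        With the default ``limit=2`` the search stops as soon as the read is
        known to be multi-mapping; pass ``limit=None`` for report-all mode.
        """
        _check_read(read)
        placements: list[tuple[str, int, str]] = []
        if "N" in read:
            return placements
        rc = reverse_complement(read)
        for name in self.references:
            remain = None if limit is None else limit - len(placements)
            for i in self._occurrences(name, read, remain):
                placements.append((name, i, "+"))
            if limit is not None and len(placements) >= limit:
                return placements
            # both orientations always scanned: a palindromic read matching
            # one locus on both strands yields two occurrences (multi)
            remain = None if limit is None else limit - len(placements)
            for i in self._occurrences(name, rc, remain):
                placements.append((name, i, "-"))
            if limit is not None and len(placements) >= limit:
                return placements
        return placements

    def _classify_seq(self, read: str):
        placements = self.locate(read, limit=2)
        if not placements:
            return (UNMAPPED, None, None, None)
        if len(placements) > 1:
            return (MULTI, None, None, None)
        ref, start, strand = placements[0]
        return (UNIQUE, ref, start, strand)

    def classify(self, read: str):
        return self._classify_cached(read)


def _check_read(read: str) -> None:
    if not read:
        raise ValueError("empty read")
    bad = set(read) - VALID_BASES
    if bad:
        raise ValueError(f"invalid symbols in read: {sorted(bad)}")


def build_index(references) -> SequenceIndex:
    return SequenceIndex(references)


def classify_read(index: SequenceIndex, read: str, read_id: str = "read") -> ReadAlignment:
    status, ref, start, strand = index.classify(read)
    return ReadAlignment(read_id, status, len(read), ref, start, strand)


def two_pass_filter(
    reads, genome_index: SequenceIndex, target_index: SequenceIndex
) -> list[ReadAlignment]:
    """Genome-uniqueness filtering followed by target mapping.

    Reads classified multi on the genome are discarded; the survivors
    (genome-unique or genome-unmapped) are classified against the target and
    only unique target placements are returned.

    ``reads`` is an iterable of sequences or (read_id, sequence) pairs.
    """
    out: list[ReadAlignment] = []
    for i, item in enumerate(reads):
        if isinstance(item, tuple):
            read_id, seq = item
        else:
            read_id, seq = f"read{i}", item
        g_status, *_ = genome_index.classify(seq)
        if g_status == MULTI:
            continue
        aln = classify_read(target_index, seq, read_id)
        if aln.status == UNIQUE:
            out.append(aln)
    return out
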