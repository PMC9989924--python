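"""TSS-relative promoter coordinates and consensus/edit-distance motif scanning.

Coordinates are counted from the transcription start site with +1 the first
transcribed base and -1 the base immediately upstream; position 0 does not
exist. Consensus patterns use IUPAC degenerate codes ('x'/'X' in informal
consensus notation is accepted and mapped to N); matching cost is Levenshtein
edit distance where a sequence base matching the degenerate set costs 0 and
substitutions/indels cost 1 — an 8-nt site can therefore match a 9-nt
consensus, which pure Hamming distance cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SEQUENCE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PromoterError(ValueError):
    """Raised for invalid sequences, patterns or coordinates."""


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter stored 5'→3' on the sense strand with a declared TSS.

    ``tss_offset`` is the 1-based index in ``sequence`` of the +1 position.
    """

    id: str
    sequence: str
    tss_offset: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for i, ch in enumerate(seq, start=1):
            if ch not in SEQUENCE_ALPHABET:
                raise PromoterError(
                    f"{self.id}: invalid character {ch!r} at position {i}"
                )
        if not 1 <= self.tss_offset <= len(seq):
            raise PromoterError(
                f"{self.id}: tss offset {self.tss_offset} outside sequence "
                f"of length {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC consensus with a maximum allowed edit distance."""

    consensus: str
    max_edit_distance: int = 0

    def __post_init__(self) -> None:
        cons = self.consensus.upper().replace("X", "N")
        object.__setattr__(self, "consensus", cons)
        if not cons:
            raise PromoterError("empty consensus")
        for ch in cons:
            if ch not in IUPAC:
                raise PromoterError(f"invalid IUPAC code {ch!r} in consensus")
        if self.max_edit_distance < 0:
            raise PromoterError("max_edit_distance must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    """A consensus match; start/end are closed TSS-relative coordinates (no 0)."""

    promoter_id: str
    start: int
    end: int
    matched: str
    edit_distance: int
    consensus: str
    strand: str = "+"


def read_promoters(path: str | Path) -> list[PromoterSequence]:
    """Read promoter FASTA; the TSS offset comes from a header token ``tss=<int>``.

    Records lacking the token default the TSS to the sequence end (the whole
    record is treated as upstream). Lowercase input is uppercased.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PromoterError(f"{path.name}: no FASTA records found")
    promoters = []
    for rec in records:
        seq = str(rec.seq).upper()
        tss = len(seq)
        for token in rec.description.split():
            if token.startswith("tss="):
                try:
                    tss = int(token[4:])
                except ValueError:
                    raise PromoterError(
                        f"{rec.id}: malformed tss token {token!r}"
                    ) from None
        promoters.append(PromoterSequence(id=rec.id, sequence=seq, tss_offset=tss))
    return promoters


def _coord_key(coord: int) -> int:
    """Map no-zero TSS coordinates onto contiguous integers (-1 -> 0, +1 -> 1)."""
    if coord == 0:
        raise PromoterError("no position 0 in TSS-relative convention")
    return coord + 1 if coord < 0 else coord


def interval_length(start: int, end: int) -> int:
    """Count of positions in the closed TSS-relative interval, skipping 0."""
    ks, ke = _coord_key(start), _coord_key(end)
    if ks > ke:
        raise PromoterError(f"start {start} is after end {end} in TSS-relative order")
    return ke - ks + 1


def to_tss_relative(promoter: PromoterSequence, string_index: int) -> int:
    """1-based string index → TSS-relative coordinate (tss_offset maps to +1)."""
    if not 1 <= string_index <= len(promoter):
        raise PromoterError(
            f"string index {string_index} outside sequence of length {len(promoter)}"
        )
    delta = string_index - promoter.tss_offset
    return delta + 1 if delta >= 0 else delta


def from_tss_relative(promoter: PromoterSequence, coord: int) -> int:
    """Inverse of :func:`to_tss_relative`."""
    if coord == 0:
        raise PromoterError("no position 0 in TSS-relative convention")
    delta = coord - 1 if coord > 0 else coord
    idx = promoter.tss_offset + delta
    if not 1 <= idx <= len(promoter):
        raise PromoterError(f"coordinate {coord} outside sequence")
    return idx


def _match_cost(seq_char: str, pattern_code: str) -> int:
    # sequence N is treated leniently: any overlap with the code's set matches
    seq_set = IUPAC.get(seq_char, frozenset())
    return 0 if seq_set & IUPAC[pattern_code] else 1


def motif_edit_distance(window: str, consensus: str) -> int:
    """Levenshtein distance of a sequence window to an IUPAC consensus.

    Degenerate-set matches cost 0; substitutions and indels cost 1.
    """
    w, p = window.upper(), consensus.upper().replace("X", "N")
    prev = list(range(len(w) + 1))
    for i, pc in enumerate(p, start=1):
        cur = [i] + [0] * len(w)
        for j, wc in enumerate(w, start=1):
            cur[j] = min(
                prev[j] + 1,  # delete consensus char
                cur[j - 1] + 1,  # insert window char
                prev[j - 1] + _match_cost(wc, pc),
            )
        prev = cur
    return prev[-1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_string(seq: str, pattern: MotifPattern) -> list[tuple[int, int, int]]:
    """All kept hits on a raw string as (start0, length, distance).

    For each anchor (start position) the candidate windows of length
    m-k .. m+k are compared; the minimal-distance, then shortest, window is
    kept if its distance is within ``max_edit_distance``.
    """
    m = len(pattern.consensus)
    k = pattern.max_edit_distance
    L = len(seq)
    hits = []
    for start in range(L):
        best: tuple[int, int] | None = None  # (distance, length)
        lo = max(1, m - k)
        hi = min(m + k, L - start)
        for length in range(lo, hi + 1):
            d = motif_edit_distance(seq[start : start + length], pattern.consensus)
            if d <= k and (best is None or (d, length) < best):
                best = (d, length)
        if best is not None:
            hits.append((start, best[1], best[0]))
    return hits


def scan_consensus(
    promoter: PromoterSequence,
    pattern: MotifPattern,
    include_reverse: bool = False,
) -> list[MotifHit]:
    """Scan a promoter for consensus matches within the allowed edit distance.

    Forward (sense) strand only by default; ``include_reverse=True`` also
    scans the reverse complement, reporting hits with sense-strand
    coordinates and strand '-'. A pattern longer than the sequence yields an
    empty result. Overlapping hits are allowed; per anchor the
    minimal-distance, then shortest, hit is kept.
    """
    seq = promoter.sequence
    results: list[MotifHit] = []
    for start0, length, dist in _scan_string(seq, pattern):
        results.append(
            MotifHit(
                promoter_id=promoter.id,
                start=to_tss_relative(promoter, start0 + 1),
                end=to_tss_relative(promoter, start0 + length),
                matched=seq[start0 : start0 + length],
                edit_distance=dist,
                consensus=pattern.consensus,
                strand="+",
            )
        )
    if include_reverse:
        rc = reverse_complement(seq)
        L = len(seq)
        for start0, length, dist in _scan_string(rc, pattern):
            # map the reverse-complement window back onto sense coordinates
            sense_start0 = L - (start0 + length)
            results.append(
                MotifHit(
                    promoter_id=promoter.id,
                    start=to_tss_relative(promoter, sense_start0 + 1),
                    end=to_tss_relative(promoter, sense_start0 + length),
                    matched=rc[start0 : start0 + length],
                    edit_distance=dist,
                    consensus=pattern.consensus,
                    strand="-",
                )
            )
    results.sort(key=lambda h: (_coord_key(h.start), _coord_key(h.end), h.strand))
    return results
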