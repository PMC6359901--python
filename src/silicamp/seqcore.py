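"""Sequence primitives: IUPAC degenerate-base algebra, primer matching, FASTA/FASTQ I/O.

Reads are plain A/C/G/T/N strings (uppercased, U converted to T on ingest);
primers are IUPAC strings where degenerate codes such as ``Y`` or ``N`` denote
sets of allowed bases.  A window base matches a primer code when it belongs to
the code's base set; an ``N`` in a *read* matches nothing unless the primer
code itself is ``N`` (an uncalled base carries no evidence).
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from glob import glob
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TySequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: base sets for the 15 IUPAC nucleotide codes
IUPAC_SETS: dict[str, frozenset[str]] = {
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

#: complement of each IUPAC code (complement of its base set)
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

READ_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes map to the
    code of the complemented base set, e.g. R<->Y, B<->V).

    Raises ``ValueError`` naming the first offending position for characters
    outside the 15-code alphabet.
    """
    out = []
    for i, c in enumerate(seq):
        try:
            out.append(IUPAC_COMPLEMENT[c])
        except KeyError:
            raise ValueError(
                f"invalid IUPAC character {c!r} at position {i} in {seq!r}"
            ) from None
    return "".join(reversed(out))


def normalize_bases(raw: str, *, origin: str = "<sequence>") -> str:
    """Uppercase, convert U to T, and validate against A/C/G/T/N."""
    bases = raw.upper().replace("U", "T")
    for i, c in enumerate(bases):
        if c not in READ_ALPHABET:
            raise ValueError(
                f"{origin}: invalid base {c!r} at position {i} "
                "(expected A/C/G/T/N)"
            )
    return bases


@dataclass(frozen=True)
class Sequence:
    """A named read or reference sequence over A/C/G/T/N."""

    id: str
    bases: str

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "Sequence":
        return cls(id, normalize_bases(raw, origin=id))

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "Sequence":
        return Sequence(self.id, reverse_complement(self.bases))


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-coded primer and its role in the pair."""

    seq: str
    role: str = "forward"  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("primer sequence must be non-empty")
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer role must be forward/reverse, got {self.role!r}")
        for i, c in enumerate(self.seq):
            if c not in IUPAC_SETS:
                raise ValueError(
                    f"invalid IUPAC character {c!r} at position {i} "
                    f"in {self.role} primer {self.seq!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "DegeneratePrimer":
        return DegeneratePrimer(reverse_complement(self.seq), self.role)


def primer_matches(window: str, primer: "DegeneratePrimer | str",
                   max_mismatches: int = 0) -> bool:
    """True iff ``window`` matches the degenerate primer with at most
    ``max_mismatches`` positions outside the primer code's base set.

    ``window`` must have the primer's exact length; an N in the window only
    matches a primer N.
    """
    pat = primer.seq if isinstance(primer, DegeneratePrimer) else primer
    if len(window) != len(pat):
        raise ValueError(
            f"window length {len(window)} != primer length {len(pat)}"
        )
    mism = 0
    for w, p in zip(window, pat):
        if w == "N":
            if p != "N":
                mism += 1
        elif w not in IUPAC_SETS[p]:
            mism += 1
        if mism > max_mismatches:
            return False
    return True


def _primer_regex(pattern: str) -> re.Pattern[str]:
    """Compile a degenerate primer into a regex of character classes.

    Only valid for exact (0-mismatch) matching.  Read N never matches except
    against a primer N, so N is included in a class only for code N.
    """
    parts = []
    for c in pattern:
        bases = "".join(sorted(IUPAC_SETS[c]))
        if c == "N":
            bases += "N"
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


class _PrimerScanner:
    """Finds all match offsets of one degenerate primer in a read.

    Uses a compiled regex on the 0-mismatch fast path and a positionwise
    scan otherwise.
    """

    def __init__(self, pattern: str, max_mismatches: int = 0) -> None:
        self.pattern = pattern
        self.max_mismatches = max_mismatches
        self._re = _primer_regex(pattern) if max_mismatches == 0 else None

    def find_all(self, bases: str) -> list[int]:
        if self._re is not None:
            # overlapping matches via zero-width lookahead
            return [m.start() for m in
                    re.finditer(f"(?=(?:{self._re.pattern}))", bases)]
        L = len(self.pattern)
        return [i for i in range(len(bases) - L + 1)
                if primer_matches(bases[i:i + L], self.pattern,
                                  self.max_mismatches)]

    def find_first(self, bases: str, start: int = 0) -> int | None:
        if self._re is not None:
            m = self._re.search(bases, start)
            return m.start() if m else None
        L = len(self.pattern)
        for i in range(start, len(bases) - L + 1):
            if primer_matches(bases[i:i + L], self.pattern, self.max_mismatches):
                return i
        return None

    def matches_at_end(self, bases: str) -> bool:
        L = len(self.pattern)
        if len(bases) < L:
            return False
        tail = bases[-L:]
        if self._re is not None:
            return self._re.fullmatch(tail) is not None
        return primer_matches(tail, self.pattern, self.max_mismatches)


def scan_for_primer(read: "Sequence | str",
                    primers: "dict[str, str] | TySequence[str]",
                    max_mismatches: int = 0) -> list[tuple[int, str]]:
    """All (offset, primer id) pairs at which any listed primer matches.

    ``primers`` is a mapping of id -> IUPAC string, or a sequence of IUPAC
    strings (each string doubling as its own id).
    """
    bases = read.bases if isinstance(read, Sequence) else read
    if not isinstance(primers, dict):
        primers = {p: p for p in primers}
    hits: list[tuple[int, str]] = []
    for name, pat in primers.items():
        scanner = _PrimerScanner(pat, max_mismatches)
        hits.extend((off, name) for off in scanner.find_all(bases))
    hits.sort(key=lambda t: (t[0], t[1]))
    return hits


@dataclass(frozen=True)
class PrimerPairContext:
    """The forward/reverse primer pair and the derived site patterns.

    The assembled ("extension") orientation of an amplicon is::

        [forward-primer site] [inter-primer region] [RC(reverse primer) site]

    ``starting_set`` holds the two primer sequences whose presence in a read
    (in either orientation) marks it as covering a region boundary — the
    forward primer and the reverse complement of the reverse primer.
    ``finishing_set`` holds the patterns that terminate extension in the two
    possible extension orientations; only the first is consulted because all
    reads are canonicalised into forward-primer orientation.
    """

    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    max_mismatches: int = 0

    @classmethod
    def from_strings(cls, forward: str, reverse: str,
                     max_mismatches: int = 0) -> "PrimerPairContext":
        return cls(DegeneratePrimer(forward, "forward"),
                   DegeneratePrimer(reverse, "reverse"),
                   max_mismatches)

    @property
    def start_site(self) -> str:
        """Pattern opening the region on the extension strand (the forward primer)."""
        return self.forward.seq

    @property
    def end_site(self) -> str:
        """Pattern closing the region on the extension strand (RC of the reverse primer)."""
        return reverse_complement(self.reverse.seq)

    @property
    def starting_set(self) -> tuple[str, str]:
        return (self.forward.seq, reverse_complement(self.reverse.seq))

    @property
    def finishing_set(self) -> tuple[str, str]:
        return (reverse_complement(self.reverse.seq),
                reverse_complement(self.forward.seq))

    def start_scanner(self) -> _PrimerScanner:
        return _PrimerScanner(self.start_site, self.max_mismatches)

    def end_scanner(self) -> _PrimerScanner:
        return _PrimerScanner(self.end_site, self.max_mismatches)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O

def _open_maybe_gzip(path: Path) -> io.TextIOWrapper:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _expand_paths(paths) -> list[Path]:
    if isinstance(paths, (str, Path)):
        paths = [paths]
    out: list[Path] = []
    for p in paths:
        p = str(p)
        if any(ch in p for ch in "*?["):
            matched = sorted(glob(p))
            if not matched:
                raise FileNotFoundError(f"no files match pattern {p!r}")
            out.extend(Path(m) for m in matched)
        else:
            path = Path(p)
            if not path.exists():
                raise FileNotFoundError(f"input file not found: {p}")
            out.append(path)
    return out


def read_sequences(paths) -> Iterator[Sequence]:
    """Stream Sequences from FASTA/FASTQ files (gzip detected by magic bytes).

    ``paths`` may be a single path, an iterable of paths, or a glob pattern.
    Format is auto-detected from the first record character ('>' FASTA,
    '@' FASTQ).  Qualities are discarded; this tool never uses them.
    """
    for path in _expand_paths(paths):
        with _open_maybe_gzip(path) as handle:
            head = handle.read(1)
            if head == "":
                logger.warning("input file %s is empty", path)
                continue
            handle.seek(0)
            if head == ">":
                fmt = "fasta"
            elif head == "@":
                fmt = "fastq"
            else:
                raise ValueError(
                    f"{path}: unrecognised format (first character {head!r}; "
                    "expected '>' or '@')"
                )
            index = 0
            try:
                for rec in SeqIO.parse(handle, fmt):
                    yield Sequence.from_raw(rec.id, str(rec.seq))
                    index += 1
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed {fmt} record #{index + 1}: {exc}"
                ) from exc


def write_fasta(seqs: Iterable["Sequence | tuple[str, str]"], path,
                wrap: int = 80) -> int:
    """Write sequences as FASTA wrapped at ``wrap`` columns; returns a count."""
    n = 0
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=wrap)
        records = []
        for s in seqs:
            if isinstance(s, Sequence):
                rec = SeqRecord(Seq(s.bases), id=s.id, description="")
            else:
                sid, bases = s
                rec = SeqRecord(Seq(bases), id=sid, description="")
            records.append(rec)
            n += 1
        writer.write_file(records)
    return n
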