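"""Glucocorticoid-response-element (GRE) promoter scanning.

Scans a promoter sequence for matches to an IUPAC consensus — by default
the canonical GRE palindrome RGNACANNNTGTNCY (two half-sites separated by
a fixed 3-bp spacer) — on either or both strands, allowing a mismatch
budget.  Hits containing a CpG dinucleotide (the methylatable positions a
pyrosequencing assay would target) can then be filtered out, and
coordinates reported relative to the transcription start site in
promoter-style signed numbering (base immediately upstream of the TSS is
-1; there is no position 0).

Proprietary position-weight matrices are deliberately out of scope: the
scanner is a transparent consensus matcher whose pattern and mismatch
budget are user-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MotifModel",
    "GREHit",
    "DEFAULT_GRE",
    "scan_gre",
    "filter_cpg_hits",
    "to_tss_coordinates",
    "read_promoter_fasta",
    "hits_to_bed",
]

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_SEQ_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class MotifModel:
    """IUPAC consensus with a mismatch budget and strand selection."""

    pattern: str = "RGNACANNNTGTNCY"
    max_mismatches: int = 0
    strands: str = "both"  # "+", "-", or "both"

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("pattern must be non-empty")
        bad = set(pat) - set(_IUPAC)
        if bad:
            raise ValueError(f"pattern contains non-IUPAC symbols: {sorted(bad)}")
        if not 0 <= self.max_mismatches < len(pat):
            raise ValueError("max_mismatches must lie in [0, pattern length)")
        if self.strands not in ("+", "-", "both"):
            raise ValueError("strands must be '+', '-' or 'both'")
        object.__setattr__(self, "pattern", pat)


#: Canonical GRE palindrome: AGAACAnnnTGTTCT-like half-sites, R/Y wobble.
DEFAULT_GRE = MotifModel()


@dataclass(frozen=True)
class GREHit:
    """One motif hit in 1-based inclusive plus-strand coordinates."""

    start: int
    end: int
    strand: str
    mismatches: int
    matched: str  # plus-strand substring covered by the hit
    contains_cpg: bool
    tss_relative: tuple[int, int] | None = None  # signed (start, end), no 0


def _mismatch_count(window: str, pattern: str, budget: int) -> int | None:
    """Mismatches of window vs IUPAC pattern, or None once over budget.

    An N in the *sequence* never counts as a match, whatever the pattern
    symbol allows.
    """
    mm = 0
    for base, sym in zip(window, pattern):
        if base == "N" or base not in _IUPAC[sym]:
            mm += 1
            if mm > budget:
                return None
    return mm


def scan_gre(sequence: str, model: MotifModel = DEFAULT_GRE) -> list[GREHit]:
    """All motif matches with <= max_mismatches, on the configured strands.

    Coordinates are 1-based inclusive on the input (plus) strand; a minus-
    strand hit at plus coordinates [s, e] means the reverse complement of
    that window matches the pattern.
    """
    seq = str(sequence).upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    pat = model.pattern
    L = len(pat)
    rc_pat = None
    if model.strands in ("-", "both"):
        # matching the reverse complement of the pattern on the plus strand
        # is equivalent to matching the pattern on the minus strand
        rc_pat = str(Seq(pat).reverse_complement())
    hits: list[GREHit] = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if model.strands in ("+", "both"):
            mm = _mismatch_count(window, pat, model.max_mismatches)
            if mm is not None:
                hits.append(
                    GREHit(i + 1, i + L, "+", mm, window, "CG" in window)
                )
        if rc_pat is not None:
            mm = _mismatch_count(window, rc_pat, model.max_mismatches)
            if mm is not None:
                hits.append(
                    GREHit(i + 1, i + L, "-", mm, window, "CG" in window)
                )
    return hits


def filter_cpg_hits(hits: list[GREHit]) -> list[GREHit]:
    """Keep hits whose plus-strand window contains the CG dinucleotide.

    A CpG is strand-symmetric (CG pairs with CG), so the plus-strand
    representation decides for both strands.  Coordinates are unchanged.
    """
    return [h for h in hits if h.contains_cpg]


def to_tss_coordinates(hits: list[GREHit], tss_position: int) -> list[GREHit]:
    """Attach signed TSS-relative coordinates (promoter-style, no zero).

    A base at 1-based sequence position i upstream of the TSS maps to
    -(tss_position - i); the base at the TSS itself is +1 and downstream
    positions continue positive.
    """
    if tss_position < 1:
        raise ValueError("tss_position is 1-based and must be >= 1")

    def signed(i: int) -> int:
        d = i - tss_position
        return d + 1 if d >= 0 else d

    return [replace(h, tss_relative=(signed(h.start), signed(h.end))) for h in hits]


def read_promoter_fasta(path) -> tuple[str, str]:
    """First record of a FASTA file as (name, uppercase sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def hits_to_bed(hits: list[GREHit], name: str) -> str:
    """BED-like TSV: name, start, end, strand, mismatches, contains_cpg, tss_relative."""
    lines = ["#name\tstart\tend\tstrand\tmismatches\tcontains_cpg\ttss_relative"]
    for h in hits:
        tss = "." if h.tss_relative is None else f"{h.tss_relative[0]}/{h.tss_relative[1]}"
        lines.append(
            f"{name}\t{h.start}\t{h.end}\t{h.strand}\t{h.mismatches}"
            f"\t{int(h.contains_cpg)}\t{tss}"
        )
    return "\n".join(lines) + "\n"
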