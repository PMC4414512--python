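"""Read preprocessing: demultiplexing, primer trimming, QC and length filter.

Mirrors the upstream stages of an amplicon run: reads are grouped by
barcode, primer sequences are clipped from both ends (Hamming matching with
a small mismatch tolerance — no indels inside the primer match), run-level
quality statistics are computed (Q20 = Phred >= 20), and short post-trim
reads are removed (length >= 40 retained).  Quality strings stay in register
with sequences through every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .primers import (
    DEFAULT_PRIMER_PAIRS,
    PrimerPair,
    iupac_hamming,
    reverse_complement,
)

__all__ = [
    "ReadRecord",
    "QCStats",
    "read_fastq",
    "write_fastq",
    "demultiplex",
    "trim_primers",
    "quality_trim",
    "quality_stats",
    "q20_percent",
    "length_filter",
]


@dataclass(frozen=True)
class ReadRecord:
    """One read with Phred+33 qualities and trimming provenance flags."""

    read_id: str
    sequence: str
    qualities: str
    barcode: str | None = None
    trimmed_fwd: bool = False
    trimmed_rev: bool = False
    pair: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qualities]


@dataclass(frozen=True)
class QCStats:
    """Run-level quality summary."""

    n_reads: int
    called_nt: int
    q20_nt: int
    per_barcode: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.q20_nt > self.called_nt:
            raise ValueError("q20_nt cannot exceed called_nt")

    @property
    def q20_pct(self) -> float:
        return q20_percent(self.called_nt, self.q20_nt)

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "called_nt": self.called_nt,
            "q20_nt": self.q20_nt,
            "q20_pct": self.q20_pct,
            "per_barcode": dict(self.per_barcode),
        }


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a FASTQ file (Sanger Phred+33)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [
            ReadRecord(read_id=title.split()[0], sequence=seq.upper(), qualities=qual)
            for title, seq, qual in FastqGeneralIterator(fh)
        ]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_map: Mapping[str, str],
    max_mismatch: int = 1,
    enforce_distance: bool = True,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to barcodes by their 5' prefix and clip the barcode.

    A read is assigned only when exactly one barcode lies within
    *max_mismatch* of its prefix; ambiguous or unmatched reads go to the
    unassigned bin.  A well-formed barcode set has equal lengths and
    pairwise Hamming distance > 2*max_mismatch (which makes ambiguity
    impossible); violations raise unless ``enforce_distance=False``.
    """
    labels = list(barcode_map)
    seqs = [barcode_map[l].upper() for l in labels]
    if not seqs:
        raise ValueError("empty barcode map")
    blen = len(seqs[0])
    if any(len(s) != blen for s in seqs):
        raise ValueError("barcodes must all have the same length")
    if enforce_distance:
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = iupac_hamming(seqs[i], seqs[j])
                if d <= 2 * max_mismatch:
                    raise ValueError(
                        f"barcodes {labels[i]!r} and {labels[j]!r} are at Hamming "
                        f"distance {d} <= 2*max_mismatch={2 * max_mismatch}"
                    )
    bins: dict[str, list[ReadRecord]] = {l: [] for l in labels}
    unassigned: list[ReadRecord] = []
    for read in reads:
        prefix = read.sequence[:blen]
        if len(prefix) < blen:
            unassigned.append(read)
            continue
        hits = [
            (iupac_hamming(prefix, s), l)
            for l, s in zip(labels, seqs)
            if iupac_hamming(prefix, s) <= max_mismatch
        ]
        if len(hits) != 1:
            unassigned.append(read)
            continue
        label = hits[0][1]
        bins[label].append(
            replace(
                read,
                sequence=read.sequence[blen:],
                qualities=read.qualities[blen:],
                barcode=label,
            )
        )
    return bins, unassigned


def _prefix_mismatches(seq: str, probe: str) -> int | None:
    if len(seq) < len(probe):
        return None
    return iupac_hamming(seq[: len(probe)], probe)


def _suffix_mismatches(seq: str, probe: str) -> int | None:
    if len(seq) < len(probe):
        return None
    return iupac_hamming(seq[-len(probe) :], probe)


def trim_primers(
    read: ReadRecord,
    pairs: Sequence[PrimerPair] = DEFAULT_PRIMER_PAIRS,
    max_mismatch: int = 2,
) -> ReadRecord:
    """Clip primer sequences from the 5' and 3' read ends.

    Every pair is tried in both read orientations: a forward-orientation
    read starts with the forward primer and ends with the reverse complement
    of the reverse primer; a reverse-orientation read starts with the
    reverse primer and ends with the reverse complement of the forward
    primer.  The candidate clipping the most ends with the fewest total
    mismatches wins; qualities are clipped in register.  Reads in which no
    primer is found pass through with both flags unset.
    """
    if not read.sequence:
        raise ValueError(f"{read.read_id}: empty read")
    best: tuple[int, int, int, int, str] | None = None  # (-n_clips, mm, clip5, clip3, pair)
    for pair in pairs:
        for p5, p3 in (
            (pair.forward, reverse_complement(pair.reverse)),
            (pair.reverse, reverse_complement(pair.forward)),
        ):
            mm5 = _prefix_mismatches(read.sequence, p5)
            hit5 = mm5 is not None and mm5 <= max_mismatch
            # the 3' probe must not overlap a clipped 5' primer
            remaining = read.sequence[len(p5) :] if hit5 else read.sequence
            mm3 = _suffix_mismatches(remaining, p3)
            hit3 = mm3 is not None and mm3 <= max_mismatch
            n_clips = int(hit5) + int(hit3)
            if n_clips == 0:
                continue
            total_mm = (mm5 if hit5 else 0) + (mm3 if hit3 else 0)
            cand = (
                -n_clips,
                total_mm,
                len(p5) if hit5 else 0,
                len(p3) if hit3 else 0,
                pair.name,
            )
            if best is None or cand < best:
                best = cand
    if best is None:
        return read
    _, _, clip5, clip3, pair_name = best
    end = len(read.sequence) - clip3
    return replace(
        read,
        sequence=read.sequence[clip5:end],
        qualities=read.qualities[clip5:end],
        trimmed_fwd=clip5 > 0,
        trimmed_rev=clip3 > 0,
        pair=pair_name,
    )


def quality_trim(read: ReadRecord, window: int = 10, min_mean_q: float = 15.0) -> ReadRecord:
    """Optional sliding-window 3' quality trim (off by default in the pipeline).

    Scans from the 3' end and clips while the trailing window's mean Phred
    is below *min_mean_q*.
    """
    phred = read.phred()
    end = len(phred)
    while end >= window:
        win = phred[end - window : end]
        if sum(win) / window >= min_mean_q:
            break
        end -= 1
    return replace(read, sequence=read.sequence[:end], qualities=read.qualities[:end])


def q20_percent(called_nt: int, q20_nt: int) -> float:
    """Percentage of called bases at Phred >= 20, rounded to 2 decimals."""
    if called_nt <= 0:
        raise ValueError("called_nt must be > 0")
    if q20_nt > called_nt or q20_nt < 0:
        raise ValueError("q20_nt must be in [0, called_nt]")
    return round(100.0 * q20_nt / called_nt, 2)


def quality_stats(reads: Iterable[ReadRecord]) -> QCStats:
    """Run-level QC: read count, called bases, Q20 bases, per-barcode reads."""
    n_reads = 0
    called = 0
    q20 = 0
    per_barcode: dict[str, int] = {}
    for r in reads:
        n_reads += 1
        called += len(r.sequence)
        q20 += sum(1 for c in r.qualities if ord(c) - 33 >= 20)
        if r.barcode is not None:
            per_barcode[r.barcode] = per_barcode.get(r.barcode, 0) + 1
    if called == 0:
        raise ValueError("no called nucleotides in input")
    return QCStats(n_reads=n_reads, called_nt=called, q20_nt=q20, per_barcode=per_barcode)


def length_filter(
    reads: Iterable[ReadRecord], min_len: int = 40
) -> tuple[list[ReadRecord], int]:
    """Keep reads with post-trim length >= min_len (boundary retained)."""
    retained: list[ReadRecord] = []
    rejected = 0
    for r in reads:
        if len(r.sequence) >= min_len:
            retained.append(r)
        else:
            rejected += 1
    return retained, rejected
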