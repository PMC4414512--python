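"""Glocal read-to-panel alignment with a mapping-quality gate.

Each trimmed read is aligned end-to-end (global in the read) against any
contiguous stretch (local in the reference) of every panel region, on both
strands.  The best-scoring (region, strand) wins; mapping quality is a
uniqueness score computed from the margin to the second-best candidate,

    MAPQ = min(60, 6 * (best_score - second_best_score)),  0 on exact ties,

a documented surrogate for short-read-mapper estimators: the downstream
filter only needs a monotone uniqueness score gated at >= 20.  Reads whose
best score is not positive are reported unmapped.

Scoring defaults (match +1, mismatch -4, gap open 6, gap extend 1; a gap of
length k costs open + k*extend) mirror widely used short-read mapper
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .primers import reverse_complement
from .refpanel import ReferencePanel

__all__ = [
    "AlignmentScoring",
    "GlocalResult",
    "AlignmentResult",
    "PanelIndex",
    "glocal_align",
    "map_read",
    "map_reads",
    "filter_alignments",
    "write_sam",
    "read_sam",
]

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentScoring:
    """Alignment scoring and the retention thresholds applied downstream."""

    match: int = 1
    mismatch_penalty: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    min_mapq: int = 20
    min_len: int = 40

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("penalties must be positive")
        if not (0 <= self.min_mapq <= 60):
            raise ValueError("min_mapq must be in [0, 60]")


@dataclass(frozen=True)
class GlocalResult:
    """Outcome of one pairwise glocal alignment."""

    score: int
    cigar: str
    n_mismatch: int
    n_ins: int
    n_del: int
    ref_start: int
    ref_end: int

    @property
    def aligned_ref_bases(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def nm(self) -> int:
        return self.n_mismatch + self.n_ins + self.n_del


@dataclass
class AlignmentResult:
    """Best panel assignment for one read."""

    read_id: str
    species: str | None
    pair: str | None
    strand: str  # "+", "-" or "*" for unmapped
    score: int
    second_best_score: int
    mapq: int
    n_mismatch: int
    n_ins: int
    n_del: int
    aligned_ref_bases: int
    cigar: str
    ref_start: int
    read_len: int
    seq: str = ""
    qual: str = ""

    @property
    def mapped(self) -> bool:
        return self.species is not None

    @property
    def key(self) -> tuple[str, str] | None:
        if self.species is None:
            return None
        return (self.species, self.pair)

    @property
    def nm(self) -> int:
        return self.n_mismatch + self.n_ins + self.n_del


def _ops_to_cigar(ops: np.ndarray) -> tuple[str, int, int, int]:
    """Collapse an op array into a CIGAR string and (mismatch, ins, del) counts."""
    cigar = []
    n_mm = int((ops == _kernels.OP_MISMATCH).sum())
    n_ins = int((ops == _kernels.OP_INS).sum())
    n_del = int((ops == _kernels.OP_DEL).sum())
    sam_code = {0: "M", 1: "M", 2: "I", 3: "D"}
    run_op = None
    run_len = 0
    for op in ops:
        c = sam_code[int(op)]
        if c == run_op:
            run_len += 1
        else:
            if run_op is not None:
                cigar.append(f"{run_len}{run_op}")
            run_op, run_len = c, 1
    if run_op is not None:
        cigar.append(f"{run_len}{run_op}")
    return "".join(cigar), n_mm, n_ins, n_del


def glocal_align(read: str, region_seq: str, scoring: AlignmentScoring | None = None) -> GlocalResult:
    """Align *read* end-to-end against a local stretch of *region_seq*."""
    if not read or not region_seq:
        raise ValueError("read and region must be non-empty")
    if scoring is None:
        scoring = AlignmentScoring()
    q = encode_seq(read)
    r = encode_seq(region_seq)
    score, ref_start, ref_end, ops = _kernels.align_traceback(
        q, r,
        np.int32(scoring.match), np.int32(scoring.mismatch_penalty),
        np.int32(scoring.gap_open), np.int32(scoring.gap_extend),
    )
    cigar, n_mm, n_ins, n_del = _ops_to_cigar(ops)
    return GlocalResult(int(score), cigar, n_mm, n_ins, n_del, int(ref_start), int(ref_end))


class PanelIndex:
    """Encoded panel regions, cached for batch alignment."""

    def __init__(self, panel: ReferencePanel):
        self.panel = panel
        self.keys: list[tuple[str, str]] = [r.key for r in panel]
        self.seqs: list[str] = [r.target_seq for r in panel]
        lens = [len(s) for s in self.seqs]
        self.ref_lens = np.asarray(lens, dtype=np.int64)
        width = max(lens)
        self.refs = np.full((len(self.seqs), width), 4, dtype=np.int8)
        for i, s in enumerate(self.seqs):
            self.refs[i, : len(s)] = encode_seq(s)


def map_read(
    read_id: str,
    seq: str,
    panel: ReferencePanel | PanelIndex,
    scoring: AlignmentScoring | None = None,
    qual: str = "",
) -> AlignmentResult:
    """Assign one read to its best panel region (both strands considered)."""
    return _map_one(read_id, seq, qual, _as_index(panel), scoring or AlignmentScoring())


def map_reads(
    reads: Iterable[tuple[str, str, str]],
    panel: ReferencePanel | PanelIndex,
    scoring: AlignmentScoring | None = None,
) -> list[AlignmentResult]:
    """Batch :func:`map_read` over (read_id, sequence, quality) triples."""
    index = _as_index(panel)
    sc = scoring or AlignmentScoring()
    return [_map_one(rid, seq, qual, index, sc) for rid, seq, qual in reads]


def _as_index(panel: ReferencePanel | PanelIndex) -> PanelIndex:
    if isinstance(panel, PanelIndex):
        return panel
    if len(panel) == 0:
        raise ValueError("panel is empty")
    return PanelIndex(panel)


def _map_one(
    read_id: str, seq: str, qual: str, index: PanelIndex, scoring: AlignmentScoring
) -> AlignmentResult:
    if not seq:
        return AlignmentResult(read_id, None, None, "*", 0, 0, 0, 0, 0, 0, 0, "*", -1, 0, seq, qual)
    args = (
        np.int32(scoring.match), np.int32(scoring.mismatch_penalty),
        np.int32(scoring.gap_open), np.int32(scoring.gap_extend),
    )
    fwd = encode_seq(seq)
    rev = encode_seq(reverse_complement(seq))
    scores_f = _kernels.score_many(fwd, index.refs, index.ref_lens, *args)
    scores_r = _kernels.score_many(rev, index.refs, index.ref_lens, *args)
    all_scores = np.concatenate([scores_f, scores_r])
    order = np.argsort(all_scores, kind="stable")
    best_idx = int(order[-1])
    best = int(all_scores[best_idx])
    second = int(all_scores[int(order[-2])]) if all_scores.size > 1 else _kernels.NEG
    if best <= 0:
        return AlignmentResult(
            read_id, None, None, "*", best, second, 0, 0, 0, 0, 0, "*", -1, len(seq), seq, qual
        )
    n = len(index.keys)
    strand = "+" if best_idx < n else "-"
    region_i = best_idx % n
    species, pair = index.keys[region_i]
    q = fwd if strand == "+" else rev
    score, ref_start, ref_end, ops = _kernels.align_traceback(
        q, encode_seq(index.seqs[region_i]), *args
    )
    cigar, n_mm, n_ins, n_del = _ops_to_cigar(ops)
    mapq = 0 if best == second else max(0, min(60, 6 * (best - second)))
    return AlignmentResult(
        read_id=read_id,
        species=species,
        pair=pair,
        strand=strand,
        score=best,
        second_best_score=second,
        mapq=mapq,
        n_mismatch=n_mm,
        n_ins=n_ins,
        n_del=n_del,
        aligned_ref_bases=int(ref_end - ref_start),
        cigar=cigar,
        ref_start=int(ref_start),
        read_len=len(seq),
        seq=seq,
        qual=qual,
    )


def filter_alignments(
    results: Iterable[AlignmentResult], scoring: AlignmentScoring | None = None
) -> tuple[list[AlignmentResult], dict[str, int]]:
    """Apply the retention filters: read length >= min_len, MAPQ >= min_mapq.

    Boundary values are retained.  Returns (retained, tally) where tally
    counts rejections by reason ('unmapped', 'short_read', 'low_mapq').
    """
    sc = scoring or AlignmentScoring()
    retained: list[AlignmentResult] = []
    tally = {"unmapped": 0, "short_read": 0, "low_mapq": 0}
    for res in results:
        if not res.mapped:
            tally["unmapped"] += 1
        elif res.read_len < sc.min_len:
            tally["short_read"] += 1
        elif res.mapq < sc.min_mapq:
            tally["low_mapq"] += 1
        else:
            retained.append(res)
    return retained, tally


# ---------------------------------------------------------------------------
# SAM 1.x output


def _region_name(species: str, pair: str) -> str:
    return f"{species}|{pair}"


def write_sam(
    results: Iterable[AlignmentResult], panel: ReferencePanel, path: str | Path
) -> None:
    """Write alignments as SAM 1.x.

    One @SQ line per panel region (SN = ``species|pair``); flag 16 encodes the
    reverse strand (SEQ/QUAL stored reference-oriented), flag 4 unmapped.
    Tags: NM (edit distance), AS (score), XS (second best), XM/XI/XD
    (mismatch / inserted / deleted base counts).
    """
    try:
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for region in panel:
                fh.write(
                    f"@SQ\tSN:{_region_name(region.species, region.primer_pair)}"
                    f"\tLN:{len(region.target_seq)}\n"
                )
            fh.write("@PG\tID:ampliconid\tPN:ampliconid\n")
            for res in results:
                if not res.mapped:
                    seq = res.seq or "*"
                    qual = res.qual or "*"
                    fh.write(
                        f"{res.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n"
                    )
                    continue
                flag = 16 if res.strand == "-" else 0
                if res.strand == "-":
                    seq = reverse_complement(res.seq) if res.seq else "*"
                    qual = res.qual[::-1] if res.qual else "*"
                else:
                    seq = res.seq or "*"
                    qual = res.qual or "*"
                fh.write(
                    "\t".join(
                        [
                            res.read_id,
                            str(flag),
                            _region_name(res.species, res.pair),
                            str(res.ref_start + 1),
                            str(res.mapq),
                            res.cigar,
                            "*",
                            "0",
                            "0",
                            seq,
                            qual,
                            f"NM:i:{res.nm}",
                            f"AS:i:{res.score}",
                            f"XS:i:{res.second_best_score}",
                            f"XM:i:{res.n_mismatch}",
                            f"XI:i:{res.n_ins}",
                            f"XD:i:{res.n_del}",
                        ]
                    )
                    + "\n"
                )
    except OSError as exc:
        raise OSError(f"failed writing SAM to {path}: {exc}") from exc


def read_sam(path: str | Path) -> list[AlignmentResult]:
    """Re-parse a SAM file written by :func:`write_sam`."""
    results: list[AlignmentResult] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        qname, flag, rname, pos, mapq, cigar = f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[5]
        seq, qual = f[9], f[10]
        tags = {}
        for t in f[11:]:
            name, _type, val = t.split(":", 2)
            tags[name] = int(val)
        if flag & 4:
            results.append(
                AlignmentResult(
                    qname, None, None, "*", 0, 0, 0, 0, 0, 0, 0, "*", -1,
                    0 if seq == "*" else len(seq),
                    "" if seq == "*" else seq, "" if qual == "*" else qual,
                )
            )
            continue
        species, pair = rname.split("|")
        strand = "-" if flag & 16 else "+"
        stored_seq = seq if seq != "*" else ""
        stored_qual = qual if qual != "*" else ""
        if strand == "-" and stored_seq:
            stored_seq = reverse_complement(stored_seq)
            stored_qual = stored_qual[::-1]
        n_mm = tags.get("XM", 0)
        n_ins = tags.get("XI", 0)
        n_del = tags.get("XD", 0)
        ref_len = sum(
            int(n) for n, op in _iter_cigar(cigar) if op in "MD"
        )
        results.append(
            AlignmentResult(
                read_id=qname,
                species=species,
                pair=pair,
                strand=strand,
                score=tags.get("AS", 0),
                second_best_score=tags.get("XS", 0),
                mapq=mapq,
                n_mismatch=n_mm,
                n_ins=n_ins,
                n_del=n_del,
                aligned_ref_bases=ref_len,
                cigar=cigar,
                ref_start=pos - 1,
                read_len=len(stored_seq) if stored_seq else 0,
                seq=stored_seq,
                qual=stored_qual,
            )
        )
    return results


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""
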