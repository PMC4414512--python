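"""Quantification: count tables, error rates, correlations, detection calls.

Turns filtered alignments into the experiment's result objects: mapped-read
counts per (species, primer pair), per-species aggregation and reads-per-ng
normalization, per-(species, pair) sequencing error rates (mismatch + indel
bases over aligned reference bases), Pearson correlations between libraries
(computed on raw counts), and species detection calls gated on a minimum
read count across a minimum number of primer pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentResult
from .simulate import PoolSpec

__all__ = [
    "CountTable",
    "ErrorRateCell",
    "ErrorRateTable",
    "DetectionCall",
    "LibraryComparison",
    "count_by_region",
    "aggregate_by_species",
    "normalize_per_ng",
    "estimate_error_rates",
    "pearson_correlation",
    "call_species",
    "compare_libraries",
]


@dataclass(frozen=True)
class CountTable:
    """Mapped-read counts per (species, primer pair) for one library."""

    library_id: str
    counts: Mapping[tuple[str, str], int]
    unassigned: int = 0

    def __post_init__(self) -> None:
        for key, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {key}")
        if self.unassigned < 0:
            raise ValueError("unassigned must be >= 0")

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp, _ in self.counts:
            seen.setdefault(sp)
        return list(seen)

    @property
    def pairs(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pr in self.counts:
            seen.setdefault(pr)
        return list(seen)

    def get(self, species: str, pair: str) -> int:
        return int(self.counts.get((species, pair), 0))

    def pair_total(self, pair: str) -> int:
        return sum(c for (sp, pr), c in self.counts.items() if pr == pair)

    def species_total(self, species: str) -> int:
        return sum(c for (sp, pr), c in self.counts.items() if sp == species)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        """Species x pair DataFrame of counts (missing cells = 0)."""
        df = pd.DataFrame(0, index=self.species, columns=self.pairs, dtype=int)
        for (sp, pr), c in self.counts.items():
            df.loc[sp, pr] = c
        return df


def count_by_region(
    alignments: Iterable[AlignmentResult],
    library_id: str = "library",
    unassigned: int = 0,
) -> CountTable:
    """Tally retained reads per assigned (species, pair), idxstats-style.

    *alignments* should already be filtered; any unmapped entries present
    are tallied into ``unassigned`` rather than a region cell.
    """
    counts: dict[tuple[str, str], int] = {}
    extra_unassigned = 0
    for res in alignments:
        if res.key is None:
            extra_unassigned += 1
            continue
        counts[res.key] = counts.get(res.key, 0) + 1
    return CountTable(
        library_id=library_id, counts=counts, unassigned=unassigned + extra_unassigned
    )


def aggregate_by_species(
    table: CountTable, class_map: Mapping[str, str] | None = None
) -> dict:
    """Per-species totals, per-pair species proportions and optional
    class-level (e.g. mammal vs avian) proportions.

    Proportions within each pair sum to 1 over species; pairs with an
    all-zero column are reported under ``undefined_pairs`` instead.
    """
    if not table.counts:
        raise ValueError("empty count table")
    species_totals = {sp: table.species_total(sp) for sp in table.species}
    proportions: dict[tuple[str, str], float] = {}
    undefined: list[str] = []
    for pair in table.pairs:
        tot = table.pair_total(pair)
        if tot == 0:
            undefined.append(pair)
            continue
        for sp in table.species:
            proportions[(sp, pair)] = table.get(sp, pair) / tot
    out = {
        "species_totals": species_totals,
        "proportions": proportions,
        "undefined_pairs": undefined,
    }
    if class_map is not None:
        class_props: dict[tuple[str, str], float] = {}
        for pair in table.pairs:
            tot = table.pair_total(pair)
            if tot == 0:
                continue
            acc: dict[str, int] = {}
            for sp in table.species:
                cls = class_map.get(sp, "other")
                acc[cls] = acc.get(cls, 0) + table.get(sp, pair)
            for cls, c in acc.items():
                class_props[(cls, pair)] = c / tot
        out["class_proportions"] = class_props
    return out


def normalize_per_ng(table: CountTable, pool: PoolSpec) -> dict[tuple[str, str], float]:
    """Reads per nanogram of each species' per-reaction DNA.

    value = count / (reaction_ng * mass share of the species) — a rough
    between-species amplification-efficiency comparison.
    """
    out: dict[tuple[str, str], float] = {}
    for (sp, pair), c in table.counts.items():
        if sp not in pool.masses:
            raise KeyError(f"species {sp!r} counted but absent from pool {pool.name!r}")
        out[(sp, pair)] = c / pool.per_reaction_ng(sp)
    return out


@dataclass(frozen=True)
class ErrorRateCell:
    mismatch_bases: int
    inserted_bases: int
    deleted_bases: int
    aligned_ref_bases: int

    def rate(self, substitutions_only: bool = False) -> float:
        num = self.mismatch_bases
        if not substitutions_only:
            num += self.inserted_bases + self.deleted_bases
        return num / self.aligned_ref_bases


@dataclass(frozen=True)
class ErrorRateTable:
    """Per-(species, pair) error counts and rates from filtered alignments."""

    cells: Mapping[tuple[str, str], ErrorRateCell]
    substitutions_only: bool = False

    def rate(self, species: str, pair: str) -> float:
        return self.cells[(species, pair)].rate(self.substitutions_only)

    def rates(self) -> dict[tuple[str, str], float]:
        return {k: c.rate(self.substitutions_only) for k, c in self.cells.items()}

    def _marginal(self, index: int) -> dict[str, float]:
        acc: dict[str, list[int]] = {}
        for key, c in self.cells.items():
            label = key[index]
            num = c.mismatch_bases
            if not self.substitutions_only:
                num += c.inserted_bases + c.deleted_bases
            cur = acc.setdefault(label, [0, 0])
            cur[0] += num
            cur[1] += c.aligned_ref_bases
        return {k: n / d for k, (n, d) in acc.items() if d > 0}

    def marginal_by_pair(self) -> dict[str, float]:
        return self._marginal(1)

    def marginal_by_species(self) -> dict[str, float]:
        return self._marginal(0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                species=sp,
                pair=pr,
                mismatch_bases=c.mismatch_bases,
                inserted_bases=c.inserted_bases,
                deleted_bases=c.deleted_bases,
                aligned_ref_bases=c.aligned_ref_bases,
                rate=c.rate(self.substitutions_only),
            )
            for (sp, pr), c in self.cells.items()
        ]
        return pd.DataFrame(rows)


def estimate_error_rates(
    alignments: Iterable[AlignmentResult], substitutions_only: bool = False
) -> ErrorRateTable:
    """Aggregate per-read error counts into per-(species, pair) rates.

    The numerator counts mismatched plus inserted plus deleted bases (the
    dominant error mode of semiconductor sequencing is homopolymer indels,
    so indels belong in the error rate; pass ``substitutions_only=True`` for
    a sensitivity analysis).  The denominator is aligned *reference* bases,
    which keeps rates <= 1 under deletions.  Cells with zero aligned bases
    are omitted.
    """
    acc: dict[tuple[str, str], list[int]] = {}
    for res in alignments:
        if res.key is None:
            continue
        cur = acc.setdefault(res.key, [0, 0, 0, 0])
        cur[0] += res.n_mismatch
        cur[1] += res.n_ins
        cur[2] += res.n_del
        cur[3] += res.aligned_ref_bases
    cells = {
        key: ErrorRateCell(*vals)
        for key, vals in acc.items()
        if vals[3] > 0
    }
    return ErrorRateTable(cells=cells, substitutions_only=substitutions_only)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN for constant input (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    from scipy.stats import pearsonr

    return float(pearsonr(x, y).statistic)


@dataclass(frozen=True)
class DetectionCall:
    """Detection verdict for one species in one library."""

    species: str
    detected: bool
    supporting: Mapping[str, int]  # pair -> read count among pairs >= min_reads
    min_reads: int
    min_pairs: int


def call_species(
    table: CountTable,
    min_reads: int = 2,
    min_pairs: int = 1,
    species: Sequence[str] | None = None,
) -> list[DetectionCall]:
    """Call a species present when >= min_pairs primer pairs each contribute
    >= min_reads assigned reads.

    *species* extends the universe beyond the table (panel species with zero
    counts are reported as not detected).
    """
    if min_reads < 1 or min_pairs < 1:
        raise ValueError("thresholds must be >= 1")
    universe = list(table.species)
    for sp in species or ():
        if sp not in universe:
            universe.append(sp)
    calls: list[DetectionCall] = []
    for sp in universe:
        supporting = {
            pr: table.get(sp, pr) for pr in table.pairs if table.get(sp, pr) >= min_reads
        }
        calls.append(
            DetectionCall(
                species=sp,
                detected=len(supporting) >= min_pairs,
                supporting=supporting,
                min_reads=min_reads,
                min_pairs=min_pairs,
            )
        )
    return calls


@dataclass(frozen=True)
class LibraryComparison:
    """Pearson r between two libraries over one slice of count cells."""

    library_a: str
    library_b: str
    slice_name: str
    n: int
    r: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


def compare_libraries(
    tables: Sequence[CountTable],
    class_map: Mapping[str, str] | None = None,
    exclude_species: Sequence[str] = (),
) -> pd.DataFrame:
    """Correlation matrix between libraries over count-cell slices.

    Slices: all cells, each species class (when *class_map* given), each
    primer pair, and each pair x class.  Correlations use raw counts over
    the union of cell keys (missing cells are 0); degenerate slices
    (constant or fewer than 3 cells) are flagged NaN, never reported as a
    correlation.  ``exclude_species`` drops species from every slice.
    """
    if len(tables) < 2:
        raise ValueError("need at least two libraries")
    keys: list[tuple[str, str]] = []
    seen = set()
    common = None
    for t in tables:
        tkeys = set(t.counts)
        common = tkeys if common is None else (common & tkeys)
        for k in t.counts:
            if k not in seen and k[0] not in exclude_species:
                seen.add(k)
                keys.append(k)
    if common is not None and not common:
        raise ValueError("libraries share no (species, pair) cells")

    def slices() -> dict[str, list[tuple[str, str]]]:
        out = {"all": keys}
        pairs = sorted({pr for _, pr in keys})
        if class_map is not None:
            classes = sorted({class_map.get(sp, "other") for sp, _ in keys})
            for cls in classes:
                out[cls] = [k for k in keys if class_map.get(k[0], "other") == cls]
        for pr in pairs:
            out[pr] = [k for k in keys if k[1] == pr]
            if class_map is not None:
                for cls in sorted({class_map.get(sp, "other") for sp, _ in keys}):
                    out[f"{pr}/{cls}"] = [
                        k for k in keys if k[1] == pr and class_map.get(k[0], "other") == cls
                    ]
        return out

    rows: list[LibraryComparison] = []
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            a, b = tables[i], tables[j]
            for name, ks in slices().items():
                if len(ks) < 3:
                    r = float("nan")
                else:
                    xa = [a.get(*k) for k in ks]
                    xb = [b.get(*k) for k in ks]
                    try:
                        r = pearson_correlation(xa, xb)
                    except ValueError:
                        r = float("nan")
                rows.append(
                    LibraryComparison(a.library_id, b.library_id, name, len(ks), r)
                )
    return pd.DataFrame(
        [
            dict(
                library_a=c.library_a,
                library_b=c.library_b,
                slice=c.slice_name,
                n=c.n,
                r=c.r,
                defined=c.defined,
            )
            for c in rows
        ]
    )
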