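"""Reference panel construction by in-silico PCR.

Given mitochondrial reference sequences and universal primer pairs, this
module locates primer binding sites (IUPAC-aware, with a configurable
mismatch tolerance), extracts the amplicon target region between the two
primers for each (species, primer pair), and assembles the multi-species
reference panel that reads are later assigned to.

Conventions
-----------
* Coordinates are 0-based, half-open, on the top strand of the stored
  reference sequence.
* Target regions EXCLUDE the primers: reads are primer-trimmed before
  alignment, so the panel holds only the species-informative interior.
* Panel FASTA headers are ``species|pair|source_id|start-end`` with the same
  coordinate convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .primers import (
    PrimerPair,
    iupac_hamming,
    reverse_complement,
    validate_dna,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PrimerMatch",
    "AmpliconRegion",
    "ReferencePanel",
    "NoAmpliconError",
    "find_primer_sites",
    "in_silico_pcr",
    "build_panel",
    "discriminability_report",
    "read_species_fasta",
]


class NoAmpliconError(ValueError):
    """No compatible forward/reverse site pair on a reference."""


@dataclass(frozen=True)
class PrimerMatch:
    """One primer binding site on the top strand of a reference."""

    primer_name: str
    orientation: str  # "forward" | "reverse"
    start: int  # 0-based
    end: int  # half-open
    mismatches: int


@dataclass(frozen=True)
class AmpliconRegion:
    """The target region between (excluding) the two primers for one
    (species, primer pair) — the unit reads are assigned to."""

    species: str
    primer_pair: str
    target_seq: str
    source_id: str
    target_start: int
    target_end: int
    full_len: int  # amplicon length including both primers
    mismatches_fwd: int = 0
    mismatches_rev: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.target_seq) != self.target_end - self.target_start:
            raise ValueError("target_seq length inconsistent with coordinates")

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.primer_pair)


@dataclass
class ReferencePanel:
    """Collection of amplicon regions keyed by (species, primer pair)."""

    regions: dict[tuple[str, str], AmpliconRegion] = field(default_factory=dict)

    def add(self, region: AmpliconRegion, *, allow_duplicate: bool = False) -> None:
        if region.key in self.regions and not allow_duplicate:
            raise ValueError(f"duplicate panel entry for {region.key}")
        self.regions.setdefault(region.key, region)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[AmpliconRegion]:
        return iter(self.regions.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.regions

    def __getitem__(self, key: tuple[str, str]) -> AmpliconRegion:
        return self.regions[key]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp, _ in self.regions:
            seen.setdefault(sp)
        return list(seen)

    @property
    def pairs(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pr in self.regions:
            seen.setdefault(pr)
        return list(seen)

    def regions_for_pair(self, pair_name: str) -> list[AmpliconRegion]:
        return [r for r in self if r.primer_pair == pair_name]

    # ---- serialization -------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        """Serialize as FASTA with ``species|pair|source_id|start-end`` headers."""
        with open(path, "w") as fh:
            for r in self:
                fh.write(
                    f">{r.species}|{r.primer_pair}|{r.source_id}|"
                    f"{r.target_start}-{r.target_end} full_len={r.full_len} "
                    f"mm_fwd={r.mismatches_fwd} mm_rev={r.mismatches_rev}\n"
                )
                fh.write(r.target_seq + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferencePanel":
        from Bio import SeqIO

        panel = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.id.split("|")
            if len(fields) != 4:
                raise ValueError(f"panel FASTA header not species|pair|source|start-end: {rec.id}")
            species, pair, source_id, span = fields
            start, end = (int(x) for x in span.split("-"))
            meta = dict(
                kv.split("=") for kv in rec.description.split()[1:] if "=" in kv
            )
            panel.add(
                AmpliconRegion(
                    species=species,
                    primer_pair=pair,
                    target_seq=str(rec.seq).upper(),
                    source_id=source_id,
                    target_start=start,
                    target_end=end,
                    full_len=int(meta.get("full_len", end - start)),
                    mismatches_fwd=int(meta.get("mm_fwd", 0)),
                    mismatches_rev=int(meta.get("mm_rev", 0)),
                )
            )
        return panel

    def manifest(self):
        """Panel manifest as a pandas DataFrame (one row per region)."""
        import pandas as pd

        rows = [
            dict(
                species=r.species,
                pair=r.primer_pair,
                source_id=r.source_id,
                start=r.target_start,
                end=r.target_end,
                full_len=r.full_len,
                mismatches_fwd=r.mismatches_fwd,
                mismatches_rev=r.mismatches_rev,
            )
            for r in self
        ]
        return pd.DataFrame(rows)


def find_primer_sites(
    reference: str,
    primer: str,
    orientation: str = "forward",
    max_mismatch: int = 0,
    primer_name: str = "primer",
) -> list[PrimerMatch]:
    """Scan every window of *reference* for the primer binding site.

    For ``orientation="reverse"`` the primer (given as synthesized) is
    reverse-complemented before scanning, so reported coordinates always
    refer to the top strand.  Matches are IUPAC-aware: an ambiguity code in
    either sequence matches any compatible base at zero cost.  Returned
    sorted by (mismatches, start).
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward|reverse, got {orientation!r}")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    reference = validate_dna(reference, name="reference")
    probe = primer if orientation == "forward" else reverse_complement(primer)
    probe = validate_dna(probe, name=primer_name)
    k = len(probe)
    if len(reference) < k:
        return []
    hits: list[PrimerMatch] = []
    for start in range(len(reference) - k + 1):
        mm = _window_mismatches(reference, start, probe, max_mismatch)
        if mm <= max_mismatch:
            hits.append(PrimerMatch(primer_name, orientation, start, start + k, mm))
    hits.sort(key=lambda m: (m.mismatches, m.start))
    return hits


def _window_mismatches(reference: str, start: int, probe: str, cap: int) -> int:
    # early-exit Hamming scan; IUPAC-aware through the shared set table
    from .primers import IUPAC_SETS

    mm = 0
    for i, ch in enumerate(probe):
        if IUPAC_SETS[reference[start + i]].isdisjoint(IUPAC_SETS[ch]):
            mm += 1
            if mm > cap:
                return mm
    return mm


def in_silico_pcr(
    reference: str,
    pair: PrimerPair,
    max_mismatch: int = 3,
    max_product: int = 2000,
    species: str = "",
    source_id: str = "",
) -> AmpliconRegion:
    """Predict the PCR product of *pair* on *reference*.

    Both the stored strand and its reverse complement are scanned, so the
    amplicon is found regardless of reference orientation.  Among all
    (forward site, downstream reverse site) combinations producing a product
    of at most *max_product* bp, the one with the fewest total primer
    mismatches is returned, ties broken by shortest product.  The returned
    region excludes the primers from ``target_seq``; ``full_len`` is the
    complete product length.
    """
    if max_product <= pair.primer_len_sum:
        raise ValueError("max_product must exceed the summed primer lengths")
    reference = validate_dna(reference, name="reference")

    best: tuple[int, int, AmpliconRegion] | None = None
    for strand, seq in (("+", reference), ("-", reverse_complement(reference))):
        fwd_sites = find_primer_sites(seq, pair.forward, "forward", max_mismatch, pair.name)
        rev_sites = find_primer_sites(seq, pair.reverse, "reverse", max_mismatch, pair.name)
        for f in fwd_sites:
            for r in rev_sites:
                if r.start < f.end:
                    continue
                product_len = r.end - f.start
                if product_len > max_product:
                    continue
                total_mm = f.mismatches + r.mismatches
                if best is None or (total_mm, product_len) < (best[0], best[1]):
                    target = seq[f.end : r.start]
                    region = AmpliconRegion(
                        species=species,
                        primer_pair=pair.name,
                        target_seq=target,
                        source_id=source_id,
                        target_start=f.end,
                        target_end=r.start,
                        full_len=product_len,
                        mismatches_fwd=f.mismatches,
                        mismatches_rev=r.mismatches,
                        provenance=f"in_silico_pcr strand={strand}",
                    )
                    best = (total_mm, product_len, region)
    if best is None:
        raise NoAmpliconError(
            f"no amplicon for primer pair {pair.name} on reference "
            f"{source_id or '<unnamed>'} at max_mismatch={max_mismatch}"
        )
    return best[2]


def read_species_fasta(
    path: str | Path, species_map: Mapping[str, str] | None = None
) -> dict[str, tuple[str, str]]:
    """Read a multi-FASTA of references, returning species -> (source_id, seq).

    The species label comes from a ``species=<label>`` key in the record
    description, or from *species_map* (record id -> species), e.g. loaded
    from a sidecar TSV.
    """
    from Bio import SeqIO

    out: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        species = None
        for token in rec.description.split():
            if token.startswith("species="):
                species = token.split("=", 1)[1]
        if species is None and species_map is not None:
            species = species_map.get(rec.id)
        if species is None:
            raise ValueError(
                f"record {rec.id}: no species label (need 'species=' in the "
                "description or a sidecar id->species map)"
            )
        if species in out:
            raise ValueError(f"duplicate reference for species {species!r}")
        out[species] = (rec.id, str(rec.seq).upper())
    return out


def build_panel(
    references: Mapping[str, tuple[str, str]],
    pairs: Sequence[PrimerPair] | None = None,
    max_mismatch: int = 3,
    max_product: int = 2000,
) -> ReferencePanel:
    """Run in-silico PCR for every (species, primer pair) and assemble the panel.

    *references* maps species -> (source_id, sequence), as produced by
    :func:`read_species_fasta`.  Missing (species, pair) combinations are
    logged as warnings, not fatal — mirroring real panels where some primer
    pairs fail on some taxa.
    """
    from .primers import DEFAULT_PRIMER_PAIRS

    if pairs is None:
        pairs = DEFAULT_PRIMER_PAIRS
    names = [p.name for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError("primer pair names must be unique within a panel")
    panel = ReferencePanel()
    missing: list[tuple[str, str]] = []
    for species, (source_id, seq) in references.items():
        for pair in pairs:
            try:
                region = in_silico_pcr(
                    seq, pair, max_mismatch, max_product, species=species, source_id=source_id
                )
            except NoAmpliconError:
                missing.append((species, pair.name))
                continue
            panel.add(region)
    if missing:
        logger.warning(
            "no amplicon for %d (species, pair) combinations: %s",
            len(missing),
            ", ".join(f"{s}/{p}" for s, p in missing),
        )
    if not panel.regions:
        raise NoAmpliconError("no amplicons found for any (species, pair)")
    return panel


def discriminability_report(panel: ReferencePanel, pair_name: str):
    """Pairwise p-distances between species targets for one primer pair.

    Distances are computed from glocal pairwise alignment (mismatches plus
    gap columns, including the unaligned reference overhang, over the total
    alignment columns), symmetrized by averaging the two alignment
    directions.  Returns ``(DataFrame, min_distance)``.  This stands in for
    a phylogenetic-tree readout: the minimum inter-species distance is the
    margin available for unambiguous read assignment.
    """
    import pandas as pd

    regions = panel.regions_for_pair(pair_name)
    if len(regions) < 2:
        raise ValueError(f"discriminability needs >=2 species for pair {pair_name!r}")
    species = [r.species for r in regions]
    n = len(regions)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_p_distance(regions[i].target_seq, regions[j].target_seq)
            mat[i, j] = mat[j, i] = d
    df = pd.DataFrame(mat, index=species, columns=species)
    min_dist = float(mat[np.triu_indices(n, k=1)].min())
    return df, min_dist


def pairwise_p_distance(a: str, b: str) -> float:
    """Symmetric p-distance between two sequences via glocal alignment.

    Each direction aligns one sequence end-to-end against the other; the
    distance counts mismatches + gap columns + uncovered reference overhang
    over total columns.  The two directions are averaged.
    """
    return 0.5 * (_directed_p_distance(a, b) + _directed_p_distance(b, a))


def _directed_p_distance(query: str, ref: str) -> float:
    from .align import AlignmentScoring, glocal_align

    res = glocal_align(query, ref, AlignmentScoring())
    n_match = len(query) - res.n_mismatch - res.n_ins
    overhang = len(ref) - res.aligned_ref_bases
    cols = n_match + res.n_mismatch + res.n_ins + res.n_del + overhang
    return (res.n_mismatch + res.n_ins + res.n_del + overhang) / cols
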