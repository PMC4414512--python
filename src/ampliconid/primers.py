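"""Universal PCR primer pairs and IUPAC-aware sequence utilities.

The identification strategy rests on "universal" primer pairs whose binding
sites are conserved across many vertebrate species while the region between
them carries species-specific differences.  Three such pairs targeting the
mitochondrial 12S and 16S rRNA genes are bundled as :data:`DEFAULT_PRIMER_PAIRS`:
``12S_KH`` and ``16S_KH`` (designed from mammalian 12S/16S alignments) and
``16S_Ki`` (a second 16S pair also validated in birds, reptiles and fishes).

Primers are stored 5'→3' as synthesized, i.e. the reverse primer is the
reverse complement of the template top strand at its annealing site.  IUPAC
ambiguity codes in a primer match any compatible template base and never
count as a mismatch (standard degenerate-primer semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "IUPAC_SETS",
    "PrimerPair",
    "DEFAULT_PRIMER_PAIRS",
    "reverse_complement",
    "iupac_match",
    "iupac_hamming",
    "validate_dna",
    "load_primer_tsv",
    "write_primer_tsv",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of *seq*; IUPAC codes map to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, name: str = "sequence") -> str:
    """Upper-case *seq* and reject characters outside the IUPAC alphabet.

    Raises ``ValueError`` naming the first offending position.
    """
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise ValueError(f"{name}: non-DNA character {ch!r} at position {i}")
    return up


def iupac_match(a: str, b: str) -> bool:
    """True when codes *a* and *b* are compatible (their base sets intersect)."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def iupac_hamming(a: str, b: str) -> int:
    """Position-wise count of incompatible codes between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("iupac_hamming requires equal-length sequences")
    return sum(1 for x, y in zip(a, b) if IUPAC_SETS[x].isdisjoint(IUPAC_SETS[y]))


@dataclass(frozen=True)
class PrimerPair:
    """A named universal primer pair.

    Parameters
    ----------
    name:
        Short identifier, unique within a primer set (e.g. ``12S_KH``).
    forward, reverse:
        Primer sequences 5'→3' as synthesized.  The reverse primer anneals to
        the top strand, i.e. it equals the reverse complement of the top-strand
        segment it covers.
    annealing_temp:
        Annealing temperature in °C (metadata only; no thermodynamic model).
    expected_len_range:
        Inclusive ``(min, max)`` of the full amplicon length in bp, primers
        included.
    """

    name: str
    forward: str
    reverse: str
    annealing_temp: float = 60.0
    expected_len_range: tuple[int, int] = (0, 10_000)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("primer pair needs a non-empty name")
        object.__setattr__(self, "forward", validate_dna(self.forward, name=f"{self.name} forward"))
        object.__setattr__(self, "reverse", validate_dna(self.reverse, name=f"{self.name} reverse"))
        if not self.forward or not self.reverse:
            raise ValueError(f"{self.name}: primer sequences must be non-empty")
        lo, hi = self.expected_len_range
        if lo > hi:
            raise ValueError(f"{self.name}: expected_len_range min > max")

    @property
    def primer_len_sum(self) -> int:
        return len(self.forward) + len(self.reverse)


#: The three bundled universal mtDNA primer pairs with their annealing
#: temperatures and the product-size ranges observed across the 13 study
#: species (pig, horse, cattle, sheep, rabbit, human, rat and six birds).
DEFAULT_PRIMER_PAIRS: tuple[PrimerPair, ...] = (
    PrimerPair(
        name="12S_KH",
        forward="CCCAAACTGGGATTAGATACCC",
        reverse="GTTTGCTGAAGATGGCGGTA",
        annealing_temp=59.0,
        expected_len_range=(215, 222),
    ),
    PrimerPair(
        name="16S_KH",
        forward="GACGAGAAGACCCTATGGAGC",
        reverse="TCCGAGGTCGCCCCAACC",
        annealing_temp=59.0,
        expected_len_range=(112, 121),
    ),
    PrimerPair(
        name="16S_Ki",
        forward="GCCTGTTTACCAAAAACATCAC",
        reverse="CTCCATAGGGTCTTCTCGTCTT",
        annealing_temp=62.0,
        expected_len_range=(243, 249),
    ),
)


def primer_pair_by_name(name: str, pairs: Iterable[PrimerPair] = DEFAULT_PRIMER_PAIRS) -> PrimerPair:
    for p in pairs:
        if p.name == name:
            return p
    raise KeyError(f"no primer pair named {name!r}")


def load_primer_tsv(path: str | Path) -> list[PrimerPair]:
    """Load primer pairs from a TSV with columns
    ``name forward reverse annealing_temp min_len max_len`` (header optional)."""
    pairs: list[PrimerPair] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() == "name":
            continue
        name, fwd, rev = parts[:3]
        temp = float(parts[3]) if len(parts) > 3 else 60.0
        rng = (int(parts[4]), int(parts[5])) if len(parts) > 5 else (0, 10_000)
        pairs.append(PrimerPair(name, fwd, rev, temp, rng))
    if not pairs:
        raise ValueError(f"{path}: no primer pairs found")
    names = [p.name for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate primer pair names")
    return pairs


def write_primer_tsv(pairs: Iterable[PrimerPair], path: str | Path) -> None:
    lines = ["name\tforward\treverse\tannealing_temp\tmin_len\tmax_len"]
    for p in pairs:
        lo, hi = p.expected_len_range
        lines.append(f"{p.name}\t{p.forward}\t{p.reverse}\t{p.annealing_temp:g}\t{lo}\t{hi}")
    Path(path).write_text("\n".join(lines) + "\n")
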