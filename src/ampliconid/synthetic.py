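"""Synthetic mitochondrial reference sequences for the 13 study species.

Real panels are built from curated mtDNA references; this module generates
stand-in references so every pipeline stage can be exercised end-to-end
without downloads.  For each primer pair an ancestral target sequence is
drawn, and each species receives its own copy diverged by substitutions
(default 15% per site) and a few deletions so that full amplicon lengths
spread across the per-pair product-size ranges, mimicking the length
variation seen across real vertebrate mitochondrial genomes.  A
deterministic repair step enforces a minimum pairwise edit distance between
species targets so that species assignment is well-posed for any seed.

The default species set mirrors a meat-authentication study design: seven
mammals (pig, horse, cattle, sheep, rabbit, human, rat) and six birds
(chicken, turkey, pheasant, duck, goose, pigeon).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .primers import DEFAULT_PRIMER_PAIRS, PrimerPair, reverse_complement

__all__ = [
    "MAMMAL_SPECIES",
    "AVIAN_SPECIES",
    "ALL_SPECIES",
    "SPECIES_CLASS",
    "synthetic_references",
    "write_reference_fasta",
]

MAMMAL_SPECIES: tuple[str, ...] = ("pig", "horse", "cattle", "sheep", "rabbit", "human", "rat")
AVIAN_SPECIES: tuple[str, ...] = ("chicken", "turkey", "pheasant", "duck", "goose", "pigeon")
ALL_SPECIES: tuple[str, ...] = MAMMAL_SPECIES + AVIAN_SPECIES

#: species -> "mammal" | "avian" for grouped summaries
SPECIES_CLASS: dict[str, str] = {
    **{s: "mammal" for s in MAMMAL_SPECIES},
    **{s: "avian" for s in AVIAN_SPECIES},
}

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _delete(rng: np.random.Generator, seq: str, k: int) -> str:
    if k <= 0:
        return seq
    keep = np.ones(len(seq), dtype=bool)
    keep[rng.choice(len(seq), size=k, replace=False)] = False
    return "".join(np.array(list(seq))[keep])


def _edit_distance(a: str, b: str) -> int:
    """Full-length edit distance proxy via glocal alignment + ref overhang."""
    from .align import glocal_align

    res = glocal_align(a, b)
    return res.nm + (len(b) - res.aligned_ref_bases)


def synthetic_references(
    species: Sequence[str] = ALL_SPECIES,
    pairs: Sequence[PrimerPair] = DEFAULT_PRIMER_PAIRS,
    seed: int = 0,
    divergence: float = 0.15,
    min_target_distance: int = 8,
    flank: int = 60,
    spacer: int = 40,
) -> dict[str, tuple[str, str]]:
    """Generate one synthetic mitochondrial reference per species.

    Each reference carries exact binding sites for every primer pair with a
    species-specific target between them; roughly half the references are
    stored reverse-complemented to exercise strand handling.  Returns
    species -> (source_id, sequence), ready for
    :func:`ampliconid.refpanel.build_panel`.
    """
    if not (0 < divergence < 1):
        raise ValueError("divergence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    # ancestral target per pair, sized to the top of the product range
    ancestral: dict[str, str] = {}
    for pair in pairs:
        lo, hi = pair.expected_len_range
        tlen = hi - pair.primer_len_sum
        if tlen <= 0:
            raise ValueError(f"{pair.name}: product range smaller than the primers")
        ancestral[pair.name] = _random_seq(rng, tlen)

    # species targets: deletions spread lengths over the range, then diverge
    targets: dict[tuple[str, str], str] = {}
    for sp in species:
        for pair in pairs:
            lo, hi = pair.expected_len_range
            span = hi - lo
            k = int(rng.integers(0, span + 1)) if span > 0 else 0
            t = _delete(rng, ancestral[pair.name], k)
            targets[(sp, pair.name)] = _mutate(rng, t, divergence)

    # repair: guarantee a minimum pairwise edit distance within each pair
    for pair in pairs:
        sps = list(species)
        for i in range(len(sps)):
            for j in range(i + 1, len(sps)):
                a_key, b_key = (sps[i], pair.name), (sps[j], pair.name)
                guard = 0
                while _edit_distance(targets[a_key], targets[b_key]) < min_target_distance:
                    targets[b_key] = _mutate_one(rng, targets[b_key])
                    guard += 1
                    if guard > 200:  # pragma: no cover - defensive
                        raise RuntimeError("target repair failed to converge")

    refs: dict[str, tuple[str, str]] = {}
    for sp in species:
        parts = [_random_seq(rng, flank)]
        for pair in pairs:
            parts.append(pair.forward)
            parts.append(targets[(sp, pair.name)])
            parts.append(reverse_complement(pair.reverse))
            parts.append(_random_seq(rng, spacer))
        parts.append(_random_seq(rng, max(0, flank - spacer)))
        seq = "".join(parts)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        refs[sp] = (f"synthetic_{sp}", seq)
    return refs


def _mutate_one(rng: np.random.Generator, seq: str) -> str:
    i = int(rng.integers(0, len(seq)))
    choices = [b for b in "ACGT" if b != seq[i]]
    return seq[:i] + choices[int(rng.integers(0, 3))] + seq[i + 1 :]


def write_reference_fasta(
    refs: Mapping[str, tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    """Write references as multi-FASTA with ``species=`` description keys."""
    with open(path, "w") as fh:
        for sp, (source_id, seq) in refs.items():
            fh.write(f">{source_id} species={sp}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
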