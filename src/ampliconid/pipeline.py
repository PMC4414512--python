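"""End-to-end orchestration: panel -> simulate -> preprocess -> align -> quantify.

A :class:`RunConfig` holds every path, threshold and the seed; identical
configs and seeds give identical outputs.  Every intermediate is persisted
under the output directory and a machine-readable manifest records the
thresholds, the seed and per-stage read conservation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .align import AlignmentScoring, PanelIndex, filter_alignments, map_reads, write_sam
from .preprocess import (
    length_filter,
    quality_stats,
    read_fastq,
    trim_primers,
    write_fastq,
)
from .primers import DEFAULT_PRIMER_PAIRS, PrimerPair
from .quantify import call_species, count_by_region, estimate_error_rates
from .refpanel import ReferencePanel, build_panel, read_species_fasta
from .simulate import (
    EfficiencyModel,
    ErrorModel,
    PoolSpec,
    builtin_pool,
    simulate_library,
    write_fastq as write_sim_fastq,
    write_truth_tsv,
)
from .synthetic import ALL_SPECIES, synthetic_references

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the ledger so far."""

    def __init__(self, stage: str, cause: Exception, ledger: Mapping[str, Any]):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.ledger = dict(ledger)


@dataclass
class RunConfig:
    """Full run configuration; every threshold is echoed into the manifest."""

    out_dir: str = "ampliconid_run"
    seed: int = 0
    # panel
    refs_fasta: str | None = None  # None -> synthetic references
    species: Sequence[str] | None = None  # synthetic species set (default: all 13)
    panel_max_mismatch: int = 3
    # simulation
    pool: str | Mapping = "c1"  # builtin code or PoolSpec mapping
    n_reads: int = 10_000
    sub_rate: float = 0.002
    hp_slope: float = 0.01
    hp_max: float = 0.2
    efficiency_zero: Sequence[Mapping] = field(default_factory=list)
    reads_fastq: str | None = None  # pre-existing reads skip the simulator
    # preprocess
    trim_max_mismatch: int = 2
    min_len: int = 40
    # align
    min_mapq: int = 20
    # quantify
    min_reads: int = 2
    min_pairs: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _build_pool(spec: str | Mapping) -> PoolSpec:
    if isinstance(spec, str):
        return builtin_pool(spec)
    return PoolSpec.from_dict(spec)


def run_pipeline(config: RunConfig, pairs: Sequence[PrimerPair] = DEFAULT_PRIMER_PAIRS) -> dict:
    """Execute all stages; returns the result bundle and writes everything
    under ``config.out_dir``."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ledger: dict[str, Any] = {"version": __version__, "config": _jsonable(asdict(config))}
    bundle: dict[str, Any] = {}

    # --- panel ----------------------------------------------------------
    stage = "build_panel"
    try:
        if config.refs_fasta:
            refs = read_species_fasta(config.refs_fasta)
        else:
            refs = synthetic_references(
                species=tuple(config.species) if config.species else ALL_SPECIES,
                pairs=pairs,
                seed=config.seed,
            )
        panel = build_panel(refs, pairs, max_mismatch=config.panel_max_mismatch)
        panel.to_fasta(out / "panel.fa")
        panel.manifest().to_csv(out / "panel_manifest.tsv", sep="\t", index=False)
        ledger[stage] = {"n_regions": len(panel), "n_species": len(panel.species)}
        bundle["panel"] = panel
    except Exception as exc:
        raise StageError(stage, exc, ledger) from exc

    # --- simulate / load reads -----------------------------------------
    stage = "simulate"
    try:
        pool = _build_pool(config.pool)
        eff = EfficiencyModel.uniform()
        for entry in config.efficiency_zero:
            eff = eff.with_zero(entry["species"], entry["pair"])
        if config.reads_fastq:
            raw_reads = read_fastq(config.reads_fastq)
            sim_reads = None
        else:
            err = ErrorModel(
                sub_rate=config.sub_rate, hp_slope=config.hp_slope, hp_max=config.hp_max
            )
            sim_reads = simulate_library(
                pool, panel, eff, err, n_reads=config.n_reads, seed=config.seed, pairs=pairs
            )
            write_sim_fastq(sim_reads, out / "reads.fq")
            write_truth_tsv(sim_reads, out / "truth.tsv")
            raw_reads = read_fastq(out / "reads.fq")
        ledger[stage] = {"n_reads": len(raw_reads), "pool": pool.name}
        bundle["pool"] = pool
        bundle["truth"] = sim_reads
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc, ledger) from exc

    # --- preprocess -----------------------------------------------------
    stage = "preprocess"
    try:
        qc = quality_stats(raw_reads)
        trimmed = [trim_primers(r, pairs, config.trim_max_mismatch) for r in raw_reads]
        kept, n_short = length_filter(trimmed, config.min_len)
        write_fastq(kept, out / "trimmed.fq")
        (out / "qc.json").write_text(json.dumps(qc.to_dict(), indent=2) + "\n")
        ledger[stage] = {
            "n_in": len(raw_reads),
            "n_out": len(kept),
            "n_short": n_short,
            "q20_pct": qc.q20_pct,
        }
        assert len(kept) + n_short == len(raw_reads)
        bundle["qc"] = qc
    except Exception as exc:
        raise StageError(stage, exc, ledger) from exc

    # --- align ----------------------------------------------------------
    stage = "align"
    try:
        scoring = AlignmentScoring(min_mapq=config.min_mapq, min_len=config.min_len)
        index = PanelIndex(panel)
        results = map_reads(((r.read_id, r.sequence, r.qualities) for r in kept), index, scoring)
        retained, tally = filter_alignments(results, scoring)
        write_sam(results, panel, out / "raw.sam")
        write_sam(retained, panel, out / "filtered.sam")
        _write_assignments(retained, out / "assignments.tsv")
        conserved = len(retained) + sum(tally.values()) == len(results)
        ledger[stage] = {
            "n_in": len(results),
            "n_retained": len(retained),
            "rejections": tally,
            "conserved": conserved,
        }
        if not conserved:
            raise RuntimeError("read conservation violated in alignment filtering")
        bundle["alignments"] = retained
        bundle["rejections"] = tally
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc, ledger) from exc

    # --- quantify -------------------------------------------------------
    stage = "quantify"
    try:
        unassigned = len(results) - len(retained)
        table = count_by_region(retained, library_id=pool.name, unassigned=unassigned)
        table.to_frame().to_csv(out / "counts.tsv", sep="\t")
        errors = estimate_error_rates(retained)
        errors.to_frame().to_csv(out / "error_rates.tsv", sep="\t", index=False)
        calls = call_species(
            table, config.min_reads, config.min_pairs, species=panel.species
        )
        with open(out / "detection.tsv", "w") as fh:
            fh.write("species\tdetected\tsupporting_pairs\tmin_reads\tmin_pairs\n")
            for c in calls:
                supp = ",".join(f"{p}:{n}" for p, n in sorted(c.supporting.items()))
                fh.write(
                    f"{c.species}\t{int(c.detected)}\t{supp}\t{c.min_reads}\t{c.min_pairs}\n"
                )
        ledger[stage] = {
            "total_counted": table.total,
            "unassigned": table.unassigned,
            "detected": [c.species for c in calls if c.detected],
        }
        bundle["counts"] = table
        bundle["error_rates"] = errors
        bundle["detection"] = calls
    except Exception as exc:
        raise StageError(stage, exc, ledger) from exc

    ledger["conservation"] = {
        "input_reads": len(raw_reads),
        "post_trim": len(kept),
        "counted_plus_unassigned": table.total + table.unassigned,
        "reconciles": table.total + table.unassigned == len(kept),
    }
    (out / "manifest.json").write_text(json.dumps(ledger, indent=2) + "\n")
    bundle["manifest"] = ledger
    return bundle


def _write_assignments(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tspecies\tpair\tstrand\tmapq\tNM\n")
        for r in results:
            fh.write(f"{r.read_id}\t{r.species}\t{r.pair}\t{r.strand}\t{r.mapq}\t{r.nm}\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
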