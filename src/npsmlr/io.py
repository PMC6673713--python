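"""Readers and writers for the pipeline's file formats.

Event-alignment tables use the ``nanopolish eventalign`` TSV dialect
(columns ``contig``, ``position``, ``reference_kmer``, ``read_name``,
``event_level_mean``; extra columns are ignored).  Interval outputs are
0-based half-open BED/bedGraph; tabular outputs are tab-separated with
a header line and ``.`` for missing values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from npsmlr.accessibility import AccessibleRegion, PromoterCall
from npsmlr.decoder import MoleculeScores, Nucleosome, NucleosomePath
from npsmlr.signal_models import EventObservation, KmerModel, MethylationCall

logger = logging.getLogger("npsmlr")

__all__ = [
    "GeneRecord",
    "RunConfig",
    "read_eventalign",
    "read_annotation",
    "read_model_table",
    "write_model_table",
    "read_scores",
    "write_scores",
    "scores_to_molecules",
    "write_nucleosome_bed",
    "read_nucleosome_bed",
    "write_bedgraph",
    "write_regions_bed",
    "write_layout_bed",
    "write_manifest",
    "load_config",
]

EVENTALIGN_COLUMNS = ["contig", "position", "reference_kmer", "read_name", "event_level_mean"]

MISSING = "."


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str


@dataclass
class RunConfig:
    """Pipeline thresholds and seeds (YAML-loadable).

    Defaults mirror the published rules: score cutoff 0.5, region/peak
    length >= 100 bp, adjacent-site distance < 100 bp, peak factor
    1.5 x mean ratio, promoter window -500/+100 around the TSS.
    """

    score_cutoff: float = 0.5
    min_region_len: int = 100
    max_pair_distance: int = 100
    peak_factor: float = 1.5
    promoter_upstream: int = 500
    promoter_downstream: int = 100
    min_site_coverage: int = 5
    min_pos_events: int = 20
    max_events_per_kmer: int = 10
    sigma_eps: float = 1e-3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "min_region_len",
            "max_pair_distance",
            "peak_factor",
            "promoter_upstream",
            "promoter_downstream",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path: Union[str, Path, None]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def read_eventalign(path: Union[str, Path]) -> Iterator[EventObservation]:
    """Stream events from a ``nanopolish eventalign``-dialect TSV.

    Rows with an unparseable position or event level are skipped with a
    warning; a missing required column is fatal.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in EVENTALIGN_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"event-alignment table is missing columns: {missing}")
        idx = {c: header.index(c) for c in header}
        n_skipped = 0
        for line_no, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            try:
                kmer = fields[idx["reference_kmer"]]
                obs = EventObservation(
                    read_id=fields[idx["read_name"]],
                    reference_position=int(fields[idx["position"]]),
                    kmer=kmer,
                    event_level=float(fields[idx["event_level_mean"]]),
                    strand=fields[idx["strand"]] if "strand" in idx else "+",
                    chrom=fields[idx["contig"]],
                )
            except (ValueError, IndexError) as err:
                n_skipped += 1
                logger.warning("skipping malformed event row %d: %s", line_no, err)
                continue
            yield obs
        if n_skipped:
            logger.warning("skipped %d malformed event rows in %s", n_skipped, path)


def read_annotation(path: Union[str, Path]) -> list[GeneRecord]:
    """Gene records from a BED-like annotation (chrom, start, end, gene_id, score, strand).

    The TSS is ``start`` for ``+`` genes and ``end - 1`` for ``-``
    genes (0-based).  Unknown strand symbols and duplicate gene ids are
    fatal.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"annotation rows need 6 BED columns, got {len(fields)}")
            chrom, start, end, gene_id, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand symbol {strand!r} for gene {gene_id}")
            if gene_id in seen:
                raise ValueError(f"duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            tss = int(start) if strand == "+" else int(end) - 1
            genes.append(GeneRecord(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
    return genes


MODEL_COLUMNS = [
    "kmer", "mu0", "sigma0", "rho", "mu1", "sigma1", "mu2", "sigma2",
    "discrimination", "n_neg", "n_pos",
]


def write_model_table(models: dict[str, KmerModel], path: Union[str, Path]) -> None:
    rows = [
        {c: getattr(m, c) for c in MODEL_COLUMNS}
        for m in (models[k] for k in sorted(models))
    ]
    pd.DataFrame(rows, columns=MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_model_table(path: Union[str, Path]) -> dict[str, KmerModel]:
    df = pd.read_csv(path, sep="\t")
    models = {}
    for row in df.itertuples(index=False):
        m = KmerModel(
            kmer=row.kmer, mu0=row.mu0, sigma0=row.sigma0, rho=row.rho,
            mu1=row.mu1, sigma1=row.sigma1, mu2=row.mu2, sigma2=row.sigma2,
            discrimination=row.discrimination, n_neg=int(row.n_neg), n_pos=int(row.n_pos),
        )
        models[m.kmer] = m
    return models


SCORE_COLUMNS = ["read_id", "chrom", "position", "strand", "score", "chosen_kmer", "n_events"]


def write_scores(calls: Iterable[MethylationCall], path: Union[str, Path]) -> None:
    rows = [
        {
            "read_id": c.read_id,
            "chrom": c.chrom,
            "position": c.site_position,
            "strand": c.strand,
            "score": MISSING if c.score is None else f"{c.score:.6g}",
            "chosen_kmer": c.chosen_kmer,
            "n_events": c.n_events_used,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scores(path: Union[str, Path]) -> list[MethylationCall]:
    df = pd.read_csv(path, sep="\t", dtype={"score": str})
    calls = []
    for row in df.itertuples(index=False):
        score = None if row.score == MISSING else float(row.score)
        calls.append(
            MethylationCall(
                read_id=str(row.read_id),
                site_position=int(row.position),
                score=score,
                chosen_kmer=str(row.chosen_kmer),
                n_events_used=int(row.n_events),
                strand=str(row.strand),
                chrom=str(row.chrom),
            )
        )
    return calls


def scores_to_molecules(
    calls: Sequence[MethylationCall],
    spans: Optional[dict[str, tuple[int, int]]] = None,
) -> list[MoleculeScores]:
    """Group per-site calls into :class:`MoleculeScores`, one per read.

    FILTERED calls are dropped (they are invisible downstream).  The
    aligned span defaults to the hull of the read's called sites plus
    one base; ``spans`` overrides per read id.
    """
    by_read: dict[tuple[str, str, str], list[MethylationCall]] = {}
    for c in calls:
        if c.score is None:
            continue
        by_read.setdefault((c.read_id, c.chrom, c.strand), []).append(c)
    molecules = []
    for (read_id, chrom, strand), group in sorted(by_read.items()):
        group.sort(key=lambda c: c.site_position)
        pos = np.asarray([c.site_position for c in group])
        if spans and read_id in spans:
            start, end = spans[read_id]
        else:
            start, end = int(pos[0]), int(pos[-1]) + 1
        molecules.append(
            MoleculeScores(
                read_id=read_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                positions=pos,
                scores=np.asarray([c.score for c in group]),
            )
        )
    return molecules


def write_nucleosome_bed(paths: Iterable[NucleosomePath], out: Union[str, Path]) -> None:
    """Nucleosome calls as BED6+1 (name=read id, score=log-likelihood, +trunc flags)."""
    with open(out, "w") as fh:
        for path in paths:
            for nuc in path.nucleosomes:
                flags = ("T" if nuc.truncated_start else MISSING) + (
                    "T" if nuc.truncated_end else MISSING
                )
                fh.write(
                    f"{path.chrom}\t{nuc.start}\t{nuc.end}\t{path.read_id}\t"
                    f"{path.log_likelihood:.6g}\t{path.strand}\t{flags}\n"
                )


def read_nucleosome_bed(path: Union[str, Path]) -> list[NucleosomePath]:
    """Re-assemble per-read NucleosomePath objects from a nucleosome BED."""
    by_read: dict[tuple[str, str, str, float], list[Nucleosome]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, read_id, ll, strand, flags = line.rstrip("\n").split("\t")[:7]
            nuc = Nucleosome(
                int(start), int(end),
                truncated_start=flags[0] == "T",
                truncated_end=flags[1] == "T",
            )
            by_read.setdefault((read_id, chrom, strand, float(ll)), []).append(nuc)
    paths = []
    for (read_id, chrom, strand, ll), nucs in sorted(by_read.items()):
        nucs.sort(key=lambda n: n.start)
        start = min(n.start for n in nucs)
        end = max(n.end for n in nucs)
        paths.append(NucleosomePath(read_id, chrom, start, end, strand, nucs, ll))
    return paths


def write_bedgraph(
    chrom: str, start: int, values: np.ndarray, out: Union[str, Path]
) -> None:
    """Run-length-encoded bedGraph of a per-base track."""
    values = np.asarray(values)
    with open(out, "w") as fh:
        if values.size == 0:
            return
        run_start = 0
        for i in range(1, values.size + 1):
            if i == values.size or values[i] != values[run_start]:
                fh.write(
                    f"{chrom}\t{start + run_start}\t{start + i}\t{values[run_start]:.6g}\n"
                )
                run_start = i


def write_regions_bed(regions: Iterable[AccessibleRegion], out: Union[str, Path]) -> None:
    with open(out, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{r.score:.6g}\t{MISSING}\n")


def write_layout_bed(
    layout: Sequence[tuple[int, int]], out: Union[str, Path], chrom: str = "sim", name: str = "truth"
) -> None:
    with open(out, "w") as fh:
        for s, e in layout:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_promoter_calls(calls: Iterable[PromoterCall], out: Union[str, Path]) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "read_id": c.read_id,
            "promoter_start": c.promoter_start,
            "promoter_end": c.promoter_end,
            "score": f"{c.score:.6g}",
            "status": c.status,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "read_id", "promoter_start", "promoter_end", "score", "status"],
    ).to_csv(out, sep="\t", index=False)


def write_manifest(out_dir: Union[str, Path], command: str, params: dict, seed: int) -> Path:
    """Write a small JSON run manifest (version, config hash, seed)."""
    from npsmlr import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(params, sort_keys=True, default=str)
    manifest = {
        "tool": "npsmlr",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "params": params,
    }
    path = out_dir / f"{command}.manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
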