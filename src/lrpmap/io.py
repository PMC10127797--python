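"""Readers, writers, and run configuration.

Formats: bedGraph for binned coverage, BED6 for peaks/planted sites, GFF3 or
BED for TU/TSS annotation, TSV for matrices and posterior summaries (with
the conventional value / ci.lo / ci.hi / P_diff column names), and a JSON
run manifest recording the config hash and every seed used. Internal
coordinates are 0-based half-open everywhere; GFF3's 1-based inclusive
coordinates are converted at the boundary. Readers validate and reject
malformed records with the offending line number rather than coercing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .peakcall import PeakCall
from .regulation import TSSAnnotation, TranscriptionUnit
from .tracks import OccupancyTrack, SampleMeta


def read_bedgraph(
    path: str | Path,
    bin_size: int,
    meta: SampleMeta | None = None,
    replicon: str | None = None,
    allow_negative: bool = False,
) -> OccupancyTrack:
    """Read a bedGraph file into a binned track.

    Records must be sorted, non-overlapping, non-negative (unless
    ``allow_negative``, for signed score tracks), and on a single replicon;
    violations are rejected with the line number. Mixed-width records are
    re-binned to ``bin_size`` by length-weighted mean.
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(parts)}")
            chrom, s, e, v = parts
            try:
                s_i, e_i, v_f = int(s), int(e), float(v)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: unparseable record: {err}") from None
            if e_i <= s_i:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            if v_f < 0 and not allow_negative:
                raise ValueError(f"{path}:{lineno}: negative coverage {v_f}")
            if chroms and chrom != chroms[-1]:
                raise ValueError(f"{path}:{lineno}: multiple replicons ({chroms[-1]!r}, {chrom!r})")
            if replicon is not None and chrom != replicon:
                raise ValueError(f"{path}:{lineno}: unknown replicon {chrom!r} (expected {replicon!r})")
            if starts and s_i < ends[-1]:
                raise ValueError(f"{path}:{lineno}: overlapping or unsorted record")
            chroms.append(chrom)
            starts.append(s_i)
            ends.append(e_i)
            values.append(v_f)
    if not starts:
        raise ValueError(f"{path}: no bedGraph records")

    length = ends[-1]
    n_bins = -(-length // bin_size)
    acc = np.zeros(n_bins)
    cov = np.zeros(n_bins)
    for s_i, e_i, v_f in zip(starts, ends, values):
        b0, b1 = s_i // bin_size, -(-e_i // bin_size)
        for b in range(b0, b1):
            lo = max(s_i, b * bin_size)
            hi = min(e_i, (b + 1) * bin_size)
            acc[b] += v_f * (hi - lo)
            cov[b] += hi - lo
    with np.errstate(invalid="ignore"):
        binned = np.where(cov > 0, acc / np.maximum(cov, 1), 0.0)
    meta = meta or SampleMeta("WT", "Min", "Log")
    return OccupancyTrack(chroms[-1], bin_size, binned, meta, "raw")


def write_bedgraph(track: OccupancyTrack, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for i, v in enumerate(track.values):
            fh.write(
                f"{track.replicon}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.6g}\n"
            )


def read_annotation(
    path: str | Path,
) -> tuple[list[TSSAnnotation], list[TranscriptionUnit]]:
    """Read TU/TSS annotation from GFF3 (1-based, converted) or BED6.

    GFF3 feature lines typed ``transcription_start_site``/``TSS`` become
    explicit TSSs; every other feature line becomes a TU. When no explicit
    TSS features exist, TSSs are derived from the strand-appropriate TU
    ends. Malformed strands or coordinates are rejected with line numbers.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    tus: list[TranscriptionUnit] = []
    explicit_tss: list[TSSAnnotation] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if is_gff:
                if len(parts) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
                _, _, ftype, start, end, _, strand, _, attrs = parts
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: malformed strand {strand!r}")
                s0 = int(start) - 1          # GFF3 is 1-based inclusive
                e0 = int(end)
                ident = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                ).get("ID", f"feature{lineno}")
                if ftype.lower() in ("transcription_start_site", "tss"):
                    explicit_tss.append(TSSAnnotation(s0, strand, ident))
                else:
                    tus.append(TranscriptionUnit(ident, s0, e0, strand))
            else:
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(parts)}")
                _, start, end, name, _, strand = parts[:6]
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: malformed strand {strand!r}")
                tus.append(TranscriptionUnit(name, int(start), int(end), strand))
    if explicit_tss:
        tss = explicit_tss
    else:
        tss = [TSSAnnotation(tu.tss_position, tu.strand, tu.tu_id) for tu in tus]
    return tss, tus


def write_annotation_gff3(
    tus: Sequence[TranscriptionUnit],
    path: str | Path,
    replicon: str = "simrep",
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for tu in tus:
            fh.write(
                f"{replicon}\tlrpmap\ttranscript\t{tu.start + 1}\t{tu.end}\t.\t"
                f"{tu.strand}\t.\tID={tu.tu_id}\n"
            )


def write_peaks_bed(peaks: Sequence[PeakCall], path: str | Path) -> None:
    """Peaks as BED6: name = site id, score = occupancy, strand = '.'."""
    path = Path(path)
    with path.open("w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.replicon}\t{p.start}\t{p.end}\tpeak{i:05d}\t{p.score:.4f}\t.\n"
            )


def read_peaks_bed(path: str | Path) -> list[PeakCall]:
    path = Path(path)
    out: list[PeakCall] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, _, score, _ = parts[:6]
            s, e = int(start), int(end)
            out.append(PeakCall(chrom, s, e, s // 1, float(score)))
    return out


def config_hash(config) -> str:
    """Stable short hash of a (nested) dataclass or mapping configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    outdir: str | Path,
    config,
    seeds: Mapping[str, int],
    tables: Mapping[str, pd.DataFrame] | None = None,
    tracks: Mapping[str, OccupancyTrack] | None = None,
    peaks: Mapping[str, Sequence[PeakCall]] | None = None,
) -> dict:
    """Write all result artefacts plus a JSON run manifest.

    Tables go to TSV (posterior-summary tables keep the value / ci.lo /
    ci.hi / P_diff headers produced upstream), tracks to bedGraph, peak sets
    to BED6. The manifest records the config hash and every seed used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, df in (tables or {}).items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p.name)
    for name, track in (tracks or {}).items():
        p = outdir / f"{name}.bedgraph"
        write_bedgraph(track, p)
        written.append(p.name)
    for name, peakset in (peaks or {}).items():
        p = outdir / f"{name}.bed"
        write_peaks_bed(peakset, p)
        written.append(p.name)
    manifest = {
        "config_hash": config_hash(config),
        "seeds": dict(seeds),
        "files": sorted(written),
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration; round-trips unchanged through
    ``save_run_config``."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg


def save_run_config(cfg: Mapping, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
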