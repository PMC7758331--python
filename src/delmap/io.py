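"""Readers and writers for the exchange formats of the pipeline.

Canonical formats: long-format TSV for counts (line, chrom, start, end,
count), TSV for phenotypes and traits, YAML/JSON for the genome layout,
BED (0-based half-open) for intervals and dosage calls, bedGraph for log2
tracks, and JSON for reports.  Readers validate and reject malformed input
rather than coercing it; every writer's output is accepted by its paired
reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import BinIndex, GenomeLayout, GenomicBin, build_bins
from .karyotype import BinCountPanel

LONG_COLUMNS = ["line", "chrom", "start", "end", "count"]


def write_layout(layout: GenomeLayout, path) -> None:
    path = Path(path)
    records = layout.to_records()
    if path.suffix == ".json":
        path.write_text(json.dumps({"chromosomes": records}, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump({"chromosomes": records}, sort_keys=False))


def read_layout(path) -> GenomeLayout:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "chromosomes" not in data:
        raise ValueError(f"{path}: layout file must contain a 'chromosomes' list")
    return GenomeLayout.from_records(data["chromosomes"])


def write_counts(panel: BinCountPanel, path) -> None:
    """Counts in canonical long format, sorted by (line order, bin index)."""
    rows = []
    for line in panel.lines:
        vals = panel.counts.loc[line].to_numpy()
        for b, v in zip(panel.bins.bins, vals):
            rows.append((line, b.chrom, b.start, b.end, v))
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_counts(path, layout: GenomeLayout, bin_width: int | None = None) -> BinCountPanel:
    """Read a counts TSV (long or wide) against a layout.

    Long format needs columns (line, chrom, start, end, count); wide format
    needs (chrom, start, end) plus one column per line.  Bins must tile the
    layout; duplicated (line, bin) rows, negative counts and unknown
    chromosomes are validation errors.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if set(LONG_COLUMNS).issubset(df.columns):
        long = df
    elif {"chrom", "start", "end"}.issubset(df.columns):
        value_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
        long = df.melt(
            id_vars=["chrom", "start", "end"], value_vars=value_cols,
            var_name="line", value_name="count",
        )
    else:
        raise ValueError(
            f"{path}: expected long columns {LONG_COLUMNS} or a wide matrix "
            "with (chrom, start, end) plus one column per line"
        )
    bad_chroms = sorted(set(long["chrom"]) - set(layout.names))
    if bad_chroms:
        raise ValueError(f"{path}: unknown chromosomes {bad_chroms}")
    if (long["count"] < 0).any():
        n = int((long["count"] < 0).sum())
        raise ValueError(f"{path}: {n} negative count(s)")
    dup = long.duplicated(subset=["line", "chrom", "start"], keep=False)
    if dup.any():
        rows = (long.index[dup] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: duplicated (line, bin) rows at file lines {rows}")

    # reconstruct the bin list from the unique (chrom, start, end) triples,
    # ordered by the layout's chromosome order
    ubins = long[["chrom", "start", "end"]].drop_duplicates()
    order = {name: i for i, name in enumerate(layout.names)}
    ubins = ubins.sort_values(
        by=["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    bins = [
        GenomicBin(r.chrom, int(r.start), int(r.end), i)
        for i, r in enumerate(ubins.itertuples())
    ]
    bi = BinIndex(bins)
    key_to_idx = {(b.chrom, b.start): b.index for b in bins}
    lines = list(dict.fromkeys(long["line"]))
    line_idx = {l: i for i, l in enumerate(lines)}
    arr = np.zeros((len(lines), len(bins)), dtype=float)
    filled = np.zeros((len(lines), len(bins)), dtype=bool)
    for r in long.itertuples():
        i = line_idx[r.line]
        j = key_to_idx[(r.chrom, int(r.start))]
        arr[i, j] = r.count
        filled[i, j] = True
    if not filled.all():
        raise ValueError(
            f"{path}: ragged input, {int((~filled).sum())} (line, bin) cells missing"
        )
    counts = pd.DataFrame(arr, index=lines)
    if np.all(arr == np.floor(arr)):
        counts = counts.astype(np.int64)
    return BinCountPanel(bins=bi, counts=counts)


def write_bed(intervals: Sequence[tuple], path) -> None:
    """BED3+ writer; rows are tuples (chrom, start, end[, name[, score]])."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if start >= end:
                raise ValueError(f"invalid BED interval {chrom}:{start}-{end}")
            rest = [str(x) for x in iv[3:]]
            fh.write("\t".join([chrom, str(start), str(end), *rest]) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            out.append((chrom, start, end, *parts[3:]))
    return out


def write_bedgraph(bins: BinIndex, values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for b, v in zip(bins.bins, values):
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{v:.6g}\n")


def write_phenotypes(phenotypes: dict[str, str], path) -> None:
    symbols = {"viable": "+", "non_viable": "-", "unknown": "NA"}
    with open(path, "w") as fh:
        fh.write("line\tviability\n")
        for line, ph in phenotypes.items():
            fh.write(f"{line}\t{symbols.get(ph, ph)}\n")


def read_phenotypes(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"line", "viability"}.issubset(df.columns):
        raise ValueError(f"{path}: phenotype TSV needs columns (line, viability)")
    mapping = {"+": "viable", "-": "non_viable", "−": "non_viable", "NA": "unknown"}
    out = {}
    for r in df.itertuples():
        v = mapping.get(r.viability, r.viability)
        if v not in ("viable", "non_viable", "unknown"):
            raise ValueError(f"{path}: bad viability value {r.viability!r} for {r.line}")
        out[r.line] = v
    return out


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
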