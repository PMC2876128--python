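"""Readers and writers for the plain-text interchange formats.

* probe table: TSV with header ``marker  chrom  pos  log2ratio``,
  sorted by (chrom, pos), ``#`` comment lines allowed;
* region files: BED-like TSV ``chrom  start  end  copy_number`` with
  0-based half-open bp coordinates;
* per-SNP calls: probe table columns plus ``copy_number`` and
  ``posterior_of_call``;
* segment calls: BED4+3 ``chrom start end copy_number n_markers
  mean_probability short_flag``;
* model configuration: YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CrpModel, ProbeSeries, Segment, default_model
from .simulate import TruthRegion

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_regions_bed",
    "write_regions_bed",
    "regions_to_marker_labels",
    "write_per_snp_calls",
    "write_segments_bed",
    "read_segments_bed",
    "load_model_config",
    "dump_model_config",
]

PROBE_COLUMNS = ["marker", "chrom", "pos", "log2ratio"]


def read_probe_table(path: str | Path) -> list[ProbeSeries]:
    """Read a probe TSV into per-chromosome series (file order preserved)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except Exception as e:
        raise ValueError(f"malformed probe table {path}: {e}") from e
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} lacks columns {missing}")
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        out.append(
            ProbeSeries(
                chromosome=str(chrom),
                ids=sub["marker"].to_numpy(dtype=object),
                pos_bp=sub["pos"].to_numpy(dtype=np.int64),
                value=sub["log2ratio"].to_numpy(dtype=float),
            )
        )
    return out


def write_probe_table(series_list: list[ProbeSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "marker": s.ids,
                "chrom": s.chromosome,
                "pos": s.pos_bp,
                "log2ratio": s.value,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """BED3+1 regions: chrom, start, end (0-based half-open bp), copy_number."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "copy_number"],
        dtype={"chrom": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"empty or inverted region {bad['chrom']}:{bad['start']}-{bad['end']}")
    return df


def write_regions_bed(regions: list[TruthRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{r.copy_number}\n")


def regions_to_marker_labels(
    regions: pd.DataFrame, series_list: list[ProbeSeries], normal_state: int = 2
) -> dict[str, np.ndarray]:
    """Per-chromosome per-marker copy numbers from bp regions.

    A marker belongs to a region when start <= pos < end.
    """
    out = {s.chromosome: np.full(s.T, normal_state) for s in series_list}
    by_chrom = {s.chromosome: s for s in series_list}
    for _, row in regions.iterrows():
        chrom = str(row["chrom"])
        if chrom not in by_chrom:
            continue
        pos = by_chrom[chrom].pos_bp
        sel = (pos >= row["start"]) & (pos < row["end"])
        out[chrom][sel] = int(row["copy_number"])
    return out


def write_per_snp_calls(
    series_list: list[ProbeSeries],
    paths: dict[str, np.ndarray],
    call_posteriors: dict[str, np.ndarray],
    path: str | Path,
) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "marker": s.ids,
                    "chrom": s.chromosome,
                    "pos": s.pos_bp,
                    "log2ratio": s.value,
                    "copy_number": paths[s.chromosome],
                    "posterior_of_call": call_posteriors[s.chromosome],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_segments_bed(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chromosome}\t{seg.start_bp}\t{seg.end_bp}\t{seg.state}\t"
                f"{seg.n_markers}\t{seg.mean_probability:.6g}\t{int(seg.short)}\n"
            )


def read_segments_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "copy_number", "n_markers", "mean_probability", "short"],
        dtype={"chrom": str},
    )


def load_model_config(path: str | Path) -> CrpModel:
    """Build a CRP model from a YAML configuration.

    Keys: states (list of copy numbers), means (list or mapping),
    sds (scalar, list or mapping), m, morgans_per_mb, normal.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    states = tuple(int(s) for s in cfg.get("states", (0, 1, 2, 3, 4)))
    means = cfg.get("means")
    if isinstance(means, (list, tuple)):
        means = dict(zip(states, (float(v) for v in means)))
    elif isinstance(means, dict):
        means = {int(k): float(v) for k, v in means.items()}
    sds = cfg.get("sds")
    if isinstance(sds, (list, tuple)):
        sds = dict(zip(states, (float(v) for v in sds)))
    elif isinstance(sds, dict):
        sds = {int(k): float(v) for k, v in sds.items()}
    return default_model(
        m=int(cfg.get("m", 4)),
        means=means,
        sds=sds,
        morgans_per_mb=float(cfg.get("morgans_per_mb", 0.01)),
        states=states,
        normal=int(cfg.get("normal", 2)),
    )


def dump_model_config(model: CrpModel, path: str | Path) -> None:
    cfg = {
        "states": list(model.states.labels),
        "normal": model.states.normal,
        "means": {int(s): float(model.emission.mean[s]) for s in model.states.labels},
        "sds": {int(s): float(model.emission.sd[s]) for s in model.states.labels},
        "m": model.patterns.m,
        "morgans_per_mb": model.transition.morgans_per_mb,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
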