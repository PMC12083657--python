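"""Readers and writers for the pipeline's file schemas.

Conventions: genomic positions are 1-based (VCF convention); spatial
coordinates are millimetres; biopsy y-coordinates lie in [0, circumference).
Tables are UTF-8 text, tab- or comma-delimited (the delimiter is sniffed from
the header line). Write/read round-trips are identity on canonical files.

Schemas
-------
biopsies (TSV): biopsy_id, section_id, x, y, circumference, diameter
mutation calls (TSV): biopsy_id, gene, chrom, pos, ref, alt, consequence,
    vaf_rep1, vaf_rep2, log_ratio_rep1, log_ratio_rep2, adjusted_vaf
barcodes (CSV): barcode_id, sample_id, x, y, cluster — Loupe-style
    "Barcode,Cluster" exports (plus coordinates) are accepted
clone sizes (TSV): region_id, clone_size, count, time_days[, covariate]
lattice grids: plain integer CSV matrices with entries in {-1, 0, +1}

VCF ingest maps INFO tags onto the mutation-call schema:
    BIOPSY (biopsy id), GENE, CSQC (consequence class), VAF1, VAF2,
    LR1, LR2 (per-replicate log probability ratios), AVAF (adjusted VAF);
one VCF record corresponds to one (mutation, biopsy) call.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .clones import Biopsy, Clone, MutationCall
from .fission import CloneSizeObservations
from .lattice import LatticeState, SimResult

__all__ = [
    "SchemaError",
    "read_biopsies",
    "write_biopsies",
    "read_mutation_calls",
    "write_mutation_calls",
    "read_mutation_vcf",
    "read_barcodes",
    "write_barcodes",
    "read_clone_sizes",
    "write_clone_sizes",
    "read_grid",
    "write_grid",
    "write_sim_results",
    "write_clones",
]

PathLike = Union[str, Path]

BIOPSY_COLUMNS = ["biopsy_id", "section_id", "x", "y", "circumference", "diameter"]
CALL_COLUMNS = [
    "biopsy_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "vaf_rep1",
    "vaf_rep2",
    "log_ratio_rep1",
    "log_ratio_rep2",
    "adjusted_vaf",
]
BARCODE_COLUMNS = ["barcode_id", "sample_id", "x", "y", "cluster"]
CLONE_SIZE_COLUMNS = ["region_id", "clone_size", "count", "time_days"]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def _sniff_sep(path: PathLike) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: PathLike, required: Sequence[str], rename: Optional[dict] = None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_sniff_sep(path), encoding="utf-8", float_precision="round_trip"
    )
    if rename:
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_biopsies(path: PathLike) -> list[Biopsy]:
    df = _read_table(path, BIOPSY_COLUMNS[:5])
    if df["biopsy_id"].duplicated().any():
        dup = df.loc[df["biopsy_id"].duplicated(), "biopsy_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate biopsy_id {dup!r}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                Biopsy(
                    biopsy_id=str(row["biopsy_id"]),
                    section_id=str(row["section_id"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    circumference=float(row["circumference"]),
                    diameter=float(row.get("diameter", 2.0)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {idx + 2}: {exc}") from exc
    return out


def write_biopsies(biopsies: Sequence[Biopsy], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "biopsy_id": b.biopsy_id,
                "section_id": b.section_id,
                "x": b.x,
                "y": b.y,
                "circumference": b.circumference,
                "diameter": b.diameter,
            }
            for b in biopsies
        ],
        columns=BIOPSY_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_mutation_calls(path: PathLike) -> list[MutationCall]:
    df = _read_table(path, CALL_COLUMNS)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                MutationCall(
                    biopsy_id=str(row["biopsy_id"]),
                    gene=str(row["gene"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    consequence=str(row["consequence"]),
                    vaf_rep1=float(row["vaf_rep1"]),
                    vaf_rep2=float(row["vaf_rep2"]),
                    log_ratio_rep1=float(row["log_ratio_rep1"]),
                    log_ratio_rep2=float(row["log_ratio_rep2"]),
                    adjusted_vaf=float(row["adjusted_vaf"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {idx + 2}: {exc}") from exc
    return out


def write_mutation_calls(calls: Sequence[MutationCall], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "biopsy_id": c.biopsy_id,
                "gene": c.gene,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "consequence": c.consequence,
                "vaf_rep1": c.vaf_rep1,
                "vaf_rep2": c.vaf_rep2,
                "log_ratio_rep1": c.log_ratio_rep1,
                "log_ratio_rep2": c.log_ratio_rep2,
                "adjusted_vaf": c.adjusted_vaf,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


_VCF_TAGS = {
    "BIOPSY": "biopsy_id",
    "GENE": "gene",
    "CSQC": "consequence",
    "VAF1": "vaf_rep1",
    "VAF2": "vaf_rep2",
    "LR1": "log_ratio_rep1",
    "LR2": "log_ratio_rep2",
    "AVAF": "adjusted_vaf",
}


def read_mutation_vcf(path: PathLike) -> list[MutationCall]:
    """Read calls from a VCF using the documented INFO-tag convention.

    One VCF record = one (mutation, biopsy) call; required INFO tags are
    BIOPSY, GENE, CSQC, VAF1, VAF2, LR1, LR2, AVAF (see module docstring).
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            info = rec.info
            missing = [t for t in _VCF_TAGS if t not in info]
            if missing:
                raise SchemaError(
                    f"{path}: record {rec.chrom}:{rec.pos} missing INFO tag(s) {missing}"
                )
            if rec.alts is None or len(rec.alts) != 1:
                raise SchemaError(
                    f"{path}: record {rec.chrom}:{rec.pos} must have exactly one ALT"
                )
            out.append(
                MutationCall(
                    biopsy_id=str(info["BIOPSY"]),
                    gene=str(info["GENE"]),
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(rec.alts[0]),
                    consequence=str(info["CSQC"]),
                    vaf_rep1=float(info["VAF1"]),
                    vaf_rep2=float(info["VAF2"]),
                    log_ratio_rep1=float(info["LR1"]),
                    log_ratio_rep2=float(info["LR2"]),
                    adjusted_vaf=float(info["AVAF"]),
                )
            )
    return out


def read_barcodes(path: PathLike) -> pd.DataFrame:
    """Barcode CSV; Loupe-style 'Barcode'/'Cluster' headers are accepted."""
    df = _read_table(
        path,
        BARCODE_COLUMNS,
        rename={"Barcode": "barcode_id", "Cluster": "cluster"},
    )
    if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
        raise SchemaError(f"{path}: non-finite barcode coordinates")
    if df["barcode_id"].duplicated().any():
        dup = df.loc[df["barcode_id"].duplicated(), "barcode_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate barcode_id {dup!r}")
    return df[BARCODE_COLUMNS]


def write_barcodes(barcodes: pd.DataFrame, path: PathLike) -> None:
    barcodes[BARCODE_COLUMNS].to_csv(path, index=False)


def read_clone_sizes(path: PathLike, n_max: Optional[int] = None) -> list[CloneSizeObservations]:
    df = _read_table(path, CLONE_SIZE_COLUMNS)
    out = []
    for rid, grp in df.groupby("region_id", sort=True):
        times = grp["time_days"].unique()
        if len(times) != 1:
            raise SchemaError(f"{path}: region {rid!r} has inconsistent time_days")
        top = int(grp["clone_size"].max()) if n_max is None else n_max
        counts = np.zeros(top, dtype=np.int64)
        for _, row in grp.iterrows():
            size = int(row["clone_size"])
            if size < 1:
                raise SchemaError(f"{path}: region {rid!r} has clone_size < 1")
            counts[min(size, top) - 1] += int(row["count"])
        cov = None
        if "covariate" in grp.columns and not grp["covariate"].isna().all():
            cov = float(grp["covariate"].iloc[0])
        out.append(
            CloneSizeObservations(
                region_id=str(rid), counts=counts, t=float(times[0]), covariate=cov
            )
        )
    return out


def write_clone_sizes(observations: Sequence[CloneSizeObservations], path: PathLike) -> None:
    rows = []
    for obs in observations:
        for size, count in enumerate(obs.counts, start=1):
            if count == 0:
                continue
            row = {
                "region_id": obs.region_id,
                "clone_size": size,
                "count": int(count),
                "time_days": obs.t,
            }
            if obs.covariate is not None:
                row["covariate"] = obs.covariate
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_grid(path: PathLike) -> LatticeState:
    grid = np.loadtxt(path, delimiter=_sniff_sep(path), dtype=np.int64)
    return LatticeState(grid)


def write_grid(state: LatticeState, path: PathLike) -> None:
    np.savetxt(path, state.grid, fmt="%d", delimiter=",")


def write_sim_results(results: Sequence[SimResult], path: PathLike) -> None:
    """Tidy CSV: replicate, step, half, labelled, unlabelled, empty, aggregation."""
    rows = []
    for rep, res in enumerate(results):
        for half, counts, agg in (
            ("left", res.counts_left, res.aggregation_left),
            ("right", res.counts_right, res.aggregation_right),
        ):
            for k, step_no in enumerate(res.recorded_steps):
                rows.append(
                    {
                        "replicate": rep,
                        "step": int(step_no),
                        "half": half,
                        "labelled": int(counts[k, 0]),
                        "unlabelled": int(counts[k, 1]),
                        "empty": int(counts[k, 2]),
                        "aggregation": float(agg[k]) if math.isfinite(agg[k]) else "",
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_clones(clones: Sequence[Clone], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "gene": c.gene,
                "consequence": c.consequence,
                "n_biopsies": c.n_biopsies,
                "max_vaf": c.max_vaf,
                "biopsy_ids": ";".join(c.biopsy_ids),
            }
            for c in clones
        ]
    ).to_csv(path, sep="\t", index=False)
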