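"""Integration of spatial-transcriptomic neighbourhoods with mutation calls.

Spatial barcodes (crypt-sized capture spots, each assigned to one expression
cluster) are mapped geometrically onto the 2 mm biopsies used for targeted
sequencing. From the joint table the module derives:

- per-sample *cluster coverage*: the fraction of a sample's barcodes in each
  cluster (a compositional vector summing to one);
- Kendall tau-b correlations between coverage by a target cluster (e.g. the
  tumour cluster) and coverage by every other cluster across samples;
- *tumour-associated* mutation flags: any non-synonymous SNV detected in a
  biopsy containing at least ``threshold`` (default 5) barcodes mapping to
  the tumour cluster;
- per-gene *malignancy scores*: tumour-associated / total non-synonymous
  mutation counts;
- per-cluster barcode probabilities for a class of mutations (the chance for
  a barcode in a biopsy holding such a mutation to fall in each cluster);
- ordinary-least-squares associations between per-biopsy responses (mean
  sub-10% VAF, clone counts, ...) and per-biopsy cluster coverage.

Per-cluster correlation tables report raw two-sided p-values (no multiple-
testing correction, mirroring per-cluster reporting conventions); pass
``adjust="bh"`` to add Benjamini–Hochberg adjusted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clones import Biopsy, MutationCall, periodic_distance

__all__ = [
    "AnnotatedMutation",
    "RegressionFit",
    "map_barcodes_to_biopsies",
    "cluster_coverage",
    "coverage_correlation",
    "classify_tumour_associated",
    "malignancy_score",
    "barcode_cluster_probability",
    "association_regression",
    "mutation_count_correlation",
]

BARCODE_COLUMNS = ("barcode_id", "sample_id", "x", "y", "cluster")


@dataclass(frozen=True)
class AnnotatedMutation:
    """A mutation call annotated with its tumour-cluster context."""

    call: MutationCall
    tumour_associated: bool
    n_tumour_barcodes_in_biopsy: int

    def __post_init__(self) -> None:
        if self.tumour_associated and self.call.consequence == "synonymous":
            raise ValueError("a synonymous SNV cannot be tumour-associated")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of a per-biopsy response on a cluster-coverage predictor."""

    slope: float
    intercept: float
    slope_p: float
    intercept_p: float
    n: int
    filter_note: str = ""


def map_barcodes_to_biopsies(
    barcodes: pd.DataFrame, biopsies: Sequence[Biopsy]
) -> pd.DataFrame:
    """Assign each barcode to the biopsy whose disc it falls in.

    A barcode is assigned to a biopsy when it lies within ``diameter/2`` of
    the biopsy centre (distances periodic along y); when several discs
    overlap the nearest centre wins. The returned frame is ``barcodes`` plus
    a ``biopsy_id`` column (None where unassigned). Biopsy ``section_id``
    must match barcode ``sample_id``.
    """
    missing = [c for c in BARCODE_COLUMNS if c not in barcodes.columns]
    if missing:
        raise ValueError(f"barcode table missing columns: {missing}")
    by_sample: dict[str, list[Biopsy]] = {}
    for b in biopsies:
        by_sample.setdefault(b.section_id, []).append(b)

    out = barcodes.copy()
    assigned: list[Optional[str]] = []
    for row in barcodes.itertuples(index=False):
        cands = by_sample.get(row.sample_id, [])
        best_id, best_d = None, np.inf
        for b in cands:
            d = periodic_distance((row.x, row.y), (b.x, b.y), b.circumference)
            if d <= b.diameter / 2.0 and d < best_d:
                best_id, best_d = b.biopsy_id, d
        assigned.append(best_id)
    out["biopsy_id"] = assigned
    return out


def cluster_coverage(barcodes: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fraction of barcodes in each cluster (rows sum to 1)."""
    if barcodes.empty:
        raise ValueError("barcode table is empty")
    counts = (
        barcodes.groupby(["sample_id", "cluster"], sort=True).size().unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def coverage_correlation(
    coverage: pd.DataFrame, target_cluster, adjust: Optional[str] = None
) -> pd.DataFrame:
    """Kendall tau-b between target-cluster coverage and every other cluster's.

    One row per non-target cluster with columns ``tau`` and ``p`` (two-sided);
    clusters whose coverage is constant across samples get NaN and
    ``undefined=True``. Raw p-values are reported per cluster; with
    ``adjust="bh"`` a ``p_adj`` column (Benjamini–Hochberg) is added.
    """
    if len(coverage) < 3:
        raise ValueError("need coverage for at least 3 samples")
    if target_cluster not in coverage.columns:
        raise KeyError(f"target cluster {target_cluster!r} not in coverage table")
    target = coverage[target_cluster].to_numpy()
    rows = []
    for cl in coverage.columns:
        if cl == target_cluster:
            continue
        x = coverage[cl].to_numpy()
        if np.allclose(x, x[0]) or np.allclose(target, target[0]):
            rows.append({"cluster": cl, "tau": np.nan, "p": np.nan, "undefined": True})
            continue
        tau, p = stats.kendalltau(target, x)
        rows.append({"cluster": cl, "tau": float(tau), "p": float(p), "undefined": False})
    out = pd.DataFrame(rows).set_index("cluster")
    if adjust == "bh":
        out["p_adj"] = _bh_adjust(out["p"].to_numpy())
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def tumour_barcode_counts(
    mapped_barcodes: pd.DataFrame, tumour_cluster
) -> pd.Series:
    """Per-biopsy count of barcodes mapping to the tumour cluster."""
    assigned = mapped_barcodes[mapped_barcodes["biopsy_id"].notna()]
    return (
        assigned[assigned["cluster"] == tumour_cluster]
        .groupby("biopsy_id")
        .size()
        .astype(int)
    )


def classify_tumour_associated(
    calls: Sequence[MutationCall],
    mapped_barcodes: pd.DataFrame,
    tumour_cluster,
    threshold: int = 5,
) -> list[AnnotatedMutation]:
    """Flag non-synonymous SNVs in biopsies with >= threshold tumour-cluster barcodes.

    Biopsies absent from the barcode map contribute a count of zero (flag
    False). Raising the threshold can only remove flags (monotonicity).
    """
    counts = tumour_barcode_counts(mapped_barcodes, tumour_cluster)
    out = []
    for c in calls:
        n = int(counts.get(c.biopsy_id, 0))
        flag = c.is_nonsynonymous and n >= threshold
        out.append(
            AnnotatedMutation(call=c, tumour_associated=flag, n_tumour_barcodes_in_biopsy=n)
        )
    return out


def malignancy_score(annotated: Sequence[AnnotatedMutation]) -> pd.DataFrame:
    """Per-gene proportion of non-synonymous mutations that are tumour-associated.

    Columns: ``n_tumour_associated``, ``n_nonsynonymous``, ``score``. Genes
    with only synonymous calls appear with score NaN (undefined, not zero).
    """
    rows: dict[str, dict[str, int]] = {}
    for a in annotated:
        g = rows.setdefault(a.call.gene, {"n_tumour_associated": 0, "n_nonsynonymous": 0})
        if a.call.is_nonsynonymous:
            g["n_nonsynonymous"] += 1
            if a.tumour_associated:
                g["n_tumour_associated"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "gene"
    with np.errstate(invalid="ignore"):
        out["score"] = np.where(
            out["n_nonsynonymous"] > 0,
            out["n_tumour_associated"] / out["n_nonsynonymous"].replace(0, np.nan),
            np.nan,
        )
    return out


def barcode_cluster_probability(
    annotated: Sequence[AnnotatedMutation],
    mapped_barcodes: pd.DataFrame,
    mutation_class: str = "tumour_associated",
) -> pd.Series:
    """Per-cluster fraction of barcodes lying in biopsies that hold a mutation class.

    ``mutation_class`` is ``"tumour_associated"`` or ``"synonymous"``. All
    barcodes assigned to a qualifying biopsy are pooled (barcode-weighted)
    and the fraction per cluster returned; the vector sums to one.
    """
    if mutation_class == "tumour_associated":
        qualifying = {a.call.biopsy_id for a in annotated if a.tumour_associated}
    elif mutation_class == "synonymous":
        qualifying = {a.call.biopsy_id for a in annotated if a.call.consequence == "synonymous"}
    else:
        raise ValueError(f"unknown mutation class {mutation_class!r}")
    pool = mapped_barcodes[mapped_barcodes["biopsy_id"].isin(qualifying)]
    if pool.empty:
        raise ValueError(f"no barcodes fall in biopsies holding a {mutation_class} mutation")
    frac = pool.groupby("cluster").size() / len(pool)
    return frac.rename("probability")


def association_regression(
    response: pd.Series,
    predictor: pd.Series,
    filter_note: str = "",
) -> RegressionFit:
    """OLS of a per-biopsy response on a per-biopsy coverage predictor.

    Both series are aligned on their (biopsy) index; rows with missing values
    are dropped. ``filter_note`` records any upstream filtering (e.g.
    "adjusted VAF < 0.10") for provenance.
    """
    import statsmodels.api as sm

    df = pd.concat({"y": response, "x": predictor}, axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 observations")
    x = df["x"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("constant predictor; regression undefined")
    fit = sm.OLS(df["y"].to_numpy(dtype=float), sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_p=float(fit.pvalues[1]),
        intercept_p=float(fit.pvalues[0]),
        n=len(df),
        filter_note=filter_note,
    )


def _in_class(a: AnnotatedMutation, mutation_class: str) -> bool:
    if mutation_class == "tumour_associated":
        return a.tumour_associated
    if mutation_class == "non_tumour_associated":
        return not a.tumour_associated
    if mutation_class == "synonymous":
        return a.call.consequence == "synonymous"
    raise ValueError(f"unknown mutation class {mutation_class!r}")


def mutation_count_correlation(
    annotated: Sequence[AnnotatedMutation],
    coverage: pd.DataFrame,
    biopsy_to_sample: dict[str, str],
    mutation_class: str = "tumour_associated",
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Kendall tau-b between per-sample mutation counts and cluster coverage.

    Counts mutations of the requested class (``"tumour_associated"``,
    ``"non_tumour_associated"`` or the ``"synonymous"`` control) per sample
    and correlates the counts with every cluster's coverage across samples.
    Samples without any mutation of the class count zero.
    """
    counts = pd.Series(0, index=coverage.index, dtype=int)
    for a in annotated:
        if not _in_class(a, mutation_class):
            continue
        sample = biopsy_to_sample.get(a.call.biopsy_id)
        if sample in counts.index:
            counts[sample] += 1
    if len(coverage) < 3:
        raise ValueError("need coverage for at least 3 samples")
    y = counts.to_numpy(dtype=float)
    rows = []
    for cl in coverage.columns:
        x = coverage[cl].to_numpy()
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            rows.append({"cluster": cl, "tau": np.nan, "p": np.nan, "undefined": True})
            continue
        tau, p = stats.kendalltau(y, x)
        rows.append({"cluster": cl, "tau": float(tau), "p": float(p), "undefined": False})
    out = pd.DataFrame(rows).set_index("cluster")
    out.attrs["n_mutations"] = int(counts.sum())
    if adjust == "bh":
        out["p_adj"] = _bh_adjust(out["p"].to_numpy())
    return out
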