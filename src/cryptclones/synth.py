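"""Synthetic-data generators with the statistical structure the pipeline assumes.

Every pipeline input can be generated here with known ("planted") ground
truth, so each analysis stage is testable end-to-end without animal data:

- clone-size tables follow the Yule–Furry geometric law at planted fission
  rates;
- biopsy layouts are regular grids of 2 mm punches on the opened colon
  (y periodic at the circumference);
- spatial barcodes carry cluster labels drawn from a nearest-seed spatial
  field, so clusters form contiguous neighbourhoods; per-sample coverage of
  the designated repair and tumour clusters both increase with a latent
  sample "severity", planting a positive cross-sample coverage correlation;
- mutation-call tables contain planted clones: the same SNV emitted in every
  biopsy of a spatially connected footprint, with beta-distributed VAF noise
  around a clone-level mean drawn log-uniformly on [0.001, 0.3]. Tumour-class
  clones are seeded preferentially over tumour/repair-cluster territory with
  a configurable log-odds enrichment; false positive calls carry one negative
  replicate log-probability-ratio so the dual-replicate filter removes them.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clones import Biopsy, MutationCall, build_adjacency
from .fission import CloneSizeObservations

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "gen_clone_sizes",
    "gen_biopsy_layout",
    "gen_barcode_assignments",
    "gen_mutation_calls",
    "generate_dataset",
]

#: genes mutated in IBD / colitis-associated cancer, split by class: the
#: tumour class mirrors CAC drivers, the inflammation class IL-17-pathway and
#: chromatin-remodelling genes recurrently mutated in non-dysplastic IBD
#: epithelium. The panel is conceptual, not a claim about any assay design.
TUMOUR_GENES = ("Ctnnb1", "Smad4", "Apc", "Kras", "Trp53")
INFLAMMATION_GENES = ("Il17ra", "Il17rc", "Pigr", "Nfkbiz", "Arid1a", "Bcor", "Rela")

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults for the synthetic cohort.

    Sixteen tissue samples, each an 6x3 grid of 2 mm biopsies (288 biopsies
    in total), sixteen expression clusters with the tumour cluster labelled
    10 and the epithelial-repair cluster labelled 4, and lineage-tracing
    clone sizes read 210 days (7 months) after induction.
    """

    n_samples: int = 16
    n_cols: int = 6
    n_rows: int = 3
    spacing: float = 2.0  # mm, = one biopsy diameter
    biopsy_diameter: float = 2.0  # mm
    n_clusters: int = 16
    tumour_cluster: int = 10
    repair_cluster: int = 4
    n_cluster_seeds: int = 12  # spatial patches per sample (contiguity scale)
    barcode_spacing: float = 0.25  # mm between spots
    enrichment: float = 2.5  # log-odds for tumour-class clone placement
    false_call_rate: float = 0.10  # false calls per biopsy
    vaf_concentration: float = 30.0  # beta concentration of per-biopsy VAF noise
    mean_tumour_clones: float = 4.0  # per sample at severity 1
    mean_inflammation_clones: float = 2.0  # per sample
    mean_synonymous_clones: float = 2.0  # per sample
    # lineage-tracing arm
    n_regions: int = 9  # 3 mice x 3 regions
    clone_time_days: float = 210.0
    clones_per_region: int = 200
    rho_range: tuple[float, float] = (0.002, 0.02)  # 1/days


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every generated dataset."""

    seed: int
    rho_by_region: dict[str, float] = field(default_factory=dict)
    clone_footprints: dict[str, list[str]] = field(default_factory=dict)
    clone_class: dict[str, str] = field(default_factory=dict)  # tumour|inflammation|synonymous
    severities: dict[str, float] = field(default_factory=dict)
    n_clusters: int = 16
    tumour_cluster: int = 10
    repair_cluster: int = 4
    enrichment: float = 2.5
    false_call_rate: float = 0.10
    vaf_concentration: float = 30.0
    n_false_calls: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    """All generated pipeline inputs plus their planted truth."""

    biopsies: list[Biopsy]
    calls: list[MutationCall]
    barcodes: pd.DataFrame
    clone_sizes: list[CloneSizeObservations]
    truth: SyntheticTruth


def gen_clone_sizes(
    rho: float,
    t: float,
    n_clones: int,
    seed: int,
    region_id: str = "region",
    n_max: Optional[int] = None,
    covariate: Optional[float] = None,
) -> CloneSizeObservations:
    """I.i.d. clone sizes from the Yule–Furry geometric law, tabulated as counts.

    A clone observed at time ``t`` has size ``n`` with probability
    ``e^{-rho t}(1 - e^{-rho t})^{n-1}``, i.e. geometric with success
    probability ``e^{-rho t}`` and mean ``e^{rho t}``.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    rng = np.random.default_rng(seed)
    p = float(np.exp(-rho * t))
    sizes = rng.geometric(p, size=n_clones) if p < 1.0 else np.ones(n_clones, dtype=np.int64)
    return CloneSizeObservations.from_sizes(
        region_id, sizes, t, n_max=n_max, covariate=covariate
    )


def gen_biopsy_layout(
    n_cols: int,
    n_rows: int,
    spacing: float = 2.0,
    circumference: Optional[float] = None,
    section_id: str = "S0",
    diameter: float = 2.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> list[Biopsy]:
    """Regular biopsy grid on one opened-colon section, y wrapped at the circumference."""
    circ = circumference if circumference is not None else n_rows * spacing
    rng = np.random.default_rng(seed)
    out = []
    k = 0
    for c in range(n_cols):
        for r in range(n_rows):
            x = (c + 0.5) * spacing
            y = (r + 0.5) * spacing
            if jitter > 0:
                x += float(rng.normal(0, jitter))
                y += float(rng.normal(0, jitter))
            out.append(
                Biopsy(
                    biopsy_id=f"{section_id}_b{k:03d}",
                    section_id=section_id,
                    x=x,
                    y=float(y % circ),
                    circumference=circ,
                    diameter=diameter,
                )
            )
            k += 1
    return out


def _sample_barcodes(
    section: Sequence[Biopsy],
    config: SyntheticConfig,
    severity: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Cluster-labelled barcode grid for one sample.

    Labels come from a nearest-seed Voronoi field (contiguous patches); the
    seed-label weights of the repair and tumour clusters grow with the sample
    severity, so coverage by both rises together across samples.
    """
    section_id = section[0].section_id
    circ = section[0].circumference
    xs = np.array([b.x for b in section])
    x_lo, x_hi = xs.min() - config.spacing / 2, xs.max() + config.spacing / 2

    gx = np.arange(x_lo, x_hi, config.barcode_spacing)
    gy = np.arange(0.0, circ, config.barcode_spacing)
    px, py = np.meshgrid(gx, gy, indexing="ij")
    px = px.ravel()
    py = py.ravel()

    n_seeds = config.n_cluster_seeds
    sx = rng.uniform(x_lo, x_hi, n_seeds)
    sy = rng.uniform(0.0, circ, n_seeds)
    weights = np.ones(config.n_clusters)
    weights[config.repair_cluster] = 1.0 + 6.0 * severity
    weights[config.tumour_cluster] = 0.1 + 4.0 * severity**2
    labels = rng.choice(config.n_clusters, size=n_seeds, p=weights / weights.sum())
    # tumours arise inside repairing tissue: a tumour patch drags its nearest
    # neighbouring patch toward the repair label
    for s in np.nonzero(labels == config.tumour_cluster)[0]:
        d = (sx - sx[s]) ** 2 + np.minimum(np.abs(sy - sy[s]), circ - np.abs(sy - sy[s])) ** 2
        d[s] = np.inf
        labels[int(np.argmin(d))] = config.repair_cluster

    dx = px[:, None] - sx[None, :]
    dy = np.abs(py[:, None] - sy[None, :])
    dy = np.minimum(dy, circ - dy)
    nearest = np.argmin(dx**2 + dy**2, axis=1)
    cluster = labels[nearest]

    return pd.DataFrame(
        {
            "barcode_id": [f"{section_id}_bc{i:05d}" for i in range(len(px))],
            "sample_id": section_id,
            "x": px,
            "y": py,
            "cluster": cluster.astype(int),
        }
    )


def gen_barcode_assignments(
    layout: Sequence[Biopsy],
    config: Optional[SyntheticConfig] = None,
    severities: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Barcode tables for every section in ``layout`` (one sample per section)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    sections: dict[str, list[Biopsy]] = {}
    for b in layout:
        sections.setdefault(b.section_id, []).append(b)
    frames = []
    for sid in sorted(sections):
        sev = severities.get(sid, 0.5) if severities else 0.5
        frames.append(_sample_barcodes(sections[sid], config, sev, rng))
    return pd.concat(frames, ignore_index=True)


def _biopsy_cluster_fractions(
    section: Sequence[Biopsy], barcodes: pd.DataFrame, cluster: int
) -> np.ndarray:
    """Fraction of each biopsy's overlying barcodes in the given cluster."""
    from .neighbourhoods import map_barcodes_to_biopsies

    mapped = map_barcodes_to_biopsies(barcodes, section)
    out = np.zeros(len(section))
    grouped = mapped[mapped["biopsy_id"].notna()].groupby("biopsy_id")
    frac = grouped.apply(
        lambda g: float((g["cluster"] == cluster).mean()), include_groups=False
    )
    for i, b in enumerate(section):
        out[i] = float(frac.get(b.biopsy_id, 0.0))
    return out


def _grow_footprint(
    graph, seed_id: str, size: int, rng: np.random.Generator
) -> list[str]:
    """Connected biopsy set grown from a seed by randomised breadth-first search."""
    members = [seed_id]
    frontier = set(graph.neighbors(seed_id))
    while len(members) < size and frontier:
        nxt = sorted(frontier)[int(rng.integers(len(frontier)))]
        members.append(nxt)
        frontier |= set(graph.neighbors(nxt))
        frontier -= set(members)
    return sorted(members)


def _mutation_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def gen_mutation_calls(
    truth: SyntheticTruth,
    layout: Sequence[Biopsy],
    barcodes: pd.DataFrame,
    config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
) -> list[MutationCall]:
    """Plant clones on the layout and emit their per-biopsy mutation calls.

    Each planted clone emits one row per footprint biopsy sharing a single
    (chrom, pos, ref, alt) key; per-biopsy adjusted VAFs are beta-distributed
    around the clone mean. Tumour-class clones choose their seed biopsy with
    weight ``exp(enrichment * (tumour + repair coverage))``; inflammation-class
    and synonymous clones are seeded uniformly. False calls (one per event,
    negative log-ratio in replicate 2) are appended at the configured rate and
    recorded in ``truth.n_false_calls``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    sections: dict[str, list[Biopsy]] = {}
    for b in layout:
        sections.setdefault(b.section_id, []).append(b)

    gene_loci = {
        g: (f"chr{(i % 19) + 1}", 1_000_000 * (i + 1))
        for i, g in enumerate(TUMOUR_GENES + INFLAMMATION_GENES)
    }
    counter = 0
    calls: list[MutationCall] = []

    for sid in sorted(sections):
        section = sections[sid]
        sev = truth.severities.get(sid, 0.5)
        graph = build_adjacency(section, dist_threshold=config.spacing)
        sample_bc = barcodes[barcodes["sample_id"] == sid]
        tum = _biopsy_cluster_fractions(section, sample_bc, truth.tumour_cluster)
        rep = _biopsy_cluster_fractions(section, sample_bc, truth.repair_cluster)

        n_tumour = rng.poisson(config.mean_tumour_clones * sev)
        n_inflam = rng.poisson(config.mean_inflammation_clones)
        n_syn = rng.poisson(config.mean_synonymous_clones)
        plan = (
            [("tumour", "missense")] * n_tumour
            + [("inflammation", rng.choice(["missense", "nonsense"])) for _ in range(n_inflam)]
            + [("synonymous", "synonymous")] * n_syn
        )
        w_enriched = np.exp(truth.enrichment * (tum + rep))
        w_enriched = w_enriched / w_enriched.sum()
        for clone_class, consequence in plan:
            if clone_class == "tumour":
                gene = str(rng.choice(TUMOUR_GENES))
                seed_idx = int(rng.choice(len(section), p=w_enriched))
            else:
                gene = str(rng.choice(INFLAMMATION_GENES))
                seed_idx = int(rng.integers(len(section)))
            size = min(int(rng.geometric(0.6)), 4)
            footprint = _grow_footprint(graph, section[seed_idx].biopsy_id, size, rng)

            chrom, base = gene_loci[gene]
            pos = base + counter
            counter += 1
            ref = str(rng.choice(_BASES))
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            key = _mutation_key(chrom, pos, ref, alt)
            truth.clone_footprints[key] = footprint
            truth.clone_class[key] = clone_class

            mean_vaf = float(np.exp(rng.uniform(np.log(1e-3), np.log(0.3))))
            kappa = truth.vaf_concentration
            for bid in footprint:
                vaf = float(
                    np.clip(rng.beta(mean_vaf * kappa, (1 - mean_vaf) * kappa), 2e-4, 0.999)
                )
                noise = rng.normal(1.0, 0.05, size=2)
                calls.append(
                    MutationCall(
                        biopsy_id=bid,
                        gene=gene,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        consequence=str(consequence),
                        vaf_rep1=float(np.clip(vaf * noise[0], 0.0, 1.0)),
                        vaf_rep2=float(np.clip(vaf * noise[1], 0.0, 1.0)),
                        log_ratio_rep1=float(rng.uniform(0.5, 5.0)),
                        log_ratio_rep2=float(rng.uniform(0.5, 5.0)),
                        adjusted_vaf=vaf,
                    )
                )

        # false positives: removable by the dual-replicate filter
        n_false = rng.poisson(truth.false_call_rate * len(section))
        for _ in range(n_false):
            b = section[int(rng.integers(len(section)))]
            gene = str(rng.choice(TUMOUR_GENES + INFLAMMATION_GENES))
            chrom, base = gene_loci[gene]
            pos = base + 500_000 + counter
            counter += 1
            ref = str(rng.choice(_BASES))
            alt = str(rng.choice([x for x in _BASES if x != ref]))
            vaf = float(rng.uniform(2e-4, 2e-3))
            calls.append(
                MutationCall(
                    biopsy_id=b.biopsy_id,
                    gene=gene,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    consequence=str(rng.choice(["missense", "synonymous"])),
                    vaf_rep1=vaf,
                    vaf_rep2=vaf,
                    log_ratio_rep1=float(rng.uniform(0.1, 2.0)),
                    log_ratio_rep2=float(rng.uniform(-3.0, -0.1)),
                    adjusted_vaf=vaf,
                )
            )
            truth.n_false_calls += 1
    return calls


def generate_dataset(
    config: Optional[SyntheticConfig] = None, seed: int = 0
) -> SyntheticDataset:
    """Generate a full coherent cohort: layouts, barcodes, calls and clone sizes."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        seed=seed,
        n_clusters=config.n_clusters,
        tumour_cluster=config.tumour_cluster,
        repair_cluster=config.repair_cluster,
        enrichment=config.enrichment,
        false_call_rate=config.false_call_rate,
        vaf_concentration=config.vaf_concentration,
    )

    layout: list[Biopsy] = []
    for s in range(config.n_samples):
        sid = f"S{s:02d}"
        truth.severities[sid] = float(rng.uniform(0.0, 1.0))
        layout.extend(
            gen_biopsy_layout(
                config.n_cols,
                config.n_rows,
                spacing=config.spacing,
                section_id=sid,
                diameter=config.biopsy_diameter,
                seed=int(rng.integers(2**31 - 1)),
            )
        )

    barcodes = gen_barcode_assignments(
        layout, config, truth.severities, seed=int(rng.integers(2**31 - 1))
    )
    calls = gen_mutation_calls(
        truth, layout, barcodes, config, seed=int(rng.integers(2**31 - 1))
    )

    clone_sizes = []
    lo, hi = config.rho_range
    rhos = np.linspace(lo, hi, config.n_regions)
    for i, rho in enumerate(rhos):
        rid = f"R{i:02d}"
        # covariate: % Trop2-positive area, increasing with the planted rate
        cov = float(np.clip(100 * rho / hi * 0.6 + rng.normal(0, 3), 0, 100))
        truth.rho_by_region[rid] = float(rho)
        clone_sizes.append(
            gen_clone_sizes(
                float(rho),
                config.clone_time_days,
                config.clones_per_region,
                seed=int(rng.integers(2**31 - 1)),
                region_id=rid,
                n_max=30,
                covariate=cov,
            )
        )

    return SyntheticDataset(
        biopsies=layout,
        calls=calls,
        barcodes=barcodes,
        clone_sizes=clone_sizes,
        truth=truth,
    )
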