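"""Synthetic spatial-transcriptomics sections with known ground truth.

The generator emulates the structure the pipeline assumes: several serial
sections of one tissue, each a rectangular barcoded array (default 33 x 35)
whose spots belong to one of three spatially contiguous region classes
(non-malignant, DCIS, IDC). Genes live non-overlapping on one toy
chromosome with alternating strands; molecule counts per (spot, gene) are
negative binomial with class-specific signature genes boosted by a planted
log2 fold change, per-spot library-depth variation, and one MALAT1-like
ultra-high expressor that soaks up a fixed fraction of all molecules. Each
molecule becomes a BED read whose 3' end scatters around the gene's
termination site with Gaussian jitter.

Everything is reproducible from the seed; the same seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CLASSES, GeneModel, SpotLabel, labels_to_series

__all__ = ["SimConfig", "SimTruth", "SimResult", "layout_regions", "simulate"]

MALAT1_NAME = "MALAT1"


@dataclass
class SimConfig:
    """Parameters of the synthetic scene (defaults are the study conditions)."""

    seed: int = 17
    n_datasets: int = 4
    grid_width: int = 33
    grid_height: int = 35
    n_genes: int = 300
    n_signature_per_class: int = 20
    log2fc_effect: float = 3.0
    nb_dispersion: float = 0.2
    #: log2 range of per-gene baseline mean molecules per spot (background genes)
    base_mean_log2_range: tuple[float, float] = (-2.5, 1.5)
    #: log2 range for signature (marker) genes; markers are modeled as
    #: moderately expressed — see docs/methods.md for the arithmetic argument
    signature_mean_log2_range: tuple[float, float] = (0.0, 2.0)
    spot_depth_lognormal_sigma: float = 0.35
    malat1_fraction: float = 0.15
    read_span: int = 48
    tts_jitter_sd: float = 8.0
    #: layout of the region classes: "stripes" or "blobs"
    region_layout: str = "stripes"
    gene_length: int = 2000
    gene_gap: int = 1000
    #: how far past the annotated gene body a jittered 3' end may fall
    jitter_clip: int = 100
    chrom: str = "chrT"

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.grid_width < 1 or self.grid_height < 1:
            raise ValueError("dataset count and grid dimensions must be positive")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if 3 * self.n_signature_per_class > self.n_genes - 1:
            raise ValueError("signature genes exceed available genes")
        if not (0.0 <= self.malat1_fraction < 1.0):
            raise ValueError("malat1_fraction must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.region_layout not in ("stripes", "blobs"):
            raise ValueError("region_layout must be 'stripes' or 'blobs'")
        if self.read_span < 1 or self.tts_jitter_sd < 0:
            raise ValueError("invalid read geometry")


@dataclass
class SimTruth:
    """Planted ground truth of one simulation."""

    classes: pd.Series                       # (dataset, x, y) -> class
    signature_genes: dict[str, list[str]]    # class -> gene ids
    base_means: dict[str, float]             # gene id -> baseline mean
    depth: pd.Series                         # (dataset, x, y) -> depth factor
    gene_tts: dict[str, int]
    log2fc_effect: float

    def to_json_dict(self) -> dict:
        return {
            "classes": {f"{d}|{x}|{y}": c
                        for (d, x, y), c in self.classes.items()},
            "signature_genes": self.signature_genes,
            "base_means": self.base_means,
            "depth": {f"{d}|{x}|{y}": float(v)
                      for (d, x, y), v in self.depth.items()},
            "gene_tts": self.gene_tts,
            "log2fc_effect": self.log2fc_effect,
        }


@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    reads: dict[str, pd.DataFrame]           # dataset id -> read table
    labels: list[SpotLabel]
    truth: SimTruth

    @property
    def labels_series(self) -> pd.Series:
        return labels_to_series(self.labels)


def layout_regions(width: int, height: int, kind: str = "stripes",
                   seed: int = 0) -> np.ndarray:
    """Per-spot class indices on a (width, height) grid, ``arr[x-1, y-1]``.

    ``stripes``: three vertical bands covering ~(0.6, 0.2, 0.2) of the
    columns — non-malignant, then DCIS, then IDC — mimicking the class
    imbalance of annotated tissue. ``blobs``: two random-growth blobs
    (DCIS, IDC), each ~20% of the spots, on a non-malignant background.
    """
    if width < 1 or height < 1:
        raise ValueError("grid must be non-empty")
    arr = np.zeros((width, height), dtype=np.int64)
    if kind == "stripes":
        b1 = int(round(0.6 * width))
        b2 = int(round(0.8 * width))
        arr[b1:b2, :] = 1
        arr[b2:, :] = 2
        return arr
    if kind != "blobs":
        raise ValueError("kind must be 'stripes' or 'blobs'")
    rng = np.random.default_rng(seed)
    target = max(1, int(round(0.2 * width * height)))
    for cls in (1, 2):
        free = np.flatnonzero(arr.ravel() == 0)
        start = int(rng.choice(free))
        blob = {(start // height, start % height)}
        frontier = set()

        def neighbours(cell):
            x, y = cell
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nx, ny = x + dx, y + dy
                if 0 <= nx < width and 0 <= ny < height and arr[nx, ny] == 0:
                    yield nx, ny

        frontier.update(c for c in neighbours((start // height, start % height))
                        if c not in blob)
        while len(blob) < target and frontier:
            ordered = sorted(frontier)
            cell = ordered[int(rng.integers(len(ordered)))]
            frontier.discard(cell)
            blob.add(cell)
            frontier.update(c for c in neighbours(cell) if c not in blob)
        for x, y in blob:
            arr[x, y] = cls
    return arr


def _place_genes(config: SimConfig) -> list[GeneModel]:
    genes = []
    for i in range(config.n_genes):
        start = 1000 + i * (config.gene_length + config.gene_gap)
        end = start + config.gene_length
        strand = "+" if i % 2 == 0 else "-"
        name = MALAT1_NAME if i == config.n_genes - 1 else f"G{i:04d}"
        genes.append(GeneModel(gene_id=name, gene_name=name, chrom=config.chrom,
                               strand=strand, start=start, end=end))
    return genes


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate annotation, per-section reads, labels and ground truth.

    When ``out_dir`` is given, writes ``genes.gtf``, one
    ``dataset_<i>.bed`` per section, ``labels.tsv`` and ``truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config)
    regular = genes[:-1]
    n_reg = len(regular)
    n_sig = config.n_signature_per_class

    sig_idx = rng.choice(n_reg, size=3 * n_sig, replace=False)
    signature_genes = {
        cls: sorted(regular[i].gene_id for i in sig_idx[k * n_sig:(k + 1) * n_sig])
        for k, cls in enumerate(CLASSES)
    }
    is_sig_for = np.zeros((n_reg, 3), dtype=bool)
    for k in range(3):
        is_sig_for[sig_idx[k * n_sig:(k + 1) * n_sig], k] = True

    lo, hi = config.base_mean_log2_range
    base = 2.0 ** rng.uniform(lo, hi, size=n_reg)
    slo, shi = config.signature_mean_log2_range
    base[sig_idx] = 2.0 ** rng.uniform(slo, shi, size=sig_idx.size)
    base_means = {g.gene_id: float(b) for g, b in zip(regular, base)}

    w, h = config.grid_width, config.grid_height
    n_spots = w * h
    xs, ys = np.meshgrid(np.arange(1, w + 1), np.arange(1, h + 1), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()

    labels: list[SpotLabel] = []
    truth_cls_keys, truth_cls_vals = [], []
    depth_keys, depth_vals = [], []
    reads: dict[str, pd.DataFrame] = {}
    effect = 2.0 ** config.log2fc_effect
    alpha = config.nb_dispersion

    for d in range(1, config.n_datasets + 1):
        ds = f"dataset_{d}"
        layout = layout_regions(w, h, kind=config.region_layout,
                                seed=config.seed * 1000 + d)
        cls_of_spot = layout[xs - 1, ys - 1]            # 0..2 per spot
        depth = rng.lognormal(mean=0.0, sigma=config.spot_depth_lognormal_sigma,
                              size=n_spots)

        mean = np.broadcast_to(base, (n_spots, n_reg)).copy()
        for k in range(3):
            boost = np.outer(cls_of_spot == k, is_sig_for[:, k])
            mean[boost] *= effect
        mean *= depth[:, None]
        malat_mean = (config.malat1_fraction / (1.0 - config.malat1_fraction)
                      * mean.sum(axis=1))
        mean = np.column_stack([mean, malat_mean])

        if alpha > 0:
            lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
        else:
            lam = mean
        counts = rng.poisson(lam)

        spot_rep = np.repeat(np.arange(n_spots), counts.sum(axis=1))
        gene_rep = np.concatenate(
            [np.repeat(np.arange(n_reg + 1), counts[s]) for s in range(n_spots)]
        ) if counts.sum() else np.array([], dtype=int)
        n_mol = spot_rep.size

        tts = np.array([g.tts for g in genes])
        gstart = np.array([g.start for g in genes])
        gend = np.array([g.end for g in genes])
        gplus = np.array([g.strand == "+" for g in genes])

        jitter = np.round(rng.normal(0.0, config.tts_jitter_sd, size=n_mol)
                          ).astype(np.int64)
        pos3 = tts[gene_rep] + jitter
        plus = gplus[gene_rep]
        lo_clip = np.where(plus, gstart[gene_rep],
                           gstart[gene_rep] - config.jitter_clip)
        hi_clip = np.where(plus, gend[gene_rep] - 1 + config.jitter_clip,
                           gend[gene_rep] - 1)
        pos3 = np.clip(pos3, lo_clip, hi_clip)

        start = np.where(plus, pos3 + 1 - config.read_span, pos3)
        end = np.where(plus, pos3 + 1, pos3 + config.read_span)
        gene_names = np.array([g.gene_name for g in genes], dtype=object)
        reads[ds] = pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": start,
                "end": end,
                "name": [f"m{i}" for i in range(n_mol)],
                "score": 0,
                "strand": np.where(plus, "+", "-"),
                "gene_tag": gene_names[gene_rep],
                "x": xs[spot_rep],
                "y": ys[spot_rep],
                "dataset": ds,
            }
        )

        for s in range(n_spots):
            labels.append(SpotLabel(ds, int(xs[s]), int(ys[s]),
                                    CLASSES[cls_of_spot[s]]))
        truth_cls_keys.extend((ds, int(xs[s]), int(ys[s])) for s in range(n_spots))
        truth_cls_vals.extend(CLASSES[c] for c in cls_of_spot)
        depth_keys.extend((ds, int(xs[s]), int(ys[s])) for s in range(n_spots))
        depth_vals.extend(depth)

    idx = pd.MultiIndex.from_tuples(truth_cls_keys, names=["dataset", "x", "y"])
    truth = SimTruth(
        classes=pd.Series(truth_cls_vals, index=idx, name="class"),
        signature_genes=signature_genes,
        base_means=base_means,
        depth=pd.Series(
            depth_vals,
            index=pd.MultiIndex.from_tuples(depth_keys,
                                            names=["dataset", "x", "y"]),
            name="depth",
        ),
        gene_tts={g.gene_id: g.tts for g in genes},
        log2fc_effect=config.log2fc_effect,
    )
    result = SimResult(config=config, genes=genes, reads=reads,
                       labels=labels, truth=truth)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SimResult, out_dir: Path) -> None:
    from . import io as stio

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "genes.gtf", "wt") as fh:
        for g in result.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write("\t".join([
                g.chrom, "stsig_sim", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")
    for ds, rd in result.reads.items():
        stio.write_spatial_bed(rd, out_dir / f"{ds}.bed")
    stio.write_labels(result.labels, out_dir / "labels.tsv")
    payload = {"config": asdict(result.config),
               "truth": result.truth.to_json_dict()}
    with open(out_dir / "truth.json", "wt") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
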