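"""End-to-end orchestration: tracks in, segmentation + reports out.

The full flow mirrors a chromatin-state analysis of a heterochromatic
compartment: binarize occupancy tracks on a bin grid, train the 4-state HMM,
Viterbi-decode and label the states, convert the path to a segmentation, then
summarise state proportions, per-state protein enrichment and region feature
densities.  Identical config + inputs give byte-identical outputs; every
report carries a header with the package version, seed and a config hash.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hmm import (
    BernoulliHMM,
    binarize,
    label_states,
    path_to_segmentation,
    stack_tracks,
    train_hmm,
    viterbi_decode,
)
from .intervals import (
    FormatError,
    GenomicInterval,
    bin_genome,
    intervals_to_track,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
)
from .regions import (
    DensityReport,
    NamedRegion,
    feature_density,
    load_region_partition,
)
from .stats import enrichment_table, state_proportions

__all__ = ["PipelineConfig", "run_full", "run_density_report", "worked_example_report"]

log = logging.getLogger("chromstates")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the package conventions."""

    chrom_sizes: str = ""
    tracks_manifest: str = ""
    genes: str | None = None
    orc_sites: str | None = None
    partition: str | None = None
    outdir: str = "chromstates_out"
    bin_size: int = 200
    n_states: int = 4
    seed: int = 17
    n_restarts: int = 5
    quantile: float = 0.9
    alpha: float = 0.001
    counting_rule: str = "start_in"
    skip_unknown: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (output location excluded)."""
        d = asdict(self)
        d.pop("outdir")
        payload = repr(sorted(d.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _header(config: PipelineConfig, **extra) -> str:
    lines = [f"# chromstates {__version__}",
             f"# seed: {config.seed}",
             f"# config_hash: {config.config_hash()}",
             f"# bin_size: {config.bin_size}",
             f"# alpha: {config.alpha}"]
    lines += [f"# {k}: {v}" for k, v in extra.items()]
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path, config: PipelineConfig, **extra) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header(config, **extra))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def _read_manifest(path) -> list[tuple[str, str, str]]:
    rows = []
    base = os.path.dirname(os.path.abspath(path))
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, lineno, "manifest needs track_id, path, role")
            tid, tpath, role = fields[:3]
            if role not in ("promoter", "elongation", "other"):
                raise FormatError(path, lineno, f"unknown role {role!r}")
            if not os.path.isabs(tpath):
                tpath = os.path.join(base, tpath)
            rows.append((tid, tpath, role))
    if not rows:
        raise FormatError(path, None, "empty track manifest")
    return rows


def _load_track(tid, tpath, grid, skip_unknown):
    """Load one occupancy track; returns (track, is_peaks).

    bedGraph input is continuous signal (binarized later at a quantile); BED
    input is peak calls, already a binary presence/absence signal.
    """
    name = tpath[:-3] if tpath.endswith(".gz") else tpath
    if name.endswith((".bedgraph", ".bg")):
        track = read_bedgraph(tpath, grid, "mean", track_id=tid,
                              skip_unknown=skip_unknown)
        return track, False
    ivs = read_bed(tpath, grid.chrom_sizes, skip_unknown=skip_unknown)
    return intervals_to_track(ivs, grid, "presence", track_id=tid), True


def _binarize_track(track, is_peaks, quantile):
    """Peak tracks threshold at zero (any overlap = occupied); continuous
    tracks at the configured occupancy quantile."""
    if is_peaks:
        bt = binarize(track, 0.5)
        bt.bits = (track.values > 0).astype(np.uint8)
        bt.threshold = 0.0
        return bt
    return binarize(track, quantile)


def run_full(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Returns a summary dict (also written as ``summary.yml``) with the labeled
    model, state proportions, output paths and all parameters.
    """
    os.makedirs(config.outdir, exist_ok=True)
    log.info("reading genome and tracks")
    sizes = read_chrom_sizes(config.chrom_sizes)
    grid = bin_genome(sizes, config.bin_size)

    manifest = _read_manifest(config.tracks_manifest)
    marker_config = {}
    binarized = []
    for tid, tpath, role in manifest:
        track, is_peaks = _load_track(tid, tpath, grid, config.skip_unknown)
        binarized.append(_binarize_track(track, is_peaks, config.quantile))
        if role in ("promoter", "elongation") and role not in marker_config:
            marker_config[role] = tid
    matrix = stack_tracks(binarized)

    log.info("training %d-state HMM on %d tracks x %d bins",
             config.n_states, matrix.n_tracks, matrix.n_bins)
    model = train_hmm(matrix, K=config.n_states, seed=config.seed,
                      n_restarts=config.n_restarts)
    if config.n_states == 4 and {"promoter", "elongation"} <= set(marker_config):
        label_states(model, marker_config)
    labels = getattr(model, "labels_", None) or {}

    path = viterbi_decode(model, matrix)
    seg = path_to_segmentation(path, grid, labels)

    out = {}
    model_path = os.path.join(config.outdir, "model.yml")
    model.to_yaml(model_path)
    out["model"] = model_path
    seg_path = os.path.join(config.outdir, "states.bed")
    seg.to_bed(seg_path)
    out["segmentation"] = seg_path

    # regions: named partition where provided, otherwise the whole genome
    regions = []
    if config.partition:
        regions = [r for r in load_region_partition(config.partition)
                   if r.interval is not None]
    genome_regions = [GenomicInterval(c, 0, sizes[c]) for c in sizes]

    prop_rows = []
    props = state_proportions(seg, genome_regions, "genome")
    prop_rows += [{"compartment": "genome", "state": lab, "fraction": frac}
                  for lab, frac in sorted(props.fractions.items())]
    for r in regions:
        try:
            rp = state_proportions(seg, [r.interval], r.name)
        except ValueError:
            continue
        prop_rows += [{"compartment": r.name, "state": lab, "fraction": frac}
                      for lab, frac in sorted(rp.fractions.items())]
    prop_df = pd.DataFrame(prop_rows)
    prop_path = os.path.join(config.outdir, "proportions.tsv")
    _write_tsv(prop_df, prop_path, config)
    out["proportions"] = prop_path

    comp_regions = [r.interval for r in regions] or genome_regions
    comp_name = "+".join(r.name for r in regions) or "genome"
    tracks = [_load_track(tid, tpath, grid, config.skip_unknown)[0]
              for tid, tpath, _ in manifest]
    enr = enrichment_table(tracks, seg, comp_regions, genome_regions, grid,
                           alpha=config.alpha, compartment_name=comp_name)
    enr_path = os.path.join(config.outdir, "enrichment.tsv")
    _write_tsv(enr, enr_path, config, compartment=comp_name,
               sampling_unit=enr.attrs["sampling_unit"])
    out["enrichment"] = enr_path

    if config.genes and regions:
        dens = run_density_report(config, regions=regions)
        dens_path = os.path.join(config.outdir, "densities.tsv")
        _write_tsv(dens, dens_path, config)
        out["densities"] = dens_path

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_bins": int(grid.n_bins),
        "n_tracks": matrix.n_tracks,
        "log_likelihood": float(model.log_likelihood_),
        "converged": bool(model.converged_),
        "labels": {int(k): v for k, v in labels.items()},
        "genome_proportions": {lab: float(frac)
                               for lab, frac in sorted(props.fractions.items())},
        "significant_enrichments": int(enr["significant"].sum()),
        "outputs": out,
    }
    with open(os.path.join(config.outdir, "summary.yml"), "wt", encoding="utf-8") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    log.info("pipeline complete: %s", config.outdir)
    return summary


def run_density_report(config: PipelineConfig,
                       regions: list[NamedRegion] | None = None) -> pd.DataFrame:
    """Gene (and ORC-site) density per named region, one row per feature class."""
    if regions is None:
        if not config.partition:
            raise ValueError("no region partition configured")
        regions = [r for r in load_region_partition(config.partition)
                   if r.interval is not None]
    if not regions:
        raise ValueError("region partition contains no regions with coordinates")
    sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
    feature_sets = {}
    if config.genes:
        feature_sets["genes"] = read_bed(config.genes, sizes,
                                         skip_unknown=config.skip_unknown)
    if config.orc_sites:
        feature_sets["orc_sites"] = read_bed(config.orc_sites, sizes,
                                             skip_unknown=config.skip_unknown)
    if not feature_sets:
        raise ValueError("no annotation files configured")
    rows = []
    for fclass, features in feature_sets.items():
        for r in regions:
            rep = feature_density(features, r, config.counting_rule)
            rows.append({"region": r.name, "feature_class": fclass,
                         "length_mb": rep.length_mb, "count": rep.feature_count,
                         "density_per_mb": rep.density_per_mb,
                         "display_density": rep.display_density})
    return pd.DataFrame(rows)


def worked_example_report(entries: list[tuple[str, int, float]]) -> pd.DataFrame:
    """Density report from inline (name, count, length_mb) rows — no BED needed."""
    rows = []
    for name, count, length_mb in entries:
        rep = DensityReport.from_counts(name, count, length_mb)
        rows.append({"region": name, "length_mb": rep.length_mb,
                     "count": rep.feature_count,
                     "density_per_mb": rep.density_per_mb,
                     "display_density": rep.display_density})
    return pd.DataFrame(rows)


def plot_proportions(prop_df: pd.DataFrame, path) -> None:
    """Grouped bar chart of state fractions per compartment (one figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .hmm import STATE_RGB

    pivot = prop_df.pivot(index="compartment", columns="state", values="fraction")
    colors = [tuple(int(c) / 255 for c in STATE_RGB[s].split(","))
              if s in STATE_RGB else None for s in pivot.columns]
    ax = pivot.plot.bar(color=colors, figsize=(7, 4), rot=20)
    ax.set_ylabel("fraction of unmasked bp")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
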