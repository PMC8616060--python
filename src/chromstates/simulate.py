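"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: binarized
multi-protein occupancy sampled from a known 4-state chromatin HMM,
region-structured gene/ORC annotations with Poisson densities, and per-tissue
RPKM vectors realizing requested expression-category counts.  All generators
are pure functions of (spec, seed) — a single explicitly seeded pseudorandom
stream per call, no global state.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .hmm import (
    BernoulliHMM,
    BinarizedTrack,
    BinaryMatrix,
    path_to_segmentation,
    stack_tracks,
)
from .intervals import BinnedGenome, ChromSizes, GenomicInterval, write_bed
from .regions import ExpressionCategory, NamedRegion, save_region_partition

__all__ = [
    "DEFAULT_TRACK_IDS",
    "GeneratorSpec",
    "HetEuDataset",
    "default_truth_model",
    "generate_tracks",
    "generate_annotations",
    "generate_rpkm",
    "het_eu_preset",
    "simulate_dataset",
]

#: Marker tracks of the default truth model: an interband/promoter marker, a
#: transcription-elongation marker, two heterochromatin marks and two
#: chromatin-remodelling-associated proteins.
DEFAULT_TRACK_IDS = ["CHRIZ", "RNA-polII", "H3K9me2", "HP1", "SuVar3-9", "MRG15"]

_DEFAULT_EMISSIONS = np.array([
    # CHRIZ  polII  H3K9me2  HP1   SuVar  MRG15
    [0.90,  0.50,  0.10,   0.10, 0.10,  0.60],   # Aquamarine: promoters/interbands
    [0.15,  0.80,  0.30,   0.15, 0.30,  0.55],   # Lazurite: gene bodies
    [0.30,  0.30,  0.30,   0.30, 0.30,  0.30],   # Malachite: moderate bands
    [0.05,  0.05,  0.05,   0.05, 0.05,  0.05],   # Ruby: condensed, protein-poor
])

#: Variant with every pair of state profiles at least 0.4 apart in some track
#: (Malachite carries a moderate heterochromatin-mark signature), the
#: separation regime under which parameter-recovery guarantees are stated.
_SEPARATED_EMISSIONS = np.array([
    [0.90,  0.50,  0.10,   0.10, 0.10,  0.60],   # Aquamarine
    [0.15,  0.80,  0.30,   0.15, 0.30,  0.55],   # Lazurite
    [0.30,  0.30,  0.50,   0.45, 0.50,  0.30],   # Malachite
    [0.05,  0.05,  0.05,   0.05, 0.05,  0.05],   # Ruby
])

_DEFAULT_LABELS = {0: "Aquamarine", 1: "Lazurite", 2: "Malachite", 3: "Ruby"}


def default_truth_model(self_transition: float = 0.95,
                        strong_separation: bool = False) -> BernoulliHMM:
    """The 4-state, 6-track generating model used throughout the test suite.

    With ``strong_separation`` the Malachite profile carries a moderate
    H3K9me2/HP1/SuVar signature so that every pair of state profiles differs
    by at least 0.4 in some track; the default profiles keep Malachite flat at
    0.3, which leaves the Malachite–Ruby pair closer (0.25) and makes decoding
    slightly harder.
    """
    K = 4
    A = np.full((K, K), (1 - self_transition) / (K - 1))
    np.fill_diagonal(A, self_transition)
    E = _SEPARATED_EMISSIONS if strong_separation else _DEFAULT_EMISSIONS
    return BernoulliHMM.from_params(
        np.full(K, 1 / K), A, E,
        track_ids=DEFAULT_TRACK_IDS, labels=_DEFAULT_LABELS)


@dataclass
class GeneratorSpec:
    """Everything needed to generate a reproducible synthetic dataset."""

    seed: int = 17
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chrSim": 10_000_000})
    bin_size: int = 200
    hmm_truth: BernoulliHMM | None = None
    track_noise: float = 0.0  # per-bit flip probability
    gaps: list[GenomicInterval] = field(default_factory=list)
    region_densities: dict[NamedRegion, float] = field(default_factory=dict)
    feature_width: int = 500
    rpkm_spec: dict[ExpressionCategory, int] = field(default_factory=dict)
    n_tissues: int = 29

    def __post_init__(self):
        if not 0 <= self.track_noise < 0.5:
            raise ValueError("track_noise must be in [0, 0.5)")
        if any(d < 0 for d in self.region_densities.values()):
            raise ValueError("region densities must be >= 0")
        if self.hmm_truth is None:
            self.hmm_truth = default_truth_model()

    @property
    def grid(self) -> BinnedGenome:
        return BinnedGenome(ChromSizes(dict(self.chrom_sizes)), self.bin_size)


def _gap_mask(spec: GeneratorSpec, grid: BinnedGenome) -> np.ndarray:
    mask = np.ones(grid.n_bins, dtype=bool)
    from .intervals import intervals_to_track

    if spec.gaps:
        gap = intervals_to_track(spec.gaps, grid, "presence")
        mask &= gap.values == 0
    return mask


def generate_tracks(spec: GeneratorSpec) -> tuple[BinaryMatrix, np.ndarray]:
    """Sample (observation matrix, true state path) from the truth model.

    The state path is drawn chromosome by chromosome (each chromosome is an
    independent chain; assembly-gap bins are masked and split the chain
    further), bits come from the per-state Bernoulli emissions, and optional
    flip noise corrupts each bit independently.
    """
    model = spec.hmm_truth
    model._validate_params_arrays()
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    mask = _gap_mask(spec, grid)
    # chromosome boundaries also break the chain: build a per-chromosome mask
    X = np.zeros((grid.n_bins, model.emissionprob_.shape[1]), dtype=np.uint8)
    states = np.full(grid.n_bins, -1, dtype=np.int32)
    for chrom in grid.chrom_sizes:
        sl = grid.chrom_slice(chrom)
        sub_mask = mask[sl]
        if not sub_mask.any():
            continue
        Xc, sc = model.sample(sub_mask.size, random_state=rng, mask=sub_mask)
        X[sl] = Xc
        states[sl] = sc
    if spec.track_noise > 0:
        flips = rng.random(X.shape) < spec.track_noise
        obs = states >= 0
        X[obs] ^= flips[obs].astype(np.uint8)
    tracks = [BinarizedTrack(tid, X[:, m].copy(), mask.copy(), np.nan)
              for m, tid in enumerate(model.track_ids_ or
                                      [f"track{m}" for m in range(X.shape[1])])]
    return stack_tracks(tracks), states


def generate_annotations(spec: GeneratorSpec) -> list[GenomicInterval]:
    """Point-like features with region-dependent Poisson density.

    Per region the feature count is Poisson(density × length_mb); starts are
    uniform inside the region and features are short fixed-width intervals
    clipped to the region end.
    """
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    out: list[GenomicInterval] = []
    n_feat = 0
    for region, density in spec.region_densities.items():
        iv = region.interval
        if iv is None:
            raise ValueError(f"region {region.name!r} has unknown coordinates")
        iv.validate(grid.chrom_sizes)
        count = rng.poisson(density * region.length_mb)
        starts = np.sort(rng.integers(iv.start, iv.end, size=count))
        for s in starts:
            n_feat += 1
            out.append(GenomicInterval(
                iv.chrom, int(s), int(min(s + spec.feature_width, iv.end)),
                name=f"feature{n_feat}"))
    return out


_RPKM_RANGES = {
    ExpressionCategory.ExtremelyLowNone: (0.0, 1.0),
    ExpressionCategory.VeryLow: (1.0, 3.0),
    ExpressionCategory.Low: (4.0, 10.0),
    ExpressionCategory.Moderate: (11.0, 25.0),
    ExpressionCategory.ModerateHigh: (26.0, 50.0),
    ExpressionCategory.High: (51.0, 100.0),
    ExpressionCategory.VeryHigh: (101.0, 1000.0),
    ExpressionCategory.ExtremelyHigh: (1000.0 + 1e-9, 5000.0),
}


def generate_rpkm(spec: GeneratorSpec) -> np.ndarray:
    """A per-tissue RPKM vector realizing the requested category counts.

    Values are drawn uniformly inside each category's RPKM range and the
    vector is shuffled, so classifying it recovers the counts exactly.
    """
    total = sum(spec.rpkm_spec.values())
    if total != spec.n_tissues:
        raise ValueError(f"category counts sum to {total}, expected {spec.n_tissues}")
    rng = np.random.default_rng(spec.seed)
    values = []
    for cat, n in spec.rpkm_spec.items():
        lo, hi = _RPKM_RANGES[ExpressionCategory(cat)]
        values.extend(rng.uniform(lo, hi, size=n))
    values = np.array(values)
    rng.shuffle(values)
    return values


@dataclass
class HetEuDataset:
    """Two-compartment construction mirroring a het-vs-eu state comparison."""

    grid: BinnedGenome
    matrix: BinaryMatrix
    states: np.ndarray          # true generating path
    labels: dict[int, str]
    het_regions: list[GenomicInterval]
    eu_regions: list[GenomicInterval]
    het_target: dict[str, float]
    eu_target: dict[str, float]


def het_eu_preset(seed: int = 17, n_bins_per_compartment: int = 500_000,
                  bin_size: int = 200, mixing: float = 0.9) -> HetEuDataset:
    """Generate the heterochromatin-vs-euchromatin comparison scenario.

    Two compartments share the default emission profiles but differ in their
    state mix: the heterochromatic chain is constructed with a stationary Ruby
    fraction of 0.70 (active Aquamarine+Lazurite 0.10), the euchromatic chain
    with Ruby 0.519 (active 0.30) — so the active fraction in heterochromatin
    is one-third of the euchromatic one by construction.  Transition matrices
    are ``mixing * I + (1 - mixing) * 1 pi^T``, whose stationary distribution
    is exactly ``pi``.
    """
    pis = {
        "het": np.array([0.04, 0.06, 0.20, 0.70]),
        "eu": np.array([0.12, 0.18, 0.181, 0.519]),
    }
    sizes = ChromSizes({"chr3Het": n_bins_per_compartment * bin_size,
                        "chrEu": n_bins_per_compartment * bin_size})
    grid = BinnedGenome(sizes, bin_size)
    rng = np.random.default_rng(seed)
    X = np.zeros((grid.n_bins, len(DEFAULT_TRACK_IDS)), dtype=np.uint8)
    states = np.full(grid.n_bins, -1, dtype=np.int32)
    for chrom, key in (("chr3Het", "het"), ("chrEu", "eu")):
        pi = pis[key]
        A = mixing * np.eye(4) + (1 - mixing) * np.tile(pi, (4, 1))
        model = BernoulliHMM.from_params(pi, A, _DEFAULT_EMISSIONS,
                                         track_ids=DEFAULT_TRACK_IDS,
                                         labels=_DEFAULT_LABELS)
        sl = grid.chrom_slice(chrom)
        Xc, sc = model.sample(sl.stop - sl.start, random_state=rng)
        X[sl], states[sl] = Xc, sc
    tracks = [BinarizedTrack(tid, X[:, m].copy(),
                             np.ones(grid.n_bins, dtype=bool), np.nan)
              for m, tid in enumerate(DEFAULT_TRACK_IDS)]
    het_len = sizes["chr3Het"]
    eu_len = sizes["chrEu"]
    return HetEuDataset(
        grid=grid, matrix=stack_tracks(tracks), states=states,
        labels=dict(_DEFAULT_LABELS),
        het_regions=[GenomicInterval("chr3Het", 0, het_len)],
        eu_regions=[GenomicInterval("chrEu", 0, eu_len)],
        het_target={_DEFAULT_LABELS[k]: float(pis["het"][k]) for k in range(4)},
        eu_target={_DEFAULT_LABELS[k]: float(pis["eu"][k]) for k in range(4)},
    )


def simulate_dataset(spec: GeneratorSpec, outdir) -> dict[str, str]:
    """Write a complete synthetic input directory for the CLI pipeline.

    Emits chrom.sizes, one peak-interval BED per track plus a track manifest,
    gene and ORC annotation BEDs, a region partition, and a truth file
    (generating model as YAML plus the true segmentation as BED).  Returns the
    mapping of logical names to paths.
    """
    os.makedirs(outdir, exist_ok=True)
    grid = spec.grid
    matrix, states = generate_tracks(spec)
    paths: dict[str, str] = {}

    p = os.path.join(outdir, "chrom.sizes")
    with open(p, "wt", encoding="utf-8") as fh:
        for chrom, length in grid.chrom_sizes.entries.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_sizes"] = p

    track_dir = os.path.join(outdir, "tracks")
    os.makedirs(track_dir, exist_ok=True)
    manifest = os.path.join(outdir, "tracks.tsv")
    roles = {"CHRIZ": "promoter", "RNA-polII": "elongation"}
    with open(manifest, "wt", encoding="utf-8") as mfh:
        mfh.write("#track_id\tpath\trole\n")
        for m, tid in enumerate(matrix.track_ids):
            seg = path_to_segmentation(
                np.where(matrix.mask, matrix.data[m].astype(np.int32), -1), grid)
            peaks = [iv for iv, lab in seg if lab == "state1"]
            bed = os.path.join(track_dir, f"{tid}.bed")
            write_bed(peaks, bed)
            mfh.write(f"{tid}\t{bed}\t{roles.get(tid, 'other')}\n")
    paths["manifest"] = manifest

    genes = generate_annotations(spec)
    p = os.path.join(outdir, "genes.bed")
    write_bed(genes, p)
    paths["genes"] = p

    if spec.region_densities:
        p = os.path.join(outdir, "partition.tsv")
        save_region_partition(list(spec.region_densities), p)
        paths["partition"] = p

    p = os.path.join(outdir, "truth_model.yml")
    spec.hmm_truth.to_yaml(p)
    paths["truth_model"] = p
    p = os.path.join(outdir, "truth_states.bed")
    labels = getattr(spec.hmm_truth, "labels_", None) or {}
    path_to_segmentation(states, grid, labels).to_bed(p, rgb=False)
    paths["truth_states"] = p
    return paths
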