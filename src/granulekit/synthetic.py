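"""Synthetic inputs with known ground truth for every pipeline stage.

The generators here emulate the four input classes the quantification stages
consume, each alongside an exact truth record so recovery can be scored:

* multi-channel fluorescence scenes of Gaussian spot "granules" on noisy
  background, with the realized per-granule intensities, molecule partition
  fraction *f* and granule area fraction *v* computed on the pixel grid;
* FRAP traces following the first-order recovery model, optionally with
  acquisition photobleaching and Gaussian noise;
* per-gene read-count tables with a low-count control background and a
  heavy-tailed signal population in two replicates;
* short toeprint intervals placed on gene models with configurable
  5'UTR/CDS/3'UTR weights.

Spots are isotropic 2-D Gaussians truncated at 4 sigma, matching the
diffraction-limited appearance of sub-resolution granules while keeping
footprints finite.  All generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frap import FrapTrace
from .iclip import GeneModel

logger = logging.getLogger(__name__)

#: Spot footprint truncation radius, in units of sigma.
TRUNCATION_SIGMA = 4.0


@dataclass(frozen=True)
class GranuleSpec:
    """One spot: centre (x, y) in pixels, width sigma, per-channel peak AU."""

    center: tuple[float, float]
    sigma: float
    amplitude: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(a < 0 for a in self.amplitude):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class SceneTruth:
    """Inputs of a synthetic scene plus the quantities realized on the grid.

    ``partition_fraction`` per channel is the fraction of that channel's
    non-camera signal (spots + diffuse cytoplasm) lying inside the granule
    footprint mask — the molecule fraction *f* a perfect mask-based
    measurement recovers, which includes the cytoplasmic molecules sitting
    under the footprint.  ``volume_fraction`` *v* is the granule footprint
    area over the cell area (a 2-D stand-in for the granule volume fraction).
    """

    granules: tuple[GranuleSpec, ...]
    background_mean: float
    background_sd: float
    pixel_size: float = 0.1  # micrometres per pixel
    cytoplasm_level: tuple[float, ...] = ()
    # realized on the pixel grid by make_image:
    granule_intensity: np.ndarray | None = None  # (n_granules, n_channels)
    channel_fractions: np.ndarray | None = None  # (n_granules, n_channels)
    partition_fraction: np.ndarray | None = None  # f per channel
    volume_fraction: float | None = None  # v
    granule_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background sd must be non-negative")


def _spot_footprint(
    shape: tuple[int, int], g: GranuleSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel rows, cols and unit-amplitude Gaussian values inside 4 sigma."""
    cx, cy = g.center
    r = TRUNCATION_SIGMA * g.sigma
    y0, y1 = max(0, int(np.floor(cy - r))), min(shape[0], int(np.ceil(cy + r)) + 1)
    x0, x1 = max(0, int(np.floor(cx - r))), min(shape[1], int(np.ceil(cx + r)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    inside = d2 <= r * r
    vals = np.exp(-d2 / (2.0 * g.sigma**2)) * inside
    return yy[inside], xx[inside], vals[inside]


def make_image(
    scene: SceneTruth, shape: tuple[int, int], seed: int
) -> tuple[np.ndarray, SceneTruth]:
    """Render a scene into a (channels, y, x) image plus its realized truth.

    Each channel is Gaussian camera noise around the background mean, plus an
    optional uniform diffuse cytoplasm level, plus the sum of truncated
    Gaussian spots.  The returned truth record carries the per-granule
    integrated intensities, per-channel partition fraction and the granule
    footprint area fraction, all computed by direct summation on the pixel
    grid.
    """
    rng = np.random.default_rng(seed)
    n_ch = len(scene.granules[0].amplitude) if scene.granules else max(len(scene.cytoplasm_level), 1)
    for g in scene.granules:
        if len(g.amplitude) != n_ch:
            raise ValueError("all granules must define the same channel count")
        cx, cy = g.center
        r = TRUNCATION_SIGMA * g.sigma
        if not (-r <= cx < shape[1] + r and -r <= cy < shape[0] + r):
            raise ValueError(f"granule at {g.center} lies outside the image")

    cyto = scene.cytoplasm_level or tuple(0.0 for _ in range(n_ch))
    image = rng.normal(scene.background_mean, scene.background_sd, size=(n_ch,) + tuple(shape))
    image += np.asarray(cyto, dtype=float)[:, None, None]

    n_pix = shape[0] * shape[1]
    granule_I = np.zeros((len(scene.granules), n_ch))
    mask = np.zeros(shape, dtype=bool)
    for i, g in enumerate(scene.granules):
        rows, cols, vals = _spot_footprint(shape, g)
        mask[rows, cols] = True
        for c in range(n_ch):
            spot = g.amplitude[c] * vals
            image[c, rows, cols] += spot
            granule_I[i, c] = spot.sum()

    spot_total = granule_I.sum(axis=0)
    cyto_arr = np.asarray(cyto, dtype=float)
    cyto_total = cyto_arr * n_pix
    signal_total = spot_total + cyto_total
    in_mask = spot_total + cyto_arr * mask.sum()  # spots are fully inside the mask
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(signal_total > 0, in_mask / np.maximum(signal_total, 1e-300), np.nan)
        fractions = np.where(
            spot_total > 0, granule_I / np.maximum(spot_total, 1e-300), 0.0
        )
    realized = SceneTruth(
        granules=scene.granules,
        background_mean=scene.background_mean,
        background_sd=scene.background_sd,
        pixel_size=scene.pixel_size,
        cytoplasm_level=tuple(cyto),
        granule_intensity=granule_I,
        channel_fractions=fractions,
        partition_fraction=f,
        volume_fraction=float(mask.sum() / n_pix),
        granule_mask=mask,
    )
    return image, realized


def place_centers(
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    seed: int,
    margin: float = 0.0,
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    """Rejection-sample n spot centres with a minimum pairwise distance."""
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} centres with separation {min_separation} "
                f"in shape {shape}; lower the density"
            )
        x = rng.uniform(margin, shape[1] - margin)
        y = rng.uniform(margin, shape[0] - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_separation**2 for cx, cy in centers):
            centers.append((x, y))
    return centers


def scene_for_partition(
    f: float,
    v: float,
    shape: tuple[int, int] = (256, 256),
    sigma: float = 1.5,
    amplitude: float = 400.0,
    background: tuple[float, float] = (100.0, 5.0),
    pixel_size: float = 0.1,
    seed: int = 0,
) -> SceneTruth:
    """Build a single-channel scene targeting partition fraction f and
    granule area fraction v.

    The granule count follows from v and the spot footprint area; the diffuse
    cytoplasm level follows from f and the total spot signal.  The exact
    realized f and v land on the pixel grid and are reported by
    :func:`make_image`.
    """
    if not (0 < f < 1) or not (0 < v < 1):
        raise ValueError("f and v must lie strictly inside (0, 1)")
    if f <= v:
        raise ValueError("f must exceed v; granules cannot be dimmer than cytoplasm")
    n_pix = shape[0] * shape[1]
    footprint = np.pi * (TRUNCATION_SIGMA * sigma) ** 2
    n = max(1, int(round(v * n_pix / footprint)))
    centers = place_centers(
        n, shape, min_separation=2 * TRUNCATION_SIGMA * sigma, seed=seed,
        margin=TRUNCATION_SIGMA * sigma,
    )
    granules = tuple(
        GranuleSpec(center=c, sigma=sigma, amplitude=(amplitude,)) for c in centers
    )
    spot_integral = amplitude * 2.0 * np.pi * sigma**2  # truncation loss ~3e-4
    total_spot = n * spot_integral
    # the mask-based f counts cytoplasm under the footprint as granule signal:
    # f = (S + c*A) / (S + c*N)  with footprint area A ~ v*N
    v_eff = n * footprint / n_pix
    cyto = total_spot * (1.0 - f) / (n_pix * (f - v_eff))
    return SceneTruth(
        granules=granules,
        background_mean=background[0],
        background_sd=background[1],
        pixel_size=pixel_size,
        cytoplasm_level=(cyto,),
    )


@dataclass(frozen=True)
class FrapTruth:
    """Parameters of the first-order FRAP forward model.

    Post-bleach normalized intensity is
    ``nI(t) = bleach_depth + a_rec * (1 - exp(-k * (t - t_bleach)))``;
    the whole raw trace decays as ``exp(-photobleach_rate * t)`` and Gaussian
    noise of sd ``noise_sd`` (normalized units) is added.
    """

    a_rec: float = 0.8
    k: float = 0.02  # 1/s
    bleach_depth: float = 0.2
    photobleach_rate: float = 0.0  # 1/s
    noise_sd: float = 0.0
    dt: float = 3.0  # s between frames
    n_frames: int = 100
    n_prebleach: int = 5
    intensity_scale: float = 1000.0  # AU of the unbleached granule
    background_level: float = 100.0  # AU

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_rec <= 1.0:
            raise ValueError("a_rec must lie in [0, 1]")
        if self.k < 0 or self.photobleach_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_frames < 3 or not (0 < self.n_prebleach < self.n_frames):
            raise ValueError("need >= 3 frames with the bleach inside the trace")

    def normalized_ideal(self, times: np.ndarray) -> np.ndarray:
        """Noise-free nI(t) before photobleaching."""
        t_bleach = times[self.n_prebleach]
        post = self.bleach_depth + self.a_rec * (1.0 - np.exp(-self.k * (times - t_bleach)))
        return np.where(np.arange(times.size) < self.n_prebleach, 1.0, post)


def make_frap_trace(truth: FrapTruth, seed: int) -> tuple[FrapTrace, FrapTruth]:
    """Simulate one FRAP trace (AU intensity + background columns)."""
    rng = np.random.default_rng(seed)
    times = np.arange(truth.n_frames) * truth.dt
    n_ideal = truth.normalized_ideal(times)
    decayed = n_ideal * np.exp(-truth.photobleach_rate * times)
    noisy = decayed + rng.normal(0.0, truth.noise_sd, size=times.size)
    span = truth.intensity_scale - truth.background_level
    intensity = truth.background_level + span * noisy
    background = np.full(times.size, truth.background_level)
    trace = FrapTrace(
        times=times,
        intensity=intensity,
        background=background,
        bleach_index=truth.n_prebleach,
    )
    return trace, truth


@dataclass(frozen=True)
class CountTruth:
    """Generating law of a synthetic iCLIP count table.

    The control library and unbound genes draw from a negative-binomial
    background (low counts); bound genes draw from a shifted log-normal
    signal tail in both replicates, reproducing the background-vs-signal
    separation the thresholding rule assumes.
    """

    n_genes: int = 1000
    n_bound: int = 60
    control_nb: tuple[float, float] = (2.0, 0.2)  # numpy (n, p): mean n(1-p)/p = 8
    signal_lognorm: tuple[float, float, float] = (5.0, 0.8, 40.0)  # mu, sigma, shift
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_bound <= self.n_genes:
            raise ValueError("n_bound must not exceed n_genes")


def make_count_table(truth: CountTruth) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Simulate (control, rep1, rep2) counts; returns the table and the ids
    of the genes drawn from the signal law.

    The index is ``gene_0001``-style ids; bound genes are a random subset.
    Ground truth for any threshold comes from direct enumeration of the
    realized counts (see :func:`truly_bound`).
    """
    rng = np.random.default_rng(truth.seed)
    ids = [f"gene_{i:05d}" for i in range(truth.n_genes)]
    bound_idx = rng.choice(truth.n_genes, size=truth.n_bound, replace=False)
    bound = np.zeros(truth.n_genes, dtype=bool)
    bound[bound_idx] = True

    r, p = truth.control_nb
    mu, sg, shift = truth.signal_lognorm

    def background(size: int) -> np.ndarray:
        return rng.negative_binomial(r, p, size=size)

    def signal(size: int) -> np.ndarray:
        return np.round(shift + rng.lognormal(mu, sg, size=size)).astype(int)

    control = background(truth.n_genes)
    rep1 = background(truth.n_genes)
    rep2 = background(truth.n_genes)
    rep1[bound] = signal(truth.n_bound)
    rep2[bound] = signal(truth.n_bound)

    table = pd.DataFrame(
        {"control": control, "rep1": rep1, "rep2": rep2},
        index=pd.Index(ids, name="gene_id"),
    )
    table["length"] = rng.integers(500, 5000, size=truth.n_genes)
    return table, tuple(np.array(ids)[bound])


def truly_bound(table: pd.DataFrame, threshold: float) -> tuple[str, ...]:
    """Ground-truth enumeration: genes at/above threshold in both replicates."""
    out = [
        gid
        for gid, row in table.iterrows()
        if row["rep1"] >= threshold and row["rep2"] >= threshold
    ]
    return tuple(out)


def make_gene_models(
    n: int,
    seed: int,
    chrom: str = "chrI",
    len_utr5: tuple[int, int] = (100, 300),
    len_cds: tuple[int, int] = (600, 2400),
    len_utr3: tuple[int, int] = (150, 600),
    spacing: int = 3000,
) -> list[GeneModel]:
    """Lay out n non-overlapping single-isoform gene models on one chromosome,
    alternating strands."""
    rng = np.random.default_rng(seed)
    models = []
    cursor = spacing
    for i in range(n):
        l5 = int(rng.integers(*len_utr5))
        lc = int(rng.integers(*len_cds))
        l3 = int(rng.integers(*len_utr3))
        strand = "+" if i % 2 == 0 else "-"
        start = cursor
        end = start + l5 + lc + l3
        models.append(
            GeneModel(
                gene_id=f"g{i:04d}", chrom=chrom, start=start, end=end,
                strand=strand, len_utr5=l5, len_cds=lc, len_utr3=l3,
            )
        )
        cursor = end + spacing
    return models


def make_toeprints(
    models: list[GeneModel],
    region_weights: tuple[float, float, float],
    n: int,
    seed: int,
    length: int = 20,
) -> pd.DataFrame:
    """Place n toeprint intervals on the models by 5'UTR/CDS/3'UTR weight.

    For each toeprint a gene is drawn uniformly, a region by the weights
    (weights of regions a gene lacks are redistributed proportionally, with a
    log message), and the strand-aware 5' end uniformly within the region.
    Returns a BED6-style frame (chrom, start, end, name, score, strand) in
    0-based half-open genomic coordinates.
    """
    w = np.asarray(region_weights, dtype=float)
    if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("region weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    regions = ("utr5", "cds", "utr3")
    rows = []
    for i in range(n):
        g = models[int(rng.integers(len(models)))]
        lens = np.array([g.len_utr5, g.len_cds, g.len_utr3], dtype=float)
        wg = w * (lens > 0)
        if wg.sum() == 0:
            continue  # weights only on regions this gene lacks
        if wg.sum() < 1.0 - 1e-12:
            logger.info(
                "toeprints: gene %s lacks a weighted region; weights renormalized",
                g.gene_id,
            )
        wg = wg / wg.sum()
        region = regions[int(rng.choice(3, p=wg))]
        lo, hi = g.region_bounds(region)
        tpos = int(rng.integers(lo, hi))  # transcript-oriented 5' end
        g5 = g.transcript_to_genomic(tpos)
        if g.strand == "+":
            start, end = g5, min(g5 + length, g.end)
        else:
            start, end = max(g5 - length + 1, g.start), g5 + 1
        rows.append((g.chrom, start, end, f"tp{i:06d}", 0, g.strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
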