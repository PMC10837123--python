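"""Synthetic ground-truth generators for every input the pipeline consumes.

The quantification procedures in this package (edge-strip association
scoring, skeleton morphometrics, mixing colocalization, import-trace
normalisation, TMRM correction, pulldown enrichment statistics) were
designed for microscopy and plate-reader data that cannot be bundled with
the code.  This module fabricates each input with a known ground truth so
that every downstream estimator can be tested as a recovery problem:

* tubular mitochondrial phantoms with controllable fragmentation, width
  and curvature, plus a noiseless per-tube label map;
* a precursor channel in which a chosen fraction of organelles carries an
  exterior "enveloping" shell (the surface-association phenotype);
* two-population mixing images in which a chosen fraction of organelles
  is labelled in both channels;
* split-luciferase import traces: a 30 s luminescence baseline followed
  by a saturating rise, in technical triplicate with a per-well
  fluorescence normaliser;
* TMRM time series with a protonophore (CCCP)-induced potential collapse;
* protein intensity tables with a planted enriched subset.

All randomness flows through one ``numpy.random.Generator`` seeded per
call; the same seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .preprocess import ImageStack

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "round_half_away",
    "gen_mito_image",
    "gen_association_channel",
    "gen_mixing_image",
    "gen_import_traces",
    "gen_import_run",
    "gen_tmrm_series",
    "gen_protein_table",
]


# ---------------------------------------------------------------------------
# parameter / ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomParams:
    """Geometry, optics and noise of a tubular-network phantom.

    Parameters
    ----------
    image_shape : (H, W) in pixels.
    n_tubes : number of tubules drawn; fragmentation is controlled jointly
        by ``n_tubes`` and ``tube_length_range``.
    tube_length_range : (min, max) centreline length in pixels.
    tube_radius : tube half-width in pixels (>= 1).
    curvature : sd of the per-step heading change in radians; 0 gives
        straight tubes.
    branch_prob : probability that a tube sprouts one side branch.
    psf_sigma : Gaussian point-spread sd in pixels (0 disables blurring).
    gaussian_sd : additive read-noise sd in intensity units.
    poisson : apply Poisson (shot) noise before the Gaussian read noise.
    tube_intensity : plateau intensity of a tube interior.
    seed : fully determines the output.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_tubes: int = 30
    tube_length_range: tuple[float, float] = (20.0, 60.0)
    tube_radius: float = 2.0
    curvature: float = 0.15
    branch_prob: float = 0.0
    psf_sigma: float = 1.0
    gaussian_sd: float = 2.0
    poisson: bool = False
    tube_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_radius < 1:
            raise ValueError("tube_radius must be >= 1 pixel")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        lo, hi = self.tube_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("tube_length_range must be 0 < min <= max")


@dataclass
class GroundTruth:
    """Known truth accompanying a synthetic dataset.

    Only the fields relevant to the generator that produced it are filled;
    the rest keep their neutral defaults.
    """

    label_map: np.ndarray | None = None
    associated_labels: set[int] = field(default_factory=set)
    true_association_fraction: float | None = None
    dual_labels: set[int] = field(default_factory=set)
    true_mixing_pcc_regime: str | None = None  # "mixed" | "unmixed"
    true_amplitude: float | None = None
    true_reduction: float | None = None
    true_enriched_ids: set[str] = field(default_factory=set)
    overlap_pairs: set[tuple[int, int]] = field(default_factory=set)

    @property
    def labels(self) -> set[int]:
        if self.label_map is None:
            return set()
        return set(np.unique(self.label_map)) - {0}

    @property
    def n_objects(self) -> int:
        return len(self.labels)

    def to_json(self, path) -> None:
        payload = {}
        for key, val in asdict(self).items():
            if key == "label_map":
                continue
            if isinstance(val, set):
                val = sorted(val)
            payload[key] = val
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used to convert ``fraction * n_objects`` into an object count; banker's
    rounding would make count-recovery tests depend on parity.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# tubular phantoms
# ---------------------------------------------------------------------------

def _tube_path(rng: np.random.Generator, shape: tuple[int, int],
               length: float, curvature: float, margin: float) -> np.ndarray:
    """Random smooth centreline as an (n, 2) float array of (row, col)."""
    h, w = shape
    start = np.array([rng.uniform(margin, h - margin),
                      rng.uniform(margin, w - margin)])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    n_steps = max(int(round(length)), 2)
    pts = np.empty((n_steps, 2))
    pts[0] = start
    pos = start.copy()
    for i in range(1, n_steps):
        heading += rng.normal(0.0, curvature)
        step = np.array([np.sin(heading), np.cos(heading)])
        pos = pos + step
        # reflect off the margins so tubes stay in frame
        for ax, limit in ((0, h), (1, w)):
            if pos[ax] < margin or pos[ax] > limit - margin:
                pos[ax] = np.clip(pos[ax], margin, limit - margin)
                heading = np.pi - heading if ax == 1 else -heading
        pts[i] = pos
    return pts


def _rasterize_tube(path: np.ndarray, radius: float,
                    shape: tuple[int, int]) -> tuple[np.ndarray, tuple]:
    """Anti-aliased tube footprint in a local bounding box.

    Returns (intensity in [0, 1], bbox slices).  A pixel is fully inside
    when its centre is within ``radius`` of the centreline; coverage ramps
    linearly over the following pixel for a 1-px anti-aliasing band.
    """
    pad = int(np.ceil(radius)) + 2
    r0 = max(int(np.floor(path[:, 0].min())) - pad, 0)
    r1 = min(int(np.ceil(path[:, 0].max())) + pad + 1, shape[0])
    c0 = max(int(np.floor(path[:, 1].min())) - pad, 0)
    c1 = min(int(np.ceil(path[:, 1].max())) + pad + 1, shape[1])
    box = np.ones((r1 - r0, c1 - c0), dtype=bool)
    rr = np.clip(np.round(path[:, 0]).astype(int) - r0, 0, box.shape[0] - 1)
    cc = np.clip(np.round(path[:, 1]).astype(int) - c0, 0, box.shape[1] - 1)
    box[rr, cc] = False
    dist = ndi.distance_transform_edt(box)
    cover = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return cover, (slice(r0, r1), slice(c0, c1))


def gen_mito_image(params: PhantomParams) -> tuple[ImageStack, GroundTruth]:
    """Render a tubular mitochondrial phantom plus its noiseless label map.

    The label map assigns each pixel the index (1-based, draw order) of
    the tube whose centreline it belongs to; where tubes overlap the later
    tube wins, and any pair of tubes that overlaps or touches (8-adjacency,
    under which connected components merge) is recorded in
    ``GroundTruth.overlap_pairs`` so object-count oracles can account for
    merges exactly.

    Raises
    ------
    ValueError
        If the image is too small to place a tube at all.
    """
    h, w = params.image_shape
    margin = params.tube_radius + 3.0
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(
            f"image_shape {params.image_shape} too small for tubes of "
            f"radius {params.tube_radius}")

    rng = np.random.default_rng(params.seed)
    clean = np.zeros((h, w), dtype=np.float64)
    label_map = np.zeros((h, w), dtype=np.int32)
    overlap_pairs: set[tuple[int, int]] = set()

    for idx in range(1, params.n_tubes + 1):
        length = rng.uniform(*params.tube_length_range)
        path = _tube_path(rng, (h, w), length, params.curvature, margin)
        if params.branch_prob > 0 and rng.uniform() < params.branch_prob:
            k = rng.integers(1, len(path) - 1)
            branch = _tube_path(rng, (h, w), length / 2.0,
                                params.curvature, margin)
            branch = branch - branch[0] + path[k]
            branch[:, 0] = np.clip(branch[:, 0], margin, h - margin)
            branch[:, 1] = np.clip(branch[:, 1], margin, w - margin)
            path = np.vstack([path, branch])
        cover, sl = _rasterize_tube(path, params.tube_radius, (h, w))
        core = cover >= 0.5
        # record overlap OR contact: 8-connected components merge on touch
        halo = ndi.binary_dilation(core, structure=np.ones((3, 3)))
        hit = np.unique(label_map[sl][halo])
        for other in hit:
            if other:
                overlap_pairs.add((int(other), idx))
        clean[sl] = np.maximum(clean[sl], params.tube_intensity * cover)
        label_map[sl][core] = idx

    noisy = clean.copy()
    if params.psf_sigma > 0:
        noisy = ndi.gaussian_filter(noisy, params.psf_sigma)
    if params.poisson:
        noisy = rng.poisson(np.clip(noisy, 0, None)).astype(np.float64)
    if params.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, params.gaussian_sd, noisy.shape)

    stack = ImageStack(pixels=noisy[np.newaxis], axes="CYX",
                       channel_names=["mito"])
    truth = GroundTruth(label_map=label_map, overlap_pairs=overlap_pairs)
    return stack, truth


def gen_association_channel(truth: GroundTruth, fraction: float,
                            shell_intensity: float = 100.0,
                            shell_width: float = 4.0,
                            seed: int = 0, *,
                            psf_sigma: float = 1.0,
                            gaussian_sd: float = 10.0) -> np.ndarray:
    """Second (precursor) channel: exterior shells on a subset of objects.

    ``round_half_away(fraction * n_objects)`` objects, chosen uniformly at
    random, receive a shell occupying the exterior distance band
    (0, ``shell_width``] around their boundary; the shell pixels are those
    whose nearest object is the shelled one, mirroring how the edge-strip
    scorer assigns contested pixels.  ``truth.associated_labels`` and
    ``truth.true_association_fraction`` are updated in place.

    The default ``shell_intensity / gaussian_sd`` = 10 is the weakest
    signal-to-noise regime the recovery tests target.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if shell_intensity < 0:
        raise ValueError("shell_intensity must be non-negative")
    if truth.label_map is None:
        raise ValueError("GroundTruth carries no label_map")

    rng = np.random.default_rng(seed)
    labels = sorted(truth.labels)
    n_pick = round_half_away(fraction * len(labels))
    picked = set(int(v) for v in rng.choice(labels, size=n_pick,
                                            replace=False)) if n_pick else set()

    dist, (ir, ic) = ndi.distance_transform_edt(
        truth.label_map == 0, return_indices=True)
    owner = truth.label_map[ir, ic]
    shell = (dist > 0) & (dist <= shell_width) & np.isin(owner, list(picked))

    clean = np.where(shell, float(shell_intensity), 0.0)
    if psf_sigma > 0:
        clean = ndi.gaussian_filter(clean, psf_sigma)
    if gaussian_sd > 0:
        clean = clean + rng.normal(0.0, gaussian_sd, clean.shape)

    truth.associated_labels = picked
    truth.true_association_fraction = (
        len(picked) / len(labels) if labels else 0.0)
    return clean


def gen_mixing_image(mix_fraction: float, params: PhantomParams,
                     seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    """Two-channel phantom of intercellular mitochondrial mixing.

    A fraction ``mix_fraction`` of organelles carries signal in both the
    green and red channels (mitochondria that have exchanged material);
    the remainder alternates between green-only and red-only populations.
    """
    if not 0.0 <= mix_fraction <= 1.0:
        raise ValueError("mix_fraction must lie in [0, 1]")
    geom = PhantomParams(**{**asdict(params), "seed": seed})
    base, truth = gen_mito_image(
        PhantomParams(**{**asdict(geom), "psf_sigma": 0.0,
                         "gaussian_sd": 0.0, "poisson": False}))
    label_map = truth.label_map
    labels = sorted(truth.labels)
    rng = np.random.default_rng(seed + 1)

    n_dual = round_half_away(mix_fraction * len(labels))
    order = rng.permutation(labels)
    dual = set(int(v) for v in order[:n_dual])
    singles = [int(v) for v in order[n_dual:]]
    green_only = set(singles[0::2])
    red_only = set(singles[1::2])

    clean = base.pixels[0]
    green = np.where(np.isin(label_map, list(dual | green_only)), clean, 0.0)
    red = np.where(np.isin(label_map, list(dual | red_only)), clean, 0.0)

    out = np.empty((2,) + clean.shape)
    for i, chan in enumerate((green, red)):
        img = ndi.gaussian_filter(chan, params.psf_sigma) \
            if params.psf_sigma > 0 else chan
        if params.gaussian_sd > 0:
            img = img + rng.normal(0.0, params.gaussian_sd, img.shape)
        out[i] = img

    truth.dual_labels = dual
    truth.true_mixing_pcc_regime = "mixed" if mix_fraction >= 0.5 else "unmixed"
    stack = ImageStack(pixels=out, axes="CYX",
                       channel_names=["green", "red"])
    return stack, truth


# ---------------------------------------------------------------------------
# plate-reader traces
# ---------------------------------------------------------------------------

def gen_import_traces(amplitude: float, rate: float = 0.01, lag: float = 0.0,
                      baseline_s: float = 30.0, duration_s: float = 1800.0,
                      dt: float = 6.0, noise_sd: float = 0.0,
                      n_technical: int = 3, fluor_value: float = 1.0,
                      condition: str = "condition", seed: int = 0,
                      well_prefix: str = "A") -> pd.DataFrame:
    """Split-luciferase import traces for one condition, long format.

    Each technical replicate reads background noise for ``baseline_s``
    seconds (the pre-injection luminescence baseline), then follows a
    lagged saturating exponential
    ``amplitude * (1 - exp(-rate * (t - baseline_s - lag)))`` plus noise.
    Raw luminescence is scaled by ``fluor_value`` — the per-well eqFP670
    fluorescence recorded in the ``eqfp670_fluor`` column — so that the
    normalisation pipeline has a real per-well factor to divide out.

    Columns: time_s, well, condition, technical_rep, luminescence,
    eqfp670_fluor.
    """
    if fluor_value <= 0:
        raise ValueError("fluor_value must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 0.5 * dt, dt)
    rise = np.where(
        t > baseline_s + lag,
        amplitude * (1.0 - np.exp(-rate * np.clip(t - baseline_s - lag, 0, None))),
        0.0)
    frames = []
    for rep in range(1, n_technical + 1):
        noise = rng.normal(0.0, noise_sd, t.shape) if noise_sd > 0 else 0.0
        frames.append(pd.DataFrame({
            "time_s": t,
            "well": f"{well_prefix}{rep}",
            "condition": condition,
            "technical_rep": rep,
            "luminescence": fluor_value * (rise + noise),
            "eqfp670_fluor": float(fluor_value),
        }))
    return pd.concat(frames, ignore_index=True)


def gen_import_run(amplitudes: dict[str, float], seed: int = 0,
                   **kwargs) -> pd.DataFrame:
    """One plate-reader run: several conditions sharing acquisition settings.

    ``amplitudes`` maps condition name -> true amplitude; per-well eqFP670
    values are drawn log-uniformly in [0.5, 2] to exercise stage-1
    normalisation. Remaining keyword arguments pass through to
    :func:`gen_import_traces`.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for i, (cond, amp) in enumerate(amplitudes.items()):
        fluor = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        frames.append(gen_import_traces(
            amplitude=amp, condition=cond, fluor_value=fluor,
            seed=int(rng.integers(0, 2**31 - 1)),
            well_prefix=chr(ord("A") + i), **kwargs))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# TMRM time series
# ---------------------------------------------------------------------------

def gen_tmrm_series(n_frames: int = 20, cccp_frame: int = 14,
                    mito_intensity: float = 100.0,
                    post_cccp_intensity: float = 0.0,
                    image_shape: tuple[int, int] = (128, 128),
                    n_objects: int = 8, noise_sd: float = 0.0,
                    seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    """TMRM movie: polarised mitochondria, then a CCCP-induced collapse.

    Frames ``0 .. cccp_frame-1`` show objects at ``mito_intensity``;
    from ``cccp_frame`` onwards their intensity drops to
    ``post_cccp_intensity`` (residual dye), emulating protonophore
    depolarisation used as the background control.
    """
    if not 0 < cccp_frame <= n_frames:
        raise ValueError("cccp_frame must lie in (0, n_frames]")
    params = PhantomParams(image_shape=image_shape, n_tubes=n_objects,
                           tube_length_range=(8.0, 20.0), tube_radius=2.0,
                           psf_sigma=0.0, gaussian_sd=0.0, seed=seed)
    _, truth = gen_mito_image(params)
    objects = truth.label_map > 0
    rng = np.random.default_rng(seed)
    movie = np.empty((n_frames,) + tuple(image_shape))
    for f in range(n_frames):
        level = mito_intensity if f < cccp_frame else post_cccp_intensity
        frame = np.where(objects, level, 0.0)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        movie[f] = frame
    stack = ImageStack(pixels=movie, axes="TYX", channel_names=["tmrm"])
    return stack, truth


# ---------------------------------------------------------------------------
# protein intensity tables
# ---------------------------------------------------------------------------

def gen_protein_table(n_proteins: int = 2000, n_enriched: int = 100,
                      log2_effect: float = 2.0, replicate_sd: float = 0.5,
                      n_reps: int = 3, seed: int = 0
                      ) -> tuple[pd.DataFrame, GroundTruth]:
    """Pulldown intensity table with a planted enriched subset.

    Log-normal protein abundances over ``n_reps`` biological replicates
    per group (the trapped-precursor "+MTX" pulldown versus the imported
    "-MTX" control).  The first ``n_enriched`` proteins are shifted by
    ``log2_effect`` on the log2 scale in the +MTX group; replicate scatter
    has sd ``replicate_sd`` log2 units.

    Returns the table (rows = proteins, columns ``minusMTX_i`` /
    ``plusMTX_i``) indexed by protein id, and the ground truth holding the
    planted ids.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    base = rng.normal(20.0, 2.0, n_proteins)

    cols = {}
    for rep in range(1, n_reps + 1):
        cols[f"minusMTX_{rep}"] = base + rng.normal(0, replicate_sd, n_proteins)
    effect = np.zeros(n_proteins)
    effect[:n_enriched] = log2_effect
    for rep in range(1, n_reps + 1):
        cols[f"plusMTX_{rep}"] = (base + effect
                                  + rng.normal(0, replicate_sd, n_proteins))
    table = pd.DataFrame({k: np.exp2(v) for k, v in cols.items()}, index=ids)
    table.index.name = "protein_id"
    truth = GroundTruth(true_enriched_ids=set(ids[:n_enriched]))
    return table, truth
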