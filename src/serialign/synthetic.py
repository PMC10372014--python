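"""Synthetic serial-section series with known ground truth.

Emulates the structure of a stack of serial histology sections: one
"tissue" (a smooth random blob with Perlin-like texture and scattered
dark nuclei) on a bright slide background, re-imaged once per section
with a different simulated stain, a random rigid displacement, and a
smooth random non-rigid deformation.  Nuclei centroids are tracked
through the exact ground-truth warps, giving corresponding landmarks in
every image for registration-error evaluation.

Simulated staining uses Beer-Lambert absorbance with one RGB absorbance
vector per image, which reproduces the stain-to-stain colour variation
that the chroma standardization step must cancel, without attempting a
physical stain model.

All randomness comes from a single seeded generator: the same seed
always yields a bit-identical series.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

__all__ = ["SyntheticParams", "SyntheticSeries", "generate_series",
           "generate_fluorescence_series", "write_series"]

# absorbance vectors loosely mimicking common chromogens
# (hematoxylin, DAB, Fast Red, eosin, aniline blue)
DEFAULT_PALETTE = [
    (0.65, 0.70, 0.29),
    (0.27, 0.57, 0.78),
    (0.21, 0.80, 0.55),
    (0.09, 0.95, 0.28),
    (0.74, 0.41, 0.53),
]


@dataclass
class SyntheticParams:
    """Generator settings.

    Sizes are pixels at registration scale; ``max_translation_frac`` is a
    fraction of the image width; the deformation is a Gaussian-smoothed
    random field with peak magnitude ``deformation_amplitude_px`` and
    correlation length ``deformation_sigma_px``.
    """

    n_images: int = 5
    size: int = 850
    max_rotation_deg: float = 10.0
    max_translation_frac: float = 0.05
    deformation_amplitude_px: float = 5.0
    deformation_sigma_px: float = 45.0
    n_nuclei: int = 200
    content_jitter: float = 0.08
    section_drift: float = 0.25
    stain_palette: list = field(default_factory=lambda: list(DEFAULT_PALETTE))
    n_channels: int = 3  # fluorescence rounds only


@dataclass
class SyntheticSeries:
    """Images plus exact ground truth.

    ``true_rigid[k]`` maps base-frame (image 0) coordinates into image
    k's frame; ``true_fields[k]`` is the backward deformation lookup
    (image-k frame), so base = R_k^-1 (p + d_k(p)) exactly.  ``landmarks``
    are corresponding nuclei centroids per image, (x, y).
    """

    images: list
    true_rigid: list
    true_fields: list
    landmarks: list
    seed: int
    params: SyntheticParams
    pixel_size_um: float = 1.0


def _smooth_noise(rng, shape, sigma):
    return ndi.gaussian_filter(rng.standard_normal(shape), sigma)


def _bilinear(field: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Sample a 2D field at (x, y) positions, bilinear, edge-clamped."""
    coords = np.stack([xy[:, 1], xy[:, 0]])  # row, col
    return ndi.map_coordinates(field, coords, order=1, mode="nearest")


def _rotation_about(cx, cy, angle_deg, tx=0.0, ty=0.0):
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    to0 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    rot = np.array([[c, -s, tx], [s, c, ty], [0, 0, 1]], dtype=float)
    back = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    return back @ rot @ to0


def _texture(rng, shape):
    """Multi-octave Perlin-like texture, normalized to [0, 1]."""
    tex = (ndi.gaussian_filter(rng.random(shape), 1.5)
           + 0.6 * ndi.gaussian_filter(rng.random(shape), 6)
           + 0.4 * ndi.gaussian_filter(rng.random(shape), 18))
    return (tex - tex.min()) / max(np.ptp(tex), 1e-9)


def _base_tissue(rng, p: SyntheticParams):
    n = p.size
    blob = _smooth_noise(rng, (n, n), n / 7)
    yy, xx = np.mgrid[0:n, 0:n]
    radial = np.hypot(xx - n / 2, yy - n / 2) / (n / 2)
    shape_field = blob / max(np.ptp(blob), 1e-9) - 0.45 * radial
    mask = shape_field > np.percentile(shape_field, 55)
    mask = ndi.binary_fill_holes(ndi.binary_opening(mask, iterations=3))
    tex = _texture(rng, (n, n))

    # nuclei well inside the tissue so landmarks survive warping
    interior = ndi.binary_erosion(mask, iterations=8)
    rows, cols = np.nonzero(interior)
    if len(rows) < p.n_nuclei:
        raise ValueError("tissue too small for requested nuclei count")
    pick = rng.choice(len(rows), size=p.n_nuclei, replace=False)
    centers = np.column_stack([cols[pick], rows[pick]]).astype(float)
    centers += rng.uniform(-0.5, 0.5, centers.shape)  # sub-pixel positions

    nuclei = np.zeros((n, n))
    for x, y in centers:
        _stamp(nuclei, x, y)

    # transient (non-landmark) nuclei: present in a contiguous run of
    # sections only, giving real feature turnover along the stack
    n_extra = int(1.5 * p.n_nuclei)
    pick2 = rng.choice(len(rows), size=min(n_extra, len(rows)), replace=False)
    extra_centers = np.column_stack([cols[pick2], rows[pick2]]).astype(float)
    extra_centers += rng.uniform(-0.5, 0.5, extra_centers.shape)
    return tex, mask.astype(float), nuclei, centers, extra_centers


def _stamp(field: np.ndarray, x: float, y: float, sigma: float = 1.6,
           win: int = 5) -> None:
    n = field.shape[0]
    x0, y0 = int(x), int(y)
    ys = slice(max(y0 - win, 0), min(y0 + win + 1, n))
    xs = slice(max(x0 - win, 0), min(x0 + win + 1, n))
    wy, wx = np.mgrid[ys, xs]
    field[ys, xs] += np.exp(-((wx - x) ** 2 + (wy - y) ** 2) / (2 * sigma**2))


def _section_nuclei(rng, shape, nuclei, extra_centers, p: SyntheticParams):
    """Per-section nuclei fields: persistent landmarks plus transients
    alive over a random contiguous window of sections."""
    span = max(2, p.n_images // 3)
    starts = rng.integers(-span + 1, p.n_images, size=len(extra_centers))
    lengths = 1 + rng.integers(1, 2 * span, size=len(extra_centers))
    fields = []
    for k in range(p.n_images):
        fk = nuclei.copy()
        alive = (starts <= k) & (k < starts + lengths)
        for x, y in extra_centers[alive]:
            _stamp(fk, x, y)
        fields.append(fk)
    return fields


def _section_textures(rng, tex: np.ndarray, p: SyntheticParams):
    """Texture random walk along the stack: neighboring sections share most
    of their structure, distant sections progressively less (feature
    turnover between serial slices)."""
    out = [tex]
    cur = tex
    a = np.clip(p.section_drift, 0.0, 1.0)
    for _ in range(1, p.n_images):
        if a > 0:
            fresh = _texture(rng, tex.shape)
            cur = (1 - a) * cur + a * fresh
            cur = (cur - cur.min()) / max(np.ptp(cur), 1e-9)
        out.append(cur)
    return out


def _sample_deformation(rng, p: SyntheticParams):
    n = p.size
    if p.deformation_amplitude_px > p.size / 20:
        raise ValueError("deformation amplitude too large for the tissue size")
    if p.deformation_amplitude_px == 0:
        return np.zeros((n, n)), np.zeros((n, n))
    dx = _smooth_noise(rng, (n, n), p.deformation_sigma_px)
    dy = _smooth_noise(rng, (n, n), p.deformation_sigma_px)
    mag = np.hypot(dx, dy)
    scale = p.deformation_amplitude_px / max(mag.max(), 1e-9)
    return dx * scale, dy * scale


def _forward_landmarks(base_xy, R, dx, dy, iters: int = 25):
    """Solve p + d(p) = R x by fixed point -> landmark positions in image k."""
    h = np.column_stack([base_xy, np.ones(len(base_xy))])
    target = (h @ R.T)[:, :2]
    p = target.copy()
    for _ in range(iters):
        disp = np.column_stack([_bilinear(dx, p), _bilinear(dy, p)])
        p_new = target - disp
        if np.abs(p_new - p).max() < 1e-3:
            p = p_new
            break
        p = p_new
    return p


def _warp_scalar(img, R, dx, dy, order=1, cval=0.0):
    """Backward-warp: out(p) = img(R^-1 (p + d(p)))."""
    n = img.shape[0]
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    px = xx + dx
    py = yy + dy
    Rinv = np.linalg.inv(R)
    sx = Rinv[0, 0] * px + Rinv[0, 1] * py + Rinv[0, 2]
    sy = Rinv[1, 0] * px + Rinv[1, 1] * py + Rinv[1, 2]
    return ndi.map_coordinates(img, [sy, sx], order=order, mode="constant",
                               cval=cval)


def _series_transforms(rng, p: SyntheticParams):
    """Per-image rigid matrices and deformation fields (image 0 = identity)."""
    rigids, fields = [np.eye(3)], [(np.zeros((p.size,) * 2),) * 2]
    c = (p.size - 1) / 2
    for _ in range(1, p.n_images):
        ang = rng.uniform(-p.max_rotation_deg, p.max_rotation_deg)
        t = rng.uniform(-p.max_translation_frac, p.max_translation_frac, 2) * p.size
        rigids.append(_rotation_about(c, c, ang, t[0], t[1]))
        fields.append(_sample_deformation(rng, p))
    return rigids, fields


def generate_series(params: SyntheticParams | None = None,
                    seed: int = 0) -> SyntheticSeries:
    """Generate a brightfield-like serial-section series with ground truth."""
    p = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    tex, mask, nuclei, centers, extra = _base_tissue(rng, p)
    texs = _section_textures(rng, tex, p)
    nuc_fields = _section_nuclei(rng, mask.shape, nuclei, extra, p)
    rigids, fields = _series_transforms(rng, p)

    images, landmarks = [], []
    for k in range(p.n_images):
        R, (dx, dy) = rigids[k], fields[k]
        density = mask * (0.35 + 0.5 * texs[k]) + 1.6 * nuc_fields[k] * mask
        dk = _warp_scalar(density, R, dx, dy)
        mk = _warp_scalar(mask, R, dx, dy)
        if p.content_jitter > 0:
            g = _smooth_noise(rng, dk.shape, 25)
            jitter = 1.0 + p.content_jitter * g / max(g.std(), 1e-9)
        else:
            jitter = 1.0
        dk = np.clip(dk * jitter, 0, None) * (mk > 0.5)
        absorb = np.array(p.stain_palette[k % len(p.stain_palette)])
        absorb = absorb * rng.uniform(0.85, 1.15)
        trans = np.exp(-dk[..., None] * absorb[None, None, :] * 2.2)
        rgb = np.clip(245.0 * trans + rng.normal(0, 1.5, trans.shape), 0, 255)
        images.append(rgb.astype(np.uint8))
        landmarks.append(_forward_landmarks(centers, R, dx, dy))

    return SyntheticSeries(images=images, true_rigid=rigids,
                           true_fields=fields, landmarks=landmarks,
                           seed=seed, params=p)


def generate_fluorescence_series(params: SyntheticParams | None = None,
                                 seed: int = 0) -> SyntheticSeries:
    """Generate CyCIF-like rounds sharing a nuclear channel.

    Each round is a multichannel image whose first channel ("DAPI") is
    derived from the same nuclei field; the remaining channels are
    round-specific marker patterns.  Background is dark.
    """
    p = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    tex, mask, nuclei, centers, _ = _base_tissue(rng, p)
    rigids, fields = _series_transforms(rng, p)

    # stain/wash rounds re-image the same physical section: the nuclear
    # channel is shared across rounds (no section-to-section turnover);
    # dim tissue autofluorescence gives the channel realistic texture
    dapi_base = nuclei + 0.15 * tex * mask
    images, landmarks = [], []
    for k in range(p.n_images):
        R, (dx, dy) = rigids[k], fields[k]
        dapi = _warp_scalar(dapi_base, R, dx, dy)
        chans = [np.clip(dapi * 255 * 1.2, 0, 255)]
        for _ in range(1, p.n_channels):
            marker_base = ndi.gaussian_filter(rng.random(mask.shape), 4) * mask
            chans.append(np.clip(_warp_scalar(marker_base, R, dx, dy) * 220,
                                 0, 255))
        img = np.stack(chans, axis=-1).astype(np.uint8)
        images.append(img)
        landmarks.append(_forward_landmarks(centers, R, dx, dy))

    return SyntheticSeries(images=images, true_rigid=rigids,
                           true_fields=fields, landmarks=landmarks,
                           seed=seed, params=p)


def map_to_base(series: SyntheticSeries, k: int, xy: np.ndarray) -> np.ndarray:
    """Map image-k coordinates to the base (image 0) frame via ground truth."""
    R, (dx, dy) = series.true_rigid[k], series.true_fields[k]
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    moved = xy + np.column_stack([_bilinear(dx, xy), _bilinear(dy, xy)])
    h = np.column_stack([moved, np.ones(len(moved))])
    return (h @ np.linalg.inv(R).T)[:, :2]


def write_series(series: SyntheticSeries, out_dir: str | os.PathLike,
                 fluorescence: bool = False) -> None:
    """Write the series as TIFFs + landmark CSVs + a ground-truth JSON."""
    from .slide_io import SlideImage, write_registered

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for k, (img, lm) in enumerate(zip(series.images, series.landmarks)):
        name = f"section_{k:02d}"
        slide = SlideImage(
            name=name, levels=[img],
            is_rgb=not fluorescence,
            channel_names=(["DAPI"] + [f"marker{i}" for i in
                                       range(1, img.shape[-1])]
                           if fluorescence and img.ndim == 3 else []),
            pixel_size_um=series.pixel_size_um,
        )
        write_registered(slide, os.path.join(out_dir, name + ".ome.tif"))
        np.savetxt(os.path.join(out_dir, name + "_landmarks.csv"), lm,
                   delimiter=",", header="x,y", comments="")
    truth = {
        "seed": series.seed,
        "params": asdict(series.params),
        "true_rigid": [m.tolist() for m in series.true_rigid],
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
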