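"""End-to-end orchestration: read -> mask -> process -> match -> order ->
serial rigid -> serial non-rigid (-> optional micro) -> error report.

The library entry point is :func:`register_series` (in-memory arrays or
:class:`SlideImage` objects); :func:`run_registration` wraps it with
directory input, artifact writing, and config serialization for the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import features as feat
from . import masking, ordering, preprocessing, rigid
from . import nonrigid as nr
from .error_metrics import ErrorReport, feature_error
from .nonrigid import DisplacementField
from .slide_io import SlideImage, get_registration_image, read_slide
from .warping import TransformChain

logger = logging.getLogger("serialign")

__all__ = ["RunConfig", "RegistrationResult", "register_series",
           "run_registration"]


@dataclass
class RunConfig:
    """All pipeline settings; serializable round trip via YAML."""

    src_dir: str = ""
    dst_dir: str = ""
    max_dim: int = 850
    seed: int = 0
    log_level: str = "INFO"
    preprocessing: dict = dc_field(default_factory=lambda: {
        "chroma": preprocessing.DEFAULT_CHROMA,
        "hue": preprocessing.DEFAULT_HUE,
        "tv_weight": preprocessing.DEFAULT_TV_WEIGHT,
        "if_channel": None,
    })
    features: dict = dc_field(default_factory=lambda: {
        "detector": "sift",
        "ransac_threshold_px": feat.RANSAC_THRESHOLD_PX,
    })
    ordering: dict = dc_field(default_factory=lambda: {
        "mode": "auto",        # auto | filename
        "reference": None,     # image name or series index
    })
    rigid: dict = dc_field(default_factory=lambda: {
        "mi_refine": False,
    })
    nonrigid: dict = dc_field(default_factory=lambda: {
        "method": "tvl1",
        "max_dim": 850,
    })
    micro: dict = dc_field(default_factory=lambda: {
        "fraction": 0.0,       # 0 disables micro-registration
        "tile": 512,
        "direct_to_reference": False,
    })

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if hasattr(cfg, key):
                current = getattr(cfg, key)
                if isinstance(current, dict) and isinstance(val, dict):
                    current.update(val)
                else:
                    setattr(cfg, key, val)
        return cfg


@dataclass
class RegistrationResult:
    chains: list[TransformChain]
    ordering: ordering.SeriesOrdering
    matches: dict
    masks: list[masking.TissueMask]
    processed: list[preprocessing.ProcessedImage]
    rigid_result: rigid.RigidResult
    fields: list[DisplacementField]
    errors: dict[str, ErrorReport]
    names: list[str] = dc_field(default_factory=list)
    pixel_size_um: float | None = None
    timings: dict = dc_field(default_factory=dict)


def _is_rgb(img: np.ndarray, slide: SlideImage | None) -> bool:
    if slide is not None:
        return slide.is_rgb
    return img.ndim == 3 and img.shape[2] == 3


def _make_chains(rigid_result, fields, scales, full_shapes, canvas_offset,
                 canvas_shape):
    chains = []
    for t, f, r, fs in zip(rigid_result.transforms, fields, scales,
                           full_shapes):
        chains.append(TransformChain(
            rigid=t, nonrigid=f, registration_scale=r, full_shape=fs,
            canvas_offset=tuple(canvas_offset),
            canvas_shape=tuple(canvas_shape)))
    return chains


def register_series(
    images: list,
    config: RunConfig | None = None,
    slides: list[SlideImage] | None = None,
    names: list[str] | None = None,
) -> RegistrationResult:
    """Register a series of images (arrays at registration scale).

    ``images`` are RGB (H, W, 3) or multichannel fluorescence arrays; at
    least two are required.  When ``slides`` are given, pyramid levels
    and metadata (pixel size, channel names) come from them.
    """
    cfg = config or RunConfig()
    if len(images) < 2:
        raise ValueError("need at least 2 images to register")
    n = len(images)
    names = names or [f"image_{i}" for i in range(n)]
    slides = slides or [None] * n
    timings = {}
    t_start = time.time()

    # -- mask + process -----------------------------------------------------
    masks, processed = [], []
    for i, img in enumerate(images):
        img = np.asarray(img)
        if _is_rgb(img, slides[i]):
            m = masking.make_tissue_mask(img)
            p = preprocessing.process_brightfield(
                img, chroma=cfg.preprocessing["chroma"],
                hue=cfg.preprocessing["hue"], source_index=i)
        else:
            p = preprocessing.process_fluorescence(
                slides[i] if slides[i] is not None else img,
                channel=cfg.preprocessing["if_channel"], source_index=i)
            m = masking.make_tissue_mask(p)
        p.mask = m.mask
        masks.append(m)
        processed.append(p)
    processed = preprocessing.normalize_image_set(processed)
    tv = cfg.preprocessing["tv_weight"]
    processed = [preprocessing.denoise(p, tv) for p in processed]
    timings["preprocess_s"] = time.time() - t_start
    logger.info("processed %d images (%.1fs)", n, timings["preprocess_s"])

    # -- features + matches -------------------------------------------------
    t0 = time.time()
    feature_sets = []
    for i, (p, m) in enumerate(zip(processed, masks)):
        fs = feat.detect_and_describe(p.pixels, m.mask,
                                      detector=cfg.features["detector"],
                                      name=names[i])
        feature_sets.append(fs)
        logger.info("image %s: %d keypoints", names[i], len(fs))
    matches = feat.match_all_pairs(
        feature_sets, ransac_threshold=cfg.features["ransac_threshold_px"],
        seed=cfg.seed)
    timings["features_s"] = time.time() - t0

    # -- order + reference --------------------------------------------------
    so = ordering.build_similarity(matches, n=n)
    if cfg.ordering["mode"] == "filename":
        so.order = sorted(range(n), key=lambda i: names[i])
        so.S_std = so.S / max(so.S.max(), 1)
        so.Dm = 1 - so.S_std
        np.fill_diagonal(so.Dm, 0)
    else:
        so = ordering.order_by_similarity(so)
    ref = cfg.ordering["reference"]
    if isinstance(ref, str):
        ref = names.index(ref)
    so = ordering.choose_reference(so, ref)
    logger.info("series order %s, reference %s", so.order,
                names[so.reference_image])

    # -- serial rigid -------------------------------------------------------
    t0 = time.time()
    shapes = [p.pixels.shape for p in processed]
    rr = rigid.serial_rigid_register(matches, so, image_shapes=shapes)
    if cfg.rigid["mi_refine"]:
        ref_img = processed[so.reference_image].pixels
        for i in range(n):
            if i == so.reference_image:
                continue
            ms = feat.get_pair(matches, i, so.reference_image)
            pts = (ms.xy_i, ms.xy_j) if not ms.is_empty else None
            rr.transforms[i] = rigid.mi_refine(
                processed[i].pixels, ref_img, rr.transforms[i],
                matches_xy=pts)
    timings["rigid_s"] = time.time() - t0

    # -- non-rigid ----------------------------------------------------------
    t0 = time.time()
    nr_mask, bbox = nr.build_nonrigid_mask(masks, rr)
    scales = [p.scale for p in processed]
    reg_scale = scales[0]

    def crop_source(i):
        def _source(desired_scale):
            if slides[i] is not None and len(slides[i].levels) > 1:
                want = int(round(max(slides[i].full_shape)
                                 * desired_scale * reg_scale))
                sc = get_registration_image(slides[i], max_dim=max(want, 16))
                return sc.pixels, sc.scale / reg_scale
            return np.asarray(images[i]), 1.0
        return _source

    def reprocess(arr, idx):
        if _is_rgb(np.asarray(arr), slides[idx]):
            return preprocessing.process_brightfield(
                np.asarray(arr), chroma=cfg.preprocessing["chroma"],
                hue=cfg.preprocessing["hue"], source_index=idx)
        ch = cfg.preprocessing["if_channel"]
        if slides[idx] is not None:
            if ch is None:
                ch = preprocessing.default_fluorescence_channel(
                    slides[idx].channel_names)
            elif isinstance(ch, str):
                ch = slides[idx].channel_index(ch)
        return preprocessing.process_fluorescence(
            np.asarray(arr), channel=ch, source_index=idx)

    crops, crop_scale = nr.extract_nonrigid_images(
        [crop_source(i) for i in range(n)], rr, bbox,
        target_dim=cfg.nonrigid["max_dim"], process=reprocess,
        registration_scale=reg_scale)
    crops = preprocessing.normalize_image_set(crops)
    x0, y0, w, h = bbox
    crop_shape = crops[0].pixels.shape
    from skimage.transform import resize as _resize
    cx0 = int(round(x0 - rr.canvas_offset[0]))
    cy0 = int(round(y0 - rr.canvas_offset[1]))
    mask_crop = nr_mask.mask[cy0:cy0 + int(h), cx0:cx0 + int(w)]
    flow_mask = _resize(mask_crop.astype(float), crop_shape, order=0,
                        preserve_range=True) > 0.5
    fields = nr.serial_nonrigid_register(
        crops, so, method=cfg.nonrigid["method"], mask=flow_mask)
    for f in fields:
        f.bbox = bbox
        f.scale = crop_scale
    timings["nonrigid_s"] = time.time() - t0

    # -- optional micro-registration ---------------------------------------
    if cfg.micro["fraction"]:
        t0 = time.time()
        micro_dim = int(round(max(w, h) * cfg.micro["fraction"] / reg_scale))
        micro_crops, micro_scale = nr.extract_nonrigid_images(
            [crop_source(i) for i in range(n)], rr, bbox,
            target_dim=micro_dim, process=reprocess,
            registration_scale=reg_scale)
        micro_crops = preprocessing.normalize_image_set(micro_crops)
        micro_mask = _resize(mask_crop.astype(float),
                             micro_crops[0].pixels.shape, order=0,
                             preserve_range=True) > 0.5
        fields = nr.micro_register(
            micro_crops, fields, so, method=cfg.nonrigid["method"],
            tile=cfg.micro["tile"],
            direct_to_reference=cfg.micro["direct_to_reference"],
            mask=micro_mask)
        for f in fields:
            f.bbox = bbox
            f.scale = micro_scale
        timings["micro_s"] = time.time() - t0

    # -- chains + error reports --------------------------------------------
    full_shapes = [
        slides[i].full_shape if slides[i] is not None
        else (np.asarray(images[i]).shape[1], np.asarray(images[i]).shape[0])
        for i in range(n)
    ]
    pixel_size = next((s.pixel_size_um for s in slides
                       if s is not None and s.pixel_size_um), None)
    chains = _make_chains(rr, fields, scales, full_shapes, rr.canvas_offset,
                          rr.canvas_shape)
    ident = rigid.RigidResult(
        transforms=[rigid.RigidTransform.identity() for _ in range(n)],
        canvas_offset=np.zeros(2), canvas_shape=rr.canvas_shape)
    unreg_chains = _make_chains(ident, [None] * n, scales, full_shapes,
                                (0, 0), rr.canvas_shape)
    rigid_chains = _make_chains(rr, [None] * n, scales, full_shapes,
                                rr.canvas_offset, rr.canvas_shape)
    adjacent = [(min(a, b), max(a, b))
                for a, b in zip(so.order, so.order[1:])]
    errors = {
        "unregistered": feature_error(matches, unreg_chains, pairs=adjacent,
                                      pixel_size_um=pixel_size,
                                      stage="unregistered"),
        "rigid": feature_error(matches, rigid_chains, pairs=adjacent,
                               pixel_size_um=pixel_size, stage="rigid"),
        "nonrigid": feature_error(matches, chains, pairs=adjacent,
                                  pixel_size_um=pixel_size, stage="nonrigid"),
    }
    timings["total_s"] = time.time() - t_start
    for stage, rep in errors.items():
        logger.info("%s sample error: %.2f %s", stage, rep.sample_error,
                    rep.units)
    return RegistrationResult(
        chains=chains, ordering=so, matches=matches, masks=masks,
        processed=processed, rigid_result=rr, fields=fields, errors=errors,
        names=names, pixel_size_um=pixel_size, timings=timings)


def stage_chains(result: RegistrationResult,
                 stage: str) -> list[TransformChain]:
    """Chains truncated to a pipeline stage.

    ``stage`` is "unregistered" (identity), "rigid" (no displacement
    fields), or "nonrigid" (the full chains) — useful for comparing how
    much each stage contributes to the alignment.
    """
    n = len(result.chains)
    scales = [c.registration_scale for c in result.chains]
    shapes = [c.full_shape for c in result.chains]
    rr = result.rigid_result
    if stage == "unregistered":
        ident = rigid.RigidResult(
            transforms=[rigid.RigidTransform.identity() for _ in range(n)],
            canvas_offset=np.zeros(2), canvas_shape=rr.canvas_shape)
        return _make_chains(ident, [None] * n, scales, shapes, (0, 0),
                            rr.canvas_shape)
    if stage == "rigid":
        return _make_chains(rr, [None] * n, scales, shapes,
                            rr.canvas_offset, rr.canvas_shape)
    if stage == "nonrigid":
        return result.chains
    raise ValueError(f"unknown stage {stage!r}")


def _serialize_chains(result: RegistrationResult, out_dir: str) -> None:
    meta = []
    os.makedirs(out_dir, exist_ok=True)
    field_arrays = {}
    for name, chain in zip(result.names, result.chains):
        entry = {
            "name": name,
            "rigid_matrix": chain.rigid.matrix.tolist(),
            "registration_scale": chain.registration_scale,
            "full_shape": list(chain.full_shape),
            "canvas_offset": list(map(float, chain.canvas_offset)),
            "canvas_shape": list(map(int, chain.canvas_shape)),
        }
        if chain.nonrigid is not None:
            entry["field_bbox"] = list(map(float, chain.nonrigid.bbox))
            entry["field_scale"] = chain.nonrigid.scale
            field_arrays[f"{name}_X"] = chain.nonrigid.X
            field_arrays[f"{name}_Y"] = chain.nonrigid.Y
        meta.append(entry)
    with open(os.path.join(out_dir, "chains.json"), "w") as fh:
        json.dump({
            "order": list(map(int, result.ordering.order)),
            "reference_index": int(result.ordering.reference_index),
            "images": meta,
        }, fh, indent=1)
    if field_arrays:
        np.savez_compressed(os.path.join(out_dir, "fields.npz"),
                            **field_arrays)


def load_chains(out_dir: str) -> dict[str, TransformChain]:
    """Load chains serialized by :func:`run_registration`."""
    with open(os.path.join(out_dir, "chains.json")) as fh:
        meta = json.load(fh)
    fields = {}
    npz_path = os.path.join(out_dir, "fields.npz")
    if os.path.exists(npz_path):
        with np.load(npz_path) as npz:
            fields = {k: npz[k] for k in npz.files}
    chains = {}
    for entry in meta["images"]:
        nrf = None
        if f"{entry['name']}_X" in fields:
            nrf = DisplacementField(
                X=fields[f"{entry['name']}_X"],
                Y=fields[f"{entry['name']}_Y"],
                bbox=tuple(entry["field_bbox"]),
                scale=entry["field_scale"])
        chains[entry["name"]] = TransformChain(
            rigid=rigid.RigidTransform(
                matrix=np.array(entry["rigid_matrix"])),
            nonrigid=nrf,
            registration_scale=entry["registration_scale"],
            full_shape=tuple(entry["full_shape"]),
            canvas_offset=tuple(entry["canvas_offset"]),
            canvas_shape=tuple(entry["canvas_shape"]))
    return chains


def run_registration(config: RunConfig) -> RegistrationResult:
    """Directory-based pipeline run with artifacts written to dst_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    paths = sorted(
        os.path.join(config.src_dir, f) for f in os.listdir(config.src_dir)
        if f.lower().endswith((".tif", ".tiff", ".png")))
    if len(paths) < 2:
        raise ValueError(
            f"need at least 2 readable images in {config.src_dir}")
    slides = [read_slide(p) for p in paths]
    regs = [get_registration_image(s, max_dim=config.max_dim)
            for s in slides]
    result = register_series([r.pixels for r in regs], config,
                             slides=slides, names=[s.name for s in slides])
    for chain, r in zip(result.chains, regs):
        chain.registration_scale = r.scale
    os.makedirs(config.dst_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.dst_dir, "config.yaml"))
    _serialize_chains(result, config.dst_dir)
    _write_previews(result, config.dst_dir)
    _write_error_report(result, config.dst_dir)
    return result


def _write_previews(result: RegistrationResult, out_dir: str) -> None:
    import imageio.v3 as iio

    from .warping import warp_image

    prev_dir = os.path.join(out_dir, "previews")
    os.makedirs(prev_dir, exist_ok=True)
    for name, chain, p in zip(result.names, result.chains, result.processed):
        r = chain.registration_scale
        img = np.clip(p.pixels / max(p.pixels.max(), 1e-9) * 255, 0, 255)
        warped = warp_image(img.astype(np.uint8), chain, source_scale=r,
                            target_scale=r)
        iio.imwrite(os.path.join(prev_dir, f"{name}.png"), warped)


def _write_error_report(result: RegistrationResult, out_dir: str) -> None:
    import pandas as pd

    rows = []
    for stage, rep in result.errors.items():
        for p in rep.per_pair:
            rows.append({"stage": stage, "i": p.i, "j": p.j,
                         "median_distance": p.median_distance,
                         "n_matches": p.n_matches, "units": rep.units})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "error_report.csv"),
                              index=False)
    summary = {stage: {"sample_error": rep.sample_error, "units": rep.units}
               for stage, rep in result.errors.items()}
    with open(os.path.join(out_dir, "error_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
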