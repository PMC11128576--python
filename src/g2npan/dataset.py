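"""Synthetic group-structured fused-image quality datasets.

Multimodal medical fusion images (MMFI) combine a structural modality (CT/MRI:
sharp anatomy) with a functional one (PET/SPECT: diffuse activity concentrated
around a lesion). Quality-assessment databases for MMFI group the outputs of
many fusion algorithms applied to one source pair, attach a radiologist mean
opinion score (MOS, 1-5) to each fused image, and designate the highest-MOS
image of each group as that group's reference. Such databases are not public,
so this module emulates their *shape*: per-group sets of fusion variants of a
shared scene whose quality is driven by known distortion severities, with MOS
monotone in severity and a per-group highest-MOS reference.

Every function here is a pure function of (config, seed). Images are stored as
8-bit RGB PNG with a CSV manifest; grayscale scenes are replicated to three
channels so downstream networks see a fixed channel count.

The distortion bank (blur, additive noise, modality-weight imbalance, local
detail loss in a patch) is an explicit stand-in for the uneven failure modes of
real fusion algorithms; see docs/methods.md for what it does and does not
emulate.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

_FLOAT = np.float32

MANIFEST_COLUMNS = ["file_path", "group_id", "variant_id", "mos",
                    "is_reference", "severity_path"]


# --------------------------------------------------------------------- types
@dataclass
class FusedImage:
    """One fused raster: the unit of assessment."""

    pixels: np.ndarray  # (H, W, 3) float32 in [0, 1]
    group_id: int
    variant_id: int
    mos: float | None = None
    severity_map: np.ndarray | None = None  # (H, W) in [0, 1]; synthetic only

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=_FLOAT)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")
        if self.mos is not None and not (1.0 <= self.mos <= 5.0):
            raise ValueError(f"mos must lie in [1, 5], got {self.mos}")
        if self.severity_map is not None:
            self.severity_map = np.asarray(self.severity_map, dtype=_FLOAT)
            if self.severity_map.shape != self.pixels.shape[:2]:
                raise ValueError("severity_map spatial shape must match pixels")


@dataclass
class ImageGroup:
    """The fusion variants of one source pair plus its designated reference."""

    group_id: int
    variants: list[FusedImage]
    reference_variant_id: int | None = None

    @property
    def reference(self) -> FusedImage:
        for v in self.variants:
            if v.variant_id == self.reference_variant_id:
                return v
        raise ValueError(f"group {self.group_id}: no variant with id "
                         f"{self.reference_variant_id}")

    def validate(self) -> None:
        if not self.variants:
            raise ValueError(f"group {self.group_id} is empty")
        shapes = {v.pixels.shape for v in self.variants}
        if len(shapes) != 1:
            raise ValueError(f"group {self.group_id}: mixed shapes {shapes}")
        if any(v.group_id != self.group_id for v in self.variants):
            raise ValueError(f"group {self.group_id}: variant with foreign group id")
        if self.reference_variant_id is not None:
            best = max(v.mos for v in self.variants)
            if self.reference.mos != best:
                raise ValueError(
                    f"group {self.group_id}: reference MOS {self.reference.mos} "
                    f"is not the group maximum {best}")


@dataclass
class DatasetManifest:
    rows: pd.DataFrame
    meta: dict
    path: str | None = None


@dataclass
class DatasetConfig:
    """Defaults mirror the emulated database: 129 source pairs (120 color +
    9 grayscale) x 10 fusion variants = 1,290 images of 128 x 128 pixels."""

    n_groups: int = 129
    n_variants: int = 10
    size: int = 128
    n_grayscale: int = 9
    seed: int = 0
    mos_noise_sd: float = 0.0  # bounded rater noise on the MOS; off by default
    severity_max: float = 0.9
    struct_weight: float = 0.55  # modality weight of the structural image

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------- generation
def _check_size(size: int) -> None:
    if size < 32 or (size & (size - 1)) != 0:
        raise ValueError(
            f"size must be a power of two >= 32, got {size}")


def generate_source_pair(group_seed: int, size: int = 128):
    """Synthesize one (structural, functional) source-image pair.

    The structural image is piecewise smooth with sharp edges (random ellipses
    and rectangles plus mild texture, mimicking anatomy); the functional image
    is a low-frequency blob field concentrated inside a random "lesion" region
    (mimicking tracer uptake). Deterministic given ``group_seed``.
    """
    _check_size(size)
    rng = np.random.default_rng(np.random.SeedSequence((int(group_seed), 0x5AFE)))
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size

    structural = np.full((size, size), 0.12)
    for _ in range(rng.integers(3, 7)):
        cx, cy = rng.uniform(0.15, 0.85, 2)
        ax, ay = rng.uniform(0.06, 0.3, 2)
        ang = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
        v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
        mask = (u / ax) ** 2 + (v / ay) ** 2 <= 1.0
        structural[mask] = rng.uniform(0.25, 0.95)
    for _ in range(rng.integers(1, 3)):
        x0, y0 = rng.uniform(0.1, 0.6, 2)
        w, h = rng.uniform(0.08, 0.3, 2)
        mask = (xx >= x0) & (xx <= x0 + w) & (yy >= y0) & (yy <= y0 + h)
        structural[mask] = rng.uniform(0.2, 0.9)
    texture = gaussian_filter(rng.normal(size=(size, size)), sigma=1.5)
    structural = structural + 0.03 * texture / (np.abs(texture).max() + 1e-12)

    lx, ly = rng.uniform(0.25, 0.75, 2)
    radius = rng.uniform(0.12, 0.3)
    r2 = ((xx - lx) ** 2 + (yy - ly) ** 2) / radius**2
    lesion = np.exp(-(r2**2))  # smooth plateau with soft edge
    blobs = np.zeros((size, size))
    for _ in range(rng.integers(3, 6)):
        bx = lx + rng.uniform(-0.6, 0.6) * radius
        by = ly + rng.uniform(-0.6, 0.6) * radius
        bs = rng.uniform(0.08, 0.2)
        blobs += rng.uniform(0.4, 1.0) * np.exp(
            -((xx - bx) ** 2 + (yy - by) ** 2) / (2 * bs**2))
    functional = lesion * blobs
    functional = 0.9 * functional / (functional.max() + 1e-12)

    return (np.clip(structural, 0, 1).astype(_FLOAT),
            np.clip(functional, 0, 1).astype(_FLOAT))


_FUNCTIONAL_TINT = np.array([1.0, 0.55, 0.15], dtype=_FLOAT)  # hot-metal tint


def clean_fusion(structural: np.ndarray, functional: np.ndarray,
                 color: bool = True, struct_weight: float = 0.55) -> np.ndarray:
    """Ideal weighted fusion of a source pair, as an (H, W, 3) image."""
    s_rgb = np.repeat(structural[..., None], 3, axis=2)
    if color:
        f_rgb = functional[..., None] * _FUNCTIONAL_TINT
    else:
        f_rgb = np.repeat(functional[..., None], 3, axis=2)
    fused = struct_weight * s_rgb + (1.0 - struct_weight) * f_rgb
    return np.clip(fused, 0, 1).astype(_FLOAT)


def _degrade(clean_inputs, severity: float, rng: np.random.Generator,
             color: bool, struct_weight: float):
    """Apply the severity-scaled distortion bank; returns (image, severity_map)."""
    structural, functional = clean_inputs
    size = structural.shape[0]
    sev_map = np.full((size, size), severity, dtype=_FLOAT)
    if severity == 0.0:
        return clean_fusion(structural, functional, color, struct_weight), \
            np.zeros((size, size), dtype=_FLOAT)

    # modality-weight imbalance: over/under-weights one modality
    shift = severity * 0.35 * (1 if rng.random() < 0.5 else -1)
    img = clean_fusion(structural, functional, color,
                       np.clip(struct_weight + shift, 0.05, 0.95))
    # global blur
    sigma = 2.5 * severity
    if sigma > 0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    # local detail loss: a patch is additionally smoothed away
    ps = size // 3
    py, px = rng.integers(0, size - ps, 2)
    patch = img[py:py + ps, px:px + ps]
    img[py:py + ps, px:px + ps] = gaussian_filter(
        patch, sigma=(3.0 * severity + 1.0, 3.0 * severity + 1.0, 0))
    sev_map[py:py + ps, px:px + ps] = np.clip(1.5 * severity, 0, 1)
    # additive noise
    img = img + rng.normal(scale=0.06 * severity, size=img.shape)
    return np.clip(img, 0, 1).astype(_FLOAT), sev_map


def synthesize_fusion_variants(pair, n_variants: int, severity_grid,
                               variant_seed: int, color: bool = True,
                               struct_weight: float = 0.55,
                               group_id: int = 0) -> list[FusedImage]:
    """Emulate the output of `n_variants` fusion algorithms of graded quality.

    Each variant is the clean fusion of `pair` degraded by a severity-scaled
    mixture of blur, noise, modality-weight imbalance, and local detail loss;
    ``severity_map`` records the per-pixel applied severity. Severity 0 yields
    the clean fusion exactly.
    """
    severity_grid = [float(s) for s in severity_grid]
    if not severity_grid:
        raise ValueError("severity_grid must be non-empty")
    if n_variants != len(severity_grid):
        raise ValueError(
            f"n_variants ({n_variants}) != len(severity_grid) ({len(severity_grid)})")
    if len(set(severity_grid)) != len(severity_grid):
        raise ValueError("severities must be distinct")
    for s in severity_grid:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"severity {s} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((int(variant_seed), 0xD15)))
    out = []
    for vid, s in enumerate(severity_grid):
        pixels, sev_map = _degrade(pair, s, rng, color, struct_weight)
        out.append(FusedImage(pixels=pixels, group_id=group_id, variant_id=vid,
                              mos=None, severity_map=sev_map))
    return out


def assign_mos(severity: float, noise_sd: float = 0.0,
               rng: np.random.Generator | None = None) -> float:
    """Map distortion severity to a MOS on the 1-5 scale: 5 - 4*severity,
    optionally plus bounded rater noise, clipped to [1, 5]."""
    if not (0.0 <= severity <= 1.0):
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    mos = 5.0 - 4.0 * float(severity)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        mos += float(np.clip(rng.normal(scale=noise_sd), -2 * noise_sd, 2 * noise_sd))
    return float(np.clip(mos, 1.0, 5.0))


def select_reference(group: ImageGroup, tie_seed: int = 0) -> int:
    """Designate the highest-MOS variant as reference; ties are broken
    uniformly at random under ``tie_seed``."""
    if not group.variants:
        raise ValueError(f"group {group.group_id} is empty")
    best = max(v.mos for v in group.variants)
    winners = [v.variant_id for v in group.variants if v.mos == best]
    if len(winners) == 1:
        return winners[0]
    rng = np.random.default_rng(np.random.SeedSequence((int(tie_seed), 0x71E)))
    return int(rng.choice(winners))


def _severity_grid(n: int, severity_max: float, rng: np.random.Generator):
    """One zero severity plus n-1 jittered, distinct, increasing severities."""
    base = np.linspace(0.0, severity_max, n)
    jitter = rng.uniform(-0.25, 0.25, n) * (base[1] - base[0] if n > 1 else 0)
    jitter[0] = 0.0
    grid = np.clip(base + jitter, 0.0, 1.0)
    grid = np.maximum.accumulate(grid + np.arange(n) * 1e-6)  # keep distinct
    order = rng.permutation(n)  # variant id should not encode quality rank
    return grid[order]


def make_image_groups(config: DatasetConfig) -> list[ImageGroup]:
    """Generate the full dataset in memory (no disk I/O)."""
    if config.n_groups <= 0:
        raise ValueError("n_groups must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xDA7A)))
    groups = []
    for gid in range(config.n_groups):
        gseed = int(rng.integers(0, 2**31 - 1))
        color = gid >= config.n_grayscale
        pair = generate_source_pair(gseed, config.size)
        grid = _severity_grid(config.n_variants, config.severity_max,
                              np.random.default_rng(
                                  np.random.SeedSequence((gseed, 0x981))))
        variants = synthesize_fusion_variants(
            pair, config.n_variants, grid, variant_seed=gseed, color=color,
            struct_weight=config.struct_weight, group_id=gid)
        mos_rng = np.random.default_rng(np.random.SeedSequence((gseed, 0x305)))
        for v, s in zip(variants, grid):
            v.mos = assign_mos(s, config.mos_noise_sd, mos_rng)
        group = ImageGroup(group_id=gid, variants=variants)
        group.reference_variant_id = select_reference(group, tie_seed=gseed)
        group.validate()
        groups.append(group)
    return groups


# ----------------------------------------------------------------------- I/O
def _write_png(path: str, arr: np.ndarray) -> None:
    Image.fromarray(np.round(arr * 255).astype(np.uint8)).save(path)


def _read_png(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    return (np.asarray(Image.open(path), dtype=_FLOAT) / 255.0)


def build_dataset(config: DatasetConfig, out_dir: str) -> DatasetManifest:
    """Write a synthetic dataset (PNG images + severity maps + CSV manifest +
    YAML metadata) under ``out_dir`` and return its manifest."""
    groups = make_image_groups(config)
    img_dir = os.path.join(out_dir, "images")
    sev_dir = os.path.join(out_dir, "severity")
    try:
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(sev_dir, exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}: {exc}") from exc
    rows = []
    for g in groups:
        for v in g.variants:
            rel_img = f"images/g{g.group_id:04d}_v{v.variant_id}.png"
            rel_sev = f"severity/g{g.group_id:04d}_v{v.variant_id}.png"
            _write_png(os.path.join(out_dir, rel_img), v.pixels)
            _write_png(os.path.join(out_dir, rel_sev), v.severity_map)
            rows.append((rel_img, g.group_id, v.variant_id, v.mos,
                         int(v.variant_id == g.reference_variant_id), rel_sev))
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    meta = {"image_size": config.size, "channel_policy": "rgb-replicated",
            "seed": config.seed, **{k: v for k, v in config.to_dict().items()
                                    if k not in ("size", "seed")}}
    manifest_path = os.path.join(out_dir, "manifest.csv")
    df.to_csv(manifest_path, index=False, float_format="%.6f")
    with open(os.path.join(out_dir, "meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return DatasetManifest(rows=df, meta=meta, path=manifest_path)


def load_dataset(manifest_path: str) -> list[ImageGroup]:
    """Reconstruct ImageGroups from a manifest written by :func:`build_dataset`
    (or any external dataset following the same CSV contract)."""
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, keep_default_na=False)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"malformed manifest: missing columns {sorted(missing_cols)}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    seen: set[tuple[int, int]] = set()
    groups: dict[int, ImageGroup] = {}
    for _, row in df.iterrows():
        try:
            gid, vid = int(row.group_id), int(row.variant_id)
            mos = float(row.mos)
            is_ref = int(row.is_reference)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed manifest row: {row.to_dict()}") from exc
        if (gid, vid) in seen:
            raise ValueError(f"duplicate (group, variant) = ({gid}, {vid})")
        seen.add((gid, vid))
        pixels = _read_png(os.path.join(base, str(row.file_path)))
        if pixels.ndim == 2:
            pixels = np.repeat(pixels[..., None], 3, axis=2)
        sev = None
        if str(row.severity_path):
            sev = _read_png(os.path.join(base, str(row.severity_path)))
        img = FusedImage(pixels=pixels, group_id=gid, variant_id=vid,
                         mos=mos, severity_map=sev)
        grp = groups.setdefault(gid, ImageGroup(group_id=gid, variants=[]))
        grp.variants.append(img)
        if is_ref:
            if grp.reference_variant_id is not None:
                raise ValueError(f"group {gid}: more than one is_reference row")
            grp.reference_variant_id = vid
    out = []
    for gid in sorted(groups):
        grp = groups[gid]
        if grp.reference_variant_id is None:
            raise ValueError(f"group {gid}: no is_reference row")
        grp.validate()
        out.append(grp)
    return out
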