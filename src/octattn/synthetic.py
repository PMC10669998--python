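"""Synthetic retinal OCT B-scan generator.

Real OCT B-scans show a dark vitreous above a smoothly curved retina made of
stacked horizontal bands of distinct reflectivity (RNFL, plexiform/nuclear
layers, photoreceptor/RPE complex, choroid), a central foveal depression,
and strong multiplicative speckle.  This module renders grayscale images
with exactly those ingredients and plants a configurable disease effect —
fractional thinning of the RNFL band plus a texture perturbation — so that
a two-class (bipolar vs control) dataset with two scan orientations can be
generated at any size, reproducibly from a seed.

The generator emulates the published dataset's *structure* (two classes, two
orientations, 403 bipolar + 912 control images per orientation, fixed
train/test counts); it makes no claim about actual bipolar OCT morphology.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "LayerBandSpec",
    "SyntheticConfig",
    "DatasetManifest",
    "CASES",
    "CLASSES",
    "default_bands",
    "render_scan",
    "generate_dataset",
    "fixed_split",
    "measure_rnfl_thickness",
    "table_train_counts",
]

CASES = ("left_to_right", "top_to_bottom")
CLASSES = ("bipolar", "control")


@dataclass(frozen=True)
class LayerBandSpec:
    """One horizontal reflectivity band of the rendered retina.

    ``mean_thickness`` and ``thickness_sd`` are in pixels (per-image jitter);
    ``brightness`` is the band's mean reflectivity in [0, 1] and
    ``texture_sd`` the within-band additive texture noise.
    """

    name: str
    mean_thickness: float
    thickness_sd: float
    brightness: float
    texture_sd: float

    def __post_init__(self) -> None:
        if self.mean_thickness <= 0:
            raise ValueError(f"band {self.name}: mean_thickness must be > 0")
        if not 0.0 <= self.brightness <= 1.0:
            raise ValueError(f"band {self.name}: brightness must lie in [0, 1]")


def default_bands(scale: float = 1.0) -> tuple[LayerBandSpec, ...]:
    """A plausible inner-to-outer band stack at 224-pixel resolution.

    Thicknesses are loosely proportioned after macular B-scans (bright thin
    RNFL on top, dark nuclear layers, bright photoreceptor/RPE complex,
    textured choroid); they are rendering choices, not biometry.  ``scale``
    shrinks or grows all thicknesses, e.g. ``image_side / 224`` for non-224
    rendering.
    """
    stack = (
        ("RNFL", 14.0, 0.7, 0.78, 0.04),
        ("GCL_IPL", 12.0, 1.0, 0.45, 0.03),
        ("INL", 8.0, 0.8, 0.32, 0.03),
        ("OPL", 6.0, 0.8, 0.50, 0.03),
        ("ONL", 13.0, 1.0, 0.22, 0.02),
        ("PR_RPE", 7.0, 0.8, 0.88, 0.03),
        ("choroid", 28.0, 2.0, 0.55, 0.06),
    )
    return tuple(
        LayerBandSpec(n, t * scale, sd * scale, b, tex) for n, t, sd, b, tex in stack
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one generated dataset.

    ``rnfl_thinning`` is the fractional reduction of the RNFL band's mean
    thickness in the bipolar class (0.40 = a 40% thinner band);
    ``texture_perturb_sd`` is added to the RNFL texture noise for that class.
    ``speckle_sd`` is the log-standard-deviation of multiplicative log-normal
    speckle (mean 1).  ``counts`` maps class name -> images per orientation.
    """

    image_side: int = 224
    bands: tuple[LayerBandSpec, ...] = field(default_factory=default_bands)
    foveal_dip_depth: float = 10.0
    surface_curve_amp: float = 6.0
    vitreous_level: float = 0.05
    speckle_sd: float = 0.05
    rnfl_thinning: float = 0.40
    texture_perturb_sd: float = 0.02
    rpe_texture_perturb_sd: float = 0.0
    counts: dict[str, int] = field(
        default_factory=lambda: {"bipolar": 403, "control": 912}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rnfl_thinning < 1.0:
            raise ValueError("rnfl_thinning must lie in [0, 1)")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be >= 0")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("image counts must be non-negative")
        total = sum(b.mean_thickness for b in self.bands)
        if total + self.surface_curve_amp + self.foveal_dip_depth >= self.image_side:
            raise ValueError(
                f"band stack ({total:.0f}px) plus surface relief does not fit "
                f"in an image of side {self.image_side}"
            )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DatasetManifest:
    """Labeled image records plus provenance.

    ``records`` is a DataFrame with columns ``id, case, class, split, path``;
    ``provenance`` carries the generating config hash and seed.
    """

    records: pd.DataFrame
    provenance: dict

    def counts(self) -> pd.DataFrame:
        return self.records.groupby(["case", "class", "split"]).size().unstack(fill_value=0)

    def subset(self, case: str | None = None, split: str | None = None) -> pd.DataFrame:
        df = self.records
        if case is not None and case != "merged":
            df = df[df["case"] == case]
        if split is not None:
            df = df[df["split"] == split]
        return df.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(records=pd.read_csv(path), provenance={"source": str(path)})


def render_scan(config: SyntheticConfig, cls: str, case: str,
                rng: np.random.Generator) -> np.ndarray:
    """Render one grayscale B-scan as a float array in [0, 1].

    The retinal surface is a shallow parabola with a central Gaussian foveal
    dip; bands are stacked beneath it with per-image thickness jitter.  For
    ``cls="bipolar"`` the RNFL mean thickness is scaled by
    ``1 - rnfl_thinning`` and its texture noise widened; an optional RPE
    texture perturbation is off by default.  ``case="top_to_bottom"`` is the
    90-degree-rotated geometry.  Deterministic given the generator state.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
    if case not in CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {CASES}")
    side = config.image_side
    cols = np.arange(side)
    center = (side - 1) / 2.0
    # retinal surface: shallow parabola + foveal Gaussian dip
    parabola = config.surface_curve_amp * ((cols - center) / center) ** 2
    dip = config.foveal_dip_depth * np.exp(-0.5 * ((cols - center) / (side / 10.0)) ** 2)
    surface = 0.22 * side + parabola + dip

    img = np.full((side, side), config.vitreous_level, dtype=np.float64)
    img += rng.normal(0.0, 0.01, size=img.shape)

    rows = np.arange(side)[:, None]
    top = surface[None, :]
    carry = 0.0  # thickness removed from a thinned band, returned to the next
    for band in config.bands:
        mean_t = band.mean_thickness + carry
        carry = 0.0
        tex_sd = band.texture_sd
        if cls == "bipolar" and band.name == "RNFL":
            # The deficit is added to the band below so every deeper boundary
            # stays where it is in the control class: the image evidence for
            # the disease is confined to the RNFL band itself, which is what
            # makes the explainability localization property well-posed.
            carry = mean_t * config.rnfl_thinning
            mean_t *= 1.0 - config.rnfl_thinning
            tex_sd += config.texture_perturb_sd
        if cls == "bipolar" and band.name == "PR_RPE":
            tex_sd += config.rpe_texture_perturb_sd
        # Jitter is truncated at +/-2 sd so per-class thickness supports are
        # bounded: with RNFL sd 0.7 the control band never drops below
        # 14 - 1.4 px while a >=30%-thinned band never exceeds 9.8 + 1.4 px,
        # keeping the classes threshold-separable by construction.
        jitter = rng.normal(0.0, band.thickness_sd) if band.thickness_sd > 0 else 0.0
        jitter = float(np.clip(jitter, -2 * band.thickness_sd, 2 * band.thickness_sd))
        thickness = max(1.0, mean_t + jitter)
        bottom = top + thickness
        mask = (rows >= top) & (rows < bottom)
        img[mask] = band.brightness
        if tex_sd > 0:
            img[mask] += rng.normal(0.0, tex_sd, size=int(mask.sum()))
        top = bottom

    if config.speckle_sd > 0:
        sd = config.speckle_sd
        # log-normal with unit mean: exp(N(-sd^2/2, sd))
        img *= np.exp(rng.normal(-0.5 * sd * sd, sd, size=img.shape))

    img = np.clip(img, 0.0, 1.0)
    if case == "top_to_bottom":
        img = np.rot90(img)
    return np.ascontiguousarray(img)


def measure_rnfl_thickness(image: np.ndarray, case: str = "left_to_right",
                           threshold: float = 0.60) -> float:
    """Median pixel thickness of the top bright band (the rendered RNFL).

    Scans each column from the top for the first contiguous run of pixels
    above ``threshold`` (the RNFL is rendered distinctly brighter than the
    band below it) and returns the median run length over off-center
    columns.  This is the oracle measurement used to verify the class
    effect and to build the threshold reference classifier.
    """
    if case == "top_to_bottom":
        image = np.rot90(image, -1)
    side = image.shape[1]
    lo, hi = side // 8, 3 * side // 8  # off-center: avoid the foveal dip
    cols = list(range(lo, hi)) + list(range(side - hi, side - lo))
    runs = []
    bright = image > threshold
    for c in cols:
        col = bright[:, c]
        idx = np.flatnonzero(col)
        if idx.size == 0:
            continue
        start = idx[0]
        run = 1
        while start + run < col.size and col[start + run]:
            run += 1
        runs.append(run)
    if not runs:
        return 0.0
    return float(np.median(runs))


def _image_rng(seed: int, case: str, cls: str, index: int) -> np.random.Generator:
    """Per-image generator, independent of generation order."""
    ss = np.random.SeedSequence(
        [seed, CASES.index(case), CLASSES.index(cls), index]
    )
    return np.random.default_rng(ss)


def generate_dataset(config: SyntheticConfig, output_dir) -> DatasetManifest:
    """Render and write the full two-case dataset as 8-bit grayscale PNGs.

    Layout: ``<output_dir>/<case>/<class>/<image_id>.png``.  Every image gets
    its own seed stream derived from ``config.seed`` and its (case, class,
    index) coordinates, so the dataset is byte-reproducible and insensitive
    to generation order.  Returns the manifest (all records initially in the
    ``unsplit`` state; see :func:`fixed_split`).
    """
    root = Path(output_dir)
    rows = []
    for case in CASES:
        for cls in CLASSES:
            n = config.counts.get(cls, 0)
            cls_dir = root / case / cls
            if n > 0:
                cls_dir.mkdir(parents=True, exist_ok=True)
            for i in range(n):
                rng = _image_rng(config.seed, case, cls, i)
                img = render_scan(config, cls, case, rng)
                img8 = np.round(img * 255.0).astype(np.uint8)
                image_id = f"{case}_{cls}_{i:04d}"
                path = cls_dir / f"{image_id}.png"
                Image.fromarray(img8, mode="L").save(path)
                rows.append((image_id, case, cls, "unsplit", str(path)))
    records = pd.DataFrame(rows, columns=["id", "case", "class", "split", "path"])
    provenance = {"config_hash": config.config_hash(), "seed": config.seed}
    return DatasetManifest(records=records, provenance=provenance)


def fixed_split(manifest: DatasetManifest, train_counts: dict[tuple[str, str], int],
                seed: int) -> DatasetManifest:
    """Assign exactly ``train_counts[(case, class)]`` records per stratum to
    the train split, the remainder to test; reproducible under ``seed``.
    """
    df = manifest.records.copy()
    rng = np.random.default_rng(seed)
    split = pd.Series("test", index=df.index)
    for (case, cls), want in train_counts.items():
        idx = df.index[(df["case"] == case) & (df["class"] == cls)]
        if want > len(idx):
            raise ValueError(
                f"stratum (case={case}, class={cls}) has {len(idx)} images, "
                f"cannot assign {want} to train"
            )
        chosen = rng.choice(idx.to_numpy(), size=want, replace=False)
        split.loc[chosen] = "train"
    df["split"] = split
    return DatasetManifest(records=df, provenance=dict(manifest.provenance))


def table_train_counts(train_per_class: dict[str, int] | None = None) -> dict[tuple[str, str], int]:
    """The published per-stratum train counts (303 bipolar / 684 control)."""
    per = train_per_class or {"bipolar": 303, "control": 684}
    return {(case, cls): per[cls] for case in CASES for cls in per}
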