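"""Seeded generator of blastocyst-like tomographic phantoms and clinical
factor tables, so the full pipeline is testable without any real data.

Geometry: the circular culture-well frame is mapped to the full image frame,
so one pixel spans ``well_diameter_um / image_px`` micrometres. The
blastocyst is a sphere (bright shell, dark blastocoel cavity, and a bright
inner-cell-mass blob placed above the equator) sampled at ``n_slices``
heights with 10-um pitch; per-slice masks cover exactly the rendered
blastocyst cross-section, never the well frame.

All randomness flows from one integer seed through counter-based
``np.random.default_rng([seed, stream, index])`` splitting, so every output
is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cee_features import FACTOR_ORDER, RegressionSpec, cee_feature_vector
from .segmentation import SliceStack


class GeometryError(ValueError):
    pass


def load_default_marginals() -> dict:
    text = resources.files("embryo3d.data").joinpath("cohort_marginals.json").read_text()
    return json.loads(text)


@dataclass
class PhantomParams:
    image_px: int = 364
    n_slices: int = 11
    slice_pitch_um: float = 10.0
    well_diameter_um: float = 280.0
    blastocyst_diameter_um: float | None = None  # None -> drawn per embryo
    shell_thickness_um: float = 12.0
    icm_radius_um: float = 25.0
    icm_height_frac: float = 0.45  # ICM center height as a fraction of R
    noise_sd: float = 0.03
    n_debris: int = 14  # background clutter blobs per slice (mean)
    blur_sigma_by_offset: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_slices % 2 != 1:
            raise ValueError("n_slices must be odd")
        if self.blur_sigma_by_offset is None:
            c = self.center_slice
            self.blur_sigma_by_offset = {
                i: 0.5 + 0.12 * abs(i - c) for i in range(self.n_slices)
            }

    @property
    def center_slice(self) -> int:
        return (self.n_slices - 1) // 2

    @property
    def pixel_size_um(self) -> float:
        return self.well_diameter_um / self.image_px


@dataclass
class SyntheticEmbryo:
    embryo_id: str
    stack: SliceStack
    masks: np.ndarray  # (n_slices, H, W) bool
    cee: dict[str, float]
    outcome: int
    latent_quality: float
    implant_probability: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# image rendering

_BG = 0.12
_WELL = 0.50
_CAVITY = 0.28


def render_noiseless_slice(params: PhantomParams, slice_index: int,
                           diameter_um: float, quality: float,
                           jitter_px: tuple[float, float] = (0.0, 0.0),
                           phases: tuple[float, float] = (0.0, 0.0),
                           ring_intensity: float = _WELL,
                           debris: list | None = None):
    """Render one slice without noise/blur; returns (image, mask).

    ``debris`` is an optional list of (y, x, radius_px, intensity) clutter
    blobs rendered in the background only (never inside the mask).
    """
    px = params.image_px
    scale = params.pixel_size_um
    r_blast_px = (diameter_um / 2.0) / scale
    well_r_px = px / 2.0 * 0.98
    if r_blast_px >= well_r_px:
        raise GeometryError(
            f"blastocyst radius {r_blast_px:.1f}px >= well radius {well_r_px:.1f}px"
        )
    yy, xx = np.mgrid[0:px, 0:px].astype(np.float64)
    cy = px / 2.0 + jitter_px[0]
    cx = px / 2.0 + jitter_px[1]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    img = np.full((px, px), _BG)
    # well frame: annular ring near the image border
    ring_w = max(2.0, 0.02 * px)
    r_center = np.hypot(yy - px / 2.0, xx - px / 2.0)
    img[(r_center >= well_r_px - ring_w) & (r_center <= well_r_px)] = ring_intensity
    for (db_y, db_x, db_r, db_i) in debris or []:
        blob = np.hypot(yy - db_y, xx - db_x) <= db_r
        img[blob & (rr > r_blast_px * 1.08)] = db_i

    z_um = (slice_index - params.center_slice) * params.slice_pitch_um
    R_um = diameter_um / 2.0
    mask = np.zeros((px, px), dtype=bool)
    if abs(z_um) < R_um:
        r_um = np.sqrt(R_um ** 2 - z_um ** 2)
        r_px = r_um / scale
        # shell irregularity grows as quality falls
        amp = 0.04 * (1.0 - quality)
        boundary = r_px * (1.0 + amp * np.sin(3 * theta + phases[0])
                           + 0.7 * amp * np.sin(5 * theta + phases[1]))
        inside = rr <= boundary
        mask = inside
        shell_px = max(1.5, params.shell_thickness_um / scale)
        cavity = rr <= boundary - shell_px
        img[inside] = 0.85  # shell brightness fixed: quality signal must
        img[cavity] = _CAVITY  # survive per-volume min-max normalization
        # ICM: a sphere well above the equator (mostly invisible on the
        # center slice, so the 3-D stack carries extra signal); its size and
        # brightness relative to the shell encode the quality
        icm_r_um = params.icm_radius_um * (0.5 + 1.0 * quality)
        icm_z_um = params.icm_height_frac * R_um
        dz = z_um - icm_z_um
        if abs(dz) < icm_r_um:
            icm_rpx = np.sqrt(icm_r_um ** 2 - dz ** 2) / scale
            off = max(r_px - shell_px - icm_r_um / scale, 0.0) * 0.8
            icm_cy, icm_cx = cy - off, cx
            icm = np.hypot(yy - icm_cy, xx - icm_cx) <= icm_rpx
            img[icm & cavity] = 0.45 + 0.40 * quality
    return img, mask


def generate_stack(params: PhantomParams, quality: float = 0.5,
                   embryo_id: str = "phantom-0") -> tuple[SliceStack, np.ndarray]:
    """Render the full tomographic stack plus ground-truth masks.

    Noise and blur are seeded by ``params.seed``; the same seed reproduces
    the stack bit-identically.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng([int(params.seed), 0x57AC])
    diameter = params.blastocyst_diameter_um
    if diameter is None:
        marg = load_default_marginals()["avg_diameter"]
        diameter = float(np.clip(rng.normal(marg["mean"], marg["sd"]),
                                 marg["min"], marg["max"]))
    jitter = tuple(rng.uniform(-0.02, 0.02, size=2) * params.image_px)
    phases = tuple(rng.uniform(0, 2 * np.pi, size=2))
    ring_intensity = float(rng.uniform(0.40, 0.85))
    px = params.image_px
    r_blast_px = (diameter / 2.0) / params.pixel_size_um
    slices, masks = [], []
    for i in range(params.n_slices):
        # background clutter: seeded debris blobs between embryo and ring
        debris = []
        # per-stack brightness ceiling randomizes the min-max scale of
        # unmasked volumes; masked volumes are unaffected
        debris_peak = float(rng.uniform(0.7, 1.3))
        for _ in range(int(rng.poisson(params.n_debris))):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(min(r_blast_px * 1.15, px * 0.47), px * 0.47)
            debris.append((px / 2 + rad * np.sin(ang),
                           px / 2 + rad * np.cos(ang),
                           rng.uniform(0.015, 0.05) * px,
                           rng.uniform(0.4, debris_peak)))
        img, mask = render_noiseless_slice(params, i, diameter, quality,
                                           jitter_px=jitter, phases=phases,
                                           ring_intensity=ring_intensity,
                                           debris=debris)
        # low-frequency optical mottle on the background only: removed by
        # masking, so background elimination measurably helps downstream
        mottle = gaussian_filter(rng.normal(size=img.shape), sigma=0.05 * px)
        sd = mottle.std() or 1.0
        amp = rng.uniform(0.10, 0.30)
        img = np.where(mask, img, np.clip(img + amp * mottle / sd, 0.0, None))
        sigma = params.blur_sigma_by_offset.get(i, 0.5)
        img = gaussian_filter(img, sigma=sigma)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        slices.append(np.clip(img, 0.0, 1.0))
        masks.append(mask)
    stack = SliceStack(
        embryo_id=embryo_id,
        slices=np.stack(slices),
        pixel_size_um=params.pixel_size_um,
        slice_pitch_um=params.slice_pitch_um,
        meta={"diameter_um": diameter, "quality": quality},
    )
    return stack, np.stack(masks)


# ---------------------------------------------------------------------------
# clinical factor table


def _maxent_categorical(support: np.ndarray, target_mean: float) -> np.ndarray:
    """Maximum-entropy pmf on ``support`` with the requested mean
    (exponential-family tilt, lambda solved by bisection)."""
    support = np.asarray(support, dtype=float)
    if not (support.min() < target_mean < support.max()):
        raise ValueError("target mean outside support range")

    def mean_at(lam):
        w = np.exp(lam * (support - support.mean()))
        p = w / w.sum()
        return float(p @ support) - target_mean

    lam = optimize.brentq(mean_at, -50.0, 50.0)
    w = np.exp(lam * (support - support.mean()))
    return w / w.sum()


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Underlying normal location whose [lo, hi]-truncated mean hits target."""

    def f(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    span = 4.0 * sd
    return optimize.brentq(f, target_mean - span, target_mean + span)


def sample_factor(name: str, n: int, rng: np.random.Generator,
                  marginals: dict | None = None) -> np.ndarray:
    marg = (marginals or load_default_marginals())[name]
    if marg["kind"] == "ordinal":
        support = np.asarray(marg["support"], dtype=float)
        p = _maxent_categorical(support, marg["mean"])
        return rng.choice(support, size=n, p=p)
    loc = _truncnorm_loc(marg["mean"], marg["sd"], marg["min"], marg["max"])
    a = (marg["min"] - loc) / marg["sd"]
    b = (marg["max"] - loc) / marg["sd"]
    x = stats.truncnorm.rvs(a, b, loc=loc, scale=marg["sd"], size=n,
                            random_state=rng)
    if marg.get("integer"):
        x = np.clip(np.round(x), marg["min"], marg["max"])
    return x


def generate_cee_table(n: int, seed: int,
                       marginals: dict | None = None) -> pd.DataFrame:
    """Sample n records whose marginals match the reference cohort:
    mean-preserving truncated normals for continuous factors, maximum-entropy
    categoricals for ordinal grades. Factors are drawn independently."""
    if n < 1:
        raise ValueError("n must be >= 1")
    marginals = marginals or load_default_marginals()
    cols = {}
    for j, name in enumerate(FACTOR_ORDER):
        rng = np.random.default_rng([int(seed), 0xCEE, j])
        cols[name] = sample_factor(name, n, rng, marginals)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# outcome model


def implantation_probability(record, specs: dict[str, RegressionSpec],
                             latent_quality: float,
                             weight_image: float = 0.5) -> float:
    """Convex combination of the mean regression output (clipped to [0,1])
    and the image-side latent quality."""
    if not (0.0 <= weight_image <= 1.0):
        raise ValueError("weight_image must be in [0, 1]")
    vec = cee_feature_vector(record, specs)
    cee_part = float(np.clip(vec.mean(), 0.0, 1.0))
    return (1.0 - weight_image) * cee_part + weight_image * float(latent_quality)


def generate_outcome(record, latent_quality: float,
                     specs: dict[str, RegressionSpec], weight_image: float,
                     seed: int) -> int:
    """Bernoulli implantation label with :func:`implantation_probability`."""
    p = implantation_probability(record, specs, latent_quality, weight_image)
    rng = np.random.default_rng([int(seed), 0x0D7])
    return int(rng.random() < p)


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(n: int, seed: int, specs: dict[str, RegressionSpec],
                    params: PhantomParams | None = None,
                    weight_image: float = 0.5,
                    marginals: dict | None = None,
                    render: bool = True) -> list[SyntheticEmbryo]:
    """Full synthetic cohort: stacks + masks + CEE records + outcomes.

    ``latent_quality`` drives the image (diameter, shell regularity, ICM
    size/brightness) so the image branch carries signal beyond the CEE table;
    the blastocyst diameter is drawn correlated with quality and written into
    the CEE record so the two stay consistent.
    """
    params = params or PhantomParams()
    marginals = marginals or load_default_marginals()
    table = generate_cee_table(n, seed, marginals)
    diam = marginals["avg_diameter"]
    embryos = []
    rho = 0.6
    for i in range(n):
        rng = np.random.default_rng([int(seed), 0xE0B, i])
        # bimodal quality spreads the outcome probability enough for the
        # image branch to be learnable at desk-scale cohort sizes
        quality = float(rng.beta(0.25, 0.25))
        z_q = stats.norm.ppf(np.clip(quality, 1e-6, 1 - 1e-6))
        z_n = rng.normal()
        loc = _truncnorm_loc(diam["mean"], diam["sd"], diam["min"], diam["max"])
        d = loc + diam["sd"] * (rho * z_q + np.sqrt(1 - rho ** 2) * z_n)
        d = float(np.clip(d, diam["min"], diam["max"]))
        record = table.iloc[i].to_dict()
        record["avg_diameter"] = d
        outcome = generate_outcome(record, quality, specs, weight_image,
                                   seed=int(rng.integers(2 ** 31)))
        p = implantation_probability(record, specs, quality, weight_image)
        embryo_id = f"E{i:05d}"
        if render:
            # expanded/hatching blastocysts can exceed the well diameter in
            # the reference cohort; the rendered sphere is capped to fit the
            # frame while the CEE record keeps the drawn value
            d_render = min(d, 0.90 * params.well_diameter_um)
            p_i = replace(params, blastocyst_diameter_um=d_render,
                          seed=int(np.random.default_rng(
                              [int(seed), 0x1A6, i]).integers(2 ** 31)))
            stack, masks = generate_stack(p_i, quality=quality,
                                          embryo_id=embryo_id)
        else:
            stack, masks = None, None
        embryos.append(SyntheticEmbryo(
            embryo_id=embryo_id, stack=stack, masks=masks, cee=record,
            outcome=outcome, latent_quality=quality, implant_probability=p,
        ))
    return embryos


def cohort_table(embryos: list[SyntheticEmbryo]) -> pd.DataFrame:
    rows = []
    for e in embryos:
        row = {"embryo_id": e.embryo_id, **e.cee, "outcome": e.outcome,
               "latent_quality": e.latent_quality}
        rows.append(row)
    return pd.DataFrame(rows)
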