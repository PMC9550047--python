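"""Synthetic shoulder-phantom cohorts for exercising the segmentation pipeline.

Each phantom emulates the statistical structure of a coronal shoulder MRI
around the rotator cuff: four labelled structures (muscle, humerus, cuff
tendon, humeral-head cartilage) on a strongly anisotropic grid, plus one
deliberately *unlabelled* confuser — a thin tube whose intensity matches the
tendon's, standing in for the biceps long head.  Because the confuser looks
like tendon but carries no ground-truth label, a naive model predicts it as
tendon, producing exactly the false-positive failure mode the two-stage
secondary-labelling procedure is designed to remove.

Geometry is deliberately crude (ellipsoid + cylinder humerus, spherical-cap
shells for cartilage and tendon, a prism of muscle) but preserves the
adjacency relations that matter: the tendon caps the humeral head over the
cartilage, abuts the muscle medially, and the confuser runs near — but never
touching — the tendon.  A per-case tear category (intact … massive) carves an
azimuthal gap of increasing width out of the tendon sheet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volio import ImageVolume, LabelMap, write_labelmap, write_volume

__all__ = [
    "TEAR_CATEGORIES",
    "TEAR_FRACTIONS",
    "CLASS_NAMES",
    "PhantomSpec",
    "PhantomCase",
    "PlacementError",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

# ordinal tear-severity categories; the fraction is the azimuthal share of the
# tendon sheet removed (strictly increasing => monotone tendon volume)
TEAR_CATEGORIES = ("intact", "partial", "small", "medium", "large", "massive")
TEAR_FRACTIONS = {
    "intact": 0.0,
    "partial": 0.1,
    "small": 0.2,
    "medium": 0.35,
    "large": 0.55,
    "massive": 0.8,
}

# label indices of the ground-truth classes (confuser intentionally absent)
CLASS_NAMES = {0: "background", 1: "muscle", 2: "humerus", 3: "tendon", 4: "cartilage"}
N_CLASSES = 5


class PlacementError(RuntimeError):
    """Raised when the grid is too small to place a named structure."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``class_intensities`` maps structure name -> mean intensity; the confuser
    intensity must stay within 10% of the intensity range of the tendon's so
    the two remain genuinely confusable.
    """

    grid_shape: tuple[int, int, int] = (16, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 0.29, 0.29)
    tear_category: str = "intact"
    class_intensities: dict = field(
        default_factory=lambda: {
            "background": 0.05,
            "muscle": 0.35,
            "humerus": 0.90,
            "tendon": 0.55,
            "cartilage": 0.75,
            "confuser": 0.55,
        }
    )
    noise_sd: float = 0.05
    bias_amplitude: float = 0.15
    confuser_gap_mm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 8 for g in self.grid_shape):
            raise ValueError(f"all grid_shape entries must be >= 8, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing entries must be > 0, got {self.spacing_mm}")
        if self.tear_category not in TEAR_CATEGORIES:
            raise ValueError(
                f"tear_category must be one of {TEAR_CATEGORIES}, got {self.tear_category!r}"
            )
        ints = self.class_intensities
        rng_span = max(ints.values()) - min(ints.values())
        if abs(ints["confuser"] - ints["tendon"]) > 0.1 * rng_span:
            raise ValueError(
                "confuser intensity must be within 10% of the intensity range "
                "of the tendon intensity (it must be tendon-like)"
            )
        if self.noise_sd < 0 or self.bias_amplitude < 0 or self.confuser_gap_mm < 0:
            raise ValueError("noise_sd, bias_amplitude and confuser_gap_mm must be >= 0")


@dataclass
class PhantomCase:
    """One synthetic patient: image + ground truth + confuser mask + tear size."""

    image: ImageVolume
    truth: LabelMap
    confuser_mask: np.ndarray
    tear_category: str
    case_id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.truth.shape:
            raise ValueError("image and truth must share the grid")
        if self.image.spacing_mm != self.truth.spacing_mm:
            raise ValueError("image and truth must share the spacing")
        if np.any(self.confuser_mask & (self.truth.labels != 0)):
            raise ValueError("confuser mask must not overlap labelled foreground")


def _coords_mm(shape, spacing):
    """Voxel-centre coordinate grids in mm, axis order (slice,row,col)."""
    axes = [
        (np.arange(n, dtype=np.float32) + 0.5) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterize one phantom case, deterministic in ``spec`` (incl. its seed).

    The image is the sum of class indicators times their mean intensities,
    modulated by a smooth multiplicative bias field and additive Gaussian
    noise.  Raises :class:`PlacementError` when the grid cannot host a
    structure.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(g) for g in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)
    Z, Y, X = _coords_mm(shape, spacing)
    ext = tuple(n * s for n, s in zip(shape, spacing))

    # per-case anatomical jitter so cohorts are not clones of one geometry:
    # head position, head size and the orientation of the cap axis all vary
    jit = rng.uniform(-1.0, 1.0, size=6)
    head_c = np.array(
        [
            0.50 * ext[0] + 0.04 * ext[0] * jit[0],
            0.62 * ext[1] + 0.04 * ext[1] * jit[1],
            0.62 * ext[2] + 0.04 * ext[2] * jit[2],
        ]
    )
    r_head = 0.24 * min(ext[1], ext[2]) * (1.0 + 0.08 * jit[3])
    t_cart = 0.22 * r_head
    t_tend = 0.40 * r_head

    dz, dy, dx = Z - head_c[0], Y - head_c[1], X - head_c[2]
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    # cap axis: roughly "up" (toward the acromion = decreasing row index),
    # tilted by up to ~12 degrees per case
    a, b = np.deg2rad(12) * jit[4], np.deg2rad(12) * jit[5]
    up = np.array([np.sin(a), -np.cos(a) * np.cos(b), np.cos(a) * np.sin(b)])
    up /= np.linalg.norm(up)
    rr = np.maximum(r, 1e-6)
    cos_theta = np.where(
        r > 1e-6, (dz * up[0] + dy * up[1] + dx * up[2]) / rr, 1.0
    )

    humerus = r <= r_head
    # shaft: cylinder running inferiorly from the head
    shaft_r = 0.60 * r_head
    shaft = (np.sqrt(dz**2 + dx**2) <= shaft_r) & (dy >= 0) & (Y <= 0.97 * ext[1])
    humerus = humerus | shaft

    cartilage = (r > r_head) & (r <= r_head + t_cart) & (cos_theta > np.cos(np.deg2rad(75)))
    tendon_full = (
        (r > r_head + t_cart)
        & (r <= r_head + t_cart + t_tend)
        & (cos_theta > np.cos(np.deg2rad(70)))
    )

    # tear: carve a nested azimuthal window out of the tendon sheet
    frac = TEAR_FRACTIONS[spec.tear_category]
    phi0 = rng.uniform(-np.pi, np.pi)
    tendon = tendon_full
    if frac > 0:
        phi = np.arctan2(dz, dx)  # azimuth about the "up" axis
        dphi = np.angle(np.exp(1j * (phi - phi0)))
        tendon = tendon_full & ~(np.abs(dphi) <= frac * np.pi)

    muscle_box = (
        (X >= 0.02 * ext[2])
        & (X <= 0.35 * ext[2])
        & (Y >= 0.15 * ext[1])
        & (Y <= 0.75 * ext[1])
        & (Z >= 0.15 * ext[0])
        & (Z <= 0.85 * ext[0])
    )
    muscle = muscle_box & ~(humerus | cartilage | tendon_full)

    for name, mask in [
        ("muscle", muscle),
        ("humerus", humerus),
        ("tendon", tendon),
        ("cartilage", cartilage),
    ]:
        if not mask.any():
            raise PlacementError(f"grid {shape} too small to place structure '{name}'")

    truth = np.zeros(shape, dtype=np.int16)
    # priority order resolves rare shell overlaps deterministically
    truth[muscle] = 1
    truth[humerus] = 2
    truth[tendon] = 3
    truth[cartilage] = 4

    confuser = _place_confuser(
        truth, tendon_full, r, cos_theta, np.arctan2(dz, dx),
        (r_head, t_cart, t_tend), spacing, spec.confuser_gap_mm, rng,
    )

    # image synthesis: indicators x intensities, bias field, Gaussian noise
    ints = spec.class_intensities
    img = np.full(shape, ints["background"], dtype=np.float32)
    img[muscle] = ints["muscle"]
    img[humerus] = ints["humerus"]
    img[tendon] = ints["tendon"]
    img[cartilage] = ints["cartilage"]
    img[confuser] = ints["confuser"]

    if spec.bias_amplitude > 0:
        ph = rng.uniform(0, 2 * np.pi, size=3)
        bias = 1.0 + spec.bias_amplitude * (
            np.cos(2 * np.pi * Z / ext[0] + ph[0])
            * np.cos(2 * np.pi * Y / ext[1] + ph[1])
            * np.cos(2 * np.pi * X / ext[2] + ph[2])
        )
        img = img * bias.astype(np.float32)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    return PhantomCase(
        image=ImageVolume(values=img.astype(np.float32), spacing_mm=spacing),
        truth=LabelMap(labels=truth, spacing_mm=spacing, n_classes=N_CLASSES),
        confuser_mask=confuser,
        tear_category=spec.tear_category,
        case_id=f"phantom-s{spec.seed}",
    )


def _place_confuser(truth, tendon_full, r, cos_theta, phi, radii, spacing, gap_mm, rng):
    """Carve the biceps analogue: a tendon-like shell strip past the cap edge.

    The confuser occupies the same radial shell as the tendon (so its local
    appearance — a curved band of tendon intensity hugging the humeral head —
    is indistinguishable from the cuff tendon) but sits at higher polar
    angle, beyond the cap's 70° edge, over a narrow seeded-random azimuthal
    window.  A distance-transform erosion then guarantees the ``gap_mm``
    clearance from the (untorn) tendon sheet, and any voxel already carrying
    a ground-truth label is excluded, keeping the confuser unlabelled by
    construction.
    """
    r_head, t_cart, t_tend = radii
    # like the real biceps long head, the confuser occupies a *consistent*
    # anatomical position — a band past the cap edge running roughly along
    # the slice axis — with mild per-case jitter, staying clear of the cap by
    # at least the angular equivalent of the gap
    theta0 = max(
        np.deg2rad(85 + rng.uniform(-5, 5)),
        np.deg2rad(70) + gap_mm / max(r_head + t_cart, 1e-6),
    )
    theta1 = theta0 + np.deg2rad(40)
    ct0, ct1 = np.cos(theta0), np.cos(theta1)

    phi0 = np.pi / 2 + np.deg2rad(rng.uniform(-15, 15))
    half_width = np.deg2rad(45)
    dphi = np.angle(np.exp(1j * (phi - phi0)))

    strip = (
        (r > r_head + t_cart)
        & (r <= r_head + t_cart + t_tend)
        & (cos_theta <= ct0)
        & (cos_theta > ct1)
        & (np.abs(dphi) <= half_width)
    )
    # enforce the clearance exactly against the untorn sheet
    dist_tendon = ndimage.distance_transform_edt(~tendon_full, sampling=spacing)
    confuser = strip & (dist_tendon >= gap_mm) & (truth == 0)
    if not confuser.any():
        raise PlacementError("grid too small to place structure 'confuser'")
    return confuser


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    category_mix: dict | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n`` phantoms with tear categories allocated per ``category_mix``.

    Category counts are the largest-remainder quota of ``mix * n`` (so a
    uniform mix over six categories at n=6 yields one case of each), assigned
    to cases in a seeded random order.  Per-case seeds derive deterministically
    from the cohort seed.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if base_spec is None:
        base_spec = PhantomSpec()
    if category_mix is None:
        category_mix = {c: 1.0 / len(TEAR_CATEGORIES) for c in TEAR_CATEGORIES}
    cats = [c for c in TEAR_CATEGORIES if category_mix.get(c, 0) > 0]
    probs = np.array([category_mix[c] for c in cats], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("category_mix proportions must sum to 1")

    # largest-remainder quota
    raw = probs * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    assigned = [c for c, k in zip(cats, counts) for _ in range(k)]

    rng = np.random.default_rng(seed)
    assigned = [assigned[i] for i in rng.permutation(n)]
    case_seeds = rng.integers(0, 2**31 - 1, size=n)

    cases = []
    for i, (cat, cseed) in enumerate(zip(assigned, case_seeds)):
        spec = replace(base_spec, tear_category=cat, seed=int(cseed))
        case = generate_phantom(spec)
        case.case_id = f"case{i:03d}"
        cases.append(case)
    return cases


def write_cohort(cases: list[PhantomCase], out_dir: str | os.PathLike) -> str:
    """Write paired NIfTI files plus a CSV manifest; returns the manifest path."""
    import csv

    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(os.fspath(out_dir), "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "tear_category"])
        for case in cases:
            write_volume(case.image, os.path.join(out_dir, f"{case.case_id}_img.nii.gz"))
            write_labelmap(case.truth, os.path.join(out_dir, f"{case.case_id}_lbl.nii.gz"))
            cmask = LabelMap(
                labels=case.confuser_mask.astype(np.int16),
                spacing_mm=case.truth.spacing_mm,
                n_classes=2,
            )
            write_labelmap(cmask, os.path.join(out_dir, f"{case.case_id}_confuser.nii.gz"))
            w.writerow([case.case_id, case.tear_category])
    return manifest


def load_cohort(out_dir: str | os.PathLike) -> list[PhantomCase]:
    """Read a cohort previously written by :func:`write_cohort`."""
    import csv

    from .volio import read_labelmap, read_volume

    cases = []
    with open(os.path.join(os.fspath(out_dir), "manifest.csv")) as fh:
        for row in csv.DictReader(fh):
            cid = row["case_id"]
            image = read_volume(os.path.join(out_dir, f"{cid}_img.nii.gz"))
            truth = read_labelmap(os.path.join(out_dir, f"{cid}_lbl.nii.gz"), N_CLASSES)
            conf = read_labelmap(os.path.join(out_dir, f"{cid}_confuser.nii.gz"), 2)
            cases.append(
                PhantomCase(
                    image=image,
                    truth=truth,
                    confuser_mask=conf.labels.astype(bool),
                    tear_category=row["tear_category"],
                    case_id=cid,
                )
            )
    return cases
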