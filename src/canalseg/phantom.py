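"""Synthetic paired micro-CT / CBCT tooth phantoms with known canal geometry.

No public dataset of paired micro-CT and CBCT tooth scans exists, so this
module generates parameterized digital teeth that reproduce the imaging
physics the segmentation problem hinges on: a bright enamel cap over a
dentin body (enamel > dentin > canal/background intensity), internal tapered
root canals opening into a pulp chamber, optional canal curvature, accessory
branches and inter-canal isthmuses; a high-resolution "micro-CT" rendering;
and a degraded "CBCT" rendering obtained by rigid pose offset, Gaussian
point-spread blur, downsampling to a clinical voxel size (200 or 80 µm) and
additive noise.

Scale note: the phantoms are miniature teeth (roots of a few mm) rendered at
the literal scanner voxel sizes (30 µm micro-CT, 200/80 µm CBCT). This keeps
grids at a few million voxels while preserving the governing ratio of canal
diameter to CBCT voxel size — the mechanism that makes fine canals hard to
segment at coarse resolution.

The z axis runs from root apex (z = 0 side) to crown top; axial slices are
``data[k]``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform
from .volume import BinaryMask, Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "generate_tooth",
    "simulate_cbct",
    "degrade_labels",
    "generate_cohort",
    "contrast_separation",
]

UCT_VOXEL_MM = 0.03          # micro-CT isotropic voxel size
MARGIN_MM = 0.45             # background margin around the tooth
APEX_SEAL_MM = 0.35          # canal ends this far short of the root apex


@dataclass
class PhantomSpec:
    """Generative description of one synthetic tooth.

    ``tooth_class`` is "SR" (single-rooted) or "M" (molar); molars have 2–3
    roots and may carry an isthmus between canals. Canal radii taper linearly
    from ``canal_radius_coronal`` at the pulp chamber to
    ``canal_radius_apical`` near the apex. ``canal_curvature`` is the lateral
    bend (mm) of the root/canal axis, quadratic in arc position. Intensities
    must be ordered enamel > dentin > canal (canal space images like
    background soft tissue/air).
    """

    tooth_class: str = "SR"
    n_roots: int = 1
    root_length: float = 3.0          # mm
    crown_radius: float = 1.15        # mm
    canal_radius_coronal: float = 0.26
    canal_radius_apical: float = 0.10
    canal_curvature: float = 0.0      # mm lateral bend
    accessory_canal: bool = False
    accessory_level: float = 0.45     # fraction of root length (0 apex, 1 coronal)
    isthmus: bool = False
    enamel_intensity: float = 2000.0
    dentin_intensity: float = 1000.0
    canal_intensity: float = 100.0    # also the background level
    voxel_size: float = UCT_VOXEL_MM
    seed: int = 0

    def validate(self) -> None:
        if self.tooth_class not in ("SR", "M"):
            raise ValueError(f"tooth_class must be 'SR' or 'M', got {self.tooth_class!r}")
        if self.tooth_class == "SR" and self.n_roots != 1:
            raise ValueError("single-rooted teeth must have exactly one root")
        if not 1 <= self.n_roots <= 3:
            raise ValueError("n_roots must be between 1 and 3")
        if self.canal_radius_apical > self.canal_radius_coronal:
            raise ValueError("canal must taper: apical radius <= coronal radius")
        if min(self.canal_radius_apical, self.canal_radius_coronal) <= 0:
            raise ValueError("canal radii must be positive")
        if not (self.enamel_intensity > self.dentin_intensity > self.canal_intensity):
            raise ValueError("intensities must satisfy enamel > dentin > canal")
        if self.isthmus and self.tooth_class != "M":
            raise ValueError("isthmus is only defined for molars")
        if self.root_length <= 0 or self.crown_radius <= 0 or self.voxel_size <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class PhantomPair:
    """One rendered phantom: micro-CT bundle plus its degraded CBCT twin."""

    spec: PhantomSpec
    uct: Volume3D
    tooth_gt: BinaryMask
    canal_gt: BinaryMask
    cbct: Volume3D
    pose: RigidTransform  # micro-CT world -> CBCT world


def _root_layout(spec: PhantomSpec) -> list[dict]:
    """Per-root base/apex in-plane centers and radii (world mm, (y, x))."""
    if spec.n_roots == 1:
        bases = [(0.0, 0.0)]
    else:
        sep = 0.52 * spec.crown_radius
        if spec.n_roots == 2:
            bases = [(0.0, -sep), (0.0, sep)]
        else:
            bases = [(-sep * 0.9, -sep * 0.8), (-sep * 0.9, sep * 0.8), (sep, 0.0)]
    roots = []
    r_base = (0.72 if spec.n_roots == 1 else 0.42) * spec.crown_radius
    for b in bases:
        roots.append(
            {
                "base": np.asarray(b),
                # roots converge slightly toward the tooth axis at the apex
                "apex": np.asarray(b) * 0.55,
                "r_base": r_base,
                "r_apex": 0.16,
            }
        )
    return roots


def _axis_at(root: dict, spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    """In-plane (y, x) medial-axis position for heights z in [0, L]."""
    L = spec.root_length
    s = np.clip(1.0 - z / L, 0.0, 1.0)  # 0 coronal, 1 at apex
    straight = root["base"][None, :] + (root["apex"] - root["base"])[None, :] * s[:, None]
    bend = spec.canal_curvature * s**2  # quadratic bend, applied along +x
    out = straight.copy()
    out[:, 1] += bend
    return out


def generate_tooth(spec: PhantomSpec):
    """Rasterize a phantom: returns ``(uct, tooth_gt, canal_gt)`` at 30 µm.

    The tooth solid is the union of a crown ellipsoid (enamel shell over a
    dentin core) and tapered root cones; the canal system is a set of
    tapering tubes along each root's (optionally curved) medial axis, fused
    to a pulp-chamber cavity inside the crown, ending short of the apex so
    the whole canal is an enclosed cavity (as a thresholded micro-CT model
    resolves it). Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    v = spec.voxel_size
    L = spec.root_length
    crown_az = 0.85 * spec.crown_radius           # crown semi-axis along z
    roots = _root_layout(spec)

    spread = max(
        float(np.max(np.abs(np.concatenate([[r["base"], r["apex"]] for r in roots]))))
        + max(r["r_base"] for r in roots),
        spec.crown_radius,
    ) + abs(spec.canal_curvature)
    half_xy = spread + MARGIN_MM
    # crown center sits just above the root junction so crown and roots
    # overlap over a band (an enclosed pulp chamber needs a solid neck)
    crown_cz = L + 0.35 * crown_az
    z_top = crown_cz + crown_az + MARGIN_MM
    z_bot = -MARGIN_MM

    nz = int(np.ceil((z_top - z_bot) / v))
    nxy = int(np.ceil(2 * half_xy / v))
    origin = np.array([z_bot, -half_xy, -half_xy])

    zs = origin[0] + np.arange(nz) * v
    yy = (origin[1] + np.arange(nxy) * v)[:, None]
    xx = (origin[2] + np.arange(nxy) * v)[None, :]

    tooth = np.zeros((nz, nxy, nxy), bool)
    enamel = np.zeros_like(tooth)
    canal = np.zeros_like(tooth)

    crown_c = np.array([crown_cz, 0.0, 0.0])
    inner_scale = 0.74

    chamber_c = np.array([crown_cz - 0.15 * crown_az, 0.0, 0.0])
    chamber_axes = np.array([0.5 * crown_az, 0.45 * spec.crown_radius,
                             0.45 * spec.crown_radius])
    # chamber must reach each canal top; widen it to cover root-base offsets
    base_span = max(float(np.max(np.abs([r["base"] for r in roots]))), 0.0)
    chamber_axes[1:] = np.maximum(chamber_axes[1:], base_span + 2.2 * spec.canal_radius_coronal)
    chamber_axes[1:] = np.minimum(chamber_axes[1:],
                                  0.92 * inner_scale * spec.crown_radius)

    # per-root canal vertical span: tubes run from the root junction (where
    # the chamber floor reaches) down to the apical seal
    canal_top = L
    canal_bot = APEX_SEAL_MM

    acc_root = 0
    acc_dir = None
    acc_len = 0.0
    if spec.accessory_canal:
        acc_root = int(rng.integers(0, len(roots)))
        phi = rng.uniform(0, 2 * np.pi)
        acc_dir = np.array([-0.6, np.sin(phi), np.cos(phi)])
        acc_dir /= np.linalg.norm(acc_dir)

    for k, z in enumerate(zs):
        # crown ellipsoids
        dz = (z - crown_c[0]) / crown_az
        if abs(dz) <= 1.0:
            rad2 = (yy - crown_c[1]) ** 2 + (xx - crown_c[2]) ** 2
            lim = (1.0 - dz**2) * spec.crown_radius**2
            outer = rad2 <= lim
            dz_i = (z - crown_c[0]) / (inner_scale * crown_az)
            if abs(dz_i) <= 1.0:
                lim_i = (1.0 - dz_i**2) * (inner_scale * spec.crown_radius) ** 2
                inner = rad2 <= lim_i
            else:
                inner = np.zeros_like(outer)
            tooth[k] |= outer
            enamel[k] |= outer & ~inner
        # roots
        if 0.0 <= z <= L:
            s = z / L
            for root in roots:
                c = _axis_at(root, spec, np.array([z]))[0]
                r = root["r_apex"] + (root["r_base"] - root["r_apex"]) * s
                # rounded apex: shrink radius near the very tip
                if z < 0.3:
                    r *= max(z / 0.3, 0.05)
                tooth[k] |= (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r**2
        # pulp chamber
        dzc = (z - chamber_c[0]) / chamber_axes[0]
        if abs(dzc) <= 1.0:
            rad2n = ((yy - chamber_c[1]) / chamber_axes[1]) ** 2 + (
                (xx - chamber_c[2]) / chamber_axes[2]
            ) ** 2
            canal[k] |= rad2n <= (1.0 - dzc**2)
        # root canals
        if canal_bot <= z <= canal_top:
            szc = np.clip(z / L, 0.0, 1.0)
            r_can = spec.canal_radius_apical + (
                spec.canal_radius_coronal - spec.canal_radius_apical
            ) * szc
            for root in roots:
                c = _axis_at(root, spec, np.array([z]))[0]
                canal[k] |= (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r_can**2

    # accessory canal: thin lateral tube leaving a main canal part-way down a root
    if spec.accessory_canal:
        root = roots[acc_root]
        z0 = canal_bot + spec.accessory_level * (L - canal_bot)
        c0 = _axis_at(root, spec, np.array([z0]))[0]
        start = np.array([z0, c0[0], c0[1]])
        s_frac = z0 / L
        r_root_here = root["r_apex"] + (root["r_base"] - root["r_apex"]) * s_frac
        acc_len = max(r_root_here - 0.12, 0.2)
        r_acc = 0.4 * spec.canal_radius_apical
        n_steps = max(int(acc_len / (0.5 * v)), 2)
        for t in np.linspace(0.0, 1.0, n_steps):
            p = start + acc_dir * (t * acc_len)
            k = int(round((p[0] - origin[0]) / v))
            if not 0 <= k < nz:
                continue
            canal[k] |= (yy - p[1]) ** 2 + (xx - p[2]) ** 2 <= r_acc**2

    # isthmus: thin web joining the first two canals over a mid-root band.
    # A dentin sheath is added around it so the web remains an enclosed
    # cavity even where it crosses the inter-root (furcation) gap.
    if spec.isthmus and len(roots) >= 2:
        z_lo, z_hi = 0.55 * L, 0.75 * L
        half_th = 0.05
        sheath = half_th + 0.18
        for k, z in enumerate(zs):
            if not z_lo <= z <= z_hi:
                continue
            a = _axis_at(roots[0], spec, np.array([z]))[0]
            b = _axis_at(roots[1], spec, np.array([z]))[0]
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                continue
            ty = (yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]
            t = np.clip(ty / denom, 0.0, 1.0)
            py = a[0] + t * ab[0]
            px = a[1] + t * ab[1]
            d2 = (yy - py) ** 2 + (xx - px) ** 2
            tooth[k] |= d2 <= sheath**2
            canal[k] |= d2 <= half_th**2

    canal &= tooth  # enforce containment
    enamel &= tooth & ~canal

    img = np.full(tooth.shape, spec.canal_intensity, np.float32)
    img[tooth] = spec.dentin_intensity
    img[enamel] = spec.enamel_intensity
    img[canal] = spec.canal_intensity
    img += rng.normal(0.0, 0.02 * spec.dentin_intensity, img.shape).astype(np.float32)

    uct = Volume3D(img, v, origin)
    tooth_gt = BinaryMask(tooth.astype(np.uint8), v, origin.copy())
    canal_gt = BinaryMask(canal.astype(np.uint8), v, origin.copy())
    return uct, tooth_gt, canal_gt


def simulate_cbct(
    uct: Volume3D,
    target_voxel: float,
    psf_sigma: float | None = None,
    noise_sd: float | None = None,
    pose: RigidTransform | None = None,
    seed: int = 0,
) -> Volume3D:
    """Render a degraded CBCT twin of a micro-CT volume.

    The micro-CT world is mapped through ``pose`` into the CBCT world, the
    image is convolved with an isotropic Gaussian point-spread function of
    width ``psf_sigma`` (mm; default 1.0 × target voxel), resampled linearly
    onto an isotropic grid of ``target_voxel`` mm, and corrupted with
    additive Gaussian noise (default sd 5% of the 98th-percentile intensity,
    a dentin-level proxy). Deterministic per seed.
    """
    target_voxel = float(target_voxel)
    src_v = float(uct.voxel_size[0])
    if target_voxel <= src_v:
        raise ValueError(
            f"CBCT voxel ({target_voxel} mm) must exceed the source voxel ({src_v} mm)"
        )
    if pose is None:
        pose = RigidTransform.identity()
    if psf_sigma is None:
        psf_sigma = 1.0 * target_voxel
    if noise_sd is None:
        noise_sd = 0.05 * float(np.percentile(uct.data, 98))

    src = uct.data.astype(np.float32)
    fill = float(src.min())
    if psf_sigma > 0:
        src = ndimage.gaussian_filter(
            src, sigma=[psf_sigma / s for s in uct.voxel_size], mode="nearest"
        )

    # CBCT grid: axis-aligned box covering the posed source extent + margin
    n = np.asarray(uct.shape)
    corners = np.array(
        [[a, b, c] for a in (0, n[0] - 1) for b in (0, n[1] - 1) for c in (0, n[2] - 1)],
        float,
    )
    world = pose.apply(corners * uct.voxel_size + uct.origin)
    lo = world.min(axis=0) - 2 * target_voxel
    hi = world.max(axis=0) + 2 * target_voxel
    n_out = np.ceil((hi - lo) / target_voxel).astype(int)

    idx = np.stack(
        np.meshgrid(*[np.arange(m) for m in n_out], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = idx * target_voxel + lo
    back = pose.inverse().apply(centers)
    src_idx = (back - uct.origin) / uct.voxel_size
    vals = ndimage.map_coordinates(
        src, src_idx.T, order=1, mode="constant", cval=fill
    ).reshape(tuple(n_out))

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, vals.shape).astype(np.float32)
    return Volume3D(vals.astype(np.float32), target_voxel, lo)


def degrade_labels(
    gt: BinaryMask, dilate_voxels: int, boundary_jitter_sd: float = 0.0, seed: int = 0
) -> BinaryMask:
    """Simulate over-inclusive manual annotation of a mask.

    Manual CBCT annotation tends to overestimate structure boundaries; this
    surrogate dilates the ground truth by ``dilate_voxels`` and then toggles
    boundary voxels at random (probability proportional to
    ``boundary_jitter_sd``, capped at 0.5), never eating into the 1-voxel
    eroded core of the original mask. With jitter 0 the output is a strict
    superset of the input, so its recall of the original is 1 while its
    precision drops.
    """
    if dilate_voxels < 0:
        raise ValueError("dilate_voxels must be >= 0")
    fg = gt.as_bool()
    out = fg.copy()
    structure = ndimage.generate_binary_structure(3, 1)
    if dilate_voxels > 0:
        out = ndimage.binary_dilation(out, structure=structure, iterations=dilate_voxels)
    if boundary_jitter_sd > 0 and out.any():
        rng = np.random.default_rng(seed)
        interior = ndimage.binary_erosion(out, structure=structure, border_value=0)
        inner_bnd = out & ~interior
        outer_bnd = ndimage.binary_dilation(out, structure=structure) & ~out
        p = min(0.5, 0.5 * boundary_jitter_sd)
        core = ndimage.binary_erosion(fg, structure=structure, border_value=0)
        drop = inner_bnd & (rng.random(out.shape) < p) & ~core
        add = outer_bnd & (rng.random(out.shape) < p)
        out = (out & ~drop) | add
    return BinaryMask(out.astype(np.uint8), gt.voxel_size.copy(), gt.origin.copy())


def _sample_spec(rng: np.random.Generator, tooth_class: str) -> PhantomSpec:
    """Draw one tooth description from the cohort distribution."""
    if tooth_class == "SR":
        return PhantomSpec(
            tooth_class="SR",
            n_roots=1,
            root_length=float(rng.uniform(2.7, 3.4)),
            crown_radius=float(rng.uniform(1.0, 1.3)),
            canal_radius_coronal=float(rng.uniform(0.22, 0.30)),
            canal_radius_apical=float(rng.uniform(0.08, 0.12)),
            canal_curvature=float(rng.uniform(0.0, 0.35)),
            accessory_canal=bool(rng.random() < 0.3),
            accessory_level=float(rng.uniform(0.3, 0.6)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return PhantomSpec(
        tooth_class="M",
        n_roots=int(rng.integers(2, 4)),
        root_length=float(rng.uniform(2.4, 3.1)),
        crown_radius=float(rng.uniform(1.3, 1.6)),
        canal_radius_coronal=float(rng.uniform(0.18, 0.26)),
        canal_radius_apical=float(rng.uniform(0.07, 0.10)),
        canal_curvature=float(rng.uniform(0.0, 0.3)),
        accessory_canal=bool(rng.random() < 0.3),
        accessory_level=float(rng.uniform(0.3, 0.6)),
        isthmus=bool(rng.random() < 0.5),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _sample_pose(rng: np.random.Generator, max_rot_deg=10.0, max_trans_mm=1.0) -> RigidTransform:
    axis = rng.normal(size=3)
    angle = float(rng.uniform(0.2, max_rot_deg))
    trans = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
    return RigidTransform.from_axis_angle(axis, angle, trans)


def generate_cohort(
    n_sr: int,
    n_m: int,
    voxel: float = 0.08,
    seed: int = 0,
    psf_sigma: float | None = None,
    noise_sd: float | None = None,
) -> list[PhantomPair]:
    """Generate a reproducible cohort of paired micro-CT / CBCT phantoms.

    Per-tooth geometry is drawn from seeded ranges; each tooth gets a random
    rigid pose offset (rotation ≤ 10°, translation ≤ 1 mm) between its
    micro-CT and CBCT worlds, mimicking repositioning between scanners.
    """
    if n_sr < 0 or n_m < 0:
        raise ValueError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)
    pairs: list[PhantomPair] = []
    for tooth_class, count in (("SR", n_sr), ("M", n_m)):
        for _ in range(count):
            spec = _sample_spec(rng, tooth_class)
            uct, tooth_gt, canal_gt = generate_tooth(spec)
            pose = _sample_pose(rng)
            cbct = simulate_cbct(
                uct, voxel, psf_sigma=psf_sigma, noise_sd=noise_sd, pose=pose,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            pairs.append(PhantomPair(spec, uct, tooth_gt, canal_gt, cbct, pose))
    return pairs


def contrast_separation(image: Volume3D, region_a: BinaryMask, region_b: BinaryMask) -> float:
    """Separation of two tissue regions: |mean_a − mean_b| / pooled sd.

    Used to quantify the canal-vs-dentin contrast loss between CBCT voxel
    sizes; both region masks must live on the image grid.
    """
    for r in (region_a, region_b):
        if not image.same_grid(r):
            raise ValueError("region masks must share the image grid")
        if r.count == 0:
            raise ValueError("regions must be non-empty")
    a = image.data[region_a.as_bool()]
    b = image.data[region_b.as_bool()]
    pooled = np.sqrt((a.var() * a.size + b.var() * b.size) / (a.size + b.size))
    if pooled == 0:
        return float("inf")
    return float(abs(a.mean() - b.mean()) / pooled)


def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)
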