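"""Synthetic tensor phantoms and DWI simulation with known ground truth.

Real neonatal DTI cannot ship with a toolkit, so every stage is exercised
on phantoms: anisotropic fiber bundles (straight, arc, or polyline
centerlines) embedded in a near-isotropic background on a grid whose
default voxel size, 1.6 x 1.6 x 2.0 mm, mirrors a typical neonatal
acquisition.  Bundle voxels receive a cylindrically symmetric tensor whose
principal axis follows the local centerline tangent; diffusion-weighted
signals are synthesized from the tensor model over a 16-volume scheme
(15 directions at b = 800 s/mm^2 plus one b = 0) and optionally corrupted
with Rician noise.  All generators are pure functions of their spec and
seed, so reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reliability import PairedMeasurements
from .tensor import DiffusionTensorVolume, DwiVolume, GradientScheme

DEFAULT_VOXEL_SIZE = (1.6, 1.6, 2.0)  # mm, neonatal-protocol-like
DEFAULT_B_VALUE = 800.0               # s/mm^2

# Typical tensor eigenvalues (mm^2/s): immature white matter is strongly
# anisotropic; neonatal background tissue diffuses fast and isotropically.
DEFAULT_BUNDLE_EIGENVALUES = (1.7e-3, 0.4e-3, 0.4e-3)
DEFAULT_BACKGROUND_EIGENVALUES = (1.2e-3, 1.2e-3, 1.2e-3)


@dataclass(frozen=True)
class BundleSpec:
    """One fiber bundle: a centerline, a radius, and its eigenvalues.

    ``centerline`` is one of
      ("straight", start_mm, end_mm)
      ("arc", center_mm, radius_mm, axis, angle_start_deg, angle_end_deg)
      ("polyline", [p0_mm, p1_mm, ...])
    The tensor at each voxel within ``radius`` (mm) of the centerline has
    its principal axis along the local tangent, eigenvalues
    (lambda_par, lambda_perp, lambda_perp) with lambda_par > lambda_perp.
    """

    centerline: tuple
    radius: float
    eigenvalues: tuple[float, float, float] = DEFAULT_BUNDLE_EIGENVALUES

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("bundle radius must be positive")
        lpar, lperp, lperp2 = self.eigenvalues
        if not (lpar > lperp > 0) or lperp != lperp2:
            raise ValueError(
                "eigenvalues must be (l_par, l_perp, l_perp) with "
                "l_par > l_perp > 0")

    def sample(self, n: int = 512) -> tuple[np.ndarray, np.ndarray]:
        """Dense (points, unit tangents) sampling of the centerline, mm."""
        kind = self.centerline[0]
        if kind == "straight":
            _, start, end = self.centerline
            start = np.asarray(start, dtype=float)
            end = np.asarray(end, dtype=float)
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts = start + t * (end - start)
            tan = np.tile((end - start) / np.linalg.norm(end - start), (n, 1))
            return pts, tan
        if kind == "arc":
            _, center, radius, axis, a0, a1 = self.centerline
            center = np.asarray(center, dtype=float)
            ang = np.deg2rad(np.linspace(a0, a1, n))
            in_plane = [a for a in range(3) if a != axis]
            pts = np.tile(center, (n, 1))
            pts[:, in_plane[0]] += radius * np.cos(ang)
            pts[:, in_plane[1]] += radius * np.sin(ang)
            tan = np.zeros((n, 3))
            tan[:, in_plane[0]] = -np.sin(ang)
            tan[:, in_plane[1]] = np.cos(ang)
            return pts, tan
        if kind == "polyline":
            verts = np.asarray(self.centerline[1], dtype=float)
            seg_len = np.linalg.norm(np.diff(verts, axis=0), axis=1)
            n_per = np.maximum((n * seg_len / seg_len.sum()).astype(int), 2)
            pts, tan = [], []
            for (p0, p1), m in zip(zip(verts[:-1], verts[1:]), n_per):
                t = np.linspace(0.0, 1.0, m)[:, None]
                pts.append(p0 + t * (p1 - p0))
                u = (p1 - p0) / np.linalg.norm(p1 - p0)
                tan.append(np.tile(u, (m, 1)))
            return np.vstack(pts), np.vstack(tan)
        raise ValueError(f"unknown centerline kind {kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry, bundles, background, and noise for one phantom."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    bundles: tuple[BundleSpec, ...] = ()
    background_eigenvalues: tuple[float, float, float] = \
        DEFAULT_BACKGROUND_EIGENVALUES
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma cannot be negative")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size
        return a


def _tensor_from_axis(axis: np.ndarray, lpar: float, lperp: float
                      ) -> np.ndarray:
    """Cylindrically symmetric tensor with principal direction ``axis``."""
    u = axis / np.linalg.norm(axis)
    return lperp * np.eye(3) + (lpar - lperp) * np.outer(u, u)


def make_tensor_phantom(spec: PhantomSpec
                        ) -> tuple[DiffusionTensorVolume, dict[int, np.ndarray]]:
    """Build the tensor field and per-bundle ground-truth masks.

    Voxel centers within a bundle's radius of its centerline get the
    bundle tensor oriented along the nearest centerline tangent; everything
    else gets the isotropic background.  Where bundles overlap, every
    bundle records the voxel in its mask but the later-listed bundle's
    tensor wins.
    """
    shape = spec.shape
    centers = (np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                    indexing="ij"), axis=-1) + 0.5) \
        * np.asarray(spec.voxel_size)
    flat = centers.reshape(-1, 3)

    lbg = np.asarray(spec.background_eigenvalues, dtype=float)
    tensors = np.zeros(shape + (3, 3))
    tensors[..., 0, 0] = lbg[0]
    tensors[..., 1, 1] = lbg[1]
    tensors[..., 2, 2] = lbg[2]

    masks: dict[int, np.ndarray] = {}
    for bi, bundle in enumerate(spec.bundles):
        pts, tans = bundle.sample()
        # nearest centerline sample per voxel center (grids are small)
        d2 = ((flat[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(len(flat)), nearest])
        inside = (dist <= bundle.radius).reshape(shape)
        masks[bi] = inside
        lpar, lperp, _ = bundle.eigenvalues
        for vi in np.flatnonzero(inside.ravel()):
            tensors.reshape(-1, 3, 3)[vi] = _tensor_from_axis(
                tans[nearest[vi]], lpar, lperp)

    mask = np.ones(shape, dtype=bool)
    vol = DiffusionTensorVolume.from_matrices(tensors, spec.affine, mask)
    return vol, masks


def default_scheme(n_directions: int = 15,
                   b_value: float = DEFAULT_B_VALUE) -> GradientScheme:
    """Deterministic gradient table: one b=0 plus n spiral directions.

    Directions are a golden-angle spiral over the upper hemisphere
    (antipodal directions are equivalent for diffusion), giving an
    approximately uniform, well-conditioned design without randomness.
    """
    i = np.arange(n_directions)
    z = (i + 0.5) / n_directions          # upper hemisphere only
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z ** 2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    directions = np.vstack([np.zeros(3), dirs])
    b_values = np.concatenate([[0.0], np.full(n_directions, b_value)])
    return GradientScheme(directions=directions, b_values=b_values)


def synthesize_dwi(tensor_volume: DiffusionTensorVolume,
                   scheme: GradientScheme, s0: float = 1000.0,
                   noise_sigma: float = 0.0, seed: int = 0) -> DwiVolume:
    """Forward-simulate DWI signals S_i = s0 exp(-b_i g_i^T D g_i).

    ``noise_sigma`` > 0 applies Rician corruption (magnitude of the complex
    signal with independent Gaussian noise of that SD on both channels), the
    magnitude-MR convention; 0 is noiseless.  Deterministic given the seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma cannot be negative")
    mats = tensor_volume.as_matrices()
    g = scheme.directions
    b = scheme.b_values
    # per-direction apparent diffusion g^T D g over the whole grid
    adc = np.einsum("...ij,ni,nj->...n", mats, g, g)
    signal = s0 * np.exp(-b * adc)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        re = signal + rng.normal(0.0, noise_sigma, signal.shape)
        im = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt(re ** 2 + im ** 2)
    return DwiVolume(signal=signal, affine=tensor_volume.affine,
                     scheme=scheme)


def simulate_paired_measurements(true_values, sw: float, seed: int = 0
                                 ) -> PairedMeasurements:
    """Two noisy repeats per subject: truth + independent N(0, sw^2) error."""
    true_values = np.asarray(true_values, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sw, size=(2, len(true_values))) if sw > 0 \
        else np.zeros((2, len(true_values)))
    return PairedMeasurements(
        subject_ids=np.arange(len(true_values)),
        m1=true_values + noise[0], m2=true_values + noise[1])


def straight_bundle_phantom(n_bundle_voxels: int = 20, radius_vox: float = 1.1,
                            shape: tuple[int, int, int] | None = None,
                            voxel_size=DEFAULT_VOXEL_SIZE,
                            bundle_eigenvalues=DEFAULT_BUNDLE_EIGENVALUES,
                            ) -> PhantomSpec:
    """Convenience spec: one x-aligned straight bundle through grid center."""
    if shape is None:
        shape = (n_bundle_voxels + 6, 11, 11)
    vx = np.asarray(voxel_size)
    y = (shape[1] / 2) * vx[1]
    z = (shape[2] / 2) * vx[2]
    x0 = 3 * vx[0]
    x1 = (3 + n_bundle_voxels) * vx[0]
    bundle = BundleSpec(
        centerline=("straight", (x0, y, z), (x1, y, z)),
        radius=radius_vox * float(min(vx[1], vx[2])),
        eigenvalues=bundle_eigenvalues)
    return PhantomSpec(shape=shape, voxel_size=voxel_size, bundles=(bundle,))
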