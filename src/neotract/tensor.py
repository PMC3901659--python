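"""Diffusion tensor estimation, eigen-decomposition, and scalar maps.

The diffusion tensor model describes water displacement in each voxel by a
symmetric positive 3x3 tensor D (mm^2/s).  For a gradient direction g (unit
vector) and diffusion weighting b (s/mm^2) the single-tensor signal model is

    S(g, b) = S0 * exp(-b * g^T D g)

Taking logs makes the model linear in the six unique tensor elements plus
ln S0, so the tensor is recovered per voxel by ordinary least squares on the
log signal.  Eigen-decomposition of D yields the principal diffusion
direction (the eigenvector of the largest eigenvalue, which deterministic
tractography follows) and the rotation-invariant scalar maps:

    MD = (l1 + l2 + l3) / 3        mean diffusivity
    AD = l1                        axial diffusivity
    RD = (l2 + l3) / 2             radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy in [0, 1]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Fixed storage order of the six unique tensor elements.
TENSOR_ELEMENT_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# (row, col) of each stored element in the full 3x3 matrix.
_ELEMENT_INDICES = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: one direction and b-value per volume.

    Directions of non-zero-b volumes must be unit vectors; at least six
    linearly independent outer products are required for the tensor to be
    identifiable.
    """

    directions: np.ndarray  # (n, 3), unit vectors (b=0 rows may be zero)
    b_values: np.ndarray    # (n,), s/mm^2

    def __post_init__(self):
        directions = np.asarray(self.directions, dtype=float)
        b_values = np.asarray(self.b_values, dtype=float)
        if directions.ndim != 2 or directions.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if b_values.shape != (directions.shape[0],):
            raise ValueError(
                f"gradient table length mismatch: {directions.shape[0]} "
                f"directions vs {b_values.shape[0]} b-values"
            )
        if not np.any(b_values == 0):
            raise ValueError("scheme must contain at least one b=0 volume")
        dwi = b_values > 0
        norms = np.linalg.norm(directions[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero-b directions must have unit norm")
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "b_values", b_values)
        if np.linalg.matrix_rank(self.design_matrix()[:, 1:]) < 6:
            raise ValueError(
                "fewer than 6 independent gradient directions: "
                "tensor is not identifiable"
            )

    def __len__(self) -> int:
        return self.directions.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    def design_matrix(self) -> np.ndarray:
        """Log-signal design matrix, columns ``[lnS0, Dxx..Dzz]``.

        Off-diagonal columns carry the factor 2 from expanding g^T D g, so
        the solved coefficients are the stored tensor elements directly.
        """
        g = self.directions
        b = self.b_values
        cols = [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -b * g[:, 1] ** 2,
            -2 * b * g[:, 1] * g[:, 2],
            -b * g[:, 2] ** 2,
        ]
        return np.stack(cols, axis=1)


@dataclass
class DwiVolume:
    """4-D diffusion-weighted signal with its gradient scheme and affine."""

    signal: np.ndarray  # (x, y, z, n_volumes), scanner units, non-negative
    affine: np.ndarray  # 4x4 voxel-to-world (mm)
    scheme: GradientScheme

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, gradient)")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but scheme "
                f"has {len(self.scheme)} entries"
            )
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class DiffusionTensorVolume:
    """Per-voxel symmetric tensor stored as six unique elements.

    Element order is ``TENSOR_ELEMENT_ORDER`` = (Dxx, Dxy, Dxz, Dyy, Dyz,
    Dzz); symmetry is by construction.
    """

    tensor: np.ndarray  # (x, y, z, 6), mm^2/s
    affine: np.ndarray  # 4x4
    mask: np.ndarray    # (x, y, z) bool

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensor.ndim != 4 or self.tensor.shape[3] != 6:
            raise ValueError("tensor must have shape (x, y, z, 6)")
        if self.mask.shape != self.tensor.shape[:3]:
            raise ValueError("mask shape does not match tensor grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand the six stored elements to full (x, y, z, 3, 3) matrices."""
        m = np.zeros(self.shape + (3, 3))
        for k, (i, j) in enumerate(_ELEMENT_INDICES):
            m[..., i, j] = self.tensor[..., k]
            m[..., j, i] = self.tensor[..., k]
        return m

    @classmethod
    def from_matrices(cls, matrices, affine, mask) -> "DiffusionTensorVolume":
        matrices = np.asarray(matrices, dtype=float)
        six = np.stack(
            [matrices[..., i, j] for (i, j) in _ELEMENT_INDICES], axis=-1
        )
        return cls(tensor=six, affine=np.asarray(affine), mask=mask)


@dataclass
class EigenSystemVolume:
    """Per-voxel eigenvalues (descending) and matching eigenvectors.

    ``eigenvectors[..., :, i]`` is the unit eigenvector of
    ``eigenvalues[..., i]``; the principal direction e1 is column 0.
    """

    eigenvalues: np.ndarray   # (x, y, z, 3), descending
    eigenvectors: np.ndarray  # (x, y, z, 3, 3), orthonormal columns
    affine: np.ndarray
    mask: np.ndarray

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


@dataclass
class ScalarMaps:
    """FA/MD/AD/RD grids sharing the tensor grid's affine."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = field(default=None)


def fit_tensor(
    dwi: DwiVolume,
    mask: np.ndarray | None = None,
    signal_floor: float | None = None,
) -> DiffusionTensorVolume:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    Parameters
    ----------
    dwi : DwiVolume
        4-D signal with gradient scheme (at least one b=0 volume).
    mask : bool array, optional
        Voxels to fit; defaults to all voxels.
    signal_floor : float, optional
        Non-positive signals are clamped here before the log.  Defaults to
        1e-3 times the smallest positive signal in the volume.

    Returns
    -------
    DiffusionTensorVolume
        Least-squares tensor at every masked voxel; zeros elsewhere.
    """
    if mask is None:
        mask = np.ones(dwi.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask shape does not match DWI grid")
    if not mask.any():
        raise ValueError("empty mask: no voxels to fit")

    signal = dwi.signal[mask]  # (n_vox, n_grad)
    positive = signal > 0
    if signal_floor is None:
        if positive.any():
            signal_floor = signal[positive].min() * 1e-3
        else:
            raise ValueError("no positive signal inside mask")
    n_clamped = int((~positive).sum())
    if n_clamped:
        log.info("clamped %d non-positive signal samples to %g",
                 n_clamped, signal_floor)
        signal = np.where(positive, signal, signal_floor)

    design = dwi.scheme.design_matrix()          # (n_grad, 7)
    coef = np.linalg.pinv(design) @ np.log(signal).T  # (7, n_vox)

    tensor = np.zeros(dwi.shape + (6,))
    tensor[mask] = coef[1:].T
    return DiffusionTensorVolume(tensor=tensor, affine=dwi.affine, mask=mask)


def _lexicographic_tiebreak(evals: np.ndarray, evecs: np.ndarray,
                            tol: float = 1e-12) -> None:
    """Order eigenvectors of (near-)degenerate eigenvalues lexicographically.

    Operates in place on a single voxel's descending (3,) eigenvalues and
    (3, 3) eigenvector columns so degenerate decompositions are emitted
    deterministically.
    """
    for a, b in ((0, 1), (1, 2), (0, 1)):
        if abs(evals[a] - evals[b]) < tol:
            va, vb = evecs[:, a], evecs[:, b]
            if tuple(vb) > tuple(va):
                evecs[:, [a, b]] = evecs[:, [b, a]]
                evals[[a, b]] = evals[[b, a]]


def eigendecompose(tensor_volume: DiffusionTensorVolume) -> EigenSystemVolume:
    """Eigen-decompose every masked voxel's tensor.

    Eigenvalues are sorted descending.  Eigenvector signs are canonicalized
    so each vector's largest-magnitude component is positive (tracking
    re-aligns signs locally anyway); ties within 1e-12 in eigenvalue are
    broken lexicographically on the eigenvectors for determinism.
    """
    mats = tensor_volume.as_matrices()
    bad = ~np.isfinite(mats).all(axis=(-2, -1)) & tensor_volume.mask
    if bad.any():
        voxel = tuple(int(c) for c in np.argwhere(bad)[0])
        raise ValueError(f"non-finite tensor elements at voxel {voxel}")

    evals = np.zeros(tensor_volume.shape + (3,))
    evecs = np.zeros(tensor_volume.shape + (3, 3))
    evecs[..., :, :] = np.eye(3)

    m = tensor_volume.mask
    w, v = np.linalg.eigh(mats[m])  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    # sign convention: largest-|component| of each eigenvector positive
    arg = np.argmax(np.abs(v), axis=1)                     # (n, 3)
    signs = np.sign(np.take_along_axis(v, arg[:, None, :], axis=1))
    signs[signs == 0] = 1.0
    v = v * signs
    # rare exact degeneracies: deterministic lexicographic column order
    tied = (np.abs(np.diff(w, axis=1)) < 1e-12).any(axis=1)
    if tied.any():
        w_t, v_t = w[tied].copy(), v[tied].copy()
        for i in range(w_t.shape[0]):
            _lexicographic_tiebreak(w_t[i], v_t[i])
        w[tied], v[tied] = w_t, v_t
    evals[m] = w
    evecs[m] = v
    return EigenSystemVolume(
        eigenvalues=evals, eigenvectors=evecs,
        affine=tensor_volume.affine, mask=tensor_volume.mask,
    )


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Closed-form fractional anisotropy from (..., 3) eigenvalues.

    FA of the zero tensor is defined as 0 (the 0/0 limit is left
    undefined by the formula).
    """
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = ((evals - mean) ** 2).sum(axis=-1)
    den = (evals ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def scalar_maps(eigensystems: EigenSystemVolume) -> ScalarMaps:
    """Derive the FA/MD/AD/RD maps from per-voxel eigenvalues."""
    evals = eigensystems.eigenvalues
    fa = fa_from_eigenvalues(evals)
    md = evals.mean(axis=-1)
    ad = evals[..., 0]
    rd = evals[..., 1:].mean(axis=-1)
    m = eigensystems.mask
    return ScalarMaps(
        fa=np.where(m, fa, 0.0),
        md=np.where(m, md, 0.0),
        ad=np.where(m, ad, 0.0),
        rd=np.where(m, rd, 0.0),
        affine=eigensystems.affine,
        mask=m,
    )
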