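"""Synthetic Gaussian-phantom fixtures.

Real EM reconstructions are well approximated by sums of anisotropic 3D
Gaussians, which is also the representation external GMM fitters use.
The generators here build:

* single phantom maps — a list of Gaussian blobs evaluated at voxel
  centers, blurred to a nominal resolution and overlaid with additive
  white Gaussian background noise;
* map *pairs* with controlled compositional overlap — a fraction of the
  blobs is shared between the maps (the rest replaced), and the second
  map is expressed in its own frame so that a known rigid transform
  brings it onto the first;
* pose *ensembles* around a reference transform — a cluster of small
  perturbations (near/correct fits) and a cluster of large ones
  (far/incorrect fits), mimicking the output of a rigid-body fitter.

Everything is deterministic under the seed recorded in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import FitEnsemble
from .volume_io import SIGMA_PER_RESOLUTION, DensityMap, RigidTransform

__all__ = ["Blob", "PhantomSpec", "make_phantom", "make_pair", "make_ensemble", "default_spec"]


@dataclass(frozen=True)
class Blob:
    """One anisotropic Gaussian: center (Å), 3×3 covariance (Å²), amplitude."""

    center: tuple[float, float, float]
    covariance: np.ndarray
    amplitude: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a phantom map.

    ``resolution`` enters as an isotropic Gaussian blur added to every
    blob's covariance, with real-space sigma chosen so the blur's Fourier
    transform falls to half amplitude at spatial frequency 1/resolution —
    the same convention the low-pass filter uses.
    """

    blobs: tuple[Blob, ...]
    grid_shape: tuple[int, int, int] = (48, 48, 48)  # (nx, ny, nz)
    spacing: float = 2.0
    resolution: float = 8.0
    noise_sd: float = 0.02
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


def default_spec(
    n_blobs: int = 6,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    spacing: float = 2.0,
    resolution: float = 8.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> PhantomSpec:
    """A multi-blob phantom emulating a mid-size complex.

    Blob centers are scattered over the central half of the grid and
    covariances are random anisotropic SPD matrices with principal sigmas
    of 4–9 Å, roughly domain-sized features.
    """
    rng = np.random.default_rng(seed)
    extent = (np.array(grid_shape, dtype=float) - 1) * spacing
    lo, hi = 0.3 * extent, 0.7 * extent
    blobs = []
    for _ in range(n_blobs):
        center = rng.uniform(lo, hi)
        sigmas = rng.uniform(4.0, 9.0, size=3)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        cov = q @ np.diag(sigmas**2) @ q.T
        blobs.append(Blob(tuple(center), cov, amplitude=float(rng.uniform(0.8, 1.2))))
    return PhantomSpec(
        blobs=tuple(blobs),
        grid_shape=grid_shape,
        spacing=spacing,
        resolution=resolution,
        noise_sd=noise_sd,
        seed=seed,
    )


def _check_cov(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float).reshape(3, 3)
    if not np.allclose(cov, cov.T, atol=1e-9):
        raise ValueError("covariance must be symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    return cov


def make_phantom(spec: PhantomSpec) -> DensityMap:
    """Evaluate the blob sum plus seeded noise at every voxel center."""
    nx, ny, nz = spec.grid_shape
    sigma_res = SIGMA_PER_RESOLUTION * spec.resolution
    iz, iy, ix = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    pts = (
        np.stack([ix, iy, iz], axis=-1).astype(float) * spec.spacing
        + np.asarray(spec.origin)
    ).reshape(-1, 3)
    data = np.zeros(pts.shape[0])
    for blob in spec.blobs:
        cov = _check_cov(blob.covariance) + sigma_res**2 * np.eye(3)
        d = pts - np.asarray(blob.center, dtype=float)
        maha = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        data += blob.amplitude * np.exp(-0.5 * maha)
    data = data.reshape(nz, ny, nx)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return DensityMap(
        data=data,
        spacing=spec.spacing,
        origin=spec.origin,
        resolution=spec.resolution,
    )


def make_pair(
    spec: PhantomSpec,
    shared_fraction: float,
    t: RigidTransform,
    seed: int | None = None,
) -> tuple[DensityMap, DensityMap, RigidTransform]:
    """Phantom pair with partial compositional overlap and a known pose.

    Map 1 contains all blobs of ``spec``.  Map 2 keeps a random subset of
    ``shared_fraction`` of them (the rest replaced by fresh blobs at new
    positions) and is expressed in its own coordinate frame: applying the
    returned ground-truth transform ``t`` maps it back onto map 1.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = len(spec.blobs)
    n_shared = int(round(shared_fraction * n))
    shared_idx = rng.choice(n, size=n_shared, replace=False)
    tinv = t.inverse()
    centers2 = []
    covs2 = []
    amps2 = []
    for i in sorted(shared_idx):
        b = spec.blobs[i]
        centers2.append(tinv.apply(np.asarray(b.center, dtype=float)))
        covs2.append(tinv.rotation @ _check_cov(b.covariance) @ tinv.rotation.T)
        amps2.append(b.amplitude)
    extent = (np.array(spec.grid_shape, dtype=float) - 1) * spec.spacing
    grid_center = np.asarray(spec.origin) + 0.5 * extent
    # recenter map 2's content on its own grid, as a deposited map would be,
    # and fold the recentering shift into the returned ground-truth transform
    if centers2:
        d = grid_center - np.mean(centers2, axis=0)
    else:
        d = np.zeros(3)
    centers2 = [c + d for c in centers2]
    lo, hi = 0.3 * extent, 0.7 * extent
    for _ in range(n - n_shared):
        # replacement material absent from map 1
        donor = spec.blobs[rng.integers(n)]
        centers2.append(rng.uniform(lo, hi) + np.asarray(spec.origin))
        covs2.append(_check_cov(donor.covariance))
        amps2.append(donor.amplitude)
    blobs2 = tuple(
        Blob(tuple(c), cov, a) for c, cov, a in zip(centers2, covs2, amps2)
    )
    map1 = make_phantom(spec)
    spec2 = replace(
        spec, blobs=blobs2, seed=(spec.seed if seed is None else seed) + 1
    )
    map2 = make_phantom(spec2)
    t_true = RigidTransform(t.rotation, t.translation - t.rotation @ d)
    return map1, map2, t_true


def _random_rotation(rng: np.random.Generator, angle_scale_deg: float) -> np.ndarray:
    """Rotation about a uniformly random axis by |N(0, scale)| degrees."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(abs(rng.normal(0.0, angle_scale_deg)))
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _perturb(
    reference: RigidTransform,
    rng: np.random.Generator,
    shift_scale: float,
    angle_scale: float,
    pivot: np.ndarray,
) -> RigidTransform:
    dr = _random_rotation(rng, angle_scale)
    dt = rng.normal(0.0, shift_scale / np.sqrt(3.0), size=3)
    # rotate about the pivot (the aligned structure's center), then shift
    pert = RigidTransform(dr, dt + pivot - dr @ pivot)
    return pert.compose(reference)


def make_ensemble(
    reference: RigidTransform,
    n_near: int,
    n_far: int,
    near_scale: tuple[float, float] = (1.0, 2.0),
    far_scale: tuple[float, float] = (30.0, 90.0),
    seed: int = 0,
    symmetry_ops: list[np.ndarray] | None = None,
    pivot=(0.0, 0.0, 0.0),
) -> FitEnsemble:
    """Bimodal pose ensemble around a reference transform.

    ``near_scale``/``far_scale`` are (translation Å, rotation degrees)
    perturbation scales; translations are isotropic Gaussian with the
    stated expected magnitude and rotations use a uniform random axis with
    half-normal angle, applied about ``pivot`` (pass the structure center
    so large rotations reorient the density instead of sweeping it away).
    The near cluster emulates correct fits, the far cluster incorrect ones.
    """
    if min(near_scale) <= 0 or min(far_scale) <= 0:
        raise ValueError("perturbation scales must be positive")
    rng = np.random.default_rng(seed)
    pivot = np.asarray(pivot, dtype=float)
    fits = [
        _perturb(reference, rng, *near_scale, pivot=pivot) for _ in range(n_near)
    ] + [
        _perturb(reference, rng, *far_scale, pivot=pivot) for _ in range(n_far)
    ]
    ens = FitEnsemble(
        reference=reference,
        fits=fits,
        symmetry_ops=symmetry_ops if symmetry_ops is not None else [np.eye(3)],
    )
    ens.compute_alcps()
    return ens
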