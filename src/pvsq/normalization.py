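"""Intensity normalization of T1-weighted volumes.

The downstream vesselness threshold is a single fixed cutoff applied to
every exam, so the intensity scale must be comparable across scanners
and sessions. Normalization rescales the whole volume multiplicatively
so that the mean white-matter intensity equals a fixed target
(110 by convention for T1w).

Two ways of estimating the WM mean are provided:

``mask_mean``
    the plain mean inside the supplied WM mask (the default — the
    pipeline already receives a curated WM mask);
``fcm``
    the mean of the voxels assigned (by highest membership) to the
    brightest cluster of a fuzzy c-means intensity clustering, which
    reproduces the behaviour of FCM-based normalizers when masks are
    broad or unedited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask3D, Volume3D, check_same_grid

WM_TARGET_DEFAULT = 110.0


class DegenerateClusteringError(ValueError):
    """Raised when the intensities cannot support k distinct clusters."""


@dataclass
class FCMResult:
    """Result of a 1-D fuzzy c-means clustering of voxel intensities.

    ``cluster_means`` are sorted ascending, so on T1w the white-matter
    cluster is the last (brightest) one; ``membership`` has one row per
    voxel inside the mask and one column per cluster, rows summing to 1.
    """

    cluster_means: np.ndarray
    membership: np.ndarray
    wm_cluster_index: int
    n_iter: int
    converged: bool


def _init_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    # k-means++-style greedy seeding on the 1-D intensity sample
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            raise DegenerateClusteringError(
                "intensities are constant inside the mask; cannot separate clusters"
            )
        centers.append(x[rng.choice(len(x), p=d2 / total)])
    return np.sort(np.asarray(centers, dtype=float))


def fcm_classify(
    volume: Volume3D,
    mask: BinaryMask3D,
    k: int = 3,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> FCMResult:
    """Fuzzy c-means clustering of the intensities inside ``mask``.

    Alternates the standard fixed-point updates: cluster means are
    membership^m weighted intensity averages, memberships follow
    inverse-distance weighting with exponent 2/(fuzziness-1). Stops when
    the largest membership change drops below ``tol``.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not (fuzziness > 1):
        raise ValueError(f"fuzziness must be > 1, got {fuzziness}")
    check_same_grid(volume, mask)
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")

    x = np.asarray(volume.data[mask.data], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateClusteringError(
            "intensities are constant inside the mask; cannot separate clusters"
        )
    rng = np.random.default_rng(seed)
    centers = _init_centers(x, k, rng)
    expo = 2.0 / (fuzziness - 1.0)
    u = np.full((len(x), k), 1.0 / k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = np.abs(x[:, None] - centers[None, :])
        # exact-hit voxels get full membership in their cluster
        zero = d < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-expo)
            u_new = inv / inv.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u_new[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        um = u_new ** fuzziness
        centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        if delta < tol:
            converged = True
            break

    order = np.argsort(centers)
    centers = centers[order]
    u = u[:, order]
    return FCMResult(
        cluster_means=centers,
        membership=u,
        wm_cluster_index=k - 1,  # brightest cluster on T1w
        n_iter=it,
        converged=converged,
    )


def wm_mean(
    volume: Volume3D,
    wm_mask: BinaryMask3D,
    method: str = "mask_mean",
    **fcm_kwargs,
) -> float:
    """Estimate the white-matter mean intensity.

    With ``mask_mean`` this is the plain mean inside the mask; with
    ``fcm`` it is the mean of the voxels hard-assigned to the brightest
    FCM cluster within the mask.
    """
    check_same_grid(volume, wm_mask)
    if wm_mask.n_voxels == 0:
        raise ValueError("white-matter mask is empty")
    if method == "mask_mean":
        return float(volume.data[wm_mask.data].mean())
    if method == "fcm":
        res = fcm_classify(volume, wm_mask, **fcm_kwargs)
        x = np.asarray(volume.data[wm_mask.data], dtype=float)
        assign = np.argmax(res.membership, axis=1)
        sel = assign == res.wm_cluster_index
        if not sel.any():
            raise DegenerateClusteringError("no voxels assigned to the WM cluster")
        return float(x[sel].mean())
    raise ValueError(f"unknown normalization method {method!r}")


def normalize_wm(
    volume: Volume3D,
    wm_mask: BinaryMask3D,
    target: float = WM_TARGET_DEFAULT,
    method: str = "mask_mean",
    **fcm_kwargs,
) -> Volume3D:
    """Rescale a volume so the WM mean equals ``target``.

    The scaling is global and multiplicative (output = input * target/m
    where m is the estimated WM mean), which makes the downstream
    segmentation invariant to the acquisition's overall intensity scale.
    """
    m = wm_mean(volume, wm_mask, method=method, **fcm_kwargs)
    if m <= 0:
        raise ValueError(f"white-matter mean must be positive, got {m}")
    return Volume3D(volume.data * (target / m), volume.affine)
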