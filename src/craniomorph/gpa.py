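"""Generalized Procrustes analysis and the symmetric component of shape.

Configurations are translated to a common centroid, scaled to unit
centroid size and rotated by least squares onto an iteratively updated
mean (full Procrustes fit, reflections disallowed).  Aligned shapes are
projected into the tangent space at the mean for multivariate statistics.
For structures with object symmetry, the symmetric shape component is
the average of each aligned configuration and its reflected, relabelled
and re-superimposed copy.

Because a Procrustes alignment is only defined up to a global rotation,
the converged mean is put in a canonical orientation (principal axes,
deterministic signs) and all aligned shapes are rotated with it; the
result is then invariant to arbitrary rigid motion and scaling of the
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import SymmetryScheme

#: reflection across the y = 0 plane used when forming mirror copies
_REFLECT_Y = np.diag([1.0, -1.0, 1.0])


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances to their centroid (mm)."""
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 1e-12:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def opa_fit(
    source: np.ndarray, target: np.ndarray, allow_reflection: bool = False
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes rotation of source onto target.

    Both inputs are assumed centered (and typically unit centroid size).
    Returns the 3x3 rotation R minimizing ||source @ R - target||_F and the
    minimized Frobenius distance.  det(R) = +1 unless reflections are allowed;
    a zero singular value (rank-deficient cross-covariance) is resolved by
    flipping the axis with the smallest singular value.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    u, s, vt = np.linalg.svd(source.T @ target)
    rot = u @ vt
    if not allow_reflection and np.linalg.det(rot) < 0:
        flip = np.ones(len(s))
        flip[-1] = -1.0  # smallest singular value
        rot = (u * flip) @ vt
    residual = float(np.linalg.norm(source @ rot - target))
    return rot, residual


@dataclass
class ProcrustesResult:
    """Aligned shapes, mean shape, sizes and tangent coordinates."""

    aligned: np.ndarray  # (n, k, 3), dimensionless Procrustes coordinates
    mean_shape: np.ndarray  # (k, 3), unit centroid size
    centroid_sizes: np.ndarray  # (n,), mm
    tangent_coords: np.ndarray  # (n, 3k)
    iterations: int
    converged: bool
    ss_history: np.ndarray | None = None  # total Procrustes SS per iteration

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def _canonical_rotation(mean: np.ndarray) -> np.ndarray:
    """Rotation putting a centered shape into its principal-axes frame.

    Axes are ordered by decreasing inertia; each axis sign is fixed so the
    landmark coordinate of largest magnitude along it is positive, and the
    third axis is flipped if needed to keep a proper rotation.
    """
    _, vecs = np.linalg.eigh(mean.T @ mean)
    vecs = vecs[:, ::-1]  # descending inertia
    for j in range(3):
        proj = mean @ vecs[:, j]
        if proj[np.argmax(np.abs(proj))] < 0:
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def gpa(
    configs: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> ProcrustesResult:
    """Generalized Procrustes analysis of an (n, k, 3) array of configurations.

    Iterates least-squares rotation onto the unit-size mean until the decrease
    in total Procrustes sum of squares falls below ``tol``.  Total SS is
    non-increasing across iterations because, for centered unit-size shapes,
    the renormalized arithmetic mean is the optimal unit-size mean.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[2] != 3:
        raise ValueError("configs must be an (n, k, 3) array")
    n = configs.shape[0]
    if n < 2:
        raise ValueError("need at least two configurations")
    sizes = np.array([centroid_size(c) for c in configs])
    aligned = (configs - configs.mean(axis=1, keepdims=True)) / sizes[:, None, None]

    mean = aligned[0] / np.linalg.norm(aligned[0])
    ss_prev = np.inf
    history = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            rot, _ = opa_fit(aligned[i], mean)
            aligned[i] = aligned[i] @ rot
        mean = aligned.mean(axis=0)
        mean /= np.linalg.norm(mean)
        ss = float(((aligned - mean) ** 2).sum())
        history.append(ss)
        if ss_prev - ss < tol:
            converged = True
            break
        ss_prev = ss

    rot_c = _canonical_rotation(mean)
    mean = mean @ rot_c
    aligned = aligned @ rot_c
    return ProcrustesResult(
        aligned=aligned,
        mean_shape=mean,
        centroid_sizes=sizes,
        tangent_coords=tangent_project(aligned, mean),
        iterations=iterations,
        converged=converged,
        ss_history=np.array(history),
    )


def tangent_project(aligned: np.ndarray, mean_shape: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes into the tangent space at the mean.

    Each vectorized shape is projected onto the hyperplane orthogonal to the
    mean-shape direction; the projection is idempotent.
    """
    aligned = np.asarray(aligned, dtype=float)
    x = aligned.reshape(aligned.shape[0], -1)
    mu = mean_shape.ravel()
    mu = mu / np.linalg.norm(mu)
    return x - np.outer(x @ mu, mu)


def reflect_relabel(config: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Mirror image of a configuration with left/right labels swapped."""
    return config[scheme.relabel_permutation()] @ _REFLECT_Y


def symmetrize(aligned: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Symmetric component of each aligned shape.

    For each specimen the mirror image is formed, relabelled under the pairing
    scheme, re-superimposed onto the original by ordinary Procrustes rotation,
    and averaged with it.  The output is a fixed point of that map (exactly
    symmetric up to numerical precision) and the operation is idempotent.
    """
    aligned = np.asarray(aligned, dtype=float)
    out = np.empty_like(aligned)
    for i, x in enumerate(aligned):
        y = reflect_relabel(x, scheme)
        rot, _ = opa_fit(y, x)
        out[i] = 0.5 * (x + y @ rot)
    return out


def asymmetry_residual(config: np.ndarray, scheme: SymmetryScheme) -> float:
    """Frobenius distance between a shape and its symmetrized self."""
    sym = symmetrize(config[None], scheme)[0]
    return float(np.linalg.norm(config - sym))


def symmetric_gpa(
    configs: np.ndarray, scheme: SymmetryScheme, tol: float = 1e-10
) -> ProcrustesResult:
    """GPA, symmetrization, and a final GPA over the symmetric shapes.

    All downstream statistics operate on the symmetric component; original
    centroid sizes (mm) are carried through.
    """
    first = gpa(configs, tol=tol)
    sym = symmetrize(first.aligned, scheme)
    final = gpa(sym, tol=tol)
    final.centroid_sizes = first.centroid_sizes
    return final
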