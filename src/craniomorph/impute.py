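"""Missing-landmark estimation: mirror-imaging and thin-plate splines.

Bilateral landmarks whose partner is present are recovered by reflecting
the partner across the specimen's midsagittal plane.  Remaining missing
landmarks (midline, or pairs missing on both sides) are mapped from a
complete reference configuration through a 3D thin-plate spline (TPS)
fitted on the shared present landmarks — the smoothest interpolant in
the bending-energy sense.  Estimation runs mirror-first, TPS second; the
two stages never increase the number of missing landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .landmarks import LandmarkSet, SymmetryScheme


@dataclass(frozen=True)
class MidsagittalPlane:
    """Plane {x : normal . x = offset} with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.normal - self.offset

    def reflect(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        d = self.signed_distance(points)
        return points - 2.0 * d[:, None] * self.normal


class InsufficientConstraintsError(ValueError):
    """Midsagittal plane cannot be estimated; fall back to TPS imputation."""


def fit_midsagittal_plane(
    lm: LandmarkSet, scheme: SymmetryScheme
) -> MidsagittalPlane:
    """Least-squares midsagittal plane of a bilaterally symmetric configuration.

    The plane minimizes squared distances of present midline landmarks and of
    complete-pair midpoints to the plane, while aligning its normal with the
    left-right difference vectors of complete pairs.  Deterministic.
    """
    mid_pts = [lm.coords[i] for i in scheme.midline if not lm.missing[i]]
    midpoints, diffs = [], []
    for left, right in scheme.paired:
        if not lm.missing[left] and not lm.missing[right]:
            midpoints.append(0.5 * (lm.coords[left] + lm.coords[right]))
            diffs.append(lm.coords[left] - lm.coords[right])
    pts = np.array(mid_pts + midpoints).reshape(-1, 3)
    n_pairs = len(diffs)
    if not (len(mid_pts) >= 3 or n_pairs >= 2):
        raise InsufficientConstraintsError(
            f"specimen {lm.specimen_id}: need >=3 midline landmarks or >=2 complete "
            "bilateral pairs to estimate the midsagittal plane; use TPS imputation"
        )
    center = pts.mean(axis=0)
    centered = pts - center
    scatter = centered.T @ centered  # in-plane point scatter
    across = np.zeros((3, 3))
    for d in diffs:
        across += np.outer(d, d)  # pair differences should be normal to plane
    # min over unit n of  n' scatter n - n' across n
    eigvals, eigvecs = np.linalg.eigh(scatter - across)
    normal = eigvecs[:, 0]
    # deterministic sign: largest-magnitude component positive
    j = int(np.argmax(np.abs(normal)))
    if normal[j] < 0:
        normal = -normal
    normal = normal / np.linalg.norm(normal)
    return MidsagittalPlane(normal=normal, offset=float(normal @ center))


def impute_mirror(lm: LandmarkSet, scheme: SymmetryScheme) -> LandmarkSet:
    """Recover missing bilateral landmarks by reflecting the present partner.

    Landmarks missing on both sides (and missing midline landmarks) are left
    untouched for the TPS stage.
    """
    targets = [
        (miss, present)
        for left, right in scheme.paired
        for miss, present in ((left, right), (right, left))
        if lm.missing[miss] and not lm.missing[present]
    ]
    if not targets:
        return lm.copy()
    plane = fit_midsagittal_plane(lm, scheme)
    out = lm.copy()
    for miss, present in targets:
        out.coords[miss] = plane.reflect(lm.coords[present])[0]
        out.missing[miss] = False
        out.provenance.setdefault("imputed", {})[int(miss)] = "mirror"
    return out


# ---------------------------------------------------------------------------
# 3D thin-plate spline


def _tps_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3D TPS kernel U(r) = -r, conditionally positive definite."""
    return -cdist(a, b)


@dataclass(frozen=True)
class TpsModel:
    """3D thin-plate spline mapping fitted on reference -> target landmarks."""

    reference_points: np.ndarray  # (m, 3)
    affine: np.ndarray  # (3, 4): y = affine @ [1, x]
    weights: np.ndarray  # (m, 3)
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([np.ones((len(points), 1)), points])
        return hom @ self.affine.T + _tps_kernel(points, self.reference_points) @ self.weights


class SingularTpsError(ValueError):
    pass


def fit_tps(reference: np.ndarray, target: np.ndarray) -> TpsModel:
    """Fit the minimum-bending-energy interpolating spline.

    Sends each reference landmark exactly onto the corresponding target
    landmark; among all such interpolants the TPS minimizes bending energy.
    Affine deformations are reproduced exactly with zero bending energy.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    m = len(reference)
    if m < 5:
        raise ValueError("need at least 5 landmarks to fit a 3D TPS")
    d = cdist(reference, reference)
    np.fill_diagonal(d, np.inf)
    dup = np.argwhere(d < 1e-9)
    if len(dup):
        i, j = dup[0]
        raise SingularTpsError(
            f"coincident reference landmarks {int(i)} and {int(j)}"
        )
    K = _tps_kernel(reference, reference)
    Q = np.hstack([np.ones((m, 1)), reference])  # (m, 4)
    L = np.zeros((m + 4, m + 4))
    L[:m, :m] = K
    L[:m, m:] = Q
    L[m:, :m] = Q.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = target
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:  # near-coplanar reference
        raise SingularTpsError(f"singular TPS system: {exc}") from exc
    weights, affine = sol[:m], sol[m:].T  # affine maps [1, x] -> y
    bending = float(np.trace(weights.T @ K @ weights))
    return TpsModel(
        reference_points=reference,
        affine=affine,
        weights=weights,
        bending_energy=max(bending, 0.0),
    )


def impute_tps(lm: LandmarkSet, reference: np.ndarray) -> LandmarkSet:
    """Map remaining missing landmarks from a complete reference through a TPS.

    The spline is fitted on the landmarks present in both configurations and
    evaluated at the reference positions of the missing landmarks.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (lm.k, 3):
        raise ValueError("reference must be a complete k x 3 configuration")
    if not lm.missing.any():
        return lm.copy()
    if lm.missing_fraction > 0.20 + 1e-12:
        raise ValueError(
            f"specimen {lm.specimen_id}: {lm.missing_fraction:.0%} missing exceeds the "
            "20% imputation limit"
        )
    present = ~lm.missing
    model = fit_tps(reference[present], lm.coords[present])
    out = lm.copy()
    miss_idx = np.where(lm.missing)[0]
    out.coords[miss_idx] = model(reference[miss_idx])
    out.missing[miss_idx] = False
    for i in miss_idx:
        out.provenance.setdefault("imputed", {})[int(i)] = "tps"
    return out


def impute_dataset(
    sets: Sequence[LandmarkSet],
    scheme: SymmetryScheme,
    reference: np.ndarray | None = None,
) -> list[LandmarkSet]:
    """Mirror-then-TPS imputation over a dataset.

    If no reference is given, the mean of fully complete specimens is used as
    the TPS reference (per group when a group has >=3 complete specimens,
    otherwise the global complete-specimen mean, computed after a shared
    Procrustes alignment).
    """
    from .gpa import gpa  # deferred: gpa imports nothing from here

    mirrored = []
    for s in sets:
        try:
            mirrored.append(impute_mirror(s, scheme))
        except InsufficientConstraintsError:
            mirrored.append(s.copy())
    if not any(s.missing.any() for s in mirrored):
        return mirrored

    if reference is None:
        complete = [s for s in mirrored if not s.missing.any()]
        if len(complete) < 2:
            raise ValueError("need >=2 complete specimens to build a TPS reference")
        res = gpa(np.stack([s.coords for s in complete]))
        scale = float(np.mean([_cs(s.coords) for s in complete]))
        global_ref = res.mean_shape * scale
        group_refs: dict[str | None, np.ndarray] = {}
        for g in {s.group for s in complete}:
            members = [i for i, s in enumerate(complete) if s.group == g]
            if len(members) >= 3:
                group_refs[g] = res.aligned[members].mean(axis=0) * scale
        refs = lambda s: group_refs.get(s.group, global_ref)  # noqa: E731
    else:
        refs = lambda s: reference  # noqa: E731

    out = []
    for s in mirrored:
        out.append(impute_tps(s, refs(s)) if s.missing.any() else s)
    return out


def _cs(config: np.ndarray) -> float:
    c = config - config.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def intra_observer_error(
    replicates: dict[str, Sequence[LandmarkSet]]
) -> tuple[np.ndarray, float]:
    """Per-landmark digitization precision from repeated extractions.

    For each landmark, the mean Euclidean deviation of the replicates from
    the specimen-wise replicate centroid, averaged over specimens; plus the
    grand mean over landmarks (mm).
    """
    ks = {s.k for reps in replicates.values() for s in reps}
    if len(ks) != 1:
        raise ValueError(f"mismatched landmark counts across replicates: {sorted(ks)}")
    (k,) = ks
    per_specimen = []
    for specimen, reps in replicates.items():
        if len(reps) < 2:
            raise ValueError(f"specimen {specimen}: need >=2 replicates")
        arr = np.stack([s.coords for s in reps])  # (r, k, 3)
        centroid = arr.mean(axis=0)
        dev = np.linalg.norm(arr - centroid, axis=2).mean(axis=0)  # (k,)
        per_specimen.append(dev)
    per_landmark = np.mean(per_specimen, axis=0)
    return per_landmark, float(per_landmark.mean())
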