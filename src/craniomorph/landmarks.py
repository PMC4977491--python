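"""Landmark configurations, symmetry schemes, and file I/O.

A specimen is a ``LandmarkSet``: a k x 3 coordinate matrix (mm) with a
per-landmark missingness mask and metadata (anatomical unit, cultural
group, dietary group, sex).  Bilateral object symmetry is described by a
``SymmetryScheme`` that partitions the landmarks into left/right pairs
and midline (unpaired) landmarks.

Two text formats are supported: the TPS landmark dialect (``LM3=`` blocks)
and a wide CSV with one specimen per row.  Missing landmarks are written
as ``NA`` tokens; both ``NA`` and the sentinel value -9999 are accepted
on read.  File indices are 1-based, internal indices 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CRANIUM_K = 39
MANDIBLE_K = 33

CULTURAL_GROUPS = ("Mesolithic", "A-group", "C-group", "Pharaonic", "Meroitic")
DIET_GROUPS = ("HG", "EF", "F")
#: cultural horizon -> dietary group
DIET_OF_GROUP = {
    "Mesolithic": "HG",
    "A-group": "EF",
    "C-group": "EF",
    "Pharaonic": "F",
    "Meroitic": "F",
}

MISSING_SENTINEL = -9999.0


class ParseError(ValueError):
    """Raised on malformed landmark files."""


@dataclass
class LandmarkSet:
    """One specimen's 3D landmark configuration plus metadata."""

    specimen_id: str
    coords: np.ndarray  # (k, 3) float, mm
    missing: np.ndarray  # (k,) bool
    anatomical_unit: str | None = None  # "cranium" | "mandible" | None
    group: str | None = None
    diet: str | None = None
    sex: str | None = None  # "m" | "f" | "u"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be a k x 3 matrix")
        if self.missing is None:
            self.missing = ~np.isfinite(self.coords).all(axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (self.k,):
            raise ValueError("missing mask must have length k")
        present = self.coords[~self.missing]
        if present.size and not np.isfinite(present).all():
            raise ValueError(
                f"specimen {self.specimen_id}: non-finite coordinates not flagged missing"
            )
        if self.anatomical_unit == "cranium" and self.k != CRANIUM_K:
            warnings.warn(
                f"cranium usually has {CRANIUM_K} landmarks, got {self.k} (generic mode)"
            )
        if self.anatomical_unit == "mandible" and self.k != MANDIBLE_K:
            warnings.warn(
                f"mandible usually has {MANDIBLE_K} landmarks, got {self.k} (generic mode)"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.k

    def copy(self) -> "LandmarkSet":
        return replace(
            self,
            coords=self.coords.copy(),
            missing=self.missing.copy(),
            provenance=dict(self.provenance),
        )


@dataclass(frozen=True)
class SymmetryScheme:
    """Left/right landmark pairing and midline set (0-based indices)."""

    paired: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __init__(
        self,
        paired: Iterable[Sequence[int]],
        midline: Iterable[int],
    ) -> None:
        object.__setattr__(
            self, "paired", tuple((int(l), int(r)) for l, r in paired)
        )
        object.__setattr__(self, "midline", tuple(int(i) for i in midline))
        used = [i for pair in self.paired for i in pair] + list(self.midline)
        if len(set(used)) != len(used):
            raise ValueError("symmetry scheme: an index appears twice")
        k = self.k
        if set(used) != set(range(k)):
            raise ValueError("symmetry scheme: indices must partition 0..k-1")

    @property
    def k(self) -> int:
        return 2 * len(self.paired) + len(self.midline)

    def relabel_permutation(self) -> np.ndarray:
        """Permutation that swaps left and right labels (midline fixed)."""
        perm = np.arange(self.k)
        for left, right in self.paired:
            perm[left], perm[right] = right, left
        return perm

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "paired": [[l + 1, r + 1] for l, r in self.paired],
            "midline": [i + 1 for i in self.midline],
            "indexing": "1-based",
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SymmetryScheme":
        data = yaml.safe_load(Path(path).read_text())
        shift = 1 if data.get("indexing", "1-based") == "1-based" else 0
        return cls(
            paired=[(l - shift, r - shift) for l, r in data["paired"]],
            midline=[i - shift for i in data["midline"]],
        )


# ---------------------------------------------------------------------------
# TPS dialect


def read_tps(path: str | Path) -> list[LandmarkSet]:
    """Read a TPS landmark file (``LM3=`` blocks, optional ``ID=`` lines).

    ``NA`` tokens or -9999 sentinel coordinates mark missing landmarks.
    """
    sets: list[LandmarkSet] = []
    lines = Path(path).read_text().splitlines()
    i, block_no = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise ParseError(f"{path}: expected LM3= at line {i + 1}, got {line!r}")
        block_no += 1
        k = int(line.split("=", 1)[1])
        coords = np.zeros((k, 3))
        missing = np.zeros(k, dtype=bool)
        i += 1
        for j in range(k):
            if i >= len(lines) or "=" in lines[i]:
                raise ParseError(
                    f"{path}: block {block_no} declares {k} landmarks "
                    f"but only {j} coordinate lines found"
                )
            tokens = lines[i].split()
            if len(tokens) != 3:
                raise ParseError(
                    f"{path}: block {block_no}, landmark {j + 1}: "
                    f"expected 3 values, got {len(tokens)}"
                )
            if any(t.upper() == "NA" for t in tokens):
                missing[j] = True
                coords[j] = np.nan
            else:
                vals = [float(t) for t in tokens]
                if all(v == MISSING_SENTINEL for v in vals):
                    missing[j] = True
                    coords[j] = np.nan
                else:
                    coords[j] = vals
            i += 1
        specimen_id = f"specimen_{block_no}"
        meta: dict[str, str] = {}
        while i < len(lines) and "=" in lines[i] and not lines[i].strip().upper().startswith("LM3="):
            key, _, value = lines[i].strip().partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            else:
                meta[key.lower()] = value.strip()
            i += 1
        sets.append(
            LandmarkSet(
                specimen_id=specimen_id,
                coords=coords,
                missing=missing,
                anatomical_unit=meta.get("unit"),
                group=meta.get("group"),
                diet=meta.get("diet"),
                sex=meta.get("sex"),
            )
        )
    return sets


def write_tps(sets: Iterable[LandmarkSet], path: str | Path) -> None:
    """Write landmark sets in the TPS dialect (missing written as ``NA``)."""
    out: list[str] = []
    for s in sets:
        out.append(f"LM3={s.k}")
        for j in range(s.k):
            if s.missing[j]:
                out.append("NA NA NA")
            else:
                out.append(" ".join(repr(float(v)) for v in s.coords[j]))
        out.append(f"ID={s.specimen_id}")
        for key, attr in (("UNIT", "anatomical_unit"), ("GROUP", "group"),
                          ("DIET", "diet"), ("SEX", "sex")):
            value = getattr(s, attr)
            if value is not None:
                out.append(f"{key}={value}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Wide CSV


def read_table(path: str | Path) -> list[LandmarkSet]:
    """Read a wide CSV: specimen_id,group,diet,sex,x1,y1,z1,...,xk,yk,zk.

    Empty cells mark missing landmarks.  Unknown group labels are kept as
    free labels with a warning.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    meta_cols = [c for c in ("specimen_id", "unit", "group", "diet", "sex") if c in df.columns]
    coord_cols = [c for c in df.columns if c not in meta_cols]
    if len(coord_cols) % 3:
        raise ParseError(f"{path}: coordinate column count {len(coord_cols)} not divisible by 3")
    sets = []
    for _, row in df.iterrows():
        vals = row[coord_cols].to_numpy(dtype=float).reshape(-1, 3)
        missing = ~np.isfinite(vals).all(axis=1)
        group = row.get("group")
        group = None if pd.isna(group) else str(group)
        if group is not None and group not in CULTURAL_GROUPS:
            warnings.warn(f"unknown group label {group!r}; kept as free label")
        sets.append(
            LandmarkSet(
                specimen_id=str(row.get("specimen_id", f"row_{_}")),
                coords=vals,
                missing=missing,
                anatomical_unit=None if pd.isna(row.get("unit")) else str(row.get("unit")),
                group=group,
                diet=None if pd.isna(row.get("diet")) else str(row.get("diet")),
                sex=None if pd.isna(row.get("sex")) else str(row.get("sex")),
            )
        )
    ks = {s.k for s in sets}
    if len(ks) > 1:
        raise ParseError(f"{path}: inconsistent landmark counts across rows: {sorted(ks)}")
    return sets


def write_table(sets: Sequence[LandmarkSet], path: str | Path) -> None:
    k = sets[0].k
    cols = ["specimen_id", "unit", "group", "diet", "sex"] + [
        f"{ax}{j + 1}" for j in range(k) for ax in "xyz"
    ]
    rows = []
    for s in sets:
        coords = s.coords.copy()
        coords[s.missing] = np.nan
        rows.append(
            [s.specimen_id, s.anatomical_unit, s.group, s.diet, s.sex, *coords.ravel()]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------


def filter_missingness(
    sets: Sequence[LandmarkSet], max_frac: float = 0.20
) -> tuple[list[LandmarkSet], list[LandmarkSet]]:
    """Partition specimens into (kept, excluded) by missing fraction.

    The threshold is strict: a specimen is kept iff missing/k < max_frac.
    """
    if not 0 < max_frac <= 1:
        raise ValueError("max_frac must be in (0, 1]")
    kept = [s for s in sets if s.missing_fraction < max_frac]
    excluded = [s for s in sets if s.missing_fraction >= max_frac]
    return kept, excluded


def stacked_coords(sets: Sequence[LandmarkSet]) -> np.ndarray:
    """Stack complete specimens into an (n, k, 3) array; errors if any missing."""
    for s in sets:
        if s.missing.any():
            raise ValueError(f"specimen {s.specimen_id} still has missing landmarks")
    return np.stack([s.coords for s in sets])
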