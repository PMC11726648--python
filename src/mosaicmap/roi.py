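"""Domain-specific patch sets on the 1000-patch cortical parcellation.

A restricted thin-patch fraction is computed over a subset of patches that
is topographically associated with a clinical function of interest (for
example, the extremity motor representation).  This module derives such
patch sets: it matches a statistical surface map to its best-fitting
candidate network map by spatial correlation, projects a binary surface
mask onto a patch parcellation by per-patch vertex overlap, and reads and
writes plain-text patch lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: vertex label meaning "not part of any patch" (e.g. medial wall)
UNASSIGNED = -1


class RoiError(ValueError):
    """Raised for invalid maps, empty projections, or mismatched spaces."""


@dataclass(frozen=True)
class SurfaceMap:
    """A per-vertex (or per-patch) scalar map living on a named space."""

    name: str
    values: np.ndarray
    space_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise RoiError(f"map {self.name!r}: values must be a nonempty 1-D vector")


@dataclass(frozen=True)
class ParcellationLabels:
    """Per-vertex patch assignment; UNASSIGNED (-1) marks unlabeled vertices."""

    space_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.size == 0:
            raise RoiError("labels must be a nonempty 1-D integer vector")
        if labels.min() < UNASSIGNED:
            raise RoiError("labels must be >= -1 (UNASSIGNED)")


@dataclass(frozen=True)
class PatchSet:
    """An ordered set of 0-based patch indices with free-text provenance."""

    name: str
    indices: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise RoiError(f"patch set {self.name!r} is empty")
        if any(i < 0 for i in idx):
            raise RoiError(f"patch set {self.name!r} has negative indices")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise RoiError(f"patch set {self.name!r}: indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, i: int) -> bool:
        return int(i) in set(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def validate_range(self, n_patches: int) -> None:
        if self.indices[-1] >= n_patches:
            raise RoiError(
                f"patch set {self.name!r}: index {self.indices[-1]} out of range "
                f"for {n_patches} patches"
            )


def best_matching_network(
    target: SurfaceMap, candidates: Sequence[SurfaceMap]
) -> tuple[int, float]:
    """Pick the candidate map most similar to ``target``.

    Similarity is the spatial Pearson correlation over vertices at which
    both maps are finite.  Candidates with zero variance over those
    vertices are excluded with a warning; ties break toward the lowest
    candidate index.

    Returns
    -------
    (index, similarity)
        Index of the winning candidate and its signed correlation.
    """
    if len(candidates) == 0:
        raise RoiError("no candidate maps supplied")
    for cand in candidates:
        if cand.space_id != target.space_id:
            raise RoiError(
                f"candidate {cand.name!r} lives on space {cand.space_id!r}, "
                f"target on {target.space_id!r}"
            )
        if cand.values.shape != target.values.shape:
            raise RoiError(f"candidate {cand.name!r} length mismatch with target")

    best_index, best_sim = -1, -np.inf
    for i, cand in enumerate(candidates):
        finite = np.isfinite(target.values) & np.isfinite(cand.values)
        if finite.sum() < 2:
            logger.warning("candidate %r: fewer than 2 shared finite vertices; excluded", cand.name)
            continue
        t, c = target.values[finite], cand.values[finite]
        if np.ptp(t) == 0 or np.ptp(c) == 0:
            logger.warning("candidate %r: zero-variance map; similarity undefined, excluded", cand.name)
            continue
        sim = float(np.corrcoef(t, c)[0, 1])
        if sim > best_sim:  # strict > keeps the lowest-index winner on ties
            best_index, best_sim = i, sim
    if best_index < 0:
        raise RoiError("all candidate maps excluded (zero variance or no finite overlap)")
    return best_index, best_sim


def mask_to_patches(
    mask: SurfaceMap,
    labels: ParcellationLabels,
    overlap_threshold: float = 0.5,
    name: str | None = None,
) -> PatchSet:
    """Project a binary vertex mask onto the patch parcellation.

    Patch ``j`` is included iff the fraction of its vertices covered by the
    mask is at least ``overlap_threshold``.
    """
    if mask.space_id != labels.space_id:
        raise RoiError(f"mask space {mask.space_id!r} != labels space {labels.space_id!r}")
    if mask.values.shape != labels.labels.shape:
        raise RoiError("mask and labels length mismatch")
    vals = mask.values
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise RoiError("mask values must be binary (0/1)")
    if not 0 < overlap_threshold <= 1:
        raise RoiError("overlap_threshold must be in (0, 1]")

    assigned = labels.labels >= 0
    lab = labels.labels[assigned]
    inmask = vals[assigned]
    n_per_patch = np.bincount(lab)
    n_covered = np.bincount(lab, weights=inmask)
    present = n_per_patch > 0
    frac = np.zeros_like(n_covered)
    frac[present] = n_covered[present] / n_per_patch[present]
    selected = np.flatnonzero(present & (frac >= overlap_threshold))
    if selected.size == 0:
        raise RoiError(
            f"mask {mask.name!r} selects no patches at threshold {overlap_threshold}; "
            "lower --threshold or check the mask"
        )
    return PatchSet(
        name=name or f"{mask.name}_patches",
        indices=tuple(int(i) for i in selected),
        provenance=f"mask={mask.name} labels_space={labels.space_id} threshold={overlap_threshold}",
    )


def union_patchsets(a: PatchSet, b: PatchSet, name: str | None = None) -> PatchSet:
    """Sorted union of two patch sets on the same parcellation."""
    merged = tuple(sorted(set(a.indices) | set(b.indices)))
    prov = "; ".join(p for p in (a.provenance, b.provenance) if p)
    return PatchSet(name=name or f"{a.name}+{b.name}", indices=merged, provenance=prov)


def write_patchset(patch_set: PatchSet, path: str | Path) -> None:
    """Write a patch set as plain text, one 1-based patch label per line."""
    path = Path(path)
    lines = [f"# name: {patch_set.name}"]
    if patch_set.provenance:
        lines.append(f"# provenance: {patch_set.provenance}")
    lines += [str(i + 1) for i in patch_set.indices]
    path.write_text("\n".join(lines) + "\n")


def load_patchset(path: str | Path, name: str | None = None) -> PatchSet:
    """Read a plain-text patch set (1-based labels, ``#`` comment lines)."""
    path = Path(path)
    indices: list[int] = []
    set_name = name or path.stem
    provenance_lines: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comment = line.lstrip("#").strip()
            if comment.startswith("name:") and name is None:
                set_name = comment.removeprefix("name:").strip()
            elif comment.startswith("provenance:"):
                provenance_lines.append(comment.removeprefix("provenance:").strip())
            continue
        indices.append(int(line) - 1)
    return PatchSet(
        name=set_name,
        indices=tuple(sorted(set(indices))),
        provenance="; ".join(provenance_lines),
    )
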